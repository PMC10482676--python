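"""Event detection on depolarization-positive optical voltage traces.

The detection chain per sweep is: remove the narrow reversed-polarity
blue-light artifacts locked to the stimulation pulses, estimate the
sub-threshold envelope (o-Sub, a moving average with spike frames masked),
detect o-APs as matched-filtered threshold crossings of the residual,
measure stimulus-locked PSPs of either polarity per pulse, and find burst
periods as depolarized o-Sub stretches validated by their firing rate.

Thresholds are expressed in multiples of the noise SD, estimated as
1.4826 x MAD of the residual on the pre-stimulus baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .synthgen import StimProtocol, ap_kernel

MAD_TO_SD = 1.4826


# ---------------------------------------------------------------------------
# Event containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class APEvent:
    frame: int
    amplitude: float
    half_width_ms: float


@dataclass(frozen=True)
class PSPEvent:
    pulse_index: int
    polarity: str           # 'E' or 'I'
    amplitude: float        # magnitude, > 0
    latency_ms: float


@dataclass(frozen=True)
class Burst:
    start: int              # frame, inclusive
    end: int                # frame, exclusive
    n_aps: int
    rate_hz: float


@dataclass
class EventSet:
    """All events detected on one sweep."""

    aps: list[APEvent] = field(default_factory=list)
    psps: list[PSPEvent] = field(default_factory=list)
    bursts: list[Burst] = field(default_factory=list)

    @property
    def ap_frames(self) -> np.ndarray:
        return np.asarray([a.frame for a in self.aps], int)

    def to_dict(self) -> dict:
        return {
            "aps": [[a.frame, a.amplitude, a.half_width_ms] for a in self.aps],
            "psps": [[p.pulse_index, p.polarity, p.amplitude, p.latency_ms]
                     for p in self.psps],
            "bursts": [[b.start, b.end, b.n_aps, b.rate_hz]
                       for b in self.bursts],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy one-event-per-row table across the three event classes."""
        rows = []
        for a in self.aps:
            rows.append({"kind": "ap", "frame": a.frame,
                         "amplitude": a.amplitude,
                         "half_width_ms": a.half_width_ms})
        for p in self.psps:
            rows.append({"kind": "psp", "pulse_index": p.pulse_index,
                         "polarity": p.polarity, "amplitude": p.amplitude,
                         "latency_ms": p.latency_ms})
        for b in self.bursts:
            rows.append({"kind": "burst", "start": b.start, "end": b.end,
                         "n_aps": b.n_aps, "rate_hz": b.rate_hz})
        return pd.DataFrame(rows)


@dataclass
class OSub:
    """Sub-threshold envelope of a trace (spike-masked moving average)."""

    values: np.ndarray
    window_frames: int


# ---------------------------------------------------------------------------
# Noise estimation
# ---------------------------------------------------------------------------

def _noise_level_sd(residual: np.ndarray,
                    baseline: slice | None = None) -> tuple[float, float]:
    """Baseline level and noise SD of a residual trace, robustly.

    The level is the median of the pre-stimulus baseline when given
    (otherwise of the whole residual).  The SD is the scaled median
    (MAD x 1.4826) of the negative deviations below the level across the
    whole residual: depolarizing events only push the residual up, so the
    negative side stays noise-dominated even under dense spike trains.
    """
    residual = np.asarray(residual, float)
    level = float(np.median(residual[baseline] if baseline is not None
                            else residual))
    dev = residual[residual <= level] - level
    if dev.size == 0:
        return level, 0.0
    return level, MAD_TO_SD * float(np.median(np.abs(dev)))


def estimate_noise_sd(residual: np.ndarray,
                      baseline: slice | None = None) -> float:
    """Robust noise SD of a residual trace (see :func:`_noise_level_sd`)."""
    return _noise_level_sd(residual, baseline)[1]


# ---------------------------------------------------------------------------
# Artifact removal
# ---------------------------------------------------------------------------

def remove_stim_artifacts(trace: np.ndarray, protocol: StimProtocol,
                          max_width_frames: int = 2, k: float = 3.0,
                          noise_sd: float | None = None) -> np.ndarray:
    """Remove narrow reversed-polarity stimulation artifacts.

    Only samples inside the short window at each pulse onset that dip below
    the local baseline by more than ``k`` noise SDs, in runs of at most
    ``max_width_frames`` frames, are replaced by linear interpolation.
    Everything else — including wide negative deflections such as IPSPs and
    negative transients away from the pulses — is untouched, so the
    operation is idempotent and a no-op on artifact-free traces.
    """
    trace = np.asarray(trace, float)
    out = trace.copy()
    n = len(trace)
    if noise_sd is None:
        b = min(protocol.baseline_frames, n)
        seg = trace[:b] if b >= 10 else trace
        seg = seg - ndimage.median_filter(seg, size=11, mode="nearest")
        noise_sd = MAD_TO_SD * float(np.median(np.abs(seg - np.median(seg))))
    win = max_width_frames
    for onset in protocol.pulse_onsets:
        onset = int(onset)
        lo, hi = onset, min(onset + win, n)
        if lo >= n:
            continue
        before = trace[max(0, lo - 6):lo]
        if before.size == 0:
            continue
        base = np.median(before)        # pre-pulse level, PSP-rise free
        # absolute floor so exact-zero noise does not flag flat samples
        local = trace[max(0, lo - 15):min(n, hi + 15)]
        thr = max(k * noise_sd, 0.05 * np.ptp(local))
        bad = np.flatnonzero(out[lo:hi] < base - thr) + lo
        if bad.size == 0 or bad.size > max_width_frames:
            continue
        left = max(0, bad.min() - 1)
        right = min(n - 1, bad.max() + 1)
        keep = [i for i in range(left, right + 1) if i not in set(bad)]
        if not keep:
            continue
        out[bad] = np.interp(bad, keep, out[keep])
    return out


# ---------------------------------------------------------------------------
# o-AP detection
# ---------------------------------------------------------------------------

def _matched_filter(residual: np.ndarray,
                    template: np.ndarray | None = None) -> np.ndarray:
    """Cross-correlate with a peak-aligned, unit-norm o-AP template."""
    if template is None:
        template = ap_kernel(3)
    tpl = np.asarray(template, float)
    tpl = tpl / np.linalg.norm(tpl)
    off = int(np.argmax(tpl))
    return np.correlate(residual, tpl, mode="full")[off:off + len(residual)]


def detect_aps(trace: np.ndarray, osub: OSub | np.ndarray,
               k_mad: float = 3.5, frame_rate_hz: float = 600.0,
               template: np.ndarray | None = None,
               min_separation: int = 2,
               noise_sd: float | None = None,
               baseline: slice | None = None,
               max_half_width_ms: float = 6.0,
               level: float | None = None) -> list[APEvent]:
    """Detect o-APs as matched-filtered peaks of the spike residual.

    The residual (trace minus o-Sub) is cross-correlated with a normalized
    o-AP template (default: the 3-frame biexponential waveform); local
    maxima of the filtered residual exceeding ``k_mad`` noise SDs above the
    residual's baseline level, at least ``min_separation`` frames apart,
    are events.  Amplitudes are measured on the raw residual relative to
    o-Sub; half-widths at half amplitude with linear sub-frame
    interpolation.  Peaks wider than ``max_half_width_ms`` are
    sub-threshold fluctuations, not o-APs (which span 3-4 frames at
    600 Hz), and are rejected.

    The o-Sub envelope must not contain the spikes it is meant to exclude:
    use :func:`percentile_envelope` for a spike-robust first pass, then
    re-detect against the spike-masked :func:`compute_osub` (this is what
    :func:`detect_events` does).
    """
    trace = np.asarray(trace, float)
    if np.isnan(trace).all():
        raise ValueError("trace is all-NaN")
    sub = osub.values if isinstance(osub, OSub) else np.asarray(osub, float)
    residual = trace - sub
    filt = _matched_filter(residual, template)

    if level is None or noise_sd is None:
        est_level, est_sd = _noise_level_sd(filt, baseline)
        if level is None:
            level = est_level
        if noise_sd is None:
            noise_sd = est_sd
    if noise_sd > 0:
        height = level + k_mad * noise_sd
    else:
        # degenerate noise-free input: ignore sub-scale ripple
        top = filt.max() - level
        if top <= 0:
            return []
        height = level + 0.25 * top
    peaks, _ = signal.find_peaks(filt, height=height, distance=min_separation)

    events: list[APEvent] = []
    n = len(residual)
    for p in peaks:
        # refine to the raw-residual maximum within one frame
        lo, hi = max(0, p - 1), min(n, p + 2)
        f = lo + int(np.argmax(residual[lo:hi]))
        amp = float(residual[f])
        if amp <= 0:
            continue
        half = amp / 2.0
        wide_frames = max_half_width_ms * frame_rate_hz / 1000.0
        left = float(f) - wide_frames
        for i in range(f, max(-1, f - 10), -1):
            if residual[i] < half:
                left = i + (half - residual[i]) / (residual[i + 1] - residual[i])
                break
        right = float(f)
        found_right = False
        for i in range(f, min(n, f + 10)):
            if residual[i] < half:
                prev = residual[i - 1]
                right = i - 1 + (prev - half) / (prev - residual[i])
                found_right = True
                break
        if not found_right:
            right = float(f) + wide_frames
        hw_ms = max(right - left, 0.0) / frame_rate_hz * 1000.0
        if hw_ms > max_half_width_ms:
            continue
        events.append(APEvent(frame=int(f), amplitude=amp, half_width_ms=hw_ms))
    # deduplicate refined frames
    seen, out = set(), []
    for ev in events:
        if ev.frame not in seen:
            seen.add(ev.frame)
            out.append(ev)
    return out


# ---------------------------------------------------------------------------
# o-Sub
# ---------------------------------------------------------------------------

def percentile_envelope(trace: np.ndarray, window_frames: int = 51,
                        percentile: float = 10.0) -> OSub:
    """Spike-robust rolling low-percentile envelope of a trace.

    Positive-going spikes barely move a low percentile, so this envelope
    does not inflate under dense trains the way a moving average does (even
    at 150 Hz firing, 3-frame spikes leave a quarter of a 51-frame window
    at the noise floor).  It serves as the reference of the candidate o-AP
    pass, before any spike frames are known and can be masked.
    """
    trace = np.asarray(trace, float)
    size = min(max(window_frames, 3), len(trace))
    env = ndimage.percentile_filter(trace, percentile, size=size,
                                    mode="nearest")
    return OSub(env, window_frames)


def detect_aps_iterative(trace: np.ndarray, k_mad: float = 3.5,
                         osub_window: int = 25,
                         frame_rate_hz: float = 600.0,
                         template: np.ndarray | None = None,
                         baseline: slice | None = None,
                         n_iter: int = 2) -> tuple[list[APEvent], OSub]:
    """Candidate-then-refine o-AP detection with a converging spike mask.

    A candidate pass against the percentile envelope (threshold relaxed by
    one noise SD, used only for masking) seeds the spike mask; the
    moving-average o-Sub is then recomputed with the mask and detection
    repeated at the full threshold, ``n_iter`` times, so spikes missed by
    the candidate pass stop inflating the envelope.  Returns the final
    events and o-Sub.
    """
    trace = np.asarray(trace, float)
    env0 = percentile_envelope(trace, 2 * osub_window + 1)
    aps = detect_aps(trace, env0, k_mad=max(k_mad - 1.0, 2.0),
                     frame_rate_hz=frame_rate_hz, template=template,
                     baseline=baseline)
    # mask the union of all passes: a spike missed by one pass must not
    # inflate the envelope under itself on the next
    mask_frames: set[int] = {a.frame for a in aps}
    osub = compute_osub(trace, sorted(mask_frames), osub_window)
    for _ in range(n_iter):
        aps = detect_aps(trace, osub, k_mad=k_mad,
                         frame_rate_hz=frame_rate_hz, template=template,
                         baseline=baseline)
        mask_frames |= {a.frame for a in aps}
        osub = compute_osub(trace, sorted(mask_frames), osub_window)
    return aps, osub


def compute_osub(trace: np.ndarray, ap_frames: np.ndarray | list | None = None,
                 window_frames: int = 25) -> OSub:
    """Sub-threshold envelope: centered moving average after AP masking.

    AP frames +/- 1 frame are masked and linearly interpolated before
    smoothing so the envelope is insensitive to spike removal.  A window
    spanning the whole trace returns the global mean everywhere.
    """
    if window_frames < 3:
        raise ValueError("osub window must be >= 3 frames")
    trace = np.asarray(trace, float)
    n = len(trace)
    x = trace.copy()
    frames = np.asarray(ap_frames if ap_frames is not None else [], int)
    if frames.size:
        mask = np.zeros(n, bool)
        for f in frames:
            mask[max(0, f - 1):f + 2] = True
        good = np.flatnonzero(~mask)
        if good.size:
            x = np.interp(np.arange(n), good, x[good])
    if window_frames >= n:
        return OSub(np.full(n, x.mean()), window_frames)
    sm = ndimage.uniform_filter1d(x, size=window_frames, mode="nearest")
    return OSub(sm, window_frames)


# ---------------------------------------------------------------------------
# PSP detection
# ---------------------------------------------------------------------------

def detect_psps(trace: np.ndarray, osub: OSub | np.ndarray,
                protocol: StimProtocol,
                ap_frames: np.ndarray | list | None = None,
                min_amp: float | None = None,
                noise_sd: float | None = None,
                smooth_frames: int = 3) -> list[PSPEvent]:
    """Detect the stimulus-locked o-PSP (either polarity) at every pulse.

    For each pulse, the AP-masked, lightly smoothed trace is referenced to
    its value just before the pulse; the extremum of the deflection within
    the inter-pulse window is the PSP.  Polarity follows the sign of the
    deflection; events smaller than ``min_amp`` (default 2 noise SDs, the
    ~2-3 mV optical floor) are discarded.
    """
    trace = np.asarray(trace, float)
    n = len(trace)
    x = trace.copy()
    frames = np.asarray(ap_frames if ap_frames is not None else [], int)
    if frames.size:
        mask = np.zeros(n, bool)
        for f in frames:
            mask[max(0, f - 1):f + 2] = True
        good = np.flatnonzero(~mask)
        if good.size:
            x = np.interp(np.arange(n), good, x[good])
    if smooth_frames > 1:
        x = ndimage.uniform_filter1d(x, size=smooth_frames, mode="nearest")
    if min_amp is None:
        if noise_sd is None:
            sub = osub.values if isinstance(osub, OSub) else np.asarray(osub)
            noise_sd = estimate_noise_sd(
                trace - sub, slice(0, protocol.baseline_frames))
        min_amp = 2.0 * noise_sd
    ipi = protocol.inter_pulse_frames
    events: list[PSPEvent] = []
    for p, onset in enumerate(protocol.pulse_onsets):
        onset = int(onset)
        w0 = min(onset + 1, n)
        w1 = min(onset + ipi, n)
        if w1 <= w0:
            continue
        base = x[max(0, onset - 2):onset + 1].mean()
        window = x[w0:w1] - base
        i = int(np.argmax(np.abs(window)))
        amp = float(window[i])
        if abs(amp) <= min_amp:      # inclusive: zero deflection never counts
            continue
        latency = (w0 + i - onset) / protocol.frame_rate_hz * 1000.0
        events.append(PSPEvent(pulse_index=p,
                               polarity="E" if amp > 0 else "I",
                               amplitude=abs(amp), latency_ms=latency))
    return events


# ---------------------------------------------------------------------------
# Burst detection
# ---------------------------------------------------------------------------

def detect_bursts(trace: np.ndarray, osub: OSub,
                  ap_frames: np.ndarray | list,
                  frame_rate_hz: float = 600.0,
                  baseline: slice | None = None,
                  depol_k: float = 2.0, min_aps: int = 2,
                  rate_mult: float = 2.0,
                  noise_sd: float | None = None) -> list[Burst]:
    """Detect burst periods from o-Sub kinetics, validated by firing rate.

    Candidate intervals are stretches where o-Sub exceeds its local slow
    level by ``depol_k`` noise SDs (gaps shorter than two smoothing windows
    merged); an interval is a burst iff it contains at least ``min_aps``
    o-APs and its intra-burst rate is at least ``rate_mult`` times the
    whole-sweep rate.  The local level is a slow rolling median of o-Sub,
    so a sustained PSP-train elevation does not chain separate burst
    envelopes into one candidate.
    """
    sub = osub.values
    n = len(sub)
    frames = np.sort(np.asarray(ap_frames, int))
    if baseline is None:
        baseline = slice(0, max(10, n // 5))
    slow = ndimage.median_filter(sub, size=min(8 * osub.window_frames + 1, n),
                                 mode="nearest")
    detr = sub - slow
    base = float(np.median(detr[baseline]))
    if noise_sd is None:
        # noise scale of the thresholded quantity: the smoothed envelope
        # fluctuates far less than the raw residual
        noise_sd = estimate_noise_sd(detr, baseline)
    thr = depol_k * noise_sd
    if thr == 0:
        # degenerate noise-free input: only pronounced depolarizations
        # (top three quarters of the envelope excursion) are candidates
        thr = 0.25 * (detr.max() - base)
    if thr <= 0:
        return []
    above = detr > base + thr
    lab, nlab = ndimage.label(above)
    intervals = [(int(sl[0].start), int(sl[0].stop))
                 for sl in ndimage.find_objects(lab)]
    # merge intervals separated by short gaps
    merged: list[list[int]] = []
    gap = 2 * osub.window_frames
    for a, b in intervals:
        if merged and a - merged[-1][1] < gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    total_rate = len(frames) / (n / frame_rate_hz)
    bursts: list[Burst] = []
    for a, b in merged:
        inside = frames[(frames >= a) & (frames < b)]
        dur = (b - a) / frame_rate_hz
        if len(inside) < min_aps or dur <= 0:
            continue
        rate = len(inside) / dur
        if rate < rate_mult * max(total_rate, 1e-9):
            continue
        bursts.append(Burst(start=a, end=b, n_aps=len(inside), rate_hz=rate))
    return bursts


# ---------------------------------------------------------------------------
# Compound decomposition
# ---------------------------------------------------------------------------

def decompose_compound(trace_a: np.ndarray, trace_b: np.ndarray,
                       window_frames: int = 25) -> np.ndarray:
    """Difference of moving averages of two conditions (A - B).

    Used to isolate a compound-response component, e.g. the disynaptic
    inhibitory part of a mixed PSP by subtracting the pharmacologically
    isolated monosynaptic excitation.  ``window_frames=1`` returns the raw
    difference.
    """
    a = np.asarray(trace_a, float)
    b = np.asarray(trace_b, float)
    if a.shape != b.shape:
        raise ValueError("condition traces must have equal length")
    if window_frames <= 1:
        return a - b
    sa = ndimage.uniform_filter1d(a, size=window_frames, mode="nearest")
    sb = ndimage.uniform_filter1d(b, size=window_frames, mode="nearest")
    return sa - sb


# ---------------------------------------------------------------------------
# Per-sweep orchestration
# ---------------------------------------------------------------------------

def detect_events(trace: np.ndarray, protocol: StimProtocol,
                  k_mad: float = 3.5, osub_window: int = 25,
                  min_psp_amp: float | None = None,
                  depol_k: float = 2.0, min_aps: int = 2,
                  rate_mult: float = 2.0,
                  ap_template: np.ndarray | None = None,
                  ) -> tuple[EventSet, OSub, np.ndarray]:
    """Full detection chain on one sweep.

    Artifact removal, then two-pass o-Sub/AP estimation: a candidate pass
    against the spike-robust percentile envelope (threshold relaxed by one
    noise SD, used only to mask spike frames), the final pass against the
    spike-masked moving-average o-Sub.  PSP and burst detection follow.
    Returns ``(events, osub, cleaned trace)``.
    """
    fr = protocol.frame_rate_hz
    bl = slice(0, protocol.baseline_frames)
    clean = remove_stim_artifacts(trace, protocol)
    aps, osub1 = detect_aps_iterative(clean, k_mad=k_mad,
                                      osub_window=osub_window,
                                      frame_rate_hz=fr,
                                      template=ap_template, baseline=bl)
    frames = [a.frame for a in aps]
    sigma = estimate_noise_sd(clean - osub1.values, bl)
    psps = detect_psps(clean, osub1, protocol, frames,
                       min_amp=min_psp_amp, noise_sd=sigma)
    bursts = detect_bursts(clean, osub1, frames, frame_rate_hz=fr,
                           baseline=bl, depol_k=depol_k, min_aps=min_aps,
                           rate_mult=rate_mult)
    return EventSet(aps=aps, psps=psps, bursts=bursts), osub1, clean
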