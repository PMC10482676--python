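"""Synthetic Voltron-like recordings with known ground truth.

Emulates soma-targeted GEVI (Voltron-ST) sweeps recorded at ~600 Hz under a
20 Hz blue-light optogenetic pulse train ("Op"): optical action potentials
spanning 3-4 frames, sub-threshold postsynaptic potentials of either
polarity, bursts riding on depolarized envelopes, narrow reversed-polarity
stimulation artifacts, monoexponential photobleaching and Gaussian shot
noise.  Every simulated object carries a ground-truth twin so each
downstream analysis stage can be scored exactly.

Sign convention: emitted traces are depolarization-positive, i.e. already
"reversed" relative to raw Voltron fluorescence (which dims on
depolarization).  Movie rendering undoes the reversal so that trace
extraction can be tested end to end.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class ProtocolError(ValueError):
    """Raised for physically inconsistent stimulation protocols."""


# ---------------------------------------------------------------------------
# Stimulation protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimProtocol:
    """Timing of one all-optical sweep: baseline, pulse train, post period.

    All durations are seconds, the pulse width is milliseconds.  Frame
    indices are derived, rounding to the nearest frame.
    """

    frame_rate_hz: float = 600.0
    baseline_s: float = 0.5
    op_freq_hz: float = 20.0
    op_duration_s: float = 1.0
    pulse_width_ms: float = 2.0
    post_s: float = 1.0
    n_sweeps: int = 7

    def __post_init__(self) -> None:
        for name in ("frame_rate_hz", "baseline_s", "op_freq_hz",
                     "op_duration_s", "pulse_width_ms", "post_s"):
            if getattr(self, name) <= 0:
                raise ProtocolError(f"{name} must be > 0")
        if self.frame_rate_hz <= 2 * self.op_freq_hz:
            raise ProtocolError(
                "frame_rate_hz must exceed twice the stimulation frequency "
                f"({self.frame_rate_hz} Hz vs {self.op_freq_hz} Hz pulses)")

    # -- derived frame bookkeeping ------------------------------------
    @property
    def baseline_frames(self) -> int:
        return int(round(self.baseline_s * self.frame_rate_hz))

    @property
    def op_frames(self) -> int:
        return int(round(self.op_duration_s * self.frame_rate_hz))

    @property
    def post_frames(self) -> int:
        return int(round(self.post_s * self.frame_rate_hz))

    @property
    def n_frames(self) -> int:
        return self.baseline_frames + self.op_frames + self.post_frames

    @property
    def n_pulses(self) -> int:
        return int(round(self.op_freq_hz * self.op_duration_s))

    @property
    def pulse_onsets(self) -> np.ndarray:
        """Frame index of each blue pulse, evenly spaced through the Op."""
        spacing = self.frame_rate_hz / self.op_freq_hz
        onsets = self.baseline_frames + np.round(
            np.arange(self.n_pulses) * spacing).astype(int)
        return onsets

    @property
    def inter_pulse_frames(self) -> int:
        return int(round(self.frame_rate_hz / self.op_freq_hz))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimProtocol":
        return cls(**{k: v for k, v in d.items()
                      if k in {f.name for f in dataclasses.fields(cls)}})


def make_protocol(frame_rate_hz: float = 600.0,
                  op_freq_hz: float = 20.0,
                  op_duration_s: float = 1.0,
                  baseline_s: float = 0.5,
                  post_s: float = 1.0,
                  pulse_width_ms: float = 2.0,
                  n_sweeps: int = 7) -> StimProtocol:
    """Build a validated stimulation protocol (see :class:`StimProtocol`)."""
    return StimProtocol(frame_rate_hz=frame_rate_hz, baseline_s=baseline_s,
                        op_freq_hz=op_freq_hz, op_duration_s=op_duration_s,
                        pulse_width_ms=pulse_width_ms, post_s=post_s,
                        n_sweeps=n_sweeps)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Exact bookkeeping of everything injected into a synthetic sweep."""

    archetype: str
    seed: int
    ap_frames: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    # (pulse index, polarity 'E'/'I', amplitude)
    psps: list = field(default_factory=list)
    # (start frame, end frame) inclusive/exclusive
    burst_intervals: list = field(default_factory=list)
    artifact_frames: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def to_dict(self) -> dict:
        return {
            "archetype": self.archetype,
            "seed": self.seed,
            "ap_frames": np.asarray(self.ap_frames).tolist(),
            "psps": [[int(p), str(pol), float(a)] for p, pol, a in self.psps],
            "burst_intervals": [[int(a), int(b)] for a, b in self.burst_intervals],
            "artifact_frames": np.asarray(self.artifact_frames).tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# Archetypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Archetype:
    """Parameters of a stereotyped postsynaptic response type (PRT).

    Amplitudes are in arbitrary dF units; with the default ``noise_sd=1``
    of :func:`simulate_trace` an amplitude of 5 corresponds to SNR 5, and
    the conventional ~2-3 mV optical detection floor maps onto ~2x the
    noise SD.
    """

    name: str
    ap_amplitude: float = 5.0
    ap_width_frames: int = 3          # o-APs span 3-4 frames at 600 Hz
    epsp_amplitude: float = 2.5
    ipsp_amplitude: float = 0.0       # magnitude; injected negative-going
    psp_tau_ms: float = 8.0
    pp_ratio: float = 1.0             # per-pulse multiplicative PSP scaling
    ap_latency_frames: int = 2        # synaptic + spike delay after a pulse
    ap_prob: float = 0.0              # P(spike) per pulse (locked firing)
    baseline_rate_hz: float = 0.0     # spontaneous Poisson firing
    burst_rate_hz: float = 0.0        # burst occurrence rate during/after Op
    burst_n_aps: int = 5
    burst_intra_hz: float = 80.0
    burst_envelope: float = 3.0
    burst_post: bool = False          # bursts in the post period (rebound)
    switch: bool = False              # alternate E / I dominated sweeps

    def __post_init__(self):
        if not 3 <= self.ap_width_frames <= 4:
            raise ValueError("o-AP width must be 3-4 frames at 600 Hz")
        if self.epsp_amplitude < 0 or self.ipsp_amplitude < 0:
            raise ValueError("PSP amplitudes are magnitudes, >= 0")


ARCHETYPES: dict[str, Archetype] = {
    "locked_single_ap": Archetype("locked_single_ap", ap_prob=1.0,
                                  epsp_amplitude=2.5),
    "rhythmic_burst": Archetype("rhythmic_burst", epsp_amplitude=2.0,
                                burst_rate_hz=3.5, burst_post=True),
    "onset_burst": Archetype("onset_burst", epsp_amplitude=2.0,
                             burst_rate_hz=-1.0),  # sentinel: single onset burst
    "facilitating_pp": Archetype("facilitating_pp", epsp_amplitude=2.0,
                                 pp_ratio=1.15),
    "depressing_pp": Archetype("depressing_pp", epsp_amplitude=3.5,
                               pp_ratio=0.8),
    "inhibitory": Archetype("inhibitory", epsp_amplitude=0.0,
                            ipsp_amplitude=2.5),
    "inhibitory_rebound_burst": Archetype("inhibitory_rebound_burst",
                                          epsp_amplitude=0.0,
                                          ipsp_amplitude=2.5,
                                          burst_rate_hz=-2.0,  # rebound burst
                                          burst_post=True),
    "subthreshold_only": Archetype("subthreshold_only", epsp_amplitude=2.5),
    "spontaneous_firing": Archetype("spontaneous_firing",
                                    epsp_amplitude=2.0,
                                    baseline_rate_hz=5.0),
    "nonconnected": Archetype("nonconnected", epsp_amplitude=0.0),
    "switch": Archetype("switch", epsp_amplitude=2.5, ipsp_amplitude=2.5,
                        switch=True),
}


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def ap_kernel(width_frames: int = 3) -> np.ndarray:
    """Biexponential o-AP waveform resampled to span ``width_frames`` frames.

    The peak sits at index ``argmax``; amplitude is normalized to 1.
    """
    if width_frames == 3:
        k = np.array([0.45, 1.0, 0.35])
    elif width_frames == 4:
        k = np.array([0.30, 1.0, 0.50, 0.15])
    else:
        raise ValueError("o-AP width must be 3 or 4 frames")
    return k


def psp_kernel(tau_ms: float, frame_rate_hz: float,
               length_frames: int | None = None) -> np.ndarray:
    """Alpha-function PSP waveform, peak normalized to 1."""
    if length_frames is None:
        length_frames = int(round(6 * tau_ms / 1000.0 * frame_rate_hz)) + 1
    t = np.arange(length_frames) / frame_rate_hz * 1000.0  # ms
    k = (t / tau_ms) * np.exp(1.0 - t / tau_ms)
    return k


def _add_kernel(trace: np.ndarray, frame: int, kernel: np.ndarray,
                amplitude: float, align_peak: bool = True) -> None:
    """Add ``amplitude * kernel`` in place with the kernel peak at ``frame``."""
    off = int(np.argmax(kernel)) if align_peak else 0
    start = frame - off
    for i, v in enumerate(kernel):
        j = start + i
        if 0 <= j < len(trace):
            trace[j] += amplitude * v


# ---------------------------------------------------------------------------
# Trace simulation
# ---------------------------------------------------------------------------

def simulate_trace(archetype: str | Archetype,
                   protocol: StimProtocol,
                   noise_sd: float = 1.0,
                   bleach_tau_s: float | None = None,
                   seed: int = 0,
                   sweep_index: int = 0,
                   baseline_f: float = 100.0,
                   artifacts: bool = True,
                   artifact_amplitude: float = 5.0,
                   artifact_width_frames: int = 1,
                   ) -> tuple[np.ndarray, GroundTruth]:
    """Simulate one depolarization-positive sweep plus its ground truth.

    Parameters
    ----------
    archetype
        Name from :data:`ARCHETYPES` or an :class:`Archetype` instance.
    noise_sd
        SD of additive Gaussian noise (shot-noise surrogate).
    bleach_tau_s
        Time constant of multiplicative monoexponential photobleaching;
        ``None`` disables bleaching.
    sweep_index
        Used by the "switch" archetype to alternate E- and I-dominated
        sweeps.
    baseline_f
        DC fluorescence level, so bleaching acts multiplicatively on a
        positive signal.
    artifacts
        Inject narrow reversed-polarity (negative-going) blue-light
        artifacts at every pulse onset.
    """
    if isinstance(archetype, str):
        try:
            arch = ARCHETYPES[archetype]
        except KeyError:
            raise ValueError(f"unknown archetype {archetype!r}") from None
    else:
        arch = archetype
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    n = protocol.n_frames
    fr = protocol.frame_rate_hz
    trace = np.zeros(n)
    gt = GroundTruth(archetype=arch.name, seed=seed)

    onsets = protocol.pulse_onsets
    delay = 3  # synaptic delay in frames before a PSP rises
    kpsp = psp_kernel(arch.psp_tau_ms, fr)
    kap = ap_kernel(arch.ap_width_frames)

    # --- stimulus-locked PSPs ---------------------------------------
    e_amp = arch.epsp_amplitude
    i_amp = arch.ipsp_amplitude
    if arch.switch:
        if sweep_index % 2 == 0:
            i_amp = 0.0
        else:
            e_amp = 0.0
    ap_frames: list[int] = []
    for p, onset in enumerate(onsets):
        scale = arch.pp_ratio ** p
        if e_amp > 0:
            a = e_amp * scale
            _add_kernel(trace, onset + delay, kpsp, a, align_peak=False)
            gt.psps.append((p, "E", a))
        if i_amp > 0:
            a = i_amp * scale
            _add_kernel(trace, onset + delay, kpsp, -a, align_peak=False)
            gt.psps.append((p, "I", a))
        if arch.ap_prob > 0 and (arch.ap_prob >= 1.0
                                 or rng.random() < arch.ap_prob):
            ap_frames.append(int(onset) + arch.ap_latency_frames)

    # --- spontaneous firing -----------------------------------------
    if arch.baseline_rate_hz > 0:
        expected = arch.baseline_rate_hz * n / fr
        n_spont = rng.poisson(expected)
        frames = np.sort(rng.choice(n, size=min(n_spont, n), replace=False))
        # enforce a refractory spacing of 4 frames
        kept: list[int] = []
        for f in frames:
            if not kept or f - kept[-1] >= 4:
                kept.append(int(f))
        ap_frames.extend(kept)

    # --- bursts ------------------------------------------------------
    burst_starts: list[int] = []
    op0, op1 = protocol.baseline_frames, protocol.baseline_frames + protocol.op_frames
    if arch.burst_rate_hz > 0:
        period = int(round(fr / arch.burst_rate_hz))
        stop = n if arch.burst_post else op1
        burst_starts = list(range(op0 + 10, stop - 60, period))
    elif arch.burst_rate_hz == -1.0:        # single onset burst
        burst_starts = [op0 + 5]
    elif arch.burst_rate_hz == -2.0:        # single rebound burst after Op
        burst_starts = [op1 + 20]
    intra_gap = max(4, int(round(fr / arch.burst_intra_hz)))
    for start in burst_starts:
        frames = [start + 3 + i * intra_gap for i in range(arch.burst_n_aps)]
        frames = [f for f in frames if f < n - 2]
        if len(frames) < 2:
            continue
        end = frames[-1] + 5
        # smooth depolarized envelope under the burst
        env_len = end - start + 6
        env = np.hanning(env_len) * arch.burst_envelope
        for i, v in enumerate(env):
            j = start - 3 + i
            if 0 <= j < n:
                trace[j] += v
        ap_frames.extend(frames)
        gt.burst_intervals.append((start, end))

    # --- o-APs --------------------------------------------------------
    ap_frames = sorted(set(f for f in ap_frames if 0 <= f < n))
    for f in ap_frames:
        _add_kernel(trace, f, kap, arch.ap_amplitude)
    gt.ap_frames = np.asarray(ap_frames, int)

    # --- stimulation artifacts (reversed polarity, 1-2 frames) -------
    if artifacts:
        art = []
        for onset in onsets:
            for w in range(artifact_width_frames):
                f = int(onset) + w
                if f < n:
                    trace[f] -= artifact_amplitude
                    art.append(f)
        gt.artifact_frames = np.asarray(art, int)

    # --- DC level, bleaching, noise ----------------------------------
    trace += baseline_f
    if bleach_tau_s is not None:
        t = np.arange(n) / fr
        trace *= np.exp(-t / bleach_tau_s)
    if noise_sd > 0:
        trace += rng.normal(0.0, noise_sd, size=n)
    return trace, gt


def simulate_sweeps(archetype: str | Archetype, protocol: StimProtocol,
                    noise_sd: float = 1.0, bleach_tau_s: float | None = None,
                    seed: int = 0, **kwargs
                    ) -> tuple[np.ndarray, list[GroundTruth]]:
    """Simulate ``protocol.n_sweeps`` sweeps; returns (sweeps x frames, truths)."""
    traces, truths = [], []
    for s in range(protocol.n_sweeps):
        tr, gt = simulate_trace(archetype, protocol, noise_sd=noise_sd,
                                bleach_tau_s=bleach_tau_s,
                                seed=seed + 1000 * s, sweep_index=s, **kwargs)
        traces.append(tr)
        truths.append(gt)
    return np.asarray(traces), truths


def regular_train(rate_hz: float, duration_s: float = 10.0,
                  frame_rate_hz: float = 600.0, baseline_s: float = 0.5,
                  snr: float = 5.0, ap_width_frames: int = 3,
                  noise_sd: float = 1.0, seed: int = 0,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Regular o-AP train for rate-resolution benchmarks.

    Spikes are injected at the frame nearest each regular spike time (event
    timing is quantized to the frame clock, as in frame-limited recordings)
    with peak amplitude ``snr * noise_sd``.  A silent ``baseline_s`` stretch
    precedes the train so detectors can estimate the noise floor.

    Returns (trace, true peak frames).
    """
    rng = np.random.default_rng(seed)
    b = int(round(baseline_s * frame_rate_hz))
    n = b + int(round(duration_s * frame_rate_hz))
    n_spikes = int(np.floor(duration_s * rate_hz))
    frames = b + np.round(np.arange(n_spikes) * frame_rate_hz / rate_hz).astype(int)
    frames = np.unique(frames[frames < n - 2])
    trace = np.zeros(n)
    k = ap_kernel(ap_width_frames)
    amp = snr * (noise_sd if noise_sd > 0 else 1.0)
    for f in frames:
        _add_kernel(trace, int(f), k, amp)
    if noise_sd > 0:
        trace += rng.normal(0.0, noise_sd, size=n)
    return trace, frames


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------

def circular_roi_layout(n_rois: int, shape: tuple[int, int] = (96, 96),
                        radius_px: int = 6, margin_px: int = 6
                        ) -> list[tuple[int, int, int]]:
    """Grid of non-overlapping circular ROI footprints (cy, cx, r)."""
    h, w = shape
    step = 2 * radius_px + 2 * margin_px
    layout = []
    cy, cx = radius_px + margin_px, radius_px + margin_px
    for _ in range(n_rois):
        if cx + radius_px >= w:
            cx = radius_px + margin_px
            cy += step
        if cy + radius_px >= h:
            raise ValueError("frame too small for the requested ROI count")
        layout.append((cy, cx, radius_px))
        cx += step
    return layout


def render_movie(traces: np.ndarray,
                 roi_layout: list[tuple[int, int, int]],
                 shape: tuple[int, int] = (96, 96),
                 psf_sigma_px: float = 0.0,
                 photon_noise: bool = False,
                 background: float = 500.0,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Render traces into a raw-polarity movie stack plus a label mask.

    Each ROI is a uniform disk whose fluorescence is ``background - trace``
    (raw Voltron polarity: depolarization dims the pixel).  An optional
    Gaussian PSF blurs the footprints; optional Poisson noise emulates
    photon counting.  Footprints must not overlap.
    """
    traces = np.atleast_2d(np.asarray(traces, float))
    if len(roi_layout) != traces.shape[0]:
        raise ValueError("one layout entry per trace required")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, np.uint16)
    footprints = []
    for lab, (cy, cx, r) in enumerate(roi_layout, start=1):
        fp = ((yy - cy) ** 2 + (xx - cx) ** 2) <= r ** 2
        if (mask[fp] != 0).any():
            raise ValueError("overlapping ROI footprints in layout")
        mask[fp] = lab
        footprints.append(fp.astype(float))
    weights = []
    for fp in footprints:
        if psf_sigma_px > 0:
            fp = ndimage.gaussian_filter(fp, psf_sigma_px)
        weights.append(fp)
    weights = np.asarray(weights)                    # rois x h x w
    # movie[t] = background - sum_i w_i * trace_i[t]
    movie = background - np.einsum("it,iyx->tyx", traces, weights)
    if photon_noise:
        rng = np.random.default_rng(seed)
        movie = rng.poisson(np.clip(movie, 0, None)).astype(float)
    return movie, mask
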