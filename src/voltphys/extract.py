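"""Per-ROI trace extraction, bleach correction, and somatic validation.

Traces are the per-frame pixel mean over each labeled ROI, multiplied by -1
so depolarization is positive (Voltron fluorescence dims on depolarization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize


def extract_traces(movie: np.ndarray, label_mask: np.ndarray,
                   reverse: bool = True, min_pixels: int = 1) -> pd.DataFrame:
    """Extract one trace per ROI label (frames x ROIs DataFrame).

    The ROI statistic is the pixel mean; with ``reverse`` the series is
    negated so that depolarization points up.  Labels smaller than
    ``min_pixels`` are skipped with a warning.
    """
    movie = np.asarray(movie, float)
    label_mask = np.asarray(label_mask)
    if movie.ndim != 3:
        raise ValueError(f"movie must be frames x H x W, got {movie.shape}")
    if movie.shape[1:] != label_mask.shape:
        raise ValueError(
            f"mask shape {label_mask.shape} != frame shape {movie.shape[1:]}")
    labels = np.unique(label_mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("label mask contains no ROIs")
    out = {}
    for lab in labels:
        sel = label_mask == lab
        if sel.sum() < min_pixels:
            warnings.warn(f"ROI {lab} has fewer than {min_pixels} pixels; skipped")
            continue
        tr = movie[:, sel].mean(axis=1)
        out[int(lab)] = -tr if reverse else tr
    if not out:
        raise ValueError("no ROI met the minimum pixel count")
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Bleach correction
# ---------------------------------------------------------------------------

def _rolling_percentile(x: np.ndarray, percentile: float, window: int) -> np.ndarray:
    window = min(window, len(x))
    if window % 2 == 0:
        window += 1
    return ndimage.percentile_filter(x, percentile, size=window, mode="nearest")


def correct_bleach(trace: np.ndarray, frame_rate_hz: float = 600.0,
                   method: str = "monoexp", percentile: float = 20.0,
                   window: int = 101, event_frames: np.ndarray | None = None,
                   ) -> tuple[np.ndarray, dict]:
    """Remove multiplicative photobleaching from a trace.

    A monoexponential ``a * exp(-t/tau) + c`` is fitted to the rolling
    low-percentile envelope (robust to event transients; detected event
    frames can additionally be masked) and the trace is divided by the
    trend normalized to its initial value.

    Returns ``(detrended trace, fit info)`` with ``fit['tau_s']`` the
    recovered bleaching time constant (``inf`` when no decay is detected).
    """
    trace = np.asarray(trace, float)
    if not np.isfinite(trace).all():
        raise ValueError("trace contains non-finite values")
    if method != "monoexp":
        raise ValueError(f"unknown bleach-correction method {method!r}")
    x = trace.copy()
    if event_frames is not None and len(event_frames):
        mask = np.zeros(len(x), bool)
        for f in np.asarray(event_frames, int):
            mask[max(0, f - 1):f + 2] = True
        good = ~mask
        x = np.interp(np.arange(len(x)), np.flatnonzero(good), x[good])
    env = _rolling_percentile(x, percentile, window)
    t = np.arange(len(x)) / frame_rate_hz
    scale = np.ptp(env)
    level = max(abs(env).max(), 1.0)
    if scale < 1e-9 * level:
        return trace.copy(), {"tau_s": np.inf, "fitted": False}

    def model(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    try:
        p0 = (env[0] - env[-1], t[-1] / 2, env[-1])
        popt, _ = optimize.curve_fit(
            model, t, env, p0=p0,
            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000)
    except RuntimeError:
        return trace.copy(), {"tau_s": np.inf, "fitted": False}
    a, tau, c = popt
    trend = model(t, *popt)
    if trend[0] <= 0 or abs(a) < 1e-6 * level:
        return trace.copy(), {"tau_s": np.inf, "fitted": False}
    detrended = trace / (trend / trend[0])
    return detrended, {"tau_s": float(tau), "a": float(a), "c": float(c),
                       "fitted": True}


# ---------------------------------------------------------------------------
# Concentric somatic validation
# ---------------------------------------------------------------------------

@dataclass
class ConcentricProfile:
    """Ring-wise o-AP amplitude profile around an ROI center.

    A somatic signal decays with distance from the soma: the verdict is
    ``True`` when the innermost ring amplitude exceeds the outermost by the
    configured ratio and ring means are non-increasing within one noise SD.
    ``partial`` flags rings truncated by the frame border; ``somatic`` is
    ``None`` when no APs were available.
    """

    radii_px: np.ndarray
    ap_amplitude: np.ndarray
    burst_length: np.ndarray | None
    somatic: bool | None
    partial: bool


def concentric_validate(movie: np.ndarray, center: tuple[float, float],
                        ap_frames: np.ndarray,
                        ring_width_px: int = 2, n_rings: int = 4,
                        amp_ratio: float = 1.2,
                        burst_intervals: list | None = None,
                        ) -> ConcentricProfile:
    """Validate the somatic origin of a trace via concentric ring analysis.

    ``center`` is (row, col) of the ROI centroid.  Ring traces are reversed
    pixel means over annuli of width ``ring_width_px``; the per-ring o-AP
    amplitude is the mean peak height above the ring median at the supplied
    AP frames.
    """
    movie = np.asarray(movie, float)
    n, h, w = movie.shape
    cy, cx = center
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(yy - cy, xx - cx)
    radii, amps, blens = [], [], []
    partial = False
    ap_frames = np.asarray(ap_frames, int)
    for i in range(n_rings):
        r0, r1 = i * ring_width_px, (i + 1) * ring_width_px
        sel = (dist >= r0) & (dist < r1)
        expected_area = np.pi * (r1 ** 2 - r0 ** 2)
        if sel.sum() < 0.8 * expected_area:
            partial = True
        if not sel.any():
            radii.append(r1)
            amps.append(np.nan)
            blens.append(np.nan)
            continue
        ring = -movie[:, sel].mean(axis=1)
        base = np.median(ring)
        if len(ap_frames):
            peaks = [ring[max(0, f - 1):f + 2].max() - base
                     for f in ap_frames if f < n]
            amps.append(float(np.mean(peaks)))
        else:
            amps.append(np.nan)
        if burst_intervals:
            blens.append(float(np.mean([(b - a) for a, b in burst_intervals])))
        else:
            blens.append(np.nan)
        radii.append(r1)
    radii = np.asarray(radii, float)
    amps = np.clip(np.asarray(amps, float), 0, None)
    if not len(ap_frames) or np.isnan(amps).all():
        return ConcentricProfile(radii, amps, None, None, partial)
    # noise scale: median ring-trace SD after median removal
    sigmas = []
    for i in range(n_rings):
        r0, r1 = i * ring_width_px, (i + 1) * ring_width_px
        sel = (dist >= r0) & (dist < r1)
        if sel.any():
            ring = -movie[:, sel].mean(axis=1)
            sigmas.append(1.4826 * np.median(np.abs(ring - np.median(ring))))
    tol = float(np.median(sigmas)) if sigmas else 0.0
    ok_ratio = amps[0] >= amp_ratio * amps[-1]
    ok_mono = all(amps[i + 1] <= amps[i] + tol for i in range(len(amps) - 1))
    burst = np.asarray(blens, float) if burst_intervals else None
    return ConcentricProfile(radii, amps, burst, bool(ok_ratio and ok_mono),
                             partial)
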