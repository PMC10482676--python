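"""The canonical o-phys parameter set over the sweep's temporal segments.

A sweep is divided into Baseline, the 20 Hz stimulation train ("Op") and
the after-period ("Post"); Op and Post are halved (Op-1/Op-2,
Post-1/Post-2) and Op is additionally quartered (q1-q4, 250 ms each for a
1 s train).  Thirty named parameters are computed per sweep and averaged
across a ROI's sweeps; the 29-parameter clustering set excludes the binary
bimodality flag, which is a thresholded copy of Sarle's coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventSet, OSub
from .io import CLUSTER_FEATURES, FEATURE_NAMES, ConnectomeTable
from .synthgen import StimProtocol

#: Sarle's bimodality coefficient of the uniform distribution.
BIMODALITY_UNIFORM = 5.0 / 9.0


# ---------------------------------------------------------------------------
# Temporal segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentBounds:
    """Frame ranges (start, stop) of the sweep's analysis segments."""

    baseline: tuple[int, int]
    op: tuple[int, int]
    op1: tuple[int, int]
    op2: tuple[int, int]
    post1: tuple[int, int]
    post2: tuple[int, int]
    quarters: tuple[tuple[int, int], ...]   # q1..q4 tiling Op
    uneven: bool = False                    # Op not divisible into 4 quarters

    def duration_s(self, seg: tuple[int, int], frame_rate_hz: float) -> float:
        return (seg[1] - seg[0]) / frame_rate_hz


def segment_bounds(protocol: StimProtocol) -> SegmentBounds:
    """Split a sweep into Baseline / Op halves+quarters / Post halves."""
    b = protocol.baseline_frames
    op0, op1_ = b, b + protocol.op_frames
    post0, post1_ = op1_, op1_ + protocol.post_frames
    op_mid = op0 + (op1_ - op0) // 2
    post_mid = post0 + (post1_ - post0) // 2
    nq = op1_ - op0
    quarter_s = nq / 4 / protocol.frame_rate_hz
    uneven = nq % 4 != 0 or abs(quarter_s - 0.25) > 1e-9
    edges = [op0 + int(round(i * nq / 4)) for i in range(5)]
    quarters = tuple((edges[i], edges[i + 1]) for i in range(4))
    if uneven:
        warnings.warn(
            f"Op quarters are {quarter_s * 1000:.1f} ms (nearest-frame "
            "splits), not the canonical 250 ms")
    return SegmentBounds(
        baseline=(0, b), op=(op0, op1_),
        op1=(op0, op_mid), op2=(op_mid, op1_),
        post1=(post0, post_mid), post2=(post_mid, post1_),
        quarters=quarters, uneven=uneven)


# ---------------------------------------------------------------------------
# Bimodality
# ---------------------------------------------------------------------------

def bimodality_coefficient(values, prose_variant: bool = False) -> float:
    """Sarle's bimodality coefficient, (skewness^2 + 1) / kurtosis.

    Population moments and non-excess kurtosis are used so the uniform
    distribution calibrates to 5/9; values above 5/9 indicate a bimodal (or
    multimodal) distribution.  ``prose_variant`` computes skewness^2 /
    kurtosis instead (which is 0 for any symmetric distribution and does
    not reproduce the uniform calibration).  Returns NaN for fewer than 4
    values or zero variance.
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        return float("nan")
    m = x.mean()
    d = x - m
    m2 = np.mean(d ** 2)
    if m2 <= 0:
        return float("nan")
    skew = np.mean(d ** 3) / m2 ** 1.5
    kurt = np.mean(d ** 4) / m2 ** 2
    if kurt == 0:
        return float("nan")
    if prose_variant:
        return float(skew ** 2 / kurt)
    return float((skew ** 2 + 1.0) / kurt)


# ---------------------------------------------------------------------------
# Per-sweep parameter extraction
# ---------------------------------------------------------------------------

def _seg_rate(frames: np.ndarray, seg: tuple[int, int], fr: float) -> float:
    dur = (seg[1] - seg[0]) / fr
    if dur <= 0:
        return float("nan")
    return ((frames >= seg[0]) & (frames < seg[1])).sum() / dur


def _overlap(burst, seg) -> float:
    return max(0, min(burst.end, seg[1]) - max(burst.start, seg[0]))


def _burst_stats(bursts, seg, fr):
    """(count, mean overlap length in s) of bursts overlapping a segment."""
    lens = [_overlap(b, seg) / fr for b in bursts if _overlap(b, seg) > 0]
    n = len(lens)
    return n, (float(np.mean(lens)) if lens else float("nan"))


def _ratio(num: float, den: float) -> float:
    if not np.isfinite(num) or not np.isfinite(den) or den == 0:
        return float("nan")
    return num / den


def _sweep_features(events: EventSet, osub: OSub, bounds: SegmentBounds,
                    protocol: StimProtocol) -> dict[str, float]:
    fr = protocol.frame_rate_hz
    frames = events.ap_frames
    sub = osub.values
    f: dict[str, float] = {}

    psp_e = [p for p in events.psps if p.polarity == "E"]
    psp_i = [p for p in events.psps if p.polarity == "I"]
    f["o-EPSP"] = float(len(psp_e))
    f["o-IPSP"] = float(len(psp_i))

    by_pulse = {p.pulse_index: p.amplitude for p in events.psps}
    f["Paired Pulse 2-1"] = _ratio(by_pulse.get(1, np.nan),
                                   by_pulse.get(0, np.nan))
    f["Paired Pulse 3-2"] = _ratio(by_pulse.get(2, np.nan),
                                   by_pulse.get(1, np.nan))

    q = bounds.quarters
    qm = [sub[a:b].mean() if b > a else np.nan for a, b in q]
    f["Subthr Slope q2-q1"] = qm[1] - qm[0]
    f["Subthr Slope q4-q1"] = qm[3] - qm[0]

    op = bounds.op
    in_op = frames[(frames >= op[0]) & (frames < op[1])]
    f["AP onset"] = ((in_op[0] - op[0]) / fr * 1000.0 if in_op.size
                     else float("nan"))

    n_aps = len(frames)
    if n_aps:
        in_burst = sum(
            ((frames >= b.start) & (frames < b.end)).sum()
            for b in events.bursts)
        f["AP % in burst"] = 100.0 * in_burst / n_aps
    else:
        f["AP % in burst"] = float("nan")

    def burst_ap_freq(seg):
        tot_dur, tot_aps = 0.0, 0
        for b in events.bursts:
            ov = _overlap(b, seg)
            if ov > 0:
                tot_dur += ov / fr
                tot_aps += ((frames >= max(b.start, seg[0]))
                            & (frames < min(b.end, seg[1]))).sum()
        return tot_aps / tot_dur if tot_dur > 0 else float("nan")

    post = (bounds.post1[0], bounds.post2[1])
    f["Burst AP freq (Op)"] = burst_ap_freq(op)
    f["Burst AP freq (Post)"] = burst_ap_freq(post)

    r_op1 = _seg_rate(frames, bounds.op1, fr)
    r_op2 = _seg_rate(frames, bounds.op2, fr)
    r_post1 = _seg_rate(frames, bounds.post1, fr)
    r_post2 = _seg_rate(frames, bounds.post2, fr)
    f["AP freq 2nd/1st (Op)"] = _ratio(r_op2, r_op1)
    f["AP freq 2nd/1st (Post)"] = _ratio(r_post2, r_post1)
    f["AP freq (Baseline)"] = _seg_rate(frames, bounds.baseline, fr)
    f["AP freq (Op-1)"] = r_op1
    f["AP freq (Op-2)"] = r_op2
    f["AP freq (Post-1)"] = r_post1
    f["AP freq (Post-2)"] = r_post2

    for name, seg in (("Op-1", bounds.op1), ("Op-2", bounds.op2),
                      ("Post-1", bounds.post1), ("Post-2", bounds.post2)):
        n, mean_len = _burst_stats(events.bursts, seg, fr)
        f[f"Burst num ({name})"] = float(n)
        f[f"Burst length ({name})"] = mean_len
    f["Burst length (Op-2/Op-1)"] = _ratio(f["Burst length (Op-2)"],
                                           f["Burst length (Op-1)"])
    f["Burst length (Post-2/Post-1)"] = _ratio(f["Burst length (Post-2)"],
                                               f["Burst length (Post-1)"])

    # per-sweep baseline AP count; summed (not averaged) across sweeps
    f["AP num"] = float(((frames >= bounds.baseline[0])
                         & (frames < bounds.baseline[1])).sum())
    return f


def extract_features(sweeps: list[tuple[EventSet, OSub]],
                     bounds: SegmentBounds,
                     protocol: StimProtocol) -> pd.Series:
    """Average per-sweep parameters into one ROI feature vector.

    Ratios undefined on a sweep (zero denominator) are NaN there and
    excluded from the cross-sweep mean; "AP num" is the total baseline
    spike count over all sweeps; the bimodality pair is computed on o-AP
    peak times pooled across sweeps.
    """
    if not sweeps:
        raise ValueError("at least one sweep required")
    per_sweep = [_sweep_features(ev, os_, bounds, protocol)
                 for ev, os_ in sweeps]
    out: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN means
        for name in FEATURE_NAMES:
            if name in ("AP bimodality coeff", "AP bimodality binary"):
                continue
            vals = np.asarray([s[name] for s in per_sweep], float)
            if name == "AP num":
                out[name] = float(np.nansum(vals))
            else:
                out[name] = float(np.nanmean(vals))
    pooled_times = np.concatenate([
        ev.ap_frames / protocol.frame_rate_hz for ev, _ in sweeps])
    coeff = bimodality_coefficient(pooled_times)
    out["AP bimodality coeff"] = coeff
    out["AP bimodality binary"] = float(
        np.isfinite(coeff) and coeff > BIMODALITY_UNIFORM)
    return pd.Series({n: out[n] for n in FEATURE_NAMES})


# ---------------------------------------------------------------------------
# Connectome summaries
# ---------------------------------------------------------------------------

def connectome_summary(table: ConnectomeTable) -> dict[str, float]:
    """Population-level connectivity fractions from a feature table.

    Percentages of neurons with more than three o-PSPs (the connectivity
    criterion), with any o-IPSP, and with evoked firing during the Op;
    plus, when cluster labels are present, the spontaneous-firing fraction
    per cluster (baseline firing rate > 0).
    """
    df = table.df
    n = len(df)
    psps = df["o-EPSP"].fillna(0) + df["o-IPSP"].fillna(0)
    evoked = (df["AP freq (Op-1)"].fillna(0) > 0) | \
             (df["AP freq (Op-2)"].fillna(0) > 0)
    out = {
        "n_neurons": float(n),
        "pct_connected": 100.0 * float((psps > 3).mean()),
        "pct_ipsp": 100.0 * float((df["o-IPSP"].fillna(0) > 0).mean()),
        "pct_evoked_firing": 100.0 * float(evoked.mean()),
    }
    if "cluster" in df.columns:
        spont = df["AP freq (Baseline)"].fillna(0) > 0
        for cl, grp in df.groupby("cluster"):
            out[f"pct_spontaneous_cluster_{int(cl)}"] = \
                100.0 * float(spont[grp.index].mean())
    return out
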