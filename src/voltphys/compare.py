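"""Multi-recording comparison and end-to-end pipeline orchestration.

Repeated recordings of the same field of view are aligned by mutual
nearest-centroid ROI matching; per-parameter changes between recordings
are flagged against a relative-change cutoff (default 25%): increased
above +cutoff, decreased below -cutoff, otherwise unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import classify as vclassify
from . import events as vevents
from . import features as vfeatures
from . import synthgen
from .io import FEATURE_NAMES, write_feature_table, ConnectomeTable


class ConfigError(ValueError):
    """Pipeline configuration is missing or names an invalid field."""


# ---------------------------------------------------------------------------
# ROI matching
# ---------------------------------------------------------------------------

def _centroids(mask: np.ndarray) -> dict[int, tuple[float, float]]:
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("empty label mask")
    cents = ndimage.center_of_mass(np.ones_like(mask), mask, labels)
    return {int(lab): (float(cy), float(cx))
            for lab, (cy, cx) in zip(labels, cents)}


def match_rois(mask_a: np.ndarray, mask_b: np.ndarray,
               max_shift_px: float = 5.0
               ) -> tuple[dict[int, int], list[int], list[int]]:
    """Pair ROIs across two recordings of the same field of view.

    Pairs are mutual nearest centroids within ``max_shift_px``.  Returns
    ``(pairs a->b, unmatched in a, unmatched in b)``.
    """
    mask_a = np.asarray(mask_a)
    mask_b = np.asarray(mask_b)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share frame geometry")
    ca = _centroids(mask_a)
    cb = _centroids(mask_b)
    la, lb = list(ca), list(cb)
    A = np.array([ca[k] for k in la])
    B = np.array([cb[k] for k in lb])
    D = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
    pairs: dict[int, int] = {}
    for i, lab_a in enumerate(la):
        j = int(np.argmin(D[i]))
        if D[i, j] <= max_shift_px and int(np.argmin(D[:, j])) == i:
            pairs[lab_a] = lb[j]
    matched_b = set(pairs.values())
    unmatched_a = [k for k in la if k not in pairs]
    unmatched_b = [k for k in lb if k not in matched_b]
    return pairs, unmatched_a, unmatched_b


# ---------------------------------------------------------------------------
# Change report
# ---------------------------------------------------------------------------

@dataclass
class ChangeReport:
    """Per-ROI before/after comparison of one o-phys parameter."""

    parameter: str
    cutoff: float
    table: pd.DataFrame     # roi_a, roi_b, before, after, rel_change, status

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "parameter": self.parameter, "cutoff": self.cutoff,
            "rows": self.table.to_dict(orient="records")}, indent=1))


def _status(before: float, after: float, cutoff: float) -> tuple[float, str]:
    if before == 0:
        if after == 0:
            return 0.0, "unchanged"
        return float("inf"), "increased" if after > 0 else "decreased"
    change = (after - before) / before
    if change > cutoff:
        return change, "increased"
    if change < -cutoff:
        return change, "decreased"
    return change, "unchanged"


def compare_recordings(features_a: pd.DataFrame, features_b: pd.DataFrame,
                       parameter: str,
                       pairing: dict[int, int] | None = None,
                       cutoff: float = 0.25) -> ChangeReport:
    """Flag per-ROI parameter changes between two recordings.

    ``features_a``/``features_b`` are ROI-indexed feature tables (rows per
    ROI, canonical parameter columns).  Without an explicit ``pairing``,
    identically indexed rows are compared.  The relative change is
    referenced to the "before" value.
    """
    for df in (features_a, features_b):
        if parameter not in df.columns:
            raise KeyError(f"parameter {parameter!r} not in feature table")
    if pairing is None:
        common = [i for i in features_a.index if i in features_b.index]
        pairing = {i: i for i in common}
    rows = []
    for a, b in pairing.items():
        before = float(features_a.loc[a, parameter])
        after = float(features_b.loc[b, parameter])
        if np.isnan(before) or np.isnan(after):
            change, status = float("nan"), "unchanged"
        else:
            change, status = _status(before, after, cutoff)
        rows.append({"roi_a": a, "roi_b": b, "before": before,
                     "after": after, "rel_change": change, "status": status})
    return ChangeReport(parameter=parameter, cutoff=cutoff,
                        table=pd.DataFrame(rows))


def total_burst_length(events_per_sweep, frame_rate_hz: float = 600.0
                       ) -> tuple[float, list[float]]:
    """Total burst duration per sweep (s) and its cross-sweep mean."""
    per_sweep = [sum((b.end - b.start) / frame_rate_hz for b in ev.bursts)
                 for ev in events_per_sweep]
    return float(np.mean(per_sweep)), per_sweep


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _require(config: dict, key: str):
    if key not in config:
        raise ConfigError(f"missing configuration field: {key!r}")
    return config[key]


def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Run traces -> events -> features (-> classification -> suggestions).

    ``config`` fields:

    - ``protocol``: dict of :class:`~voltphys.synthgen.StimProtocol` fields
    - ``input``: either ``{"synthetic": {"archetypes": [...], "noise_sd":
      ..., "seed": ...}}`` or ``{"traces": {roi: sweeps x frames array}}``
    - ``model`` (optional): path to a saved :class:`ClusterModel`
    - ``target_clusters`` (optional): cluster ids whose members should be
      suggested for follow-up

    Returns a report dict with per-ROI features, assignments and suggested
    ROIs; artifacts are written to ``outdir`` when given.
    """
    proto = synthgen.StimProtocol.from_dict(_require(config, "protocol"))
    inp = _require(config, "input")
    bounds = vfeatures.segment_bounds(proto)

    roi_sweeps: dict[object, np.ndarray] = {}
    truth: dict[object, str] = {}
    if "synthetic" in inp:
        spec = inp["synthetic"]
        seed = int(spec.get("seed", 0))
        noise = float(spec.get("noise_sd", 1.0))
        for r, arche in enumerate(_require(spec, "archetypes"), start=1):
            sweeps, _ = synthgen.simulate_sweeps(
                arche, proto, noise_sd=noise, seed=seed + 10_000 * r)
            roi_sweeps[r] = sweeps
            truth[r] = arche
    elif "traces" in inp:
        for r, arr in inp["traces"].items():
            roi_sweeps[r] = np.atleast_2d(np.asarray(arr, float))
    else:
        raise ConfigError("input must contain 'synthetic' or 'traces'")

    feats = {}
    events_by_roi = {}
    for r, sweeps in roi_sweeps.items():
        per_sweep = []
        evs = []
        for tr in sweeps:
            ev, osub, _ = vevents.detect_events(tr, proto)
            per_sweep.append((ev, osub))
            evs.append(ev)
        feats[r] = vfeatures.extract_features(per_sweep, bounds, proto)
        events_by_roi[r] = evs
    fdf = pd.DataFrame(feats).T
    fdf.index.name = "neuron_id"

    report: dict = {
        "n_rois": len(fdf),
        "features": fdf,
        "archetypes": truth or None,
    }
    model_path = config.get("model")
    if model_path is None:
        report["warning"] = "no classifier model given; stopped after features"
        report["assignments"] = None
        report["suggested"] = None
    else:
        model = vclassify.ClusterModel.from_json(model_path)
        cols = model.params.columns
        assignments = dict(zip(
            fdf.index, vclassify.classify_table(fdf[cols], model)))
        report["assignments"] = assignments
        targets = set(config.get("target_clusters", []))
        report["suggested"] = sorted(
            r for r, c in assignments.items() if c in targets)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tdf = fdf.reset_index()
        write_feature_table(ConnectomeTable(tdf), outdir / "features.csv")
        ev_json = {str(r): [e.to_dict() for e in evs]
                   for r, evs in events_by_roi.items()}
        (outdir / "events.json").write_text(json.dumps(ev_json))
        summary = {k: v for k, v in report.items() if k != "features"}
        summary["assignments"] = (
            {str(k): v for k, v in report["assignments"].items()}
            if report["assignments"] else None)
        (outdir / "report.json").write_text(json.dumps(summary, default=str))
    return report
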