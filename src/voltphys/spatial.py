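"""Spatial connectome statistics in a tiled-FOV micrometre frame.

ROIs are mapped from pixel coordinates in tiled fields of view to XYZ in
µm; on those coordinates the module computes voxelized criterion maps,
per-cluster density cores, the average-minimal-distance (AMD) label-shuffle
test, and the coherence between feature-space and physical-space cluster
centroid layouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import pearsonr


# ---------------------------------------------------------------------------
# Coordinate frame
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoordinateFrame:
    """FOV tiling specification for pixel -> µm mapping.

    FOVs of ``fov_um`` (width x height, default 200 x 350 µm²) tile each
    coronal section without overlap; X grows medio-laterally with tile
    column, Y dorso-ventrally with tile row, Z is the section's
    anterior-posterior coordinate.
    """

    fov_um: tuple[float, float] = (200.0, 350.0)
    pixel_size_um: float = 1.0
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


def map_fov_coords(tile: tuple[int, int], centroid_px: tuple[float, float],
                   frame: CoordinateFrame, section_ap_um: float
                   ) -> np.ndarray:
    """Map an ROI centroid (col_px, row_px) in a tile to XYZ µm.

    ``tile`` is (column, row) within the tiling; the centroid must lie
    inside the FOV.
    """
    cx, cy = centroid_px
    w, h = frame.fov_um
    x_in = cx * frame.pixel_size_um
    y_in = cy * frame.pixel_size_um
    if not (0 <= x_in <= w and 0 <= y_in <= h):
        raise ValueError(f"centroid {centroid_px} outside the {w}x{h} µm FOV")
    x = frame.origin_um[0] + tile[0] * w + x_in
    y = frame.origin_um[1] + tile[1] * h + y_in
    return np.array([x, y, float(section_ap_um)])


# ---------------------------------------------------------------------------
# Voxel criterion maps
# ---------------------------------------------------------------------------

def voxel_map(coords: np.ndarray, criterion: np.ndarray,
              voxel_um: float = 200.0) -> pd.DataFrame:
    """Per-voxel percentage of neurons fulfilling a boolean criterion.

    Voxels are ``voxel_um`` cubes; empty voxels are undefined and excluded
    (not reported as 0%).  Returns one row per occupied voxel with the
    integer voxel index, its center XYZ, the neuron count and the
    percentage.
    """
    coords = np.asarray(coords, float)
    criterion = np.asarray(criterion, bool)
    if voxel_um <= 0:
        raise ValueError("voxel size must be positive")
    if coords.shape[0] != criterion.shape[0]:
        raise ValueError("criterion vector must align with coordinates")
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    idx = np.floor(coords / voxel_um).astype(int)
    keys, inverse, counts = np.unique(idx, axis=0, return_inverse=True,
                                      return_counts=True)
    hits = np.bincount(inverse, weights=criterion.astype(float),
                       minlength=len(keys))
    centers = (keys + 0.5) * voxel_um
    return pd.DataFrame({
        "ix": keys[:, 0], "iy": keys[:, 1], "iz": keys[:, 2],
        "x_um": centers[:, 0], "y_um": centers[:, 1], "z_um": centers[:, 2],
        "n": counts, "pct": 100.0 * hits / counts,
    })


# ---------------------------------------------------------------------------
# Density cores
# ---------------------------------------------------------------------------

def density_core(coords: np.ndarray, radius_um: float = 300.0
                 ) -> tuple[int, np.ndarray, np.ndarray]:
    """Density core of a cluster: the member with the most neighbors.

    For each neuron the number of other cluster members within
    ``radius_um`` is counted; the core is the neuron with the highest count
    (ties go to the lowest index).  Returns
    ``(core index, distance of each neuron to the core, neighbor counts)``.
    """
    coords = np.atleast_2d(np.asarray(coords, float))
    D = cdist(coords, coords)
    counts = ((D <= radius_um).sum(axis=1) - 1).astype(int)   # exclude self
    core = int(np.argmax(counts))
    return core, D[core], counts


# ---------------------------------------------------------------------------
# AMD shuffle test
# ---------------------------------------------------------------------------

def amd_metric(observed: float, expected_mean: float) -> float:
    """Normalized distance contrast (observed-expected)/(observed+expected).

    Ranges over [-1, 1]: negative means the observed minimal distance is
    smaller than chance (spatial aggregation), positive larger than chance
    (segregation).  NaN when both terms are 0.
    """
    if observed == 0 and expected_mean == 0:
        return float("nan")
    return (observed - expected_mean) / (observed + expected_mean)


@dataclass
class AMDResult:
    """Outcome of the average-minimal-distance label-shuffle test."""

    ref_cluster: int
    target_cluster: int
    observed_amd: float                      # µm
    expected_amd: float                      # mean over shuffles, µm
    expected_sem: float                      # s.e. of the shuffle mean
    metric: float                            # amd_metric(observed, expected)
    per_cell_metric: np.ndarray              # one value per reference cell
    metric_sem: float                        # bootstrap s.e.m. over cells
    shuffle_amds: np.ndarray = field(repr=False, default=None)
    p_value: float = float("nan")            # empirical two-sided shuffle rank
    n_shuffles: int = 1000
    seed: int = 0
    flagged: bool = False                    # singleton same-cluster case


def _min_dists(D: np.ndarray, ref_idx: np.ndarray, tgt_idx: np.ndarray,
               same: bool) -> np.ndarray:
    """Per-reference-cell minimal distance to the target set."""
    sub = D[np.ix_(ref_idx, tgt_idx)]
    if same:
        # exclude self-distances on the diagonal of the same index set
        sub = sub.copy()
        pos = {v: j for j, v in enumerate(tgt_idx)}
        for i, r in enumerate(ref_idx):
            if r in pos:
                sub[i, pos[r]] = np.inf
    return sub.min(axis=1)


def amd_shuffle_test(coords: np.ndarray, labels: np.ndarray,
                     ref_cluster, target_cluster,
                     n_shuffles: int = 1000, seed: int = 0,
                     n_boot: int = 1000) -> AMDResult:
    """AMD of a cluster pair against a cluster-identity shuffle null.

    The observed AMD is the mean over reference-cluster cells of the
    minimal distance to a target-cluster cell (self excluded when the
    clusters coincide).  The null shuffles the full label vector
    ``n_shuffles`` times and recomputes the statistic; the per-cell metric
    contrasts each cell's minimal distance with the null mean, and its
    s.e.m. is bootstrapped over reference cells.
    """
    coords = np.asarray(coords, float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    ref_idx = np.flatnonzero(labels == ref_cluster)
    tgt_idx = np.flatnonzero(labels == target_cluster)
    if ref_idx.size == 0 or tgt_idx.size == 0:
        raise ValueError("both clusters must be non-empty")
    same = ref_cluster == target_cluster
    flagged = same and ref_idx.size < 2
    D = cdist(coords, coords)
    if flagged:
        obs_cells = np.array([np.nan])
        observed = float("nan")
    else:
        obs_cells = _min_dists(D, ref_idx, tgt_idx, same)
        observed = float(obs_cells.mean())
    shuffle_amds = np.full(n_shuffles, np.nan)
    n = len(labels)
    if not flagged:
        for s in range(n_shuffles):
            perm = rng.permutation(n)
            r = perm[ref_idx]
            t = perm[tgt_idx]
            shuffle_amds[s] = _min_dists(D, r, t, same).mean()
    expected = float(shuffle_amds.mean()) if not flagged else float("nan")
    per_cell = np.array([amd_metric(o, expected) for o in obs_cells])
    # bootstrap s.e.m. of the mean per-cell metric
    if np.isfinite(per_cell).any() and per_cell.size > 1:
        boots = rng.choice(per_cell, size=(n_boot, per_cell.size))
        sem = float(np.nanmean(boots, axis=1).std())
    else:
        sem = float("nan")
    if np.isfinite(observed):
        lo = (shuffle_amds <= observed).sum()
        hi = (shuffle_amds >= observed).sum()
        p = 2.0 * (min(lo, hi) + 1) / (n_shuffles + 1)
        p = min(p, 1.0)
    else:
        p = float("nan")
    return AMDResult(
        ref_cluster=ref_cluster, target_cluster=target_cluster,
        observed_amd=observed, expected_amd=expected,
        expected_sem=(float(shuffle_amds.std() / np.sqrt(n_shuffles))
                      if not flagged else float("nan")),
        metric=amd_metric(observed, expected) if np.isfinite(observed)
        else float("nan"),
        per_cell_metric=per_cell, metric_sem=sem,
        shuffle_amds=shuffle_amds, p_value=p,
        n_shuffles=n_shuffles, seed=seed, flagged=flagged)


# ---------------------------------------------------------------------------
# Centroid-distance coherence
# ---------------------------------------------------------------------------

def centroid_distance_coherence(feature_centroids: np.ndarray | pd.DataFrame,
                                coords: np.ndarray, labels: np.ndarray
                                ) -> tuple[np.ndarray, np.ndarray, float]:
    """Correlation of feature-space and physical-space centroid layouts.

    Spatial centroids are per-cluster mean XYZ, ordered like the rows of
    ``feature_centroids``; both k x k pairwise distance matrices are
    returned together with the Pearson correlation of their upper
    triangles.  Requires at least 3 clusters.
    """
    if isinstance(feature_centroids, pd.DataFrame):
        ids = list(feature_centroids.index)
        F = feature_centroids.to_numpy(float)
    else:
        F = np.asarray(feature_centroids, float)
        ids = list(range(1, len(F) + 1))
    k = len(ids)
    if k < 3:
        raise ValueError("need at least 3 clusters for a meaningful correlation")
    coords = np.asarray(coords, float)
    labels = np.asarray(labels)
    S = np.array([coords[labels == cid].mean(axis=0) for cid in ids])
    df = pdist(F)
    ds = pdist(S)
    r = float(pearsonr(df, ds)[0])
    return squareform(df), squareform(ds), r
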