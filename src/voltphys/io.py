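"""Readers and writers for movie stacks, label masks and feature tables.

Movies travel as multi-page TIFF or HDF5 stacks; feature ("connectome")
tables as comma-separated text with one neuron per row.  Because header
dialects of deposited tables vary, column names are matched after folding
case, whitespace and punctuation onto the canonical parameter names.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

log = logging.getLogger("voltphys")


class FormatError(ValueError):
    """Unreadable or structurally invalid input file."""


class SchemaError(ValueError):
    """Table does not satisfy the feature-table schema."""


#: The canonical o-phys parameter names, in order.  The first 29 drive
#: clustering; "AP bimodality binary" is a thresholded copy of the
#: coefficient and is stored but excluded from the clustering set.
FEATURE_NAMES: tuple[str, ...] = (
    "o-EPSP", "o-IPSP",
    "Paired Pulse 2-1", "Paired Pulse 3-2",
    "Subthr Slope q2-q1", "Subthr Slope q4-q1",
    "AP onset", "AP bimodality coeff", "AP bimodality binary",
    "AP % in burst",
    "Burst AP freq (Op)", "AP freq 2nd/1st (Op)",
    "Burst AP freq (Post)", "AP freq 2nd/1st (Post)",
    "AP num",
    "AP freq (Baseline)", "AP freq (Op-1)", "AP freq (Op-2)",
    "AP freq (Post-1)", "AP freq (Post-2)",
    "Burst num (Op-1)", "Burst num (Op-2)",
    "Burst num (Post-1)", "Burst num (Post-2)",
    "Burst length (Op-1)", "Burst length (Op-2)", "Burst length (Op-2/Op-1)",
    "Burst length (Post-1)", "Burst length (Post-2)",
    "Burst length (Post-2/Post-1)",
)

#: Feature subset used for clustering and classification (29 parameters).
CLUSTER_FEATURES: tuple[str, ...] = tuple(
    n for n in FEATURE_NAMES if n != "AP bimodality binary")

_META_ALIASES = {
    "neuron_id": ("neuron id", "neuron", "id", "roi id", "roi", "cell id", "cell"),
    "animal_id": ("animal id", "animal", "mouse id", "mouse"),
    "cluster": ("cluster", "cluster label", "cluster id", "ophys cluster"),
    "x": ("x", "x um", "ml", "m l"),
    "y": ("y", "y um", "dv", "d v"),
    "z": ("z", "z um", "ap", "a p"),
}


def _fold(name: str) -> str:
    """Fold case, whitespace and punctuation for header matching."""
    return re.sub(r"[^a-z0-9]+", " ", str(name).lower()).strip()


_CANON = {_fold(n): n for n in FEATURE_NAMES}
for _alias, _canon in {
    "o epsp": "o-EPSP", "oepsp": "o-EPSP", "o ipsp": "o-IPSP",
    "ap percent in burst": "AP % in burst",
}.items():
    _CANON.setdefault(_alias, _canon)


# ---------------------------------------------------------------------------
# Movies and masks
# ---------------------------------------------------------------------------

def read_movie(path) -> tuple[np.ndarray, float | None]:
    """Read a TIFF or HDF5 movie stack.

    Returns ``(movie, frame_rate_hz)`` where the movie is a
    frames x height x width array and the frame rate is ``None`` unless
    stored in the file (HDF5 attribute ``frame_rate_hz``).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            movie = tifffile.imread(path)
            rate = None
        elif suffix in (".h5", ".hdf5"):
            with h5py.File(path, "r") as fh:
                ds = fh["movie"]
                movie = ds[...]
                rate = ds.attrs.get("frame_rate_hz")
                rate = float(rate) if rate is not None else None
        else:
            raise FormatError(f"unsupported movie format: {path.name}")
    except (OSError, KeyError, ValueError) as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"cannot read movie stack {path}: {exc}") from exc
    movie = np.asarray(movie)
    if movie.ndim == 2:                       # single-frame stack
        movie = movie[None]
    if movie.ndim != 3:
        raise FormatError(f"expected a 2D/3D stack, got shape {movie.shape}")
    return movie, rate


def write_movie(path, movie: np.ndarray, frame_rate_hz: float | None = None,
                dtype=np.uint16) -> None:
    """Write a movie as multi-page TIFF or HDF5 (clipped to the dtype range)."""
    path = Path(path)
    movie = np.asarray(movie)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        info = np.iinfo(dtype)
        data = np.clip(np.round(movie), info.min, info.max).astype(dtype)
        tifffile.imwrite(path, data)
    elif suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("movie", data=movie)
            if frame_rate_hz is not None:
                ds.attrs["frame_rate_hz"] = float(frame_rate_hz)
    else:
        raise FormatError(f"unsupported movie format: {path.name}")


def read_label_mask(path) -> np.ndarray:
    mask = tifffile.imread(Path(path))
    if mask.ndim != 2:
        raise FormatError(f"label mask must be 2D, got shape {mask.shape}")
    return mask.astype(np.int32)


def write_label_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(mask).astype(np.uint16))


# ---------------------------------------------------------------------------
# Feature / connectome tables
# ---------------------------------------------------------------------------

@dataclass
class ConnectomeTable:
    """Validated per-neuron o-phys parameter table.

    ``df`` holds one row per neuron with a unique ``neuron_id`` column, the
    canonical parameter columns (:data:`FEATURE_NAMES`, in order) and any
    of the optional ``animal_id``, ``cluster``, ``x``, ``y``, ``z`` columns.
    """

    df: pd.DataFrame
    feature_names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def __post_init__(self) -> None:
        present = [n for n in self.feature_names if n in self.df.columns]
        missing = [n for n in CLUSTER_FEATURES if n not in self.df.columns]
        if missing:
            raise SchemaError("missing required parameter columns: "
                              + ", ".join(missing))
        self.feature_names = tuple(present)
        if "neuron_id" not in self.df.columns:
            self.df = self.df.copy()
            self.df.insert(0, "neuron_id", np.arange(len(self.df)))
        ids = self.df["neuron_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise SchemaError(f"duplicated neuron id: {dup!r}")
        if "cluster" in self.df.columns:
            cl = pd.to_numeric(self.df["cluster"], errors="coerce")
            if (cl.dropna() <= 0).any() or (cl.dropna() % 1 != 0).any():
                raise SchemaError("cluster labels must be positive integers")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def features(self) -> pd.DataFrame:
        """Parameter columns only, canonical order."""
        return self.df[list(self.feature_names)]

    @property
    def cluster_features(self) -> pd.DataFrame:
        """The 29-parameter clustering feature matrix."""
        cols = [n for n in CLUSTER_FEATURES if n in self.df.columns]
        return self.df[cols]

    @property
    def coords(self) -> np.ndarray | None:
        if all(c in self.df.columns for c in ("x", "y", "z")):
            return self.df[["x", "y", "z"]].to_numpy(float)
        return None


def read_connectome_table(path, dialect: dict | None = None) -> ConnectomeTable:
    """Read a comma-separated per-neuron parameter table.

    ``dialect`` optionally maps raw header names to canonical names (for
    deposited files whose exact headers differ from the folded defaults).
    """
    df = pd.read_csv(path)
    rename: dict[str, str] = {}
    dialect = {_fold(k): v for k, v in (dialect or {}).items()}
    for col in df.columns:
        folded = _fold(col)
        if folded in dialect:
            rename[col] = dialect[folded]
        elif folded in _CANON:
            rename[col] = _CANON[folded]
        else:
            for meta, aliases in _META_ALIASES.items():
                if folded in aliases:
                    rename[col] = meta
                    break
    df = df.rename(columns=rename)
    table = ConnectomeTable(df)
    log.info("read %d neurons from %s", len(table), path)
    return table


def write_feature_table(table: ConnectomeTable | pd.DataFrame, path) -> None:
    """Write a table in the canonical CSV dialect (NaN as empty field)."""
    df = table.df if isinstance(table, ConnectomeTable) else table
    meta = [c for c in ("neuron_id", "animal_id", "cluster", "x", "y", "z")
            if c in df.columns]
    feats = [c for c in FEATURE_NAMES if c in df.columns]
    other = [c for c in df.columns if c not in meta + feats]
    df[meta + feats + other].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Config plumbing
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
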