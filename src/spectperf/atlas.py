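"""Domain types and tabular/volumetric I/O shared by every pipeline stage.

The package works in two coordinate systems:

* **volumes** — 3-D grids (atlas labels, tracer activity, tissue fractions)
  stored as NIfTI-1, axis order (x, y, z), 0-based voxel indexing, with the
  hemisphere of a voxel determined by the sign of its x offset from the grid
  midplane;
* **tables** — tidy TSV frames keyed by atlas region name codes (``STG``,
  ``H``, ``MO`` ...) and, after relabeling, by side *relative to the
  epileptogenic zone* (``i`` ipsilateral, ``c`` contralateral).

Missing cells in perfusion tables are absent rows, never zeros: the clinical
tables list only the structures that pass a subject's threshold, so absence
carries no perfusion information.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "LabelVolume",
    "ActivityVolume",
    "TissueMaps",
    "read_region_table",
    "write_region_table",
    "read_perfusion_table",
    "write_perfusion_table",
    "read_subject_table",
    "relabel_sides",
    "read_label_volume",
    "read_activity_volume",
    "write_volume",
]

HEMISPHERES = ("left", "right", "midline")
GROUPS = (
    "temporal", "frontal", "parietal", "occipital",
    "limbic", "subcortical", "brainstem", "cerebellum",
)
STATES = ("ictal", "interictal")
SIDES = ("i", "c", "midline")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _ascii(s: str) -> str:
    """Normalize accented region codes (e.g. ``Ínsul``) to ASCII keys."""
    return (
        unicodedata.normalize("NFKD", str(s))
        .encode("ascii", "ignore")
        .decode("ascii")
        .strip()
    )


# --------------------------------------------------------------------------
# volumes
# --------------------------------------------------------------------------

@dataclass
class LabelVolume:
    """Integer atlas labels on a 3-D grid; 0 is background."""

    labels: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError("label volume must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("labels must be integers")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def validate_against(self, regions: pd.DataFrame) -> None:
        present = set(np.unique(self.labels)) - {0}
        known = set(regions["region_id"])
        unknown = present - known
        if unknown:
            raise FormatError(f"labels not in region table: {sorted(unknown)}")


@dataclass
class ActivityVolume:
    """Non-negative tracer activity (counts per voxel) on a 3-D grid."""

    activity: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.ndim != 3:
            raise FormatError("activity volume must be 3-D")
        if np.any(self.activity < 0):
            raise FormatError("activity must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.activity.shape


@dataclass
class TissueMaps:
    """Gray-matter / white-matter / CSF probability maps in [0, 1]."""

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    _tol: float = field(default=1e-6, repr=False)

    def __post_init__(self) -> None:
        self.gm, self.wm, self.csf = (
            np.asarray(a, dtype=float) for a in (self.gm, self.wm, self.csf)
        )
        for a in (self.gm, self.wm, self.csf):
            if np.any(a < -self._tol) or np.any(a > 1 + self._tol):
                raise FormatError("tissue fractions must lie in [0, 1]")
        if np.any(self.gm + self.wm + self.csf > 1 + self._tol):
            raise FormatError("tissue fractions must sum to <= 1 per voxel")


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def write_volume(vol, path) -> None:
    """Write a LabelVolume or ActivityVolume as NIfTI-1."""
    if isinstance(vol, LabelVolume):
        data, vs = vol.labels.astype(np.int32), vol.voxel_size_mm
    elif isinstance(vol, ActivityVolume):
        data, vs = vol.activity.astype(np.float64), vol.voxel_size_mm
    else:
        raise TypeError(f"cannot write {type(vol).__name__} as a volume")
    nib.save(nib.Nifti1Image(data, _affine(vs)), str(path))


def _load_nifti(path):
    img = nib.load(str(path))
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), vs


def read_label_volume(path) -> LabelVolume:
    data, vs = _load_nifti(path)
    return LabelVolume(np.rint(data).astype(np.int32), vs)


def read_activity_volume(path) -> ActivityVolume:
    data, vs = _load_nifti(path)
    return ActivityVolume(np.asarray(data, dtype=float), vs)


# --------------------------------------------------------------------------
# region table
# --------------------------------------------------------------------------

def read_region_table(path) -> pd.DataFrame:
    """Read and validate an atlas region lookup table.

    Expects TSV columns ``region_id, name, hemisphere, group, is_gray``.
    Bilateral pairing is enforced: every non-midline name code must appear
    exactly once per hemisphere.
    """
    df = pd.read_csv(path, sep="\t", dtype={"name": str})
    required = {"region_id", "name", "hemisphere", "group", "is_gray"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"region table missing columns: {sorted(missing)}")
    df["name"] = df["name"].map(_ascii)
    df["is_gray"] = df["is_gray"].astype(bool)
    if df["region_id"].duplicated().any():
        dup = df.loc[df["region_id"].duplicated(), "region_id"].tolist()
        raise FormatError(f"duplicate region_id: {dup}")
    if (df["region_id"] <= 0).any():
        raise FormatError("region_id must be positive")
    bad = set(df["hemisphere"]) - set(HEMISPHERES)
    if bad:
        raise FormatError(f"unknown hemisphere token: {sorted(bad)}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise FormatError(f"unknown group token: {sorted(bad)}")
    lateral = df[df["hemisphere"] != "midline"]
    sides = lateral.groupby("name")["hemisphere"].agg(lambda h: tuple(sorted(h)))
    unpaired = sides[sides != ("left", "right")]
    if len(unpaired):
        raise FormatError(
            f"unpaired bilateral structures: {sorted(unpaired.index)}"
        )
    return df.reset_index(drop=True)


def write_region_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# perfusion table
# --------------------------------------------------------------------------

def read_perfusion_table(path) -> pd.DataFrame:
    """Read a per-subject perfusion-index table.

    TSV columns ``subject_id, state, name, side, pi``; one row per
    non-missing value. ``side`` is relative to the epileptogenic zone.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "name": str})
    required = {"subject_id", "state", "name", "side", "pi"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"perfusion table missing columns: {sorted(missing)}")
    df["name"] = df["name"].map(_ascii)
    bad = set(df["state"]) - set(STATES)
    if bad:
        raise FormatError(f"unknown state token: {sorted(bad)}")
    bad = set(df["side"]) - set(SIDES)
    if bad:
        raise FormatError(f"unknown side token: {sorted(bad)}")
    if not len(df):
        return df
    df["pi"] = pd.to_numeric(df["pi"])
    if (df["pi"] <= 0).any():
        raise FormatError("perfusion index must be positive")
    key = ["subject_id", "state", "name", "side"]
    if df.duplicated(key).any():
        raise FormatError("duplicate (subject, state, name, side) rows")
    return df.reset_index(drop=True)


def write_perfusion_table(df: pd.DataFrame, path, decimals: int = 3) -> None:
    out = df.copy()
    out["pi"] = out["pi"].map(lambda v: f"{v:.{decimals}f}")
    out.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# subject roster
# --------------------------------------------------------------------------

def read_subject_table(path) -> pd.DataFrame:
    """Read the subject roster (group, EZ laterality, ictal validity ...)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "epilepsy_group", "ez_laterality", "ictal_valid"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"subject table missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise FormatError("duplicate subject_id")
    bad = set(df["epilepsy_group"]) - {"TLE", "FLE", "PQE"}
    if bad:
        raise FormatError(f"unknown epilepsy group: {sorted(bad)}")
    bad = set(df["ez_laterality"]) - {"left", "right"}
    if bad:
        raise FormatError(f"EZ laterality must be left/right, got {sorted(bad)}")
    df["ictal_valid"] = df["ictal_valid"].astype(bool)
    return df.reset_index(drop=True)


def relabel_sides(hemisphere, ez_laterality: str):
    """Map anatomical hemisphere labels to EZ-relative side labels.

    ``i`` = ipsilateral (same side as the epileptogenic zone), ``c`` =
    contralateral; midline values pass through unchanged. Accepts a scalar or
    a sequence; returns the same shape.
    """
    if ez_laterality not in ("left", "right"):
        raise FormatError(f"ez_laterality must be left/right, got {ez_laterality!r}")

    def one(h: str) -> str:
        if h == "midline":
            return "midline"
        if h not in ("left", "right"):
            raise FormatError(f"unknown hemisphere token: {h!r}")
        return "i" if h == ez_laterality else "c"

    if isinstance(hemisphere, str):
        return one(hemisphere)
    out = [one(h) for h in hemisphere]
    if isinstance(hemisphere, pd.Series):
        return pd.Series(out, index=hemisphere.index, name=hemisphere.name)
    return out
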