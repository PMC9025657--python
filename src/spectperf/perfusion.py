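"""Regional mean activity and the perfusion index.

The perfusion index (PI) of a region is its mean tracer activity (counts per
voxel) divided by the mean activity of the *remaining* gray matter — a
leave-one-out, voxel-weighted reference: PI = 1 means parity with the rest
of the gray matter, below 1 hypoperfusion, above 1 hyperperfusion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import atlas as _atlas

__all__ = [
    "regional_means",
    "perfusion_index",
    "perfusion_indexes",
    "build_perfusion_table",
]


def regional_means(
    activity: _atlas.ActivityVolume,
    labels: _atlas.LabelVolume,
    regions: pd.DataFrame,
) -> pd.DataFrame:
    """Arithmetic mean activity and voxel count per atlas region.

    Returns a frame with columns ``region_id, name, hemisphere, is_gray,
    n_voxels, mean``; raises if any region of the table has no voxels.
    """
    if activity.shape != labels.shape:
        raise ValueError(
            f"shape mismatch: activity {activity.shape} vs labels {labels.shape}"
        )
    labels.validate_against(regions)
    lab = labels.labels.ravel()
    act = activity.activity.ravel()
    nmax = int(max(lab.max(), regions["region_id"].max())) + 1
    counts = np.bincount(lab, minlength=nmax)
    sums = np.bincount(lab, weights=act, minlength=nmax)

    out = regions[["region_id", "name", "hemisphere", "is_gray"]].copy()
    out["n_voxels"] = counts[out["region_id"]]
    empty = out.loc[out["n_voxels"] == 0]
    if len(empty):
        missing = [f"{n}/{h}" for n, h in zip(empty["name"], empty["hemisphere"])]
        raise ValueError(f"regions with zero voxels: {missing}")
    out["mean"] = sums[out["region_id"]] / out["n_voxels"]
    return out.reset_index(drop=True)


def _gm_totals(means: pd.DataFrame) -> tuple[np.ndarray, float, float]:
    gm = means["is_gray"].to_numpy(dtype=bool)
    n = means["n_voxels"].to_numpy(dtype=float)
    m = means["mean"].to_numpy(dtype=float)
    total_vox = float(n[gm].sum())
    total_act = float((n[gm] * m[gm]).sum())
    return gm, total_vox, total_act


def perfusion_indexes(means: pd.DataFrame, regions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Perfusion index for every gray-matter region in a means frame.

    The denominator for region r is the voxel-weighted mean over all
    gray-matter voxels excluding r's own voxels. Non-gray rows get NaN.
    """
    means = means.copy()
    if "n_voxels" not in means:
        means["n_voxels"] = 1  # equal weights when counts are not carried
    gm, total_vox, total_act = _gm_totals(means)
    n = means["n_voxels"].to_numpy(dtype=float)
    m = means["mean"].to_numpy(dtype=float)

    pi = np.full(len(means), np.nan)
    for idx in np.flatnonzero(gm):
        rest_vox = total_vox - n[idx]
        rest_act = total_act - n[idx] * m[idx]
        if rest_vox <= 0:
            raise ValueError("remaining gray matter is empty")
        denom = rest_act / rest_vox
        if denom == 0:
            raise ZeroDivisionError("remaining gray matter has zero activity")
        pi[idx] = m[idx] / denom
    out = means.copy()
    out["pi"] = pi
    return out


def perfusion_index(means: pd.DataFrame, name: str, hemisphere: str) -> float:
    """Perfusion index of one region identified by (name, hemisphere)."""
    table = perfusion_indexes(means)
    row = table[(table["name"] == name) & (table["hemisphere"] == hemisphere)]
    if not len(row):
        raise KeyError(f"region ({name}, {hemisphere}) not in means table")
    if not row["is_gray"].iloc[0]:
        raise ValueError(f"region ({name}, {hemisphere}) is not gray matter")
    return float(row["pi"].iloc[0])


def build_perfusion_table(
    subject: pd.Series | dict,
    interictal_means: pd.DataFrame,
    ictal_means: pd.DataFrame | None = None,
    decimals: int | None = None,
) -> pd.DataFrame:
    """Assemble one subject's perfusion-index rows in EZ-relative coordinates.

    ``subject`` needs ``subject_id``, ``ez_laterality`` and ``ictal_valid``.
    Ictal rows are emitted only when the ictal tracer uptake was truly ictal
    (``ictal_valid``); subjects with post-ictal uptake contribute interictal
    rows only.
    """
    subject = dict(subject)
    ez = subject.get("ez_laterality")
    if ez not in ("left", "right"):
        raise _atlas.FormatError(
            f"subject {subject.get('subject_id')!r} missing EZ laterality"
        )
    frames = []
    states = [("interictal", interictal_means)]
    if bool(subject.get("ictal_valid")) and ictal_means is not None:
        states.append(("ictal", ictal_means))
    for state, means in states:
        t = perfusion_indexes(means)
        t = t[t["is_gray"]].copy()
        t["side"] = _atlas.relabel_sides(t["hemisphere"], ez)
        t["subject_id"] = subject["subject_id"]
        t["state"] = state
        frames.append(t[["subject_id", "state", "name", "side", "pi"]])
    out = pd.concat(frames, ignore_index=True)
    if decimals is not None:
        out["pi"] = out["pi"].round(decimals)
    return out
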