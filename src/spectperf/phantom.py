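"""Synthetic SPECT-like phantoms and cohort perfusion-index tables.

Two complementary generators make every downstream stage testable without
any acquisition:

* :func:`build_phantom` / :func:`degrade` produce voxel data — a bilateral
  atlas-labeled grid with region-wise ground-truth activity, degraded by a
  Gaussian point-spread function (detector response) followed by Poisson
  counting noise.  Regions are disjoint axis-aligned boxes mirrored about
  the x midplane; no anatomical realism is attempted, because partial-volume
  mixing and the perfusion index depend only on geometry/PSF overlap.

* :func:`simulate_cohort` produces cohort-level perfusion-index tables with
  the statistical structure the threshold analysis assumes: non-epileptogenic
  regions scatter around parity (PI ~ 1), designated epileptogenic-zone
  regions are shifted down interictally and up ictally.

All randomness flows through explicit integer seeds; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import atlas as _atlas
from . import datasets
from .perfusion import perfusion_indexes

__all__ = [
    "FWHM_TO_SIGMA",
    "PhantomSpec",
    "gaussian_blur",
    "build_phantom",
    "degrade",
    "simulate_cohort",
    "CohortResult",
    "EZ_REGIONS_BY_GROUP",
]

#: FWHM = sigma * 2 sqrt(2 ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_blur(volume: np.ndarray, fwhm_mm, voxel_size_mm) -> np.ndarray:
    """Separable Gaussian blur with reflective boundaries.

    The kernel on each axis is the normalized sampled Gaussian truncated at
    ``ceil(4 sigma)`` voxels; ``fwhm_mm = 0`` is the identity.
    """
    fwhm_mm = float(fwhm_mm)
    if fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be >= 0")
    out = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return out.copy()
    for axis, vox in enumerate(voxel_size_mm):
        sigma = fwhm_mm * FWHM_TO_SIGMA / float(vox)
        radius = int(np.ceil(4.0 * sigma))
        x = np.arange(-radius, radius + 1, dtype=float)
        kernel = np.exp(-0.5 * (x / sigma) ** 2)
        kernel /= kernel.sum()
        out = ndimage.convolve1d(out, kernel, axis=axis, mode="reflect")
    return out


class GeometryError(ValueError):
    """Raised when regions cannot be placed disjointly on the grid."""


@dataclass
class PhantomSpec:
    """Declarative description of one synthetic phantom.

    ``region_activity`` maps ``(name, hemisphere)`` to a true mean activity
    (arbitrary units, default 1.0 for unmentioned regions); ``ez_regions``
    lists the regions carrying the epileptogenic effect, whose activity is
    multiplied by ``ez_effect`` (< 1 models interictal hypoperfusion, > 1
    ictal hyperperfusion).
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    geometry_seed: int = 0
    region_activity: dict = field(default_factory=dict)
    ez_regions: tuple = ()
    ez_effect: float = 1.0
    psf_fwhm_mm: float = 9.0
    count_scale: float = 100.0
    noise_seed: int = 0

    def validate(self, regions: pd.DataFrame) -> None:
        keys = set(zip(regions["name"], regions["hemisphere"]))
        for k, v in self.region_activity.items():
            if tuple(k) not in keys:
                raise ValueError(f"region_activity key {k!r} not in atlas")
            if v <= 0:
                raise ValueError(f"activity for {k!r} must be > 0")
        for k in self.ez_regions:
            if tuple(k) not in keys:
                raise ValueError(f"ez region {k!r} not in atlas")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")
        if self.ez_effect <= 0:
            raise ValueError("ez_effect must be > 0")
        if self.count_scale <= 0:
            raise ValueError("count_scale must be > 0")


def _slot_grid(n: int, half_x: int, ny: int, nz: int):
    """Smallest (a, b, c) slot lattice with a*b*c >= n inside one hemisphere."""
    a = b = c = 1
    while a * b * c < n:
        extents = (half_x / a, ny / b, nz / c)
        i = int(np.argmax(extents))
        if i == 0:
            a += 1
        elif i == 1:
            b += 1
        else:
            c += 1
        if a > half_x or b > ny or c > nz:
            raise GeometryError(
                f"cannot place {n} bilateral regions on grid "
                f"({2 * half_x}+, {ny}, {nz})"
            )
    return a, b, c


def build_phantom(spec: PhantomSpec, regions: pd.DataFrame | None = None):
    """Construct a noiseless bilateral phantom from a spec.

    Returns ``(LabelVolume, TissueMaps, ActivityVolume, PhantomTruth)`` where
    the activity is piecewise constant at ``region_activity x ez_effect`` and
    PhantomTruth is a frame with the true regional means and the true
    perfusion index of every region, computed from the noiseless, unblurred
    layout.
    """
    if regions is None:
        regions = datasets.load_atlas()
    spec.validate(regions)
    sx, sy, sz = spec.shape
    if regions["hemisphere"].eq("midline").any():
        raise GeometryError("midline regions are not placeable; use lateralized halves")

    codes = list(dict.fromkeys(regions["name"]))
    right_start = (sx + 1) // 2
    half_x = sx - right_start
    a, b, c = _slot_grid(len(codes), half_x, sy, sz)
    dx, dy, dz = half_x // a, sy // b, sz // c
    margins = tuple(1 if d >= 3 else 0 for d in (dx, dy, dz))
    if min(dx - 2 * margins[0], dy - 2 * margins[1], dz - 2 * margins[2]) < 1:
        raise GeometryError("grid too small for disjoint region boxes")

    slots = [(i, j, k) for i in range(a) for j in range(b) for k in range(c)]
    rng = np.random.default_rng(spec.geometry_seed)
    order = rng.permutation(len(slots))

    ids = {(r["name"], r["hemisphere"]): r["region_id"] for _, r in regions.iterrows()}
    labels = np.zeros(spec.shape, dtype=np.int32)
    for code, si in zip(codes, order):
        i, j, k = slots[si]
        x0 = right_start + i * dx + margins[0]
        x1 = right_start + (i + 1) * dx - margins[0]
        y0, y1 = j * dy + margins[1], (j + 1) * dy - margins[1]
        z0, z1 = k * dz + margins[2], (k + 1) * dz - margins[2]
        labels[x0:x1, y0:y1, z0:z1] = ids[(code, "right")]
        # mirror about the x midplane
        labels[sx - x1:sx - x0, y0:y1, z0:z1] = ids[(code, "left")]

    ez = {tuple(k) for k in spec.ez_regions}
    act_of = {}
    for (name, hemi), rid in ids.items():
        v = float(spec.region_activity.get((name, hemi), 1.0))
        if (name, hemi) in ez:
            v *= spec.ez_effect
        act_of[rid] = v
    activity = np.zeros(spec.shape, dtype=float)
    for rid, v in act_of.items():
        activity[labels == rid] = v

    gray_ids = set(regions.loc[regions["is_gray"], "region_id"])
    gm = np.isin(labels, sorted(gray_ids)).astype(float)
    tissue = _atlas.TissueMaps(gm, np.zeros(spec.shape), np.zeros(spec.shape),
                               spec.voxel_size_mm)

    truth = regions[["region_id", "name", "hemisphere", "is_gray"]].copy()
    truth["true_mean"] = truth["region_id"].map(act_of)
    counts = np.bincount(labels.ravel(), minlength=labels.max() + 1)
    truth["n_voxels"] = truth["region_id"].map(lambda r: int(counts[r]))
    truth["true_pi"] = perfusion_indexes(
        truth.rename(columns={"true_mean": "mean"}), regions
    )["pi"].to_numpy()
    truth["is_ez"] = [
        (n, h) in ez for n, h in zip(truth["name"], truth["hemisphere"])
    ]

    return (
        _atlas.LabelVolume(labels, spec.voxel_size_mm),
        tissue,
        _atlas.ActivityVolume(activity, spec.voxel_size_mm),
        truth,
    )


def degrade(
    activity: _atlas.ActivityVolume,
    psf_fwhm_mm: float,
    count_scale: float,
    noise_seed: int,
    noise: bool = True,
) -> _atlas.ActivityVolume:
    """Forward model: PSF blur, then Poisson counting noise.

    The blurred activity is scaled by ``count_scale`` (expected counts per
    voxel at activity 1.0), Poisson-sampled per voxel, and rescaled back.
    ``noise=False`` returns the blurred volume unchanged (the infinite-count
    limit).
    """
    if count_scale <= 0:
        raise ValueError("count_scale must be > 0")
    blurred = gaussian_blur(activity.activity, psf_fwhm_mm, activity.voxel_size_mm)
    if not noise:
        return _atlas.ActivityVolume(blurred, activity.voxel_size_mm)
    rng = np.random.default_rng(noise_seed)
    observed = rng.poisson(count_scale * np.clip(blurred, 0, None)) / count_scale
    return _atlas.ActivityVolume(observed.astype(float), activity.voxel_size_mm)


# --------------------------------------------------------------------------
# cohort-level generator
# --------------------------------------------------------------------------

#: Ipsilateral name codes designated epileptogenic per epilepsy group.
EZ_REGIONS_BY_GROUP = {
    "TLE": ("A", "H", "PHG", "Entor", "STG", "MTG", "ITG"),
    "FLE": ("SFG", "MFG", "IFG", "PrecG", "MOFG", "LOFG", "STRAG"),
    "PQE": ("SOG", "MOG", "IOG", "Cuneus", "LingG"),
}


@dataclass
class CohortResult:
    """Simulated cohort: roster, perfusion table, and ground truth."""

    roster: pd.DataFrame
    perfusion: pd.DataFrame
    truth: pd.DataFrame


def _truncated_normal(rng, mean, sigma, size):
    """Normal draw resampled to stay positive (PI is a positive ratio)."""
    out = rng.normal(mean, sigma, size)
    while np.any(out <= 0):
        bad = out <= 0
        out[bad] = rng.normal(mean, sigma, bad.sum())
    return out


def simulate_cohort(
    n_per_group: dict | None = None,
    delta_inter: float = 0.15,
    delta_ictal: float = 0.25,
    sigma: float = 0.07,
    seed: int = 0,
    regions: pd.DataFrame | None = None,
) -> CohortResult:
    """Simulate per-subject perfusion-index tables for three epilepsy groups.

    Non-epileptogenic regions draw PI from a positive-truncated
    Normal(1.0, ``sigma``); the group's ipsilateral epileptogenic-zone
    regions are shifted by ``-delta_inter`` interictally and
    ``+delta_ictal`` ictally.  Deterministic given ``seed``.
    """
    if n_per_group is None:
        n_per_group = {"TLE": 5, "FLE": 5, "PQE": 5}
    if regions is None:
        regions = datasets.load_atlas()
    rng = np.random.default_rng(seed)

    roster_rows, pi_rows, truth_rows = [], [], []
    for group in ("TLE", "FLE", "PQE"):
        ez_names = set(EZ_REGIONS_BY_GROUP[group])
        for idx in range(int(n_per_group.get(group, 0))):
            sid = f"SIM-{group}-{idx + 1}"
            ez_lat = "left" if rng.random() < 0.5 else "right"
            roster_rows.append(
                {"subject_id": sid, "epilepsy_group": group,
                 "ez_laterality": ez_lat, "ictal_valid": True}
            )
            side = _atlas.relabel_sides(regions["hemisphere"], ez_lat)
            is_ez = regions["name"].isin(ez_names).to_numpy() & (
                np.asarray(side) == "i"
            )
            for name, sd_, ez_flag in zip(regions["name"], side, is_ez):
                truth_rows.append(
                    {"subject_id": sid, "name": name, "side": sd_,
                     "is_ez": bool(ez_flag)}
                )
            for state, shift in (("interictal", -delta_inter),
                                 ("ictal", +delta_ictal)):
                means = np.where(is_ez, 1.0 + shift, 1.0)
                pis = _truncated_normal(rng, means, sigma, len(means))
                for name, sd_, pi in zip(regions["name"], side, pis):
                    pi_rows.append(
                        {"subject_id": sid, "state": state, "name": name,
                         "side": sd_, "pi": float(pi)}
                    )

    return CohortResult(
        roster=pd.DataFrame(
            roster_rows,
            columns=["subject_id", "epilepsy_group", "ez_laterality",
                     "ictal_valid"],
        ),
        perfusion=pd.DataFrame(
            pi_rows, columns=["subject_id", "state", "name", "side", "pi"]
        ),
        truth=pd.DataFrame(
            truth_rows, columns=["subject_id", "name", "side", "is_ez"]
        ),
    )
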