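"""Partial-volume correction by regional transfer-matrix inversion.

The scanner's point-spread function mixes signal between adjacent regions
(the partial volume effect).  Under the assumptions of a shift-invariant
symmetric PSF and region-homogeneous activity, the observed regional means
``m`` relate to the true means ``t`` through a square cross-contamination
matrix: ``m = omega @ t`` with ``omega[i, j]`` the fraction of region j's
signal observed within region i (the mean, over region i's voxels, of the
PSF-blurred indicator of region j).  Correction is the dense linear solve
``t = omega^{-1} m``; unlabeled voxels form one extra background compartment
that is solved jointly and then discarded, so spill-in from outside gray
matter is not attributed to gray regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import atlas as _atlas
from .phantom import gaussian_blur

__all__ = ["TransferMatrix", "MTCDiagnostics", "build_transfer_matrix", "apply_mtc"]

BACKGROUND = 0  # label id of the background compartment


@dataclass
class TransferMatrix:
    """Region cross-contamination fractions under the PSF.

    ``region_ids`` orders the rows/columns of ``omega``; it includes the
    background compartment (id 0) last when the grid has unlabeled voxels.
    """

    region_ids: list
    omega: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        k = len(self.region_ids)
        if self.omega.shape != (k, k):
            raise ValueError("omega must be square over region_ids")


def build_transfer_matrix(
    labels: _atlas.LabelVolume,
    psf_fwhm_mm: float,
    regions: pd.DataFrame,
    include_background: bool = True,
) -> TransferMatrix:
    """Geometric transfer matrix of an atlas under a Gaussian PSF.

    With ``psf_fwhm_mm = 0`` the result is the identity.  Raises when a
    region of the table has no voxels (its row would be undefined).
    """
    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be >= 0")
    lab = labels.labels
    ids = list(regions["region_id"])
    for rid, name, hemi in zip(ids, regions["name"], regions["hemisphere"]):
        if not np.any(lab == rid):
            raise ValueError(f"region {name}/{hemi} (id {rid}) has no voxels")
    if include_background and np.any(lab == BACKGROUND):
        ids = ids + [BACKGROUND]

    masks = [lab == rid for rid in ids]
    k = len(ids)
    omega = np.empty((k, k), dtype=float)
    for j, mask_j in enumerate(masks):
        blurred = gaussian_blur(mask_j.astype(float), psf_fwhm_mm,
                                labels.voxel_size_mm)
        for i, mask_i in enumerate(masks):
            omega[i, j] = float(blurred[mask_i].mean())
    return TransferMatrix(region_ids=ids, omega=omega)


@dataclass
class MTCDiagnostics:
    """Numerical diagnostics of one correction solve."""

    condition_number: float
    residual_norm: float
    negative_regions: list


def apply_mtc(
    observed_means: np.ndarray,
    transfer: TransferMatrix,
    cond_max: float = 1e6,
) -> tuple[np.ndarray, MTCDiagnostics]:
    """Solve ``omega @ t = m`` for the corrected regional means.

    Means must be ordered as ``transfer.region_ids``.  An ill-conditioned
    matrix (condition number above ``cond_max``) raises; negative corrected
    means are flagged in the diagnostics but retained, since clipping would
    bias downstream ratio indexes.
    """
    m = np.asarray(observed_means, dtype=float)
    omega = transfer.omega
    if m.shape != (omega.shape[0],):
        raise ValueError(
            f"observed means length {m.shape} does not match omega {omega.shape}"
        )
    cond = float(np.linalg.cond(omega))
    if not np.isfinite(cond) or cond > cond_max:
        raise np.linalg.LinAlgError(
            f"transfer matrix ill-conditioned (cond={cond:.3g} > {cond_max:.3g})"
        )
    corrected = np.linalg.solve(omega, m)
    residual = float(np.linalg.norm(omega @ corrected - m))
    negatives = [
        rid for rid, v in zip(transfer.region_ids, corrected) if v < 0
    ]
    return corrected, MTCDiagnostics(cond, residual, negatives)
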