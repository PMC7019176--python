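"""ROI-level summaries: non-enhanced fractions, mean Ktrans, muscle ROIs.

The study conventions are reproduced exactly: the tumor mask is a manual
segmentation given as input; muscle reference ROIs are 5x5 in-plane pixel
blocks placed in the four central tumor slices, kept at least one pixel
clear of the tumor border and as close as possible to the optical axis of
the treatment light beam; means of Ktrans are taken over enhanced,
converged voxels only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conc import ConcMaps, auc_map
from .pk import ToftsFit

__all__ = ["RoiSet", "StudySummary", "nonenhanced_fraction",
           "place_muscle_rois", "summarize_study"]

BLOCK = 5          # muscle ROI edge, pixels
SPACING = 1        # clearance to the tumor border, pixels
N_CENTRAL_SLICES = 4


@dataclass
class RoiSet:
    """Tumor mask plus muscle reference blocks.

    ``muscle_rois`` holds ``(z, x0, y0)`` top-left corners of 5x5 blocks.
    """

    tumor_mask: np.ndarray
    muscle_rois: list[tuple[int, int, int]]
    beam_axis: tuple[float, float]

    def muscle_mask(self) -> np.ndarray:
        out = np.zeros_like(self.tumor_mask, dtype=bool)
        for z, x0, y0 in self.muscle_rois:
            out[x0:x0 + BLOCK, y0:y0 + BLOCK, z] = True
        return out


@dataclass
class StudySummary:
    """Scalar study outcomes; NaN marks an empty compartment."""

    nonenhanced_fraction_tumor: float
    nonenhanced_fraction_muscle: float
    mean_ktrans_tumor_enhanced: float
    mean_ktrans_muscle: float
    mean_auc_tumor: float
    n_voxels: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        row = {
            "nonenhanced_fraction_tumor_pct": self.nonenhanced_fraction_tumor,
            "nonenhanced_fraction_muscle_pct": self.nonenhanced_fraction_muscle,
            "mean_ktrans_tumor_enhanced_per_min": self.mean_ktrans_tumor_enhanced,
            "mean_ktrans_muscle_per_min": self.mean_ktrans_muscle,
            "mean_auc_tumor_mM_s": self.mean_auc_tumor,
        }
        row.update({f"n_{k}": v for k, v in sorted(self.n_voxels.items())})
        return pd.DataFrame([row])


def nonenhanced_fraction(enhanced_mask: np.ndarray, roi_mask: np.ndarray) -> float:
    """Percentage of ROI voxels that are non-enhanced."""
    n_roi = int(np.count_nonzero(roi_mask))
    if n_roi == 0:
        raise ValueError("ROI is empty")
    n_non = int(np.count_nonzero(roi_mask & ~enhanced_mask))
    return 100.0 * n_non / n_roi


def _feasible_blocks(tumor_slice: np.ndarray) -> np.ndarray:
    """Boolean grid of top-left corners whose padded 5x5 block avoids tumor."""
    nx, ny = tumor_slice.shape
    # Forbidden zone: tumor dilated by the required spacing (Chebyshev).
    pad = np.zeros((nx + 2 * SPACING, ny + 2 * SPACING), dtype=bool)
    pad[SPACING:SPACING + nx, SPACING:SPACING + ny] = tumor_slice
    win = np.lib.stride_tricks.sliding_window_view(pad, (BLOCK + 2 * SPACING,
                                                         BLOCK + 2 * SPACING))
    return ~win.any(axis=(2, 3))  # shape (nx - BLOCK + 1, ny - BLOCK + 1)


def place_muscle_rois(tumor_mask: np.ndarray, beam_axis: tuple[float, float],
                      n_slices: int = N_CENTRAL_SLICES) -> RoiSet:
    """Place the muscle reference blocks of the study protocol.

    The middle ``n_slices`` of the tumor's slice extent are selected (ties
    toward the smaller index); in each, the 5x5 block nearest the beam axis
    whose one-pixel-padded bounding box is tumor-free is chosen.  Slices
    with no feasible block are skipped with a warning.
    """
    zs = np.flatnonzero(tumor_mask.any(axis=(0, 1)))
    if zs.size < n_slices:
        raise ValueError(f"tumor must intersect at least {n_slices} slices")
    zmin, zmax = int(zs[0]), int(zs[-1])
    extent = zmax - zmin + 1
    start = zmin + (extent - n_slices) // 2
    chosen = range(start, start + n_slices)

    bx, by = beam_axis
    rois: list[tuple[int, int, int]] = []
    for z in chosen:
        feas = _feasible_blocks(tumor_mask[:, :, z])
        if not feas.any():
            warnings.warn(f"no feasible muscle block in slice {z}; skipped")
            continue
        x0s, y0s = np.nonzero(feas)
        cx = x0s + (BLOCK - 1) / 2.0
        cy = y0s + (BLOCK - 1) / 2.0
        d2 = (cx - bx) ** 2 + (cy - by) ** 2
        k = int(np.argmin(d2))  # ties: first in row-major order
        rois.append((z, int(x0s[k]), int(y0s[k])))
    return RoiSet(tumor_mask=tumor_mask.astype(bool), muscle_rois=rois,
                  beam_axis=(float(bx), float(by)))


def _mean_or_nan(values: np.ndarray) -> float:
    return float(values.mean()) if values.size else float("nan")


def summarize_study(fit: ToftsFit, conc: ConcMaps, rois: RoiSet) -> StudySummary:
    """Aggregate the study outcome quantities over tumor and muscle ROIs.

    Ktrans means are restricted to enhanced & converged voxels (mirroring
    the analysis of enhanced tumor pixels); non-enhanced fractions are
    computed over valid voxels of each compartment.
    """
    tumor = rois.tumor_mask & conc.valid
    muscle = rois.muscle_mask() & conc.valid

    frac_tumor = nonenhanced_fraction(conc.enhanced, tumor) if tumor.any() else float("nan")
    frac_muscle = nonenhanced_fraction(conc.enhanced, muscle) if muscle.any() else float("nan")

    fit_tumor = tumor & conc.enhanced & fit.converged
    fit_muscle = muscle & conc.enhanced & fit.converged
    mean_kt_tumor = _mean_or_nan(fit.ktrans[fit_tumor])
    mean_kt_muscle = _mean_or_nan(fit.ktrans[fit_muscle])

    auc = auc_map(conc)
    auc_tumor = auc[tumor]
    mean_auc = _mean_or_nan(auc_tumor[np.isfinite(auc_tumor)])

    return StudySummary(
        nonenhanced_fraction_tumor=frac_tumor,
        nonenhanced_fraction_muscle=frac_muscle,
        mean_ktrans_tumor_enhanced=mean_kt_tumor,
        mean_ktrans_muscle=mean_kt_muscle,
        mean_auc_tumor=mean_auc,
        n_voxels={
            "tumor": int(tumor.sum()),
            "muscle": int(muscle.sum()),
            "tumor_enhanced_fitted": int(fit_tumor.sum()),
            "muscle_enhanced_fitted": int(fit_muscle.sum()),
        },
    )
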