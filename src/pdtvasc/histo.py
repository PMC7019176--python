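"""Histology perfusion and necrosis quantification.

Perfusion is read out from the Hoechst 33342 channel: the dye is injected
minutes before sacrifice, so only perfused tissue is stained, and a
manually selected intensity threshold splits the tumor into perfused and
non-perfused compartments.  Necrosis masks come from manual H&E
segmentation and are inputs.  The module reports the necrotic fraction of
the tumor, the non-perfused fraction, and their overlap (share of the
necrotic area that is non-perfused).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

__all__ = ["HistoSection", "PerfusionStats", "classify_perfusion",
           "perfusion_stats", "suggest_otsu_threshold"]


@dataclass
class HistoSection:
    """Registered section images and masks; ``threshold`` is manual."""

    hoechst: np.ndarray
    tumor_mask: np.ndarray
    necrosis_mask: np.ndarray
    threshold: float | None = None
    cd31: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
        self.necrosis_mask = np.asarray(self.necrosis_mask, dtype=bool)
        if self.tumor_mask.shape != self.hoechst.shape:
            raise ValueError("tumor mask must match the image shape")
        if np.any(self.necrosis_mask & ~self.tumor_mask):
            raise ValueError("necrosis mask must lie inside the tumor mask")


@dataclass
class PerfusionStats:
    necrotic_fraction: float            # % of tumor
    nonperfused_fraction: float         # % of tumor
    necrotic_nonperfused_overlap: float  # % of necrosis that is non-perfused


def classify_perfusion(section: HistoSection) -> np.ndarray:
    """Perfused mask: Hoechst >= threshold, restricted to the tumor.

    The threshold must be supplied (it is a manual, per-section choice);
    there is no automatic default.
    """
    if section.threshold is None:
        raise ValueError("a manual Hoechst threshold is required; "
                         "see suggest_otsu_threshold for a starting point")
    if section.threshold <= 0:
        raise ValueError("threshold must be > 0")
    return (section.hoechst >= section.threshold) & section.tumor_mask


def perfusion_stats(section: HistoSection, perfused: np.ndarray) -> PerfusionStats:
    """Area fractions of necrosis, non-perfusion and their overlap."""
    tumor = section.tumor_mask
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        raise ValueError("tumor mask is empty")
    necro = section.necrosis_mask
    nonperf = tumor & ~np.asarray(perfused, dtype=bool)
    n_necro = int(necro.sum())
    overlap = (100.0 * int((necro & nonperf).sum()) / n_necro
               if n_necro else float("nan"))
    return PerfusionStats(
        necrotic_fraction=100.0 * n_necro / n_tumor,
        nonperfused_fraction=100.0 * int(nonperf.sum()) / n_tumor,
        necrotic_nonperfused_overlap=overlap,
    )


def suggest_otsu_threshold(section: HistoSection) -> float:
    """Otsu threshold of the in-tumor Hoechst intensities — a helper for
    choosing the manual threshold, never applied automatically."""
    vals = section.hoechst[section.tumor_mask]
    if vals.size == 0:
        raise ValueError("tumor mask is empty")
    return float(threshold_otsu(vals))
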