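"""Digital phantom: ground-truth tissue maps and simulated VFA/DCE signals.

The phantom emulates the study geometry at desk scale — an ellipsoidal
subcutaneous tumor with a concentric non-enhancing core (Ktrans = 0,
modelling vascular shutdown after photodynamic therapy) above a uniform
muscle slab — and pushes known (T1, M0, Ktrans, ve) maps through the exact
forward chain (AIF -> Tofts tissue curve -> relaxivity -> SPGR signal), so
every downstream stage can be validated by parameter recovery.

Rim Ktrans and ve vary smoothly across the tumor (Ktrans in
[0.05, 1] min^-1 along x, ve in [0.1, 0.6] along y) so that recovery is
probed over the physiological range rather than at a single operating
point.  Rician noise is the default measurement model for magnitude MR
data; Gaussian is available for linear-regime checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conc import DceSeries
from .kinetics import (DEGENERATE_RATE_TOL, aif_concentration, spgr_signal,
                       tissue_concentration)
from .protocol import AifParams, NoiseSpec, ScanProtocol
from .t1map import VfaSeries

__all__ = ["PhantomTruth", "default_truth", "simulate_study", "sigma_for_snr",
           "aif_concentration", "tissue_concentration", "spgr_signal",
           "tissue_concentration_map"]


@dataclass
class PhantomTruth:
    """Ground-truth voxel maps the simulation is generated from."""

    t1_map: np.ndarray        # s; 0 outside tissue
    m0_map: np.ndarray        # signal units; 0 outside tissue
    ktrans_map: np.ndarray    # min^-1
    ve_map: np.ndarray        # fraction
    tumor_mask: np.ndarray
    nonenhanced_core_mask: np.ndarray
    voxel_size: tuple[float, float, float] = (0.625, 0.625, 1.3)  # mm

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.t1_map, self.m0_map, self.ktrans_map,
                                    self.ve_map, self.tumor_mask,
                                    self.nonenhanced_core_mask)}
        if len(shapes) != 1:
            raise ValueError("all truth maps must share one grid shape")
        if np.any(self.nonenhanced_core_mask & ~self.tumor_mask):
            raise ValueError("non-enhancing core must lie inside the tumor")
        if np.any(self.ktrans_map[self.nonenhanced_core_mask] != 0.0):
            raise ValueError("Ktrans must be exactly 0 inside the core")
        perf = self.ktrans_map > 0
        if np.any((self.ve_map[perf] <= 0) | (self.ve_map[perf] > 1)):
            raise ValueError("ve must lie in (0, 1] wherever Ktrans > 0")
        if np.any(self.t1_map[self.tissue_mask] <= 0):
            raise ValueError("T1 must be positive in tissue")

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.m0_map > 0


def _ellipsoid(shape, center, semi):
    idx = np.indices(shape, dtype=float)
    r2 = sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return r2 <= 1.0


def default_truth(shape=(64, 64, 17), core_volume_fraction: float = 0.3,
                  t1_tumor: float = 1.9, t1_muscle: float = 1.5,
                  m0: float = 1000.0, ktrans_muscle: float = 0.10,
                  ve_muscle: float = 0.15) -> PhantomTruth:
    """Build the default study phantom.

    Tumor: centered ellipsoid with semi-axes 20%/20%/35% of the grid;
    core: concentric ellipsoid scaled to ``core_volume_fraction`` of the
    tumor volume, with Ktrans = 0 (non-perfused).  Muscle: an in-plane
    ring surrounding the tumor at 2-8 voxels Chebyshev distance on every
    tumor-bearing slice — the tumor sits embedded in musculature, as in a
    subcutaneous hind-leg model, which also guarantees the reference-ROI
    placement always finds muscle tissue near the beam axis.  The
    one-voxel shell between tumor and muscle is left empty as a
    segmentation margin.  T1 defaults are typical 7T tissue values;
    Ktrans/ve in muscle are resting-muscle literature values.
    """
    from scipy.ndimage import binary_dilation

    shape = tuple(shape)
    center = (shape[0] // 2, int(0.4 * shape[1]), shape[2] // 2)
    semi = (0.2 * shape[0], 0.2 * shape[1], 0.35 * shape[2])
    tumor = _ellipsoid(shape, center, semi)
    core = _ellipsoid(shape, center, tuple(s * core_volume_fraction ** (1 / 3) for s in semi))
    core &= tumor

    inplane = np.ones((3, 3, 1), dtype=bool)
    near = binary_dilation(tumor, structure=inplane, iterations=1)
    far = binary_dilation(tumor, structure=inplane, iterations=8)
    muscle = far & ~near
    muscle[:1], muscle[-1:] = False, False
    muscle[:, :1], muscle[:, -1:] = False, False

    t1 = np.zeros(shape)
    m0_map = np.zeros(shape)
    ktrans = np.zeros(shape)
    ve = np.zeros(shape)

    t1[tumor] = t1_tumor
    t1[muscle] = t1_muscle
    m0_map[tumor | muscle] = m0

    # Smooth in-plane gradients over the enhancing rim.
    xi, yi = np.indices(shape)[:2]
    ux = np.clip((xi - (center[0] - semi[0])) / (2 * semi[0]), 0.0, 1.0)
    uy = np.clip((yi - (center[1] - semi[1])) / (2 * semi[1]), 0.0, 1.0)
    rim = tumor & ~core
    ktrans[rim] = 0.05 + 0.95 * ux[rim]
    ve[rim] = 0.1 + 0.5 * uy[rim]
    ktrans[muscle] = ktrans_muscle
    ve[muscle] = ve_muscle

    return PhantomTruth(t1_map=t1, m0_map=m0_map, ktrans_map=ktrans,
                        ve_map=ve, tumor_mask=tumor,
                        nonenhanced_core_mask=core)


def tissue_concentration_map(ktrans, ve, aif: AifParams, t, t0: float):
    """Vectorized Tofts curves for per-voxel (ktrans, ve) arrays.

    Same closed form as :func:`tissue_concentration` broadcast over a flat
    voxel axis; returns an array (n_voxels, n_times) in mM.
    """
    ktrans = np.atleast_1d(np.asarray(ktrans, dtype=float))
    ve = np.atleast_1d(np.asarray(ve, dtype=float))
    t = np.asarray(t, dtype=float)
    perf = ktrans > 0
    if np.any((ve[perf] <= 0) | (ve[perf] > 1)):
        raise ValueError("ve must lie in (0, 1] wherever ktrans > 0")

    out = np.zeros((ktrans.size, t.size))
    if not np.any(perf):
        return out
    kt_s = (ktrans[perf] / 60.0)[:, None]
    kep_s = kt_s / ve[perf][:, None]
    d = np.clip(t - t0, 0.0, None)[None, :]
    post = (t >= t0)[None, :]
    e_kep = np.exp(-kep_s * d)
    acc = np.zeros_like(e_kep)
    for a_i, tau_i in ((aif.a1, aif.tau1), (aif.a2, aif.tau2)):
        gap = kep_s - 1.0 / tau_i
        degen = np.abs(gap) < DEGENERATE_RATE_TOL
        safe_gap = np.where(degen, 1.0, gap)
        generic = a_i * (np.exp(-d / tau_i) - e_kep) / safe_gap
        acc += np.where(degen, a_i * d * e_kep, generic)
    out[perf] = kt_s * acc * post
    return out


def _apply_noise(signal: np.ndarray, noise: NoiseSpec, rng) -> np.ndarray:
    if noise.sigma == 0:
        return signal
    if noise.model == "gaussian":
        return signal + rng.normal(0.0, noise.sigma, signal.shape)
    n1 = rng.normal(0.0, noise.sigma, signal.shape)
    n2 = rng.normal(0.0, noise.sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2 ** 2)


def simulate_study(truth: PhantomTruth, protocol: ScanProtocol,
                   aif: AifParams, noise: NoiseSpec) -> tuple[VfaSeries, DceSeries]:
    """Forward-simulate the VFA T1 scan and the DCE scan from the truth maps.

    Per tissue voxel the VFA signals follow the SPGR equation at each flip
    angle; the dynamic signals follow R1(t) = R1_pre + r1 C(t) with C(t)
    the closed-form Tofts curve under the study AIF.  Noise is then drawn
    once for each series from ``noise.seed`` (Rician by default), so the
    same spec reproduces the same series bit for bit.
    """
    tissue = truth.tissue_mask
    shape = tissue.shape
    rng = np.random.default_rng(noise.seed)

    t1_v = truth.t1_map[tissue]
    m0_v = truth.m0_map[tissue]

    vfa = np.zeros(shape + (len(protocol.vfa_flip_angles),))
    for j, alpha in enumerate(protocol.vfa_flip_angles):
        vfa[tissue, j] = spgr_signal(m0_v, t1_v, alpha, protocol.tr_vfa)

    times = protocol.frame_times
    c_vox = tissue_concentration_map(truth.ktrans_map[tissue],
                                     truth.ve_map[tissue], aif, times,
                                     protocol.t0)
    r1_vox = (1.0 / t1_v)[:, None] + protocol.r1_relaxivity * c_vox
    dce = np.zeros(shape + (times.size,))
    dce[tissue] = spgr_signal(m0_v[:, None], 1.0 / r1_vox,
                              protocol.fa_dce, protocol.tr_dce)

    vfa = _apply_noise(vfa, noise, rng)
    dce = _apply_noise(dce, noise, rng)

    vfa_series = VfaSeries(signal=vfa, angles=protocol.vfa_flip_angles,
                           protocol=protocol, mask=tissue.copy())
    dce_series = DceSeries(signal=dce, times=times, protocol=protocol,
                           mask=tissue.copy())
    return vfa_series, dce_series


def sigma_for_snr(truth: PhantomTruth, protocol: ScanProtocol,
                  snr: float) -> float:
    """Noise sigma giving a target baseline SNR in the tumor.

    SNR is defined on the pre-injection dynamic signal: mean baseline SPGR
    signal over tumor tissue divided by the Gaussian channel sigma.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    vox = truth.tumor_mask & truth.tissue_mask
    s = spgr_signal(truth.m0_map[vox], truth.t1_map[vox],
                    protocol.fa_dce, protocol.tr_dce)
    return float(s.mean() / snr)
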