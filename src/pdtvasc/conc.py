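"""DCE signal to contrast-agent concentration, and enhancement classification.

Per voxel the dynamic signal is converted through the spoiled-gradient-echo
model: an effective M0 is calibrated from the mean pre-injection signal and
the pre-contrast R1 of the T1 map, each frame is inverted to R1(t), and

    C(t) = (R1(t) - R1_pre) / r1

with r1 the longitudinal relaxivity of the contrast agent.  Voxels are then
classified as enhanced or non-enhanced by the rule: non-enhanced iff the
median concentration after the injection time is smaller than twice the
sample SD of the pre-injection frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kinetics import invert_spgr
from .protocol import ScanProtocol
from .t1map import R1Map

__all__ = ["DceSeries", "ConcMaps", "signal_to_concentration",
           "classify_enhancement", "auc_map"]


@dataclass
class DceSeries:
    """Dynamic contrast-enhanced series: ``signal[x, y, z, n_frames]``."""

    signal: np.ndarray
    times: np.ndarray
    protocol: ScanProtocol
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.signal.shape[-1] != self.times.size:
            raise ValueError("last signal axis must index the frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.sum(self.times < self.protocol.t0) < 3:
            raise ValueError("need at least 3 pre-injection frames")
        if self.mask.shape != self.signal.shape[:-1]:
            raise ValueError("mask shape must match the spatial grid")


@dataclass
class ConcMaps:
    """Concentration time-courses and the enhancement classification."""

    conc: np.ndarray          # mM, [x, y, z, n_frames]; NaN = non-invertible frame
    r1_t: np.ndarray          # s^-1, same shape
    enhanced: np.ndarray      # bool, defined on mask & valid only
    baseline_frames: np.ndarray  # indices of the pre-injection frames
    times: np.ndarray         # s
    t0: float                 # s
    valid: np.ndarray         # bool: voxels with a usable R1_pre


def _classify(conc, times, t0):
    """Vectorized enhancement rule on curves stacked along the last axis."""
    pre = times < t0
    post = ~pre
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        med_post = np.nanmedian(conc[..., post], axis=-1)
        sd_pre = np.nanstd(conc[..., pre], axis=-1, ddof=1)
    nonenh = med_post < 2.0 * sd_pre
    # Degenerate zero baseline SD: non-enhanced iff the post median is <= 0.
    zero_sd = sd_pre == 0.0
    nonenh = np.where(zero_sd, med_post <= 0.0, nonenh)
    return ~nonenh & np.isfinite(med_post)


def classify_enhancement(conc_curve, times, t0: float) -> bool:
    """Return True when a single concentration curve is enhanced.

    Non-enhanced iff median(C(t >= t0)) < 2 * sample SD(C(t < t0)); with a
    degenerate zero baseline SD the curve is non-enhanced iff the
    post-injection median is <= 0.  Frames carried as NaN are excluded.
    """
    conc_curve = np.asarray(conc_curve, dtype=float)
    times = np.asarray(times, dtype=float)
    if conc_curve.shape[-1] != times.size:
        raise ValueError("curve and times must have equal length")
    if np.sum(times < t0) < 2 or np.sum(times >= t0) < 1:
        raise ValueError("need >= 2 pre-injection and >= 1 post-injection frames")
    return bool(_classify(conc_curve, times, t0))


def signal_to_concentration(dce: DceSeries, r1map: R1Map) -> ConcMaps:
    """Convert a DCE series to concentration maps and classify enhancement.

    The effective equilibrium signal M0 is calibrated per voxel from the
    mean of all pre-injection frames together with R1_pre, so that any
    scaling difference between the VFA and dynamic acquisitions (receiver
    gain, TE) cancels.  Frames whose signal falls outside the invertible
    SPGR range are carried as NaN and excluded from medians and SDs.
    Voxels without a valid R1_pre are excluded entirely.
    """
    prot = dce.protocol
    times = dce.times
    pre = times < prot.t0
    baseline_frames = np.flatnonzero(pre)

    valid = r1map.valid & dce.mask
    shape = dce.signal.shape
    conc = np.full(shape, np.nan)
    r1_t = np.full(shape, np.nan)

    sig = dce.signal[valid]                      # (n_vox, n_frames)
    r1_pre = r1map.r1_pre[valid][:, None]        # (n_vox, 1)
    s_base = sig[:, pre].mean(axis=1)[:, None]

    a = np.deg2rad(prot.fa_dce)
    e1 = np.exp(-prot.tr_dce * r1_pre)
    shape_factor = np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))
    with np.errstate(divide="ignore", invalid="ignore"):
        m0_eff = s_base / shape_factor

    r1_vox = invert_spgr(sig, m0_eff, prot.fa_dce, prot.tr_dce)
    # Reference the concentration to the baseline rate recovered from the
    # same calibration (algebraically r1_pre, but bit-exact on the baseline
    # frames, so noiseless pre-injection C(t) is exactly zero).
    r1_base = invert_spgr(s_base, m0_eff, prot.fa_dce, prot.tr_dce)
    r1_base = np.where(np.isfinite(r1_base), r1_base, r1_pre)
    c_vox = (r1_vox - r1_base) / prot.r1_relaxivity

    r1_t[valid] = r1_vox
    conc[valid] = c_vox

    enhanced = np.zeros(shape[:-1], dtype=bool)
    enhanced[valid] = _classify(c_vox, times, prot.t0)

    return ConcMaps(conc=conc, r1_t=r1_t, enhanced=enhanced,
                    baseline_frames=baseline_frames, times=times,
                    t0=prot.t0, valid=valid)


def auc_map(conc: ConcMaps, window: tuple[float, float] | None = None) -> np.ndarray:
    """Trapezoidal area under the concentration curve, mM * s, per voxel.

    ``window`` is a (start, end) pair in seconds; the default integrates
    from the injection time to the end of the scan.  Window endpoints that
    fall between frames are handled by linear interpolation of the curve,
    so the integral covers the exact requested window.  Non-invertible
    (NaN) frames are linearly interpolated over before integration; voxels
    with no finite frame come back NaN.
    """
    times = conc.times
    if window is None:
        window = (conc.t0, float(times[-1]))
    lo, hi = window
    if not (times[0] <= lo < hi <= times[-1]):
        raise ValueError("window must be non-empty and inside the scan")

    inside = (times > lo) & (times < hi)
    t = np.concatenate(([lo], times[inside], [hi]))
    curves = conc.conc
    bad = ~np.isfinite(curves)
    if np.any(bad):
        curves = curves.copy()
        flat = curves.reshape(-1, times.size)
        for i in np.flatnonzero(bad.reshape(-1, times.size).any(axis=1)):
            row = flat[i]
            ok = np.isfinite(row)
            flat[i] = np.interp(times, times[ok], row[ok]) if ok.any() else np.nan

    def _at(tq):
        j = int(np.searchsorted(times, tq))
        if j < times.size and times[j] == tq:
            return curves[..., j]
        w = (tq - times[j - 1]) / (times[j] - times[j - 1])
        return (1.0 - w) * curves[..., j - 1] + w * curves[..., j]

    vals = np.concatenate([_at(lo)[..., None], curves[..., inside],
                           _at(hi)[..., None]], axis=-1)
    return np.trapezoid(vals, t, axis=-1)
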