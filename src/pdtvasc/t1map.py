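"""Voxelwise pre-contrast T1/M0 estimation from variable-flip-angle data.

The estimator follows the classic DESPOT1 scheme: a linearized fit of
S/sin(a) against S/tan(a) (slope E1 = exp(-TR/T1)) provides screening and
initialization, followed by a bounded nonlinear least-squares refinement of
the spoiled-gradient-echo model.  The refinement profiles out M0 (which
enters the model linearly) and searches T1 alone on a log grid plus
golden-section polish, which keeps the whole map fit vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .kinetics import invert_spgr, spgr_signal  # re-exported: invert_spgr
from .protocol import ScanProtocol

__all__ = ["VfaSeries", "R1Map", "VfaT1Fitter", "fit_t1_vfa", "invert_spgr"]


@dataclass
class VfaSeries:
    """Multi-flip-angle SPGR volume: ``signal[x, y, z, n_angles]``."""

    signal: np.ndarray
    angles: tuple[float, ...]
    protocol: ScanProtocol
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.angles = tuple(float(a) for a in self.angles)
        if len(self.angles) < 2:
            raise ValueError("need at least 2 flip angles")
        if any(b <= a for a, b in zip(self.angles, self.angles[1:])):
            raise ValueError("flip angles must be strictly increasing")
        if self.signal.shape[-1] != len(self.angles):
            raise ValueError("last signal axis must index the flip angles")
        if self.mask.shape != self.signal.shape[:-1]:
            raise ValueError("mask shape must match the spatial grid")


@dataclass
class R1Map:
    """Pre-contrast relaxation-rate map with fit diagnostics."""

    r1_pre: np.ndarray       # s^-1, NaN where invalid
    m0: np.ndarray           # signal units, NaN where invalid
    fit_residual: np.ndarray  # RMS residual, signal units
    valid: np.ndarray        # bool

    @property
    def t1(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 1.0 / self.r1_pre


class VfaT1Fitter(BaseEstimator):
    """Voxelwise (M0, T1) estimator for variable-flip-angle SPGR data.

    Parameters
    ----------
    angles_deg : sequence of float
        Flip angles of the acquisitions, degrees, strictly increasing.
    tr : float
        Repetition time in seconds.
    t1_bounds : (float, float)
        Search bounds for T1 in seconds.  The defaults exclude non-tissue
        solutions.
    n_grid : int
        Size of the log-spaced T1 screening grid used to bracket the
        nonlinear refinement.

    Attributes (after :meth:`fit` on ``X`` of shape (n_voxels, n_angles))
    ----------
    t1_, m0_ : ndarray (n_voxels,) — estimates, NaN where invalid
    r1_ : ndarray — 1/t1_
    residual_ : ndarray — per-voxel RMS residual
    valid_ : ndarray of bool — voxels with a physical fit
    """

    def __init__(self, angles_deg=(2.0, 3.0, 5.0, 7.0, 10.0, 13.0, 20.0),
                 tr: float = 0.020, t1_bounds=(0.05, 10.0), n_grid: int = 200):
        self.angles_deg = angles_deg
        self.tr = tr
        self.t1_bounds = t1_bounds
        self.n_grid = n_grid

    def _rss_profiled(self, X, t1_vals):
        """RSS over voxels for each candidate T1, with M0 profiled out.

        X: (n_vox, n_angles); t1_vals: (n_t1,).  Returns rss (n_vox, n_t1)
        and the profiled m0 (n_vox, n_t1).
        """
        a = np.deg2rad(np.asarray(self.angles_deg, dtype=float))
        e1 = np.exp(-self.tr / np.asarray(t1_vals, dtype=float))[:, None]
        f = np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))  # (n_t1, n_angles)
        num = X @ f.T                     # (n_vox, n_t1)
        den = np.sum(f * f, axis=1)       # (n_t1,)
        m0 = np.clip(num / den, 0.0, None)
        ss_x = np.sum(X * X, axis=1, keepdims=True)
        rss = ss_x - 2.0 * m0 * num + m0 * m0 * den
        return np.clip(rss, 0.0, None), m0

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(tuple(self.angles_deg)):
            raise ValueError("X must be (n_voxels, n_angles)")
        n = X.shape[0]
        a = np.deg2rad(np.asarray(self.angles_deg, dtype=float))

        # Linearized DESPOT1 screen: S/sin = E1 * S/tan + M0 (1 - E1).
        ysin = X / np.sin(a)
        xtan = X / np.tan(a)
        xm = xtan.mean(axis=1, keepdims=True)
        ym = ysin.mean(axis=1, keepdims=True)
        sxx = np.sum((xtan - xm) ** 2, axis=1)
        sxy = np.sum((xtan - xm) * (ysin - ym), axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = sxy / sxx
        nonzero = np.any(X != 0.0, axis=1)
        valid = nonzero & np.isfinite(slope) & (slope > 0.0) & (slope < 1.0)

        t1 = np.full(n, np.nan)
        m0 = np.full(n, np.nan)
        resid = np.full(n, np.nan)
        if np.any(valid):
            Xv = X[valid]
            lo, hi = self.t1_bounds
            grid = np.exp(np.linspace(np.log(lo), np.log(hi), self.n_grid))
            rss, _ = self._rss_profiled(Xv, grid)
            idx = np.argmin(rss, axis=1)
            # Golden-section polish inside the bracketing grid cells, on log T1.
            gl = np.log(grid[np.maximum(idx - 1, 0)])
            gh = np.log(grid[np.minimum(idx + 1, self.n_grid - 1)])
            invphi = (np.sqrt(5.0) - 1.0) / 2.0
            for _ in range(60):
                c = gh - invphi * (gh - gl)
                d = gl + invphi * (gh - gl)
                rc = self._rss_pointwise(Xv, np.exp(c))
                rd = self._rss_pointwise(Xv, np.exp(d))
                left = rc < rd
                gh = np.where(left, d, gh)
                gl = np.where(left, gl, c)
            t1v = np.exp(0.5 * (gl + gh))
            rssv, m0v = self._rss_pointwise(Xv, t1v, return_m0=True)
            t1[valid] = t1v
            m0[valid] = m0v
            resid[valid] = np.sqrt(rssv / Xv.shape[1])

        self.t1_ = t1
        self.m0_ = m0
        with np.errstate(divide="ignore"):
            self.r1_ = 1.0 / t1
        self.residual_ = resid
        self.valid_ = valid
        return self

    def _rss_pointwise(self, X, t1_per_voxel, return_m0=False):
        """RSS with a distinct candidate T1 per voxel (M0 profiled).

        Residuals are formed explicitly (not via the expanded quadratic),
        which avoids catastrophic cancellation near the minimum and keeps
        the golden-section comparisons meaningful to machine precision.
        """
        a = np.deg2rad(np.asarray(self.angles_deg, dtype=float))
        e1 = np.exp(-self.tr / np.asarray(t1_per_voxel, dtype=float))[:, None]
        f = np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))  # (n_vox, n_angles)
        num = np.sum(X * f, axis=1)
        den = np.sum(f * f, axis=1)
        m0 = np.clip(num / den, 0.0, None)
        r = X - m0[:, None] * f
        rss = np.sum(r * r, axis=1)
        if return_m0:
            return rss, m0
        return rss

    def predict(self, X=None):
        """Reconstructed noiseless signals at the acquisition angles."""
        f = np.stack([spgr_signal(1.0, np.where(self.valid_, self.t1_, 1.0), a, self.tr)
                      for a in self.angles_deg], axis=-1)
        out = self.m0_[:, None] * f
        out[~self.valid_] = np.nan
        return out


def fit_t1_vfa(series: VfaSeries) -> R1Map:
    """Fit (M0, T1) voxel by voxel inside ``series.mask``.

    Voxels whose linearized slope is non-physical (E1 outside (0, 1)) or
    that are identically zero are flagged invalid and carried as NaN,
    never as zeros.
    """
    if not np.any(series.mask):
        raise ValueError("mask is empty")
    shape = series.signal.shape[:-1]
    flat = series.signal[series.mask]
    est = VfaT1Fitter(angles_deg=series.angles, tr=series.protocol.tr_vfa).fit(flat)

    def _expand(values, fill=np.nan, dtype=float):
        out = np.full(shape, fill, dtype=dtype)
        out[series.mask] = values
        return out

    return R1Map(
        r1_pre=_expand(est.r1_),
        m0=_expand(est.m0_),
        fit_residual=_expand(est.residual_),
        valid=_expand(est.valid_, fill=False, dtype=bool),
    )
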