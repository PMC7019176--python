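"""Voxelwise Tofts-Kermode pharmacokinetic fitting.

The standard (two-parameter) Tofts model is fitted to each enhanced voxel's
concentration curve by bounded nonlinear least squares against the
closed-form solution under the fixed bi-exponential population AIF.  The
residual surface is multimodal at low SNR, so initialization is multi-start
on a coarse (Ktrans, ve) grid: the residual sum of squares is evaluated at
every grid start, the best few starts are refined with a trust-region
solver, and the lowest final RSS wins (ties broken toward the smaller
Ktrans).  kep = Ktrans/ve is reported as a derived quantity, never fitted
independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .conc import ConcMaps
from .kinetics import DEGENERATE_RATE_TOL, tissue_concentration
from .protocol import AifParams

__all__ = ["ToftsFit", "ToftsFitter", "fit_tofts", "pk_map"]

DEFAULT_START_GRID = ((0.01, 0.1, 0.5), (0.1, 0.3, 0.6))  # Ktrans min^-1 x ve


@dataclass
class ToftsFit:
    """Per-voxel Tofts parameter maps; NaN marks voxels outside the fit set."""

    ktrans: np.ndarray     # min^-1
    ve: np.ndarray         # fraction
    kep: np.ndarray        # min^-1, = ktrans/ve
    rss: np.ndarray        # mM^2
    converged: np.ndarray  # bool
    fitted: np.ndarray     # bool: voxel was in the enhanced & valid set


class ToftsFitter(BaseEstimator):
    """Bounded multi-start Tofts-Kermode estimator for concentration curves.

    Parameters
    ----------
    times_s : array — frame times in seconds.
    t0_s : float — injection time in seconds.
    aif : AifParams — fixed population arterial input function.
    ktrans_bounds, ve_bounds : (lo, hi) box constraints; Ktrans in min^-1.
    start_grid : (ktrans_starts, ve_starts) multi-start initialization grid.
    n_restarts : int — number of best-RSS grid starts refined per curve.

    After ``fit(X)`` on curves ``X`` of shape (n_curves, n_times), in mM
    (NaN entries are treated as missing frames and excluded):
    ``ktrans_``, ``ve_``, ``kep_``, ``rss_``, ``converged_``.
    """

    def __init__(self, times_s=None, t0_s: float = 120.0,
                 aif: AifParams = AifParams(),
                 ktrans_bounds=(0.0, 5.0), ve_bounds=(1e-3, 1.0),
                 start_grid=DEFAULT_START_GRID, n_restarts: int = 2):
        self.times_s = times_s
        self.t0_s = t0_s
        self.aif = aif
        self.ktrans_bounds = ktrans_bounds
        self.ve_bounds = ve_bounds
        self.start_grid = start_grid
        self.n_restarts = n_restarts

    def _model_factory(self):
        """Closure evaluating the closed-form curve with AIF terms cached."""
        t = np.asarray(self.times_s, dtype=float)
        d = np.clip(t - self.t0_s, 0.0, None)
        post = (t >= self.t0_s).astype(float)
        terms = ((self.aif.a1, self.aif.tau1, np.exp(-d / self.aif.tau1)),
                 (self.aif.a2, self.aif.tau2, np.exp(-d / self.aif.tau2)))

        def model(ktrans, ve):
            if ktrans <= 0:
                return np.zeros_like(d)
            kt_s = ktrans / 60.0
            kep = kt_s / ve
            e_kep = np.exp(-kep * d)
            acc = 0.0
            for a_i, tau_i, e_tau in terms:
                gap = kep - 1.0 / tau_i
                if abs(gap) < DEGENERATE_RATE_TOL:
                    acc = acc + a_i * d * e_kep
                else:
                    acc = acc + a_i * (e_tau - e_kep) / gap
            return kt_s * acc * post

        return model

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        t = np.asarray(self.times_s, dtype=float)
        if X.shape[1] != t.size:
            raise ValueError("X must be (n_curves, n_times)")
        if np.sum(t >= self.t0_s) < 10:
            raise ValueError("need at least 10 post-injection frames")

        model = self._model_factory()
        kt_starts, ve_starts = self.start_grid
        starts = sorted((float(k), float(v)) for k in kt_starts for v in ve_starts)
        start_curves = np.stack([model(k, v) for k, v in starts])  # (n_s, n_t)

        finite = np.isfinite(X)
        X0 = np.where(finite, X, 0.0)
        # RSS at every start, missing frames excluded (stable argsort keeps
        # the smallest-Ktrans start first on ties).
        resid = X0[:, None, :] - start_curves[None, :, :] * finite[:, None, :]
        start_rss = np.sum(resid * resid, axis=2)
        order = np.argsort(start_rss, axis=1, kind="stable")

        lb = np.array([self.ktrans_bounds[0], self.ve_bounds[0]])
        ub = np.array([self.ktrans_bounds[1], self.ve_bounds[1]])
        n = X.shape[0]
        ktrans = np.empty(n)
        ve = np.empty(n)
        rss = np.empty(n)
        converged = np.zeros(n, dtype=bool)

        for i in range(n):
            yobs = X0[i]
            fin = finite[i]

            def residual(p):
                return (model(p[0], p[1]) - yobs) * fin

            best = None
            for j in order[i, :max(1, self.n_restarts)]:
                p0 = np.clip(starts[j], lb, ub)
                sol = least_squares(residual, p0, bounds=(lb, ub),
                                    method="trf", ftol=1e-12, xtol=1e-10,
                                    gtol=1e-10, x_scale=[0.1, 0.1])
                cand = (sol.cost * 2.0, sol.x[0], sol.x[1], sol.status > 0)
                if best is None or cand[0] < best[0] - 1e-15 or (
                        abs(cand[0] - best[0]) <= 1e-15 and cand[1] < best[1]):
                    best = cand
            # Lower-bound candidate Ktrans = 0 (zero curve): on a tie the
            # smaller Ktrans wins, which pins all-zero curves to exactly 0.
            rss_zero = float(np.sum((yobs * fin) ** 2))
            if rss_zero <= best[0] + 1e-15:
                best = (rss_zero, 0.0, best[2], True)
            rss[i], ktrans[i], ve[i], converged[i] = best[0], best[1], best[2], best[3]

        self.ktrans_ = ktrans
        self.ve_ = ve
        self.kep_ = ktrans / ve
        self.rss_ = rss
        self.converged_ = converged
        return self

    def predict(self, X=None):
        """Model concentration curves at the fitted parameters."""
        model = self._model_factory()
        return np.stack([model(k, v) for k, v in zip(self.ktrans_, self.ve_)])


def fit_tofts(conc_curve, times, aif: AifParams, t0: float,
              n_restarts: int = 2):
    """Fit (Ktrans, ve) to one concentration curve.

    Returns ``(ktrans, ve, rss, converged)`` with Ktrans in min^-1.  NaN
    frames are excluded from the objective.
    """
    est = ToftsFitter(times_s=times, t0_s=t0, aif=aif,
                      n_restarts=n_restarts).fit(np.atleast_2d(conc_curve))
    return float(est.ktrans_[0]), float(est.ve_[0]), float(est.rss_[0]), bool(est.converged_[0])


def pk_map(conc: ConcMaps, aif: AifParams, n_restarts: int = 2) -> ToftsFit:
    """Fit the Tofts model over the enhanced & valid voxels of a study.

    Non-enhanced voxels (and voxels without a valid pre-contrast R1) are
    never fitted: their parameters are carried as NaN — undefined, which is
    deliberately distinct from Ktrans = 0.
    """
    sel = conc.enhanced & conc.valid
    shape = sel.shape
    out = {k: np.full(shape, np.nan) for k in ("ktrans", "ve", "kep", "rss")}
    conv = np.zeros(shape, dtype=bool)
    if not np.any(sel):
        warnings.warn("no enhanced voxels to fit; returning empty maps")
        return ToftsFit(out["ktrans"], out["ve"], out["kep"], out["rss"],
                        conv, sel)

    est = ToftsFitter(times_s=conc.times, t0_s=conc.t0, aif=aif,
                      n_restarts=n_restarts).fit(conc.conc[sel])
    out["ktrans"][sel] = est.ktrans_
    out["ve"][sel] = est.ve_
    out["kep"][sel] = est.kep_
    out["rss"][sel] = est.rss_
    conv[sel] = est.converged_
    return ToftsFit(out["ktrans"], out["ve"], out["kep"], out["rss"], conv, sel)
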