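"""Closed-form signal and tracer-kinetic models.

The forward chain is

    AIF Cp(t)  --Tofts-Kermode-->  tissue C(t)  --relaxivity-->  R1(t)
               --spoiled gradient echo-->  signal S(t)

and every stage here has an exact algebraic inverse or a closed-form
solution, which is what makes voxelwise parameter recovery testable.

Unit convention: times in seconds, concentrations in mM, Ktrans in min^-1
(converted to s^-1 internally), flip angles in degrees.
"""

from __future__ import annotations

import numpy as np

from .protocol import AifParams

# Switch to the analytic limit of the Tofts convolution when kep approaches
# 1/tau_i; below this gap (s^-1) the generic expression cancels
# catastrophically.
DEGENERATE_RATE_TOL = 1e-8


def aif_concentration(params: AifParams, t, t0: float):
    """Plasma concentration of the bi-exponential AIF at times ``t`` (s).

    Zero before the injection time ``t0``; for t >= t0 the sum
    A1 exp(-(t-t0)/tau1) + A2 exp(-(t-t0)/tau2), continuous from the right
    at t0 (value A1 + A2).
    """
    t = np.asarray(t, dtype=float)
    dt = t - t0
    out = np.zeros_like(dt)
    post = dt >= 0
    d = dt[post]
    out[post] = params.a1 * np.exp(-d / params.tau1) + params.a2 * np.exp(-d / params.tau2)
    return out


def tissue_concentration(ktrans: float, ve: float, aif: AifParams, t, t0: float):
    """Tofts-Kermode tissue concentration curve, closed form.

    C(t) = Ktrans * sum_i A_i [exp(-(t-t0)/tau_i) - exp(-kep (t-t0))]
                          / (kep - 1/tau_i),          kep = Ktrans/ve,
    with the analytic limit A_i Ktrans (t-t0) exp(-kep (t-t0)) when
    kep -> 1/tau_i.  ``ktrans`` in min^-1, ``ve`` a fraction in (0, 1].

    Parameters with ``ktrans == 0`` give the zero curve for any ``ve``;
    ``ve == 0`` with positive ``ktrans`` is rejected (kep undefined).
    """
    t = np.asarray(t, dtype=float)
    if ktrans < 0:
        raise ValueError("ktrans must be >= 0")
    if ktrans == 0:
        return np.zeros_like(t)
    if ve <= 0 or ve > 1:
        raise ValueError("ve must lie in (0, 1] when ktrans > 0")

    ktrans_s = ktrans / 60.0
    kep_s = ktrans_s / ve
    dt = t - t0
    post = dt >= 0
    d = dt[post]
    out = np.zeros_like(t)
    acc = np.zeros_like(d)
    e_kep = np.exp(-kep_s * d)
    for a_i, tau_i in ((aif.a1, aif.tau1), (aif.a2, aif.tau2)):
        rate_gap = kep_s - 1.0 / tau_i
        if abs(rate_gap) < DEGENERATE_RATE_TOL:
            acc += a_i * d * e_kep
        else:
            acc += a_i * (np.exp(-d / tau_i) - e_kep) / rate_gap
    out[post] = ktrans_s * acc
    return out


def spgr_signal(m0, t1, alpha: float, tr: float):
    """Steady-state spoiled gradient echo (FLASH) signal.

    S = M0 sin(a) (1 - E1) / (1 - E1 cos(a)),  E1 = exp(-TR/T1).

    ``m0`` and ``t1`` may be arrays (broadcast); ``alpha`` in degrees,
    ``tr`` and ``t1`` in seconds.  TE/T2* decay is a constant factor at
    fixed echo time and is absorbed into M0.
    """
    m0 = np.asarray(m0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    if tr <= 0:
        raise ValueError("tr must be > 0")
    if not (0.0 < alpha < 90.0):
        raise ValueError("alpha must lie strictly between 0 and 90 degrees")
    if np.any(t1 <= 0):
        raise ValueError("t1 must be > 0")
    a = np.deg2rad(alpha)
    e1 = np.exp(-tr / t1)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def invert_spgr(signal, m0, alpha: float, tr: float):
    """Exact algebraic inverse of :func:`spgr_signal`, returning R1 (s^-1).

    E1 = (M0 sin(a) - S) / (M0 sin(a) - S cos(a));  R1 = -ln(E1)/TR.

    Signals outside the invertible range (0, M0 sin(a)), where E1 would
    leave (0, 1), come back as NaN — a carrier value, not an exception —
    so that non-invertible frames can be excluded downstream.  S == 0 maps
    to the E1 = 1 boundary (R1 = 0) and is likewise flagged NaN.
    """
    signal = np.asarray(signal, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    a = np.deg2rad(alpha)
    sin_a, cos_a = np.sin(a), np.cos(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (m0 * sin_a - signal) / (m0 * sin_a - signal * cos_a)
        r1 = np.where((e1 > 0.0) & (e1 < 1.0), -np.log(np.clip(e1, 1e-300, None)) / tr, np.nan)
    return r1
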