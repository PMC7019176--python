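"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive every quantity from first
principles (fine-grid numerics, literal rule transcription, exhaustive
search) without calling the closed-form code paths they are used to check.
"""

import numpy as np
import pytest
from scipy.signal import lfilter

from pdtvasc import AifParams, ScanProtocol


@pytest.fixture(scope="session")
def protocol():
    return ScanProtocol()


@pytest.fixture(scope="session")
def aif():
    return AifParams()


def biexp_aif(aif, t, t0):
    """Term-by-term AIF evaluation, independent of the package."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    post = t >= t0
    d = t[post] - t0
    out[post] = aif.a1 * np.exp(-d / aif.tau1) + aif.a2 * np.exp(-d / aif.tau2)
    return out


def tofts_convolution_oracle(ktrans, ve, aif, t_eval, t0, dt=0.01):
    """Discrete trapezoidal convolution of the AIF with exp(-kep t).

    Exponential-integrator trapezoid recursion on a dt grid starting at the
    injection time, then linear interpolation to the requested times.
    Valid at the degenerate kep = 1/tau_i point without special-casing.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    if ktrans == 0:
        return np.zeros_like(t_eval)
    kt_s = ktrans / 60.0
    kep = kt_s / ve
    t_end = float(t_eval.max())
    n = int(np.ceil((t_end - t0) / dt)) + 1
    tf = t0 + np.arange(n + 1) * dt
    cp = aif.a1 * np.exp(-(tf - t0) / aif.tau1) + aif.a2 * np.exp(-(tf - t0) / aif.tau2)
    e = np.exp(-kep * dt)
    # initial state makes y[0] = 0 (empty integral at the injection time)
    integral, _ = lfilter([dt / 2.0, dt / 2.0 * e], [1.0, -e], cp,
                          zi=np.array([-dt / 2.0 * cp[0]]))
    c_fine = kt_s * integral
    out = np.interp(t_eval, tf, c_fine, left=0.0)
    out[t_eval < t0] = 0.0
    return out


def enhancement_rule_oracle(curve, times, t0):
    """Literal transcription of the enhancement rule; True = enhanced."""
    curve = np.asarray(curve, dtype=float)
    pre = curve[times < t0]
    post = curve[times >= t0]
    sd = float(np.std(pre, ddof=1))
    med = float(np.median(post))
    if sd == 0.0:
        return not (med <= 0.0)
    return not (med < 2.0 * sd)


def average_ranks(x):
    """Average ranks with ties, computed by explicit grouping."""
    x = np.asarray(x)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=float)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_oracle(a, b):
    """Rank-then-Pearson brute force."""
    ra, rb = average_ranks(a), average_ranks(b)
    return float(np.corrcoef(ra, rb)[0, 1])
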