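"""Numba-compiled inner loops for the separation criterion.

The criterion evaluates smoothed-CDF pseudo-observations and
product-Gaussian kernel sums at the sample points themselves, so every
pairwise matrix involved is (anti)symmetric: the Gaussian-CDF matrix
satisfies ``Phi(z_nm) = 1 - Phi(z_mn)`` and the kernel-factor matrices
are symmetric, halving the transcendental work.  These loops avoid the
large temporaries of the vectorized formulation; results agree with the
NumPy path to floating-point roundoff.
"""

from __future__ import annotations

import math

import numba
import numpy as np

_SQRT1_2 = 1.0 / math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


@numba.njit(cache=True, fastmath=True)
def pseudo_obs_self(y: np.ndarray, h: float, rescale: float) -> np.ndarray:
    """rescale * mean_m Phi((y_n - y_m)/h) for every sample n."""
    M = y.size
    acc = np.full(M, 0.5)  # diagonal term Phi(0)
    inv = _SQRT1_2 / h
    for i in range(M):
        yi = y[i]
        for j in range(i + 1, M):
            z = (yi - y[j]) * inv
            if z > 6.0:  # Phi saturates beyond machine precision
                acc[i] += 1.0
            elif z >= -6.0:
                phi = 0.5 * (1.0 + math.erf(z))
                acc[i] += phi
                acc[j] += 1.0 - phi
            else:
                acc[j] += 1.0
    out = acc * (rescale / M)
    for i in range(M):
        if out[i] < 1e-12:
            out[i] = 1e-12
        elif out[i] > 1.0 - 1e-12:
            out[i] = 1.0 - 1e-12
    return out


@numba.njit(cache=True, fastmath=True)
def terms_self(u: np.ndarray, H: float, reflect: bool) -> np.ndarray:
    """Symmetric kernel-factor matrix k((u_m - u_n)/H)/H (+ mirror images)."""
    M = u.size
    T = np.empty((M, M))
    c = _INV_SQRT_2PI / H
    inv2H2 = 0.5 / (H * H)
    cut = 8.5 * 8.5 / 2.0  # skip exp(-z^2/2) once z > 8.5 (value < 3e-16)
    for i in range(M):
        ui = u[i]
        for j in range(i, M):
            d = (u[j] - ui) * (u[j] - ui) * inv2H2
            t = math.exp(-d) if d < cut else 0.0
            if reflect:
                s0 = u[j] + ui
                s0 = s0 * s0 * inv2H2
                if s0 < cut:
                    t += math.exp(-s0)
                s1 = 2.0 - u[j] - ui
                s1 = s1 * s1 * inv2H2
                if s1 < cut:
                    t += math.exp(-s1)
            t *= c
            T[i, j] = t
            T[j, i] = t
    return T


@numba.njit(cache=True, fastmath=True)
def product_mean2(T0: np.ndarray, T1: np.ndarray) -> np.ndarray:
    """Row means of the elementwise product of two square matrices."""
    M = T0.shape[0]
    out = np.empty(M)
    for i in range(M):
        s = 0.0
        for j in range(M):
            s += T0[i, j] * T1[i, j]
        out[i] = s / M
    return out
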