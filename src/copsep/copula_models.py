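"""Parametric bivariate copula families: product, Ali-Mikhail-Haq, Clayton.

Each family provides a density on the open unit square, a CDF, an exact
sampler by conditional-distribution inversion, and the theoretical
Kendall's tau.  The copula density of a random pair ``(Y1, Y2)`` is the
joint density of ``(F1(Y1), F2(Y2))``; it equals 1 everywhere iff the
components are independent, which is what makes it the natural reference
object for the separation criterion.

Parameter domains: AMH requires ``theta`` in ``[-1, 1)``; Clayton is
restricted to ``theta > 0`` (positive dependence).  The product copula
takes no parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

__all__ = [
    "CopulaSpec",
    "copula_density",
    "copula_cdf",
    "copula_sample",
    "kendall_tau_theoretical",
    "kendall_tau_quadrature",
    "theta_from_tau",
]

#: densities are only evaluated strictly inside (eps, 1-eps)
BOUNDARY_EPS = 1e-12

_FAMILIES = ("product", "amh", "clayton")


@dataclass(frozen=True)
class CopulaSpec:
    """A copula family together with its dependence parameter.

    Parameters
    ----------
    family:
        One of ``"product"``, ``"amh"``, ``"clayton"``.
    theta:
        Dependence parameter. Ignored (must be ``None``) for the product
        copula; in ``[-1, 1)`` for AMH; strictly positive for Clayton.
    """

    family: str
    theta: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown copula family {self.family!r}; expected one of {_FAMILIES}")
        if self.family == "product":
            if self.theta is not None:
                raise ValueError("product copula takes no theta")
        elif self.theta is None:
            raise ValueError(f"{self.family} copula requires theta")
        elif self.family == "amh":
            if not (-1.0 <= self.theta < 1.0):
                raise ValueError(f"AMH requires theta in [-1, 1), got {self.theta}")
        elif self.family == "clayton":
            if not self.theta > 0.0:
                raise ValueError(f"Clayton requires theta > 0, got {self.theta}")


def _check_interior(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.shape[-1] != 2:
        raise ValueError(f"expected points in (0,1)^2, got trailing dimension {u.shape[-1]}")
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("points must lie strictly inside (0,1)^2")
    return np.clip(u, BOUNDARY_EPS, 1.0 - BOUNDARY_EPS)


def copula_density(spec: CopulaSpec, u) -> np.ndarray | float:
    """Copula density ``c(u1, u2)`` evaluated at interior points.

    ``u`` is a point or array of points with trailing dimension 2.
    Returns a scalar for a single point, an array otherwise.
    """
    pts = _check_interior(u)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    x, y = pts[..., 0], pts[..., 1]
    if spec.family == "product":
        out = np.ones_like(x)
    elif spec.family == "amh":
        th = spec.theta
        d = 1.0 - th * (1.0 - x) * (1.0 - y)
        out = (1.0 + th * ((1.0 + x) * (1.0 + y) - 3.0) + th**2 * (1.0 - x) * (1.0 - y)) / d**3
    else:  # clayton
        th = spec.theta
        s = x ** (-th) + y ** (-th) - 1.0
        out = (1.0 + th) * (x * y) ** (-1.0 - th) * s ** (-2.0 - 1.0 / th)
    return float(out[0]) if scalar else out


def copula_cdf(spec: CopulaSpec, u) -> np.ndarray | float:
    """Copula CDF ``C(u1, u2)`` at interior points."""
    pts = _check_interior(u)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    x, y = pts[..., 0], pts[..., 1]
    if spec.family == "product":
        out = x * y
    elif spec.family == "amh":
        out = x * y / (1.0 - spec.theta * (1.0 - x) * (1.0 - y))
    else:
        th = spec.theta
        out = (x ** (-th) + y ** (-th) - 1.0) ** (-1.0 / th)
    return float(out[0]) if scalar else out


def copula_sample(spec: CopulaSpec, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. pairs from the copula; returns an ``n x 2`` array.

    Sampling is by conditional-distribution inversion: ``U ~ Uniform``,
    ``W ~ Uniform``, and ``V`` solves ``C_{2|1}(V | U) = W``.  Both the
    AMH and Clayton conditional quantiles are available in closed form
    (the AMH one is the root of a quadratic), so no rejection step is
    needed and output is bit-reproducible under a seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    w = rng.uniform(size=n)
    if spec.family == "product":
        v = w
    elif spec.family == "amh":
        v = _amh_conditional_quantile(u, w, spec.theta)
    else:
        th = spec.theta
        # invert dC/du = u^{-th-1} (u^-th + v^-th - 1)^{-1/th - 1} = w
        v = (u ** (-th) * (w ** (-th / (1.0 + th)) - 1.0) + 1.0) ** (-1.0 / th)
    eps = BOUNDARY_EPS
    return np.column_stack([np.clip(u, eps, 1 - eps), np.clip(v, eps, 1 - eps)])


def _amh_conditional_quantile(u: np.ndarray, w: np.ndarray, th: float) -> np.ndarray:
    """Solve C_{2|1}(v|u) = w for v. The condition is a quadratic in v."""
    if th == 0.0:
        return w.copy()
    a = 1.0 - u
    a2 = th**2 * a**2 * w - th
    a1 = 2.0 * th * a * w * (1.0 - th * a) - (1.0 - th)
    a0 = w * (1.0 - th * a) ** 2
    disc = np.sqrt(np.maximum(a1**2 - 4.0 * a2 * a0, 0.0))
    # numerically stable quadratic roots; exactly one lies in [0, 1]
    q = -0.5 * (a1 + np.sign(a1) * disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(a2 != 0, q / np.where(a2 != 0, a2, 1.0), np.inf)
        r2 = np.where(q != 0, a0 / np.where(q != 0, q, 1.0), np.inf)
    v = np.where((r1 >= 0.0) & (r1 <= 1.0), r1, r2)
    return np.clip(v, 0.0, 1.0)


def kendall_tau_theoretical(spec: CopulaSpec) -> float:
    """Population Kendall's tau, ``tau = 4 * E[C(U, V)] - 1``.

    Closed forms: 0 for the product copula, ``theta / (theta + 2)`` for
    Clayton, and for AMH
    ``(3*theta - 2)/(3*theta) - 2*(1-theta)^2 * log(1-theta) / (3*theta^2)``.
    """
    if spec.family == "product":
        return 0.0
    th = spec.theta
    if spec.family == "clayton":
        return th / (th + 2.0)
    if th == 0.0:
        return 0.0
    return (3.0 * th - 2.0) / (3.0 * th) - 2.0 * (1.0 - th) ** 2 * np.log1p(-th) / (3.0 * th**2)


def kendall_tau_quadrature(spec: CopulaSpec, tol: float = 1e-6) -> float:
    """Kendall's tau by adaptive quadrature of ``4 * iint C c du dv - 1``.

    Slower than the closed forms but family-agnostic; accurate to
    roughly ``tol`` absolute error.
    """
    def integrand(y: float, x: float) -> float:
        pt = np.array([x, y])
        return float(copula_cdf(spec, pt)) * float(copula_density(spec, pt))

    eps = 1e-9
    val, _ = integrate.dblquad(integrand, eps, 1 - eps, eps, 1 - eps, epsabs=tol, epsrel=tol)
    return 4.0 * val - 1.0


def theta_from_tau(family: str, tau: float) -> float:
    """Invert the tau(theta) map of a family (method-of-moments estimate).

    Clayton: ``theta = 2*tau/(1 - tau)`` (requires ``tau > 0``).
    AMH: 1-D root find on ``[-1, 1)``; AMH tau is confined to roughly
    ``[-0.1817, 1/3)``, so ``tau`` outside that range is clamped.
    """
    if family == "product":
        return 0.0
    if family == "clayton":
        if tau <= 0.0:
            raise ValueError("Clayton requires positive dependence (tau > 0)")
        if tau >= 1.0:
            raise ValueError("tau must be < 1")
        return 2.0 * tau / (1.0 - tau)
    if family == "amh":
        from scipy.optimize import brentq

        lo, hi = -1.0 + 1e-10, 1.0 - 1e-10
        tau_lo = kendall_tau_theoretical(CopulaSpec("amh", lo))
        tau_hi = kendall_tau_theoretical(CopulaSpec("amh", hi))
        t = float(np.clip(tau, tau_lo + 1e-9, tau_hi - 1e-9))
        return float(brentq(lambda th: kendall_tau_theoretical(CopulaSpec("amh", th)) - t, lo, hi))
    raise ValueError(f"unknown family {family!r}")
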