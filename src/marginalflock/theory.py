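"""Analytic predictions of the flocking model with linear and marginal control.

Quasi-equilibrium theory (fixed interaction network, deep ordered phase)
yields closed or numerically evaluable predictions:

* correlation length with linear control, ``xi_sp = r1 sqrt(J n_c / g)``
  -- small stiffness g means long-range speed correlations, so
  scale-free behaviour up to size L requires ``g << a / L^2``;
* distribution of the group mean speed s and its typical (modal) value
  for both controls -- the ``s^2`` phase-space prefactor pushes the mode
  of weakly confined groups above v0 (entropic speed boost), with
  small-N exponent 1/2 for linear control and 1/8 for marginal control;
* the "stiffness wedge" ``b/L^3 << g << a/L^2`` that a size-tuned linear
  stiffness would have to occupy to grant both scale-free correlations
  and a bounded group speed;
* the low-noise divergence ``xi_sp ~ T^(-1/2)`` of the marginal theory,
  whose zero-temperature critical point makes scale-free correlations
  compatible with a finite confinement amplitude lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

__all__ = [
    "WedgeInputs",
    "TheoryPrediction",
    "xi_linear",
    "pdf_mean_speed_linear",
    "s_typical_linear",
    "pdf_mean_speed_marginal",
    "s_typical_marginal",
    "marginal_speed_asymptotics",
    "stiffness_wedge",
    "xi_marginal_scaling",
    "log_slope",
]


@dataclass(frozen=True)
class WedgeInputs:
    """Size-independent constants entering the stiffness-wedge bounds.

    ``a = r1^2 J n_c`` controls the upper (correlation) bound and
    ``b = r1^3 T / v0^2`` the lower (speed) bound.  ``margin`` makes the
    asymptotic inequalities operational: the admissible interval is
    ``[margin * b / L_min^3, a / (margin * L_max^2)]``.
    """

    L_min: float
    L_max: float
    r1: float
    J: float
    n_c: float
    T: float
    v0: float
    margin: float = 10.0

    def __post_init__(self) -> None:
        if self.L_min > self.L_max:
            raise ValueError("L_min must be <= L_max")
        if min(self.L_min, self.r1, self.J, self.n_c, self.T, self.v0) <= 0:
            raise ValueError("all wedge inputs must be > 0")
        if self.margin < 1:
            raise ValueError("margin must be >= 1")

    @property
    def a(self) -> float:
        return self.r1**2 * self.J * self.n_c

    @property
    def b(self) -> float:
        return self.r1**3 * self.T / self.v0**2


@dataclass
class TheoryPrediction:
    """A named analytic output together with the parameters that produced it."""

    quantity: str
    value: float
    params: dict = field(default_factory=dict)


def _check_positive(**kwargs: float) -> None:
    for name, val in kwargs.items():
        if val <= 0:
            raise ValueError(f"{name} must be > 0 (got {val})")


def xi_linear(r1: float, J: float, n_c: float, g: float) -> float:
    """Bulk speed-correlation length with linear control, ``r1 sqrt(J n_c / g)``.

    Strictly decreasing in the stiffness g; the g -> 0 limit is the
    critical point where the correlation length diverges.
    """
    _check_positive(r1=r1, J=J, n_c=n_c)
    if g <= 0:
        raise ValueError("xi diverges as g -> 0: no finite prediction for g <= 0")
    return r1 * np.sqrt(J * n_c / g)


def _s_max_linear(N: float, g: float, T: float, v0: float) -> float:
    sigma = np.sqrt(T / (2.0 * N * g))
    return s_typical_linear(N, g, T, v0) + 15.0 * sigma


def _neg_log_pdf_linear(s: float, N: float, g: float, T: float, v0: float) -> float:
    return -2.0 * np.log(s) + (N * g / T) * (s - v0) ** 2


def pdf_mean_speed_linear(s, N: float, g: float, T: float, v0: float):
    """Normalized density of the group mean speed under linear control.

    ``P(s) = Z^-1 s^2 exp[-(N g / T)(s - v0)^2]``; the normalization is
    computed by adaptive quadrature on [0, s_max] with s_max far enough
    into the Gaussian tail that the truncated mass is negligible.
    """
    _check_positive(N=N, g=g, T=T, v0=v0)
    s = np.asarray(s, dtype=float)
    if (s < 0).any():
        raise ValueError("mean speed s must be >= 0")
    smax = _s_max_linear(N, g, T, v0)
    z, _ = quad(lambda x: np.exp(-_neg_log_pdf_linear(x, N, g, T, v0)), 0.0, smax,
                points=[v0, s_typical_linear(N, g, T, v0)], limit=200)
    if not np.isfinite(z) or z <= 0:
        raise ValueError("non-normalizable parameters for the linear mean-speed density")
    out = np.where(s > 0, np.exp(-_neg_log_pdf_linear(np.where(s > 0, s, 1.0), N, g, T, v0)), 0.0) / z
    return out if out.ndim else float(out)


def s_typical_linear(N: float, g: float, T: float, v0: float) -> float:
    """Mode of the linear-control mean-speed density (closed form).

    ``(v0/2)(1 + sqrt(1 + 4T/(N g v0^2)))``: always above v0 for T > 0,
    approaching v0 as N -> infinity, and growing like sqrt(T/(N g)) when
    the confinement N g is weak -- the entropic speed boost.
    """
    _check_positive(N=N, g=g, v0=v0)
    if T < 0:
        raise ValueError("T must be >= 0")
    return 0.5 * v0 * (1.0 + np.sqrt(1.0 + 4.0 * T / (N * g * v0**2)))


def _s_max_marginal(N: float, lam: float, T: float, v0: float) -> float:
    return v0 * max(10.0, 5.0 + 10.0 * (T / (N * lam * v0**2)) ** 0.125)


def _neg_log_pdf_marginal(s: float, N: float, lam: float, T: float, v0: float) -> float:
    return -2.0 * np.log(s) + (N * lam / (T * v0**6)) * (v0**2 - s * s) ** 4


def pdf_mean_speed_marginal(s, N: float, lam: float, T: float, v0: float):
    """Normalized density of the group mean speed under marginal control.

    ``P(s) = Z^-1 s^2 exp[-(N lam / (T v0^6))(v0^2 - s^2)^4]``.  The
    quartic power in the exponent suppresses the entropic push of the
    s^2 prefactor far more sharply than the linear theory.
    """
    _check_positive(N=N, lam=lam, T=T, v0=v0)
    s = np.asarray(s, dtype=float)
    if (s < 0).any():
        raise ValueError("mean speed s must be >= 0")
    smax = _s_max_marginal(N, lam, T, v0)
    z, _ = quad(lambda x: np.exp(-_neg_log_pdf_marginal(x, N, lam, T, v0)), 0.0, smax,
                points=[0.5 * v0, v0, 1.5 * v0], limit=200)
    if not np.isfinite(z) or z <= 0:
        raise ValueError("non-normalizable parameters for the marginal mean-speed density")
    out = np.where(s > 0, np.exp(-_neg_log_pdf_marginal(np.where(s > 0, s, 1.0), N, lam, T, v0)), 0.0) / z
    return out if out.ndim else float(out)


def s_typical_marginal(N: float, lam: float, T: float, v0: float) -> float:
    """Mode of the marginal-control mean-speed density, by 1-D maximization.

    The density is unimodal with its mode above v0; the mode is always
    located numerically (the printed asymptotic branches are exposed
    separately by :func:`marginal_speed_asymptotics`, since they are
    approximations).
    """
    _check_positive(N=N, lam=lam, T=T, v0=v0)
    smax = _s_max_marginal(N, lam, T, v0)
    res = minimize_scalar(
        lambda s: _neg_log_pdf_marginal(s, N, lam, T, v0),
        bounds=(1e-12 * smax, smax), method="bounded",
        options={"xatol": 1e-12 * smax, "maxiter": 500})
    if not res.success:
        raise RuntimeError("mode search for the marginal mean-speed density did not converge")
    return float(res.x)


def marginal_speed_asymptotics(N: float, lam: float, T: float, v0: float) -> dict:
    """Asymptotic branches of the marginal typical speed and the crossover size.

    Below the crossover ``N* = T / (lam v0^2)`` the typical speed grows
    like ``v0 (T / (4 N lam v0^2))^{1/8}``; above it, it settles at v0.
    """
    _check_positive(N=N, lam=lam, T=T, v0=v0)
    return {
        "crossover_N": T / (lam * v0**2),
        "large_N": v0,
        "small_N": v0 * (T / (4.0 * N * lam * v0**2)) ** 0.125,
    }


def stiffness_wedge(w: WedgeInputs) -> Optional[tuple[float, float]]:
    """Admissible interval of the linear stiffness g, or None when empty.

    Returns ``[m b / L_min^3, a / (m L_max^2)]`` (m the margin factor)
    when the lower bound is below the upper one.  Shrinking L_min or
    growing L_max only ever narrows the interval: the wedge closes for a
    wide enough spectrum of group sizes, which is the tuning obstruction
    of linear control.
    """
    lo = w.margin * w.b / w.L_min**3
    hi = w.a / (w.margin * w.L_max**2)
    if lo < hi:
        return (lo, hi)
    return None


def xi_marginal_scaling(T: float, prefactor: float = 1.0) -> float:
    """Low-noise divergence of the marginal correlation length, ``c T^(-1/2)``.

    The marginal theory has a zero-temperature critical point: entropy
    alone provides the curvature of the renormalized potential, so the
    correlation length grows without bound as the noise is reduced.
    Quartering T doubles xi.
    """
    _check_positive(prefactor=prefactor)
    if T <= 0:
        raise ValueError("xi diverges as T -> 0: no finite prediction for T <= 0")
    return prefactor / np.sqrt(T)


def log_slope(x, y) -> float:
    """Least-squares slope of log(y) against log(x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("log-log slope needs strictly positive data")
    return float(np.polyfit(np.log(x), np.log(y), 1)[0])
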