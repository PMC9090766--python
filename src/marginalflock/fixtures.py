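"""Synthetic flocks and correlation curves with known correlation structure.

These generators provide ground truth for the correlation estimators:
lattice flocks with planted speed-fluctuation patterns whose zero
crossing is known by construction, and sampled correlation curves of
known analytic form (linear, exponential, cosine decay) whose integral
correlation length has a closed expression.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .observables import CorrelationCurve
from .simulate import BoxGeometry, ParticleState, init_lattice

__all__ = ["generate_planted_flock", "generate_correlation_fixture"]

_PATTERNS = ("two_domain", "sinusoidal", "linear_gradient")
_FORMS = ("linear", "exponential", "cosine")


def generate_planted_flock(L: float, spacing: float = 1.0, v0: float = 1.0,
                           pattern: str = "two_domain", amplitude: float = 0.1,
                           rng: Optional[np.random.Generator] = None,
                           wavelength: Optional[float] = None) -> ParticleState:
    """Aligned lattice flock with a planted speed-fluctuation pattern.

    Agents sit on a cubic lattice in a cubic box of side L, all flying
    along +z at speed ``v0 + dv_i``.  The fluctuation pattern varies
    along the first axis:

    * ``two_domain``      -- +a in the half-box x < L/2, -a in the other
      (two correlated domains of size L/2);
    * ``sinusoidal``      -- ``a sin(2 pi x / wavelength)`` (default
      wavelength L);
    * ``linear_gradient`` -- ``a (2x/L - 1)``.

    All patterns are mean-zero by construction (residual mean removed).
    When ``rng`` is given, positions get a small uniform jitter
    (5% of the spacing) that breaks the exact distance degeneracies of
    the lattice.  ``amplitude`` must stay below ``v0`` so speeds remain
    positive.
    """
    if pattern not in _PATTERNS:
        raise ValueError(f"pattern must be one of {_PATTERNS}")
    if amplitude >= v0:
        raise ValueError("amplitude must be < v0 so that all speeds stay positive")
    box = BoxGeometry.cubic(L)
    state = init_lattice(box, spacing=spacing, v0=v0, direction=(0.0, 0.0, 1.0))
    pos = state.positions
    if rng is not None:
        pos = pos + rng.uniform(-0.05 * spacing, 0.05 * spacing, size=pos.shape)
    x = pos[:, 0]
    if pattern == "two_domain":
        dv = np.where(x < L / 2.0, amplitude, -amplitude)
    elif pattern == "sinusoidal":
        lam = wavelength if wavelength is not None else L
        dv = amplitude * np.sin(2.0 * np.pi * x / lam)
    else:
        dv = amplitude * (2.0 * x / L - 1.0)
    dv = dv - dv.mean()
    vel = np.zeros_like(pos)
    vel[:, 2] = v0 + dv
    return ParticleState(0.0, pos, vel)


def generate_correlation_fixture(form: str, scale: float, r_max: float,
                                 bins: int) -> CorrelationCurve:
    """Correlation curve sampled from an analytic decay, with unit pair counts.

    * ``linear``      -- ``C = 1 - r/scale`` (zero crossing at ``scale``;
      the integral estimator gives xi = scale/3);
    * ``exponential`` -- ``C = exp(-r/scale)`` (no crossing; with the
      upper limit set to r_max the estimator recovers xi ~ scale);
    * ``cosine``      -- ``C = cos(pi r / (2 scale))`` (quarter period,
      zero crossing at ``scale``).
    """
    if form not in _FORMS:
        raise ValueError(f"form must be one of {_FORMS}")
    if scale <= 0 or r_max <= 0 or bins < 2:
        raise ValueError("need scale > 0, r_max > 0 and at least 2 bins")
    edges = np.linspace(0.0, r_max, bins + 1)
    r = 0.5 * (edges[:-1] + edges[1:])
    if form == "linear":
        c = 1.0 - r / scale
    elif form == "exponential":
        c = np.exp(-r / scale)
    else:
        c = np.cos(np.pi * r / (2.0 * scale))
    return CorrelationCurve(edges, c, np.ones(bins, dtype=np.int64))
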