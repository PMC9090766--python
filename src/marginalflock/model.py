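"""Cost function, confining potentials and social forces of the flocking model.

The dynamics couples the full velocity vectors of neighbouring agents
(imitation of both flight direction and speed) and confines each agent's
speed around a natural reference value ``v0`` through one of several
speed-control potentials:

* ``linear``   -- harmonic in the speed, ``g (|v| - v0)^2``; generates a
  restoring force proportional to the speed deviation.
* ``quartic``  -- the O(n)-ferromagnet quartic potential in the velocity
  vector, normalized here as ``g (v.v - v0^2)^2 / v0^2`` so that its
  small-fluctuation expansion around ``|v| = v0`` is ``4 g (|v| - v0)^2``,
  i.e. a harmonic control with four times the stiffness.  It is included
  to make explicit that quartic control is not a genuine alternative to
  linear control.
* ``marginal`` -- ``(lambda / v0^6) (v.v - v0^2)^4``.  Its second (and
  third) derivative with respect to the speed vanish at ``v0``: small
  speed fluctuations feel almost no restoring force while large ones are
  suppressed very steeply.

All potentials are rotationally invariant in the velocity vector and
non-negative, vanishing exactly at ``|v| = v0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Control",
    "ModelParams",
    "Adjacency",
    "confining_potential",
    "confining_force",
    "alignment_force",
    "cost_function",
]


class Control(str, Enum):
    """Speed-control flavour."""

    LINEAR = "linear"
    QUARTIC = "quartic"
    MARGINAL = "marginal"
    NONE = "none"


@dataclass(frozen=True)
class ModelParams:
    """Couplings and control choice of the flocking model.

    Parameters
    ----------
    J : float
        Imitation (velocity-alignment) coupling, per unit time.
    g : float
        Stiffness of the linear (or amplitude of the quartic) speed
        control, per unit time.
    lam : float
        Amplitude of the marginal speed control, per unit time.  The
        ``v0**-6`` normalization inside the potential gives ``lam`` the
        same physical dimensions as ``J`` and ``g``.
    T : float
        Strength of the white velocity noise (effective temperature).
    v0 : float
        Natural reference speed (length / time).
    dt : float
        Euler integration step (time).
    control : Control or str
        Which speed-control potential acts on the agents.
    d : int
        Space dimension; only ``d = 3`` is supported.
    """

    J: float = 1.0
    g: float = 0.0
    lam: float = 0.0
    T: float = 0.0
    v0: float = 1.0
    dt: float = 0.01
    control: Control = Control.MARGINAL
    d: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "control", Control(self.control))
        if self.J < 0 or self.g < 0 or self.lam < 0 or self.T < 0:
            raise ValueError("couplings J, g, lambda and noise strength T must be >= 0")
        if self.v0 <= 0:
            raise ValueError("reference speed v0 must be > 0")
        if self.dt <= 0:
            raise ValueError("integration step dt must be > 0")
        if self.d != 3:
            raise ValueError("only d = 3 is supported")


@dataclass
class Adjacency:
    """Symmetric boolean interaction relation on N agents.

    ``matrix[i, j]`` is True when agents i and j interact.  For a metric
    rule the relation is symmetric by construction; for a topological
    rule the raw k-nearest relation may be asymmetric and the stored
    matrix is the symmetrized one (an edge exists if either agent counts
    the other among its nearest neighbours), which keeps the pair term of
    the cost function a well-defined symmetric quadratic form.
    """

    matrix: np.ndarray
    rule: str = ""
    time: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=bool)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if m.diagonal().any():
            raise ValueError("adjacency matrix must have no self-edges")
        if not np.array_equal(m, m.T):
            raise ValueError("stored adjacency must be symmetric")
        self.matrix = m

    @property
    def n_agents(self) -> int:
        return self.matrix.shape[0]

    def degrees(self) -> np.ndarray:
        """Number of interaction partners of each agent."""
        return self.matrix.sum(axis=1)


def confining_potential(v, params: ModelParams) -> float:
    """Speed-control potential energy of a single velocity vector.

    Returns ``g (|v| - v0)^2`` (linear), ``g (v.v - v0^2)^2 / v0^2``
    (quartic) or ``(lam / v0^6) (v.v - v0^2)^4`` (marginal).  The result
    is >= 0, vanishes iff ``|v| = v0`` (for a positive amplitude) and is
    invariant under rotations of ``v``.
    """
    v = np.asarray(v, dtype=float)
    v0 = params.v0
    if params.control is Control.LINEAR:
        return params.g * (np.linalg.norm(v) - v0) ** 2
    v2 = float(v @ v)
    if params.control is Control.QUARTIC:
        return params.g * (v2 - v0**2) ** 2 / v0**2
    if params.control is Control.MARGINAL:
        return params.lam / v0**6 * (v2 - v0**2) ** 4
    raise ValueError("no confining potential defined for control='none'")


def confining_force(v, params: ModelParams) -> np.ndarray:
    """Speed-control force, the negative velocity-gradient of the potential.

    linear:   ``2 g (v/|v|) (v0 - |v|)``  (undefined at |v| = 0)
    quartic:  ``-(4 g / v0^2) (v.v - v0^2) v``
    marginal: ``(8 lam / v0^6) (v0^2 - v.v)^3 v``
    """
    v = np.asarray(v, dtype=float)
    v0 = params.v0
    if params.control is Control.LINEAR:
        speed = float(np.linalg.norm(v))
        if speed == 0.0:
            raise ValueError(
                "linear speed-control force is undefined at zero speed "
                "(the restoring direction v/|v| does not exist)"
            )
        return 2.0 * params.g * (v0 - speed) / speed * v
    v2 = float(v @ v)
    if params.control is Control.QUARTIC:
        return -4.0 * params.g / v0**2 * (v2 - v0**2) * v
    if params.control is Control.MARGINAL:
        return 8.0 * params.lam / v0**6 * (v0**2 - v2) ** 3 * v
    raise ValueError("no confining force defined for control='none'")


def alignment_force(i: int, velocities, adj: Adjacency, J: float) -> np.ndarray:
    """Imitation force on agent ``i``: ``-J sum_j n_ij (v_i - v_j)``.

    For a symmetric adjacency the alignment forces are pairwise
    antisymmetric, so they sum to zero over the whole flock.
    """
    vel = np.atleast_2d(np.asarray(velocities, dtype=float))
    n = vel.shape[0]
    if adj.n_agents != n:
        raise ValueError("adjacency and velocity list sizes do not match")
    if not 0 <= i < n:
        raise IndexError(f"agent index {i} out of range for {n} agents")
    nbr = adj.matrix[i]
    return -J * (int(nbr.sum()) * vel[i] - vel[nbr].sum(axis=0))


def _potential_batch(vel: np.ndarray, params: ModelParams) -> np.ndarray:
    v0 = params.v0
    if params.control is Control.LINEAR:
        return params.g * (np.linalg.norm(vel, axis=1) - v0) ** 2
    v2 = np.einsum("ij,ij->i", vel, vel)
    if params.control is Control.QUARTIC:
        return params.g * (v2 - v0**2) ** 2 / v0**2
    if params.control is Control.MARGINAL:
        return params.lam / v0**6 * (v2 - v0**2) ** 4
    raise ValueError("no confining potential defined for control='none'")


def cost_function(state, adj: Adjacency, params: ModelParams) -> float:
    """Total social cost ``H = (J/2) sum_{i<j} n_ij (v_i - v_j)^2 + sum_i V(v_i)``.

    ``state`` may be a ``ParticleState`` or a plain ``(N, 3)`` velocity
    array.  The pair term is normalized over unordered pairs so that the
    negative gradient of ``H`` with respect to ``v_i`` is exactly
    ``alignment_force(i) + confining_force(v_i)``, i.e. the social force
    integrated by the simulator.  With ``control='none'`` only the
    imitation term contributes.
    """
    vel = np.asarray(getattr(state, "velocities", state), dtype=float)
    if vel.shape[0] != adj.n_agents:
        raise ValueError("adjacency and state sizes do not match")
    diff = vel[:, None, :] - vel[None, :, :]
    pair_sq = np.einsum("ijk,ijk->ij", diff, diff)
    # 1/4 over ordered pairs == 1/2 over unordered pairs
    h = 0.25 * params.J * float((adj.matrix * pair_sq).sum())
    if params.control is not Control.NONE:
        h += float(_potential_batch(vel, params).sum())
    return h
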