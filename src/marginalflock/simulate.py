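"""Time evolution of a flock of self-propelled particles in a periodic box.

Agents live in a fully periodic box, interact with metric (distance
cutoff ``r_c``) or topological (``n_c`` nearest) neighbours, and evolve
by an explicit Euler scheme: positions advance with the pre-update
velocities, velocities receive the imitation force, the speed-control
force and a Gaussian increment of per-component variance ``2 T dt``.
The interaction network is rebuilt from the positions at every step
unless explicitly frozen (the frozen-network mode implements the
quasi-equilibrium approximation valid deep in the ordered phase, where
network rearrangement is much slower than velocity relaxation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .model import Adjacency, Control, ModelParams

__all__ = [
    "BoxGeometry",
    "ParticleState",
    "NeighbourRule",
    "HeterogeneitySpec",
    "Protocol",
    "Trajectory",
    "minimum_image_displacement",
    "build_adjacency",
    "init_lattice",
    "euler_step",
    "run",
    "displacement_sanity",
]

_CONTROL_CODE = {
    Control.NONE: _kernels.CONTROL_NONE,
    Control.LINEAR: _kernels.CONTROL_LINEAR,
    Control.QUARTIC: _kernels.CONTROL_QUARTIC,
    Control.MARGINAL: _kernels.CONTROL_MARGINAL,
}


@dataclass(frozen=True)
class BoxGeometry:
    """Periodic box with side lengths (L1, L2, L3); periodic on all axes."""

    L1: float
    L2: float
    L3: float

    def __post_init__(self) -> None:
        if min(self.L1, self.L2, self.L3) <= 0:
            raise ValueError("all box sides must be > 0")

    @property
    def sides(self) -> np.ndarray:
        return np.array([self.L1, self.L2, self.L3], dtype=float)

    @property
    def volume(self) -> float:
        return self.L1 * self.L2 * self.L3

    @property
    def is_cubic(self) -> bool:
        return self.L1 == self.L2 == self.L3

    @classmethod
    def cubic(cls, L: float) -> "BoxGeometry":
        return cls(L, L, L)

    @classmethod
    def elongated(cls, scale: float) -> "BoxGeometry":
        """Flock-like elongated box with aspect ratio L1/L2 = 6.

        Sides follow (8, 1.33, 0.94) * scale, rounded to integers so the
        box stays commensurate with a unit lattice (real flocks have
        L1/L2 between roughly 6 and 8; the rounded defaults sit at the
        low end of that range).
        """
        sides = np.maximum(np.rint(np.array([8.0, 4.0 / 3.0, 0.94]) * scale), 1.0)
        return cls(*sides)


@dataclass
class ParticleState:
    """Positions and velocities of N agents at a given time."""

    time: float
    positions: np.ndarray
    velocities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape or self.positions.ndim != 2 \
                or self.positions.shape[1] != 3:
            raise ValueError("positions and velocities must both have shape (N, 3)")
        if self.positions.shape[0] < 2:
            raise ValueError("a flock needs at least 2 agents")
        if not (np.isfinite(self.positions).all() and np.isfinite(self.velocities).all()):
            raise ValueError("positions and velocities must be finite")

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]

    def speeds(self) -> np.ndarray:
        return np.linalg.norm(self.velocities, axis=1)

    def copy(self) -> "ParticleState":
        return ParticleState(self.time, self.positions.copy(), self.velocities.copy())


@dataclass(frozen=True)
class NeighbourRule:
    """Interaction rule: metric (distance cutoff) or topological (k nearest)."""

    kind: str = "metric"
    r_c: float = 1.2
    n_c: int = 6

    def __post_init__(self) -> None:
        if self.kind not in ("metric", "topological"):
            raise ValueError("rule kind must be 'metric' or 'topological'")
        if self.kind == "metric" and self.r_c <= 0:
            raise ValueError("metric rule needs r_c > 0")
        if self.kind == "topological" and self.n_c < 1:
            raise ValueError("topological rule needs n_c >= 1")


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Per-agent overrides of the reference speed and/or noise strength.

    ``indices`` selects the "keystone" agents; ``v0`` and ``T``, when
    given, replace the homogeneous values for those agents only.
    """

    indices: tuple
    v0: Optional[float] = None
    T: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))
        if self.v0 is not None and self.v0 <= 0:
            raise ValueError("v0 override must be > 0")
        if self.T is not None and self.T < 0:
            raise ValueError("T override must be >= 0")

    def arrays(self, n: int, v0: float, T: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-agent (v0, T) arrays with the overrides applied."""
        if self.indices and (min(self.indices) < 0 or max(self.indices) >= n):
            raise ValueError("heterogeneity indices out of range")
        v0i = np.full(n, v0)
        Ti = np.full(n, T)
        idx = list(self.indices)
        if self.v0 is not None:
            v0i[idx] = self.v0
        if self.T is not None:
            Ti[idx] = self.T
        return v0i, Ti


@dataclass(frozen=True)
class Protocol:
    """Run protocol: thermalization, production, sampling stride, RNG seed."""

    thermalization: int = 20_000
    production: int = 1_200_000
    stride: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thermalization < 0 or self.production <= 0 or self.stride <= 0:
            raise ValueError("protocol phases must be positive")

    @property
    def n_samples(self) -> int:
        return self.production // self.stride


@dataclass
class Trajectory:
    """Sampled states of a run plus the fully resolved configuration."""

    times: np.ndarray
    positions: np.ndarray  # (S, N, 3)
    velocities: np.ndarray  # (S, N, 3)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.times.shape[0]

    def state(self, k: int) -> ParticleState:
        return ParticleState(float(self.times[k]), self.positions[k], self.velocities[k])

    def __iter__(self) -> Iterator[ParticleState]:
        for k in range(len(self)):
            yield self.state(k)

    @property
    def n_agents(self) -> int:
        return self.positions.shape[1]


def minimum_image_displacement(a, b, box: BoxGeometry) -> np.ndarray:
    """Shortest periodic displacement from ``a`` to ``b`` (componentwise <= L/2)."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    sides = box.sides
    return d - sides * np.round(d / sides)


def build_adjacency(state: ParticleState, rule: NeighbourRule, box: BoxGeometry) -> Adjacency:
    """Interaction matrix of a configuration under the given neighbour rule.

    Metric: agents interact iff their minimum-image distance is < r_c.
    Topological: the raw n_c-nearest relation is symmetrized (an edge
    exists if either agent ranks the other among its n_c nearest).
    """
    n = state.n_agents
    sides = box.sides
    if rule.kind == "metric" and rule.r_c >= sides.min() / 2:
        raise ValueError(
            f"r_c={rule.r_c} >= min(L)/2={sides.min() / 2}: minimum-image distances ambiguous"
        )
    pos = np.mod(state.positions, sides)
    tree = cKDTree(pos, boxsize=sides)
    mat = np.zeros((n, n), dtype=bool)
    if rule.kind == "metric":
        pairs = tree.query_pairs(rule.r_c, output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(
                minimum_image_displacement(pos[pairs[:, 0]], pos[pairs[:, 1]], box), axis=1
            )
            pairs = pairs[d < rule.r_c]  # strict inequality
            mat[pairs[:, 0], pairs[:, 1]] = True
            mat[pairs[:, 1], pairs[:, 0]] = True
        label = f"metric r_c={rule.r_c}"
    else:
        k = min(rule.n_c + 1, n)
        _, idx = tree.query(pos, k=k)
        rows = np.repeat(np.arange(n), k - 1)
        cols = idx[:, 1:].ravel()
        mat[rows, cols] = True
        mat |= mat.T  # symmetrize
        label = f"topological n_c={rule.n_c} (symmetrized)"
    np.fill_diagonal(mat, False)
    return Adjacency(mat, rule=label, time=state.time)


def init_lattice(box: BoxGeometry, spacing: float = 1.0, v0: float = 1.0,
                 direction=None, rng: Optional[np.random.Generator] = None) -> ParticleState:
    """Polarized flock on a cubic lattice filling the box.

    Each box side must be an integer multiple of ``spacing``; with
    ``spacing=1`` the number density is exactly 1.  All velocities are
    ``v0 * direction``; when ``direction`` is None a uniformly random
    unit vector is drawn from ``rng`` (default: the z axis if no rng).
    """
    sides = box.sides
    counts = sides / spacing
    n_axis = np.rint(counts).astype(int)
    if not np.allclose(counts, n_axis, atol=1e-9) or (n_axis < 1).any():
        raise ValueError("each box side must be a positive integer multiple of the spacing")
    grids = [np.arange(m) * spacing for m in n_axis]
    xx, yy, zz = np.meshgrid(*grids, indexing="ij")
    pos = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]).astype(float)
    if direction is None:
        if rng is None:
            direction = np.array([0.0, 0.0, 1.0])
        else:
            direction = rng.normal(size=3)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    vel = np.tile(v0 * direction, (pos.shape[0], 1))
    return ParticleState(0.0, pos, vel)


def _het_arrays(n: int, params: ModelParams,
                het: Optional[HeterogeneitySpec]) -> tuple[np.ndarray, np.ndarray]:
    if het is None:
        return np.full(n, params.v0), np.full(n, params.T)
    return het.arrays(n, params.v0, params.T)


def euler_step(state: ParticleState, params: ModelParams, rule: NeighbourRule,
               box: BoxGeometry, rng: np.random.Generator,
               het: Optional[HeterogeneitySpec] = None) -> ParticleState:
    """One explicit Euler step (reference NumPy implementation).

    The adjacency is rebuilt from the current positions, positions
    advance with the pre-update velocities, and the noise increment has
    per-component standard deviation ``sqrt(2 T dt)``.  This path mirrors
    the compiled kernel used by :func:`run` and exists for direct
    inspection and testing of single updates.
    """
    n = state.n_agents
    dt = params.dt
    v0i, Ti = _het_arrays(n, params, het)
    adj = build_adjacency(state, rule, box)
    vel = state.velocities
    a = adj.matrix.astype(float)
    f_int = params.J * (a @ vel - adj.degrees()[:, None] * vel)

    v0c = v0i[:, None]
    if params.control is Control.LINEAR:
        speeds = state.speeds()
        if (speeds == 0).any():
            bad = int(np.flatnonzero(speeds == 0)[0])
            raise FloatingPointError(
                f"zero speed for agent {bad} at t={state.time}: linear control force undefined"
            )
        f_sc = 2.0 * params.g * (v0i - speeds)[:, None] * vel / speeds[:, None]
    elif params.control is Control.QUARTIC:
        v2 = np.einsum("ij,ij->i", vel, vel)[:, None]
        f_sc = -4.0 * params.g / v0c**2 * (v2 - v0c**2) * vel
    elif params.control is Control.MARGINAL:
        v2 = np.einsum("ij,ij->i", vel, vel)[:, None]
        f_sc = 8.0 * params.lam / v0c**6 * (v0c**2 - v2) ** 3 * vel
    else:
        f_sc = np.zeros_like(vel)

    noise = rng.standard_normal((n, 3)) * np.sqrt(2.0 * Ti * dt)[:, None]
    new_pos = np.mod(state.positions + dt * vel, box.sides)
    new_vel = vel + dt * (f_int + f_sc) + noise
    if not np.isfinite(new_vel).all():
        bad = int(np.flatnonzero(~np.isfinite(new_vel).all(axis=1))[0])
        raise FloatingPointError(
            f"non-finite velocity for agent {bad} after step at t={state.time} "
            "(integration blow-up; reduce dt)"
        )
    return ParticleState(state.time + dt, new_pos, new_vel)


def _frozen_csr(state: ParticleState, rule: NeighbourRule,
                box: BoxGeometry) -> tuple[np.ndarray, np.ndarray]:
    adj = build_adjacency(state, rule, box)
    indptr = np.zeros(state.n_agents + 1, dtype=np.int64)
    np.cumsum(adj.degrees(), out=indptr[1:])
    indices = np.concatenate([np.flatnonzero(adj.matrix[i]) for i in range(state.n_agents)]
                             ).astype(np.int64)
    return indptr, indices


def _raise_kernel_failure(step: int, agent: int, code: int, phase: str) -> None:
    if code == _kernels.ZERO_SPEED:
        raise FloatingPointError(
            f"zero speed for agent {agent} at {phase} step {step}: "
            "linear control force undefined"
        )
    raise FloatingPointError(
        f"non-finite velocity for agent {agent} at {phase} step {step} "
        "(integration blow-up; reduce dt)"
    )


def run(initial: ParticleState, params: ModelParams, rule: NeighbourRule,
        box: BoxGeometry, protocol: Protocol,
        het: Optional[HeterogeneitySpec] = None,
        freeze_network: bool = False,
        check_displacement: bool = True) -> Trajectory:
    """Thermalize, then sample one state every ``protocol.stride`` steps.

    With ``freeze_network=True`` the adjacency is built once from the
    initial configuration and never rebuilt (quasi-equilibrium mode);
    otherwise the metric network follows the positions at every step.
    Topological rules are supported only in frozen mode, matching their
    use as a fixed interaction backbone.  Identical (seed, configuration)
    give bit-identical trajectories.
    """
    if check_displacement and not displacement_sanity(params, box):
        warnings.warn(
            f"per-step displacement v0*dt={params.v0 * params.dt:.3g} is not small "
            f"compared to the box (min side {box.sides.min():.3g})", stacklevel=2)
    if rule.kind == "topological" and not freeze_network:
        raise NotImplementedError(
            "per-step topological rebuilds are not supported; "
            "use freeze_network=True or the metric rule"
        )
    n = initial.n_agents
    v0i, Ti = _het_arrays(n, params, het)
    pos = np.mod(initial.positions.copy(), box.sides)
    vel = initial.velocities.copy()
    if freeze_network:
        indptr, indices = _frozen_csr(initial, rule, box)
    else:
        indptr = np.zeros(1, dtype=np.int64)
        indices = np.zeros(0, dtype=np.int64)
        if rule.r_c >= box.sides.min() / 2:
            raise ValueError("r_c must be < min(L)/2 for minimum-image adjacency")
    code = _CONTROL_CODE[params.control]
    L = box.sides
    empty_t = np.zeros(0)
    empty_s = np.zeros((0, n, 3))
    seed_t = (2 * protocol.seed) % 2**31
    seed_p = (2 * protocol.seed + 1) % 2**31

    step, agent, status = _kernels._advance(
        pos, vel, L, params.J, params.g, params.lam, code, v0i, Ti, params.dt,
        rule.r_c, freeze_network, indptr, indices, protocol.thermalization, 0,
        empty_t, empty_s, empty_s, initial.time, seed_t)
    if status != _kernels.OK:
        _raise_kernel_failure(step, agent, status, "thermalization")

    nsamp = protocol.n_samples
    out_t = np.zeros(nsamp)
    out_pos = np.zeros((nsamp, n, 3))
    out_vel = np.zeros((nsamp, n, 3))
    t0 = initial.time + protocol.thermalization * params.dt
    step, agent, status = _kernels._advance(
        pos, vel, L, params.J, params.g, params.lam, code, v0i, Ti, params.dt,
        rule.r_c, freeze_network, indptr, indices, protocol.production,
        protocol.stride, out_t, out_pos, out_vel, t0, seed_p)
    if status != _kernels.OK:
        _raise_kernel_failure(step, agent, status, "production")

    meta = {
        "J": params.J, "g": params.g, "lambda": params.lam, "T": params.T,
        "v0": params.v0, "dt": params.dt, "control": params.control.value,
        "rule": rule.kind, "r_c": rule.r_c, "n_c": rule.n_c,
        "L1": box.L1, "L2": box.L2, "L3": box.L3,
        "thermalization": protocol.thermalization, "production": protocol.production,
        "stride": protocol.stride, "seed": protocol.seed,
        "freeze_network": freeze_network, "n_agents": n,
    }
    if het is not None:
        meta["het_indices"] = list(het.indices)
        if het.v0 is not None:
            meta["het_v0"] = het.v0
        if het.T is not None:
            meta["het_T"] = het.T
    return Trajectory(out_t, out_pos, out_vel, meta)


def displacement_sanity(params: ModelParams, box: BoxGeometry, eps: float = 0.01) -> bool:
    """True iff the per-step displacement ``v0*dt`` is < eps * min box side."""
    return params.v0 * params.dt < eps * box.sides.min()
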