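"""Order parameters and spatial correlation analysis of flock configurations.

The central quantity is the equal-time connected correlation of speed
fluctuations,

    C(r) = sum_{i != j} dv_i dv_j 1[r_ij in bin] / sum_{i != j} 1[r_ij in bin]

with ``dv_i = |v_i| - (1/N) sum_k |v_k|`` the fluctuation of the
individual speed around the instantaneous group mean.  Because the
fluctuations sum to zero by construction, C(r) always changes sign at
some distance r0; the correlation length is then estimated from the
shape of C up to its first zero crossing,

    xi = int_0^{r0} r C(r) dr / int_0^{r0} C(r) dr .

For an almost linear decay this gives xi = r0/3; for a short-range
exponential decay exp(-r/xh) it recovers xi ~ xh, so the same estimator
works in both the scale-free and the short-range regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .simulate import BoxGeometry, ParticleState, Trajectory

__all__ = [
    "CorrelationCurve",
    "FlockSummary",
    "polarization",
    "speed_fluctuations",
    "connected_correlation",
    "zero_crossing",
    "correlation_length",
    "flock_summary",
    "rescale_length",
    "neighbour_counts",
    "xi_timeseries",
]


@dataclass
class CorrelationCurve:
    """Binned connected correlation: distances, C values and pair counts.

    ``C`` is defined only on bins with at least one pair (NaN elsewhere);
    ``counts`` counts ordered pairs.  ``r0`` and ``xi`` are filled in by
    :func:`zero_crossing` / :func:`correlation_length` once estimated.
    """

    edges: np.ndarray
    C: np.ndarray
    counts: np.ndarray
    r0: Optional[float] = None
    xi: Optional[float] = None
    frames: int = 1

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.edges.ndim != 1 or np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.C.shape[0] != self.edges.shape[0] - 1 or self.counts.shape != self.C.shape:
            raise ValueError("C and counts must have one entry per bin")
        if (self.counts < 0).any():
            raise ValueError("pair counts must be >= 0")
        if self.r0 is not None and self.r0 > self.edges[-1]:
            raise ValueError("r0 must lie inside the binned range")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class FlockSummary:
    """Polarization, mean speed, nearest-neighbour distance, speed histogram."""

    phi: float
    mean_speed: float
    r1: float
    hist_edges: np.ndarray
    hist_density: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0 + 1e-12:
            raise ValueError("polarization must lie in [0, 1]")
        if self.mean_speed <= 0 or self.r1 <= 0:
            raise ValueError("mean speed and r1 must be > 0")


def polarization(velocities) -> float:
    """Norm of the mean velocity orientation, ``|(1/N) sum_i v_i/|v_i||``.

    1 for a perfectly aligned flock, of order N**-1/2 for isotropic
    orientations.  Zero-speed agents have no orientation and are an error.
    """
    vel = np.asarray(velocities, dtype=float)
    speeds = np.linalg.norm(vel, axis=1)
    if (speeds == 0).any():
        raise ValueError("polarization undefined: some agent has zero speed")
    return float(np.linalg.norm((vel / speeds[:, None]).mean(axis=0)))


def speed_fluctuations(velocities) -> np.ndarray:
    """Individual speeds minus the instantaneous group mean; sums to zero."""
    vel = np.asarray(velocities, dtype=float)
    if vel.shape[0] < 2:
        raise ValueError("need at least 2 agents")
    speeds = np.linalg.norm(vel, axis=1)
    return speeds - speeds.mean()


def _bin_edges(r_max: float, bin_width: float) -> np.ndarray:
    nb = max(int(np.ceil(r_max / bin_width - 1e-9)), 1)
    return np.linspace(0.0, nb * bin_width, nb + 1)


def connected_correlation(state: ParticleState, box: Optional[BoxGeometry] = None,
                          bin_width: float = 0.3,
                          r_max: Optional[float] = None) -> CorrelationCurve:
    """Instantaneous connected speed correlation of one configuration.

    Distances are minimum-image when a periodic ``box`` is given, raw
    Euclidean otherwise (non-periodic fixture flocks).  Bins are
    half-open ``[lo, hi)`` of fixed width.  ``r_max`` defaults to half
    the smallest box side (periodic) or the largest pair distance
    (non-periodic).  The curve is a single-state quantity; average the
    derived xi over sampled states for a time average.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    pos = state.positions
    dv = speed_fluctuations(state.velocities)
    if box is not None:
        L = box.sides
        periodic = True
        if r_max is None:
            # half the smallest side: beyond L/2 minimum-image separations
            # are short along other periodic images and C(r) turns back up,
            # an artifact of the boundary conditions rather than structure
            r_max = float(L.min()) / 2.0
    else:
        L = np.ones(3)
        periodic = False
        if r_max is None:
            lo = pos.min(axis=0)
            hi = pos.max(axis=0)
            r_max = float(np.linalg.norm(hi - lo)) + bin_width
    edges = _bin_edges(r_max, bin_width)
    sums, counts = _kernels._pair_histogram(
        np.ascontiguousarray(pos), dv, L, periodic, edges)
    counts = 2 * counts  # ordered pairs
    sums = 2.0 * sums
    if counts.sum() == 0:
        raise ValueError("no pair falls inside the binned range")
    C = np.full(counts.shape, np.nan)
    nz = counts > 0
    C[nz] = sums[nz] / counts[nz]
    return CorrelationCurve(edges, C, counts)


def _trusted_bins(curve: CorrelationCurve) -> np.ndarray:
    """Mask of bins populated well enough for estimation.

    Bins holding fewer than 5% of the median pair count of the occupied
    bins (the near-origin shell of anomalously close pairs and the
    outermost corner shells) carry mostly estimator noise and are
    ignored when locating the zero crossing and integrating.
    """
    occupied = curve.counts > 0
    if not occupied.any():
        return occupied
    floor = max(1.0, 0.05 * float(np.median(curve.counts[occupied])))
    return curve.counts >= floor


def zero_crossing(curve: CorrelationCurve) -> float:
    """First distance where C(r) vanishes, by linear interpolation.

    The crossing is interpolated between the last positive and the first
    non-positive occupied bin center, scanning from the maximum of C over
    the well-populated bins: separations below the peak hold few
    anomalously close pairs whose sign is estimator noise, while the
    physical curve decays from its peak.
    """
    occupied = curve.counts > 0
    r = curve.centers[occupied]
    c = curve.C[occupied]
    trusted = _trusted_bins(curve)[occupied]
    if c.size < 2:
        raise ValueError("too few occupied bins to locate a zero crossing")
    if not trusted.any():
        raise ValueError("no bin is populated well enough to locate a crossing")
    peak = int(np.flatnonzero(trusted)[np.argmax(c[trusted])])
    if c[peak] <= 0:
        raise ValueError("correlation is nowhere positive; no crossing to locate")
    below = np.flatnonzero(c[peak:] <= 0)
    if below.size == 0:
        raise ValueError("correlation has no sign change inside the binned range")
    k = peak + int(below[0])
    if c[k] == 0.0:
        r0 = float(r[k])
    else:
        r0 = float(r[k - 1] + (r[k] - r[k - 1]) * c[k - 1] / (c[k - 1] - c[k]))
    curve.r0 = r0
    return r0


def correlation_length(curve: CorrelationCurve, r0: Optional[float] = None) -> float:
    """Integral correlation length ``int r C dr / int C dr`` over [0, r0].

    Trapezoidal quadrature on the occupied bin centers, clipped at r0;
    when r0 comes from an interpolated crossing the endpoint (r0, 0) is
    appended.  For a curve with no crossing an explicit ``r0`` (e.g. the
    largest binned distance) must be supplied.
    """
    if r0 is None:
        r0 = curve.r0 if curve.r0 is not None else zero_crossing(curve)
    trusted = _trusted_bins(curve)
    valid = trusted & (curve.centers < r0)
    r = curve.centers[valid]
    c = curve.C[valid]
    if r.size == 0:
        raise ValueError("no occupied bins below r0")
    if r0 < curve.centers[trusted][-1]:
        r = np.append(r, r0)
        c = np.append(c, 0.0)
    num = np.trapezoid(r * c, r)
    den = np.trapezoid(c, r)
    if den <= 0:
        raise ValueError("correlation integral is non-positive; xi undefined")
    xi = float(num / den)
    curve.r0 = float(r0)
    curve.xi = xi
    return xi


def _nearest_neighbour_distances(pos: np.ndarray,
                                 box: Optional[BoxGeometry]) -> np.ndarray:
    if box is not None:
        tree = cKDTree(np.mod(pos, box.sides), boxsize=box.sides)
    else:
        tree = cKDTree(pos)
    d, _ = tree.query(np.mod(pos, box.sides) if box is not None else pos, k=2)
    return d[:, 1]


def flock_summary(state: ParticleState, box: Optional[BoxGeometry] = None,
                  hist_bins: int = 40) -> FlockSummary:
    """Polarization, mean speed, mean nearest-neighbour distance, speed histogram."""
    speeds = state.speeds()
    phi = polarization(state.velocities)
    r1 = float(_nearest_neighbour_distances(state.positions, box).mean())
    dens, edges = np.histogram(speeds, bins=hist_bins, density=True)
    return FlockSummary(min(phi, 1.0), float(speeds.mean()), r1, edges, dens)


def rescale_length(l_sim: float, r1_exp: float, r1_sim: float) -> float:
    """Report a simulation length in experimental units, ``l * r1_exp / r1_sim``.

    The natural unit of a flock is its inter-particle distance; matching
    it between simulation and experiment puts lengths on a common scale.
    """
    if r1_sim <= 0:
        raise ValueError("r1_sim must be > 0")
    return l_sim * (r1_exp / r1_sim)


def neighbour_counts(state: ParticleState, box: BoxGeometry, r_c: float = 1.2) -> np.ndarray:
    """Number of metric neighbours (minimum-image distance < r_c) per agent."""
    pos = np.mod(state.positions, box.sides)
    tree = cKDTree(pos, boxsize=box.sides)
    pairs = tree.query_pairs(r_c, output_type="ndarray")
    counts = np.zeros(state.n_agents, dtype=np.int64)
    if len(pairs):
        d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
        d -= box.sides * np.round(d / box.sides)
        keep = np.linalg.norm(d, axis=1) < r_c
        np.add.at(counts, pairs[keep, 0], 1)
        np.add.at(counts, pairs[keep, 1], 1)
    return counts


def xi_timeseries(traj: Trajectory, box: BoxGeometry, bin_width: float = 0.3,
                  r_max: Optional[float] = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (r0, xi) over a sampled trajectory.

    xi is estimated independently for every sampled state and then
    averaged by the caller (time average of the instantaneous estimate,
    not the estimate of the time-averaged curve).  The occasional frame
    whose correlation stays positive across the whole analysis range
    (it can happen near the scale-free regime, where r0 ~ L/3 fluctuates)
    is clipped at the largest well-populated bin instead of being
    dropped, which would bias the average.
    """
    r0s, xis = [], []
    for st in traj:
        curve = connected_correlation(st, box=box, bin_width=bin_width, r_max=r_max)
        try:
            r0 = zero_crossing(curve)
        except ValueError:
            occupied = (curve.counts > 0) & _trusted_bins(curve)
            r0 = float(curve.centers[occupied][-1])
        r0s.append(r0)
        xis.append(correlation_length(curve, r0=r0))
    return np.array(r0s), np.array(xis)
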