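# Methods

## Model

`marginalflock` simulates N self-propelled agents in a fully periodic 3D
box. Agent i carries a position x_i and a velocity v_i and evolves by the
overdamped Langevin dynamics

    dv_i/dt = -dH/dv_i + eta_i,        dx_i/dt = v_i,

where eta_i is white Gaussian noise with ⟨eta_i(t)·eta_j(t')⟩ =
2 d T δ_ij δ(t-t') (d = 3, so per-component strength 2T) and the social
cost function is

    H = (J/2) Σ_{i<j} n_ij (v_i - v_j)^2  +  Σ_i V(v_i).

The first term makes neighbouring agents imitate each other's full
velocity vector — orientation *and* speed; n_ij is the adjacency of a
metric rule (n_ij = 1 iff the minimum-image distance r_ij < r_c) or a
symmetrized topological rule (j among i's n_c nearest, or vice versa).
The confining potential V keeps each individual speed near the natural
reference value v0, and its shape is the scientific variable:

* **linear** (harmonic): V = g (|v| - v0)^2, restoring force
  proportional to the speed deviation;
* **quartic**: V = g (v·v - v0^2)^2 / v0^2, which expands to
  4 g (|v| - v0)^2 near v0 — included to make explicit that a quartic
  confinement is a stiffened harmonic one, not a genuine alternative;
* **marginal**: V = (λ/v0^6)(v·v - v0^2)^4, whose second (and third)
  speed-derivative vanish at v0: small speed fluctuations feel nearly no
  restoring force while large ones are suppressed very steeply.

The pair term is normalized over unordered pairs so that -∂H/∂v_i is
exactly the force the integrator applies, F_int = -J Σ_j n_ij (v_i - v_j)
plus the speed-control force (2g(v/|v|)(v0-|v|) for linear,
(8λ/v0^6)(v0^2 - v·v)^3 v for marginal).

## Why two speed controls

Speed fluctuations in highly polarized natural flocks are both moderate
in amplitude and correlated across the entire group (scale-free: the
correlation length ξ grows with the group size L). Under linear control
these two traits conflict: long-range correlations require a weak
stiffness g (ξ_sp = r1 √(J n_c / g) must exceed L), but the phase-space
factor s^(d-1) in the group-speed distribution

    P(s) ∝ s^2 exp[-(N g / T)(s - v0)^2]

then pushes the typical group speed s_typical =
(v0/2)(1 + √(1 + 4T/(N g v0^2))) far above v0 in small groups — the
entropic speed boost, with small-N exponent 1/2. A size-tuned stiffness
would have to live in the wedge b/L^3 ≪ g ≪ a/L^2 (a = r1^2 J n_c,
b = r1^3 T/v0^2), which closes as the spread of observed sizes widens;
the package operationalizes the asymptotic ≪/≫ with a margin factor m
(default 10), i.e. the admissible interval [m·b/L_min^3, a/(m·L_max^2)].

Marginal control resolves the conflict: with zero curvature at v0 the
theory has a zero-temperature critical point (bulk ξ ~ T^(-1/2)), so
lowering the noise simultaneously raises the polarization and the
correlation range while the quartic-power wall keeps

    P(s) ∝ s^2 exp[-(N λ/(T v0^6))(v0^2 - s^2)^4]

sharply confined: the boost exponent drops to 1/8 and only acts below
the tiny crossover size N* = T/(λ v0^2). The typical speed under
marginal control is always computed by bounded numerical maximization of
log P (the printed 1/8-branch is an approximation, exposed separately).

## Numerical scheme

Explicit Euler with the printed update order: x_i(t+Δt) = x_i(t) +
Δt·v_i(t) (pre-update velocity), then v_i(t+Δt) = v_i(t) + Δt·F_i +
δη_i with per-component noise variance 2TΔt. The adjacency is rebuilt
from the positions at every step; for speed this is evaluated through an
exact Verlet candidate list (skin 0.3, refreshed when any displacement
exceeds half the skin), compiled with numba. A frozen-network mode keeps
the initial adjacency for the whole run; it implements the
quasi-equilibrium approximation (network rearrangement much slower than
velocity relaxation) under which the stationary distribution is
exp(-H/T) and the P(s) formulas above apply.

Integration steps: Δt = 0.01 (marginal) and Δt = 0.001 (linear), the
largest values that keep the scheme stable at the default couplings; at
the higher noise used for the noise-scaling study the marginal force
wall steepens and the same stability rule gives Δt = 0.004. A
blow-up (non-finite velocity, or zero speed under linear control, whose
restoring direction is undefined) raises an error naming the step and
agent rather than silently continuing. Runs warn when v0·Δt exceeds 1%
of the box side.

## Observables

Polarization Φ = |(1/N) Σ v_i/|v_i||; group mean speed s = (1/N) Σ |v_i|;
speed fluctuations δv_i = |v_i| - s (zero-sum by construction). The
connected correlation

    C(r) = Σ_{i≠j} δv_i δv_j 𝟙[r_ij ∈ bin] / Σ_{i≠j} 𝟙[r_ij ∈ bin]

uses fixed-width bins (default r_c/4 = 0.3), minimum-image distances in
periodic boxes and raw Euclidean distances for non-periodic fixture
flocks; self-pairs are excluded (they would add a δv² spike at r = 0
that measured curves do not contain). The correlation length is the
integral estimator ξ = ∫₀^{r0} r C dr / ∫₀^{r0} C dr with r0 the first
zero of C: for an almost linear decay ξ = r0/3 (so ξ = L/9 in scale-free
flocks with r0 = L/3), for a short-range exponential decay ξ ≈ the decay
scale. ξ is computed per sampled configuration and then time-averaged.

Estimator numerics, chosen for desk-scale N and documented because the
defaults matter:

* the binned range stops at min(L)/2 — beyond it minimum-image
  separations are short along other periodic images and C(r) turns back
  up, an artifact of the boundary conditions;
* the zero-crossing scan starts at the maximum of C over bins holding at
  least 5% of the median pair count: the few anomalously close pairs in
  the first bin carry noise, not signal;
* r0 is interpolated linearly between the bracketing bin centers; the
  quadrature runs on bin centers with the interpolated (r0, 0) endpoint
  appended, which reproduces ξ = r0/3 on a linear decay to well under 1%
  at 200 bins and gives exactly r0/2 for a constant curve;
* in per-frame time series the occasional near-scale-free frame whose C
  stays positive across the whole half-box is clipped at the largest
  well-populated bin instead of dropped (dropping would bias the mean).

## Study conditions

All simulation studies share J = 1, v0 = 1, density ρ = 1 (unit lattice
initialization, fully polarized), metric rule r_c = 1.2 (exactly n_c = 6
neighbours at t = 0, close to the biological value), λ = 1 for marginal
control. Two noise levels serve two purposes: T_LOW = 0.05,
calibrated once so the polarization matches highly ordered natural
flocks (Φ ≈ 0.99, within the observed 0.97–0.99 band), for the
finite-size phenomenology and the frozen-network quasi-equilibrium
checks; and T_BULK = 1.0, the largest noise that keeps the flock
ordered and the integrator stable at Δt = 0.004, for the noise-scaling
study. Linear-control stiffnesses:
g = 1e-3 ("scale-free": bulk ξ_sp ≈ 77 ≫ L for every box studied),
g = 2 ("stiff": bulk ξ_sp ≈ 1.7 ≪ L), and g = 0.01 for the speed-boost
study (small enough to boost the group speed measurably at N ≤ 216
while keeping the group-speed relaxation time 1/(2g) = 50 time units
short enough to average over many independent fluctuations).

Problem sizes are desk-scale by design: boxes L ∈ {8, 12, 16}
(N = 512–4096), thermalization/production 2×10³/2×10⁴ steps for
marginal runs and 10⁴/5×10⁴ for linear correlation runs (the
speed-fluctuation modes relax in ~1 time unit), and 2×10⁵/1.2×10⁶ steps
for the linear speed-boost runs (the uniform speed mode relaxes in
1/(2g) time units and needs many such periods). The fixture generator
plants two-domain, sinusoidal or linear-gradient speed patterns on a
lattice flock — mean-zero by construction, with a known zero-crossing —
and samples analytic correlation shapes; it emulates the correlation
*structure* of flock configurations, not their dynamics, boundary
(real flocks are finite and non-periodic), anisotropy or density
inhomogeneity, so estimator tests on fixtures validate the estimator,
not the model.

## Heterogeneity

A "keystone" agent receives a deviant reference speed (default ×1.2) or
noise strength while the rest of the group is homogeneous. In the
marginal model the keystone's time-averaged speed deviation shrinks as
the imitation coupling J grows — the group tames the deviant individual
once imitation is strong enough; the study reports the deviation over
J ∈ {0.25, 1, 4}.

## Known limitations

* Explicit Euler with the marginal wall is conditionally stable: at
  T ≳ 2 (λ = 1, Δt = 0.004) runs blow up; the package reports rather
  than hides this.
* **The analytic group-speed densities carry an O(T) systematic.** The
  quasi-equilibrium P(s) formulas are derived with a fixed network and
  further algebraic approximations that neglect the fluctuation
  renormalization of the confining potential: with v = V + δ the
  marginal wall ⟨(v·v − v0²)⁴⟩ acquires a term ∝ ⟨δ²⟩(v·v − v0²)² that
  shifts the effective reference speed downward by ~⟨δ²⟩/2. At desk
  scale (N = 216) the sampled equilibrium mode therefore sits a few
  percent below the predicted argmax — a deviation the test suite
  resolves and reports (the marginal quasi-equilibrium acceptance test
  is red at its stated 3-standard-error tolerance). The test comparing
  the Euler sampler against an independent Metropolis Monte-Carlo of
  exp(−H/T) on the same frozen network shows the two agree, so the
  deviation belongs to the formula, not the integrator.
* **The integral ξ estimator cannot resolve the bulk noise scaling at
  desk scale.** It compresses short-range decay scales unless r0 ≫ ξ̂,
  and the zero-sum constraint of the connected correlation pins the
  crossing at a fixed fraction of the box (~L/4) across the whole
  ordered phase at these N: measured ξ spans barely a factor 1.5
  between deep order and the disorder transition at L ≤ 16. The
  "quartering T doubles ξ" prediction is a bulk mean-field statement
  that would require boxes far beyond desk scale to test with this
  estimator; the corresponding acceptance test is left failing, with
  the measured ratio (~1.05) reported as-is by the acceptance script.
* Over long horizons the lattice melts and, as generically happens in
  ordered active matter without repulsion, density fluctuations grow
  (neighbour-count mode drifts from 6 to ~7–9 while staying unimodal);
  the lattice-sharp "peaked at 6" statement holds on the early
  production window.
* Desk-scale boxes (N ≤ 4096 vs the reference experiments' 3×10⁵) leave
  moderate finite-size scatter in ξ/L; passing the scaled-down checks
  demonstrates the mechanism, not quantitative agreement with field
  data.
* Topological neighbour rules are supported in analysis and in
  frozen-network runs, not in the per-step-rebuild integrator (the
  production simulations of this class of model are metric).
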