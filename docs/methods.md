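# Methods

## Model

The package couples two pieces of physics on a 1D interval (or 2D box) of
normalized length L:

**Field.** The concentration u(r, t) of nucleoid-bound ParA-ATP, scaled by
its cytoplasmic reservoir value, obeys

    du/dt = ∇²u + (1 − u) − χ · u^m/(K_d^m + u^m) · Σ_i θ(l_b − |r − ξ_i|).

Lengths are scaled by the ParA-ATP diffusion length (0.4 µm for the
reference in-vivo values) and times by the cytoplasm–nucleoid exchange
time, which makes both the diffusion constant and the exchange rate unity.
The last term is hydrolysis stimulated by ParB on each of M partition
complexes, modeled as spheres of radius l_b: the reaction proceeds only
inside a complex's footprint, at a maximum rate χ = kN/V (k the per-ParB
catalytic rate, N the ParB copy number, V = 2·l_b in 1D or π·l_b² in 2D),
saturating with dissociation constant K_d and Hill coefficient m (m = 1
throughout: nucleoid-bound ParA-ATP is a dimer and binds without
cooperativity).

**Cargo.** Each complex is driven up the local chemical-potential gradient
of the ligand it consumes (chemophoresis):

    dξ_i/dt = ε ∫ u^m/(K_d^m + u^m) · (∇u/u) · θ(l_b − |r − ξ_i|) dr + η_i,

with ε = DN/V, D = D_ξ/D_u the cargo's relative diffusion coefficient, and
Gaussian white noise with per-component variance 2D per unit time.  The
closed loop — cargo digs a depletion well, the well's asymmetry pushes the
cargo — is the engine: equi-positioning, directed surfing and pole-to-pole
oscillation are different operating points of the same feedback.

Boundary conditions come in matched pairs: no-flux (Neumann) field walls
with reflecting cargo walls (a cell), or periodic field with periodic cargo
(a ring, used by the analytic track).

## Numerics of the simulator

Explicit Euler for the field and Euler–Maruyama for the cargos, sharing one
time step; within a step the field is advanced first (operator splitting,
first order).  The Laplacian uses central differences with mirrored
(Neumann) or wrapped (periodic) ghost cells.  The force integral is a sum
over the footprint cells — those whose centers lie strictly within l_b of
the cargo — of hill(u)·(∇u/u)·dx^d, with one-sided gradients at Neumann
walls (mirrored ghosts would zero the wall gradient and artificially pin a
wall-adjacent cargo).  Reflection is implemented by folding (ξ → −ξ,
ξ → 2L − ξ), the standard strong-order-consistent treatment of a hard
wall.

Default dt = 0.2·dx²/d, a five-fold safety margin under the diffusion
stability bound dx²/(2d).  Two guards abort a run with a diagnostic rather
than continue silently: a negative concentration after a field step, and
u ≤ 0 inside a footprint (the log-force is singular there).  The sink term
is *reaction*-stiff when u approaches K_d with large χ (the explicit bound
is roughly dt ≲ 2·K_d/χ); runs in that regime need a smaller dt than the
diffusion default, and the 2D strong-drive demonstration (`reproduce s8`)
raises K_d to 0.01 for this reason.  Within those guards u ≥ 0 is
maintained at all times.

The 1D inner loop is compiled with numba; thermal noise is pre-drawn from
the seeded generator so the compiled and plain-Python loops produce
identical trajectories (a test pins them together to round-off).  Runs are
bit-reproducible for a fixed seed.

Initial conditions (overridable): u ≡ 1, cargos equispaced at
(2i−1)L/(2M) with a small seeded jitter; noiseless periodic runs accept a
sinusoidal field perturbation or an explicit u0 to seed symmetry breaking.

## Analytic track: steady waves on a ring

For M = 1, no noise, periodic boundaries and strong binding (u ≫ K_d, so
the Hill factor is 1), the co-moving frame z = x − vt with the cargo at
z = 0 turns the coupled system into a piecewise-linear ODE,

    U'' + vU' + (1 − U) − χ·θ(l_b − |z|) = 0,

whose solution is a sum of exponentials exp(λ± z),
λ± = (−v ± √(v²+4))/2, inside and outside the footprint.  The four
coefficients follow from a 4×4 linear system (C¹ matching at z = ±l_b,
periodic closure); basis functions are anchored at the matching points so
every exponential is bounded by one — the system stays well conditioned
for arbitrarily large L (needed by the L = 400 extrapolation runs).  The
force integral collapses to a chemical-potential difference
Δμ = ln U(l_b) − ln U(−l_b), and steady velocities are roots of

    ε·Δμ(v, χ) − v = 0.

v = 0 always solves it (the localized branch).  A ± pair of surfing
branches appears where the slope ε·∂Δμ/∂v − 1 at v = 0 turns positive; the
critical χ_c is found by bisection on that slope (tolerance 1e−4 by
default), cross-checked by a root-scan detector.  Nonzero roots are
bracketed on a coarse v-grid and polished by Brent's method to residuals
below 1e−8 (the v-grid upper bound comes from the vanishing-size speed
formula, which bounds the attainable speed).  Near χ_c the pair obeys the
pitchfork normal form |v| ∝ √(χ − χ_c) (fitted exponent 0.505 on
χ − χ_c ∈ [0.03, 0.3]).

Every profile satisfies the ring mass balance ∮(1 − U)dz = 2·l_b·χ
(integrate the ODE over the ring; derivative terms vanish), used as an
invariant test together with a second-order finite-difference
boundary-value oracle (indicator entered as exact cell-coverage fractions)
that agrees with the closed form to < 1e−4 on 4096 cells.

**Vanishing-size limit.**  As l_b → 0 at fixed k, D, N (χ, ε → ∞), the
footprint becomes a point sink of strength kN and the matching collapses
to a derivative jump.  Self-consistency then gives
√(v²+4) = kN(DN/2 + 1), i.e.

    v = ± √( [kN(DN/2+1) + 2]·[kN(DN/2+1) − 2] ),  k_c = 2/[N(DN/2+1)],

a supercritical pitchfork in k (the bracket product sits under a square
root — the finite-size solver's l_b → 0 extrapolation at L = 400 confirms
this reading and rules out the plain product, which would give the wrong
small-(k−k_c) scaling).  k_c = 0.025 at N = 40, D = 0.05, below the
finite-size value 0.0314 at l_b = 0.2: a larger cargo needs a faster
catalytic rate to move.

## Linear stability

Perturbations U = U^st + e^{λt}δU, z_ξ = e^{λt}δz about a steady wave give
a coupled eigenproblem: the field perturbation sees diffusion + advection
+ exchange plus delta-function sources at z = ±l_b (the sink indicator
moves with the cargo), and the cargo equation linearizes the log-force,
λδz = a·δz + ε[δU(l_b)/U(l_b) − δU(−l_b)/U(−l_b)] with
a = ε[U'(l_b)/U(l_b) − U'(−l_b)/U(−l_b)].  Note a > 0 on the localized
branch: against a frozen field, displacing the cargo raises the
concentration at its leading edge — the static force is destabilizing,
and stability of centering rests entirely on the field re-digging the well
fast enough.

Two independent solvers:

* **Matrix method** (the numerical oracle).  The gauge transformation
  δŨ = δU + δz·U^st′ (perturbation seen from the cargo's frame) cancels
  the edge deltas exactly, reducing the problem to the smooth rank-one
  update L_op + U^st′·rᵀ on a periodic grid (r samples δŨ at ±l_b, which
  are aligned with grid nodes).  Translation invariance becomes an exact
  zero eigenvalue (Goldstone mode), appended explicitly.  The rank-one
  structure keeps shift-invert Arnoldi cheap via the Sherman–Morrison
  identity; shifts target the soft modes near zero plus, on the localized
  branch, the static rate a.  An optional grid-doubling check refuses
  spectra whose leading eigenvalue is not converged to 1e−3.

* **Dispersion relation** (the analytic solver).  Piecewise-exponential
  ansatz for δU with exponents μ±(λ) = (−v ± √(v²+4+4λ))/2, C¹/jump
  matching at ±l_b and the cargo row close into a 5×5 determinant whose
  roots are the eigenvalues; they are polished by complex Newton iteration
  with the exact Goldstone root deflated (D(λ)/λ).  Roots reproduce the
  matrix method's leading eigenvalues to better than 1e−3.

Findings for the reference ring (l_b = 0.2, L = 40, ε = 5): the localized
branch destabilizes exactly at χ_c (exchange of stability at the
pitchfork, crossing matched to 1e−3); the surfing branch has no
eigenvalue with positive real part beyond the Goldstone zero (stable).
The localized branch's unstable rate grows monotonically with χ — the
package's direct nonlinear integration of the simplified system reproduces
the predicted rates (~3.6 at χ = 4, ~21 at χ = 5) — and *diverges* as
U^st(l_b) → 0 at χ ≈ 6.066, where the log-force itself becomes singular;
beyond that point the branch carries no unstable mode.  The reported
re-stabilization boundary is therefore the termination point of the
instability, a discontinuous (not smooth) return of Re λ to zero.  The
branch is already unphysical there anyway: U^st(0) < 0 beyond
χ* ≈ 5.517, where the strong-binding approximation has broken down;
spectra in that region carry an `unphysical_profile` flag.

## Synthetic-data / scenario defaults

All inputs are generated internally; the defaults are the study
conditions:

* **Cell-like runs** (regimes, histograms): K_d = 0.1, ε = 5, l_b = 0.2,
  L = 5, noise D = 0.05, Neumann/reflecting; χ ∈ {0.5, 2.5, 10} spans
  thermal, centered and oscillatory regimes.  Histograms use 10⁵–3·10⁵
  samples from runs of 500–2000 time units (scaled down from
  publication-size sampling; mode locations are stable under doubling).
* **Ring runs** (analytic comparisons): K_d = 0.001, ε = 5, L = 40.
* **In-vivo-style scan**: length scale 0.4 µm, l_b = 0.075 µm
  (→ 0.1875 normalized), K_d = 0.1, k = 0.1, D = 0.05, noise = D, rates
  tied to the ParB surface density via χ = kρ, ε = Dρ, ρ = N/(2l_b).
  The remaining physiological constants are assumptions of this package
  (documented here precisely because no single authoritative set exists);
  with them the onset density ρ_c sits near 100 rather than in the tens,
  but the structure of the scan — no onset for 0.6 µm cells within the
  grid, onset from 0.8 µm (M = 1) and 1.6 µm (M = 2), collapse of the
  two-cargo diagram onto the single-cargo one under (cell length)/M — is
  the meaningful, parameter-robust output.  Directed motion is declared
  where the mean speed exceeds 3× the ρ = 0 noise floor of the same cell
  length; the central-difference speed window (two 0.25-unit sampling
  intervals) must stay below the pole-to-pole half-period, else aliasing
  hides the oscillation.

What the generator does *not* emulate: ParB exchange between complexes,
nucleoid elasticity or heterogeneity, cargo–cargo steric interactions
(repulsion is purely field-mediated), 3D geometry, and stochastic
single-molecule hydrolysis.  Passing tests therefore validate the engine's
mathematics and its qualitative biology (positioning, surfing,
length-dependent onset), not quantitative agreement with any particular
measured cell.

## Numerical choices and edge cases

* Footprint membership is strict (<) on cell-center distance; the boundary
  has measure zero.  At Neumann walls footprints truncate to in-domain
  cells.  χ and ε always use the *continuum* bead volume, not the
  discretized footprint measure.
* `find_velocities` returns {0} below threshold and {−v, 0, +v} above;
  which sign a stochastic simulation realizes is spontaneous symmetry
  breaking and is not predicted.
* Velocity estimates discard the first 20% of a trajectory as transient
  and use central differences of the sampled positions.
* Batch-means standard errors for time-averaged positions use ≤ 10 long
  blocks so the block length exceeds the position correlation time.  Note
  the stationary density around an off-center equi-position is slightly
  skewed (anharmonic well against a wall), so time-averaged positions
  carry a small systematic offset from (2i−1)L/(2M); the mirror symmetry
  mean_i + mean_{M+1−i} = L is exact and is what the tests pin tightly.
* The l_b-scan records the branch's disappearance (inverse pitchfork) as
  the last grid point with a nonzero root; near the critical radius the
  root amplitude → 0 continuously.
* Matching systems for the profile cannot be singular for real v (the
  exponents satisfy v² + 4 > 0); the code still traps LinAlgError and
  reports a conditioning failure.

## Known limitations

* The simplified (strong-binding) analytic track is only valid while
  U^st > 0; the package reports, rather than hides, the parameter regions
  where it breaks (flags, exceptions).
* 2D strong-drive surfing is not reproduced at desk scales: the explicit
  scheme's reaction-limited dt makes the deep-well regime (K_d ≤ 0.001,
  χ = 50) expensive, and at the affordable K_d = 0.01 the 2D localized
  state remains stable even when seeded with a traveling well.  The 1D
  system at matched parameters surfs; the discrepancy is a cost boundary
  of this package, not a claim about the model.
* M > 1 has no analytic branch here (simulation only), and Neumann
  boundaries have no analytic steady waves.
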