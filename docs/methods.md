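# Methods

## Model overview

The simulator couples two dynamical layers on a shared geometry.

*Ecology.* N microbial strains live in a host. Strain *i* has feature
coordinates *mᵢ* in the D-dimensional unit ball; the host's behavior is a
coordinate *b* in the same space, restricted in all shipped scenarios to
the segment [0, 1] on the first axis (*b₁*, the addiction-severity
coordinate). The host contributes growth to each strain according to

r_i(t) = floor + max(0, 1 − β‖b(t) − mᵢ‖^α)

with defaults α = 3, β = 0.1, floor = 0.1, so r ranges over [0.1, 1.1] and
two strains can differ by at most β when both sit in the reachable region.
Relative abundances evolve by a forward-Euler step of the logistic
competition equation with intra-strain coefficient s and feedback cost cᵢ,
then are normalized, topped up with an immigration inflow μ/N per strain,
and normalized again. The double normalization represents a community held
at carrying capacity (strains compete for a fixed resource pool); the
inflow (μ = 10⁻⁸) guarantees a strict positive floor μ/(N(1+μ)) per strain
per step, so no result depends on permanent extinction. Negative
intermediate abundances (possible only under aggressive cost sweeps) are
clipped to zero before normalizing.

*Feedback.* Each strain senses the OLS slope of its proportion over a
rolling window of ω_m points and emits the slope's sign (neutral within
±10⁻⁶, representing sensing accuracy limits); the host carries the same
statistic of *b₁* over ω_h points. The aggregate effect
M(t) = |σ(t)|·I_b·Σ xᵢ dᵢ I_mᵢ adds to the host's baseline step, with the
result clamped to the allowed segment. Windows hold exactly ω points
(ω_m = ω_h = 10 by default) and all indicators are zero until a window has
filled, so early steps are feedback-free. The slope is computed as a fixed
dot product with centered time weights, which is algebraically the
two-pass OLS slope; a test holds it to the independent `numpy.polyfit`
oracle at 10⁻¹².

## Scenarios

**Two-strain selection.** An affecting strain at (0, 0) (effect magnitude
d, cost c) competes with a silent strain at (1, 0) while the host performs
a Laplace random walk (scale σ = 10⁻³) on [0, 1] starting at 0.5, clamped
at the ends. Initial proportions are [0.5, 0.5]. M uses the realized step
magnitude |σ_RW(t)|. The run returns the affecting strain's final
proportion after 10⁵ steps; values above 0.5 mean manipulation paid.

A closed-form observation that organizes this scenario: at coexistence the
affecting strain's proportion equilibrates to 0.5 + (adv(b) − c)/(2s),
where adv(b) = β((1−b)³ − b³) ≤ β. Costs above β can never pay, matching
the simulated collapse at c = 0.12. Near the break-even cost the feedback
pins the host close to the distance where adv ≈ c, so final proportions
concentrate only slightly above 0.5 (at s = 0.1, c = 0.09 the attainable
ceiling is 0.55 even with the host at 0), and a minority of runs in which
the host escapes upward early — random walks are sticky by the arcsine
law — end near 0. The ensemble mean is therefore a conservative, noisy
measure of selection close to the break-even cost; the direction is
decisive once the cost is a few hundredths away from β.

**Addiction episode.** Three phases. (1) *Equilibrium*: the host sits at
the origin until the composition stabilizes — criterion: consecutive-step
changes below 10⁻¹⁰ (max over strains) for 100 straight steps, capped at
10⁴ steps; hitting the cap proceeds with a manifest warning. (2)
*Addiction*: baseline steps +σ_A(t) ~ Exponential(mean σ = 10⁻⁴) while
b₁ < R, zero afterwards, for τ = 20000 steps; b₁ is clamped to [0, R]. The
feedback M stays active on the plateau (σ_A is still drawn each step and
enters M as |σ_A|). (3) *Withdrawal*: baseline steps −σ_A(t), clamp
[0, R], for a fixed 10⁵-step horizon so that φ(Withdrawal) windows are
comparable across runs. τ is counted from phase initiation whether or not
b₁ reached R. Clamping relapses at R is the default; a config switch
(`clamp_at_R=False`) lets relapses overshoot R.

Metrics: φ(phase) is the plain sum of b₁ over the phase's steps (unit-step
Riemann integral); maximal relapse is max over withdrawal pairs t₁ < t₂ of
b₁(t₂) − b₁(t₁), floored at 0, computed in linear time via suffix maxima
and tested against the quadratic brute force; `returned` means final
b₁ < 0.01.

**Ensembles and sweeps.** Each replicate derives three independent RNG
substreams (strain sampling, behavioral draws, intervention newcomers)
from `SeedSequence([base_seed, rep])`, so the no-effect baseline arm can
replay the identical behavioral draws — fold changes are paired by
construction, and changing N does not perturb the behavior sequence. The
baseline arm uses a minimal schedule recurrence; a test requires the full
simulator with all dᵢ = 0 to reproduce it bit-for-bit. Sweep cells get
seeds hashed from (base_seed, cell index). The intervention option samples
k fresh strains that enter at abundance 0 at withdrawal start and join the
inflow pool (each active strain then receives μ/(N+k)), avoiding an
arbitrary bolus size.

## Variants

- *GLV dynamics* (`dynamics_variant="glv"`): absolute abundances, update
  xᵢ ← xᵢ + xᵢ(rᵢ + Aᵢ·x) + μ/N with A = −(1−δ)I − δ·ones; no
  normalization. δ has no canonical value; the default 0.5 (strong but
  sub-intra-strain competition) is recorded in every run manifest.
  Feedback slopes and weights use relative abundances x/Σx for
  comparability with the normalized model. A divergence guard aborts if
  any abundance exceeds a configurable ceiling (default 10⁶).
- *Direct pull* (`feedback_variant="direct_pull"`): each strain pulls the
  host toward its own coordinates, M = |σ|·Σ xᵢ dᵢ (mᵢ−b)₁/‖mᵢ−b‖;
  strains within 10⁻¹² of the host are skipped (undefined direction).
- *Behavior-independent strains*: a configurable fraction of strains
  ignores the host and grows at a constant rate (default 0.6, the midpoint
  of the attainable 2D range).
- *Inflow modes*: μ/N per strain (default), constant μ per strain, or none.

## Synthetic communities

`sample_strains` draws features uniformly over the volume of the unit ball
(direction from an isotropic Gaussian, radius u^(1/D)); "uniform on the
ball" was preferred to "on the sphere surface" because strains are meant
to tile the interior niche space. Effect magnitudes are exponential with
mean E[d] for exactly round(N·fraction) affecting strains; the rest have
d = 0 and pay no cost. The generator emulates a community whose niches are
isotropically spread around the host's resting state and whose effect
sizes are heavy-tailed; it does not emulate phylogenetic correlation
between niche and effect, taxon-specific interaction networks, or
abundance distributions of real 16S/metagenomic profiles — passing tests
therefore validate the model's internal logic, not any fit to empirical
microbiome data.

## Numerical and design choices

- Forward-Euler step size is fixed at 1 (discrete time).
- Initial proportions are uniform 1/N; the two-strain scenario starts at
  [0.5, 0.5] (the model is silent on initial conditions; uniform is the
  symmetric choice).
- Strict inequalities at ±10⁻⁶ define the neutral slope band.
- The host-trend regression uses realized behavior (baseline + microbial
  effect), not the baseline schedule.
- Per-step order: compute indicators and M from histories, update b₁,
  evaluate growth at the new b₁, step the dynamics, push histories. The
  compiled kernel (numba) implements exactly this order; a dedicated test
  replays short runs through the public single-step operations and
  requires bitwise-identical behavior trajectories.
- Problem sizes in the test suite: ensemble checks run the full published
  operating point (σ = 10⁻⁴, τ = 20000, horizon = 10⁵, R = 0.7) with
  replicate counts of 50–100 per condition; richness comparisons use
  N ∈ {30, 50, 1000}.

## Known limitations

- Only resource competition couples strains (no cross-feeding, toxins or
  exploitation), and the host has no memory beyond the ω-step window.
- The stabilization criterion for the equilibrium phase is a pragmatic
  tolerance rule; communities with very slow modes (large N) may hit the
  cap and enter addiction slightly off-equilibrium (flagged per run).
- Near the break-even cost the two-strain selection signal is intrinsically
  weak (see above); conclusions there require large ensembles.
- Heatmap-scale reproductions (1000 replicates per pixel over full
  N × E[d] grids) are out of desk scale; the package ships directional
  ensemble tests and a `sweep` utility to build such grids incrementally.
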