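# Methods

## Scope and time convention

`filokin` models a single R7 photoreceptor axon terminal during the second
half of *Drosophila* pupal development.  Model time is measured in minutes
after the P40 stage, with 60 minutes per percent of pupal development
(P60 = 1200 min, P100 = 3600 min).  All rate constants are per minute.

## The developmental model

A continuous-time Markov jump process over five integer copy numbers:
short-lived filopodia (sF), long-lived filopodia (ℓF), transient bulbous
tips (sB), stabilized synaptogenic bulbous tips (synB), and synapses (S).
Eight reactions (see `filokin.kinetics`) combine zero-order generation,
first-order retraction/stabilization/maturation, and a bulb-formation
channel whose propensity carries three modulating factors:

- **f_FB(t) = ½(1 + tanh[(3/t_half)(t − t_half)])**, a developmental ramp
  of bulb-formation propensity.  t_half = 1000 min in every preset; the
  source model gives a single value and there is no evidence it varies by
  genotype, so it is treated as genotype-independent.
- **f1(synB) = B50/(synB + B50)**, saturating auto-inhibition: each
  stabilized bulb sequesters seeding factors and suppresses further bulb
  nucleation.  The literature formula is typeset as (synB + B50)/B50,
  which *increases* with synB and contradicts its own description as
  auto-inhibition; we default to the saturating-inhibition form (value 1
  at synB = 0, ½ at B50) and keep the as-typeset variant behind
  `f1_mode="as_printed"` for comparison.
- **f_F(t)**, a clamped fifth-order polynomial drive on filopodium
  generation.  The published coefficients (stored verbatim in
  `PRINTED_FF_COEFFS`) drive the clamped polynomial to zero near
  t ≈ 460 min — before P60 — which would make the published c1 estimator
  (division by f_F(P60)) undefined; the exponents have almost certainly
  drifted in typesetting.  We therefore (a) raise an explicit error on any
  division by a non-positive f_F, and (b) let parameter sets carry either
  a constant drive or a piecewise-linear `drive_table` interpolated from
  per-stage filopodia censuses.  The genotype presets use the constant
  drive f_F ≡ 1 with c1 = λ·c2, which holds the filopodial census at its
  P60 level across the window — consistent with fixed-preparation counts
  that show only mild changes in total filopodia over P40–P90.

A further simplification inherited from the source model: transient-bulb
retraction (R4) does not return the bulb to the filopodium pool.  Bulbs
are rare and r4 small, so the neglected back-flux is negligible.

### Simulation scheme

Propensities depend on time through f_F and f_FB, so plain Gillespie is
not exact.  The default scheme is thinning (Ogata rejection): within a
look-ahead window (default 10 min) the time-dependent factors are bounded
above — f_FB by its value at the window end (it is increasing), f_F by its
maximum over endpoints and interior stationary points of the polynomial
(or table nodes) — candidate events are drawn at the bound rate and
accepted with probability true/bound.  This is statistically exact.  A
1-min piecewise-constant approximation is retained behind
`scheme="piecewise_constant"`; a distributional cross-check between the
two schemes is part of the test suite.  Snapshots use the right-continuous
convention (the state at an event time is the post-event state).  The
all-zero state at P40 is the default initial condition.

Bulb identities are tracked through the run.  Because transient bulbs are
exchangeable and memoryless, choosing the retracting/stabilizing bulb
uniformly at random is distributionally exact; it yields per-bulb
lifetimes comparable to live-imaging track tables, with a 40-min
stability threshold (a parameter) separating transient from synaptogenic
bulbs.

## The bulbous-tip stationary chain and the KL fit

On the timescale of one imaging session the filopodial census and the
developmental ramps are frozen, so (sB, synB) form a 2-D time-homogeneous
chain on [0, N]² with bulb birth r3·f1(j), death i·c4, stabilization
i·c5 (moving [i,j] → [i−1,j+1]) and maturation j·c6, reflecting at N.
The typeset generator entry for stabilization, G([i,j],[i,j+1]) = j·c5,
neither consumes a transient bulb nor scales with i, conflicting with the
reaction sB → synB; the default `generator_mode="reaction_consistent"`
uses i·c5 into [i−1, j+1], with the as-typeset variant available.  The two
modes coincide when c5 = 0 (tested).

The stationary law is the eigenvector of Gᵀ at the eigenvalue of smallest
magnitude (analytically 0); round-off negatives are clamped and the vector
renormalized, and the residual ‖vᵀG‖∞ is reported.  A reducible chain
(multiple zero eigenvalues) raises an error naming the strongly connected
components.  Inside the fitting loop the stationary vector is obtained by
a direct null-space solve (one balance equation replaced by the
normalization constraint) — numerically identical, an order of magnitude
faster; agreement with the eigen-solve is tested.

(c5, B50, r3) are fitted by minimizing the *sum* of the two KL divergences
D(observed‖model) of the sB and synB marginals (equal weights — the source
describes a single joint minimization without weights; the choice is
recorded in the fit output).  A pseudocount of 10⁻⁶ per bin is added to
both sides; with pseudocount 0 a model-zero bin under observed mass yields
+∞ with a warning rather than being dropped.  Optimization is over
log-parameters (positivity by construction): a 5×5×5 log-spaced coarse
grid followed by Nelder–Mead from the best three candidates — fully
deterministic, no RNG.  Truncation defaults to N = 15; doubling N moves
the fitted trio by <1% when the tail mass is negligible (tested).

## Parameter estimation chain

1. **c2_sF, c2_ℓF** — inverse mean lifetime of filopodia living <8 min /
   ≥8 min; the boundary is "<" strictly for short, "≥" for long.  Censored
   tracks are excluded (count logged), not imputed; a basic nonparametric
   bootstrap is provided for c2 and λ only.
2. **λ_sF, λ_ℓF** — sample means of per-time-instance counts (the Poisson
   MLE), with the index of dispersion reported as a goodness diagnostic.
3. **c1 = λ·c2/f_F(P60)** — f_F(P60) is an explicit input (decoupled from
   the degenerate printed polynomial); non-positive values raise.
4. **c4 = 1/120 min⁻¹, fixed** — transient bulbs are too rare in all
   genotypes to estimate it per genotype.
5. **c6** — steepest inter-timepoint slope of the synapse-accumulation
   table divided by the mean synaptogenic-bulb count.  For the control
   anchors (5 synapses per 10% stage at mean 1.1 bulbs) exact arithmetic
   gives 5/(1.1·600) = 1/132 min⁻¹; the source rounds this as 1/133.  The
   implementation reports exact arithmetic.
6. **(c5, B50, r3)** — the KL fit above, with c4 and c6 held fixed.
7. **c3 = r3/((sF+ℓF)·f_FB)** at P60.

`DevelopmentalModel.fit()` runs the chain and returns results carrying
every constant with its provenance (estimated / fixed / unestimated) and
the diagnostics; missing bulb observations leave (c5, B50, c3)
unestimated with a warning rather than failing.

### Known estimator limitations

The 8-min cutoff estimator equates 1/E[X | X < 8] (resp. ≥) with the class
rate.  For exponential mixtures this is biased: the long-class mean is
inflated by the memoryless offset (E[X | X ≥ 8] = 8 + 1/c2) and each pool
is contaminated by the other class.  With well-separated classes (short
mean ≈ 2 min, long mean ≈ 30 min, as in the presets) the net biases stay
under ~7%; when the long-class mean approaches the cutoff the bias grows
and recovery tolerances no longer hold.  Window censoring (60-min
sessions) additionally length-biases surviving long tracks; the large-n
recovery tests use long windows where this vanishes.

## The mechanistic winner-takes-all model

Filopodia compete for a conserved pool of seeding factors.  Reactions:
emergence (g1, set to the control bulb-formation rate r3 at P60),
accumulation of one free seed per event at S·c_in (blocked at the cap
i = n), release at c_out, and retraction at hazard 1/i (competitive) or a
constant (upregulated).  Interpretations fixed here:

- a "time step" is one Gillespie event; exponential waiting times are
  accumulated so lifetimes are in model time, not step counts;
- retraction returns *all* of a filopodium's seeds to the free pool —
  without this the limited resource would drain irreversibly, defeating
  the model's premise; a no-return variant is not provided;
- the 1/i hazard at i = 0 is taken as 1/max(i, 1): empty filopodia retract
  at rate 1;
- the pool is initialized to round-half-up of n·B̄(P60) with n = 120
  states; B̄ values are genotype configuration inputs (control 1.1 —
  the same mean bulb count the c6 slope arithmetic uses; atg-mutant 3.5,
  the midpoint of the observed three-to-four band; upregulated 0.7, a
  synthetic stand-in for the observed reduction);
- a filopodium counts as a bulbous tip while holding at least ⌈n/4⌉
  seeds; runs are 100,000 events with the first half discarded as
  burn-in.

Resource conservation (pool + held seeds = initial pool) is asserted after
every event.  In upregulated mode the *whole-filopodium* lifespan is
exponential at the constant hazard (tested by KS); above-threshold bulb
episodes are not exponential in either mode, because most episodes end by
seed-release boundary crossings rather than retraction.  At matched pool
the competitive hazard 1/i ≥ 1/120 for all i ≤ n, so competitive episodes
do not stochastically dominate the upregulated ones; the destabilization
seen in autophagy-upregulation experiments emerges from the preset-level
comparison (smaller pool *and* lost advantage), which is what the tests
check.

## Synthetic data

The study's imaging tables are available only on request, so all estimator
inputs are generated from known ground truth:

- **Track tables / snapshots** — independent stationary immigration–death
  processes per filopodium class (births Poisson at λ·c2, lifetimes
  exponential at c2, Poisson(λ) objects alive at the window start with
  exponential residual lifetimes).  Objects alive when the window closes
  are emitted censored.  Defaults mirror the study design: 60-min windows,
  8 terminals, 1-min snapshot cadence (the live cadence of the source
  movies is unstated; it is a parameter).
- **Bulb observations** — exact Gillespie simulation of the same truncated
  2-D chain the fitter assumes, sampled on a grid after a 10% relaxation
  prefix.  Because the chain mixes on the 1/c6 ≈ 130-min scale, "large
  sample" means total_time ≳ 10⁶ min for the 15–25% recovery tolerances.
- **Fixed-timepoint tables** — 40 terminals simulated over the full course
  with per-stage means and SEMs read from each trajectory.  (Distinct
  animals per stage would be uncorrelated across stages; per-stage
  distributions are identical either way, and one trajectory per terminal
  keeps the table cheap.)

Every generator is seed-deterministic and emits a manifest (parameters,
sizes, seed, scheme) sufficient to regenerate its output bit-for-bit.

What passing recovery tests show — and do not show: they demonstrate that
the estimators are consistent for data generated by the models' own
assumptions (exponential lifetimes, Poisson counts, stationary bulb
chain).  Real terminals have measurement discretization, tracking errors,
non-exponential lifetime tails and between-terminal heterogeneity, none of
which the generators emulate.

## Genotype presets

The per-genotype source tables are not part of the public record, so the
presets are synthetic stand-ins calibrated once against the published
anchors: c4 = 1/120 min⁻¹; c6 = 1/132 min⁻¹ from the slope arithmetic;
t_half = 1000 min; a stationary mean of concurrent bulbous tips inside the
observed one-to-two band for control and three-to-four for the
atg-mutant; and a control full-course synapse count inside the 20–25
band.  Control: λ_sF = 7, λ_ℓF = 5, mean lifetimes 2 / 30 min,
r3(P60) = 0.019 min⁻¹, c5 = 0.05, B50 = 2 (stationary mean ≈ 1.6
concurrent bulbs; ≈ 23 synapses by P90).  atg-mutant: longer-lived ℓF
(35 min, λ_ℓF = 7), r3 = 0.036, B50 = 10 (mean ≈ 3.6 bulbs).
atg-upregulated: destabilized bulbs (c4 = 1/40), weak stabilization
(c5 = 0.02), near-flat feedback (B50 = 50), r3 = 0.012.

## Numerical choices

- Eigen-solve tolerance: the zero eigenvalue is accepted below 1e-9
  relative to the generator scale; stationary entries below −1e-12 of the
  vector scale trigger a warning before clamping.
- Thinning window 10 min: bounds on f_F/f_FB are tight enough that the
  rejection rate is a few percent; the window only affects speed, not
  correctness.
- Problem sizes in tests and the acceptance checks (40 terminals for the
  full-course band, 10⁴ sampling instances for dispersion, 10⁶ min of
  stationary sampling for the bulb-trio recovery, 10⁵-event mechanistic
  runs) are the package's own choices, sized so each statistical check
  sits several standard errors inside its tolerance.
- Ties/degenerate inputs: empty observation distributions, zero
  denominators in c3/c6/c1, reducible generators, and all-zero propensity
  states all raise explicit errors (or, for the never-firing simulator,
  terminate early with a logged reason).
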