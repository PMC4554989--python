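# Methods

## Model

The deformation `x(t)` of a spring (stiffness `K`) and damper (friction
`C`) in parallel, pulled by a constant force during a finite challenge
window, follows a piecewise law on the rescaled 0–100 time axis:

* **pre** (`t < τ₁`) and **post** (`t ≥ τ₂`): no external force, and the
  (massless) force balance reduces to the first-order relaxation
  `x′ = −(K/C)·x`;
* **challenge** (`τ₁ ≤ t < τ₂`): Newton's second rule with an effective
  mass equal to the perceived force, `m·x″ + C·x′ + K·x = m`,
  `m = perc·F_pert`.

The model uses the perceived force simultaneously as forcing and as
inertial mass, exactly as the force-balance equation is written; the
package implements that coupling as-is and exposes a `mass=` override on
the simulators purely so linearity-in-forcing can be checked with the mass
held fixed. Derived summaries: decay constant `T = C/K` (time to shrink by
`e` during recovery), asymptote `x_inf = perc·F_pert/K`, and `x_max`, the
deformation at `τ₂` for a system starting at rest.

**Boundary handoffs.** The equations do not define boundary velocities, so
the first-order constraint `v = −(K/C)·x` — which holds identically outside
the challenge — is imposed on entry to the challenge at `τ₁` (v = 0 for a
system at rest) and the first-order law resumes from `x(τ₂⁻)` at `τ₂`
(velocity is discontinuous there in general). `x` itself is continuous at
both boundaries by construction. Regime membership is half-open:
`τ₁` belongs to the challenge, `τ₂` to the post regime.

## Trajectory engines

The production path is the piecewise closed form: exponential relaxation
outside the challenge and, inside it, the analytic solution of the
constant-coefficient second-order equation in all three damping branches
(overdamped, critically damped within a relative discriminant tolerance of
1e-12, underdamped with the real cosine/sine form). All parameter sets
fitted in practice are overdamped (`m = 0.1` is small), but the
underdamped branch is fully supported and cross-checked; note that an
underdamped system can overshoot `x_inf` during the challenge, so the
resting-system bound `x_max ≤ x_inf` holds only in the overdamped branch.

The independent cross-check integrates the same piecewise ODE with LSODA,
restarting at `τ₁` and `τ₂` so the vector-field discontinuity never falls
inside a solver step. Default tolerances are rtol = 1e-10, atol = 1e-12:
the equivalence bound asserted in the tests is an *absolute* 1e-6 while
random-draw amplitudes reach O(1e4), where a 1e-9 relative tolerance would
not suffice. The measured worst gap over the draw ranges is ~1e-8.

Degenerate input: `perc·F_pert = 0` makes the challenge equation divide by
zero; simulation raises a dedicated error whenever the grid intersects the
challenge window, and otherwise (no force anywhere) falls back to plain
relaxation.

The default grid is 1001 points over 0–100 (step 0.1) with the challenge
at 20–60, matching the 10-hour observation window convention in which the
4-hour challenge maps to [20, 60].

## Data preparation

Two steps make heterogeneous raw measures model-ready: division by a
per-measure reference mean (fold change), then subtraction of each series'
minimum, anchoring the least disturbed observation at the model's rest
state `x = 0`. The reference is by default the grand mean of the measure
over every individual and time point of the cohort — the convention
applicable to real data, where no baseline is known — but it is an explicit
argument. The anchoring assumes each individual is near rest at some
observed time; a warning is emitted when the minimum falls strictly inside
the challenge window, where that assumption is doubtful. Missing
observations are simply absent rows; behavioral measures with no
in-challenge points are fitted from whatever points exist.

A caveat follows from the grand-mean convention: for a series whose mean
deviation over the sampled window is not small, dividing by the grand mean
shrinks the reconstructed `x` by the factor `1 + mean(x)`, which inflates
fitted `K` and `C` by roughly that factor (it cancels exactly in `T`, and
it is common to all individuals of a measure, so within-measure contrasts
and orderings are unaffected). For synthetic cohorts, where the generating
baseline is known, recovery of the generating parameters is therefore
validated with the baseline as the reference; the grand-mean default is
used everywhere a real-data workflow is emulated (CLI, end-to-end runs).

## Fitting

`F_pert = 0.1` and `perc = 1` are fixed by convention (the force scale is
arbitrary on the fold-change scale), so the fit estimates only `K` and
`C`, by unweighted least squares of the closed-form trajectory (started at
rest) at the observation times. The search runs in `(log K, log C)` —
positivity by construction, and a scale-free relative convergence tolerance
(1e-8) — with Nelder–Mead multi-started from the coarse grid
K ∈ {0.01, 0.1, 1} × C ∈ {0.1, 1, 10} and soft quadratic penalties outside
log K ∈ [log 1e-4, log 1e2], log C ∈ [log 1e-4, log 1e3]. When the best
solution lands below twice the critical damping `C_crit = √(4mK)`, a fan of
ten log-spaced C starts below `2·C_crit` is added: in the underdamped
region the residual surface in `C` splits into shallow basins one
oscillation phase apart, and the dense fan places a start in each basin.
The fit is deterministic; identical inputs give bitwise-identical results.

Flat series (no response signal) leave stiffness unidentifiable from
above: they are flagged `degenerate`, reported at the upper `K` search
bound, with MEF undefined (the MEF denominator is zero). The MEF statistic
itself raises on all-identical observations rather than passing NaN
through.

The mean-pattern fit averages observations per time point across
individuals of one measure, re-anchors the average at zero, and fits it
like any series.

## Sensitivity analysis

One-at-a-time sweeps vary `K`, `C` or `F_pert` (default 50 log-spaced
values) with the other two fixed, tabulating `x_max`, `x_inf`, `T` per
value; the canonical three sweeps are K ∈ [0.1, 1] (C = 2, F = 1),
C ∈ [0.5, 20] (K = 0.1, F = 1) and F ∈ [1, 10] (K = 0.1, C = 2). The
expected structure — `x_inf·K = perc·F_pert` exactly, `T = C/K` exactly,
`x_inf` flat in `C`, `T` flat in `F`, `x_max` falling in `C` and rising in
`F` — is asserted in the tests. One numerical caveat: at the low end of
the C sweep the (m = 1) system is underdamped and `x_max` differs from
`x_inf` only by an oscillatory residue of order `e^{−C(τ₂−τ₁)/2m}` ≈ 5e-5,
so monotonicity in `C` is asserted with a 1e-3 relative slack there; the
overdamped portion is strictly monotone. The 3×3 interplay grid crosses
low/mid/high `K` with low/mid/high `C` and returns full trajectories.

## Synthetic cohorts

The generator emulates the statistical structure of the reference
confinement design: 2 isogenic lines × 2 replicates × 4 aquaria (the
statistical individuals, 16 in total), four measures — physiological ones
sampled sparsely through the whole window including the challenge
(10 points), behavioral ones dense before/after but absent during the
challenge (13 points), since confinement makes them unobservable. Per
individual × measure, `(K, C)` are drawn lognormally (SD 0.3 on the log
scale, the between-aquarium spread plausible for such designs) around
per-line medians whose defaults mirror the per-line fitted values of the
reference study, so contrasts have a known direction (line R stiffer in
the physiological measures). Raw series are `baseline × (1 + x(t))` with
per-measure baselines spanning a 100-fold range — so normalization is
genuinely needed — and multiplicative observation noise (default 5%).
An optional equicorrelation of the log-parameters across measures supports
correlation-recovery studies. `plant_outliers` multiplies the baseline
deviation of chosen individuals by a magnitude factor, driving their
fitted parameters off by roughly that factor.

What the generator does *not* emulate: serial correlation of observation
noise, within-challenge missingness patterns beyond the all-or-nothing
behavioral censoring, non-stationary baselines, or any mechanistic
behavior. Passing round-trip tests therefore demonstrates statistical
identifiability under the design, not biological validity.

## Cohort statistics

Fits failing the ±1.5×IQR rule — `K` or `C` strictly outside the Tukey
fences of their measure, quartiles by linear interpolation (type 7),
computed on the raw parameter scale in a single frozen pass — are flagged,
never dropped. Equality with a fence (including the collapsed-fence case
of identical values) is inside. Note the operating characteristics at
cohort sizes of 8–16: the fences flag a natural lognormal draw a few
percent of the time per value, and for skewed raw-scale samples the lower
fence is often negative, so small-parameter outliers can escape a pooled
two-line computation; deterministic validation of the rule therefore uses
single-line cells with degenerate dispersion, where the planted set is
provably the flagged set. Grouping is per measure by default and
configurable.

Per-line summaries average `K`, `C`, `T`, `x_inf` as per-individual values
— deliberately *not* recomputing `T` from mean `C` over mean `K`, so the
printed mean `T` is generally not the ratio of the printed means.

The line contrast fits an OLS of `log K` (or `log C`) on
line + replicate + interaction, drops non-significant replicate terms at
0.05 (interaction before main effect, hierarchy respected) and refits; the
line term is always retained, its p-value is type-II, and per-line
estimates are back-transformed predicted log-means averaged over retained
replicate levels. With exactly one fitted value per aquarium, an
aquarium-level random effect would be confounded with the residual, so the
fixed-effects model is the appropriate formulation at this design size.
Measured at n = 8 per line over 200 seeded replicates, the contrast holds
its nominal level (type-I ≈ 0.04–0.07 at α = 0.05) and detects a 2-SD
log-median separation with power ≈ 0.94–0.97.

Pearson correlations are computed across all measure × parameter columns
on pairwise-complete non-excluded individuals, absent below 3 pairs;
p-values are unadjusted by default (exploratory-table convention) with an
optional Benjamini–Hochberg adjustment.

## Problem sizes and determinism

Validation workloads were sized for quick iteration: 100 random parameter
draws for the closed-form/integrator equivalence, 50 noiseless and 100
noisy draws for recovery, 200 replicates per arm for the contrast's error
rates, and default-size cohorts (64 series) for the end-to-end runs. Every
stochastic computation takes an explicit seed; the acceptance script
derives all of its seeds from a single `--seed`.

## Known limitations

* The coupling of forcing and inertial mass is taken as given; its units
  are not interpretable and the model cannot produce a post-challenge
  rebound (no mass during recovery). Chronic, repeated or overlapping
  stressors and habituation are out of scope.
* `C` is the weaker-identified parameter when the challenge window is
  short relative to the transient; at corners of the parameter box
  (fast transient + fast recovery vs. a sparse design) its information
  content shrinks to one near-plateau residual.
* Grand-mean normalization biases absolute `K`, `C` upward by
  `1 + mean(x)` for large-amplitude measures (see Data preparation);
  `T` and within-measure comparisons are unaffected.
* The exclusion rule inherits Tukey-fence behavior at small n (see Cohort
  statistics).
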