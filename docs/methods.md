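# Methods

## The measurement this package analyzes

Anaerobic slurry incubations of soil in gas-tight vials, spiked with
¹⁵N-labeled substrate and killed with ZnCl₂ at fixed times (default grid
0, 3, 6, 12, 24 h; three replicate vials per kill time).  The observables
are the *excess* amounts of the N₂ isotopologues ²⁹N₂ and ³⁰N₂ — excess
over the time-zero / natural-abundance baseline — in nmol N₂ per g dry
soil, as produced by isotope-ratio mass spectrometry post-processing
(instrument-specific conversion from ion currents is upstream of this
package's input contract).

Three isotope treatments are run per sample:

| treatment code | spike | role |
|---|---|---|
| `amm15` | ¹⁵NH₄⁺ | QC: no labeled N₂ may appear (preincubation removed NOx⁻) |
| `amm15_nit14` | ¹⁵NH₄⁺ + ¹⁴NO₃⁻ | QC: ²⁹N₂ but not ³⁰N₂ (anammox signature) |
| `nit15` | ¹⁵NO₃⁻ | the quantitative rate measurement |

## The pairing model and its inversion

Each N₂ molecule pairs two N atoms.  Denitrification draws both from the
nitrate/nitrite pool (¹⁵N mole fraction F_N = `f_no3`); anammox draws one
from the ammonium pool (F_A = `f_nh4`) and one from the nitrate/nitrite
pool.  Assuming random, independent pairing within each pathway, the
isotopologue fluxes are binomial in the label fractions (see
`isotope_core.pairing_forward`).  In the ¹⁵NO₃⁻ treatment F_A ≈ 0, and the
model inverts exactly:

    D = P30 / F_N²
    A = F_N⁻¹ [ P29 + 2 (1 − F_N⁻¹) P30 ]

with A the anammox rate, D the denitrification rate (both nmol N₂ g⁻¹ dry
soil h⁻¹) and P29, P30 the fitted excess production rates.  The anammox
share of total N₂ production is ra = 100·A/(A+D); it is undefined — never
reported as 0 — when A + D = 0.

Assumptions worth keeping in mind: random pairing within pathway (no
intracellular isotope fractionation), a single well-mixed NOx⁻ pool at a
known F_N, F_A ≈ 0 in the nitrate treatment, and linear accumulation over
the incubation (no substrate drawdown).  Coupled
nitrification–denitrification, Feammox, and substrate-limitation
corrections of potential rates to in-situ rates are out of scope; the QC
checks exist precisely to catch the first assumption failing.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `f_no3_default` | 0.9815 | mole fraction | nitrate tracer stock enrichment; after preincubation removes ambient NOx⁻ the post-spike pool is essentially all tracer. Overridden by a per-sample `f_no3` column when pools were measured. |
| `f_nh4` (inversion) | 0 | mole fraction | the ¹⁵NO₃⁻-treatment assumption; natural-abundance ¹⁵NH₄ contributes to the subtracted baseline, not to excess. |
| ammonium stock enrichment | 0.9914 | mole fraction | used by the generator for the ¹⁵NH₄⁺ treatments. |
| natural ¹⁵N abundance | 0.00366 | mole fraction | unlabeled-pool default. |
| `alpha` | 0.05 | — | significance level throughout (slope tests, QC, Duncan, t-tests). |
| `bootstrap_iterations` | 1000 | — | percentile CIs; 0 disables. |
| `rate_window` | none | h | optional initial linear window for the slope fits. |

## Rate regression

Production rates are ordinary least-squares slopes of excess amount versus
time, pooling all replicate points into one regression (with triplicate
vials this maximizes error df; per-replicate fits are also computed and
feed the group statistics and, optionally, the bootstrap).  Accumulation
is tested one-sided (slope > 0, t with n−2 df): production cannot be
negative at the pathway level.  Any design with ≥ 3 distinct time points
is accepted; missing values are dropped pairwise with a logged warning.
Raw (non-excess) amounts are converted by subtracting the time-zero mean
per series (`t0_mean` policy); data already expressed as excess pass
through unchanged.

Noise can push the inverted rates slightly negative; they are clamped to
zero, flagged in the report and logged, and ra is recomputed from the
clamped values.

## Uncertainty

Nonparametric bootstrap over replicate vials: within each kill time the
observations are resampled with replacement, both slopes refit, the
inversion reapplied; 95% percentile intervals over (default) 1000
iterations.  The bootstrap seed is part of the configuration and is echoed
in the report's provenance block; reports are byte-identical across reruns
with the same inputs, config and seed.  The bootstrap avoids the
linearity assumption a delta-method propagation through the inversion
would need.

ra is reported both from the mean rates (primary) and as the mean of
per-replicate ra values (secondary, `per_replicate.ra_mean`); with
triplicates and low noise the two agree closely, and reporting both makes
the choice auditable.

## Group statistics

Means ± s.e. (sd/√n) per group; one-way fixed-effects ANOVA; two-group
contrasts (rhizosphere vs non-rhizosphere within each fertilization
level) by pooled-variance Student's t-test; multi-group displays by
Duncan's multiple range test at protection level 1−(1−α)^(r−1) for a span
of r ordered means, with least significant ranges computed from the
studentized-range distribution (`scipy.stats.studentized_range`, so any
error df is supported rather than interpolating printed tables) and the
harmonic mean of group sizes in the range standard error for unbalanced
designs.  The classical step-down underlining procedure yields the
compact letter display; groups sharing a letter do not differ at α.  The
display is invariant to group input order.  Duncan's procedure is known
to be liberal; a seeded simulation test pins its familywise error for 4
groups of n=3 inside the 0.04–0.25 band at α = 0.05.

## The synthetic-data generator

`synthetic_data` emulates the incubation design: four sample groups
(rhizosphere/non-rhizosphere × control/N-fertilized) with default true
rates set to the reported group values (A/D = 0.33/0.74, 0.64/0.92,
0.08/3.66, 0.26/9.42 nmol N₂ g⁻¹ h⁻¹), all three treatments, the 5-point
kill grid, triplicates, and additive Gaussian noise (default sd 0.5 nmol
N₂ g⁻¹, a fixture choice — real-instrument noise is not recoverable from
published values) on linearly accumulating excess amounts.  Additive
(not multiplicative) noise matches the linear-regression estimand and
keeps time-zero scatter realistic.  All randomness flows through one
seeded generator, and the generating parameters are written to a truth
table for recovery scoring.

Treatment label fractions: the labeled pool gets its stock enrichment;
the unlabeled nitrate pool in the ammonium treatments gets natural
abundance (it sets the tiny ³⁰N₂ flux the signature check must *not*
detect); the ammonium pool in the nitrate treatment gets exactly zero,
because its natural ¹⁵N belongs to the subtracted baseline — this also
makes noise-free recovery exact, a deliberate validation contract.

Failed preincubation is modeled as a residual unlabeled NOx⁻ pool
(`residual_nox`, µM): in the ¹⁵NH₄⁺-only treatment NOx⁻ is the limiting
substrate, so effective process rates scale as min(residual/100 µM, 1).
With no residual pool nothing runs and both channels are pure noise; with
one, anammox of labeled ammonium produces the ¹⁵N₂ signal the
preincubation check screens for, and the failure rate grows monotonically
with pool size.  (A label-leakage mechanism into the NOx pool would give
a similar signature; the substrate-gating mechanism was chosen because it
also reproduces the no-residual null exactly.)

`simulate_pairing_stochastic` is a molecule-by-molecule oracle: pathway
assignment proportional to (A, D), then independent Bernoulli atom labels
— deliberately sharing no arithmetic with the closed-form fluxes it
cross-checks (agreement within binomial error at 10⁶ molecules is an
acceptance test).

What the generator does **not** emulate: substrate drawdown (saturating
accumulation), headspace/dissolved-gas partitioning, instrument drift,
between-vial heterogeneity in dry mass or label fraction.  Passing
recovery tests therefore demonstrate correctness of the estimator under
its own assumptions, not robustness to their violation.

## Numerical and degenerate-input choices

* Slope fits require ≥ 3 distinct times and nonzero time variance;
  perfect fits (zero residual) get one-sided p of 0 or 1 by slope sign.
* ra is displayed as nearest-integer percent, halves away from zero;
  full precision is retained internally and in JSON.
* ANOVA with zero total variance, t-tests with both groups constant and
  equal, empty groups, f_no3 = 0, and A + D = 0 all raise typed errors
  rather than returning sentinel numbers.
* Ties between group means cannot flip Duncan verdicts (gap 0 never
  exceeds a nonnegative range); sorting is stable.
* QC failure annotates (`validated: false`) but does not abort: the
  rates remain computable and inspectable.
* Problem sizes in the validation suite (e.g. 100 simulated experiments
  for recovery, 200 for QC operating characteristics, 2000 for the
  Duncan null band, 10⁶ oracle molecules) were sized to keep Monte-Carlo
  error well inside the asserted margins.

## Known limitations

Rates are potential rates of an amended, mixed slurry; the package makes
no in-situ correction.  The inversion ignores anammox ³⁰N₂ production
from a labeled ammonium pool (fine when F_A ≈ 0, wrong if applied to the
ammonium treatments — which is why the pipeline only inverts the `nit15`
series).  The bootstrap resamples vials within kill times and so captures
measurement and vial-to-vial noise, not systematic error in F_N.
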