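# n2part

Partition soil N₂ production between **anammox** (anaerobic ammonium
oxidation) and **denitrification** from ¹⁵N isotope-pairing slurry
incubations.

Soils lose fixed nitrogen as N₂ through two anaerobic pathways:
denitrification reduces NO₃⁻/NO₂⁻ stepwise to N₂ (both N atoms
nitrate-derived), while anammox combines NH₄⁺ with NO₂⁻ (one
ammonium-derived and one nitrite-derived atom per N₂).  Incubating soil
with ¹⁵NO₃⁻ and measuring the excess production rates P²⁹ and P³⁰ of the
isotopologues ²⁹N₂ and ³⁰N₂ separates the two, because random atom
pairing within each pathway fixes the isotopologue proportions: with F_N
the ¹⁵N mole fraction of the nitrate pool,

```
D = P30 / F_N²                            (denitrification rate)
A = F_N⁻¹ [ P29 + 2 (1 − F_N⁻¹) P30 ]     (anammox rate)
ra = 100 · A / (A + D)                    (% of N₂ production by anammox)
```

all rates in nmol N₂ g⁻¹ dry soil h⁻¹.  The package implements the full
analysis chain for vial kill-time series (default 0/3/6/12/24 h,
triplicate vials): treatment-based QC (¹⁵NH₄⁺ control: no labeled N₂;
¹⁵NH₄⁺+¹⁴NO₃⁻: ²⁹N₂ but not ³⁰N₂ — the anammox signature), OLS
production-rate regression with one-sided accumulation tests, the
pairing-model inversion with bootstrap confidence intervals, and the
comparison layer (means ± s.e., one-way ANOVA, Duncan's multiple range
test with compact letter display, Student's t-tests).  A synthetic
incubation generator and a stochastic atom-pairing oracle make every
stage testable without instrument data.

Intended users: biogeochemists and microbial ecologists analyzing
¹⁵N-tracer incubations of soils and sediments, and anyone needing a
transparent, reproducible reference implementation of the isotope pairing
technique with its control logic.

## Worked example

```
n2part simulate demo --seed 1          # synthetic experiment + truth table
n2part run demo/timeseries.csv -o report.txt --format text_table --seed 1
```

```
sample    zone            fert        anammox  denitrif   ra_%   ra  A   D   ra  QC
---------------------------------------------------------------------------------------
NC        non_rhizosphere control       0.090     3.653   2.41   2%  a   c   a   ok
NN        non_rhizosphere N             0.270     9.435   2.78   3%  b   d   a   ok
RC        rhizosphere     control       0.314     0.735  29.93  30%  b   a   b   ok
RN        rhizosphere     N             0.643     0.928  40.94  41%  c   b   c   ok

rates in nmol N2 g-1 dry soil h-1; groups sharing a letter do not differ (Duncan, alpha=0.05)
```

The generator's default true rates are A/D = 0.33/0.74 (rhizosphere
control, RC), 0.64/0.92 (rhizosphere fertilized, RN), 0.08/3.66 (bulk
control, NC) and 0.26/9.42 (bulk fertilized, NN) nmol N₂ g⁻¹ h⁻¹; at the
default measurement noise (sd 0.5 nmol N₂ g⁻¹) the pipeline recovers them
within a few percent, the anammox shares land near 30/41/2/3%, QC passes,
and Duncan letters separate the rhizosphere groups from the bulk groups.
JSON output (`--format json`) adds bootstrap CIs, per-replicate rates, QC
evidence and a provenance block (config, seed, input checksum); reruns
with the same seed are byte-identical.

Single inversions work without files:

```
$ n2part rates --p29 0.64 --p30 3.85
anammox         0.5042 nmol N2 g-1 h-1
denitrification 3.9965 nmol N2 g-1 h-1
ra              11.20% (displays as 11%)
```

or from Python:

```python
from n2part import LabelFractions, ProductionRates, ipt_invert, contribution
proc = ipt_invert(ProductionRates(p29=0.63601, p30=3.85337),
                  LabelFractions(f_no3=0.9815))
proc.anammox, proc.denitrification   # (0.5000, 4.0000)
contribution(0.33, 0.74)             # 30.84 -> displays as 31%
```

See `docs/methods.md` for the model, its assumptions, all tunable
parameters, and what the synthetic generator does and does not emulate.

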