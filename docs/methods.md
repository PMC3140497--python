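# Methods

This note documents the statistical procedures, the synthetic-data model,
and the design choices made where the underlying field protocol left the
analysis under-specified.

## Data model and filtering

An observation is one prey encounter: dive, site kind (systematic belt
transect vs unmeasured verification dive), transect id, replicate pass,
sampling mode (sponging / non-sponging), family, optional species and
length, and an identified flag.  Two exclusion rules produce the analysis
set:

* **Length.** Prey strictly shorter than `min_length_cm` (default 7 cm)
  are removed: prey this small are obtainable at the surface in every
  habitat and are not plausible sponge-foraging targets.  The inequality
  is strict — a 7.0 cm prey is retained.  Observations with *no* length
  estimate are retained, because only prey known or estimated to be small
  were excluded from the survey data; dropping unmeasured prey would be
  silent data loss.
* **Identification.** Prey not identifiable to family are removed by the
  identified flag alone.  In the survey all unidentifiable prey were also
  sub-threshold, so the two rules overlap there, but one rule suffices and
  makes the filter order-independent.  Both rules are idempotent and
  monotone, and they commute.

All analysis is at the family level.  Family names are matched exactly
after whitespace/case normalization, so the two stingray species collapse
into a single Dasyatidae record.

## Scopes and replicate averaging

Descriptive summaries (pooled abundance table, percentage shares,
extraction interval) use raw integer counts pooled over **all dives**,
transects plus verification.  Inference uses the **systematic transects
only**, where sponging and non-sponging covered equal substrate.  On that
branch the two replicate passes of each transect are averaged into a
single transect value; a family absent from one replicate contributes zero
to its mean (a family seen on one of two passes was genuinely absent on
the other).  Averaging happens *before* ratios are formed, so each
transect contributes one paired value.

## Pseudocount ratio and the exact signed-rank test

The per-transect statistic is `(x + 1) / (y + 1)` where `x` and `y` are
the (possibly fractional, post-averaging) counts of prey without and with
swimbladders.  The +1 offset keeps the ratio finite and positive when
either count is zero; an empty transect yields the neutral value 1.

Both paired comparisons use an exact Wilcoxon signed-rank test: zero
differences are dropped (`n_effective` counts the rest), absolute
differences are ranked with midranks for ties, `W` is the rank sum over
positive differences, and the null distribution is obtained by full
enumeration of all `2^n` sign assignments (implemented as a lattice
convolution over doubled ranks, checked in the tests against literal
enumeration).  The two-sided p doubles the smaller tail and caps at 1:
`p = min(1, 2·min(Pr(W' ≤ W), Pr(W' ≥ W)))`.  With `n = 7` and all
differences positive this gives `W = 28`, `p = 2/2^7 = 0.015625`, which
rounds to the conventionally reported 0.016.  Enumeration refuses beyond
`n = 20` (2^20 sign vectors); no large-sample approximation is provided,
deliberately — the design this package serves has 7 paired units.

The second test pairs **by transect**, not by family: per transect it sums
the abundance of the family set with nonzero total sponging abundance and
compares sponging vs non-sponging sums.  `W = 28` implies 7 paired units,
which identifies the transect as the pairing unit.

## Family-resampling test

The observed statistic — how many of the families extracted during
sponging lack swimbladders — is always computed from the data (6 of 8 in
the survey), never assumed.  The null draws `m` families uniformly with
replacement from the `N`-family candidate universe (`k` swimbladderless)
`B` times (defaults `m` = observed family count, `B` = 10,000) and counts
swimbladderless draws `X`.  Two two-tailing rules are implemented:

* **deviation** (default): p = proportion of resamples with
  `|X − mk/N| ≥ |x_obs − mk/N|`, compared in integer arithmetic
  (`|XN − mk|`) to avoid floating-point ties;
* **doubling**: twice the smaller empirical tail at `x_obs`, capped at 1.

The deviation rule is the default because with one tail empty it reduces
to a one-tailed tail sum, matching the magnitude of the reported Monte
Carlo p (≈0.013) for the survey configuration.  Since the draw is with
replacement, `X ~ Binomial(m, k/N)` exactly; the closed-form tail
(`p_exact` = 0.013514 for N=29, k=9, m=8, x=6) is computed on every run as
a cross-check, and tests assert `|p_mc − p_exact| ≤ 3·sqrt(p_exact(1 −
p_exact)/B)`.  A single integer seed drives one PCG64 generator; resamples
are `B × m` uniform family indices.

The universe always comes from the annotation file.  The historical
portion of the 29-family universe was published only as supplementary
material, so the bundled annotation list uses synthetic stand-in names for
those 16 families (3 swimbladderless, bringing the universe to 29 with
k = 9 — the composition consistent with the reported resampling p-value);
only the swimbladder tallies enter any computation.

## Synthetic study generator

The generator emulates the field protocol: 7 transects × 2 replicates × 2
modes, plus 6 verification sites swum once per mode (the verification
protocol was informal — no tape measure — so no replicates there).
Per-family encounter counts per pass are negative binomial with mean
`base_rate` (× `sponging_multiplier` under sponging) and dispersion 5
(ecological counts are overdispersed; `nb_dispersion=None` selects the
Poisson limit).  Lengths are log-normal per family — positive and
right-skewed; the sandperch profile matches the measured 12.6 ± 4.7 cm,
and several families sit partly below the 7 cm threshold.  A prey below
threshold is unidentifiable with probability 0.5 (the survey reported 19
unidentifiable prey, all sub-threshold, but not the denominator; 0.5 is a
neutral choice).  Pass duration defaults to 3 minutes (50 m at the
protocol swimming speed of ~17 m/min).

The default catalog has the published local families plus the stand-in
historical families (locally absent: `base_rate = 0`).  The six local
swimbladderless families are burrowers with `base_rate = 3` per pass and
`sponging_multiplier = 10` — the strong-enrichment regime in which every
transect difference is positive with probability near 1; swimbladdered
families are free-swimming with multipliers ≤ 1 (the striped whiptail
profile is 0: never extracted by probing).  `null_variant()` sets every
multiplier to 1, giving identical encounter distributions in both modes —
a true null for the paired tests.

What the generator does **not** emulate: spatial structure of the bay,
tides/visibility, diver detection error, within-family species
composition, and any behavioral dynamics of the dolphins themselves.
Passing simulation-based tests therefore demonstrates the statistical
machinery's operating characteristics under the assumed count model, not
field realism.

## Operating characteristics

Two simulation properties are exercised by the test suite, with study
sizes chosen to keep the suite fast while leaving negligible Monte Carlo
ambiguity against the thresholds:

* **Type-I error**: over 2,000 null studies (`null_variant` catalog, no
  verification dives), the ratio test's rejection rate at α = 0.05 must
  not exceed 0.05.  The exact test is conservative under discreteness: at
  `n = 7` the attainable p-values nearest 0.05 are 0.046875 and 0.0625.
* **Power**: over 300 studies in the tenfold-enrichment regime, the
  pipeline must report the all-positive outcome (`W = 28`,
  `p = 0.015625`) in more than 95% of studies.

## Numerical choices

* Displayed percentages round half-up to integers (105/134 → 78%); raw
  values are kept to machine precision in the JSON report.
* p-values render with 3 significant figures; comparisons in code and
  tests always use exact values (0.015625, never 0.016).
* Reports serialize with sorted keys, so identical inputs + seed produce
  byte-identical JSON; fixture writing is deterministic the same way.
* Degenerate inputs fail loudly: all-zero differences raise a
  degenerate-sample error, an unannotated family names itself in the
  error, a zero-count extraction interval is a domain error, and pipeline
  stage failures carry the stage name.

## Known limitations

* The exact test only — by design there is no normal approximation, so
  `n_effective > 20` is an error rather than an estimate.
* The resampling test treats families as exchangeable under the null;
  unequal historical encounter rates across families are not modeled.
* No multiple-testing correction is applied (three planned tests, reported
  individually).
* The verification-dive effort (duration, area) is a free design
  parameter; nothing constrains it to match the field effort.
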