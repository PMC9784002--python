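# Methods

## Model and assumptions

The pipeline evaluates n regional units on three dimensions of a health
service — needs, utilization, resource allocation — each observed through
m_d indicators (the packaged maternal-services panel uses n = 31 and
m = 3/5/4).  Three assumptions drive the design:

1. **Within a dimension, indicators are exchangeable evidence for one
   latent quality.**  All indicators in a dimension receive equal weight;
   no cross-dimension composite is ever formed, because the comparison of
   the three dimensions *against each other* is the object of interest.
2. **Only relative position carries meaning across heterogeneous
   indicators.**  Values are reduced to ranks; the non-integer variant
   interpolates the rank linearly between 1 and n within the column range,
   retaining spacing information that integer ranks discard.  Ranks (and
   hence RSR) are invariant under positive affine transforms of any
   indicator column, so units of measurement never matter.
3. **RSR scores are approximately normal across units.**  This licenses
   the probit step: the downward cumulative frequency P of each score is
   mapped through the standard-normal quantile, and a straight line
   RSR ≈ a + b·probit is fitted.  The adjusted R² of that line is the
   practical check of the assumption; grading quality is further tested by
   ANOVA/SNK on the fitted values.

## Orientation

An indicator is *high-quality* if larger values are better and
*low-quality* otherwise.  Low-quality columns are ranked descending:
R = 1 + (n−1)(X_max − X)/(X_max − X_min), which is exactly n + 1 minus the
ascending rank, so both orientations fill [1, n] and the choice of sign
convention cancels out of every downstream statistic.  (Some printed
statements of the descending formula put the constant X_max − X_min in the
numerator, which would send every unit to rank n; the antisymmetric form is
the only one consistent with ranks spanning [1, n] and is what this package
implements.)  In the maternal panel exactly one indicator — maternal
mortality rate — is low-quality.

## Probit conversion

- P = (ascending tie-averaged rank)/n × 100%.  The largest score's
  P = 100% is replaced by 100·(1 − 1/(4n)) — the standard correction that
  keeps its probit finite; for n = 31 the corrected maximum is 99.19…%,
  which prints as 99.2.
- probit = Φ⁻¹(P/100) + 5, the classical probit with the +5 offset, so
  P = 50% maps to exactly 5.  Both conventions were confirmed by
  back-computing every pair in the packaged distribution tables.
- **Ties.**  Fresh computations average ranks, giving tied scores equal P
  and probit.  When an external source fixes the order of values that tie
  only at printed precision (the packaged tables were computed from
  unrounded scores and publish strict ranks), `rank_probit` accepts a
  `tie_break` vector and produces strict ranks instead.

### A note on the packaged distribution table

The published tables are internally inconsistent about three tie pairs
(two in the 2009 needs column, one in the 2019 resources column): the
rank table and the grading tables agree with each other on the order
inside each pair, while the distribution table swaps the two members.
The fixtures keep every table verbatim; recomputation follows the rank
table, so fitted values and grades reproduce per province everywhere,
while the distribution comparison treats each printed tie group as a set.
Because tied scores have equal RSR, the swap is invisible to the
regression, the grading and the classification.

## Fitted line and grading

- OLS of RSR on probit; slope, intercept, Pearson r, adjusted R² and the
  regression p-value are all exposed.  The goodness-of-fit number
  conventionally quoted next to these grading equations is the adjusted
  R², and that is what the packaged regression summaries store.
- Grade cut-offs default to probit 4 and 6 — one probit unit (one standard
  deviation of the underlying normal) below and above the centre 5.  Low
  iff probit ≤ 4, High iff probit ≥ 6, Medium otherwise; with n = 31 and
  no ties this always yields groups of 4/22/5 because 4/31 < Φ(−1) < 5/31
  and 26/31 < Φ(1) < 27/31.
- Critical RSR values are always computed from the full-precision fitted
  coefficients, never from rounded printed ones (rounding a and b can
  shift the third decimal of a + b·cut).

## Validation statistics

- One-way ANOVA of fitted RSR across grade groups.  Since fitted values
  are an affine transform of probits, F is identical whether computed on
  fitted values or probits (this invariance is tested).  If every fitted
  value is equal, F is defined as 0.
- Homogeneity of variances: Levene's test on the fitted values by grade.
  The choice of Levene (rather than Bartlett) is a package decision; it is
  the more robust default for small, possibly non-normal groups.
- SNK-q: the stepwise Student–Newman–Keuls procedure on the sorted group
  means, q = Δ/√(MS_w/2·(1/n_i + 1/n_j)), with studentized-range critical
  values at the span of each comparison and the usual protection rule (a
  pair inside a non-significant span is not tested).  Only the
  significant/not-significant verdict per pair is the primary output.
  Groups with fewer than two members are excluded from SNK (with a
  warning) but still enter the ANOVA.

## Classification

The two-level (2×2×2) WHO type table is fixed in code.  The three-level
27-cell extension ships as packaged JSON (`data/who_map_3level.json`) and
can be swapped for a corrected reading via `load_type_map(path)`; the
shipped map was validated by exact reproduction of both published years'
per-province types and all five category counts.  The type→category map
(A/H/F balance, B low input, D shortage, E overutilization, C/G waste) is
total on A–H, and the three-level map restricted to Low/High corners
equals the two-level table (both asserted by enumeration in tests).

Category transitions between two time points are reported purely
descriptively — a 5×5 count matrix plus the per-unit change list.  No
"improvement" ordering over categories is defined or applied, because the
categories are diagnoses, not ranks.

## Synthetic data

The generator emulates the structure the analysis assumes: per dimension a
standard-normal latent quality per unit, observed through indicator-
specific affine links (random positive scale, random offset) with additive
Gaussian noise of standard deviation `noise_sd` in latent units, and a
sign flip for low-quality indicators.  Defaults mirror the study panel:
31 units, indicators split 3/5/4, the first needs indicator low-quality,
noise_sd = 0.1 (a tenth of the between-unit spread — strong indicators, so
that rank recovery is good but not exact).  Identical configs and seeds
reproduce tables bit for bit.

What it does **not** emulate: cross-dimension correlation of latent
qualities (real needs and resources co-vary with wealth), heavy-tailed or
bounded indicator distributions (rates near 100%), measurement error
correlated across indicators, and year-to-year persistence.  Passing tests
on synthetic panels therefore demonstrates correctness of the rank/score
machinery and recoverability under the model's own assumptions, not
robustness to real-data pathologies.

## Problem sizes

All published-data computations are at the study's own size (31 units, 12
indicators, two years) and run in well under a second.  The Monte-Carlo
latent-recovery benchmark uses 30 replicates of n = 200 at noise 0.1; the
brute-force rank oracle enumerates all permutations up to n = 6.

## Known limitations

- The packaged fixtures carry printed precision (3 decimals); all
  fixture-based comparisons inherit ±0.005-scale tolerances from that.
- Exactly tied RSR values at a grade boundary would make the 4/22/5 split
  and the boundary convention (≤ cut → Low) interact; the published data
  never hits a cut exactly, and fresh continuous data almost surely will
  not, but deliberately constructed ties at a cut-off fall to the lower
  grade by the ≤/≥ convention.
- The regression p-value reported is the simple-regression F/t test; no
  heteroskedasticity correction is attempted (n is small and the fit is
  diagnostic, not inferential).
- Two-level grading mode is provided for the classic 2×2×2 table, but the
  packaged pipeline always grades three levels; there is no automatic
  two-level discretization of probits.
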