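# Methods

## Scope and data flow

The pipeline turns spontaneous adverse-drug-event (ADE) reports and
person-weighted prescription records into, per drug–ADR pair: a reporting
odds ratio (ROR), a severity score and grade, an underreporting-corrected
occurrence frequency, and drug–ADR–target association statistics. Stages run
in a fixed dependency order — qualification → pair aggregation → ROR →
severity → frequency → evaluation → association — with severity deliberately
ahead of frequency, because the underreporting rate applied to a pair is
keyed to its assigned grade.

## Report qualification

Reports are qualified by: duplicate-id removal (first occurrence kept),
exclusion of nonprofessional reporters, removal of mentions under five
non-drug-induced system organ classes (the report is dropped only when no
mention survives; unknown SOC labels are retained), and restriction to
single-ingredient small-molecule drugs. Drug mentions resolve through three
routes in order — product code, exact synonym, cleaned name (case-fold,
strip a configurable dosage/form stop-token list, collapse whitespace) —
with ambiguous cleaned matches flagged unresolved rather than guessed. ADR
terms resolve case-insensitively through a preferred-term synonym table.
Unresolved mentions are flagged and audited, never silently dropped.

Contingency counting is at report granularity: for a pair, `a` is the number
of distinct reports mentioning both the drug and the ADR, `b`/`c` the
reports with only one of the two, `d` the remainder, so a+b+c+d equals the
qualified-report count for every pair. A report with several ADRs feeds
every pair it supports; a missing outcome code still counts in `a` but adds
nothing to the outcome tallies. Support filtering keeps pairs whose ADR has
≥2 reports, whose drug has ≥26 reports, and with ≥2 reports for the pair
itself (≥ semantics), all computed on pre-filter totals so order is
irrelevant. The drug threshold counts reports (not mentions); both the
interpretation and the numbers are configurable.

## Disproportionality

ROR = ad/bc with the Woolf log-normal 95% CI. With the Haldane–Anscombe
correction (default on), 0.5 is added to every cell when any cell is zero;
with it off, b·c = 0 raises an explicit undefined-result error instead of
returning infinity. The significance filter retains pairs with ROR > 1 and
one-sided P < .05 on ln ROR (z > 1.645). This one-sided 5% construction was
chosen over "95% CI lower bound > 1" (a 2.5% test) so the filter's type-I
rate matches its nominal 5% level; the reported 95% CI columns are unchanged
by the choice. Target–ADR odds ratios use the same machinery but a
two-sided test (CI excludes 1), as both directions are of interest there.

## Severity model

Score = σ(ROR) · Σₖ wₖ pₖ / log₂(penaltyₖ + 1), penalties (5,4,3,2,1),
weights (1,2,3,4,5), σ = 1/(1+e^(−log₂ ROR)). The functional form is
validated by an identity test: the five pure-outcome extremes at σ = 1 must
reproduce the printed boundaries 1/log₂6 = 0.387, 2/log₂5 = 0.861,
3/log₂4 = 1.500, 4/log₂3 = 2.524, 5/log₂2 = 5.000 at three decimals. The
form is isolated in one function (`severity_score`) so it can be swapped
without touching the pipeline.

Conditioning of P(Oₖ|Aⱼ) defaults to **per pair** (the pair's own reports);
a per-ADR pooled scope is available by config. Per-pair is the default
because observed per-drug score spreads for a single ADR can exceed the
2-fold spread that σ alone (0.5–1.0) permits, which rules out purely
ADR-global conditioning. Pairs with no outcome-bearing reports are excluded
from scoring with an audited count.

Grade zones are lower-open/upper-closed with 0 in the mild zone. Both the
score and the edges are rounded to three decimals before comparison —
matching the printed three-decimal boundaries — which is the only convention
under which a score printed as 0.387 is mild *and* each pure-outcome extreme
lands in its own grade (the full-precision moderate edge is 0.861354…,
which three-decimal rounding places back in moderate). Non-monotone custom
penalty/weight vectors are rejected when deriving boundaries, since their
grades would be ill-ordered.

## Frequency estimation

AAP (average annual prescriptions) per drug is the person-weight sum of its
resolvable prescription records over the period divided by the number of
period years. Drugs absent from the survey inherit the mean (default;
median by config) of direct AAPs in their ATC level-2 class; drugs with no
ATC code or an empty class stay unavailable and are audited. Then
Freq = n_reports / ((1−URR) · AAP · yr) with URR 0.77 for grades
life-threatening/death and 0.94 otherwise, yr defaulting to 8 (configurable;
an 8.25-year quarterly window is commonly truncated to 8). Estimates above
1 are clamped with a warning — the corrected-count estimator is not
probability-bounded. Frequency classes are left-closed/right-open at 10⁻⁴,
10⁻³, 10⁻², 10⁻¹; values within 10⁻⁹ (relative) below an edge are treated
as on the edge so that exact quotients are classified stably under floating
point.

## Grade evaluation

On the preferred terms shared with an expert table, a term is *consistent*
when the expert grades are a subset of the model's (the model set being the
union of grades over the term's retained pairs), *partially consistent* when
the sets overlap otherwise, *inconsistent* when disjoint. Strict set
equality is reported separately for transparency. Percentages are printed
to 2 dp; zero mutual terms yields an explicit empty summary.

## Target association

Pairs are crossed with their drugs' targets into distinct entries; ADRs
with exactly one target and targets with exactly one ADR are excluded in a
single pass on the initial counts (not iterated to a fixed point). Zone
assignment uses ≥-thresholds on OR and frequency; the numeric defaults
(OR ≥ 2, frequency ≥ 10⁻³) are this package's own operational choice for a
zone architecture that is otherwise defined only graphically, and should be
set explicitly in real analyses. Fatal-risk targets are those with
OR > threshold (default 2) against the pooled life-threatening/death entry
group, ranked by OR with ties broken by target id.

## Synthetic data

The generators emulate the structure the pipeline needs, not FAERS/MEPS
field nomenclature. Per drug–ADR pair and year, true events are binomial in
the prescription count and the pair's incidence; each event draws one
outcome from the pair's profile and is reported with probability 0.23 when
the outcome is "resolved with sequelae" or "fatal" and 0.06 otherwise
(the 77%/94% underreporting split, stratified on the drawn outcome). Each
reported event becomes a single-drug, single-ADR report with reporter class,
SOC label, optional product code, synonym/noisy name variants, and a
configurable fraction of missing outcomes and multi-ingredient flags.
Prescription volumes are split across 1–4 records per drug-year with
Dirichlet shares, so weight sums (not record counts) carry the volume.

Defaults that the study conditions do not pin down were chosen once as
plausible for this data type and documented here: 50% of pairs causally
linked with incidence 10^U(−4,−2); outcome profiles Dirichlet(5, 2, 1.5,
0.8, 0.7) (recovery-dominated, fatal outcomes rare); 10% nonprofessional
reporters; 10% of ADR terms under excluded SOCs; 5% multi-ingredient
mentions; 5% missing outcomes. Reporter mix and SOC distribution are
uniform-by-construction and config-overridable. Expert tables are generated
with largest-remainder allocation of subset/overlap/disjoint states so
configured fractions are hit exactly; target maps can plant one target at a
configured odds ratio among carrier drugs via odds-scaled membership rates.

What passing on this synthetic corpus shows: the estimators and filters are
correct and calibrated under the generating model (independent reports, known
thinning, clean ontologies). What it cannot show: robustness to duplicate
reports, reporting bias beyond the two-stratum thinning, polypharmacy
confounding, real vocabulary mess, or the headline counts of any real-data
analysis — those require the actual regulatory corpora.

## Problem sizes and numerics

Default test/demo simulations use 8–20 drugs, 12–30 ADRs, 4–8 years and
10⁴–10⁵ prescriptions per drug-year (hundreds to low thousands of reports),
which is ample for the calibration bands asserted (±2 percentage points on a
5% rate over 1,000 tables; 10% relative error on the mean of 20 frequency
replicates at ≥200 expected reports each). Null-calibration tables are
drawn multinomially at 5,000–8,000 reports so the normal approximation
behind the Woolf CI is in its working range. All randomness flows through
numpy `SeedSequence` streams spawned from a single config seed; identical
configs give byte-identical artifacts.

## Known limitations

The severity score inherits spontaneous-reporting bias: severe outcomes are
overrepresented even after thinning-aware frequency correction, so grades
for rarely-reported mild ADRs rest on few outcomes. The Woolf CI and the
z-tests are asymptotic; very sparse tables lean on the 0.5 correction. AAP
inference by ATC level-2 mean is coarse when a class mixes blockbuster and
niche drugs. Frequencies assume every prescription is an equal exposure
(no dose or duration), and the clamp at 1 flags, rather than fixes,
inconsistent inputs.
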