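# Methods

## Knowledge-base model

A knowledge base is a triple (findings, explanations, associations).
Findings are terminology-coded observations (SNOMED-CT/LOINC or LOCAL for
synthetic data; codes are shape-checked as non-empty tokens, never resolved
against a terminology server).  Explanations are diseases (ICD-10/LOCAL) or
medication side effects (RxNorm/LOCAL).  An association weight w(s, d) is
read as the conditional frequency P(s | d) on [0, 1]; the exact value −1
marks a negating relation.  No other negative value is legal.

Demographic and geographic metadata are **binary eligibility filters**, not
score multipliers: an explanation restricted to {Africa} simply disappears
from a North-America query, matching the appear/disappear behavior of a
region selector in an interactive differential tool.  Empty region/age sets
and sex = ANY mean "no constraint" so partially curated entries stay usable.

Age buckets are half-open and gap-free: infant [0, 6) months, child
[6 months, 13 y), adult [13 y, 61 y), elderly [61 y, ∞).  The adult range is
conventionally printed as 13–60 years, so a 60-year-old (720 months) is an
adult and elderly starts at 61 completed years; the 12–13-year boundary is
resolved by making the child interval run up to the 13th birthday.

Textual frequency descriptions map to anchor weights
(always/all = 1.0, most/usually = 0.75, often/common = 0.5,
sometimes/occasional = 0.25, rare/rarely = 0.05, never = 0,
negating = −1).  The table is module-level configuration
(`dxcover.kb.TEXTUAL_WEIGHTS`) and deliberately replaceable: the anchors are
uniform reference points, not measured quantities.

Serialization is three UTF-8 CSV tables (or one YAML document) with rows in
sorted id order and a fixed number format ("-1" exactly for negations), so
saving is byte-stable and `load(save(kb))` is the identity on all fields.
Strict loading aborts on any invariant violation; lenient loading repairs
only weights inside [−1, 1] (clamped to the nearest legal value — a −0.5 is
plausibly a mistyped negation flag; a 15 is not) and still aborts on
everything else.  `validate()` never raises: it returns one message per
violation naming the entity, rule and offending value, which is what the
`dxcover validate` command prints.

KB statistics count **positive** associations only.  In the
findings-per-explanation histogram, explanations with no positive findings
occupy bucket 0; the "≤5 findings" percentage counts buckets 1–5, so an
empty relation yields 0%, not 100%.

## Diagnosis

Candidate filtering precedes scoring.  An explanation is ineligible for a
case iff it negates an observed finding, its region set is disjoint from the
case's (both non-empty), its age groups exclude the case's age group, or its
sex constraint conflicts.  Unspecified case fields filter nothing.  Negation
is a hard filter rather than a score penalty because a negating relation is
categorical (sex-incompatible conditions, pathognomonic exclusions), not a
matter of degree.

Single-explanation mode scores each eligible candidate additively,
score(d) = Σ_{s∈S, w(s,d)>0} w(s, d), sorts by (score desc, id asc), omits
zero scores (explanations unrelated to every observed finding are not shown),
truncates to k = 20 by default, and labels tie groups (scores equal within
1e−9).  A `tie_cut_flag` marks differentials whose last shown candidate ties
with the first hidden one, making the rank-list truncation artifact
observable instead of silent.

Multi-explanation mode maximizes the symptom cover weight
m(D) = Σ_s max(0, max_{d∈D} w(s, d)).  Per-symptom **max** aggregation
(rather than sum) is the standard weighted maximum-coverage objective; it
keeps m monotone and submodular, which is exactly what justifies the greedy
marginal-gain algorithm and its (1 − 1/e) guarantee.  Greedy stops at
max_size (default 3) or when the best gain falls to ε = 1e−12 (a pure
floating-point guard, far below the 0.01 weight resolution).  Ties break by
explanation id everywhere, making every output deterministic.
`brute_force_cover` enumerates all subsets of size ≤ max_size (refusing more
than 20 candidates), preferring at equal cover value the smaller set and
then the lexicographically smallest members; its members are emitted in
within-set greedy order so the gain trace is non-increasing like greedy's.

The naive-Bayes mode multiplies a prior (uniform over eligible candidates by
default) by Π_s max(w(s, d), 0.01) and normalizes over eligible candidates;
the 0.01 likelihood floor keeps a single unrecorded finding from
hard-zeroing a candidate in a sparse knowledge base.  The floor and prior
are parameters, not tuned constants.

## Evaluation protocol

Ranks map to nested buckets (1 → Top1, 2–10 → Top10, 11–20 → Top20, else
miss) and to utility 3/2/1/0.  Summary rows report Top-1 percentage,
**cumulative** Top-20 percentage (Top-1 and Top-10 hits included — the only
reading under which the Top-20 column dominates the Top-1 column), and mean
utility.  Internal values are exact; rendering rounds percentages to
integers and scores to two decimals.

The Wilcoxon signed-rank test discards zero differences (classic treatment,
recorded in the result for transparency), midranks ties, and takes the
smaller signed-rank sum as statistic.  For ≤25 non-zero differences the
two-sided p comes from the exact null distribution, computed by shift
convolution over doubled midranks — algebraically identical to enumerating
all 2^n sign assignments but O(n · Σr) instead of O(2^n).  Beyond 25, a
normal approximation with tie-corrected variance and a 0.5 continuity
correction is used; two-sided is the conservative default.  The
approximation is within 0.02 of exact for continuous differences at
10 ≤ n ≤ 25; with heavily tied discrete data near p = 1 the gap can be
larger in any implementation, which is why the agreement property is stated
for continuous differences while discrete tied fixtures are verified against
explicit enumeration instead.

## Synthetic data

The generator emulates the documented shape of a curated KB: ~2000
explanations (18% medications), ~8000 findings, weights drawn from the
textual anchor set with a mid-heavy default mixture (the real weight
distribution is unpublished; the mixture is configuration), a ~5% negation
rate, region restriction probabilities of 0.08 per continent, and 10%/5%
age/sex constraint rates.  The findings-per-explanation law is a
**single-inflated truncated negative binomial**: 1 + NB(r, p) truncated at
67 plus a point mass at degree 1.  A plain truncated negative binomial has
two parameters and cannot satisfy the three shape anchors simultaneously
(its best fit gives 10%/46%/31% against targets 14%/42%/28%); the point
mass adds the third degree of freedom and the least-squares fit — performed
at generation time with Nelder-Mead, so the anchors remain the configuration
surface — reproduces all three anchors to within 0.1 percentage point
(empirically 13.9%/42.4%/28.2% at n = 2000).

Cases sample a ground-truth explanation uniformly among those with at least
one positive finding; each positive finding is observed with probability
observe_prob(weight) (identity by default — the literal frequency reading of
the weights), negated findings are never observed, and n_spurious
distractors are drawn uniformly from findings neither associated with nor
negated by the truth.  Demographics are sampled consistently with the
truth's constraints so the truth is always eligible for its own case.  A
case that observes nothing is redrawn; after 200 empty draws the truth's
highest-weight finding is observed directly, guaranteeing termination for
extreme configurations.  Distractors carry no co-occurrence structure and
the generator models no disease co-occurrence or epidemiological prevalence
— recovery results on synthetic cases therefore measure the engine's
behavior under independent noise, not clinical accuracy on real case mixes.

Noiseless perfect recovery (Top-1 recall 100%) is only guaranteed when
explanations have **disjoint** positive-finding signatures: with overlapping
signatures an explanation with higher weights on a subset of the observed
findings can legitimately outscore the truth.  The generator's
`unique_signatures` option assigns disjoint finding blocks for exactly this
experiment; it requires the finding pool to be at least the sum of degrees
(16 000 findings for 2000 explanations at the default shape) and raises a
configuration error otherwise.

## Problem sizes in the shipped tests

The test suite exercises greedy-vs-oracle agreement on 200 random instances
of up to 12 candidates × 15 findings (brute force enumerates ≤ 298 subsets
each), 1000 monotonicity/submodularity probes, exact signed-rank checks
against explicit 2^n enumeration up to n = 12, and recovery runs of 200
cases per noise condition on a 2000-explanation KB.  These sizes make the
whole suite run in well under a minute while keeping every statistical check
at a scale where its expected behavior is unambiguous.

## Known limitations

No synonym resolution (an exact-prefix autocompleter only), no terminology
resolution, no severity or temporal presentation modeling, no
medication–disease combination explanations in the evaluation path, and the
greedy engine scores only what is observed — it cannot require key findings
or penalize their absence.
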