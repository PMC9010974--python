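# Methods

`resuslearn` implements the measurement and analysis machinery of a
randomized training study comparing digital game-based learning (DGBL)
against a classic taught session for neonatal resuscitation, and a
synthetic-cohort generator that makes the whole pipeline testable without
any participant data. This note records the models, the parameters that
matter, and the choices made where the design was genuinely open.

## Scoring

**Knowledge test (negative marking).** A fixed bank of 21 six-option
questions, one keyed answer each, is scored +1 per correct answer, 0 per
unanswered question and −0.2 per incorrect answer, then normalized by the
number of questions; the normalized score lives in [−0.2, 1]. The −0.2
penalty is calibrated to the option count: under uniform random
answering the per-question expectation is (1/6)(+1) + (5/6)(−0.2) = 0,
so guessing carries no expected reward. `expected_random_score` returns
this expectation analytically for any bank/penalty; a vectorized
Monte-Carlo check (`monte_carlo_random_score`) simulates random sheets
and reports the mean with its standard error.

Percent printing: knowledge percentages are **truncated** to one decimal
(9/21 → 42.8) while equipment-category percentages are **rounded**
(19/21 → 90.5). The two conventions are kept separate as
`percent_floor` / `percent_round`; full precision is retained internally
and in machine-readable output.

**Equipment check.** The 40-item checklist is split into 21 totally
correct, 6 partially correct and 13 incorrect items. Selections are
counted per category and normalized by the category size. Categories are
reported separately and never netted: whether wrong picks should offset
right ones is a scoring-policy question the package does not decide.

**Act-timing regularity.** For ventilation/compression games the learner
produces acts at times t_1 < … < t_n (seconds); intervals
Δ_i = t_i − t_{i−1} are converted to hundredths of a second and judged
against the allowed band [min_timing, max_timing] = [1/max_freq,
1/min_freq]. Frequencies include the virtual assistant's interleaved
acts (+30/min for compressions, where the assistant delivers one breath
per three learner compressions; the assistant's own acts are never
scored). Band bounds are **floored** to integer hundredths — 6000/130 =
46.15 → 46 and 6000/110 = 54.54 → 54 — because rounding half-up would
give 55 and change the published band. A requested band narrower than
one hundredth (the output resolution) is rejected as degenerate.

The per-interval deviation is d_i = 0 inside the (closed) band and
otherwise, by default, the distance to the **far** endpoint,
max(|Δ_i − min|, |Δ_i − max|). A `nearest_endpoint` mode (distance to
the violated bound) is provided because "deviation from the reference
values" is also naturally read that way; the modes agree on which
intervals score zero and differ only in violation magnitude. The series
summary is the mean of the d_i (0 iff the rhythm never left the band)
and their standard deviation (irregularity). The standard deviation uses
the population divisor n by default; `ddof` switches it. Series with
fewer than two acts yield NaN summaries — missing, never a spurious
perfect 0.

**Game sessions.** Per question category the session score is
(number correct)/(questions asked); a "get help" choice is neutral — it
stays in the denominator and adds nothing, so the fraction is in [0, 1].
A points variant applies the in-game marking with a configurable penalty
(default −0.2, mirroring the written test; the in-game magnitude is a
design choice, only its sign is fixed). Response times are summarized by
medians.

## Design: stratification and the Monte-Carlo KS check

The competence stratum is the count (0–3) of prior experiences among
simulator practice, theoretical training and clinical practice.
`stratified_assign` splits each stratum between the groups in proportion
to the global target sizes, within one learner per stratum
(largest-remainder apportionment of the first group's quota); for equal
targets this is the classic ±1 balanced split. Strictly equal-within-one
stratum splits cannot reach unequal global targets like 27/21 with four
strata, so proportional shares are the operative notion of balance here.

`monte_carlo_design_check` asks how often a completely random division of
the roster (into the same group sizes) would have produced a smaller
two-sample Kolmogorov–Smirnov distance D on the pre-training scores than
the realized design did. The comparison is strict (D < d); 100,000
replicates by default. The null is simple random partitioning — not
stratified — because it models a fully random experimental design. The
implementation sorts the scores once and, per replicate, permutes group
labels over the sorted positions; D is the maximum |cumulative ECDF
difference| read at the last index of each tied run, which handles ties
exactly and vectorizes to ~0.4 s per 10⁵ replicates at n = 48. The
two-sample KS distance itself (`ks_distance`) is evaluated at the pooled
unique values; tests cross-check it against `scipy.stats.ks_2samp` and
the Monte-Carlo null against brute-force enumeration of all splits of a
small roster.

## Statistical battery

Routing follows the classical scheme: Shapiro–Wilk normality on each
sample and a variance-homogeneity check decide between t-tests and the
conservative nonparametric pair (Wilcoxon signed-rank / Mann–Whitney U).
Repeated measures across the three test administrations are gated by a
Friedman test; post-hoc pairwise tests run only when the gate opens
(p < α), carry a Bonferroni factor m, and are refused — with an explicit
`GateClosedError`, overridable by `force=True` for exploratory tables —
when it does not.

Conventions the source procedures leave open, fixed here and flagged:
Wilcoxon drops zero differences and uses the exact null for n ≤ 25
without ties, otherwise the normal approximation with continuity
correction; Mann–Whitney uses the exact distribution for groups ≤ 25
(even under ties, where it is conservative) and the tie-corrected normal
approximation above; the Friedman statistic is computed directly with
the standard tie correction (supporting k = 2 timepoints, where it
reduces to a sign test — needed for the drug-administration category
present only in sessions 1 and 4); fully tied data yield statistic 0 and
a closed gate.

**Pitman–Morgan.** Equality of variances for paired samples: with
F = s_x²/s_y² and Pearson r of the pairs,
t = (F − 1)·√(n − 2) / (2·√(F(1 − r²))) on n − 2 df. Degenerate inputs
(n < 3, a zero-variance margin, |r| = 1 with F ≠ 1) raise; an exact copy
up to a shift (F = 1, |r| = 1) returns t = 0. The identity
cov(x+y, x−y) = var(x) − var(y) makes the test equivalent to testing
zero correlation between pair sums and differences; the test suite uses
that equivalence as an independent oracle, and a 10⁴-replicate
simulation confirms the empirical type-I error sits in [0.04, 0.06] at
nominal α = 0.05 (n = 20, within-pair correlation 0.5).

## Synthetic cohorts

The generator emulates the study's structure: 48 learners split 21
(game) / 27 (classic), strata proportions (0.46, 0.27, 0.17, 0.10) over
competence levels 0–3, specialty years concentrated in the first two
years. Each learner has a latent ability (probability of answering
correctly) drawn around a per-stratum baseline (defaults 0.42–0.66,
SD 0.08); training adds a per-group gain (defaults: game 0.40, classic
0.28) and the follow-up subtracts a retention loss (game 0.01, classic
0.05, with larger spread for the classic group so follow-up variance can
grow). Question outcomes are independent Bernoulli given ability; wrong
answers split 0.8/0.2 between "incorrect" and "null". With these
defaults the written-test medians land near 43% pre-training and 70–84%
post-training with a stable follow-up.

Game sessions follow a learning curve: session-1 ability is the test-0
baseline +0.20, then increments (0.15, 0.10, 0.02) — the last one the
plateau. Response times are lognormal around a median decaying from
11.9 s by ×0.865 per session (→ ~7.7 s at session 4). Act series
accumulate Gaussian intervals around the band midpoint plus a systematic
offset; non-positive draws are resampled so timestamps stay strictly
increasing. Ventilation starts badly (offset +35, jitter 30 hundredths)
and improves ×0.55 per session; compression is too fast (offset −12 on
the [46, 54] band) with no improvement, reproducing the pattern of
clustered, uncoordinated compressions that never enter the allowed
band. A `deterministic` flag replaces all sampling with expected values
(rounded counts, exact medians, exact intervals) for exact-recovery
tests.

What the generator does **not** model: item difficulty or distractor
attractiveness (no IRT — every question is exchangeable given ability),
correlations between specialty year and stratum, practice effects on the
written test from repeated administration, or heavy-tailed response
times (a config hook exists for interval noise only). Passing tests
therefore demonstrate that the *procedures* behave correctly on data
with the study's structure, not that the study's empirical medians or
p-values are reproduced — those depend on unpublished per-resident data.

**Parameter recovery.** `parameter_recovery_suite` re-estimates, from
simulated session logs alone: per-session gains (differences of mean
fraction-correct — unbiased for the latent gain because the expected
fraction equals the ability), the response-time decay (geometric mean of
median ratios), and the session-1 ventilation offset (mean interval
minus target). Recovery is assessed with baselines low enough that
session abilities stay below 1: near the ceiling, clipping biases any
estimator of the latent gain, which is a property of the scale, not of
the estimator. Zero-noise exactness uses abilities whose products with
the per-category question counts are integral, so deterministic counts
represent them without rounding.

## Pipeline and reporting

`run_study` executes baseline equality (two-sided unpaired + KS
distance), the Monte-Carlo design check, per-group retention batteries
for knowledge and each equipment category (Friedman gate → one-sided
pre/post and two-sided post/follow-up Wilcoxon post-hocs with m = 2;
Pitman–Morgan variance decrease pre→post and increase post→follow-up),
the between-group one-sided comparison of post-minus-pre deltas, the
classic-vs-game F-test on follow-up variances, session learning curves
with one-sided monotonicity post-hocs (m = 5 for care/ventilation, 3 for
intubation/compression, matching the number of pairwise comparisons in
each family), rhythm-game summaries with the same machinery, and pooled
per-item selection counts, reported as a plain table in which an
all-zero row marks a poor distractor.

Paired analyses use complete cases only; learners missing a timepoint
are excluded and listed in the manifest. Every statistical row carries
test name, sidedness, n, α, Bonferroni m and the corrected threshold; a
closed gate appears as a status row with no p-value. Bundles are
deterministic — identical data, config and design seed give
byte-identical CSV/JSON output (stable column order, fixed float
formatting, sorted JSON keys). Dataset CSVs are written at full float
precision so that write → read → analyze reproduces the in-memory
analysis exactly.

The CLI (`resuslearn simulate | design | score | analyze`) is a thin
layer over these functions; `analyze` writes the full report bundle
(covering the report stage). Validation errors exit with code 2; closed
statistical gates are an in-band status, not a failure.

## Problem sizes and runtime

Defaults follow the study conditions: 48-learner cohorts, 100,000
design-check replicates, 10⁵-sheet random-answering checks. The test
suite uses the same sizes except where a property is invariant to scale
(small rosters for enumeration oracles; 2,000-replicate calibration
checks in the unit tier, with the full 10⁴-replicate Pitman–Morgan
calibration in the acceptance tier; 60–200 recovery replicates). The
full suite runs in well under a minute on one CPU.

## Known limitations

* The deviation statistic's far-endpoint default penalizes a violation
  by its distance to the *opposite* bound, so a just-outside interval
  near one endpoint scores at least the band width; analyses comparing
  magnitudes across differently sized bands should consider the
  nearest-endpoint mode.
* Stratified allocation balances strata counts, not the score
  distribution itself; on synthetic cohorts with large within-stratum
  score noise the realized KS distance can be mediocre even though
  strata are perfectly balanced — the design check reports exactly this.
* The Mann–Whitney exact method under ties is conservative; heavy-tie
  small-sample comparisons (e.g. equipment fractions) inherit that.
* Bonferroni is the only multiplicity correction offered, by design.
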