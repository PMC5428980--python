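# Methods

## The problem

Minute-level activity counts from wearable accelerometers carry
information about a person's short-term behaviour that whole-signal
summaries (power, entropy, mean, Pearson correlation) wash out.  The
question this package addresses is whether two groups of subjects — in
the motivating application, people who maintain a clinically meaningful
weight loss versus people who do not — can be separated by comparing the
*shape* of their activity signals rather than their moments.

## Windowed 0-dimensional persistence

A signal is a real-valued function `f` on `{1, …, n}`.  Conceptually we
sweep a horizontal threshold `t` upward and track the connected
components of the sublevel set `{i : f(i) ≤ t}` on the path graph
`1 — 2 — ⋯ — n`: a component is born at each local minimum and dies when
a local maximum merges it into a component with an older (lower)
minimum — the *elder rule*.  Each min–max pair `(birth, death)` is a
point of the persistence diagram; its vertical distance from the
diagonal `y = x` is the size of the excursion it represents, so points
near the diagonal are noise and distant points are pronounced activity
swings.

### Tie-breaking

Activity counts are integers, so ties are everywhere.  All comparisons
use the perturbed function `f̃(i) = f(i) + εi` with `ε` infinitesimal,
realised *exactly* as lexicographic comparison of `(value, index)`
pairs — no floating-point epsilon is ever added to data.  Under `f̃`
every value is distinct, so extrema and the elder rule are unambiguous;
a run of equal values behaves as a strictly increasing ramp.  Tied
extrema can produce zero-persistence points (`birth == death`), which
are retained.

### Sentinels

The boundary convention is `f(0) = +∞`, `f(n+1) = −∞`.  The left
sentinel makes a non-increasing start a local minimum; the right
sentinel makes the final plateau a local maximum and — because it is the
global minimum of the extended sequence — guarantees that the number of
minima equals the number of maxima.  Every diagram point is therefore a
finite pair; there is no essential class.  An equivalent informal rule
("drop the extremum with the largest x in the larger set") appears in
the literature; we implement only the sentinel formalism, under which
the counts never disagree.  One visible consequence: a strictly
increasing signal of length `n ≥ 2` yields one pair `(f(1), f(n))`,
while a strictly decreasing one yields the empty diagram.

### The pairing rule

Maxima `b_1 ⊏ b_2 ⊏ …` are processed in ascending `f̃` order.  For
`b_k`, the candidate set `U_k` holds the still-unpaired minima below it;
the partner is the largest candidate `a_i` such that no smaller
candidate lies positionally between `a_i` and `b_k`.  This is an `O(r²)`
literal transcription of the inductive definition, which is the right
trade-off here: windows contain ~20 samples, so `r ≤ 10`.  The test
suite proves the construction equal to an independently written
union-find sublevel sweep (elder rule with `(value, index)` seniority)
on 10⁴ random signals including heavy ties.

### Windowing

Signals are split into consecutive non-overlapping windows of
`window_length` samples (default 20; a 7000-minute recording gives 350
windows), with any trailing remainder dropped and no tapering.  One
diagram is computed per window, independently.  Short windows keep
paired extrema close in time — a minimum at breakfast is never matched
to a maximum three days later — and reduce cost by a large constant.
The known edge artefact (a window boundary that splits a monotone run
creates a false extremum on each side) is deliberately not corrected;
window lengths 15–25 behave comparably, which is the practical guard
against it.

## Diagram distances

Two windowed signals are compared window-by-window (first window against
first, and so on), giving a nonnegative distance signal whose arithmetic
mean is the scalar summary used downstream.  Three comparisons are
implemented:

* **Modified Hausdorff semimetric** (default).
  `d_mH(A,B) = max( mean_{a∈A} min_{b∈B} ‖a−b‖₂,  mean_{b∈B} min_{a∈A} ‖a−b‖₂ )`.
  Replacing the Hausdorff suprema with averages makes the value robust
  to a single outlying diagram point, which matters for spiky activity
  data.  It is symmetric, nonnegative and zero on identical diagrams but
  **violates the triangle inequality** — a semimetric.  Tests assert
  exactly the axioms that hold and deliberately not the one that fails.
* **Hausdorff distance**: the classical sup-min version, same Euclidean
  ground metric; kept as the outlier-sensitive reference point.
* **q-Wasserstein distance** (default `q = 1`): minimal assignment cost
  between the two point sets augmented with the diagonal, L∞ ground
  metric, so a point `(b, d)` may retire to the diagonal at cost
  `(d − b)/2`.  Solved exactly with the Hungarian algorithm on the
  `(|A|+|B|)²` augmented cost matrix; verified against exhaustive
  enumeration of all augmented matchings on small diagrams.  The ground
  metrics intentionally differ between the comparisons (Euclidean inside
  Hausdorff/modified-Hausdorff, L∞ inside Wasserstein), following the
  conventions each distance is usually defined with.

**Empty diagrams** arise from monotone-decreasing windows.  Policy
(default `"diagonal"`): two empty diagrams are at distance 0; a nonempty
diagram is measured against the diagonal `y = x` (directed average or
supremum of the points' distances `(d−b)/√2`), treating the diagonal as
the "nothing happened" diagram.  This is consistent with how the
Wasserstein construction already handles empties through augmentation,
so no special case is needed there.  A `"zero"` policy is available for
sensitivity analysis.

The per-window sweep used by cohort analysis is a vectorised
(padded/masked array) implementation of the same arithmetic; a dedicated
test pins it to the scalar per-window functions.

## Cohort statistics

Participants receive a weight-maintenance outcome from phase weights
`(w1, w2, w3)`: **failure** if `w2 > 0.85·w1` (less than 15% lost during
the intensive phase) or `w3 > 0.90·w1` (finished without maintaining a
10% loss); **success** if `w2 ≤ 0.85·w1` and `w3 ≤ 0.90·w1`;
**indeterminate** if the Phase-2 target was met but no Phase-3 weight
exists yet.  Indeterminate participants are excluded from pairing (with
a logged warning) rather than guessed.

Every unordered pair of labeled participants is compared and stratified
as FF, FS or SS; with 79 failures and 21 successes this gives
3081/1659/210 pairs.  Group tables report the unweighted mean and sample
(n−1) SD of pair values; group means are contrasted with an unpaired
two-sample t-test (pooled-variance Student by default, Welch by config).

**A caveat carried over deliberately:** pair values sharing a
participant are dependent, yet the t-test treats all pairs as
independent observations.  This replicates the procedure the pipeline
implements.  The consequence is a strongly anti-conservative test: on
null cohorts (zero group effect, 20+20 subjects) the nominal 5% FF-vs-SS
test rejects in roughly two thirds of cohorts, because the pooled SE
understates the variance of a group mean built from ~n²/2 dependent
pairs by a factor of about `√(1+2(n−2)ρ)`, where `ρ` is the correlation
between pair values sharing a subject.  The package therefore ships the
**random-label control**: labels are re-drawn uniformly (preserving
class sizes by default), the strata and t-tests are recomputed — the
pair values themselves are label-free and computed once — and the mean
p-value over trials is reported.  Group separation that survives this
control reflects signal structure; raw p-values from the pair t-test
should not be read at face value.

## The synthetic cohort generator

Minute counts are `round(max(0, circadian + bouts + noise))`:

| parameter | default | meaning |
|---|---|---|
| `signal_length` | 7000 min | recording length (~4.9 days) |
| `circadian_amplitude` | 650 counts/min | peak of the day-time baseline, a clipped 24 h sinusoid raised to power 1.5 (near-zero night troughs) |
| `bout_rate` | 0.045 /min | bout starts per minute at circadian peak (Bernoulli, profile-modulated) |
| `bout_duration` | 15 min | mean bout length (geometric) |
| `bout_amplitude` | 300 counts/min | mean extra activity during a bout (exponential) |
| `noise_scale` | 90 counts | SD of additive Gaussian minute noise at circadian peak (×0.15 at night) |
| `heterogeneity_delta` | 0.35 | log-scale SD of the failure group's per-subject factors |
| `n_failure`, `n_success` | 79, 21 | reference cohort composition |

The defaults were fixed once against the moments reported for a real
weight-management armband cohort (mean ≈ 290 counts/min, SD ≈ 334, power
≈ 1.96×10⁵): the generator family cannot match all three simultaneously,
and the frozen compromise produces mean ≈ 251, SD ≈ 371, power ≈
2.0×10⁵.  Group structure encodes the empirical observation that
activity profiles vary more between failures than between successes:
success subjects all use the base parameters, failure subjects
multiply amplitude, bout rate and bout amplitude by independent
log-normal factors of scale `heterogeneity_delta` and jitter their
circadian phase.  `heterogeneity_delta = 0` collapses the two groups
onto one distribution — the null configuration.

What the generator does *not* emulate: day-to-day routine differences
within a subject, weekday/weekend structure, device non-wear gaps,
autocorrelated bout intensity, or between-subject circadian phase
spread in the success group.  Passing pipeline tests on these cohorts
demonstrates that the machinery recovers injected between-subject
heterogeneity; it does not certify effect sizes on real recordings.
One visible artefact of the shared circadian phase: pairwise Pearson
correlations of synthetic signals are high (~0.7) where real cohorts
show near-zero values, since real subjects' recordings are not
clock-aligned.

Weight trajectories are generated per requested label so that the
labeling rule round-trips exactly (failures split between the
"insufficient Phase-2 loss" and "Phase-3 regain" modes).

All randomness descends from one integer seed through
`numpy.random.SeedSequence.spawn`; per-subject streams are independent
and no global state is touched.

## Numerical and design choices

* Indices are 1-based at the API surface, matching the `f(1..n)` signal
  convention; sentinel indices 0 and n+1 exist only inside the order
  relation.
* Empty and length-1 signals yield an empty diagram rather than an
  error, so windowing never fails on degenerate content.
* Zero-variance t-test input with equal means returns `t = 0, p = 1` by
  convention.
* Single-pair groups report SD as absent (`None`/empty field), never 0;
  absent groups are omitted from summaries, not zero-filled.
* `signal_power` is the mean squared amplitude and `signal_entropy` the
  Shannon entropy of a 16-bin equal-width value histogram normalised by
  `log(bins)`; both conventions are explicit, isolated and swappable,
  since "power" and "entropy" are used loosely in the activity-signal
  literature.
* Problem sizes in the test suite (10⁴ oracle signals of length ≤ 30,
  10³ Wasserstein pairs of ≤ 4 points, 100 effect-recovery and 200
  null-calibration cohorts of 20+20 subjects × 2000 minutes) were chosen
  to make the statistical assertions sharp at desk scale while the full
  suite stays in the minutes range.

## Known limitations

* The modified Hausdorff comparison is not a metric; any downstream use
  that assumes the triangle inequality (e.g. metric indexing) is out.
* The pair-level t-test is anti-conservative under dependence, as
  described above; use the random-label control.
* No window-boundary extremum correction, no overlap/tapering, no
  dynamic window sizing, no sleep/wake alignment preprocessing.
* Higher-dimensional homology, persistence landscapes/images and
  bottleneck distance are out of scope.
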