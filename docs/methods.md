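# Methods

This note documents the statistical model, the conventions and defaults the
package commits to, what the synthetic generator does and does not emulate,
and the numerical choices behind the fitting and simulation code.

## Thresholding quantities into outcomes

Raw records carry non-negative quantities per side (consumption in ml,
lick-visit counts, or 1/0 forced picks). Side-switched repeat sessions are
summed per subject × unordered pair before thresholding: side switching
exists to cancel positional bias, so its two halves are treated as one
comparison. With consumption share r = q_A/(q_A+q_B) and preference
threshold θ ∈ [0.5, 1):

- r > θ → A wins; r < 1−θ → B wins; 1−θ ≤ r ≤ θ → tie.

The tie window uses **closed bounds**: a share exactly at θ counts as a
tie. This makes θ = 0.5 ("tie only at exactly 50:50") the degenerate case
of the same rule rather than a special case. Pairs with zero total
consumption carry no directional information and are recorded as ties, with
a log warning. All storage and reporting uses the lexicographic orientation
of each pair, so loading side-swapped data changes nothing downstream.

## The worth model

Binary outcomes are modelled as Bradley–Terry comparisons,
P(i > j) = π_i/(π_i + π_j). The package maximizes this likelihood directly
rather than through the equivalent log-linear Poisson formulation; the two
routes share the same maximum, which the test suite checks against an
independent numeric maximization on small count fixtures. Worth values are
the normalized abilities w_i = π_i/Σπ_j; any constant rescaling of the
ability parametrization cancels under that normalization, so worths and
rank positions are parametrization-independent. Log-abilities λ are
reported under a sum-to-zero identification so the output is symmetric in
the option catalog.

**Tie handling** (`FitOptions.tie_handling`):

- `HALF_WIN` (default): a tie credits half a win to each side. Chosen as
  the default because it is robust with few subjects and keeps tied pairs
  as edges of the comparison graph.
- `DAVIDSON`: an explicit tie-propensity parameter ν, with
  P(tie) ∝ ν·√(π_iπ_j). Provided because a log-linear design can carry an
  undecided category; fitted by L-BFGS on (λ, log ν).
- `DROP`: ties are discarded.

**Fitting.** `HALF_WIN`/`DROP` use minorization–maximization (MM)
iterations, which are monotone in the likelihood and converge whenever the
MLE is finite. Convergence is declared when the largest log-ability change
falls below `tol` (default 1e-10); hitting `max_iter` (default 10,000)
raises a convergence error reporting the last gradient norm.

**Existence of the MLE.** The Bradley–Terry MLE is finite iff the directed
win graph is strongly connected. The fitter checks this before iterating:
with `damping=None` (the default), detection of separation — including
*group* separation, where a block of options loses every cross-comparison —
switches on a pseudo-count of 0.5 per ordered pair cell; otherwise no
damping is applied. An explicitly passed damping value is always honoured.
A disconnected comparison graph with zero damping raises an estimation
error naming the components. The applied damping is recorded in the fit log
and in every results export.

**Ranking.** Positions are dense ranks by descending worth (1 = most
preferred); exact worth ties share a position and set a flag.

## Quality measures

**Intransitivity ratio.** Per subject, every 3-subset of the subject's
option set is classified: cyclic iff all three pairwise relations are
decided and each option beats exactly one other. The ratio pools across
subjects: 100 × Σ cyclic / Σ C(n,3). The denominator is the **full**
C(n,3) per subject, including triples containing ties or missing
relations — ties make a triple non-cyclic but do not remove it from the
denominator. This convention is what makes reported values with tie-heavy
data (e.g. 60/110 triples at a 65% threshold) exact fractions of the full
triple count.

**Consensus error.** For each unordered pair, with n_A and n_B subjects
preferring each side, disagreement is d = 200·min(n_A, n_B)/(n_A + n_B):
0 at unanimity and 100 at an even split, which pins both published anchor
cases. Tied subjects express no direction and are excluded from n_A + n_B
by default (`tie_policy="exclude"`); a `"half"` policy that credits half a
subject to each side is available for sensitivity checks. Per-option CE is
the mean d over that option's pairs; overall CE is the mean of the
per-option values. Pairs with no decided subjects are excluded from both
means with a warning. The doubling of the minority share (rather than the
raw minority fraction) is required for CE to reach 100 and for values above
50 to be attainable at all.

## Positioning simulations

Given a target option compared only against `tested_against`, each run
completes every missing subject × (target, other) cell with a fair coin
between the two win directions (ties optionally included with a configured
probability, off by default), refits worths, and records the target's rank
plus the per-run I-ratio (fractional scale) and CE. Randomization is per
subject × pair — the only granularity at which per-subject tournaments, and
hence the per-run I-ratio, remain well defined.

- *Uninformed* mode keeps all runs; *informed* mode discards runs with
  I-ratio above `intransitivity_cutoff` (default 0.1) and reports the
  discard count. Retaining zero runs raises an error advising a larger
  cutoff or more runs.
- Per-option worth is summarized by mean ± z·sd/√k (normal-approximation
  95% CI) over retained runs, with pairwise CI-overlap flags.
- The ground-truth position for true-positive accounting is always the
  target's rank in a fit of the complete dataset, computed internally.
- The best run for tabular reporting is the lexicographic minimum of
  (I-ratio, CE), ties broken by run index; result tables carry the columns
  Item, Simulated position, Worth value, I-ratio, CE (%), Frequency of true
  positives, No. of true positives, Tested against.

**Run-count determination** (`determine_cutoff`) searches for the smallest
number of runs at which the target separates from every other option: run
counts grow on a doubling schedule (2, 4, 8, …, max_runs) to bound compute;
at each count the accumulated per-run worths are regressed on option
indicators with the target as reference level, the target-vs-other
contrasts are Holm-adjusted, and separation requires all adjusted p ≤ 0.05
*and* no 95% CI overlap with any other option. Exhausting max_runs sets an
`ambiguous` flag. The conjunction of the adjusted-p criterion with the
CI-overlap criterion is a deliberate design choice: descriptions of this
stopping rule elsewhere compare an interval width with a significance
level, which is not well defined; requiring both a significant contrast and
disjoint intervals is the conservative reading, and is flagged as an
interpretation rather than a canonical rule. With nothing to randomize the
answer is one run, unambiguous.

## Synthetic data

The generator emulates the two data shapes the pipeline is built for:

- `FORCED_CHOICE`: per subject × pair × trial, a (1,0)/(0,1) pick drawn
  with the Bradley–Terry probability of the generating worth vector;
  explicit ties injected at `tie_rate` as equal quantities.
- `CONSUMPTION`: per subject × pair × session, a pair of counts with
  expected shares (p, 1−p) and gamma–Poisson overdispersion: side means
  are gamma-perturbed (shape 1/noise) before Poisson sampling, so `noise`
  tunes how often a subject's observed ratio contradicts the generating
  preference. `noise=0` gives plain Poisson counts.

Scenario presets fix the study conditions for the valence-range contrast:
5 options, 11 subjects, 2 side-switched sessions per pair, consumption
style, worth vectors geometric with decay 0.45 (`WIDE_VALENCE`) or 0.9
(`NARROW_VALENCE`). Defaults `mean_total=100` counts per session and
`noise=0.25` were chosen once so that the generated quality measures at the
50% threshold land in the ranges observed in real high- vs low-valence
liquid tests (CE of order 10–20% vs 60–90%, I-ratio near 0 vs tens of
percent); with shape 1/noise = 4 the probability that a subject's counts
contradict a 0.69 generating preference is roughly 0.23, which produces
realistic disagreement without destroying wide-valence rankings.

**What the generator does not emulate:** side bias, session order and
satiation effects, subject-level heterogeneity in the worth vector, and the
empirical pattern where tie-heavy 65%-threshold data can show a *higher*
I-ratio than the same data at 50% (in the generator, raising θ converts
near-even pairs to ties, which can only remove cyclic triples, so the
generated I-ratio falls at 65%). Passing tests on synthetic data therefore
validate the estimators and the simulation machinery, not the full richness
of real consumption data.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated data:
oracle comparisons use up to 1,000 random tournaments on 5–7 options;
parameter recovery uses 500 forced-choice subjects; the valence contrast
uses 100 paired seeds; simulation behaviour uses 20 seeds × 40 runs per
tested-against size. These sizes give stable Monte-Carlo summaries at
desk scale. Every stochastic path takes an explicit seed (NumPy
`default_rng`); identical configuration and seed reproduce results
bit-for-bit, which the suite asserts for the simulation JSON and the CLI.

## Known limitations

- No covariates or subject effects in the worth model; heterogeneous
  populations are summarized, not modelled.
- CE and I-ratio are descriptive; the package deliberately attaches no
  significance tests to them.
- The consensus-error aggregation (option-mean of pair disagreements, ties
  excluded) is one of several defensible conventions; the `tie_policy`
  switch exposes the main alternative.
- Informed simulation with a tight cutoff on noisy data can discard every
  run; the error message suggests remedies rather than silently loosening
  the cutoff.
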