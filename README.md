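# pairworth

Scaled preference rankings from repeated binary choice tests.

Preference experiments — a mouse choosing between two liquids in a home-cage
system, a macaque drinking from one of two bottles, a person picking one of
two images — yield long tables of pairwise outcomes. `pairworth` combines
such repeated binary comparisons into a **scaled ranking**: not just the
order in which options are preferred, but how far apart they sit on a
probability scale. It is written for behavioural scientists and animal
welfare researchers who run two-choice preference tests and need to rank
more options than any single test can compare.

## The model and the quality measures

Outcomes are modelled with the Bradley–Terry paired-comparison model: each
option *i* has a positive ability π<sub>i</sub>, and

&nbsp;&nbsp;&nbsp;&nbsp;P(i preferred over j) = π<sub>i</sub> / (π<sub>i</sub> + π<sub>j</sub>).

The maximum-likelihood abilities, normalized so Σ<sub>i</sub> w<sub>i</sub> = 1,
are the **worth values**: each option's probability-scale position in the
ranking. Raw quantities (ml consumed, lick visits, forced picks) are first
turned into win/loss/tie outcomes at a configurable **preference
threshold** θ: with consumption share r = q<sub>A</sub>/(q<sub>A</sub>+q<sub>B</sub>),
A wins when r > θ, B wins when r < 1−θ, and anything inside the closed
window is a tie (θ = 0.5 means "tie only at an exact 50:50 split"; θ = 0.65
treats everything between 35:65 and 65:35 as undecided).

Two statistics qualify the pooled ranking:

* **Intransitivity ratio (I-ratio)** — the percentage of option triples,
  pooled over per-subject tournaments, whose pairwise preferences form a
  cycle (A > B > C > A). Counting triples suffices: every intransitive
  n-tuple contains an intransitive triple.
* **Consensus error (CE)** — scaled inter-subject disagreement. For each
  pair, d = 200·min(n<sub>A</sub>, n<sub>B</sub>)/(n<sub>A</sub>+n<sub>B</sub>),
  so unanimity scores 0 and an even split 100; per-option CE averages over
  the option's pairs and the overall CE over options.

When a new option has been compared against only some of the ranked
options, its position can be **simulated**: the missing subject × pair
outcomes are completed with fair coin flips, the model refitted, and the
target's rank recorded over many runs (*uninformed*), optionally discarding
completions whose I-ratio exceeds a cutoff (*informed*, default 0.1).

## Worked example

```python
from pairworth import PreferenceModel, generate_choices, scenario

ds = generate_choices(scenario("WIDE_VALENCE", seed=5))   # 11 subjects, 5 options
model = PreferenceModel.from_dataset(ds, threshold=0.5)
res = model.fit()
print(res.summary())
```

```
Worth scale (Bradley-Terry)
  options: 5   subjects: 11   comparisons: 110
  tie handling: half_win   damping: 0.0   logL: -15.7691

option               worth    lambda  position
O1                  0.9114    4.5599         1
O2                  0.0743    2.0525         2
O3                  0.0133    0.3334         3
O4                  0.0010   -2.2716         4
O5                  0.0001   -4.6742         5
```

The worth column sums to one; O1 is preferred with near-certainty against
any rival, the spacing showing *how strongly* each option dominates the
next. Quality of the pooled ranking:

```python
print(model.quality().summary())
```

```
CE: 9.09%   I-ratio: 0.00%   (0/110 intransitive triples)
```

Low disagreement, no cyclic choices. Now pretend O4 was only ever compared
with O1–O3 and simulate its position from 200 randomized completions:

```python
sim = res.simulate_position("O4", ["O1", "O2", "O3"], runs=200, seed=7)
print(sim.position_frequencies)   # {4: 0.755, 5: 0.245}
```

The simulation places O4 at its true rank (4) in 76% of runs — the
"frequency of true positives" — without ever testing it against O5.

The same pipeline is available from a shell:

```sh
pairworth generate --output toy.csv --scenario WIDE_VALENCE --seed 5
pairworth rank     --input toy.csv --threshold 50
pairworth quality  --input toy.csv --threshold 65
pairworth simulate --input toy.csv --target O4 --tested-against O1,O2,O3 \
                   --runs 200 --seed 7
```

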