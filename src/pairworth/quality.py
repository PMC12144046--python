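"""Quality measures for aggregated preference rankings.

Two descriptive statistics qualify a ranking pooled over subjects:

* the **intransitivity ratio** (I-ratio): the percentage of option triples,
  pooled over per-subject tournaments, whose three pairwise preferences form
  a directed cycle (A > B > C > A).  0% means every subject's choices are
  consistent with some linear order; triples containing a tie or a missing
  comparison are never cyclic, but stay in the denominator.
* the **consensus error** (CE): the scaled mean inter-subject disagreement
  over option pairs.  For a pair, unanimity scores 0 and an exact 50:50
  split of subjects scores 100; per-option CE averages over that option's
  pairs and the overall CE averages over options.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from itertools import combinations

from .data import BinaryOutcome, Outcome

logger = logging.getLogger(__name__)


class UndefinedStatisticError(ValueError):
    """The statistic's denominator is empty on the given data."""


@dataclass
class SubjectTournament:
    """One subject's directed preference relation over option pairs.

    ``relations`` maps a canonically ordered pair (a, b) with a < b to the
    winning option, or None for a tie.  At most one relation per unordered
    pair.
    """

    subject_id: str
    relations: dict[tuple[str, str], str | None] = field(default_factory=dict)

    def add(self, option_a: str, option_b: str, winner: str | None) -> None:
        pair = tuple(sorted((option_a, option_b)))
        if pair in self.relations:
            raise ValueError(f"duplicate relation for pair {pair}")
        if winner is not None and winner not in pair:
            raise ValueError(f"winner {winner!r} not in pair {pair}")
        self.relations[pair] = winner

    @property
    def options(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b in self.relations:
            seen.setdefault(a, None)
            seen.setdefault(b, None)
        return list(seen)


def tournaments_from_outcomes(
    outcomes: Sequence[BinaryOutcome],
) -> list[SubjectTournament]:
    """Group outcomes into one tournament per subject (first-appearance order)."""
    by_subject: dict[str, SubjectTournament] = {}
    for o in outcomes:
        t = by_subject.setdefault(o.subject_id, SubjectTournament(o.subject_id))
        t.add(o.option_a, o.option_b, o.winner)
    return list(by_subject.values())


def count_intransitive_triples(t: SubjectTournament) -> tuple[int, int]:
    """Count directed 3-cycles among all option triples of one subject.

    Returns (cyclic, total) where total = C(n, 3) over the subject's option
    set.  A triple is cyclic exactly when its three pairwise relations are
    all decided and each option beats exactly one of the other two
    (A > B > C > A or its reverse); ties and missing comparisons make a
    triple non-cyclic but still counted in the total.
    """
    opts = sorted(t.options)
    total = 0
    cyclic = 0
    for a, b, c in combinations(opts, 3):
        total += 1
        winners = [
            t.relations.get((a, b), None),
            t.relations.get((a, c), None),
            t.relations.get((b, c), None),
        ]
        if any(w is None for w in winners):
            continue
        # cyclic iff each option wins exactly once within the triple
        win_counts = {a: 0, b: 0, c: 0}
        for w in winners:
            win_counts[w] += 1
        if all(v == 1 for v in win_counts.values()):
            cyclic += 1
    return cyclic, total


def intransitivity_ratio(tournaments: Sequence[SubjectTournament]) -> float:
    """Pooled percentage of cyclic triples across subjects.

    100 x (sum of cyclic triples) / (sum of C(n,3) per subject); the percent
    transitivity is its complement, 100 - I-ratio.
    """
    cyclic = total = 0
    for t in tournaments:
        c, n = count_intransitive_triples(t)
        cyclic += c
        total += n
    if total == 0:
        raise UndefinedStatisticError(
            "no option triples: need at least one subject with >= 3 options"
        )
    return 100.0 * cyclic / total


def consensus_error(
    outcomes: Sequence[BinaryOutcome],
    tie_policy: str = "exclude",
) -> tuple[float, dict[str, float]]:
    """Consensus error: overall percentage and per-option breakdown.

    For each unordered pair let n_a, n_b be the numbers of subjects
    preferring each side; the pair's disagreement is
    d = 200 x min(n_a, n_b) / (n_a + n_b), so unanimity gives 0 and an even
    split gives 100.  Tied subjects are excluded from n_a + n_b under the
    default policy ("exclude"); ``tie_policy="half"`` credits half a subject
    to each side instead.  Per-option CE is the mean d over the option's
    pairs; the overall CE is the mean of the per-option values.  Pairs with
    no decided subjects are excluded from the means (logged).
    """
    if tie_policy not in ("exclude", "half"):
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    counts: dict[tuple[str, str], list[float]] = {}
    options: dict[str, None] = {}
    for o in outcomes:
        c = o.canonical()
        options.setdefault(c.option_a, None)
        options.setdefault(c.option_b, None)
        pair = (c.option_a, c.option_b)
        n = counts.setdefault(pair, [0.0, 0.0])
        if c.result is Outcome.A_WINS:
            n[0] += 1
        elif c.result is Outcome.B_WINS:
            n[1] += 1
        elif tie_policy == "half":
            n[0] += 0.5
            n[1] += 0.5
    if len(options) < 2 or not counts:
        raise UndefinedStatisticError("need >= 2 options with >= 1 compared pair")

    disagreement: dict[tuple[str, str], float] = {}
    for pair, (n_a, n_b) in counts.items():
        if n_a + n_b == 0:
            logger.warning("pair %s has no decided subjects; excluded from CE", pair)
            continue
        disagreement[pair] = 200.0 * min(n_a, n_b) / (n_a + n_b)

    per_option: dict[str, float] = {}
    for opt in options:
        ds = [d for pair, d in disagreement.items() if opt in pair]
        if ds:
            per_option[opt] = sum(ds) / len(ds)
    if not per_option:
        raise UndefinedStatisticError("every pair lacked decided subjects")
    overall = sum(per_option.values()) / len(per_option)
    return overall, per_option


@dataclass
class QualityReport:
    """Bundle of the two ranking quality measures.

    All percentages lie in [0, 100]; the overall consensus error equals the
    mean of the per-option values, and the intransitivity ratio equals
    100 x intransitive_triples / total_triples.
    """

    consensus_error_overall: float
    consensus_error_per_option: Mapping[str, float]
    intransitivity_ratio: float
    intransitive_triples: int
    total_triples: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "consensus_error_overall": self.consensus_error_overall,
                "consensus_error_per_option": dict(self.consensus_error_per_option),
                "intransitivity_ratio": self.intransitivity_ratio,
                "intransitive_triples": self.intransitive_triples,
                "total_triples": self.total_triples,
            },
            indent=2,
        )

    def summary(self) -> str:
        lines = [
            f"CE: {self.consensus_error_overall:.2f}%   "
            f"I-ratio: {self.intransitivity_ratio:.2f}%   "
            f"({self.intransitive_triples}/{self.total_triples} intransitive triples)",
            "per-option CE:",
        ]
        for opt, ce in self.consensus_error_per_option.items():
            lines.append(f"  {opt:<16}{ce:>8.2f}%")
        return "\n".join(lines)


def quality_report(
    outcomes: Sequence[BinaryOutcome],
    tournaments: Sequence[SubjectTournament] | None = None,
    ce_tie_policy: str = "exclude",
) -> QualityReport:
    """Assemble consensus error and intransitivity ratio into one report."""
    if tournaments is None:
        tournaments = tournaments_from_outcomes(outcomes)
    overall, per_option = consensus_error(outcomes, tie_policy=ce_tie_policy)
    cyclic = total = 0
    for t in tournaments:
        c, n = count_intransitive_triples(t)
        cyclic += c
        total += n
    if total == 0:
        raise UndefinedStatisticError(
            "no option triples: need at least one subject with >= 3 options"
        )
    return QualityReport(
        consensus_error_overall=overall,
        consensus_error_per_option=per_option,
        intransitivity_ratio=100.0 * cyclic / total,
        intransitive_triples=cyclic,
        total_triples=total,
    )
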