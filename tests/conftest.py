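from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pairworth import BinaryOutcome, ChoiceDataset, ChoiceRecord, Outcome
from pairworth.quality import SubjectTournament

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def outcomes_from_counts(
    counts: dict[tuple[str, str], tuple[int, int, int]],
) -> list[BinaryOutcome]:
    """Expand {(a, b): (wins_a, wins_b, ties)} into per-subject outcomes.

    Subject ids are arbitrary but unique per pair, which is all the fitter
    and the consensus error need.
    """
    out: list[BinaryOutcome] = []
    for (a, b), (wa, wb, t) in counts.items():
        k = 0
        for _ in range(wa):
            out.append(BinaryOutcome(f"S{k}", a, b, Outcome.A_WINS))
            k += 1
        for _ in range(wb):
            out.append(BinaryOutcome(f"S{k}", a, b, Outcome.B_WINS))
            k += 1
        for _ in range(t):
            out.append(BinaryOutcome(f"S{k}", a, b, Outcome.TIE))
            k += 1
    return out


def random_tournament(
    options: list[str],
    rng: np.random.Generator,
    tie_prob: float = 0.0,
    missing_prob: float = 0.0,
    subject_id: str = "S1",
) -> SubjectTournament:
    t = SubjectTournament(subject_id)
    for i, a in enumerate(options):
        for b in options[i + 1:]:
            if missing_prob and rng.random() < missing_prob:
                continue
            if tie_prob and rng.random() < tie_prob:
                t.add(a, b, None)
            else:
                t.add(a, b, a if rng.random() < 0.5 else b)
    return t


@pytest.fixture
def counts_to_outcomes():
    return outcomes_from_counts


@pytest.fixture
def make_random_tournament():
    return random_tournament


@pytest.fixture
def toy_dataset() -> ChoiceDataset:
    """Two subjects, three options, one session each, clear preferences."""
    rows = []
    for s in ("S1", "S2"):
        rows += [
            ChoiceRecord(s, "A", "B", 70, 30),
            ChoiceRecord(s, "A", "C", 80, 20),
            ChoiceRecord(s, "B", "C", 60, 40),
        ]
    return ChoiceDataset(rows)


@pytest.fixture
def symmetric_outcomes() -> list[BinaryOutcome]:
    """Each of three pairs split 50:50 across four subjects."""
    return outcomes_from_counts(
        {("A", "B"): (2, 2, 0), ("A", "C"): (2, 2, 0), ("B", "C"): (2, 2, 0)}
    )
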