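"""Synthetic choice datasets with known ground-truth worth values.

Two data styles are emulated.  FORCED_CHOICE mirrors a human picture-pair
task: each trial is a forced pick encoded as quantities (1, 0) or (0, 1),
drawn with the Bradley-Terry probability p(A) = w_A / (w_A + w_B).
CONSUMPTION mirrors animal two-bottle tests (ml drunk, lick visits): each
side-switched session yields a pair of non-negative counts whose expected
ratio equals the same p, drawn as gamma-mixed Poisson counts so the ratio's
spread is tunable through an overdispersion parameter.

Scenario presets pair a widely spread worth vector with a nearly flat one
("wide" vs "narrow" valence range) at otherwise identical sizes, the
construction used to probe how valence spread drives the quality measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .data import ChoiceDataset, ChoiceRecord


class Style(Enum):
    FORCED_CHOICE = "forced_choice"
    CONSUMPTION = "consumption"


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic dataset.

    worth_true are positive weights (normalized internally); tie_rate is the
    per-trial probability of an explicit tie (FORCED_CHOICE only); noise is
    the gamma overdispersion of CONSUMPTION counts (0 = plain Poisson);
    mean_total is the expected total count per session.
    """

    worth_true: tuple[float, ...]
    n_subjects: int = 11
    trials_per_pair: int = 2
    tie_rate: float = 0.0
    noise: float = 0.25
    style: Style = Style.CONSUMPTION
    seed: int = 0
    mean_total: float = 100.0
    option_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.worth_true) < 2:
            raise ValueError("need at least two options")
        if any(w <= 0 for w in self.worth_true):
            raise ValueError("worth weights must be strictly positive")
        if self.n_subjects < 1 or self.trials_per_pair < 1:
            raise ValueError("n_subjects and trials_per_pair must be >= 1")
        if not 0 <= self.tie_rate < 1:
            raise ValueError("tie_rate must lie in [0, 1)")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.mean_total <= 0:
            raise ValueError("mean_total must be > 0")
        if self.option_labels is not None and len(self.option_labels) != len(
            self.worth_true
        ):
            raise ValueError("option_labels must match worth_true in length")

    @property
    def labels(self) -> tuple[str, ...]:
        if self.option_labels is not None:
            return self.option_labels
        return tuple(f"O{i + 1}" for i in range(len(self.worth_true)))

    @property
    def worth_normalized(self) -> np.ndarray:
        w = np.asarray(self.worth_true, dtype=float)
        return w / w.sum()


def generate_choices(spec: GeneratorSpec) -> ChoiceDataset:
    """Draw a complete-design choice dataset from the spec; seed-reproducible.

    Every subject faces every unordered option pair in ``trials_per_pair``
    sessions.  FORCED_CHOICE emits (1,0)/(0,1) per trial (a tie, at
    tie_rate, as equal quantities); CONSUMPTION emits count pairs with
    expected shares (p, 1-p) and gamma-Poisson overdispersion ``noise``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = spec.labels
    w = spec.worth_normalized
    records: list[ChoiceRecord] = []
    for s in range(spec.n_subjects):
        subject = f"S{s + 1}"
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                p = w[i] / (w[i] + w[j])
                for trial in range(spec.trials_per_pair):
                    session = f"s{trial + 1}"
                    if spec.style is Style.FORCED_CHOICE:
                        if spec.tie_rate and rng.random() < spec.tie_rate:
                            qa, qb = 1.0, 1.0
                        elif rng.random() < p:
                            qa, qb = 1.0, 0.0
                        else:
                            qa, qb = 0.0, 1.0
                    else:
                        mean_a = spec.mean_total * p
                        mean_b = spec.mean_total * (1 - p)
                        if spec.noise > 0:
                            shape = 1.0 / spec.noise
                            mean_a = rng.gamma(shape, mean_a / shape)
                            mean_b = rng.gamma(shape, mean_b / shape)
                        qa = float(rng.poisson(mean_a))
                        qb = float(rng.poisson(mean_b))
                    records.append(
                        ChoiceRecord(
                            subject_id=subject,
                            option_a=labels[i],
                            option_b=labels[j],
                            quantity_a=qa,
                            quantity_b=qb,
                            session_id=session,
                        )
                    )
    return ChoiceDataset(records)


#: Geometric decay factors of the scenario worth vectors: 0.45 spreads the
#: options far apart on the worth scale, 0.9 leaves them nearly flat.
SCENARIO_DECAY = {"WIDE_VALENCE": 0.45, "NARROW_VALENCE": 0.9}


def scenario(name: str, seed: int = 0, n_options: int = 5) -> GeneratorSpec:
    """Preset generator specs for the two valence-range study conditions.

    Both scenarios share the consumption style and sizes of a typical
    home-cage liquid test (11 subjects, 5 liquids, side-switched repeat
    sessions); they differ only in the spread of the generating worth
    vector, geometric with decay 0.45 (WIDE_VALENCE) or 0.9
    (NARROW_VALENCE).
    """
    try:
        decay = SCENARIO_DECAY[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIO_DECAY)}"
        ) from None
    worth = tuple(decay**k for k in range(n_options))
    return GeneratorSpec(
        worth_true=worth,
        n_subjects=11,
        trials_per_pair=2,
        style=Style.CONSUMPTION,
        noise=0.25,
        seed=seed,
    )
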