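"""Monte-Carlo positioning of an incompletely tested option.

When a scaled ranking of options already exists and a new option has been
compared against only a subset of them, its position can still be estimated:
the missing subject x pair outcomes are completed at random (a fair coin
between the two win directions), the worth model is refitted, and the
target's rank recorded, repeatedly.  An *uninformed* simulation keeps every
completion; an *informed* simulation discards completions whose ranking
exceeds a preset intransitivity-ratio cutoff, on the argument that real
choice data are largely transitive.  The spread of simulated positions and
worth values (95% confidence intervals, frequency of hitting the known true
position) quantifies how much the missing comparisons matter.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Sequence
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .data import BinaryOutcome, Outcome, PreferenceThreshold
from .model import FitOptions, TieHandling, WorthScale, fit_worth
from .quality import (
    consensus_error,
    count_intransitive_triples,
    tournaments_from_outcomes,
)

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054


class SimulationConfigError(ValueError):
    """The simulation configuration contradicts the supplied outcomes."""


class EmptyResultError(RuntimeError):
    """No simulation run survived the informed-mode intransitivity filter."""


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one positioning simulation.

    ``target`` is the option whose position is sought; ``tested_against``
    names the options it was actually compared with.  ``runs`` randomized
    completions are drawn (200 by default); ``informed=True`` discards runs
    whose per-run intransitivity ratio exceeds ``intransitivity_cutoff``
    (fractional scale, default 0.1).  ``randomize_ties`` additionally allows
    simulated ties with probability ``tie_probability``.
    """

    target: str
    tested_against: tuple[str, ...] = ()
    runs: int = 200
    informed: bool = False
    intransitivity_cutoff: float = 0.1
    threshold: PreferenceThreshold = PreferenceThreshold(0.5)
    seed: int = 0
    randomize_ties: bool = False
    tie_probability: float = 1.0 / 3.0
    tie_handling: TieHandling = TieHandling.HALF_WIN

    def __post_init__(self) -> None:
        if self.target in self.tested_against:
            raise SimulationConfigError("tested_against must exclude the target")
        if self.runs < 1:
            raise SimulationConfigError("runs must be >= 1")
        if not 0 <= self.intransitivity_cutoff <= 1:
            raise SimulationConfigError("intransitivity_cutoff must lie in [0, 1]")
        if not 0 <= self.tie_probability < 1:
            raise SimulationConfigError("tie_probability must lie in [0, 1)")


@dataclass(frozen=True)
class SimulationRun:
    """One randomized completion: fitted worths, target rank, and quality.

    ``i_ratio`` is on the fractional scale (0 = fully transitive, 1 = every
    triple cyclic) to match the cutoff; ``ce`` is the overall consensus
    error percentage.
    """

    run_index: int
    worth: dict[str, float]
    position: int
    i_ratio: float
    ce: float


@dataclass
class SimulationResult:
    """Summary of all retained runs of a positioning simulation."""

    config: SimulationConfig
    options: list[str]
    runs: list[SimulationRun]
    discarded_runs: int = 0
    true_position: Optional[int] = None
    mean_worth: dict[str, float] = field(default_factory=dict)
    ci_lower: dict[str, float] = field(default_factory=dict)
    ci_upper: dict[str, float] = field(default_factory=dict)
    position_frequencies: dict[int, float] = field(default_factory=dict)
    true_positive_count: Optional[int] = None
    true_positive_frequency: Optional[float] = None

    def summarize(self) -> None:
        if not self.runs:
            raise EmptyResultError(
                "no retained runs; raise the intransitivity cutoff or add runs"
            )
        k = len(self.runs)
        if k >= 2:
            self.mean_worth, self.ci_lower, self.ci_upper = summarize_ci(self.runs)
        else:
            self.mean_worth = dict(self.runs[0].worth)
            self.ci_lower = dict(self.runs[0].worth)
            self.ci_upper = dict(self.runs[0].worth)
        pos_counts: dict[int, int] = {}
        for r in self.runs:
            pos_counts[r.position] = pos_counts.get(r.position, 0) + 1
        self.position_frequencies = {
            p: c / k for p, c in sorted(pos_counts.items())
        }
        if self.true_position is not None:
            self.true_positive_count = sum(
                1 for r in self.runs if r.position == self.true_position
            )
            self.true_positive_frequency = self.true_positive_count / k

    def to_json(self) -> str:
        return json.dumps(
            {
                "target": self.config.target,
                "tested_against": list(self.config.tested_against),
                "mode": "informed" if self.config.informed else "uninformed",
                "runs_requested": self.config.runs,
                "runs_retained": len(self.runs),
                "discarded_runs": self.discarded_runs,
                "seed": self.config.seed,
                "true_position": self.true_position,
                "true_positive_count": self.true_positive_count,
                "true_positive_frequency": self.true_positive_frequency,
                "position_frequencies": {
                    str(p): f for p, f in self.position_frequencies.items()
                },
                "mean_worth": self.mean_worth,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "runs": [
                    {
                        "run_index": r.run_index,
                        "position": r.position,
                        "i_ratio": r.i_ratio,
                        "ce": r.ce,
                        "worth": r.worth,
                    }
                    for r in self.runs
                ],
            },
            indent=2,
        )

    def to_table(self) -> pd.DataFrame:
        """Best-run row in the reporting-table column convention."""
        best = select_best_run(self)
        return pd.DataFrame(
            [
                {
                    "Item": self.config.target,
                    "Simulated position": best.position,
                    "Worth value": round(best.worth[self.config.target], 2),
                    "I-ratio": round(best.i_ratio, 2),
                    "CE (%)": round(best.ce, 2),
                    "Frequency of true positives": (
                        round(self.true_positive_frequency, 2)
                        if self.true_positive_frequency is not None
                        else None
                    ),
                    "No. of true positives": self.true_positive_count,
                    "Tested against": ", ".join(self.config.tested_against),
                }
            ]
        )


def missing_cells(
    outcomes: Sequence[BinaryOutcome],
    target: str,
    options: Sequence[str],
    subjects: Sequence[str],
) -> list[tuple[str, str]]:
    """Subject x partner cells of the target with no observed outcome."""
    observed = {
        (o.subject_id, o.pair) for o in outcomes
    }
    cells = []
    for s in subjects:
        for other in options:
            if other == target:
                continue
            pair = tuple(sorted((target, other)))
            if (s, pair) not in observed:
                cells.append((s, other))
    return cells


def mask_target(
    outcomes: Sequence[BinaryOutcome],
    target: str,
    tested_against: Sequence[str],
) -> list[BinaryOutcome]:
    """Drop every target comparison whose partner is not in tested_against."""
    kept = []
    for o in outcomes:
        pair = set(o.pair)
        if target in pair:
            other = (pair - {target}).pop()
            if other not in tested_against:
                continue
        kept.append(o)
    return kept


def randomize_unknowns(
    outcomes: Sequence[BinaryOutcome],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    options: Sequence[str],
    subjects: Sequence[str],
) -> list[BinaryOutcome]:
    """Complete the target's missing cells with coin-flip outcomes.

    Each missing subject x (target, other) cell receives a win for either
    side with probability 1/2 (or a tie with ``tie_probability`` when
    ``randomize_ties`` is on).  Observed cells are untouched; the draw is
    reproducible from the generator state.
    """
    if cfg.target not in options:
        raise SimulationConfigError(f"unknown target {cfg.target!r}")
    cells = missing_cells(outcomes, cfg.target, options, subjects)
    overlap = {other for _, other in cells} & set(cfg.tested_against)
    if overlap:
        raise SimulationConfigError(
            f"tested_against options have missing cells: {sorted(overlap)}"
        )
    completed = list(outcomes)
    for subject, other in cells:
        a, b = sorted((cfg.target, other))
        if cfg.randomize_ties and rng.random() < cfg.tie_probability:
            result = Outcome.TIE
        else:
            result = Outcome.A_WINS if rng.random() < 0.5 else Outcome.B_WINS
        completed.append(BinaryOutcome(subject, a, b, result))
    return completed


def _run_once(
    masked: Sequence[BinaryOutcome],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    options: Sequence[str],
    subjects: Sequence[str],
    run_index: int,
    fit_opts: FitOptions,
) -> SimulationRun:
    completed = randomize_unknowns(masked, cfg, rng, options, subjects)
    scale = fit_worth(completed, fit_opts, options=options)
    tournaments = tournaments_from_outcomes(completed)
    cyclic = total = 0
    for t in tournaments:
        c, n = count_intransitive_triples(t)
        cyclic += c
        total += n
    i_ratio = cyclic / total if total else 0.0
    ce, _ = consensus_error(completed)
    return SimulationRun(
        run_index=run_index,
        worth={opt: float(w) for opt, w in zip(scale.options, scale.worth)},
        position=scale.position_of(cfg.target),
        i_ratio=i_ratio,
        ce=ce,
    )


def simulate_positions(
    outcomes: Sequence[BinaryOutcome],
    cfg: SimulationConfig,
    options: Sequence[str] | None = None,
    subjects: Sequence[str] | None = None,
    true_position: int | None = None,
) -> SimulationResult:
    """Randomize -> fit -> rank -> quality, cfg.runs times, and summarize.

    ``outcomes`` must already have the target's untested comparisons absent
    (see :func:`mask_target`); informed mode retains only runs whose
    fractional intransitivity ratio is at most the cutoff.  Deterministic
    for a fixed config and seed.
    """
    if options is None:
        seen: dict[str, None] = {}
        for o in outcomes:
            seen.setdefault(o.option_a, None)
            seen.setdefault(o.option_b, None)
        options = list(seen)
    if subjects is None:
        seen_s: dict[str, None] = {}
        for o in outcomes:
            seen_s.setdefault(o.subject_id, None)
        subjects = list(seen_s)
    fit_opts = FitOptions(tie_handling=cfg.tie_handling)
    rng = np.random.default_rng(cfg.seed)
    retained: list[SimulationRun] = []
    discarded = 0
    for run_index in range(cfg.runs):
        run = _run_once(outcomes, cfg, rng, options, subjects, run_index, fit_opts)
        if cfg.informed and run.i_ratio > cfg.intransitivity_cutoff:
            discarded += 1
            continue
        retained.append(run)
    logger.info(
        "simulation %r vs %s: retained %d/%d runs",
        cfg.target, list(cfg.tested_against), len(retained), cfg.runs,
    )
    result = SimulationResult(
        config=cfg,
        options=list(options),
        runs=retained,
        discarded_runs=discarded,
        true_position=true_position,
    )
    result.summarize()
    return result


def simulate_from_complete(
    complete_outcomes: Sequence[BinaryOutcome],
    cfg: SimulationConfig,
) -> SimulationResult:
    """Mask the target's untested comparisons and simulate its position.

    The ground-truth position for true-positive accounting is the target's
    rank in a fit of the complete data, computed here rather than supplied.
    """
    seen: dict[str, None] = {}
    seen_s: dict[str, None] = {}
    for o in complete_outcomes:
        seen.setdefault(o.option_a, None)
        seen.setdefault(o.option_b, None)
        seen_s.setdefault(o.subject_id, None)
    options, subjects = list(seen), list(seen_s)
    fit_opts = FitOptions(tie_handling=cfg.tie_handling)
    full_scale = fit_worth(complete_outcomes, fit_opts, options=options)
    true_position = full_scale.position_of(cfg.target)
    masked = mask_target(complete_outcomes, cfg.target, cfg.tested_against)
    return simulate_positions(
        masked, cfg, options=options, subjects=subjects, true_position=true_position
    )


def select_best_run(result: SimulationResult) -> SimulationRun:
    """The retained run minimal under (i_ratio, ce), run_index breaking ties.

    This is the sorting used in the reporting tables: lowest achieved
    intransitivity ratio first, then lowest consensus error.
    """
    if not result.runs:
        raise EmptyResultError("no retained runs to select from")
    return min(result.runs, key=lambda r: (r.i_ratio, r.ce, r.run_index))


def summarize_ci(
    runs: Sequence[SimulationRun], level: float = 0.95
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Per-option mean worth with a normal-approximation confidence interval.

    mean +/- z * sd / sqrt(k) over the retained runs; requires k >= 2.
    """
    if len(runs) < 2:
        raise ValueError("need >= 2 retained runs for an interval")
    from scipy.stats import norm

    z = float(norm.ppf(0.5 + level / 2))
    options = list(runs[0].worth)
    mat = np.array([[r.worth[o] for o in options] for r in runs])
    mean = mat.mean(axis=0)
    half = z * mat.std(axis=0, ddof=1) / np.sqrt(len(runs))
    return (
        dict(zip(options, mean.tolist())),
        dict(zip(options, (mean - half).tolist())),
        dict(zip(options, (mean + half).tolist())),
    )


def ci_overlaps(
    result: SimulationResult, target: str
) -> dict[str, bool]:
    """Whether the target's worth CI overlaps each other option's CI."""
    lo_t, hi_t = result.ci_lower[target], result.ci_upper[target]
    return {
        o: not (hi_t < result.ci_lower[o] or result.ci_upper[o] < lo_t)
        for o in result.options
        if o != target
    }


def determine_cutoff(
    outcomes: Sequence[BinaryOutcome],
    cfg: SimulationConfig,
    max_runs: int = 512,
    options: Sequence[str] | None = None,
    subjects: Sequence[str] | None = None,
) -> tuple[int, bool]:
    """Smallest run count at which the target's position is stable.

    Run counts grow on a doubling schedule (2, 4, 8, ..., max_runs).  At
    each count the accumulated per-run worths are modelled with a linear
    model (worth ~ option indicators); the target-vs-every-other-option
    contrasts are tested with Holm-adjusted p-values, and the target's 95%
    interval must overlap no other option's.  Returns (cutoff_runs,
    ambiguous): ambiguous is set when max_runs is exhausted without
    separation, in which case the queried option's position cannot be
    pinned down at this sample size.  With nothing to randomize the answer
    is (1, False).
    """
    if max_runs < 2:
        raise ValueError("max_runs must be >= 2")
    if options is None:
        seen: dict[str, None] = {}
        for o in outcomes:
            seen.setdefault(o.option_a, None)
            seen.setdefault(o.option_b, None)
        options = list(seen)
    if subjects is None:
        seen_s: dict[str, None] = {}
        for o in outcomes:
            seen_s.setdefault(o.subject_id, None)
        subjects = list(seen_s)
    if not missing_cells(outcomes, cfg.target, options, subjects):
        return 1, False

    import statsmodels.api as sm
    from statsmodels.stats.multitest import multipletests

    fit_opts = FitOptions(tie_handling=cfg.tie_handling)
    rng = np.random.default_rng(cfg.seed)
    accumulated: list[SimulationRun] = []
    schedule = []
    k = 2
    while k < max_runs:
        schedule.append(k)
        k *= 2
    schedule.append(max_runs)

    others = [o for o in options if o != cfg.target]
    for count in schedule:
        while len(accumulated) < count:
            accumulated.append(
                _run_once(
                    outcomes, cfg, rng, options, subjects, len(accumulated), fit_opts
                )
            )
        # worth ~ option, long format over accumulated runs
        frame = pd.DataFrame(
            [
                {"worth": r.worth[o], "option": o}
                for r in accumulated
                for o in options
            ]
        )
        dummies = pd.get_dummies(frame["option"], dtype=float)
        x = sm.add_constant(dummies[others])  # target is the reference level
        ols = sm.OLS(frame["worth"], x).fit()
        pvals = [float(ols.pvalues[o]) for o in others]
        adjusted = multipletests(pvals, alpha=0.05, method="holm")[1]
        mean, lo, hi = summarize_ci(accumulated)
        lo_t, hi_t = lo[cfg.target], hi[cfg.target]
        no_overlap = all((hi_t < lo[o]) or (hi[o] < lo_t) for o in others)
        if all(p <= 0.05 for p in adjusted) and no_overlap:
            return count, False
    return max_runs, True
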