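"""Bradley-Terry worth scaling of binary preference outcomes.

The probability that option i is preferred over option j is modelled as
p(i > j) = pi_i / (pi_i + pi_j) for positive abilities pi.  "Worth values"
are the abilities normalized to sum to one, so each option's worth is its
probability-scale position in the ranking.  The maximum-likelihood abilities
are found by minorization-maximization (MM) iterations, or by quasi-Newton
optimization when an explicit tie parameter (Davidson model) is requested;
both maximize the same likelihood as the log-linear Poisson formulation used
in the paired-comparison literature.

The module exposes both a functional surface (:func:`fit_worth`,
:func:`log_likelihood`, :func:`rank_from_worth`) and a statsmodels-style
:class:`PreferenceModel` whose :meth:`~PreferenceModel.fit` returns a
:class:`WorthResults` object carrying estimates, diagnostics and summaries.
"""

from __future__ import annotations

import json
import logging
import math
from collections.abc import Sequence
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np
import pandas as pd

from .data import (
    BinaryOutcome,
    ChoiceDataset,
    Outcome,
    PreferenceThreshold,
    aggregate_sessions,
    apply_threshold,
)

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054


class EstimationError(RuntimeError):
    """The likelihood has no finite maximizer on the given data."""


class ConvergenceError(RuntimeError):
    """The fitting iteration did not converge within the iteration cap."""


class TieHandling(Enum):
    """How tied comparisons enter the likelihood.

    HALF_WIN credits half a win to each side; DAVIDSON estimates an explicit
    tie-propensity parameter nu; DROP discards ties.
    """

    HALF_WIN = "half_win"
    DAVIDSON = "davidson"
    DROP = "drop"


@dataclass(frozen=True)
class FitOptions:
    """Tuning knobs for the worth fit.

    damping is a pseudo-count added to every ordered pair cell; ``None``
    selects it automatically (0.5 when separation is detected, else 0).
    """

    tie_handling: TieHandling = TieHandling.HALF_WIN
    damping: float | None = None
    tol: float = 1e-10
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.damping is not None and self.damping < 0:
            raise ValueError("damping must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class WorthScale:
    """Fitted abilities on the worth scale.

    lam are log-abilities identified by a sum-to-zero constraint; worth are
    the normalized abilities (summing to one); positions are dense ranks with
    1 = most preferred, exact worth ties sharing a position.
    """

    options: list[str]
    lam: np.ndarray
    worth: np.ndarray
    positions: np.ndarray = field(default=None)  # type: ignore[assignment]
    tied_positions: bool = False

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.worth = np.asarray(self.worth, dtype=float)
        if self.positions is None:
            self.positions, self.tied_positions = rank_from_worth(self)

    def worth_of(self, option: str) -> float:
        return float(self.worth[self.options.index(option)])

    def position_of(self, option: str) -> int:
        return int(self.positions[self.options.index(option)])


def _pair_counts(
    outcomes: Sequence[BinaryOutcome], options: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate outcomes into win and tie count matrices.

    wins[i, j] = number of subjects for whom i beat j; ties[i, j] symmetric.
    """
    idx = {o: k for k, o in enumerate(options)}
    n = len(options)
    wins = np.zeros((n, n))
    ties = np.zeros((n, n))
    for o in outcomes:
        i, j = idx[o.option_a], idx[o.option_b]
        if o.result is Outcome.A_WINS:
            wins[i, j] += 1
        elif o.result is Outcome.B_WINS:
            wins[j, i] += 1
        else:
            ties[i, j] += 1
            ties[j, i] += 1
    return wins, ties


def _effective_wins(
    wins: np.ndarray, ties: np.ndarray, tie_handling: TieHandling, damping: float
) -> np.ndarray:
    w = wins.copy()
    if tie_handling is TieHandling.HALF_WIN:
        w += 0.5 * ties
    if damping:
        w += damping * (1 - np.eye(w.shape[0]))
    return w


def _detect_separation(w: np.ndarray) -> bool:
    """True when the MLE is infinite: the win digraph is not strongly connected.

    Covers both an option winning or losing everything and group separation
    (a block of options losing every cross-comparison); either sends the
    corresponding abilities to the boundary.
    """
    g = nx.DiGraph()
    n = w.shape[0]
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                g.add_edge(i, j)
    return not nx.is_strongly_connected(g)


def _check_connected(w: np.ndarray, options: Sequence[str]) -> None:
    g = nx.Graph()
    g.add_nodes_from(range(len(options)))
    n = len(options)
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] + w[j, i] > 0:
                g.add_edge(i, j)
    if not nx.is_connected(g):
        comps = [
            sorted(options[i] for i in comp) for comp in nx.connected_components(g)
        ]
        raise EstimationError(
            f"comparison graph is disconnected; components: {comps} "
            "(collect linking comparisons or set damping > 0)"
        )


def _bt_loglik(pi: np.ndarray, w: np.ndarray) -> float:
    n = len(pi)
    ll = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                ll += w[i, j] * math.log(pi[i] / (pi[i] + pi[j]))
    return ll


def _fit_mm(w: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, int]:
    """MM iterations for the Bradley-Terry MLE given effective win counts."""
    n = w.shape[0]
    total = w + w.T
    win_sum = w.sum(axis=1)
    pi = np.full(n, 1.0 / n)
    for it in range(1, max_iter + 1):
        denom = np.zeros(n)
        for i in range(n):
            mask = total[i] > 0
            denom[i] = np.sum(total[i, mask] / (pi[i] + pi[mask]))
        new_pi = win_sum / denom
        new_pi /= new_pi.sum()
        delta = np.max(np.abs(np.log(new_pi) - np.log(pi)))
        pi = new_pi
        if delta < tol:
            return pi, it
    # gradient of the log-likelihood wrt log-abilities, for the error report
    grad = np.array(
        [
            win_sum[i]
            - sum(
                total[i, j] * pi[i] / (pi[i] + pi[j])
                for j in range(n)
                if j != i and total[i, j] > 0
            )
            for i in range(n)
        ]
    )
    raise ConvergenceError(
        f"MM did not converge in {max_iter} iterations "
        f"(last gradient norm {np.linalg.norm(grad):.3e})"
    )


def _davidson_loglik(
    lam: np.ndarray, log_nu: float, wins: np.ndarray, ties: np.ndarray
) -> float:
    pi = np.exp(lam - lam.max())
    nu = math.exp(log_nu)
    n = len(pi)
    ll = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            m = wins[i, j] + wins[j, i] + ties[i, j]
            if m == 0:
                continue
            root = math.sqrt(pi[i] * pi[j])
            denom = pi[i] + pi[j] + nu * root
            ll += wins[i, j] * math.log(pi[i] / denom)
            ll += wins[j, i] * math.log(pi[j] / denom)
            if ties[i, j]:
                ll += ties[i, j] * math.log(nu * root / denom)
    return ll


def _fit_davidson(
    wins: np.ndarray, ties: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, float, int]:
    from scipy.optimize import minimize

    n = wins.shape[0]

    def neg(params: np.ndarray) -> float:
        lam = np.append(params[: n - 1], -params[: n - 1].sum())
        return -_davidson_loglik(lam, params[-1], wins, ties)

    res = minimize(
        neg,
        x0=np.zeros(n),
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-4:
        raise ConvergenceError(
            f"Davidson fit did not converge ({res.message}; "
            f"last gradient norm {np.linalg.norm(res.jac):.3e})"
        )
    lam = np.append(res.x[: n - 1], -res.x[: n - 1].sum())
    pi = np.exp(lam)
    return pi / pi.sum(), math.exp(res.x[-1]), res.nit


def fit_worth(
    outcomes: Sequence[BinaryOutcome],
    opts: FitOptions = FitOptions(),
    options: Sequence[str] | None = None,
) -> WorthScale:
    """Maximum-likelihood worth values for a set of binary outcomes.

    Requires at least two options and a connected comparison graph (after
    tie handling and damping).  Deterministic for fixed input.
    """
    if options is None:
        seen: dict[str, None] = {}
        for o in outcomes:
            seen.setdefault(o.option_a, None)
            seen.setdefault(o.option_b, None)
        options = list(seen)
    options = list(options)
    if len(options) < 2:
        raise EstimationError("need at least two options to scale")

    wins, ties = _pair_counts(outcomes, options)
    base = _effective_wins(wins, ties, opts.tie_handling, 0.0)
    damping = opts.damping
    if damping is None:
        damping = 0.5 if _detect_separation(base) else 0.0
        if damping:
            logger.info("separation detected; applying damping %.2f", damping)
    logger.debug(
        "fit: %d options, tie_handling=%s, damping=%s",
        len(options), opts.tie_handling.value, damping,
    )
    w = _effective_wins(wins, ties, opts.tie_handling, damping)
    if damping == 0:
        _check_connected(w, options)

    if opts.tie_handling is TieHandling.DAVIDSON:
        if damping:
            wins = wins + damping * (1 - np.eye(len(options)))
        worth, _nu, _ = _fit_davidson(wins, ties, opts.tol, opts.max_iter)
    else:
        worth, _ = _fit_mm(w, opts.tol, opts.max_iter)

    lam = np.log(worth)
    lam -= lam.mean()
    return WorthScale(options=options, lam=lam, worth=worth)


def log_likelihood(
    outcomes: Sequence[BinaryOutcome],
    scale: WorthScale,
    opts: FitOptions = FitOptions(),
) -> float:
    """The exact objective maximized by :func:`fit_worth` at ``scale``.

    Includes tie terms and damping pseudo-counts; the empty outcome set
    scores 0.
    """
    if not outcomes:
        return 0.0
    for o in outcomes:
        for opt in (o.option_a, o.option_b):
            if opt not in scale.options:
                raise KeyError(f"option {opt!r} not covered by the worth scale")
    wins, ties = _pair_counts(outcomes, scale.options)
    damping = opts.damping or 0.0
    if opts.tie_handling is TieHandling.DAVIDSON:
        if damping:
            wins = wins + damping * (1 - np.eye(len(scale.options)))
        # profile out nu at the given abilities
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda log_nu: -_davidson_loglik(scale.lam, log_nu, wins, ties),
            bounds=(-20, 20),
            method="bounded",
        )
        return -res.fun
    w = _effective_wins(wins, ties, opts.tie_handling, damping)
    return _bt_loglik(scale.worth, w)


def rank_from_worth(scale: WorthScale) -> tuple[np.ndarray, bool]:
    """Dense rank positions by descending worth (1 = most preferred).

    Exact worth ties share a position; the second return value flags their
    presence.
    """
    worth = np.asarray(scale.worth, dtype=float)
    distinct = np.unique(worth)[::-1]
    positions = np.array([int(np.where(distinct == v)[0][0]) + 1 for v in worth])
    return positions, len(distinct) < len(worth)


class PreferenceModel:
    """Paired-comparison preference model for binary choice outcomes.

    Parameters
    ----------
    outcomes
        Thresholded win/loss/tie outcomes, one per subject x unordered pair.
    options
        Optional explicit option catalog (defaults to first appearance order).

    Use :meth:`from_dataset` / :meth:`from_dataframe` to build directly from
    raw quantity records, which are session-aggregated and thresholded on the
    way in.
    """

    def __init__(
        self,
        outcomes: Sequence[BinaryOutcome],
        options: Sequence[str] | None = None,
    ) -> None:
        self.outcomes = [o.canonical() for o in outcomes]
        if options is None:
            seen: dict[str, None] = {}
            for o in outcomes:
                seen.setdefault(o.option_a, None)
                seen.setdefault(o.option_b, None)
            options = list(seen)
        self.options = list(options)
        seen_sub: dict[str, None] = {}
        for o in outcomes:
            seen_sub.setdefault(o.subject_id, None)
        self.subjects = list(seen_sub)
        self.threshold: PreferenceThreshold | None = None

    @classmethod
    def from_dataset(
        cls,
        ds: ChoiceDataset,
        threshold: PreferenceThreshold | float = 0.5,
    ) -> "PreferenceModel":
        if not isinstance(threshold, PreferenceThreshold):
            threshold = PreferenceThreshold(threshold)
        agg = aggregate_sessions(ds)
        model = cls(apply_threshold(agg, threshold), options=agg.options)
        model.threshold = threshold
        return model

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        threshold: PreferenceThreshold | float = 0.5,
        dialect: dict[str, str] | None = None,
    ) -> "PreferenceModel":
        return cls.from_dataset(
            ChoiceDataset.from_frame(frame, dialect), threshold
        )

    def fit(self, opts: FitOptions | None = None, **kwargs) -> "WorthResults":
        """Fit worth values; keyword arguments override FitOptions fields."""
        if opts is None:
            opts = FitOptions(**kwargs)
        elif kwargs:
            raise TypeError("pass either opts or keyword overrides, not both")
        wins, ties = _pair_counts(self.outcomes, self.options)
        base = _effective_wins(wins, ties, opts.tie_handling, 0.0)
        damping_applied = opts.damping
        if damping_applied is None:
            damping_applied = 0.5 if _detect_separation(base) else 0.0
        scale = fit_worth(self.outcomes, opts, options=self.options)
        resolved = FitOptions(
            tie_handling=opts.tie_handling,
            damping=damping_applied,
            tol=opts.tol,
            max_iter=opts.max_iter,
        )
        llf = log_likelihood(self.outcomes, scale, resolved)
        return WorthResults(self, scale, resolved, llf)

    def quality(self, ce_tie_policy: str = "exclude"):
        """Quality report (consensus error + intransitivity) for the data."""
        from .quality import quality_report, tournaments_from_outcomes

        return quality_report(
            self.outcomes,
            tournaments_from_outcomes(self.outcomes),
            ce_tie_policy=ce_tie_policy,
        )


class WorthResults:
    """Fitted worth scale with diagnostics, in the Results-object idiom."""

    def __init__(
        self,
        model: PreferenceModel,
        scale: WorthScale,
        opts: FitOptions,
        llf: float,
    ) -> None:
        self.model = model
        self.scale = scale
        self.opts = opts
        self.llf = llf

    @property
    def options(self) -> list[str]:
        return self.scale.options

    @property
    def params(self) -> np.ndarray:
        """Log-abilities (sum-to-zero identified)."""
        return self.scale.lam

    @property
    def worth(self) -> np.ndarray:
        return self.scale.worth

    @property
    def positions(self) -> np.ndarray:
        return self.scale.positions

    def worth_of(self, option: str) -> float:
        return self.scale.worth_of(option)

    def position_of(self, option: str) -> int:
        return self.scale.position_of(option)

    def quality(self, ce_tie_policy: str = "exclude"):
        return self.model.quality(ce_tie_policy=ce_tie_policy)

    def simulate_position(self, target: str, tested_against: Sequence[str], **kwargs):
        """Monte-Carlo positioning of ``target`` from partial comparisons.

        Masks every target comparison outside ``tested_against`` and
        repeatedly completes them at random; see
        :func:`pairworth.simulation.simulate_from_complete`.
        """
        from .simulation import SimulationConfig, simulate_from_complete

        cfg = SimulationConfig(
            target=target, tested_against=tuple(tested_against), **kwargs
        )
        return simulate_from_complete(self.model.outcomes, cfg)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "option": self.options,
                "lambda": self.scale.lam,
                "worth": self.scale.worth,
                "position": self.scale.positions,
            }
        )

    def to_json(self) -> str:
        payload = {
            "options": [
                {
                    "option": opt,
                    "lambda": float(self.scale.lam[i]),
                    "worth": float(self.scale.worth[i]),
                    "position": int(self.scale.positions[i]),
                }
                for i, opt in enumerate(self.options)
            ],
            "fit": {
                "tie_handling": self.opts.tie_handling.value,
                "damping": self.opts.damping,
                "log_likelihood": self.llf,
                "tied_positions": self.scale.tied_positions,
            },
        }
        return json.dumps(payload, indent=2)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)

    def summary(self) -> str:
        """Plain-text summary table of the fitted scale."""
        frame = self.to_frame().sort_values("position")
        lines = [
            "Worth scale (Bradley-Terry)",
            f"  options: {len(self.options)}   subjects: {len(self.model.subjects)}   "
            f"comparisons: {len(self.model.outcomes)}",
            f"  tie handling: {self.opts.tie_handling.value}   "
            f"damping: {self.opts.damping}   logL: {self.llf:.4f}",
            "",
            f"{'option':<16}{'worth':>10}{'lambda':>10}{'position':>10}",
        ]
        for _, row in frame.iterrows():
            lines.append(
                f"{row['option']:<16}{row['worth']:>10.4f}"
                f"{row['lambda']:>10.4f}{int(row['position']):>10d}"
            )
        if self.scale.tied_positions:
            lines.append("  note: exact worth ties share a position")
        return "\n".join(lines)

    def __repr__(self) -> str:
        order = [self.options[i] for i in np.argsort(-self.worth)]
        return f"<WorthResults: {' > '.join(order)}>"
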