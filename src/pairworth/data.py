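"""Binary choice data: records, datasets, thresholding, and delimited-table I/O.

A preference experiment presents pairs of options (liquids, images, ...) to
subjects and records how much of each side was consumed or whether it was
picked.  This module holds the long-format data model, session aggregation
across side-switched repeats, and the transformation from raw quantities to
win/loss/tie outcomes at a configurable preference threshold.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: Default mapping from logical field names to file column names.
DEFAULT_DIALECT: dict[str, str] = {
    "subject": "subject",
    "option_a": "option_a",
    "option_b": "option_b",
    "quantity_a": "quantity_a",
    "quantity_b": "quantity_b",
    "session": "session",
}

REQUIRED_FIELDS = ("subject", "option_a", "option_b", "quantity_a", "quantity_b")


class FormatError(ValueError):
    """A file could not be interpreted as a choice table."""


class ValidationError(ValueError):
    """A record violates a dataset invariant."""


class Outcome(Enum):
    """Thresholded result of one subject x option-pair comparison."""

    A_WINS = "A_WINS"
    B_WINS = "B_WINS"
    TIE = "TIE"


@dataclass(frozen=True)
class ChoiceRecord:
    """One observed presentation of an option pair to one subject.

    Quantities are unitless non-negative amounts (ml consumed, lick-visit
    counts, or 1/0 for a forced pick).
    """

    subject_id: str
    option_a: str
    option_b: str
    quantity_a: float
    quantity_b: float
    session_id: str | None = None

    def __post_init__(self) -> None:
        if self.option_a == self.option_b:
            raise ValidationError(
                f"option paired with itself: {self.option_a!r}"
            )
        if self.quantity_a < 0 or self.quantity_b < 0:
            raise ValidationError(
                f"negative quantity for subject {self.subject_id!r}, "
                f"pair ({self.option_a!r}, {self.option_b!r})"
            )

    def canonical(self) -> "ChoiceRecord":
        """Return the record with options in lexicographic orientation."""
        if self.option_a <= self.option_b:
            return self
        return replace(
            self,
            option_a=self.option_b,
            option_b=self.option_a,
            quantity_a=self.quantity_b,
            quantity_b=self.quantity_a,
        )


@dataclass(frozen=True)
class PreferenceThreshold:
    """Minimum choice share required to call one option preferred.

    ``theta`` is a proportion in [0.5, 1).  Shares r = q_a/(q_a+q_b) with
    1-theta <= r <= theta (closed bounds) count as ties; at theta=0.5 this
    degenerates to "tie only at an exact 50:50 split".
    """

    theta: float = 0.5

    def __post_init__(self) -> None:
        if not 0.5 <= self.theta < 1:
            raise ValidationError(f"theta must lie in [0.5, 1), got {self.theta}")

    @classmethod
    def from_percent(cls, percent: float) -> "PreferenceThreshold":
        """Build from the percentage vocabulary (50, 65) used in reports."""
        return cls(percent / 100.0)


@dataclass(frozen=True)
class BinaryOutcome:
    """Win/loss/tie for one subject x unordered option pair."""

    subject_id: str
    option_a: str
    option_b: str
    result: Outcome

    def canonical(self) -> "BinaryOutcome":
        if self.option_a <= self.option_b:
            return self
        flipped = {
            Outcome.A_WINS: Outcome.B_WINS,
            Outcome.B_WINS: Outcome.A_WINS,
            Outcome.TIE: Outcome.TIE,
        }[self.result]
        return BinaryOutcome(self.subject_id, self.option_b, self.option_a, flipped)

    @property
    def pair(self) -> tuple[str, str]:
        a, b = sorted((self.option_a, self.option_b))
        return (a, b)

    @property
    def winner(self) -> str | None:
        if self.result is Outcome.A_WINS:
            return self.option_a
        if self.result is Outcome.B_WINS:
            return self.option_b
        return None


def _first_appearance(values: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


@dataclass
class ChoiceDataset:
    """A validated collection of choice records with option/subject catalogs.

    Catalogs are ordered by first appearance and contain no duplicates; the
    (subject, unordered pair, session) triple is unique across records.
    """

    records: list[ChoiceRecord] = field(default_factory=list)
    options: list[str] = field(init=False)
    subjects: list[str] = field(init=False)

    def __post_init__(self) -> None:
        opts: list[str] = []
        for r in self.records:
            opts.extend((r.option_a, r.option_b))
        self.options = _first_appearance(opts)
        self.subjects = _first_appearance(r.subject_id for r in self.records)
        seen: set[tuple] = set()
        for i, r in enumerate(self.records):
            key = (r.subject_id, frozenset((r.option_a, r.option_b)), r.session_id)
            if key in seen:
                raise ValidationError(
                    f"duplicate subject/pair/session at record {i}: {key}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChoiceDataset):
            return NotImplemented
        return self.records == other.records

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame view (one row per record)."""
        return pd.DataFrame(
            {
                "subject": [r.subject_id for r in self.records],
                "option_a": [r.option_a for r in self.records],
                "option_b": [r.option_b for r in self.records],
                "quantity_a": [r.quantity_a for r in self.records],
                "quantity_b": [r.quantity_b for r in self.records],
                "session": [r.session_id for r in self.records],
            }
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, dialect: dict[str, str] | None = None
    ) -> "ChoiceDataset":
        d = dict(DEFAULT_DIALECT)
        if dialect:
            d.update(dialect)
        for fname in REQUIRED_FIELDS:
            if d[fname] not in frame.columns:
                raise FormatError(f"missing column {d[fname]!r} (field {fname!r})")
        has_session = d["session"] in frame.columns
        records = []
        for i, row in enumerate(frame.itertuples(index=False)):
            row_d = dict(zip(frame.columns, row))
            try:
                qa = float(row_d[d["quantity_a"]])
                qb = float(row_d[d["quantity_b"]])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"non-numeric quantity on row {i}: {exc}") from exc
            session = None
            if has_session:
                raw = row_d[d["session"]]
                session = None if pd.isna(raw) else str(raw)
            try:
                records.append(
                    ChoiceRecord(
                        subject_id=str(row_d[d["subject"]]),
                        option_a=str(row_d[d["option_a"]]),
                        option_b=str(row_d[d["option_b"]]),
                        quantity_a=qa,
                        quantity_b=qb,
                        session_id=session,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
        return cls(records)


def load_choices(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    delimiter: str = ",",
) -> ChoiceDataset:
    """Read a delimited choice table into a validated :class:`ChoiceDataset`.

    ``dialect`` maps logical field names (subject, option_a, option_b,
    quantity_a, quantity_b, session) onto the file's column names so
    externally produced tables can be read without editing.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=delimiter, dtype=str)
    return ChoiceDataset.from_frame(frame, dialect)


def write_choices(
    ds: ChoiceDataset, path: str | Path, delimiter: str = ","
) -> None:
    """Write the dataset back out as a delimited table (inverse of load)."""
    ds.to_frame().to_csv(path, sep=delimiter, index=False)


def aggregate_sessions(ds: ChoiceDataset) -> ChoiceDataset:
    """Collapse side-switched repeat sessions to one record per subject-pair.

    Quantities are summed over a subject-pair's sessions with sides aligned
    to the canonical (lexicographic) orientation.  Side switching exists only
    to cancel positional bias, so its two halves describe one comparison.
    Idempotent: already-aggregated data pass through unchanged.
    """
    sums: dict[tuple[str, str, str], list[float]] = {}
    order: list[tuple[str, str, str]] = []
    for r in ds.records:
        c = r.canonical()
        key = (c.subject_id, c.option_a, c.option_b)
        if key not in sums:
            sums[key] = [0.0, 0.0]
            order.append(key)
        sums[key][0] += c.quantity_a
        sums[key][1] += c.quantity_b
    records = [
        ChoiceRecord(sub, a, b, sums[(sub, a, b)][0], sums[(sub, a, b)][1])
        for (sub, a, b) in order
    ]
    return ChoiceDataset(records)


def apply_threshold(
    ds: ChoiceDataset, threshold: PreferenceThreshold
) -> list[BinaryOutcome]:
    """Transform aggregated quantities to win/loss/tie outcomes.

    For each subject-pair let r = q_a/(q_a+q_b): r > theta gives a win for A,
    r < 1-theta a win for B, anything in the closed window [1-theta, theta]
    a tie.  Pairs with zero total consumption are ties (logged).
    The dataset should be session-aggregated first.
    """
    outcomes = []
    for r in ds.records:
        c = r.canonical()
        total = c.quantity_a + c.quantity_b
        if total == 0:
            logger.warning(
                "zero total consumption for subject %r pair (%r, %r); recording a tie",
                c.subject_id, c.option_a, c.option_b,
            )
            result = Outcome.TIE
        else:
            share = c.quantity_a / total
            if share > threshold.theta:
                result = Outcome.A_WINS
            elif share < 1 - threshold.theta:
                result = Outcome.B_WINS
            else:
                result = Outcome.TIE
        outcomes.append(BinaryOutcome(c.subject_id, c.option_a, c.option_b, result))
    return outcomes


def count_pairs(n: int) -> int:
    """Number of unordered pairs among n options: n(n-1)/2."""
    if n < 1:
        raise ValueError(f"need at least one option, got {n}")
    return n * (n - 1) // 2


def completeness_report(
    outcomes: Sequence[BinaryOutcome],
    options: Sequence[str],
    subjects: Sequence[str],
) -> pd.DataFrame:
    """Table of subject x unordered-pair cells with no recorded outcome.

    Empty exactly when every subject compared every pair.
    """
    observed = {(o.subject_id, o.pair) for o in outcomes}
    rows = []
    opts = list(options)
    for s in subjects:
        for i, a in enumerate(opts):
            for b in opts[i + 1:]:
                pair = tuple(sorted((a, b)))
                if (s, pair) not in observed:
                    rows.append({"subject": s, "option_a": pair[0], "option_b": pair[1]})
    return pd.DataFrame(rows, columns=["subject", "option_a", "option_b"])


def outcomes_to_wide(outcomes: Sequence[BinaryOutcome]) -> pd.DataFrame:
    """Single-line-per-subject design view of thresholded outcomes.

    One row per subject, one column per canonically ordered pair
    ("A:B"), coded 1 (first option wins), -1 (second wins), 0 (tie);
    missing comparisons are NA.  This is the paired-comparison
    design-matrix convention.
    """
    pairs = sorted({o.pair for o in outcomes})
    subjects = _first_appearance(o.subject_id for o in outcomes)
    code = {Outcome.A_WINS: 1, Outcome.B_WINS: -1, Outcome.TIE: 0}
    wide = pd.DataFrame(
        index=pd.Index(subjects, name="subject"),
        columns=[f"{a}:{b}" for a, b in pairs],
        dtype="Float64",
    )
    for o in outcomes:
        c = o.canonical()
        wide.loc[c.subject_id, f"{c.option_a}:{c.option_b}"] = code[c.result]
    return wide
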