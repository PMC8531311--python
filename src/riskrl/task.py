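"""Structure of the two-block gain/loss probabilistic learning task.

The task presents pairs of stimuli drawn from five options per domain block:
two distinct sure-zero options (``Z1``, ``Z2``), a sure ±10 option (``T10``),
a sure ±20 option (``W20``), and a 50/50 risky option (``R``) paying 0 or ±20.
Outcomes are coded in units of 10 yen: gains in {0, 1, 2}, losses in
{0, -1, -2}.  Each block has 210 trials: every unordered pair of the five
options appears 20 times except the risk-preference probe {R, T10}, which
appears 30 times.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GAIN = "gain"
LOSS = "loss"
DOMAINS = (GAIN, LOSS)

OPTION_IDS = ("Z1", "Z2", "T10", "W20", "R")
OPTION_INDEX = {oid: i for i, oid in enumerate(OPTION_IDS)}

#: Number of presentations per unordered pair in one 210-trial block.
PAIR_COUNTS = {
    frozenset(p): 30 if frozenset(p) == frozenset(("R", "T10")) else 20
    for p in itertools.combinations(OPTION_IDS, 2)
}

N_TRIALS_PER_BLOCK = 210
N_TRIALS_PER_SUBJECT = 2 * N_TRIALS_PER_BLOCK

BLOCK_ORDERS = ("gain-first", "loss-first")


def _support(option_id: str, domain: str) -> tuple[tuple[int, float], ...]:
    sign = 1 if domain == GAIN else -1
    if option_id in ("Z1", "Z2"):
        return ((0, 1.0),)
    if option_id == "T10":
        return ((sign * 1, 1.0),)
    if option_id == "W20":
        return ((sign * 2, 1.0),)
    if option_id == "R":
        return ((0, 0.5), (sign * 2, 0.5))
    raise ValueError(f"unknown option id: {option_id!r}")


@dataclass(frozen=True)
class Option:
    """One of the five stimuli in a domain block.

    ``outcome_support`` lists (coded outcome, probability) pairs; sure options
    have a single support point, the risky option two equiprobable ones.
    """

    id: str
    domain: str
    outcome_support: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if self.id not in OPTION_IDS:
            raise ValueError(f"unknown option id: {self.id!r}")
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain: {self.domain!r}")
        total = sum(p for _, p in self.outcome_support)
        if abs(total - 1.0) > 1e-12:
            raise ValueError("outcome probabilities must sum to 1")

    @classmethod
    def make(cls, option_id: str, domain: str) -> "Option":
        return cls(option_id, domain, _support(option_id, domain))

    @property
    def expected_value(self) -> float:
        return sum(o * p for o, p in self.outcome_support)


def option_expected_value(option_id: str, domain: str) -> float:
    """Expected coded outcome of an option in a domain."""
    return Option.make(option_id, domain).expected_value


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered presentation plan for one 210-trial domain block."""

    domain: str
    trials: tuple[tuple[str, str], ...]
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def pair_counts(self) -> dict[frozenset, int]:
        counts: dict[frozenset, int] = {}
        for left, right in self.trials:
            key = frozenset((left, right))
            counts[key] = counts.get(key, 0) + 1
        return counts


def build_schedule(domain: str, seed: int) -> TrialSchedule:
    """Build the presentation order for one block.

    Every unordered pair appears 20 times ({R, T10}: 30 times).  Within a
    pair's presentations the left/right placement alternates (exact balance),
    and the full 210-trial multiset is then shuffled uniformly by ``seed``.
    """
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain: {domain!r}")
    if not (isinstance(seed, (int, np.integer)) and seed >= 0):
        raise ValueError("seed must be a non-negative integer")
    trials: list[tuple[str, str]] = []
    for a, b in itertools.combinations(OPTION_IDS, 2):
        n = PAIR_COUNTS[frozenset((a, b))]
        for k in range(n):
            trials.append((a, b) if k % 2 == 0 else (b, a))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    return TrialSchedule(domain, tuple(trials[i] for i in order), int(seed))


def draw_outcome(option: Option, rng: np.random.Generator) -> int:
    """Sample one coded outcome from an option's support."""
    support = option.outcome_support
    if len(support) == 1:
        return support[0][0]
    # risky option: two equiprobable support points
    return support[0][0] if rng.random() < support[0][1] else support[1][0]


@dataclass(frozen=True)
class ChoiceRecord:
    """One observed trial: the presented pair, the choice, and its outcome."""

    trial_index: int
    domain: str
    pair: tuple[str, str]
    chosen: str
    outcome_coded: int

    def __post_init__(self) -> None:
        if self.chosen not in self.pair:
            raise ValueError(
                f"chosen option {self.chosen!r} not in pair {self.pair!r}"
            )
        support = {o for o, _ in _support(self.chosen, self.domain)}
        if self.outcome_coded not in support:
            raise ValueError(
                f"outcome {self.outcome_coded} outside support of "
                f"{self.chosen!r} in {self.domain}"
            )

    @property
    def other(self) -> str:
        return self.pair[1] if self.chosen == self.pair[0] else self.pair[0]


@dataclass
class SubjectDataset:
    """All of one subject's trials across both domain blocks.

    Records are stored in presentation order (first block, then second).
    ``arrays`` compiles the trial sequence into integer arrays consumed by the
    likelihood kernel; the result is cached.
    """

    subject_id: str
    records: list[ChoiceRecord]
    block_order: str = "gain-first"
    _arrays: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.block_order not in BLOCK_ORDERS:
            raise ValueError(f"unknown block order: {self.block_order!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_trials(self) -> int:
        return len(self.records)

    def arrays(self) -> tuple[np.ndarray, ...]:
        """(chosen_idx, other_idx, outcome, domain_idx, block_start)."""
        if self._arrays is None:
            n = len(self.records)
            chosen = np.empty(n, dtype=np.int64)
            other = np.empty(n, dtype=np.int64)
            outcome = np.empty(n, dtype=np.int64)
            domain = np.empty(n, dtype=np.int64)
            block_start = np.zeros(n, dtype=np.bool_)
            prev = None
            for t, rec in enumerate(self.records):
                chosen[t] = OPTION_INDEX[rec.chosen]
                other[t] = OPTION_INDEX[rec.other]
                outcome[t] = rec.outcome_coded
                domain[t] = 0 if rec.domain == GAIN else 1
                block_start[t] = prev is None or rec.domain != prev
                prev = rec.domain
            self._arrays = (chosen, other, outcome, domain, block_start)
        return self._arrays

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject": self.subject_id,
                "domain": r.domain,
                "trial": r.trial_index,
                "opt_left": r.pair[0],
                "opt_right": r.pair[1],
                "chosen": r.chosen,
                "outcome": r.outcome_coded,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, subject_id: str) -> "SubjectDataset":
        sub = frame[frame["subject"].astype(str) == str(subject_id)]
        records = [
            ChoiceRecord(
                trial_index=int(row.trial),
                domain=str(row.domain),
                pair=(str(row.opt_left), str(row.opt_right)),
                chosen=str(row.chosen),
                outcome_coded=int(row.outcome),
            )
            for row in sub.itertuples()
        ]
        first_domain = records[0].domain if records else GAIN
        order = "gain-first" if first_domain == GAIN else "loss-first"
        return cls(str(subject_id), records, order)


def cohort_to_frame(cohort: Iterable[SubjectDataset]) -> pd.DataFrame:
    return pd.concat([d.to_frame() for d in cohort], ignore_index=True)


def cohort_from_frame(frame: pd.DataFrame) -> list[SubjectDataset]:
    return [
        SubjectDataset.from_frame(frame, sid)
        for sid in frame["subject"].astype(str).unique()
    ]
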