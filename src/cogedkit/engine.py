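"""Decision-phase engine: offer construction and staircase titration.

Each cell of the discounting procedure pairs one high-effort level with the
domain baseline at a fixed base amount ($2, $3 or $4).  Trial 1 offers equal
amounts; whichever option the participant picks becomes the *titrated* side
for the rest of the cell.  After the k-th choice the titrated offer moves by
``base / 2**k`` — down if the titrated side was chosen (it is "too
attractive"), up (capped at the base amount) otherwise.  The titrated offer
remaining after the fifth adjustment is the indifference point: with five
halved steps it pins the participant's switch point to within ``base/32``.

Amounts are carried as exact :class:`fractions.Fraction` dollars so that the
staircase arithmetic (e.g. $3/32 = $0.09375) incurs no float drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, List, Literal, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .domains import BASE_AMOUNTS, TaskDomain
from .errors import ConfigurationError, DataError, ProtocolError

Money = Union[int, Fraction]
Choice = Literal["easy", "hard"]

#: Number of calibration trials per cell, counting the initial equal-offer trial.
TRIALS_PER_CELL = 5


def _as_money(x: Money) -> Fraction:
    f = Fraction(x)
    if f <= 0:
        raise DataError(f"amounts must be positive, got {f}")
    return f


@dataclass(frozen=True)
class OfferPair:
    """One decision trial's pair of offers."""

    hard_label: str
    hard_amount: Fraction
    easy_label: str
    easy_amount: Fraction

    def amount(self, side: Choice) -> Fraction:
        return self.hard_amount if side == "hard" else self.easy_amount


@dataclass
class TitrationState:
    """Mutable state of one staircase cell (exposed for introspection)."""

    titrated_side: Optional[Choice]
    current_offer: Fraction
    step: Fraction
    trial_index: int


@dataclass
class IndifferenceRecord:
    """Outcome of one fully titrated cell."""

    participant_id: str
    domain: str
    hard_level: str
    base_amount: Fraction
    first_choice: Choice
    indifference_point: Fraction
    trial_log: List[Tuple[OfferPair, Choice]] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.indifference_point <= self.base_amount:
            raise DataError(
                f"indifference point {self.indifference_point} outside "
                f"(0, {self.base_amount}]"
            )


Agent = Callable[[OfferPair], Choice]


def run_cell(
    agent: Agent,
    domain: TaskDomain,
    hard_level: str,
    base: Money,
    participant_id: str = "anon",
) -> IndifferenceRecord:
    """Titrate one (hard level, base amount) cell to its indifference point.

    The agent is called once per calibration trial with the current
    :class:`OfferPair` and must return ``"easy"`` or ``"hard"``.
    """
    base = _as_money(base)
    titrated: Optional[Choice] = None
    current = base
    log: List[Tuple[OfferPair, Choice]] = []
    for k in range(1, TRIALS_PER_CELL + 1):
        if titrated == "easy":
            pair = OfferPair(hard_level, base, domain.baseline, current)
        elif titrated == "hard":
            pair = OfferPair(hard_level, current, domain.baseline, base)
        else:  # trial 1: equal offers
            pair = OfferPair(hard_level, base, domain.baseline, base)
        choice = agent(pair)
        if choice not in ("easy", "hard"):
            raise ProtocolError(f"agent returned {choice!r}, expected 'easy' or 'hard'")
        log.append((pair, choice))
        if titrated is None:
            titrated = choice
        step = base / 2**k
        if choice == titrated:
            current -= step
        else:
            current = min(current + step, base)
    return IndifferenceRecord(
        participant_id=participant_id,
        domain=domain.name,
        hard_level=hard_level,
        base_amount=base,
        first_choice=log[0][1],
        indifference_point=current,
        trial_log=log,
    )


def run_discounting(
    agent,
    domain: TaskDomain,
    bases: Sequence[Money] = BASE_AMOUNTS,
    seed: Optional[int] = None,
    participant_id: str = "anon",
) -> List[IndifferenceRecord]:
    """Run the full 9-cell decision phase for one participant in one domain.

    ``agent`` is either a plain choice function used for every cell, or an
    object exposing ``for_cell(domain, level, base) -> choice function`` (see
    :class:`cogedkit.cohort.ParticipantAgent`), whose per-cell policies can
    depend on the cell's effort level and base amount.

    Cells (3 levels x 3 base amounts, 5 calibration trials each = 45 decision
    trials) are presented in an order shuffled by ``seed``.
    """
    if len(domain.levels) != 3:
        raise ConfigurationError(
            f"domain {domain.name!r} declares {len(domain.levels)} hard levels; "
            "the decision phase requires exactly 3"
        )
    cells = [(level, _as_money(b)) for level in domain.levels for b in bases]
    if len(cells) != 9:
        raise ConfigurationError(f"expected 9 cells, got {len(cells)}")
    order = np.random.default_rng(seed).permutation(len(cells))
    records = []
    for idx in order:
        level, base = cells[idx]
        cell_agent = agent.for_cell(domain, level, base) if hasattr(agent, "for_cell") else agent
        records.append(run_cell(cell_agent, domain, level, base, participant_id))
    return records


def trial_log_frame(records: Sequence[IndifferenceRecord]) -> pd.DataFrame:
    """Flatten trial logs into a tidy table (one row per decision trial)."""
    rows = []
    for rec in records:
        for i, (pair, choice) in enumerate(rec.trial_log, start=1):
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "domain": rec.domain,
                    "hard_level": rec.hard_level,
                    "base": float(rec.base_amount),
                    "trial_index": i,
                    "easy_amount": float(pair.easy_amount),
                    "hard_amount": float(pair.hard_amount),
                    "choice": choice,
                }
            )
    return pd.DataFrame(rows)
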