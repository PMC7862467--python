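"""Subjective-value scoring of indifference records on the 0-2 scale.

If the participant's first (equal-offer) choice was the easy option, the easy
offer was titrated downward and the subjective value of the hard task is the
indifference point expressed as a fraction of the base amount:

    SV = IP / base                      in (0, 1]

If the first choice was the hard option, the hard offer was titrated and the
discounted quantity is the *easy* task; the estimate is reflected onto the
upper half of the scale:

    SV = (base - IP) / base + 1         in [1, 2)

Values above 1 indicate preference for the harder task.  Because offers never
reach zero, SV = 0 is unattainable, and the five-step staircase caps the
scale at 2 - 1/32 = 1.96875.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .domains import BASE_AMOUNTS, DOMAINS, TaskDomain
from .engine import IndifferenceRecord
from .errors import DataError, IncompleteDataError

__all__ = ["subjective_value", "SVTable", "score_records", "average_sv"]

#: Cells per participant x domain (3 levels x 3 base amounts).
CELLS_PER_DOMAIN = 9


def subjective_value(record: IndifferenceRecord) -> Fraction:
    """Exact subjective value of one indifference record."""
    base = Fraction(record.base_amount)
    ip = Fraction(record.indifference_point)
    if base <= 0:
        raise DataError(f"base amount must be positive, got {base}")
    if not 0 < ip <= base:
        raise DataError(f"indifference point {ip} outside (0, {base}]")
    if record.first_choice == "easy":
        return ip / base
    return (base - ip) / base + 1


@dataclass
class SVTable:
    """All subjective values of a cohort, at cell grain.

    ``records`` has one row per participant x domain x level x base with
    columns ``participant_id, domain, hard_level, base, first_choice,
    indifference_point, sv``.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "participant_id", "domain", "hard_level", "base", "first_choice",
            "indifference_point", "sv",
        }
        missing = required - set(self.records.columns)
        if missing:
            raise DataError(f"SVTable missing columns: {sorted(missing)}")

    @property
    def participants(self) -> List[str]:
        return sorted(self.records["participant_id"].unique())

    def _require_complete(self, participant: str, domain: str) -> pd.DataFrame:
        sub = self.records[
            (self.records["participant_id"] == participant)
            & (self.records["domain"] == domain)
        ]
        if len(sub) != CELLS_PER_DOMAIN:
            dom = next(d for d in DOMAINS if d.name == domain)
            expected = {(lvl, float(b)) for lvl in dom.levels for b in BASE_AMOUNTS}
            present = set(zip(sub["hard_level"], sub["base"]))
            absent = sorted(expected - present)
            raise IncompleteDataError(
                f"{participant}/{domain}: expected {CELLS_PER_DOMAIN} cells, "
                f"found {len(sub)}; missing {absent}",
                missing=absent,
            )
        return sub

    def mean_sv(self, participant: str, domain: str) -> float:
        """Mean subjective value over the 9 cells of one participant x domain."""
        return float(self._require_complete(participant, domain)["sv"].mean())

    def domain_means(self) -> pd.DataFrame:
        """Participant-level summary: one column of mean SV per domain.

        Completeness of every participant x domain block is enforced first.
        """
        for pid in self.participants:
            for domain in self.records["domain"].unique():
                self._require_complete(pid, str(domain))
        wide = (
            self.records.groupby(["participant_id", "domain"])["sv"]
            .mean()
            .unstack("domain")
        )
        wide.columns = [f"mean_sv_{c}" for c in wide.columns]
        return wide

    def level_means(self) -> pd.DataFrame:
        """Participant x domain x level means over the 3 base amounts."""
        return (
            self.records.groupby(["participant_id", "domain", "hard_level"])["sv"]
            .mean()
            .reset_index()
            .rename(columns={"hard_level": "level"})
        )


def score_records(records: Iterable[IndifferenceRecord]) -> SVTable:
    """Score a batch of indifference records into an :class:`SVTable`."""
    rows = [
        {
            "participant_id": r.participant_id,
            "domain": r.domain,
            "hard_level": r.hard_level,
            "base": float(r.base_amount),
            "first_choice": r.first_choice,
            "indifference_point": float(r.indifference_point),
            "sv": float(subjective_value(r)),
        }
        for r in records
    ]
    return SVTable(pd.DataFrame(rows))


def average_sv(table: SVTable, participant: str, domain: str) -> float:
    """Mean SV across the 9 cells; raises IncompleteDataError on missing cells."""
    return table.mean_sv(participant, domain)
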