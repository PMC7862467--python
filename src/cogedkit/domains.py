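"""Task-domain descriptors for the two effort-discounting domains.

The discounting phase pits a high-effort task level against the domain's
low-effort baseline.  In the working-memory domain the levels are N-back loads
(1-back baseline, 2/3/4-back hard); in the speech-comprehension domain they
are speech-in-noise SNRs (0 dB baseline, -4/-8/-12 dB hard).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Tuple

#: Fixed offer amounts (USD) at which each hard level is titrated.
BASE_AMOUNTS: Tuple[Fraction, ...] = (Fraction(2), Fraction(3), Fraction(4))


@dataclass(frozen=True)
class TaskDomain:
    """One cognitive domain of the discounting task.

    Parameters
    ----------
    name
        Identifier used in tables (``working_memory`` or ``speech``).
    baseline
        Label of the low-effort comparison level.
    levels
        Labels of the three high-effort levels, easiest first.
    performance_covariates
        Names of the per-level task-performance measures entered as
        covariates in the second analysis stage.
    """

    name: str
    baseline: str
    levels: Tuple[str, ...]
    performance_covariates: Tuple[str, ...]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


WORKING_MEMORY = TaskDomain(
    name="working_memory",
    baseline="1back",
    levels=("2back", "3back", "4back"),
    performance_covariates=("d_prime", "mean_rt"),
)

SPEECH = TaskDomain(
    name="speech",
    baseline="snr0",
    levels=("snr-4", "snr-8", "snr-12"),
    performance_covariates=("intelligibility",),
)

DOMAINS: Tuple[TaskDomain, ...] = (WORKING_MEMORY, SPEECH)

_BY_NAME = {d.name: d for d in DOMAINS}


def get_domain(name: str) -> TaskDomain:
    """Look up a registered domain by name."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown domain {name!r}; registered: {sorted(_BY_NAME)}"
        ) from None
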