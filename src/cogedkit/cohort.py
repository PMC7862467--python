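"""Synthetic cohorts with a domain-general latent motivation factor.

The generator draws, for each simulated participant, a proportional effort
cost for every (domain, level) cell of the discounting task.  Costs load on a
single standard-normal motivation factor shared across domains:

    cost(d, level) = level_cost_means[d][level]
                     + cost_sd * (lambda_d * M + sqrt(1 - |rho|) * eta_d)

with ``lambda_1 = sqrt(|rho|)``, ``lambda_2 = sign(rho) * sqrt(|rho|)`` and
``eta_d`` independent standard normals per domain.  Each domain factor then
has unit variance and the correlation of mean costs across domains equals the
configured ``cross_domain_rho`` exactly, which makes rho a recoverable ground
truth for the downstream analysis stages.

Costs are *fractions of the base offer* (a cost of 0.4 means the participant
gives up 40% of the offer to avoid the harder task), so a given participant
produces the same subjective value at $2, $3 and $4 offers.  Costs below 0
describe effort-seeking participants and map to subjective values above 1.

Covariates (task performance, span scores, reward-sensitivity and
need-for-cognition questionnaires) load on two further latents —
``wm_capacity_latent`` and ``reward_sensitivity_latent`` — that are drawn
independently of the motivation factor unless configured otherwise, so by
default they carry no effort-cost variance.  Bounded questionnaire totals are
produced by pushing a noisy latent through a scaled logistic and rounding to
the instrument's range; this keeps every draw inside its declared bounds
without committing to distributional claims about real instruments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Callable, Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .domains import DOMAINS, SPEECH, WORKING_MEMORY, TaskDomain
from .engine import Agent, OfferPair
from .errors import ConfigurationError, DomainError

__all__ = [
    "CohortConfig",
    "CovariateLoadings",
    "ParticipantProfile",
    "generate_cohort",
    "make_threshold_agent",
    "ParticipantAgent",
    "profiles_frame",
]

#: Default mean proportional cost per level, easiest hard level first.  The
#: pilot pattern — harder levels discounted more, with group-mean subjective
#: values roughly 0.45-0.75 — motivates the 0.25/0.40/0.55 ladder, used for
#: both domains (the pilot found no mean difference between domains).
DEFAULT_LEVEL_COST_MEANS: Dict[str, Tuple[float, float, float]] = {
    WORKING_MEMORY.name: (0.25, 0.40, 0.55),
    SPEECH.name: (0.25, 0.40, 0.55),
}


@dataclass(frozen=True)
class CovariateLoadings:
    """Loadings of observed covariates on the generator's latent traits.

    ``wm_performance``: d-prime / RT / intelligibility on the WM-capacity
    latent; ``span``: complex-span totals on the WM-capacity latent;
    ``reward``: questionnaire reward scores on the reward-sensitivity latent;
    ``ncs_motivation``: the need-for-cognition total on the motivation factor
    (kept modest — the pilot found only anecdotal NCS correlations).
    """

    wm_performance: float = 0.6
    span: float = 0.8
    reward: float = 0.8
    ncs_motivation: float = 0.3


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated cohort."""

    n_participants: int = 150
    cross_domain_rho: float = 0.5
    level_cost_means: Mapping[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_COST_MEANS)
    )
    cost_sd: float = 0.18
    choice_temperature: float = 0.0
    covariate_loadings: CovariateLoadings = field(default_factory=CovariateLoadings)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError(
                f"n_participants must be >= 2, got {self.n_participants}"
            )
        if not -1.0 < self.cross_domain_rho < 1.0:
            raise ConfigurationError(
                f"cross_domain_rho must lie strictly inside (-1, 1), got "
                f"{self.cross_domain_rho}"
            )
        if self.cost_sd < 0:
            raise ConfigurationError("cost_sd must be nonnegative")
        if self.choice_temperature < 0:
            raise ConfigurationError("choice_temperature must be nonnegative")
        for domain in DOMAINS:
            means = self.level_cost_means.get(domain.name)
            if means is None:
                raise ConfigurationError(f"missing level_cost_means for {domain.name}")
            if len(means) != len(domain.levels):
                raise ConfigurationError(
                    f"{domain.name}: expected {len(domain.levels)} level means"
                )
            if any(b < a for a, b in zip(means, means[1:])):
                raise ConfigurationError(
                    f"{domain.name}: level cost means must be nondecreasing with "
                    f"load level, got {tuple(means)}"
                )
            if any(not 0 <= m <= 1 for m in means):
                raise ConfigurationError(
                    f"{domain.name}: level cost means must lie in [0, 1]"
                )


@dataclass
class ParticipantProfile:
    """Ground-truth latent state of one simulated participant."""

    participant_id: str
    motivation_factor: float
    domain_costs: Dict[Tuple[str, str], float]
    wm_capacity_latent: float
    reward_sensitivity_latent: float
    temperature: float = 0.0
    rng: Optional[np.random.Generator] = field(default=None, repr=False)

    def cost(self, domain: TaskDomain | str, level: str) -> float:
        name = domain.name if isinstance(domain, TaskDomain) else domain
        try:
            return self.domain_costs[(name, level)]
        except KeyError:
            raise DomainError(f"no cost entry for ({name!r}, {level!r})") from None

    def mean_cost(self, domain: TaskDomain | str) -> float:
        name = domain.name if isinstance(domain, TaskDomain) else domain
        vals = [c for (d, _), c in self.domain_costs.items() if d == name]
        if not vals:
            raise DomainError(f"no cost entries for domain {name!r}")
        return float(np.mean(vals))


def _bounded_score(
    rng: np.random.Generator,
    latent: float,
    loading: float,
    lo: int,
    hi: int,
    noise_sd: float = 0.6,
    center: float = 0.0,
) -> int:
    """Latent -> integer score in [lo, hi] via a scaled logistic transform."""
    z = center + loading * latent + noise_sd * rng.standard_normal()
    return int(lo + round((hi - lo) * expit(z)))


def generate_cohort(config: CohortConfig) -> Tuple[List[ParticipantProfile], pd.DataFrame]:
    """Draw a cohort of participant profiles plus their covariate table.

    Deterministic given ``config.seed``; each participant draws from a named
    child stream of the shared seed, so profile ``i`` is unchanged when the
    cohort is enlarged.

    Returns the list of :class:`ParticipantProfile` and a wide covariate
    DataFrame indexed by ``participant_id`` with columns:
    ``d_prime_{2back,3back,4back}``, ``mean_rt_{...}`` (ms),
    ``intelligibility_{snr-4,snr-8,snr-12}``, ``lspan``, ``ospan``,
    ``symspan``, ``bas_total``, ``grapes_reward``, ``spsrq_reward``, ``ncs``.
    """
    rho = config.cross_domain_rho
    lam = math.sqrt(abs(rho))
    resid = math.sqrt(1.0 - abs(rho))
    signs = {WORKING_MEMORY.name: 1.0, SPEECH.name: math.copysign(1.0, rho) if rho else 1.0}
    load = config.covariate_loadings

    # pre-rounding level means of the performance covariates, easiest first
    dprime_means = (2.8, 2.2, 1.6)
    rt_means = (620.0, 700.0, 780.0)
    intell_means = (0.90, 0.72, 0.45)

    root = np.random.SeedSequence(config.seed)
    profiles: List[ParticipantProfile] = []
    cov_rows: List[dict] = []
    width = max(3, len(str(config.n_participants - 1)))
    for i, child in enumerate(root.spawn(config.n_participants)):
        rng = np.random.default_rng(child)
        pid = f"p{i:0{width}d}"
        m = rng.standard_normal()
        wm_lat = rng.standard_normal()
        rew_lat = rng.standard_normal()
        costs: Dict[Tuple[str, str], float] = {}
        for domain in DOMAINS:
            eta = rng.standard_normal()
            factor = lam * signs[domain.name] * m + resid * eta
            for level, mu in zip(domain.levels, config.level_cost_means[domain.name]):
                costs[(domain.name, level)] = mu + config.cost_sd * factor
        profiles.append(
            ParticipantProfile(
                participant_id=pid,
                motivation_factor=m,
                domain_costs=costs,
                wm_capacity_latent=wm_lat,
                reward_sensitivity_latent=rew_lat,
                temperature=config.choice_temperature,
                rng=rng,
            )
        )

        row: dict = {"participant_id": pid}
        for level, mu in zip(WORKING_MEMORY.levels, dprime_means):
            row[f"d_prime_{level}"] = (
                mu + load.wm_performance * wm_lat + 0.5 * rng.standard_normal()
            )
        for level, mu in zip(WORKING_MEMORY.levels, rt_means):
            row[f"mean_rt_{level}"] = max(
                200.0, mu - 40.0 * load.wm_performance * wm_lat + 60.0 * rng.standard_normal()
            )
        for level, p in zip(SPEECH.levels, intell_means):
            row[f"intelligibility_{level}"] = float(
                expit(logit(p) + 0.8 * load.wm_performance * wm_lat + 0.5 * rng.standard_normal())
            )
        row["lspan"] = _bounded_score(rng, wm_lat, load.span, 0, 42)
        row["ospan"] = _bounded_score(rng, wm_lat, load.span, 0, 75)
        row["symspan"] = _bounded_score(rng, wm_lat, load.span, 0, 42)
        row["bas_total"] = _bounded_score(rng, rew_lat, load.reward, 13, 52)
        row["grapes_reward"] = _bounded_score(rng, rew_lat, load.reward, 0, 30)
        row["spsrq_reward"] = _bounded_score(rng, rew_lat, load.reward, 0, 24)
        row["ncs"] = _bounded_score(rng, m, load.ncs_motivation, 18, 90)
        cov_rows.append(row)

    covariates = pd.DataFrame(cov_rows).set_index("participant_id")
    return profiles, covariates


def make_threshold_agent(
    profile: ParticipantProfile,
    domain: TaskDomain | str,
    level: str,
    base,
) -> Agent:
    """Build the choice policy of ``profile`` for one (domain, level, base) cell.

    The hard option is worth its offer minus ``cost * base``; the baseline
    option is worth its offer alone.  At ``temperature == 0`` the agent picks
    the higher-utility option deterministically (ties go to the easy option);
    at positive temperature the choice is logistic in the utility difference
    scaled by the temperature.
    """
    cost = profile.cost(domain, level)
    base = Fraction(base)
    effort_cost = cost * float(base)
    temperature = profile.temperature
    rng = profile.rng

    def choose(pair: OfferPair) -> str:
        u_easy = float(pair.easy_amount)
        u_hard = float(pair.hard_amount) - effort_cost
        if temperature == 0:
            return "hard" if u_hard > u_easy else "easy"
        p_easy = expit((u_easy - u_hard) / temperature)
        gen = rng if rng is not None else np.random.default_rng()
        return "easy" if gen.random() < p_easy else "hard"

    return choose


class ParticipantAgent:
    """Adapter giving :func:`cogedkit.engine.run_discounting` per-cell policies."""

    def __init__(self, profile: ParticipantProfile):
        self.profile = profile

    def for_cell(self, domain: TaskDomain, level: str, base) -> Agent:
        return make_threshold_agent(self.profile, domain, level, base)


def profiles_frame(profiles: List[ParticipantProfile]) -> pd.DataFrame:
    """Tidy ground-truth table: one row per participant x domain x level."""
    rows = [
        {
            "participant_id": p.participant_id,
            "domain": d,
            "level": level,
            "cost": c,
            "motivation_factor": p.motivation_factor,
            "wm_capacity_latent": p.wm_capacity_latent,
            "reward_sensitivity_latent": p.reward_sensitivity_latent,
        }
        for p in profiles
        for (d, level), c in sorted(p.domain_costs.items())
    ]
    return pd.DataFrame(rows)
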