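"""Z-score composites and covariate residualization of subjective values.

The second analysis stage strips task-difficulty and performance variance
from the subjective values: within each domain an OLS model predicts the
participant x level SV from task level (categorical) plus that domain's
performance covariates, and each participant keeps the mean of their row
residuals.  The third stage controls additionally for two trait composites —
working-memory capacity (sum of z-scored span totals) and reward sensitivity
(sum of z-scored questionnaire scores) — via partial correlation.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .domains import TaskDomain
from .errors import AlignmentError, DegenerateInputError
from .scoring import SVTable

__all__ = ["zscore", "zscore_composite", "composite_table", "residualize_sv"]

WM_CAPACITY_MEASURES = ("lspan", "ospan", "symspan")
REWARD_SENSITIVITY_MEASURES = ("bas_total", "grapes_reward", "spsrq_reward")


def zscore(x: pd.Series) -> pd.Series:
    """In-sample z-score (sample SD, ddof=1)."""
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateInputError(
            f"measure {x.name!r} has zero variance in the analyzed sample"
        )
    return (x - x.mean()) / sd


def zscore_composite(scores: pd.DataFrame, measures: Sequence[str]) -> pd.Series:
    """Sum of in-sample z-scores of the named measure columns."""
    missing = [m for m in measures if m not in scores.columns]
    if missing:
        raise KeyError(f"missing measure columns: {missing}")
    return sum(zscore(scores[m]) for m in measures)


def composite_table(covariates: pd.DataFrame) -> pd.DataFrame:
    """Both trait composites, indexed by participant.

    ``wm_capacity`` sums z-scored L-span, O-span and Sym-span totals;
    ``reward_sensitivity`` sums z-scored BAS total, GRAPES reward and SPSRQ
    reward scores.
    """
    return pd.DataFrame(
        {
            "wm_capacity": zscore_composite(covariates, WM_CAPACITY_MEASURES),
            "reward_sensitivity": zscore_composite(
                covariates, REWARD_SENSITIVITY_MEASURES
            ),
        }
    )


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify columns inside the span of their predecessors
        bad: List[str] = []
        for j in range(1, arr.shape[1]):
            if np.linalg.matrix_rank(arr[:, : j + 1]) == np.linalg.matrix_rank(arr[:, :j]):
                bad.append(str(X.columns[j]))
        raise DegenerateInputError(
            f"design matrix is rank-deficient (rank {rank} < {arr.shape[1]}); "
            f"collinear columns: {bad}"
        )


def residualize_sv(
    sv_table: SVTable,
    covariates: pd.DataFrame,
    domain: TaskDomain,
    grain: str = "level",
) -> pd.DataFrame:
    """Covariate-adjusted participant-level subjective values for one domain.

    With ``grain="level"`` (default) the OLS design has one row per
    participant x level (SV averaged over the three base amounts), task level
    entered as a categorical factor, and the domain's performance covariates
    matched at level grain (e.g. ``d_prime_3back`` for the 3-back rows).  The
    participant's residual is the mean of their row residuals; residuals have
    in-sample mean zero.  With ``grain="participant"`` the model is fitted on
    participant means with participant-mean covariates and no level factor.

    Returns a DataFrame indexed by ``participant_id`` with columns ``domain``
    and ``residual_sv``.
    """
    if grain not in ("level", "participant"):
        raise ValueError(f"grain must be 'level' or 'participant', got {grain!r}")

    level_means = sv_table.level_means()
    long = level_means[level_means["domain"] == domain.name].copy()
    if long.empty:
        raise AlignmentError(f"SV table has no rows for domain {domain.name!r}")
    missing = sorted(set(long["participant_id"]) - set(covariates.index))
    if missing:
        raise AlignmentError(
            f"covariate table lacks participants: {missing[:5]}"
            + ("..." if len(missing) > 5 else ""),
            offenders=missing,
        )

    for cov in domain.performance_covariates:
        cols = {lvl: f"{cov}_{lvl}" for lvl in domain.levels}
        absent = [c for c in cols.values() if c not in covariates.columns]
        if absent:
            raise KeyError(f"covariate columns missing: {absent}")
        long[cov] = [
            covariates.at[pid, cols[lvl]]
            for pid, lvl in zip(long["participant_id"], long["level"])
        ]

    # a covariate that never varies carries no adjustable variance (and would
    # be collinear with the intercept); the model degrades gracefully to the
    # remaining predictors
    active = [c for c in domain.performance_covariates if long[c].nunique() > 1]

    if grain == "participant":
        long = (
            long.groupby("participant_id")[["sv", *active]]
            .mean()
            .reset_index()
        )
        X = sm.add_constant(long[active], has_constant="add")
    else:
        X = pd.get_dummies(long["level"], prefix="level", drop_first=True, dtype=float)
        X[active] = long[active]
        X = sm.add_constant(X, has_constant="add")

    _check_rank(X)
    fit = sm.OLS(long["sv"].to_numpy(float), X).fit()
    long["resid"] = fit.resid
    out = long.groupby("participant_id")["resid"].mean().rename("residual_sv").to_frame()
    out.insert(0, "domain", domain.name)
    return out
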