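"""Three-stage cross-domain analysis as a Model/Results pair.

:class:`CrossDomainModel` holds the scored subjective values and the
covariate table of one cohort; :meth:`CrossDomainModel.fit` runs the
registered analysis ladder and returns a :class:`CrossDomainResults`:

* **Stage 1** — zero-order Bayesian correlation of the participant-level
  mean subjective values in the two domains.
* **Stage 2** — within each domain, subjective values are residualized on
  task level and the domain's performance covariates (OLS at participant x
  level grain); the participant-mean residuals of the two domains are then
  correlated.
* **Stage 3** — partial correlation of the stage-2 residuals controlling for
  the working-memory-capacity and reward-sensitivity composites (effective
  n reduced by the two fitted controls).
* **Stage 4** (optional, off by default) — exploratory correlation of the
  need-for-cognition score with the composite (two-domain mean) subjective
  value.

Participants whose 18 cells all share one first choice are flagged as
non-compliant; when any are flagged the results carry a second, flag-excluded
variant of every stage rather than silently dropping anyone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bayescorr import BFResult, PriorSpec, correlation_bf, partial_correlation_bf
from .composites import composite_table, residualize_sv
from .domains import SPEECH, WORKING_MEMORY
from .errors import AlignmentError
from .scoring import SVTable

__all__ = ["CrossDomainModel", "CrossDomainResults", "flag_noncompliance"]


def flag_noncompliance(sv_table: SVTable) -> pd.Series:
    """Flag participants who chose one option on every decision trial.

    Always choosing the high-effort (or always the low-effort) option across
    all 90 decision trials suggests non-compliance with the decision-phase
    instructions.  Such a participant is identifiable from the scored table
    alone: every cell shares one first choice *and* every staircase ran to
    its extreme (indifference point = base/32), since only a participant who
    kept choosing the titrated side on all five calibration trials ends
    there.  A participant with interior indifference points necessarily
    mixed choices during titration and is compliant.

    Returns a boolean Series indexed by participant_id.
    """
    rec = sv_table.records
    extreme = rec["indifference_point"] <= rec["base"] / 32 + 1e-12
    by = rec.assign(extreme=extreme).groupby("participant_id")
    return (
        (by["first_choice"].nunique() == 1) & by["extreme"].all()
    ).rename("noncompliant")


@dataclass
class CrossDomainResults:
    """Fitted three-stage analysis; one BFResult per stage and variant."""

    model: "CrossDomainModel"
    stages: Dict[int, BFResult]
    stages_excluded: Optional[Dict[int, BFResult]]
    flags: pd.Series
    n_analyzed: int

    def stage(self, k: int, excluded: bool = False) -> BFResult:
        source = self.stages_excluded if excluded else self.stages
        if source is None:
            raise KeyError("no flag-excluded variant: no participant was flagged")
        return source[k]

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(variant="all", stage=k, **res.as_dict()) for k, res in self.stages.items()]
        if self.stages_excluded is not None:
            rows += [
                dict(variant="flag_excluded", stage=k, **res.as_dict())
                for k, res in self.stages_excluded.items()
            ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Cross-domain cognitive-effort analysis",
            f"  participants analyzed: {self.n_analyzed}"
            f" ({int(self.flags.sum())} flagged non-compliant)",
            f"  prior: {self.model.prior.family} scale={self.model.prior.scale:.4f}"
            f" ({self.model.prior.sided}-sided)",
        ]
        names = {
            1: "stage 1  zero-order correlation of domain-mean SVs",
            2: "stage 2  correlation of performance-residualized SVs",
            3: "stage 3  partial correlation given trait composites",
            4: "stage 4  exploratory NCS correlations",
        }
        for variant, stages in [("all participants", self.stages)] + (
            [("flagged excluded", self.stages_excluded)] if self.stages_excluded else []
        ):
            lines.append(f"  [{variant}]")
            for k, res in stages.items():
                lines.append(f"    {names.get(k, k)}:")
                lines.append(f"      {res}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Posterior medians with 95% credible intervals per stage."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ks = sorted(self.stages)
        med = [self.stages[k].posterior_median_rho for k in ks]
        lo = [self.stages[k].credible_interval_95[0] for k in ks]
        hi = [self.stages[k].credible_interval_95[1] for k in ks]
        ax.errorbar(
            ks, med,
            yerr=[np.subtract(med, lo), np.subtract(hi, med)],
            fmt="o", capsize=4,
        )
        ax.axhline(0.0, color="gray", lw=0.8)
        ax.set_xticks(ks)
        ax.set_xlabel("analysis stage")
        ax.set_ylabel(r"posterior median $\rho$ (95% CI)")
        return ax


class CrossDomainModel:
    """The registered cross-domain analysis bound to one cohort's tables.

    Parameters
    ----------
    sv_table
        Cell-grain subjective values of the cohort.
    covariates
        Wide covariate table indexed by participant_id (see
        :func:`cogedkit.cohort.generate_cohort` for the schema).
    prior
        Analysis prior used by every stage.
    residual_grain
        ``"level"`` (default) or ``"participant"``; grain of the stage-2 OLS.
    """

    def __init__(
        self,
        sv_table: SVTable,
        covariates: pd.DataFrame,
        prior: Optional[PriorSpec] = None,
        residual_grain: str = "level",
    ):
        self.sv_table = sv_table
        self.covariates = covariates
        self.prior = prior or PriorSpec()
        self.residual_grain = residual_grain
        missing = sorted(set(sv_table.participants) - set(covariates.index))
        if missing:
            raise AlignmentError(
                f"covariates missing for participants {missing[:5]}", offenders=missing
            )

    @classmethod
    def from_frames(
        cls, sv_records: pd.DataFrame, covariates: pd.DataFrame, **kwargs
    ) -> "CrossDomainModel":
        """Build from raw delimited-text tables already loaded as DataFrames."""
        return cls(SVTable(sv_records), covariates, **kwargs)

    # -- fitting ------------------------------------------------------------

    def _fit_stages(self, sv_table: SVTable, stages: Sequence[int]) -> Dict[int, BFResult]:
        covs = self.covariates.loc[sv_table.participants]
        out: Dict[int, BFResult] = {}
        means = sv_table.domain_means()
        wm = means[f"mean_sv_{WORKING_MEMORY.name}"]
        sp = means[f"mean_sv_{SPEECH.name}"]
        if 1 in stages:
            r1 = float(np.corrcoef(wm, sp)[0, 1])
            out[1] = correlation_bf(r1, len(means), self.prior, label="stage1_zero_order")
        resid = None
        if 2 in stages or 3 in stages:
            rw = residualize_sv(sv_table, covs, WORKING_MEMORY, grain=self.residual_grain)
            rs = residualize_sv(sv_table, covs, SPEECH, grain=self.residual_grain)
            resid = rw["residual_sv"].rename("wm"), rs["residual_sv"].rename("speech")
        if 2 in stages:
            x, y = (v.loc[sorted(v.index)] for v in resid)
            r2 = float(np.corrcoef(x, y)[0, 1])
            out[2] = correlation_bf(r2, len(x), self.prior, label="stage2_residualized")
        if 3 in stages:
            controls = composite_table(covs)
            out[3] = partial_correlation_bf(
                resid[0], resid[1], controls, self.prior, label="stage3_partial"
            )
        if 4 in stages:
            ncs = covs["ncs"].astype(float).loc[means.index]
            composite_sv = (wm + sp) / 2.0
            r = float(np.corrcoef(ncs, composite_sv)[0, 1])
            out[4] = correlation_bf(r, len(means), self.prior, label="stage4_ncs")
        return out

    def fit(self, stages: Sequence[int] = (1, 2, 3)) -> CrossDomainResults:
        """Run the selected stages on all participants and, if any participant
        is flagged non-compliant, also on the flag-excluded subsample."""
        flags = flag_noncompliance(self.sv_table)
        results = self._fit_stages(self.sv_table, stages)
        excluded = None
        if flags.any():
            keep = flags[~flags].index
            sub = SVTable(
                self.sv_table.records[
                    self.sv_table.records["participant_id"].isin(keep)
                ].reset_index(drop=True)
            )
            excluded = self._fit_stages(sub, stages)
        return CrossDomainResults(
            model=self,
            stages=results,
            stages_excluded=excluded,
            flags=flags,
            n_analyzed=len(self.sv_table.participants),
        )
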