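"""Trait composites and covariate residualization."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

from cogedkit import (
    SPEECH,
    WORKING_MEMORY,
    CohortConfig,
    generate_cohort,
    residualize_sv,
    zscore_composite,
)
from cogedkit.composites import WM_CAPACITY_MEASURES, composite_table
from cogedkit.domains import TaskDomain
from cogedkit.errors import DegenerateInputError
from cogedkit.scoring import SVTable


def make_sv_table(sv_long):
    """Expand participant x level SVs into a full 9-cell table per domain."""
    rows = []
    for (pid, domain, level), sv in sv_long.items():
        for base in (2.0, 3.0, 4.0):
            rows.append(
                {
                    "participant_id": pid,
                    "domain": domain,
                    "hard_level": level,
                    "base": base,
                    "first_choice": "easy",
                    "indifference_point": sv * base,
                    "sv": sv,
                }
            )
    return SVTable(pd.DataFrame(rows))


class TestComposites:
    def test_mirrored_pair_sums_to_zero(self):
        scores = pd.DataFrame(
            {"lspan": [10, 30], "ospan": [20, 60], "symspan": [5, 35]},
            index=["a", "b"],
        )
        comp = zscore_composite(scores, WM_CAPACITY_MEASURES)
        assert comp.loc["a"] == pytest.approx(-comp.loc["b"])
        assert comp.sum() == pytest.approx(0.0)

    def test_zero_variance_measure_rejected_by_name(self):
        scores = pd.DataFrame(
            {"lspan": [10, 10, 10], "ospan": [1, 2, 3], "symspan": [4, 5, 6]}
        )
        with pytest.raises(DegenerateInputError, match="lspan"):
            zscore_composite(scores, WM_CAPACITY_MEASURES)

    def test_composite_latent_correlation_matches_grid_oracle(self):
        """Empirical corr(WM composite, WM latent) matches an independent
        numeric-integration oracle for the generator's logistic-rounding
        score model."""
        n = 4000
        profiles, cov = generate_cohort(CohortConfig(n_participants=n, seed=21))
        latent = np.array([p.wm_capacity_latent for p in profiles])
        comp = composite_table(cov)["wm_capacity"].to_numpy()
        r_emp = np.corrcoef(comp, latent)[0, 1]

        # oracle: g(L, E) = round((hi - lo) * expit(0.8 L + 0.6 E)) + lo
        grid = np.linspace(-6, 6, 801)
        w = norm.pdf(grid)
        w /= w.sum()
        L, E = np.meshgrid(grid, grid, indexing="ij")
        W2 = np.outer(w, w)
        stats = []
        for lo, hi in ((0, 42), (0, 75), (0, 42)):
            g = np.round((hi - lo) * expit(0.8 * L + 0.6 * E)) + lo
            mean = (g * W2).sum()
            var = ((g - mean) ** 2 * W2).sum()
            cov_gl = ((g - mean) * L * W2).sum()
            m_of_L = (g * w[None, :]).sum(axis=1)  # E[g | L]
            stats.append((mean, var, cov_gl, m_of_L))
        num = sum(c / np.sqrt(v) for _, v, c, _ in stats)
        var_sum = 3.0
        for j in range(3):
            for k in range(3):
                if j == k:
                    continue
                _, vj, _, mj = stats[j]
                _, vk, _, mk = stats[k]
                cross = ((mj - (mj * w).sum()) * (mk - (mk * w).sum()) * w).sum()
                var_sum += cross / np.sqrt(vj * vk)
        r_oracle = num / np.sqrt(var_sum)
        assert abs(r_emp - r_oracle) < 3 * (1 - r_oracle**2) / np.sqrt(n) + 0.005


class TestResidualization:
    @pytest.fixture()
    def cohort_tables(self):
        rng = np.random.default_rng(5)
        pids = [f"p{i:03d}" for i in range(80)]
        sv_long = {}
        cov = {}
        for pid in pids:
            base_sv = rng.uniform(0.3, 0.9)
            for lvl, shift in zip(WORKING_MEMORY.levels, (0.1, 0.0, -0.1)):
                sv_long[(pid, WORKING_MEMORY.name, lvl)] = base_sv + shift
            cov[pid] = {
                f"d_prime_{lvl}": rng.normal(2.0, 0.5) for lvl in WORKING_MEMORY.levels
            }
            cov[pid].update(
                {f"mean_rt_{lvl}": rng.normal(700, 60) for lvl in WORKING_MEMORY.levels}
            )
        return make_sv_table(sv_long), pd.DataFrame(cov).T

    def test_constant_covariates_reduce_to_level_only_model(self, cohort_tables):
        sv_table, cov = cohort_tables
        const = cov.copy()
        const[:] = 1.0
        res = residualize_sv(sv_table, const, WORKING_MEMORY)
        level_means = sv_table.level_means()
        wm = level_means[level_means["domain"] == WORKING_MEMORY.name]
        grand = wm.groupby("level")["sv"].mean().mean()
        expected = wm.groupby("participant_id")["sv"].mean() - grand
        assert np.allclose(res["residual_sv"], expected.loc[res.index], atol=1e-12)

    def test_perfect_linear_fit_leaves_zero_residuals(self):
        rng = np.random.default_rng(7)
        pids = [f"p{i:03d}" for i in range(40)]
        cov = {}
        sv_long = {}
        for pid in pids:
            cov[pid] = {}
            for lvl in WORKING_MEMORY.levels:
                d = rng.normal(2.0, 0.5)
                cov[pid][f"d_prime_{lvl}"] = d
                cov[pid][f"mean_rt_{lvl}"] = 700.0
                sv_long[(pid, WORKING_MEMORY.name, lvl)] = 0.2 + 0.1 * d
        res = residualize_sv(make_sv_table(sv_long), pd.DataFrame(cov).T, WORKING_MEMORY)
        assert np.allclose(res["residual_sv"], 0.0, atol=1e-10)

    def test_residualization_is_idempotent(self, cohort_tables):
        sv_table, cov = cohort_tables
        # rebuild a cell-grain table whose SVs are the row residuals
        level_means = sv_table.level_means()
        first = residualize_sv(sv_table, cov, WORKING_MEMORY)
        import statsmodels.api as sm

        long = level_means[level_means["domain"] == WORKING_MEMORY.name].copy()
        for cvar in WORKING_MEMORY.performance_covariates:
            long[cvar] = [
                cov.at[pid, f"{cvar}_{lvl}"]
                for pid, lvl in zip(long["participant_id"], long["level"])
            ]
        X = pd.get_dummies(long["level"], prefix="level", drop_first=True, dtype=float)
        X[list(WORKING_MEMORY.performance_covariates)] = long[
            list(WORKING_MEMORY.performance_covariates)
        ]
        X = sm.add_constant(X, has_constant="add")
        rowresid = sm.OLS(long["sv"].to_numpy(float), X).fit().resid
        sv2 = {
            (pid, WORKING_MEMORY.name, lvl): rv
            for pid, lvl, rv in zip(long["participant_id"], long["level"], rowresid)
        }
        second = residualize_sv(make_sv_table(sv2), cov, WORKING_MEMORY)
        assert np.allclose(second["residual_sv"], first["residual_sv"], atol=1e-10)

    def test_orthogonal_covariate_leaves_residuals_unchanged(self, cohort_tables):
        sv_table, cov = cohort_tables
        base = residualize_sv(sv_table, cov, WORKING_MEMORY)

        # construct an extra covariate exactly orthogonal to the design and SVs
        level_means = sv_table.level_means()
        long = level_means[level_means["domain"] == WORKING_MEMORY.name].copy()
        cols = []
        for cvar in WORKING_MEMORY.performance_covariates:
            cols.append(
                [
                    cov.at[pid, f"{cvar}_{lvl}"]
                    for pid, lvl in zip(long["participant_id"], long["level"])
                ]
            )
        dummies = pd.get_dummies(long["level"], drop_first=True, dtype=float)
        A = np.column_stack(
            [np.ones(len(long)), dummies.to_numpy(), *cols, long["sv"].to_numpy()]
        )
        rng = np.random.default_rng(3)
        w = rng.standard_normal(len(long))
        w -= A @ np.linalg.lstsq(A, w, rcond=None)[0]

        extended = TaskDomain(
            name=WORKING_MEMORY.name,
            baseline=WORKING_MEMORY.baseline,
            levels=WORKING_MEMORY.levels,
            performance_covariates=WORKING_MEMORY.performance_covariates + ("extra",),
        )
        cov2 = cov.copy()
        for lvl in extended.levels:
            cov2[f"extra_{lvl}"] = 0.0
        for (pid, lvl), val in zip(
            zip(long["participant_id"], long["level"]), w
        ):
            cov2.at[pid, f"extra_{lvl}"] = val
        augmented = residualize_sv(sv_table, cov2, extended)
        assert np.allclose(
            augmented["residual_sv"], base["residual_sv"], atol=1e-10
        )

    def test_rank_deficient_design_names_collinear_columns(self, cohort_tables):
        sv_table, cov = cohort_tables
        cov2 = cov.copy()
        for lvl in WORKING_MEMORY.levels:
            cov2[f"mean_rt_{lvl}"] = 2.0 * cov2[f"d_prime_{lvl}"]  # exact collinearity
        with pytest.raises(DegenerateInputError, match="mean_rt"):
            residualize_sv(sv_table, cov2, WORKING_MEMORY)

    def test_residuals_center_at_zero(self, cohort_tables):
        sv_table, cov = cohort_tables
        res = residualize_sv(sv_table, cov, WORKING_MEMORY)
        assert res["residual_sv"].mean() == pytest.approx(0.0, abs=1e-12)
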