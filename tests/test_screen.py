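"""The per-pair fits, the BH step-up, and the sequential cascade."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

import epimitm as em
from epimitm.screen import MIN_N

from conftest import PLANTED_COUNT, preprocess_to_residuals


def bh_bruteforce(ps, m):
    """Literal step-up definition: adj_i = min_{j: p_(j) >= p_i's rank} p_(j) m / j."""
    ps = np.asarray(ps, dtype=float)
    order = np.argsort(ps, kind="stable")
    k = len(ps)
    adj = np.empty(k)
    for pos in range(k):
        candidates = [
            ps[order[j]] * m / (j + 1) for j in range(pos, k)
        ]
        adj[order[pos]] = min(1.0, min(candidates))
    return adj


class TestBHAdjust:
    def test_worked_example_all_adjusted_to_largest(self):
        adj = em.bh_adjust([0.01, 0.02, 0.03, 0.04], m=4)
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04], atol=1e-15)

    def test_single_test_is_identity(self):
        assert em.bh_adjust([0.03], m=1)[0] == pytest.approx(0.03)

    def test_family_larger_than_tests_padded_implicitly(self):
        adj = em.bh_adjust([0.0008, 0.0313], m=4)
        assert adj[0] == pytest.approx(0.0032)
        assert np.all(adj >= [0.0008, 0.0313])
        assert adj[0] <= adj[1]

    def test_family_smaller_than_tests_is_an_error(self):
        with pytest.raises(ValueError, match="family size"):
            em.bh_adjust([0.1, 0.2], m=1)

    def test_matches_statsmodels_and_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = int(rng.integers(1, 60))
            ps = rng.uniform(size=k)
            ours = em.bh_adjust(ps, m=k)
            np.testing.assert_allclose(ours, bh_bruteforce(ps, k), atol=1e-12)
            ref = sm.stats.multipletests(ps, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, ref, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_adjusted_at_least_raw_and_capped_at_one(self, ps):
        adj = em.bh_adjust(ps, m=len(ps))
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)


def _covs(cohort, spec):
    return cohort[["sex", "ethnicity", spec.age_column]]


class TestFits:
    def test_count_outcome_slope_recovered_and_matches_statsmodels(self, planted_cohort, planted_residuals):
        cohort, _, truth = planted_cohort
        path = truth.planted_paths[0]
        spec = em.OutcomeSpec(path.outcome, "count")
        res = em.fit_outcome_on_cpg(
            cohort[path.outcome], planted_residuals.values[path.cpg],
            _covs(cohort, spec), "count",
        )
        expected = truth.step2_slope(path)
        assert abs(res.estimate - expected) < 3 * res.se
        # oracle: independent NB maximum-likelihood fit on the same arrays
        X = np.column_stack(
            [
                np.ones(len(cohort)),
                planted_residuals.values[path.cpg],
                _covs(cohort, spec).to_numpy(dtype=float),
            ]
        )
        ref = sm.NegativeBinomial(
            cohort[path.outcome].to_numpy(dtype=float), X
        ).fit(method="newton", tol=1e-10, disp=0)
        assert res.estimate == pytest.approx(ref.params[1], abs=1e-4)

    def test_exposure_cpg_slope_recovered_by_ols(self, planted_cohort, planted_residuals):
        cohort, _, truth = planted_cohort
        path = truth.planted_paths[0]
        res = em.fit_cpg_on_exposure(
            planted_residuals.values[path.cpg], cohort[path.exposure],
            cohort[["sex", "ethnicity"]],
        )
        assert abs(res.estimate - path.a) < 3 * res.se

    def test_total_effect_recovered(self, planted_cohort):
        cohort, _, truth = planted_cohort
        path = truth.planted_paths[0]
        spec = em.OutcomeSpec(path.outcome, "count")
        res = em.fit_outcome_on_exposure(
            cohort[path.outcome], cohort[path.exposure], _covs(cohort, spec), "count"
        )
        assert abs(res.estimate - truth.step4_slope(path)) < 3 * res.se

    def test_constant_cpg_flagged_with_p_one(self, planted_cohort):
        cohort, _, _ = planted_cohort
        const = pd.Series(0.42, index=cohort.index, name="flat")
        spec = em.OutcomeSpec("iq_age7", "continuous")
        res = em.fit_outcome_on_cpg(cohort["iq_age7"], const, _covs(cohort, spec), "continuous")
        assert not res.converged and res.raw_p == 1.0

    def test_noiseless_gaussian_fit_exact(self, planted_cohort, planted_residuals):
        cohort, _, _ = planted_cohort
        cpg = planted_residuals.values.iloc[:, 5]
        y = (2.0 * cpg).rename("iq_age7")
        spec = em.OutcomeSpec("iq_age7", "continuous")
        res = em.fit_outcome_on_cpg(y, cpg, _covs(cohort, spec), "continuous")
        assert res.estimate == pytest.approx(2.0, abs=1e-8)

    def test_collinear_exposure_flagged(self, planted_cohort, planted_residuals):
        cohort, _, _ = planted_cohort
        covs = cohort[["sex", "ethnicity"]].copy()
        covs["dup"] = cohort["pah_log"]  # exposure duplicated as covariate
        res = em.fit_cpg_on_exposure(
            planted_residuals.values.iloc[:, 0], cohort["pah_log"], covs
        )
        assert not res.converged and "rank_deficient" in res.flags

    def test_too_few_complete_cases_flagged(self, planted_cohort):
        cohort, _, _ = planted_cohort
        y = cohort["iq_age7"].copy()
        y.iloc[: len(y) - (MIN_N - 1)] = np.nan
        spec = em.OutcomeSpec("iq_age7", "continuous")
        res = em.fit_outcome_on_cpg(
            y, cohort["pah_log"], _covs(cohort, spec), "continuous"
        )
        assert not res.converged and "insufficient_n" in res.flags

    def test_null_exposure_pvalues_uniform(self):
        """Under the null the exposure-CpG screen's p-values are U(0,1)."""
        rng = np.random.default_rng(12)
        n = 120
        ps = []
        for _ in range(500):
            x = rng.normal(size=n)
            cpg = rng.normal(size=n)
            covs = np.column_stack(
                [rng.integers(0, 2, n), rng.integers(0, 2, n)]
            ).astype(float)
            res = em.fit_cpg_on_exposure(
                pd.Series(cpg, name="cg"), pd.Series(x, name="x"),
                pd.DataFrame(covs, columns=["sex", "ethnicity"]),
            )
            ps.append(res.raw_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCascade:
    def _run(self, cohort, resid, config, fixture, order=None):
        pathways, manifest = fixture
        specs = [em.OutcomeSpec(o.name, o.family) for o in config.outcomes]
        if order is not None:
            specs = [specs[i] for i in order]
        universes = {
            o.name: em.select_universe(
                pathways, em.KeywordProfile(o.name, o.keywords), manifest
            )
            for o in config.outcomes
        }
        return em.run_sequential_screen(
            cohort, resid.values, universes, specs, config.predictors
        )

    def test_planted_triple_selected_exactly(self, planted_cohort, planted_residuals, planted_config, planted_fixture):
        cohort, _, truth = planted_cohort
        casc = self._run(cohort, planted_residuals, planted_config, planted_fixture)
        path = truth.planted_paths[0]
        assert len(casc.triples) == 1
        t = casc.triples[0]
        assert (t.exposure, t.outcome) == (path.exposure, path.outcome)
        assert path.cpg in t.mediators

    def test_outcome_order_has_no_effect(self, planted_cohort, planted_residuals, planted_config, planted_fixture):
        cohort, _, _ = planted_cohort
        a = self._run(cohort, planted_residuals, planted_config, planted_fixture)
        b = self._run(
            cohort, planted_residuals, planted_config, planted_fixture,
            order=[3, 2, 1, 0],
        )
        key = ["outcome", "cpg"]
        pd.testing.assert_frame_equal(
            a.step2.sort_values(key).reset_index(drop=True),
            b.step2.sort_values(key).reset_index(drop=True),
        )
        assert a.triples == b.triples

    def test_outcomes_without_step2_hits_skip_later_steps(self, planted_cohort, planted_residuals, planted_config, planted_fixture):
        cohort, _, truth = planted_cohort
        casc = self._run(cohort, planted_residuals, planted_config, planted_fixture)
        hit_outcome = truth.planted_paths[0].outcome
        quiet = set(casc.counts.loc[casc.counts["n_significant_cpgs"] == 0, "outcome"])
        assert hit_outcome not in quiet
        assert not set(casc.step3["outcome"]) & quiet
        assert not set(casc.step4["outcome"]) & quiet

    def test_step2_family_is_universe_and_adj_at_least_raw(self, planted_cohort, planted_residuals, planted_config, planted_fixture):
        cohort, _, _ = planted_cohort
        casc = self._run(cohort, planted_residuals, planted_config, planted_fixture)
        assert (casc.step2["adj_p"] >= casc.step2["raw_p"] - 1e-12).all()
        assert (casc.step2["adj_p"] <= 1.0).all()
        counts = casc.counts.set_index("outcome")
        for outcome, grp in casc.step2.groupby("outcome"):
            assert len(grp) == counts.loc[outcome, "n_cpgs"]
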