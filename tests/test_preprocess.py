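"""QC, beta/M transforms, cell residualization, trimming, and the split."""

import numpy as np
import pandas as pd
import pytest

import epimitm as em
from epimitm.glm import ols_fit
from epimitm.preprocess import MethylationMatrix

from conftest import cell_frame


def _tiny_matrix(n_cpgs=40):
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(10, n_cpgs)),
        index=[f"S{i}" for i in range(10)],
        columns=[f"cg{i}" for i in range(n_cpgs)],
    )
    chroms = ["1"] * n_cpgs
    chroms[2], chroms[4] = "X", "Y"
    manifest = pd.DataFrame(
        {"chr": chroms, "pos": range(n_cpgs), "gene": ["G"] * n_cpgs},
        index=vals.columns,
    )
    return MethylationMatrix(vals, stage="beta"), manifest


class TestQCFilter:
    def test_low_coverage_sample_and_cpg_dropped_and_sex_chromosomes_removed(self):
        m, manifest = _tiny_matrix()
        m.values.iloc[0, 5:11] = np.nan  # sample S0: 6/40 missing -> below 95%
        m.values.iloc[1:5, 1] = np.nan  # cg1 after S0 drop: 4/9 missing -> <70%
        out, report = em.qc_filter(m, manifest)
        assert "S0" in report.dropped_samples
        assert "cg1" in report.dropped_low_coverage_cpgs
        assert set(report.dropped_sex_cpgs) == {"cg2", "cg4"}
        assert "cg2" not in out.values.columns and "cg4" not in out.values.columns

    def test_clean_autosomal_matrix_passes_unchanged_and_is_idempotent(self):
        m, manifest = _tiny_matrix()
        manifest["chr"] = "5"
        out1, _ = em.qc_filter(m, manifest)
        out2, rep2 = em.qc_filter(out1, manifest)
        pd.testing.assert_frame_equal(out1.values, m.values)
        pd.testing.assert_frame_equal(out2.values, out1.values)
        assert not rep2.dropped_samples

    def test_all_samples_dropped_is_an_error_naming_the_threshold(self):
        m, manifest = _tiny_matrix()
        m.values.iloc[:, :3] = np.nan
        with pytest.raises(ValueError, match="95%"):
            em.qc_filter(m, manifest)


class TestBetaM:
    def test_known_values_and_round_trip(self):
        vals = pd.DataFrame(
            [[0.5, 0.8, 0.2]], index=["S0"], columns=["a", "b", "c"]
        )
        m = em.beta_to_m(MethylationMatrix(vals, stage="beta"))
        assert m.stage == "M"
        assert m.values.loc["S0", "a"] == 0.0
        assert m.values.loc["S0", "b"] == pytest.approx(2.0, abs=1e-12)
        back = em.m_to_beta(m)
        np.testing.assert_allclose(back.values, vals, atol=1e-9)

    def test_boundary_betas_clamped_with_warning(self):
        vals = pd.DataFrame([[0.0, 1.0, 0.4]], index=["S0"], columns=list("abc"))
        with pytest.warns(UserWarning, match="clamped 2"):
            m = em.beta_to_m(MethylationMatrix(vals, stage="beta"))
        assert np.isfinite(m.values.to_numpy()).all()

    def test_wrong_stage_rejected(self):
        vals = pd.DataFrame([[0.1]], index=["S0"], columns=["a"])
        m = em.beta_to_m(MethylationMatrix(vals, stage="beta"))
        with pytest.raises(ValueError, match="stage"):
            em.beta_to_m(m)


class TestResidualizeCells:
    def _cells(self, n, rng):
        c = rng.dirichlet([5, 3, 2], n)
        return pd.DataFrame(c, index=[f"S{i}" for i in range(n)], columns=["a", "b", "c"])

    def test_exact_cell_combination_gives_zero_residuals(self):
        rng = np.random.default_rng(1)
        cells = self._cells(40, rng)
        mvals = cells @ np.array([2.0, -1.0, 0.5])
        m = MethylationMatrix(pd.DataFrame({"cg0": mvals}), stage="M")
        out = em.residualize_cells(m, cells)
        assert out.stage == "M_residual"
        assert np.max(np.abs(out.values.to_numpy())) < 1e-8

    def test_cell_independent_signal_survives_and_matches_ols_oracle(self):
        rng = np.random.default_rng(2)
        cells = self._cells(200, rng)
        signal = rng.normal(0, 1.0, 200)
        m = MethylationMatrix(pd.DataFrame({"cg0": signal}, index=cells.index), stage="M")
        out = em.residualize_cells(m, cells)
        # oracle: residuals from an explicit OLS on the same design
        D = np.column_stack([np.ones(200), cells.to_numpy()[:, :-1]])
        coef, *_ = np.linalg.lstsq(D, signal, rcond=None)
        np.testing.assert_allclose(
            out.values["cg0"].to_numpy(), signal - D @ coef, atol=1e-10
        )
        assert np.var(out.values["cg0"]) > 0.9 * np.var(signal)

    def test_residuals_orthogonal_to_retained_cell_columns(self):
        rng = np.random.default_rng(3)
        cells = self._cells(100, rng)
        m = MethylationMatrix(
            pd.DataFrame(rng.normal(size=(100, 5)), index=cells.index), stage="M"
        )
        out = em.residualize_cells(m, cells)
        resid = out.values.to_numpy()
        for col in cells.columns[:-1]:
            r = np.corrcoef(cells[col], resid.T)[0, 1:]
            assert np.max(np.abs(r)) < 1e-8

    def test_removes_planted_cell_confounding(self):
        """An exposure-CpG association carried only by shared cell composition
        must vanish after residualization."""
        rng = np.random.default_rng(4)
        n = 400
        cells = self._cells(n, rng)
        exposure = 3.0 * cells["a"].to_numpy() + rng.normal(0, 0.1, n)
        mvals = 2.0 * cells["a"].to_numpy() + rng.normal(0, 0.3, n)
        m = MethylationMatrix(pd.DataFrame({"cg0": mvals}, index=cells.index), stage="M")
        out = em.residualize_cells(m, cells)
        X = np.column_stack([np.ones(n), exposure])
        before = ols_fit(X, mvals)
        after = ols_fit(X, out.values["cg0"].to_numpy())
        assert abs(before.params[1]) > 0.3
        assert abs(after.params[1]) < 3 * after.bse[1]

    def test_degenerate_cell_design_fails(self):
        cells = pd.DataFrame(
            {"a": [0.5] * 10, "b": [0.25] * 10, "c": [0.25] * 10},
            index=[f"S{i}" for i in range(10)],
        )
        m = MethylationMatrix(
            pd.DataFrame({"cg0": np.arange(10.0)}, index=cells.index), stage="M"
        )
        with pytest.raises(ValueError, match="rank deficient"):
            em.residualize_cells(m, cells)


class TestTrimOutliers:
    def test_point_beyond_four_sd_removed(self):
        rng = np.random.default_rng(5)
        base = pd.Series(rng.normal(0, 1, 500))
        base.iloc[0] = 4.5 * float(base.std())
        # ensure the planted point really is past 4 SD of the full vector
        kept, removed = em.trim_outliers(base)
        if abs(base.iloc[0] - base.mean()) > 4 * base.std():
            assert 0 in removed
        assert len(kept) + len(removed) == len(base)

    def test_constant_vector_untouched(self):
        kept, removed = em.trim_outliers(pd.Series([3.0] * 20))
        assert removed == [] and len(kept) == 20

    def test_typical_gaussian_sample_loses_almost_nothing(self):
        # matches the study-scale expectation of <2 removals per variable
        rng = np.random.default_rng(6)
        _, removed = em.trim_outliers(pd.Series(rng.normal(size=240)))
        assert len(removed) < 2

    def test_single_pass_not_iterated(self):
        vals = pd.Series([0.0] * 50 + [10.0, 3.9])
        kept, removed_once = em.trim_outliers(vals)
        # only the gross outlier falls outside 4 SD of the full vector; the
        # second point would be removed only by re-computing mean/SD, which
        # the single-pass rule does not do
        assert removed_once == [50]
        _, removed_again = em.trim_outliers(kept)
        assert removed_again == [51]


class TestSplitCohort:
    def test_sizes_follow_round_to_nearest(self):
        ids = [f"S{i}" for i in range(100)]
        d, v = em.split_cohort(ids, 0.70, seed=3)
        assert len(d) == 70 and len(v) == 30

    def test_partition_is_disjoint_exhaustive_and_seeded(self):
        ids = [f"S{i}" for i in range(341)]
        d1, v1 = em.split_cohort(ids, 0.70, seed=9)
        d2, v2 = em.split_cohort(ids, 0.70, seed=9)
        assert d1 == d2 and v1 == v2
        assert set(d1).isdisjoint(v1)
        assert sorted(d1 + v1) == sorted(ids)
        d3, _ = em.split_cohort(ids, 0.70, seed=10)
        assert d3 != d1

    def test_explicit_discovery_count_override(self):
        ids = [f"S{i}" for i in range(341)]
        d, v = em.split_cohort(ids, 0.70, seed=0, n_discovery=240)
        assert (len(d), len(v)) == (240, 101)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            em.split_cohort(["only"], 0.5, seed=0)
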