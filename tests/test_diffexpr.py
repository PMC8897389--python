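import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from gammatc import diffexpr as dx
from gammatc.errors import DataError, NormalizationError
from gammatc.simulate import SimConfig, generate_counts

from conftest import make_count_matrix

STUDY_TIMES = [0.0, 0.0, 1.0, 1.0, 2.5, 4.0, 4.0, 6.0]


def study_matrix(values):
    return make_count_matrix(values, times=STUDY_TIMES)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = make_count_matrix(np.tile([[10.0], [20.0], [5.0]], (1, 4)))
        np.testing.assert_allclose(dx.size_factors(cm), 1.0)

    def test_doubled_column_doubles_factor_ratio(self):
        col = np.array([10.0, 20.0, 5.0, 100.0])
        cm = make_count_matrix(np.column_stack([col, 2 * col]))
        f = dx.size_factors(cm)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0)

    def test_matches_independent_median_of_ratios(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 1000, (200, 5))
        cm = make_count_matrix(x)
        f = dx.size_factors(cm).to_numpy()
        # independent elementwise evaluation of the estimator
        ref = np.array([np.prod(row) ** (1 / 5) for row in x])
        expect = [np.median([x[g, j] / ref[g] for g in range(200)])
                  for j in range(5)]
        np.testing.assert_allclose(f, expect, rtol=1e-12)

    def test_all_zero_rows_raise_normalization_error(self):
        x = np.array([[0.0, 5.0], [3.0, 0.0], [0.0, 0.0]])
        with pytest.raises(NormalizationError):
            dx.size_factors(make_count_matrix(x))

    def test_scaling_one_sample_scales_its_factor_and_not_lfc(self):
        cm, _ = generate_counts(SimConfig(seed=8, n_genes=150))
        f0 = dx.size_factors(cm)
        d0 = dx.estimate_dispersions(cm, f0)
        t0 = dx.wald_test(cm, f0, d0, 4.0)
        scaled = cm.values.copy()
        scaled.iloc[:, 2] *= 3.0
        cm2 = make_count_matrix(scaled.to_numpy(),
                                genes=cm.gene_ids,
                                times=list(cm.samples["time_h"]))
        f1 = dx.size_factors(cm2)
        # the geometric-mean reference absorbs c**(1/n), so the *relative*
        # factor of the scaled sample grows by exactly c
        rel0 = f0.iloc[2] / f0.iloc[0]
        rel1 = f1.iloc[2] / f1.iloc[0]
        assert rel1 / rel0 == pytest.approx(3.0, rel=1e-9)
        # all normalized counts rescale by the same c**(1/n); only the +0.5
        # moderation offset keeps the fold changes from being bit-identical
        t1 = dx.wald_test(cm2, f1, d0, 4.0)
        np.testing.assert_allclose(t1["log2fc"], t0["log2fc"], atol=0.05)


class TestDispersions:
    def test_zero_variance_replicates_hit_the_floor(self):
        # every condition constant -> moment estimates 0 -> trend at the floor
        x = np.tile(np.linspace(10.0, 500.0, 20)[:, None],
                    (1, len(STUDY_TIMES)))
        cm = study_matrix(x)
        d = dx.estimate_dispersions(cm, dx.size_factors(cm))
        assert (d < 1e-6).all()

    def test_poisson_data_yields_near_zero_dispersion(self):
        cfg = SimConfig(seed=9, n_genes=1000, n_de_per_pattern=0,
                        dispersion=0.0, baseline_log_sd=0.5)
        cm, _ = generate_counts(cfg)
        d = dx.estimate_dispersions(cm, dx.size_factors(cm))
        sel = d[cm.values.mean(axis=1) >= 50]
        assert sel.median() < 0.05

    def test_nb_dispersion_recovered_within_band(self):
        cfg = SimConfig(seed=11, n_genes=200, n_de_per_pattern=0,
                        dispersion=0.2)
        cm, _ = generate_counts(cfg)
        d = dx.estimate_dispersions(cm, dx.size_factors(cm))
        assert 0.1 <= d.median() <= 0.4


class TestWaldTest:
    def test_identical_groups_are_null(self):
        x = np.tile([[50.0], [200.0], [7.0]], (1, len(STUDY_TIMES)))
        cm = study_matrix(x)
        f = dx.size_factors(cm)
        res = dx.wald_test(cm, f, pd.Series(0.05, index=cm.gene_ids), 1.0)
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p"], 1.0, atol=1e-9)

    def test_all_zero_gene_reports_p_one(self):
        x = np.vstack([np.zeros(len(STUDY_TIMES)),
                       np.full(len(STUDY_TIMES), 60.0)])
        cm = study_matrix(x)
        res = dx.wald_test(cm, dx.size_factors(cm),
                           pd.Series(0.05, index=cm.gene_ids), 6.0)
        assert res.loc[0, "log2fc"] == 0.0 and res.loc[0, "p"] == 1.0

    def test_planted_fourfold_gene_is_recovered(self):
        rng = np.random.default_rng(12)
        n = 300
        x = rng.poisson(100, (n, len(STUDY_TIMES))).astype(float)
        planted = rng.poisson(400, 3)  # 4-fold up at the 4 h duplicates
        x[0, [5, 6]] = planted[:2]
        cm = study_matrix(x)
        f = dx.size_factors(cm)
        d = dx.estimate_dispersions(cm, f)
        res = dx.wald_test(cm, f, d, 4.0)
        assert 1.5 <= res.loc[0, "log2fc"] <= 2.5
        assert res.loc[0, "p"] < 0.01

    def test_null_simulation_type_one_error_calibrated(self):
        cfg = SimConfig(seed=5, n_genes=2000, n_de_per_pattern=0,
                        dispersion=0.1)
        cm, _ = generate_counts(cfg)
        res = dx.run_de(cm)
        rate = float((res.table["p"] < 0.05).mean())
        assert 0.03 <= rate <= 0.07


class TestBenjaminiHochberg:
    def test_single_value_unchanged(self):
        assert dx.adjust_bh([0.3])[0] == pytest.approx(0.3)

    def test_hand_evaluated_step_up(self):
        np.testing.assert_allclose(dx.adjust_bh([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0),
                    min_size=1, max_size=200))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_matches_statsmodels_reference(self, pvals):
        ours = dx.adjust_bh(pvals)
        _, ref, _, _ = multipletests(pvals, method="fdr_bh")
        np.testing.assert_allclose(ours, ref, atol=1e-12)
        assert (ours >= np.asarray(pvals) - 1e-15).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=100)
        perm = rng.permutation(100)
        np.testing.assert_allclose(dx.adjust_bh(p)[perm],
                                   dx.adjust_bh(p[perm]), atol=1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(DataError):
            dx.adjust_bh([0.5, 1.5])


class TestCallDegs:
    @pytest.mark.parametrize("lfc,padj,expected", [
        (1.2, 0.04, True),   # passes both thresholds
        (0.9, 0.04, False),  # below fold threshold
        (1.2, 0.06, False),  # above adjusted-p threshold
        (-1.5, 0.01, True),  # downregulation counts too
    ])
    def test_thresholds_are_strict(self, lfc, padj, expected):
        table = pd.DataFrame({
            "gene_id": ["g"] * 4, "timepoint": [1.0, 2.5, 4.0, 6.0],
            "log2fc": [lfc, 0, 0, 0], "se": 0.2,
            "p": [padj / 2] * 4, "padj": [padj, 1, 1, 1],
        })
        table["is_de"] = ((table["log2fc"].abs() > 1.0)
                          & (table["padj"] < 0.05))
        res = dx.DEResult(table=table, size_factors=pd.Series(dtype=float),
                          dispersions=pd.Series(dtype=float),
                          thresholds=dx.DEThresholds())
        degs = dx.call_degs(res)
        assert ("g" in degs) is expected
        if expected:
            assert degs["g"]["times"] == [1.0]
            assert degs["g"]["direction"][1.0] == (1 if lfc > 0 else -1)

    def test_non_coding_genes_are_filtered(self, study_tables):
        tab = study_tables["de_table"].copy()
        th = dx.DEThresholds()
        tab["is_de"] = (tab["log2fc"].abs() > th.lfc_min) & (tab["padj"] < th.alpha)
        res = dx.DEResult(table=tab, size_factors=pd.Series(dtype=float),
                          dispersions=pd.Series(dtype=float), thresholds=th)
        unfiltered = dx.call_degs(res)
        filtered = dx.call_degs(res, biotype=study_tables["biotype"])
        dropped = set(unfiltered) - set(filtered)
        assert dropped and all(study_tables["biotype"][g] != "protein_coding"
                               for g in dropped)

    def test_planted_truth_recovery_with_few_false_positives(self):
        cfg = SimConfig(seed=13, n_genes=530, n_de_per_pattern=4,
                        baseline_log_mean=float(np.log(200.0)),
                        baseline_log_sd=0.2, dispersion=0.05)
        cm, truth = generate_counts(cfg)
        res = dx.run_de(cm)
        degs = dx.call_degs(res, biotype=cm.biotype)
        planted = set(truth["gene_id"])
        assert len(planted & set(degs)) >= 0.9 * len(planted)
        false_pos = set(degs) - planted
        assert len(false_pos) <= 0.01 * (cfg.n_genes - len(planted)) + 3
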