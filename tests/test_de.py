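"""Expression core: filtering, TMM, dispersion, NB-GLM LRT, DEG calls."""

import numpy as np
import pandas as pd
import pytest

from cytoresponse import de
from cytoresponse.de import CountMatrix


def make_cm(arr, genes=None, samples=None, lib=None):
    arr = np.asarray(arr)
    if genes is None:
        genes = [f"G{i}" for i in range(arr.shape[0])]
    if samples is None:
        samples = [f"S{j}" for j in range(arr.shape[1])]
    samples = list(samples)
    cm = CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))
    if lib is not None:
        cm = CountMatrix(cm.counts, pd.Series(lib, index=samples))
    return cm


def design_two_group(n_per=3, treatment="IL1B", time="8h"):
    rows = []
    for i in range(n_per):
        rows.append({"sample_id": f"CTL_{i}", "treatment": "CTL",
                     "time": time, "cell_line": f"L{i}"})
    for i in range(n_per):
        rows.append({"sample_id": f"{treatment}_{i}", "treatment": treatment,
                     "time": time, "cell_line": f"L{i}"})
    return pd.DataFrame(rows)


class TestDetectExpressed:
    def test_boundary_is_strict(self):
        # cpm exactly 0.25 in every sample -> not detected
        lib = [4_000_000] * 4
        cm = make_cm([[1, 1, 1, 1], [2, 2, 2, 2]], lib=lib)
        kept = de.detect_expressed(cm, min_cpm=0.25, min_sample_fraction=0.25)
        assert not kept.iloc[0] and kept.iloc[1]

    def test_all_zero_gene_excluded(self):
        cm = make_cm([[0, 0, 0, 0], [100, 100, 100, 100]])
        assert de.detect_expressed(cm).tolist() == [False, True]

    def test_ceiling_rule_at_fraction_boundary(self):
        # 8 samples, detectable in exactly 2 = ceil(0.25 * 8) -> kept
        lib = [1_000_000] * 8
        row = [10, 10, 0, 0, 0, 0, 0, 0]
        cm = make_cm([row, [10] * 8], lib=lib)
        kept = de.detect_expressed(cm, min_sample_fraction=0.25)
        assert kept.iloc[0]
        # detectable in only 1 sample -> dropped
        cm2 = make_cm([[10, 0, 0, 0, 0, 0, 0, 0]], lib=lib)
        assert not de.detect_expressed(cm2, min_sample_fraction=0.25).iloc[0]

    def test_zero_library_size_names_sample(self):
        cm = make_cm([[1, 1], [2, 0]], lib=[100, 100])
        cm.counts["S1"] = 0
        bad = CountMatrix(cm.counts)
        with pytest.raises(ValueError, match="S1"):
            de.detect_expressed(bad)


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(100, 500)
        cm = make_cm(np.column_stack([col, col, col]))
        assert np.allclose(de.tmm_factors(cm), 1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(200, 2000)
        cm = make_cm(np.column_stack([base, 2 * base, base]))
        f = de.tmm_factors(cm)
        assert 0.97 <= f.iloc[1] / f.iloc[0] <= 1.03

    def test_composition_bias_compensated(self):
        # 30% of genes 4-fold up in one sample: unchanged genes' normalized
        # cpm ratio must return to ~1
        rng = np.random.default_rng(2)
        g = 2000
        base = rng.poisson(rng.uniform(50, 500, g))
        shifted = base.copy()
        up = rng.choice(g, size=int(0.3 * g), replace=False)
        shifted[up] = base[up] * 4
        cm = make_cm(np.column_stack([base, shifted, base]))
        f = de.tmm_factors(cm)
        eff = cm.library_sizes.to_numpy() * f.to_numpy()
        unchanged = np.setdiff1d(np.arange(g), up)
        cpm0 = base[unchanged] / eff[0]
        cpm1 = shifted[unchanged] / eff[1]
        ratio = np.median(cpm1 / np.maximum(cpm0, 1e-12))
        assert 0.95 <= ratio <= 1.05

    def test_factors_multiply_to_one_and_order_invariant(self):
        rng = np.random.default_rng(3)
        arr = rng.poisson(rng.uniform(10, 400, (300, 4)))
        cm = make_cm(arr)
        f = de.tmm_factors(cm)
        assert np.prod(f) == pytest.approx(1.0)
        perm = rng.permutation(300)
        f2 = de.tmm_factors(make_cm(arr[perm]))
        assert np.allclose(f, f2)

    def test_no_shared_nonzero_genes_errors(self):
        cm = make_cm([[5, 0], [0, 7]], lib=[1000, 1000])
        with pytest.raises(ValueError, match="shares no nonzero"):
            de.tmm_factors(cm)


class TestDispersion:
    def test_poisson_data_fits_near_zero(self):
        rng = np.random.default_rng(4)
        g, n = 1200, 12
        mu = rng.uniform(50, 800, g)
        y = rng.poisson(mu[:, None], size=(g, n))
        cm = make_cm(y)
        design = pd.DataFrame({
            "sample_id": cm.sample_ids, "treatment": ["CTL"] * 6 + ["T"] * 6,
            "time": "8h", "cell_line": "L0",
        })
        fit = de.estimate_trended_dispersion(cm, design,
                                             full_terms=("treatment",))
        assert np.median(fit.phi) < 0.01

    def test_constant_dispersion_recovered(self, two_group_null):
        cm, design, truth = two_group_null
        fit = de.estimate_trended_dispersion(cm, design,
                                             full_terms=("treatment",))
        trend = fit.bins["phi_smooth"]
        assert trend.between(0.08, 0.12).all()

    def test_equal_counts_single_group_prefers_no_overdispersion(self):
        from cytoresponse import glm

        y = np.full((1, 8), 40.0)
        X = np.ones((8, 1))
        offset = np.zeros(8)
        phi = glm.maximize_cr_common_dispersion(y, X, offset)
        assert phi < 1e-4


class TestNBLRT:
    def test_identical_groups_give_null_result(self):
        arr = np.tile([[40, 50, 60, 40, 50, 60]], (5, 1))
        cm = make_cm(arr, samples=[f"CTL_{i}" for i in range(3)]
                     + [f"IL1B_{i}" for i in range(3)])
        res = de.fit_nb_lrt(cm, design_two_group(), dispersions=0.1,
                            full_terms=("treatment",), reduced_terms=())
        assert np.allclose(res.table["log2fc"], 0.0, atol=1e-6)
        assert np.all(res.table["lr_stat"] < 1e-8)
        assert np.all(res.table["p"] > 0.999)

    def test_matches_statsmodels_single_gene(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        y = rng.poisson([30, 45, 38, 120, 100, 130])
        cm = make_cm(y[None, :], samples=[f"CTL_{i}" for i in range(3)]
                     + [f"IL1B_{i}" for i in range(3)])
        res = de.fit_nb_lrt(cm, design_two_group(), dispersions=0.05,
                            full_terms=("treatment",), reduced_terms=(),
                            norm_factors=pd.Series(1.0, index=cm.sample_ids))
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        offset = np.log(cm.library_sizes.to_numpy(float))
        fam = sm.families.NegativeBinomial(alpha=0.05)
        full = sm.GLM(y, X, family=fam, offset=offset).fit()
        red = sm.GLM(y, X[:, :1], family=fam, offset=offset).fit()
        assert res.table["log2fc"].iloc[0] == pytest.approx(
            full.params[1] / np.log(2), abs=1e-4
        )
        assert res.table["lr_stat"].iloc[0] == pytest.approx(
            2 * (full.llf - red.llf), abs=1e-4
        )

    def test_null_type_one_error_calibrated(self, two_group_null):
        cm, design, _ = two_group_null
        res = de.fit_nb_lrt(cm, design, dispersions=0.1,
                            full_terms=("treatment",), reduced_terms=())
        p = res.table["p"].dropna()
        assert 0.035 <= np.mean(p < 0.05) <= 0.065

    def test_planted_effect_recovered(self, planted_two_group):
        cm, design, truth = planted_two_group
        res = de.fit_nb_lrt(cm, design, dispersions=None,
                            full_terms=("treatment",), reduced_terms=())
        up = truth.index[truth["class"] == "shared_up"]
        assert res.table.loc[up, "log2fc"].mean() == pytest.approx(2.0,
                                                                   abs=0.15)

    def test_lr_stats_nonnegative(self, planted_two_group):
        cm, design, _ = planted_two_group
        res = de.fit_nb_lrt(cm, design, dispersions=0.1,
                            full_terms=("treatment",), reduced_terms=())
        assert (res.table["lr_stat"] >= 0).all()


class TestDEGCalls:
    @staticmethod
    def table(log2fc, p, q):
        return pd.DataFrame({
            "gene_id": [f"G{i}" for i in range(len(log2fc))],
            "log2fc": log2fc, "p": p, "q": q,
        }).set_index("gene_id", drop=False)

    def test_standard_thresholds(self):
        t = self.table([np.log2(2.5), np.log2(2.5), np.log2(0.4)],
                       [1e-4, 1e-4, 1e-4], [0.09, 0.10, 0.05])
        calls = de.call_degs_table(t)
        assert calls.loc["G0", "direction"] == "up"
        assert "G1" not in calls.index        # q == 0.10 exactly: excluded
        assert calls.loc["G2", "direction"] == "down"

    def test_fc_boundary_strict(self):
        t = self.table([1.0, 1.0001], [1e-4, 1e-4], [0.01, 0.01])
        calls = de.call_degs_table(t)       # FC == 2.0 exactly excluded
        assert "G0" not in calls.index and "G1" in calls.index

    def test_heatmap_preset(self):
        t = self.table([np.log2(1.6)], [0.04], [0.5])
        assert de.call_degs_table(t, preset="heatmap").loc["G0",
                                                           "direction"] == "up"
        assert len(de.call_degs_table(t)) == 0

    def test_threshold_monotone(self, planted_two_group):
        cm, design, _ = planted_two_group
        res = de.fit_nb_lrt(cm, design, dispersions=0.1,
                            full_terms=("treatment",), reduced_terms=())
        loose = set(res.call_degs(fdr_max=0.10).index)
        tight = set(res.call_degs(fdr_max=0.01).index)
        assert tight <= loose


class TestInteraction:
    def test_constant_fold_change_not_flagged(self):
        rng = np.random.default_rng(12)
        rows, samples = [], []
        mu = {"CTL": 100, "T": 400}
        arr = []
        for tm in ("8h", "24h"):
            for trt in ("CTL", "T"):
                for i in range(3):
                    samples.append(f"{trt}_{tm}_{i}")
                    rows.append({"sample_id": samples[-1], "treatment": trt,
                                 "time": tm, "cell_line": f"L{i}"})
                    arr.append(rng.poisson(mu[trt], 400))
        cm = make_cm(np.array(arr).T, samples=samples)
        res = de.interaction_test(cm, pd.DataFrame(rows), 0.05, "T")
        p = res.table["p"].dropna()
        # same FC at both times: interaction p should be null-uniform
        assert np.mean(p < 0.05) < 0.12

    def test_timeflip_flagged_and_classified(self):
        # 200 sign-flipping genes over an 800-gene null background
        rng = np.random.default_rng(13)
        n_flip, n_null = 200, 800
        rows, samples, arr = [], [], []
        for tm, fold in (("8h", 4.0), ("24h", 0.25)):
            for trt in ("CTL", "T"):
                for i in range(3):
                    samples.append(f"{trt}_{tm}_{i}")
                    rows.append({"sample_id": samples[-1], "treatment": trt,
                                 "time": tm, "cell_line": f"L{i}"})
                    mu = np.full(n_flip + n_null, 100.0)
                    if trt == "T":
                        mu[:n_flip] *= fold
                    arr.append(rng.poisson(rng.gamma(1 / 0.05, 0.05 * mu)))
        cm = make_cm(np.array(arr).T, samples=samples)
        res = de.interaction_test(cm, pd.DataFrame(rows), 0.05, "T")
        flip = res.table.iloc[:n_flip]
        assert (flip["q"] < 0.10).mean() >= 0.9
        flagged = flip[flip["q"] < 0.10]
        assert (flagged["pattern"] == "up_down").mean() > 0.95

    def test_missing_time_point_errors(self):
        design = design_two_group()
        cm = make_cm(np.full((3, 6), 50), samples=design["sample_id"])
        with pytest.raises(ValueError, match="time"):
            de.interaction_test(cm, design, 0.1, "IL1B")


class TestGroupTTest:
    def expr(self, values):
        cols = [f"CTL_{i}" for i in range(3)] + [f"T_{i}" for i in range(3)]
        return (pd.DataFrame(np.asarray(values)[None, :], index=["G0"],
                             columns=cols),
                pd.DataFrame({
                    "sample_id": cols, "treatment": ["CTL"] * 3 + ["T"] * 3,
                    "time": "8h", "cell_line": ["A", "B", "C"] * 2,
                }))

    def test_closed_form_example(self):
        # paired differences [1, 2, 3]: t = 2*sqrt(3) = 3.464, p ~ 0.0742
        e, d = self.expr([10, 20, 30, 11, 22, 33])
        res = de.group_ttest(e, d, "T", "8h")
        assert res["t"].iloc[0] == pytest.approx(2 * np.sqrt(3), abs=1e-6)
        assert res["p"].iloc[0] == pytest.approx(0.0742, abs=5e-4)

    def test_identical_pairs(self):
        e, d = self.expr([10, 20, 30, 10, 20, 30])
        res = de.group_ttest(e, d, "T", "8h")
        assert res["t"].iloc[0] == 0 and res["p"].iloc[0] == 1

    def test_zero_variance_nonzero_shift(self):
        e, d = self.expr([10, 20, 30, 12, 22, 32])
        res = de.group_ttest(e, d, "T", "8h")
        assert res["p"].iloc[0] == np.finfo(float).tiny

    def test_insufficient_pairs_warns(self):
        e, d = self.expr([10, 20, 30, 12, 22, 32])
        d = d[d["cell_line"] != "B"]
        d = d[~((d["treatment"] == "T") & (d["cell_line"] == "C"))]
        with pytest.warns(UserWarning):
            res = de.group_ttest(e[d["sample_id"]], d, "T", "8h")
        assert np.isnan(res["p"].iloc[0])


class TestVarianceComponents:
    def design(self):
        rows = []
        for trt in ("CTL", "T"):
            for tm in ("8h", "24h"):
                for line in ("A", "B", "C"):
                    rows.append({"sample_id": f"{trt}_{tm}_{line}",
                                 "treatment": trt, "time": tm,
                                 "cell_line": line})
        return pd.DataFrame(rows)

    def test_pure_cell_line_signal(self):
        d = self.design()
        offsets = {"A": 1.0, "B": 2.0, "C": 5.0}
        e = pd.DataFrame(
            [[offsets[c] for c in d["cell_line"]]], index=["G0"],
            columns=d["sample_id"],
        )
        table, _ = de.variance_components(e, d)
        assert table.loc["G0", "cell_line"] == pytest.approx(1.0)
        assert table.loc["G0", "treatment"] == pytest.approx(0.0, abs=1e-12)

    def test_null_mean_r2_matches_expectation(self):
        d = self.design()
        rng = np.random.default_rng(21)
        e = pd.DataFrame(rng.normal(size=(2000, len(d))),
                         columns=d["sample_id"])
        table, _ = de.variance_components(e, d)
        n = len(d)
        for f, levels in (("treatment", 2), ("time", 2), ("cell_line", 3)):
            expect = (levels - 1) / (n - 1)
            assert table[f].mean() == pytest.approx(expect, abs=0.02)

    def test_constant_rows_get_zero(self):
        d = self.design()
        e = pd.DataFrame(np.full((1, len(d)), 3.0), columns=d["sample_id"])
        table, _ = de.variance_components(e, d)
        assert (table.iloc[0] == 0).all()

    def test_dominant_cell_line_ranks_first(self, full_design_run):
        cm, design, _ = full_design_run
        from cytoresponse.patterns import expression_for_patterns

        expr = expression_for_patterns(cm)
        _, summary = de.variance_components(expr, design)
        assert summary["mean_r2"].idxmax() == "cell_line"
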