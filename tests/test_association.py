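import numpy as np
import pandas as pd
import pytest

from airscape import association as assoc

from conftest import nb_counts


def toy_cells(lumen_of):
    ids = list(lumen_of)
    return pd.DataFrame(
        {
            "cell_id": ids,
            "x_centroid": 0.0,
            "y_centroid": 0.0,
            "sample_id": "S",
            "cell_type": ["A", "A", "B", "B", "B", "A"][: len(ids)],
        }
    )


class TestAggregation:
    def test_gene_counts_sum_over_member_cells(self):
        lumen_of = {"c0": 1, "c1": 1, "c2": 1}
        cells = toy_cells(lumen_of)
        ids = pd.Series(lumen_of, name="lumen_id").rename_axis("cell_id")
        t = pd.Series({1: 0.5})
        genes = pd.DataFrame({"g": [1, 2, 3]}, index=["c0", "c1", "c2"])
        mat = assoc.aggregate_by_lumen(cells, ids, t, mode="genes", gene_counts=genes)
        assert mat.counts.loc["g", 1] == 6

    def test_celltype_counts_sum_to_offset(self):
        lumen_of = {"c0": 1, "c1": 1, "c2": 2, "c3": 2, "c4": 2}
        cells = toy_cells(lumen_of)
        ids = pd.Series(lumen_of, name="lumen_id").rename_axis("cell_id")
        t = pd.Series({1: 0.2, 2: 0.9})
        mat = assoc.aggregate_by_lumen(cells, ids, t, mode="celltypes")
        assert np.allclose(mat.counts.sum(axis=0).to_numpy(), mat.offsets.to_numpy())

    def test_matches_brute_force_groupby(self):
        rng = np.random.default_rng(0)
        n_cells, n_lumens = 300, 12
        ids = pd.Series(
            rng.integers(1, n_lumens + 1, n_cells),
            index=pd.Index([f"c{i}" for i in range(n_cells)], name="cell_id"),
            name="lumen_id",
        )
        cells = pd.DataFrame(
            {
                "cell_id": ids.index,
                "x_centroid": 0.0,
                "y_centroid": 0.0,
                "sample_id": "S",
                "cell_type": rng.choice(["A", "B", "C"], n_cells),
            }
        )
        t = pd.Series(rng.uniform(0, 1, n_lumens), index=range(1, n_lumens + 1))
        genes = pd.DataFrame(
            rng.integers(0, 5, size=(n_cells, 4)), index=ids.index, columns=list("wxyz")
        )
        mat = assoc.aggregate_by_lumen(cells, ids, t, mode="genes", gene_counts=genes)
        manual = genes.groupby(ids).sum().T
        pd.testing.assert_frame_equal(
            mat.counts[sorted(mat.counts.columns)].astype(int),
            manual[sorted(manual.columns)].astype(int),
            check_names=False,
        )

    def test_inclusion_filter_uses_presence_fraction(self):
        counts = pd.DataFrame(
            [[1] * 20, [1] * 2 + [0] * 18], index=["common", "rare"], columns=range(20)
        )
        mat = assoc.LumenFeatureMatrix(
            counts.astype(float),
            pd.Series(10.0, index=range(20)),
            pd.Series(np.linspace(0, 1, 20), index=range(20)),
            "celltypes",
        )
        assert mat.included_features() == ["common"]


class TestGamFit:
    def test_constant_rate_feature_is_flat_and_non_significant(self):
        rng = np.random.default_rng(1)
        n = 200
        t = np.sort(rng.uniform(0, 1, n))
        N = rng.integers(20, 200, n).astype(float)
        y = np.round(N * 0.4)  # exactly proportional to the offset
        fit = assoc.fit_association_gam(y, t, N)
        assert fit.converged
        assert fit.pvalue > 0.01
        assert np.ptp(fit.fitted) / fit.fitted.mean() < 0.05

    def test_offset_rescaling_leaves_rate_curve_unchanged(self):
        rng = np.random.default_rng(2)
        n = 150
        t = np.sort(rng.uniform(0, 1, n))
        N = rng.integers(20, 80, n).astype(float)
        y = nb_counts(rng, N * 0.5 * np.exp(t - 0.5))
        f1 = assoc.fit_association_gam(y, t, N)
        f2 = assoc.fit_association_gam(y * 3, t, N * 3)
        # invariance is exact under a fixed dispersion; re-estimating the
        # dispersion on the rescaled counts moves the curve only slightly
        assert np.allclose(f1.fitted, f2.fitted, rtol=1e-2)

    def test_all_zero_feature_flagged_not_fit(self):
        fit = assoc.fit_association_gam(np.zeros(50), np.linspace(0, 1, 50), np.full(50, 10.0))
        assert not fit.converged

    def test_planted_monotone_gene_detected(self):
        rng = np.random.default_rng(3)
        n = 300
        t = np.sort(rng.uniform(0, 1, n))
        N = rng.integers(30, 120, n).astype(float)
        y = nb_counts(rng, N * 0.3 * np.exp(np.log(3.0) * (t - 0.5)))
        fit = assoc.fit_association_gam(y, t, N)
        assert fit.pvalue < 1e-6


class TestCellTypeGam:
    def make_design(self, seed, n=250):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 1, n))
        N = rng.integers(30, 120, n).astype(float)
        props = pd.DataFrame(
            {
                "p_conf": np.clip(0.3 + 0.25 * np.sin(4 * t) + rng.normal(0, 0.05, n), 0.01, 0.95),
                "p_other": np.clip(rng.normal(0.2, 0.05, n), 0.01, 0.95),
            }
        )
        return rng, t, N, props

    def test_covariate_driven_gene_not_attributed_to_pseudotime(self):
        rng, t, N, props = self.make_design(4)
        mu = N * 0.3 * np.exp(1.2 * (props["p_conf"] - 0.3))
        y = nb_counts(rng, mu)
        fit = assoc.fit_celltype_gam(y, t, props, N)
        assert fit.converged
        assert fit.pvalue > 0.001  # the composition smooth absorbs the signal

    def test_pseudotime_signal_survives_covariate_control(self):
        rng, t, N, props = self.make_design(5)
        mu = N * 0.3 * np.exp(np.log(3.0) * (t - 0.5))
        y = nb_counts(rng, mu)
        fit = assoc.fit_celltype_gam(y, t, props, N)
        assert fit.pvalue < 1e-4

    def test_all_zero_gene_refused(self):
        _, t, N, props = self.make_design(6)
        fit = assoc.fit_celltype_gam(np.zeros_like(t), t, props, N)
        assert not fit.converged

    def test_constant_covariate_dropped_with_note(self):
        rng, t, N, props = self.make_design(7)
        props["p_const"] = 0.25
        y = nb_counts(rng, N * 0.3)
        fit = assoc.fit_celltype_gam(y, t, props, N)
        assert any("p_const" in n for n in fit.notes)


class TestPeakOrdering:
    def test_increasing_curve_peaks_in_last_window(self):
        t = np.linspace(0, 1, 100)
        peak = assoc.peak_time(t**2, t, window=10)
        assert peak > t[-15]

    def test_planted_peak_recovered_within_half_window(self):
        t = np.linspace(0, 1, 200)
        curve = np.exp(-((t - 0.4) ** 2) / 0.02)
        window = 20
        peak = assoc.peak_time(curve, t, window)
        half_width = (t[window] - t[0]) / 2
        assert abs(peak - 0.4) <= half_width + 1e-9

    def test_identical_curves_tie_break_by_feature_id(self):
        t = np.linspace(0, 1, 60)
        curves = pd.DataFrame([t, t], index=["b_gene", "a_gene"])
        out = assoc.peak_order(curves, t, window=10)
        assert list(out.feature) == ["a_gene", "b_gene"]

    def test_window_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            assoc.peak_time(np.ones(5), np.linspace(0, 1, 5), window=10)

    def test_ordering_invariant_to_monotone_time_rescaling(self):
        rng = np.random.default_rng(8)
        t = np.sort(rng.uniform(0, 1, 150))
        curves = pd.DataFrame(
            {i: np.exp(-((t - c) ** 2) / 0.01) for i, c in enumerate([0.2, 0.5, 0.8])}
        ).T
        o1 = assoc.peak_order(curves, t, window=15)
        o2 = assoc.peak_order(curves, t**3, window=15)
        assert list(o1.feature) == list(o2.feature)


class TestPatternClustering:
    def test_two_planted_families_separate(self):
        rng = np.random.default_rng(9)
        t = np.linspace(0, 1, 80)
        fam_a = [np.sin(2 * np.pi * t) + rng.normal(0, 0.05, 80) for _ in range(15)]
        fam_b = [t**2 + rng.normal(0, 0.05, 80) for _ in range(15)]
        curves = pd.DataFrame(fam_a + fam_b)
        out = assoc.cluster_patterns(curves, k=2)
        from sklearn.metrics import adjusted_rand_score

        truth = [0] * 15 + [1] * 15
        assert adjusted_rand_score(truth, out.pattern_cluster) >= 0.9

    def test_constant_curve_is_neither_unimodal_nor_bimodal(self):
        curves = pd.DataFrame([np.ones(50), np.sin(np.linspace(0, np.pi, 50))])
        out = assoc.cluster_patterns(curves, k=2)
        assert out.iloc[0].modality == "other"

    def test_zscoring_makes_clustering_scale_invariant(self):
        rng = np.random.default_rng(10)
        t = np.linspace(0, 1, 60)
        base = [np.sin(2 * np.pi * t + p) for p in (0, 0.1, np.pi, np.pi + 0.1)]
        curves = pd.DataFrame(base)
        scaled = curves.mul(pd.Series([10, 0.1, 5, 7]), axis=0).add(
            pd.Series([3, 0, -2, 1]), axis=0
        )
        o1 = assoc.cluster_patterns(curves, k=2)
        o2 = assoc.cluster_patterns(scaled, k=2)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(o1.pattern_cluster, o2.pattern_cluster) == 1.0


def test_bh_fdr_matches_reference_step_up():
    from statsmodels.stats.multitest import multipletests

    def reference_bh(p):
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        prev = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = m - rank_from_end
            val = min(prev, p[idx] * m / rank)
            q[idx] = val
            prev = val
        return q

    rng = np.random.default_rng(11)
    for _ in range(5):
        p = rng.uniform(0, 1, 200)
        q = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, reference_bh(p), atol=1e-12)
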