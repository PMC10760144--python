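import numpy as np
import pandas as pd
import pytest

from airscape import compstats as cs, synthdata as sd


class TestLogit:
    def test_half_maps_to_zero(self):
        assert cs.logit_transform(np.array([0.5]), 100)[0] == 0.0

    def test_antisymmetry(self):
        z = cs.logit_transform(np.array([0.2, 0.8]), 1000)
        assert z[0] == pytest.approx(-z[1])

    def test_zero_clamped_by_half_count_rule(self):
        got = cs.logit_transform(np.array([0.0]), 100)[0]
        assert got == pytest.approx(np.log(0.005 / 0.995))

    def test_strictly_monotone(self):
        p = np.linspace(0.01, 0.99, 50)
        z = cs.logit_transform(p, 10000)
        assert np.all(np.diff(z) > 0)


class TestCompositionAnova:
    def groups(self):
        return pd.Series(["u"] * 3 + ["lf"] * 3 + ["mf"] * 3)

    def test_identical_proportions_give_f_zero_p_one(self):
        props = pd.DataFrame({"a": [0.3] * 9, "b": [0.7] * 9})
        res = cs.composition_anova(props, self.groups(), pd.Series([100] * 9))
        assert res.loc["a", "F"] == 0.0
        assert res.loc["a", "pvalue"] == 1.0

    def test_group_relabeling_leaves_pvalues_unchanged(self):
        rng = np.random.default_rng(0)
        props = pd.DataFrame(rng.dirichlet([5, 5, 5], 9), columns=list("abc"))
        g1 = self.groups()
        mapping = {"u": "x", "lf": "y", "mf": "z"}
        r1 = cs.composition_anova(props, g1, pd.Series([100] * 9))
        r2 = cs.composition_anova(props, g1.map(mapping), pd.Series([100] * 9))
        assert np.allclose(r1["pvalue"], r2["pvalue"])

    def test_singleton_group_skipped_with_warning(self):
        props = pd.DataFrame({"a": [0.5] * 4})
        groups = pd.Series(["u", "u", "lf", "mf"])
        with pytest.warns(UserWarning):
            res = cs.composition_anova(props, groups, pd.Series([10] * 4))
        assert len(res) == 0

    def test_planted_shift_detected_at_study_group_sizes(self):
        counts, groups = sd.simulate_group_compositions(7, fold_change=2.0)
        props, totals = cs.proportions_from_counts(counts)
        res = cs.composition_anova(props, groups, totals, fdr=0.05)
        assert bool(res.loc["type_00", "significant"])


class TestCovariateRegression:
    def test_noise_free_association_recovered_with_correct_sign(self):
        scores = pd.Series(np.linspace(0, 10, 12))
        z = 0.4 * scores.to_numpy() - 3.0
        p = 1 / (1 + np.exp(-z))
        props = pd.DataFrame({"a": p, "b": 1 - p})
        res = cs.covariate_regression(props, scores, unit_totals=pd.Series([10000] * 12))
        assert res.loc["a", "pvalue"] < 1e-10
        assert res.loc["a", "slope"] > 0
        assert res.loc["b", "slope"] < 0

    def test_zero_variance_scores_rejected(self):
        props = pd.DataFrame({"a": [0.5, 0.4]})
        with pytest.raises(ValueError):
            cs.covariate_regression(props, pd.Series([1.0, 1.0]), unit_totals=pd.Series([10, 10]))

    def test_permuting_scores_destroys_planted_association(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(np.linspace(0, 10, 20))
        z = 0.5 * scores.to_numpy() + rng.normal(0, 0.3, 20)
        props = pd.DataFrame({"a": 1 / (1 + np.exp(-z))})
        totals = pd.Series([5000] * 20)
        base = cs.covariate_regression(props, scores, unit_totals=totals)
        assert base.loc["a", "pvalue"] < 1e-6
        broken = 0
        for _ in range(20):
            perm = pd.Series(rng.permutation(scores.to_numpy()))
            res = cs.covariate_regression(props, perm, unit_totals=totals)
            broken += res.loc["a", "pvalue"] > 0.05
        assert broken >= 18  # >= 90% of permutations lose the association


class TestNicheMarkers:
    def simulate(self, exclude_fraction=None, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for s in ("S1", "S2", "S3"):
            for niche in (1, 2):
                n = 5000
                if exclude_fraction is not None and (s, niche) == ("S1", 2):
                    n = int(exclude_fraction * 10000)
                p = np.full(20, 1 / 20)
                if niche == 2:
                    p[3] *= 6
                    p = p / p.sum()
                gidx = rng.choice(20, n, p=p)
                recs.append(
                    pd.DataFrame(
                        {"sample_id": s, "niche": niche,
                         "feature_name": [f"g{j:02d}" for j in gidx]}
                    )
                )
        return pd.concat(recs, ignore_index=True)

    def test_planted_marker_tops_its_niche(self):
        res = cs.niche_marker_genes(self.simulate())
        assert res[res.niche == 2].iloc[0].gene == "g03"

    def test_uniform_genes_have_near_zero_contrast(self):
        # no planted markers anywhere: every gene is exchangeable across
        # niches, so all contrasts hover near zero and none reach FDR
        rng = np.random.default_rng(5)
        recs = []
        for s in ("S1", "S2", "S3"):
            for niche in (1, 2):
                gidx = rng.choice(20, 5000)
                recs.append(
                    pd.DataFrame(
                        {"sample_id": s, "niche": niche,
                         "feature_name": [f"g{j:02d}" for j in gidx]}
                    )
                )
        res = cs.niche_marker_genes(pd.concat(recs, ignore_index=True))
        assert res.estimate.abs().max() < 0.3
        assert not res.significant.any()

    def test_low_contribution_sample_excluded(self):
        # S1 contributes < 5e-4 of its transcripts to niche 2 -> S1 excluded
        df = self.simulate()
        s1n2 = df[(df.sample_id == "S1") & (df.niche == 2)].index[:-2]
        df = df.drop(index=s1n2)
        res = cs.niche_marker_genes(df, min_sample_fraction=5e-4)
        n2 = res[res.niche == 2].set_index("gene")
        # still estimated from S2/S3 alone: the planted marker carries by far
        # the largest positive contrast
        assert n2.estimate.idxmax() == "g03"
        assert n2.estimate.max() > 1.0


class TestPseudobulkDe:
    def simulate(self, seed=0, fold=4.0):
        rng = np.random.default_rng(seed)
        genes = [f"G{i:02d}" for i in range(60)]
        base = rng.gamma(2.0, 50.0, 60)
        rows, ann, ncell = [], [], []
        for t in ("fibroblastic focus", "granuloma", "normal alveoli", "giant cell"):
            for _ in range(5):
                mu = base.copy()
                if t == "fibroblastic focus":
                    mu[0] *= fold
                rows.append(rng.poisson(mu * rng.uniform(0.5, 2.0) * rng.gamma(8, 1 / 8, 60)))
                ann.append(t)
                ncell.append(int(rng.integers(50, 300)))
        counts = pd.DataFrame(rows, columns=genes, index=[f"i{i}" for i in range(len(rows))])
        return counts, pd.Series(ann, index=counts.index), pd.Series(ncell, index=counts.index)

    def test_log2cpm_closed_form_for_zero_count(self):
        counts = pd.DataFrame({"g0": [0], "g1": [999]})
        lc = cs.log2_cpm(counts)
        lib = 999
        assert lc.loc[0, "g0"] == pytest.approx(np.log2(0.5 / (lib + 1) * 1e6))

    def test_lowly_expressed_genes_filtered(self):
        counts = pd.DataFrame({"hi": [10000, 12000], "lo": [1, 2]})
        kept = cs.filter_expressed(cs.log2_cpm(counts))
        assert kept == ["hi"]

    def test_planted_marker_is_top_ranked(self):
        counts, ann, ncell = self.simulate()
        res = cs.pseudobulk_de_annotations(counts, ann, ncell)
        ff = res["one_vs_rest"].query("annotation == 'fibroblastic focus'")
        assert ff.nsmallest(1, "pvalue").gene.iloc[0] == "G00"

    def test_giant_cells_excluded_from_analysis(self):
        counts, ann, ncell = self.simulate()
        res = cs.pseudobulk_de_annotations(counts, ann, ncell)
        assert "giant cell" not in set(res["one_vs_rest"].annotation)

    def test_duplicating_instances_preserves_log_fold_changes(self):
        counts, ann, ncell = self.simulate(seed=3)
        r1 = cs.pseudobulk_de_annotations(counts, ann, ncell)
        counts2 = pd.concat([counts, counts.set_axis([f"{i}b" for i in counts.index])])
        ann2 = pd.concat([ann, ann.set_axis([f"{i}b" for i in ann.index])])
        ncell2 = pd.concat([ncell, ncell.set_axis([f"{i}b" for i in ncell.index])])
        r2 = cs.pseudobulk_de_annotations(counts2, ann2, ncell2)
        m1 = r1["one_vs_rest"].set_index(["annotation", "gene"]).log2fc
        m2 = r2["one_vs_rest"].set_index(["annotation", "gene"]).log2fc
        assert np.allclose(m1, m2.loc[m1.index], atol=1e-6)

    def test_epithelial_contrasts_emitted(self):
        counts, ann, ncell = self.simulate(seed=4)
        res = cs.pseudobulk_de_annotations(
            counts, ann, ncell, epithelial_types=("normal alveoli", "granuloma")
        )
        assert len(res["epithelial"]) > 0


def test_bh_controls_fdr_under_the_null():
    rng = np.random.default_rng(5)
    from statsmodels.stats.multitest import multipletests

    false_rates = []
    for _ in range(200):
        p = rng.uniform(0, 1, 100)
        rej = multipletests(p, alpha=0.1, method="fdr_bh")[0]
        false_rates.append(1.0 if rej.any() else 0.0)
    # all hypotheses are null: any rejection is a false discovery; the
    # family-wise proportion of runs with >= 1 rejection stays near alpha
    assert np.mean(false_rates) <= 0.15
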