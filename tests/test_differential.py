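"""Moderated linear models: normalisation, BH, moderation limits,
clustering, signature scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from persisterlab.differential import (
    ModeratedLinearModel,
    bh_adjust,
    filter_detectable,
    moderated_f_select,
    normalize_log_cpm,
    score_signature,
    zscore_and_cluster,
    zscore_by_group,
)


def _toy_model(n_genes=100, delta=0.0, seed=0, n_rep=3):
    rng = np.random.default_rng(seed)
    info = pd.DataFrame(
        {"treatment": ["DMSO"] * n_rep + ["DTP"] * n_rep},
        index=[f"s{i}" for i in range(2 * n_rep)],
    )
    Y = pd.DataFrame(rng.normal(5, 1, (n_genes, 2 * n_rep)),
                     index=[f"g{i}" for i in range(n_genes)], columns=info.index)
    Y.iloc[:, n_rep:] += delta
    return ModeratedLinearModel(Y, info)


class TestFilteringAndNormalisation:
    def test_detectable_boundary(self):
        counts = pd.DataFrame(
            {"s1": [1, 5, 0, 0], "s2": [2, 0, 0, 1], "s3": [0, 0, 0, 3]},
            index=list("abcd"))
        kept = filter_detectable(counts)
        assert list(kept.index) == ["a", "d"]

    def test_all_zero_matrix(self):
        counts = pd.DataFrame(np.zeros((3, 3), dtype=int))
        assert len(filter_detectable(counts)) == 0

    def test_log_cpm_arithmetic(self):
        counts = pd.DataFrame({"s": [100, 10 ** 6 - 100]})
        out = normalize_log_cpm(counts, prior_count=0)
        assert out.iloc[0, 0] == pytest.approx(np.log2(100), abs=1e-9)

    def test_log_cpm_scale_invariance(self):
        counts = pd.DataFrame({"s": [10, 90, 400]})
        a = normalize_log_cpm(counts, prior_count=0)
        b = normalize_log_cpm(counts * 2, prior_count=0)
        assert np.allclose(a, b)

    def test_prior_count_keeps_zeros_finite(self):
        out = normalize_log_cpm(pd.DataFrame({"s": [0, 100]}), prior_count=0.5)
        assert np.isfinite(out.to_numpy()).all()

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            normalize_log_cpm(pd.DataFrame({"s": [0, 0]}), prior_count=0.5)


class TestBH:
    def test_hand_computed_stepup(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_and_equal(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_adjusted_at_least_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestModeration:
    def test_zero_prior_df_equals_ordinary_t(self):
        m = _toy_model(delta=1.0, seed=4)
        res = m.fit({"c": "DTP - DMSO"}, d_prior=0)
        tab = res.contrast_table("c")
        # ordinary two-sample equal-variance t per gene
        Y = m.data.to_numpy()
        a, b = Y[:, :3], Y[:, 3:]
        t_ref = stats.ttest_ind(b, a, axis=1, equal_var=True).statistic
        assert np.max(np.abs(tab["t"].to_numpy() - t_ref)) < 1e-10

    def test_infinite_prior_df_pools_variance(self):
        m = _toy_model(delta=1.0, seed=5)
        res = m.fit({"c": "DTP - DMSO"}, d_prior=np.inf)
        tab = res.contrast_table("c")
        s2p = res.moderation.s2_prior
        est = tab["log2fc"].to_numpy()
        z_ref = est / np.sqrt(s2p * (1 / 3 + 1 / 3))
        assert np.max(np.abs(tab["t"].to_numpy() - z_ref)) < 1e-10
        assert np.allclose(res.moderation.s2_posterior, s2p)

    def test_moderated_t_between_limits(self):
        m = _toy_model(delta=0.5, seed=6)
        res = m.fit({"c": "DTP - DMSO"})
        assert 0 < res.moderation.d_prior
        post = res.moderation.s2_posterior
        lo = np.minimum(res.moderation.s2_residual, res.moderation.s2_prior)
        hi = np.maximum(res.moderation.s2_residual, res.moderation.s2_prior)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_global_null_fdr_calibration(self):
        """Under the global null at most ~nominal fraction passes FDR<0.05."""
        m = _toy_model(n_genes=2000, delta=0.0, seed=7)
        tab = m.fit({"c": "DTP - DMSO"}).contrast_table("c")
        assert (tab["fdr"] < 0.05).mean() <= 0.07

    def test_rank_deficient_design_rejected(self):
        info = pd.DataFrame({"treatment": ["a", "a", "b", "b"],
                             "cell_line": ["x", "x", "y", "y"]},
                            index=[f"s{i}" for i in range(4)])
        Y = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)),
                         columns=info.index)
        with pytest.raises(ValueError, match="rank-deficient"):
            ModeratedLinearModel(Y, info)

    def test_cell_line_shift_invariance(self):
        """Adding a constant to one cell line's samples does not change
        treatment contrasts (the line term absorbs it)."""
        rng = np.random.default_rng(8)
        info = pd.DataFrame(
            {"treatment": ["DMSO", "DTP"] * 4,
             "cell_line": ["A"] * 4 + ["B"] * 4},
            index=[f"s{i}" for i in range(8)])
        Y = pd.DataFrame(rng.normal(size=(50, 8)), columns=info.index)
        res1 = ModeratedLinearModel(Y, info).fit({"c": "DTP - DMSO"})
        Y2 = Y.copy()
        Y2.loc[:, info.index[info.cell_line == "B"]] += 5.0
        res2 = ModeratedLinearModel(Y2, info).fit({"c": "DTP - DMSO"})
        assert np.allclose(res1.contrast_table("c")["log2fc"],
                           res2.contrast_table("c")["log2fc"])

    def test_planted_lfc_recovery(self, study, rna_fit):
        """Planted DTP log2 fold changes are recovered with small bias."""
        effects = study["effects"]
        tab = rna_fit.contrast_table("DTP_vs_DMSO")
        up = effects.index[effects["archetype"] == 3]
        est = tab.loc[tab.index.intersection(up), "log2fc"]
        assert est.mean() == pytest.approx(2.0, abs=0.3)

    def test_summary_mentions_contrast(self, rna_fit):
        s = rna_fit.summary(max_rows=2)
        assert "DTP_vs_DMSO" in s and "prior df" in s


class TestFSelect:
    def _tables(self, fdrs):
        return {line: pd.DataFrame({"fdr": f}, index=list("abcde"))
                for line, f in fdrs.items()}

    def test_min_models_rule(self):
        tables = self._tables({
            "L1": [0.01, 0.2, 0.01, 0.5, 0.01],
            "L2": [0.01, 0.01, 0.2, 0.5, 0.01],
            "L3": [0.01, 0.2, 0.01, 0.5, 0.01],
            "L4": [0.2, 0.2, 0.01, 0.5, 0.01],
        })
        sel = moderated_f_select(tables, min_models=3, top_n=10)
        assert set(sel) == {"a", "c", "e"}
        assert moderated_f_select(tables, min_models=3, top_n=1) == ["a"] or \
            moderated_f_select(tables, min_models=3, top_n=1) == ["e"]

    def test_min_models_exceeds_lines(self):
        with pytest.raises(ValueError):
            moderated_f_select(self._tables({"L1": [0.1] * 5}), min_models=2)


class TestClusterAndSignature:
    def test_constant_feature_z_is_zero(self):
        m = pd.DataFrame({"s1": [1.0, 1.0], "s2": [1.0, 2.0]}, index=["a", "b"])
        groups = pd.Series({"s1": "g", "s2": "g"})
        z = zscore_by_group(m, groups)
        assert (z.loc["a"] == 0).all()

    def test_two_archetypes_recovered(self):
        rng = np.random.default_rng(9)
        n = 40
        up = np.tile([0, 0, 2, 2], (n, 1)) + rng.normal(0, 0.05, (n, 4))
        down = np.tile([2, 2, 0, 0], (n, 1)) + rng.normal(0, 0.05, (n, 4))
        m = pd.DataFrame(np.vstack([up, down]), columns=list("wxyz"))
        groups = pd.Series("g", index=m.columns)
        out = zscore_and_cluster(m, groups, k=2, seed=0)
        labels = out["cluster"].to_numpy()
        assert len(np.unique(labels[:n])) == 1
        assert len(np.unique(labels[n:])) == 1
        assert labels[0] != labels[-1]
        # ordering is a permutation of 0..n-1
        assert sorted(out["order"]) == list(range(2 * n))

    def test_k1_single_cluster(self):
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)))
        out = zscore_and_cluster(m, pd.Series("g", index=m.columns), k=1)
        assert (out["cluster"] == 0).all()

    def test_k_validation(self):
        m = pd.DataFrame(np.ones((3, 2)))
        with pytest.raises(ValueError):
            zscore_and_cluster(m, pd.Series("g", index=m.columns), k=0)
        with pytest.raises(ValueError):
            zscore_and_cluster(m, pd.Series("g", index=m.columns), k=5)

    def test_signature_single_gene_equals_its_z(self):
        rng = np.random.default_rng(10)
        m = pd.DataFrame(rng.normal(size=(10, 6)),
                         index=[f"g{i}" for i in range(10)])
        score = score_signature(m, ["g3"])
        z3 = (m.loc["g3"] - m.loc["g3"].mean()) / m.loc["g3"].std(ddof=0)
        assert np.allclose(score, z3)

    def test_signature_missing_genes_rejected(self):
        m = pd.DataFrame(np.ones((2, 2)), index=["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            score_signature(m, ["zzz"])

    def test_planted_signature_separates_treatments(self, study):
        """An up-in-DTP gene set scores higher in DTP than DMSO samples."""
        from persisterlab.differential import normalize_log_cpm
        effects, counts, samples = (study["effects"], study["counts"],
                                    study["samples"])
        up_set = list(effects.index[effects["archetype"] == 3])
        logcpm = normalize_log_cpm(counts)
        score = score_signature(logcpm, up_set)
        dtp = score[samples.index[samples.treatment == "DTP"]]
        dmso = score[samples.index[samples.treatment == "DMSO"]]
        t = stats.ttest_ind(dtp, dmso)
        assert dtp.mean() > dmso.mean()
        assert t.pvalue < 0.05
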