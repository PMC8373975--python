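"""Signature derivation: filters, conservation score, moderated t, scoring."""

import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cmsshift as cs
from cmsshift.cms_signature import DETable, fit_f_dist
from conftest import DATA_DIR, make_matrix


class TestFilterMinExpression:
    def test_single_zero_excludes_gene(self):
        m = make_matrix([[1.0, 0.0], [2.0, 3.0]], layer="counts")
        assert cs.filter_min_expression(m) == ["g1"]

    def test_all_positive_keeps_everything(self):
        m = make_matrix(np.ones((5, 4)), layer="counts")
        assert cs.filter_min_expression(m) == [f"g{i}" for i in range(5)]

    def test_planted_zero_count(self, small_cohort):
        cfg, _, _, truth = small_cohort
        prof, _ = cs.simulate_cellline_profiles(cfg, truth, 0.5)
        vals = prof.values.copy()
        rng = np.random.default_rng(0)
        hit = rng.choice(len(vals), size=37, replace=False)
        vals.iloc[hit, 0] = 0
        vals.iloc[~vals.index.isin(vals.index[hit]), :] += 1  # everything else expressed
        m = prof.with_values(vals, "counts")
        assert len(cs.filter_min_expression(m)) == len(vals) - 37


def coc_bruteforce(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Double-loop oracle for the conservation score."""
    m = a.shape[0]
    out = np.empty(m)
    for g in range(m):
        ra, rb = [], []
        for h in range(m):
            if h == g:
                continue
            ra.append(stats.pearsonr(a[g], a[h]).statistic)
            rb.append(stats.pearsonr(b[g], b[h]).statistic)
        out[g] = stats.pearsonr(ra, rb).statistic
    return out


class TestCorrelationOfCorrelations:
    def test_identical_datasets_score_one(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(size=(8, 6)))
        coc = cs.correlation_of_correlations(m, m)
        np.testing.assert_allclose(coc.scores, 1.0, atol=1e-12)

    def test_genewise_affine_transform_scores_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 6))
        scale = rng.uniform(0.5, 3.0, size=8)
        shift = rng.normal(size=8)
        a = make_matrix(x)
        b = make_matrix(x * scale[:, None] + shift[:, None])
        coc = cs.correlation_of_correlations(a, b)
        np.testing.assert_allclose(coc.scores, 1.0, atol=1e-10)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(4)
        xa = rng.normal(size=(5, 6))
        xb = rng.normal(size=(5, 6))
        coc = cs.correlation_of_correlations(make_matrix(xa), make_matrix(xb))
        np.testing.assert_allclose(coc.scores, coc_bruteforce(xa, xb), atol=1e-12)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        a = make_matrix(rng.normal(size=(6, 5)))
        b = make_matrix(rng.normal(size=(6, 5)))
        s1 = cs.correlation_of_correlations(a, b).scores
        s2 = cs.correlation_of_correlations(b, a).scores
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_zero_variance_gene_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(5, 6))
        x[2] = 3.14
        with caplog.at_level(logging.WARNING):
            coc = cs.correlation_of_correlations(make_matrix(x), make_matrix(rng.normal(size=(5, 6))))
        assert "g2" not in coc.scores.index
        assert any("zero-variance" in r.message for r in caplog.records)


class TestModeratedT:
    def _labels(self, n2, n4, samples):
        return pd.Series(["CMS2"] * n2 + ["CMS4"] * n4, index=samples)

    def test_common_variance_shrinks_to_common_target(self):
        # every gene shares one sample variance: full shrinkage (d0 = inf),
        # the posterior variance is the same constant for all genes, and the
        # moderated t is the ordinary t times one global factor (the prior
        # scale carries the reference implementation's log-scale bias
        # correction, so the factor is close to but not exactly 1)
        rng = np.random.default_rng(7)
        noise = rng.normal(size=12)            # identical residual pattern per gene
        means = rng.normal(5, 2, size=20)
        x = means[:, None] + noise[None, :]
        x[:, 6:] += rng.normal(size=20)[:, None]
        m = make_matrix(x)
        de = cs.moderated_t_de(m, self._labels(6, 6, m.samples))
        assert np.isinf(de.d0)
        assert de.table["s2_post"].nunique() == 1
        ratio = de["t_moderated"] / de["t_ordinary"]
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)
        assert ratio.iloc[0] == pytest.approx(1.0, abs=0.1)

    def test_label_swap_negates_fc_and_t(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.normal(5, 1, size=(30, 10)))
        labels = self._labels(5, 5, m.samples)
        de = cs.moderated_t_de(m, labels)
        swapped = labels.map({"CMS2": "CMS4", "CMS4": "CMS2"})
        de2 = cs.moderated_t_de(m, swapped)
        np.testing.assert_allclose(de2["log2fc"], -de["log2fc"], atol=1e-12)
        np.testing.assert_allclose(de2["t_moderated"], -de["t_moderated"], atol=1e-12)
        np.testing.assert_allclose(de2["p"], de["p"], atol=1e-12)

    def test_shrinkage_formula_recomputed_stepwise(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, rng.uniform(0.5, 2.0, size=200)[:, None], size=(200, 14)) + 5
        m = make_matrix(x)
        de = cs.moderated_t_de(m, self._labels(7, 7, m.samples))
        # independent step-by-step recomputation of the shrinkage
        a, b = x[:, :7], x[:, 7:]
        fc = b.mean(axis=1) - a.mean(axis=1)
        s2 = (((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
              + ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)) / 12
        s2_post = (de.d0 * de.s02 + 12 * s2) / (de.d0 + 12)
        t_expected = fc / (np.sqrt(s2_post) * np.sqrt(2 / 7))
        np.testing.assert_allclose(de["t_moderated"], t_expected, rtol=1e-9)
        assert np.all(np.sign(de["log2fc"]) == np.sign(de["t_moderated"]))
        assert np.all(de["p_adj"] >= de["p"] - 1e-15)

    def test_matches_reference_limma_on_frozen_fixture(self):
        # fixture recipe: gene variances ~ scaled inverse chi-square(d0=8, s02=0.5)
        rng = np.random.default_rng(42)
        s2 = 0.5 * 8.0 / rng.chisquare(8.0, size=60)
        x = rng.normal(5, np.sqrt(s2)[:, None], size=(60, 12))
        x[:12, 6:] += rng.uniform(0.5, 2.0, size=12)[:, None]
        m = make_matrix(x, genes=[f"g{i:02d}" for i in range(60)])
        de = cs.moderated_t_de(m, self._labels(6, 6, m.samples))
        expected = pd.read_csv(f"{DATA_DIR}/limma_expected.csv", index_col=0)
        assert de.d0 == pytest.approx(13.1485244802, rel=1e-9)
        assert de.s02 == pytest.approx(0.526208885127, rel=1e-9)
        np.testing.assert_allclose(de["t_moderated"], expected["t"], rtol=1e-9)
        np.testing.assert_allclose(de["p"], expected["p"], rtol=1e-9)

    def test_small_class_rejected(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(5, 4)))
        labels = pd.Series(["CMS2", "CMS2", "CMS2", "CMS4"], index=m.samples)
        with pytest.raises(cs.DataError, match=">=2"):
            cs.moderated_t_de(m, labels)


def _detable(rows: dict) -> DETable:
    df = pd.DataFrame(rows).T
    df.columns = ["log2fc", "p"]
    df["t_moderated"] = np.sign(df["log2fc"])
    df["p_adj"] = df["p"]
    return DETable(table=df, d0=4.0, s02=1.0)


class TestBuildSignature:
    def test_exactly_enough_genes_selects_all(self):
        rows = {f"u{i}": [1.0 + i / 10, 0.01 * (i + 1)] for i in range(10)}
        rows.update({f"d{i}": [-1.0 - i / 10, 0.01 * (i + 1)] for i in range(10)})
        sig = cs.build_signature(_detable(rows))
        assert set(sig.genes) == set(rows)
        assert all(sig.weights[g] > 0 for g in sig.genes[:10])
        assert all(sig.weights[g] < 0 for g in sig.genes[10:])

    def test_tie_broken_by_absfc_then_gene_id(self):
        rows = {"aa": [1.0, 0.01], "bb": [2.0, 0.01], "cc": [1.0, 0.01]}
        rows.update({f"u{i}": [0.5, 0.5] for i in range(10)})
        rows.update({f"d{i}": [-1.0, 0.02] for i in range(10)})
        sig = cs.build_signature(_detable(rows), k_up=2, k_down=10)
        assert sig.genes[:2] == ["bb", "aa"]   # larger |fc| first, then lexicographic

    def test_insufficient_genes_error_states_counts(self):
        rows = {"u1": [1.0, 0.1], "d1": [-1.0, 0.1]}
        with pytest.raises(cs.DataError, match="1 upregulated"):
            cs.build_signature(_detable(rows), k_up=10, k_down=10)

    def test_larger_k_grows_signature_as_superset(self):
        rng = np.random.default_rng(10)
        rows = {f"g{i}": [float(rng.normal()), float(rng.uniform(0.001, 0.5))]
                for i in range(60)}
        small = cs.build_signature(_detable(rows), k_up=5, k_down=5)
        big = cs.build_signature(_detable(rows), k_up=8, k_down=8)
        assert set(small.genes) <= set(big.genes)

    def test_recovers_planted_genes(self, adjusted_cohort):
        _, adjusted, annotation, truth = adjusted_cohort
        de = cs.moderated_t_de(adjusted, annotation["cms_label"])
        sig = cs.build_signature(de)
        up_planted = {g for g, v in truth.de_log2fc.items() if v > 0}
        down_planted = {g for g, v in truth.de_log2fc.items() if v < 0}
        assert len(set(sig.genes[:10]) & up_planted) >= 8
        assert len(set(sig.genes[10:]) & down_planted) >= 8


class TestScoreSamples:
    def _signature(self):
        weights = pd.Series([2.0, 1.0, -1.0, -2.0], index=["a", "b", "c", "d"])
        return cs.CMSSignature(genes=list(weights.index), weights=weights, k_up=2, k_down=2)

    def test_column_proportional_to_weights_scores_one(self):
        sig = self._signature()
        m = make_matrix(np.array([[4.0], [2.0], [-2.0], [-4.0]]),
                        genes=list(sig.genes), layer="centered")
        assert cs.score_samples(sig, m).iloc[0] == pytest.approx(1.0)

    def test_negated_weights_score_minus_one(self):
        sig = self._signature()
        m = make_matrix(-sig.weights.to_numpy().reshape(-1, 1),
                        genes=list(sig.genes), layer="centered")
        assert cs.score_samples(sig, m).iloc[0] == pytest.approx(-1.0)

    def test_genewise_constant_is_absorbed(self):
        sig = self._signature()
        rng = np.random.default_rng(11)
        x = rng.normal(size=(4, 3))
        m1 = make_matrix(x, genes=list(sig.genes), layer="centered")
        m2 = make_matrix(x + 7.5, genes=list(sig.genes), layer="centered")
        np.testing.assert_allclose(cs.score_samples(sig, m1), cs.score_samples(sig, m2),
                                   atol=1e-12)

    def test_constant_column_reported_na_with_warning(self, caplog):
        sig = self._signature()
        m = make_matrix(np.ones((4, 1)), genes=list(sig.genes), layer="centered")
        with caplog.at_level(logging.WARNING):
            scores = cs.score_samples(sig, m)
        assert np.isnan(scores.iloc[0])

    def test_too_few_shared_genes_rejected(self):
        sig = self._signature()
        m = make_matrix(np.ones((2, 1)), genes=["a", "b"], layer="centered")
        with pytest.raises(cs.DataError, match=">=3"):
            cs.score_samples(sig, m)

    def test_treated_arms_outscore_controls_at_moderate_shift(self):
        wins = 0
        for seed in range(10):
            cfg = cs.CohortConfig(n_genes=300, n_samples_per_platform=(20, 20),
                                  n_cms2=20, n_cms4=20, n_de_genes=30, seed=100 + seed)
            matrix, annotation, truth = cs.simulate_reference_cohort(cfg)
            adj, _ = cs.batch_adjust(cs.rpm_log2(matrix), annotation["platform"])
            sig = cs.build_signature(cs.moderated_t_de(adj, annotation["cms_label"]))
            prof, ann = cs.simulate_cellline_profiles(cfg, truth, 0.5)
            avg, avg_ann = cs.average_replicates(cs.rpm_log2(prof), ann)
            scores = cs.score_samples(sig, cs.center_within_group(avg, avg_ann))
            treated = scores[avg_ann["treatment"] != "medium"].mean()
            control = scores[avg_ann["treatment"] == "medium"].mean()
            wins += treated > control
        assert wins >= 9


class TestDeriveSignature:
    def test_stage_counts_and_provenance(self, adjusted_cohort, small_cohort):
        cfg, _, _, truth = small_cohort
        _, adjusted, annotation, _ = adjusted_cohort
        prof, _ = cs.simulate_cellline_profiles(cfg, truth, 0.8)
        sig, counts = cs.derive_signature(adjusted, annotation["cms_label"], prof)
        assert counts["min_expression"] <= counts["input_genes"]
        assert counts["conserved"] <= counts["min_expression"]
        assert sig.provenance["coc_threshold"] == 0.1
        assert len(sig.genes) == 20
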