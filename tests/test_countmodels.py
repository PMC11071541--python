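"""Count statistics: normalization, DE, interaction LRT, clustering,
Fano factor and synergy."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from strainreg.countmodels import (
    DesignError,
    NormalizationError,
    StrainResponseModel,
    kmeans_profiles,
    size_factors_median_ratio,
)
from strainreg.simulate import SimulationConfig, CohortSimulator, _nb_draw


class TestSizeFactors:
    def test_doubled_sample_gives_sqrt2_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        sf = size_factors_median_ratio(counts)
        assert np.allclose(sf.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [5, 8, 13], "s2": [5, 8, 13],
                               "s3": [5, 8, 13]})
        assert np.allclose(size_factors_median_ratio(counts), 1.0)

    def test_zero_bearing_gene_excluded_from_reference(self):
        base = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        with_zero = pd.concat([base, pd.DataFrame({"s1": [0], "s2": [10**6]})],
                              ignore_index=True)
        assert np.allclose(size_factors_median_ratio(with_zero),
                           size_factors_median_ratio(base))

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, size=(100, 6)))
        sf = size_factors_median_ratio(counts)
        assert abs(np.exp(np.mean(np.log(sf))) - 1) < 1e-9

    def test_no_all_positive_gene_raises(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(NormalizationError):
            size_factors_median_ratio(counts)


class TestPairwiseDE:
    def _model(self, counts, design):
        return StrainResponseModel(counts, design)

    def test_null_type_one_error(self, null_cohort):
        """Fraction of raw p <= 0.05 near nominal on a no-effect fixture."""
        model = StrainResponseModel(null_cohort.rna_counts, null_cohort.design)
        de = model.fit_pairwise({"strain": "B6", "treatment": "Ctrl"},
                                {"strain": "B6", "treatment": "IL4"})
        frac = (de.frame["pvalue"] <= 0.05).mean()
        assert 0.02 <= frac <= 0.08

    def test_planted_power(self, default_cohort):
        """>= 80% of planted strain-specific genes pass (FDR<=0.05, 2-fold)."""
        model = StrainResponseModel(default_cohort.rna_counts,
                                    default_cohort.design)
        de = model.fit_pairwise({"strain": "B6", "treatment": "Ctrl"},
                                {"strain": "B6", "treatment": "IL4"})
        planted = [g for g, i in default_cohort.truth.interaction_genes.items()
                   if i["strain"] == "B6"]
        assert de.frame.loc[planted, "pass"].mean() >= 0.8

    def test_identical_groups_rejected(self, small_design):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(50, (20, len(small_design))),
                              columns=small_design.index)
        model = self._model(counts, small_design)
        samples = list(small_design.index[:3])
        with pytest.raises(DesignError):
            model.fit_pairwise(samples, samples)

    def test_single_sample_group_rejected(self, small_design):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(50, (20, len(small_design))),
                              columns=small_design.index)
        model = self._model(counts, small_design)
        with pytest.raises(DesignError):
            model.fit_pairwise(list(small_design.index[:1]),
                               list(small_design.index[3:6]))

    def test_unknown_group_label_rejected(self, small_design):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(50, (10, len(small_design))),
                              columns=small_design.index)
        model = self._model(counts, small_design)
        with pytest.raises(DesignError):
            model.fit_pairwise({"strain": "B6", "treatment": "Ctrl"},
                               {"strain": "CAST", "treatment": "IL4"})

    def test_bh_fdr_monotone_in_p_rank(self, default_cohort):
        model = StrainResponseModel(default_cohort.rna_counts,
                                    default_cohort.design)
        de = model.fit_pairwise({"strain": "BALB", "treatment": "Ctrl"},
                                {"strain": "BALB", "treatment": "IL4"})
        f = de.frame.sort_values("pvalue")
        assert (np.diff(f["fdr"].to_numpy()) >= -1e-12).all()
        assert f["fdr"].max() <= 1.0

    def test_uniform_size_factor_rescaling_is_absorbed(self, small_design):
        """Multiplying every size factor by c shifts only the intercept."""
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.poisson(100, (40, len(small_design))),
                              columns=small_design.index)
        sf = pd.Series(1.0, index=small_design.index)
        a = StrainResponseModel(counts, small_design,
                                size_factors=sf).fit_pairwise(
            {"strain": "B6", "treatment": "Ctrl"},
            {"strain": "B6", "treatment": "IL4"})
        b = StrainResponseModel(counts, small_design,
                                size_factors=sf * 3).fit_pairwise(
            {"strain": "B6", "treatment": "Ctrl"},
            {"strain": "B6", "treatment": "IL4"})
        # the GLM offset absorbs the rescale; only the dispersion estimated
        # from rescaled normalized counts moves (its shot-noise term is not
        # scale-free), so p-values are stable rather than bit-identical
        assert np.allclose(a.frame["lfc"], b.frame["lfc"], atol=0.05)
        assert np.allclose(a.frame["pvalue"], b.frame["pvalue"], atol=0.05)
        assert ((a.frame["pvalue"] < 0.01) == (b.frame["pvalue"] < 0.01)).mean() > 0.95

    def test_single_sample_rescaling_is_nearly_invariant(self, small_design):
        """Scaling one sample is absorbed by its size factor (approximately:
        the median-of-ratios reference itself shifts by c^(1/n))."""
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.poisson(200, (60, len(small_design))),
                              columns=small_design.index)
        scaled = counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 2
        a = self._model(counts, small_design).fit_pairwise(
            {"strain": "B6", "treatment": "Ctrl"},
            {"strain": "B6", "treatment": "IL4"})
        b = self._model(scaled, small_design).fit_pairwise(
            {"strain": "B6", "treatment": "Ctrl"},
            {"strain": "B6", "treatment": "IL4"})
        assert np.allclose(a.frame["lfc"], b.frame["lfc"], atol=5e-2)
        sig_a = a.frame["pvalue"] < 0.01
        sig_b = b.frame["pvalue"] < 0.01
        assert (sig_a == sig_b).mean() > 0.95

    def test_agrees_with_pydeseq2_on_direction_and_lfc(self, small_design):
        """Independent cross-check: fold-change estimates track DESeq2's."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(6)
        b6 = small_design[small_design["strain"] == "B6"]
        mu = rng.uniform(30, 300, size=60)
        lfc = np.zeros(60)
        lfc[:15] = rng.uniform(1, 3, size=15) * rng.choice([-1, 1], 15)
        counts = np.column_stack([
            rng.poisson(mu * (2.0 ** (lfc * (row.treatment == "IL4"))))
            for row in b6.itertuples(index=False)])
        frame = pd.DataFrame(counts, columns=b6.index,
                             index=[f"g{i}" for i in range(60)])
        mine = StrainResponseModel(frame, b6).fit_pairwise(
            {"treatment": "Ctrl"}, {"treatment": "IL4"})

        meta = b6[["treatment"]].copy()
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(counts=frame.T, metadata=meta,
                               design="~treatment", quiet=True)
            dds.deseq2()
            stats = DeseqStats(dds, contrast=["treatment", "IL4", "Ctrl"],
                               quiet=True)
            stats.summary()
        theirs = stats.results_df["log2FoldChange"].reindex(mine.frame.index)
        r = np.corrcoef(mine.frame["lfc"], theirs)[0, 1]
        assert r > 0.95
        strong = np.abs(theirs) > 0.5
        assert (np.sign(mine.frame["lfc"][strong])
                == np.sign(theirs[strong])).all()


class TestInteractionLRT:
    def test_statistic_nonnegative_everywhere(self, default_cohort):
        model = StrainResponseModel(default_cohort.rna_counts,
                                    default_cohort.design)
        res = model.fit_interaction()
        assert (res.frame["stat"] >= 0).all()
        assert (res.frame["df"] == 3).all()

    def test_null_pvalues_uniform(self, null_cohort):
        model = StrainResponseModel(null_cohort.rna_counts, null_cohort.design)
        p = model.fit_interaction().frame["pvalue"]
        assert scipy.stats.kstest(p, "uniform").pvalue > 0.01

    def test_planted_recovery_with_direction(self, default_cohort):
        model = StrainResponseModel(default_cohort.rna_counts,
                                    default_cohort.design)
        res = model.fit_interaction()
        truth = default_cohort.truth.interaction_genes
        f = res.frame.loc[list(truth)]
        correct = (f["fdr"] <= 0.05) & (
            f["direction"] == pd.Series({g: i["strain"]
                                         for g, i in truth.items()}))
        assert correct.mean() >= 0.8

    def test_single_strain_design_rejected(self, small_design):
        rng = np.random.default_rng(7)
        b6 = small_design[small_design["strain"] == "B6"]
        counts = pd.DataFrame(rng.poisson(50, (10, len(b6))), columns=b6.index)
        with pytest.raises(DesignError):
            StrainResponseModel(counts, b6).fit_interaction()

    def test_empty_design_cell_rejected(self, small_design):
        rng = np.random.default_rng(8)
        broken = small_design[~((small_design["strain"] == "BALB")
                                & (small_design["treatment"] == "IL4"))]
        counts = pd.DataFrame(rng.poisson(50, (10, len(broken))),
                              columns=broken.index)
        with pytest.raises(DesignError):
            StrainResponseModel(counts, broken).fit_interaction()

    def test_summary_mentions_models_and_counts(self, default_cohort):
        model = StrainResponseModel(default_cohort.rna_counts,
                                    default_cohort.design)
        text = model.fit_interaction().summary()
        assert "strain:treatment" in text and "B6" in text


class TestKmeansProfiles:
    def _archetypes(self, rng, n_copies=50, noise=0.1):
        archetypes = np.array([
            [0.0, 2.0, 0.0, 2.0, 0.0, 2.0],
            [2.0, 0.0, 2.0, 0.0, 2.0, 0.0],
            [1.0, 1.0, -2.0, -2.0, 1.0, 1.0],
        ])
        rows, labels = [], []
        for k, arch in enumerate(archetypes):
            for _ in range(n_copies):
                rows.append(arch + rng.normal(0, noise, size=len(arch)))
                labels.append(k)
        idx = [f"r{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=idx), np.array(labels)

    def test_recovers_archetypes_exactly(self):
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(9)
        data, labels = self._archetypes(rng)
        res = kmeans_profiles(data, k=3, seed=0)
        assert adjusted_rand_score(labels, res.labels.to_numpy()) == 1.0

    def test_k_one_puts_everything_in_cluster_one(self):
        rng = np.random.default_rng(10)
        data, _ = self._archetypes(rng, n_copies=10)
        res = kmeans_profiles(data, k=1, seed=0)
        assert (res.labels == 1).all()

    def test_scaling_a_row_preserves_assignment(self):
        rng = np.random.default_rng(11)
        data, _ = self._archetypes(rng, n_copies=20)
        res = kmeans_profiles(data, k=3, seed=3)
        scaled = data.copy()
        scaled.iloc[0] = scaled.iloc[0] * 7.5
        res2 = kmeans_profiles(scaled, k=3, seed=3)
        # correlation distance is scale-invariant: identical partition
        assert (res.labels == res2.labels).all()

    def test_constant_rows_reported_not_clustered(self):
        rng = np.random.default_rng(12)
        data, _ = self._archetypes(rng, n_copies=5)
        data.loc["flat"] = 1.0
        res = kmeans_profiles(data, k=2, seed=0)
        assert res.dropped == ["flat"]
        assert "flat" not in res.labels.index

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(13)
        data, _ = self._archetypes(rng, n_copies=15, noise=0.5)
        a = kmeans_profiles(data, k=3, seed=5)
        b = kmeans_profiles(data, k=3, seed=5)
        assert (a.labels == b.labels).all()
        assert a.objective == b.objective

    def test_invalid_k(self):
        data = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError):
            kmeans_profiles(data, k=0)


class TestFanoFactor:
    def test_poisson_fano_near_one(self, small_design):
        """var/mean of Poisson draws concentrates at 1 for many features."""
        rng = np.random.default_rng(14)
        b6ctrl = small_design[(small_design["strain"] == "B6")
                              & (small_design["treatment"] == "Ctrl")]
        counts = pd.DataFrame(rng.poisson(10, (10_000, len(small_design))),
                              columns=small_design.index)
        model = StrainResponseModel(counts, small_design)
        fano = model.fano_factor({"strain": "B6", "treatment": "Ctrl"})
        assert 0.95 <= fano.mean() <= 1.05

    def test_constant_feature_has_zero_fano(self, small_design):
        counts = pd.DataFrame(
            np.vstack([np.full(len(small_design), 7),
                       np.arange(len(small_design)) + 1]),
            columns=small_design.index)
        model = StrainResponseModel(
            counts, small_design,
            size_factors=pd.Series(1.0, index=small_design.index))
        fano = model.fano_factor({"strain": "B6", "treatment": "Ctrl"})
        assert fano.iloc[0] == 0.0

    def test_nb_fano_matches_moment_identity(self, small_design):
        """NB(mu=100, alpha=0.1) has Fano = 1 + alpha*mu = 11."""
        rng = np.random.default_rng(15)
        draws = _nb_draw(rng, np.full((10_000, 3), 100.0), 0.1)
        fano = draws.var(axis=1, ddof=1) / draws.mean(axis=1)
        assert abs(fano.mean() - 11.0) / 11.0 < 0.1

    def test_zero_mean_feature_flagged_undefined(self, small_design):
        counts = pd.DataFrame(np.vstack([np.zeros(len(small_design), int),
                                         np.full(len(small_design), 5)]),
                              columns=small_design.index)
        model = StrainResponseModel(
            counts, small_design,
            size_factors=pd.Series(1.0, index=small_design.index))
        fano = model.fano_factor({"strain": "B6", "treatment": "Ctrl"})
        assert np.isnan(fano.iloc[0])


class TestSynergy:
    def test_additive_genes_score_near_zero(self, default_cohort):
        model = StrainResponseModel(default_cohort.rna_counts,
                                    default_cohort.design)
        syn = model.synergy_scores("BALB")  # no synergy planted in BALB
        planted = set(default_cohort.truth.synergy_genes)
        additive = [g for g in syn.index if g not in planted]
        assert abs(syn.loc[additive, "score"].mean()) < 0.2

    def test_planted_synergy_flagged(self, default_cohort):
        model = StrainResponseModel(default_cohort.rna_counts,
                                    default_cohort.design)
        syn = model.synergy_scores("B6")
        planted = list(default_cohort.truth.synergy_genes)
        assert syn.loc[planted, "synergy"].mean() >= 0.8

    def test_score_finite_with_zero_control_mean(self, small_design):
        rows = []
        for strain in ("B6", "BALB"):
            for treat in ("Ctrl", "IL4", "LPS", "IL4+LPS"):
                for rep in (1, 2):
                    rows.append((f"{strain}_{treat}_{rep}", strain, treat, rep))
        design = pd.DataFrame(rows, columns=["sample", "strain", "treatment",
                                             "replicate"]).set_index(
            "sample", drop=False)
        rng = np.random.default_rng(16)
        counts = pd.DataFrame(rng.poisson(20, (10, len(design))),
                              columns=design.index)
        counts.iloc[0] = 0
        counts.iloc[0, -2:] = 50  # only IL4+LPS responds
        model = StrainResponseModel(counts, design)
        syn = model.synergy_scores("BALB")
        assert np.isfinite(syn["score"]).all()

    def test_missing_treatment_rejected(self, small_design):
        rng = np.random.default_rng(17)
        counts = pd.DataFrame(rng.poisson(20, (10, len(small_design))),
                              columns=small_design.index)
        model = StrainResponseModel(counts, small_design)
        with pytest.raises(DesignError):
            model.synergy_scores("B6")  # design lacks LPS / IL4+LPS


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_nb_sampler_poisson_limit(seed):
    """alpha = 0 degenerates to Poisson: var/mean near 1."""
    rng = np.random.default_rng(seed)
    draws = _nb_draw(rng, np.full(10_000, 10.0), 0.0)
    ratio = draws.var(ddof=1) / draws.mean()
    assert 0.9 <= ratio <= 1.1
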