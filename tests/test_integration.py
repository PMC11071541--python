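"""Enhancers, super-enhancers, comparisons and the end-to-end pipeline."""

import os

import numpy as np
import pandas as pd
import pytest

from strainreg import io as sio
from strainreg.countmodels import StrainResponseModel
from strainreg.integration import (
    PipelineError,
    boundary_proximity_test,
    call_enhancers,
    link_enhancers_to_genes,
    partition_expression_test,
    run_pipeline,
    stitch_super_enhancers,
)


def _bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


class TestCallEnhancers:
    def test_supported_peak_is_enhancer(self):
        peaks = _bed([("chr1", 100, 600, "p1", 0.0, ".")])
        k27 = _bed([("chr1", 0, 1_000, "k1", 5.0, ".")])
        assert len(call_enhancers(peaks, k27)) == 1

    def test_unsupported_peak_excluded(self):
        peaks = _bed([("chr1", 100, 600, "p1", 0.0, ".")])
        k27 = _bed([("chr1", 600, 1_000, "k1", 5.0, ".")])
        assert len(call_enhancers(peaks, k27)) == 0

    def test_output_subset_of_induced(self, default_cohort):
        peaks = default_cohort.atac_peaks.head(200)
        enh = call_enhancers(peaks, default_cohort.h3k27ac)
        assert set(enh["name"]) <= set(peaks["name"])


class TestSuperEnhancers:
    def test_stitching_gap_arithmetic(self):
        k27 = _bed([("chr1", 0, 1_000, "a", 1.0, "."),
                    ("chr1", 5_000, 6_000, "b", 1.0, "."),
                    ("chr1", 30_000, 31_000, "c", 1.0, ".")])
        _, stitched = stitch_super_enhancers(k27)
        spans = sorted((r.start, r.end) for r in stitched)
        assert spans == [(0, 6_000), (30_000, 31_000)]

    def test_dominant_region_called_super(self):
        rows = [("chr1", i * 50_000, i * 50_000 + 1_000, f"r{i}", 1.0, ".")
                for i in range(99)]
        rows.append(("chr2", 0, 1_000, "big", 100.0, "."))
        supers, stitched = stitch_super_enhancers(_bed(rows))
        assert [r.constituents for r in supers] == [["big"]]

    def test_slope_one_cutoff_matches_brute_force(self):
        """The called set equals the rank-curve evaluation at every cut."""
        rng = np.random.default_rng(0)
        rows = [("chr1", i * 40_000, i * 40_000 + 500, f"r{i}",
                 float(rng.exponential(5)), ".") for i in range(120)]
        supers, stitched = stitch_super_enhancers(_bed(rows))
        sig = np.array([r.total_signal for r in stitched])
        x = np.arange(len(sig)) / (len(sig) - 1)
        y = (sig - sig[0]) / (sig[-1] - sig[0])
        cut = max(range(len(sig)), key=lambda i: x[i] - y[i])
        assert {id(r) for r in supers} == {id(r) for r in stitched[cut + 1:]}

    def test_constant_signals_call_nothing_and_permutation_invariant(self):
        rows = [("chr1", i * 40_000, i * 40_000 + 500, f"r{i}", 2.0, ".")
                for i in range(50)]
        frame = _bed(rows)
        supers, stitched = stitch_super_enhancers(frame)
        assert supers == []
        shuffled = frame.sample(frac=1, random_state=1).reset_index(drop=True)
        supers2, stitched2 = stitch_super_enhancers(shuffled)
        assert [(r.chrom, r.start, r.end) for r in stitched] == \
            [(r.chrom, r.start, r.end) for r in stitched2]

    def test_signal_conserved_under_stitching(self):
        rng = np.random.default_rng(1)
        rows = [("chr1", int(p), int(p) + 800, f"r{i}",
                 float(rng.exponential(3)), ".")
                for i, p in enumerate(sorted(rng.integers(0, 500_000, 60)))]
        frame = _bed(rows)
        _, stitched = stitch_super_enhancers(frame)
        assert np.isclose(sum(r.total_signal for r in stitched),
                          frame["score"].sum())

    def test_tss_exclusion_drops_promoter_peaks(self):
        k27 = _bed([("chr1", 9_500, 10_500, "at_tss", 50.0, "."),
                    ("chr1", 100_000, 101_000, "far", 5.0, ".")])
        tss = pd.DataFrame({"chrom": ["chr1"], "tss": [10_000]})
        _, stitched = stitch_super_enhancers(k27, tss)
        assert [r.constituents for r in stitched] == [["far"]]

    def test_empty_input_empty_output(self):
        supers, stitched = stitch_super_enhancers(_bed([]))
        assert supers == [] and stitched == []


class TestLinkEnhancers:
    def _ann(self):
        return pd.DataFrame({
            "gene_id": ["g1", "g2"], "chrom": ["chr1", "chr1"],
            "strand": ["+", "+"], "tss": [1_000, 500_000],
            "start": [1_000, 500_000], "end": [3_000, 502_000]})

    def test_gene_counted_once_despite_multiple_elements(self):
        elements = _bed([("chr1", 5_000, 6_000, "e1", 0.0, "."),
                         ("chr1", 8_000, 9_000, "e2", 0.0, ".")])
        out = link_enhancers_to_genes(elements, self._ann(), {"g1"})
        assert out["genes_with_element"] == 1
        assert out["by_gene"]["g1"] == 2

    def test_empty_gene_set_counts_zero(self):
        elements = _bed([("chr1", 5_000, 6_000, "e1", 0.0, ".")])
        out = link_enhancers_to_genes(elements, self._ann(), set())
        assert out["genes_with_element"] == 0

    def test_nearest_gene_assignment(self):
        elements = _bed([("chr1", 499_000, 499_500, "e", 0.0, ".")])
        out = link_enhancers_to_genes(elements, self._ann(), {"g1", "g2"})
        assert out["by_gene"] == {"g2": 1}


class TestPartitionTests:
    def test_planted_partition_detected(self, default_cohort):
        """Bearing genes carry +1.5 log2 extra induction: both tests fire."""
        cohort = default_cohort
        model = StrainResponseModel(cohort.rna_counts, cohort.design)
        bearing = list(cohort.truth.motif_genes)
        lacking = [g for g, i in cohort.truth.interaction_genes.items()
                   if i["strain"] == "B6" and g not in set(bearing)]
        expr, ind = partition_expression_test(
            model, {"bearing": bearing, "lacking": lacking}, "B6")
        assert ind.pvalue < 0.01
        assert ind.mean_a > ind.mean_b

    def test_random_partition_is_null(self, default_cohort):
        cohort = default_cohort
        model = StrainResponseModel(cohort.rna_counts, cohort.design)
        rng = np.random.default_rng(5)
        pvals = []
        genes = [g for g in cohort.annotation["gene_id"]
                 if g not in cohort.truth.interaction_genes
                 and g not in cohort.truth.synergy_genes]
        for _ in range(40):
            perm = rng.permutation(genes)
            part = {"bearing": perm[:60], "lacking": perm[60:120]}
            _, ind = partition_expression_test(model, part, "B6")
            pvals.append(ind.pvalue)
        assert np.mean(np.array(pvals) <= 0.05) < 0.2

    def test_degenerate_group_rejected(self, default_cohort):
        model = StrainResponseModel(default_cohort.rna_counts,
                                    default_cohort.design)
        genes = list(default_cohort.annotation["gene_id"])
        with pytest.raises(ValueError):
            partition_expression_test(
                model, {"bearing": genes[:1], "lacking": genes[1:10]}, "B6")

    def test_constant_groups_flagged_degenerate(self):
        from strainreg.integration import _welch
        out = _welch([1.0, 1.0, 1.0], [1.0, 1.0], "a", "b")
        assert out.degenerate and np.isnan(out.pvalue)


class TestBoundaryProximity:
    def test_planted_groups_separate(self, default_cohort):
        from strainreg.chromatin import boundary_distances, tad_boundaries
        from strainreg.intervals import promoter_windows

        cohort = default_cohort
        bounds = tad_boundaries(cohort.tads["B6"], 100_000,
                                cohort.chrom_lengths)
        promoters = promoter_windows(cohort.annotation, cohort.chrom_lengths)
        dist = boundary_distances(promoters, bounds)
        res = boundary_proximity_test(
            dist.loc[cohort.truth.boundary_genes],
            dist.loc[cohort.truth.center_genes], "boundary", "center")
        assert res.pvalue < 0.01
        assert res.mean_a < res.mean_b

    def test_identical_groups_not_significant_on_average(self):
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(100):
            a = rng.exponential(50_000, size=30)
            b = rng.exponential(50_000, size=30)
            pvals.append(boundary_proximity_test(a, b).pvalue)
        assert np.mean(pvals) > 0.3

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            boundary_proximity_test([0.0, 10.0, -5.0], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    from strainreg.simulate import (CohortSimulator, SimulationConfig,
                                    write_fixture)
    out = tmp_path_factory.mktemp("fixture")
    cfg = SimulationConfig(seed=31, n_genes=220)
    write_fixture(CohortSimulator(cfg).run(), out)
    return str(out)


class TestPipeline:
    def test_full_run_writes_expected_tables(self, fixture_dir, tmp_path):
        cfg = sio.RunConfig(fixture_dir=fixture_dir,
                            out_dir=str(tmp_path / "out"), seed=31)
        report = run_pipeline(cfg)
        for table in ("pairwise_induced", "interaction_summary",
                      "cluster_sizes", "peak_overlap",
                      "enhancer_association", "partition_tests",
                      "boundary_distance", "recovery"):
            assert table in report.tables
            assert os.path.exists(os.path.join(report.out_dir,
                                               f"{table}.tsv"))
        assert os.path.exists(os.path.join(report.out_dir, "run_log.json"))
        rec = report.tables["recovery"].set_index("metric")["value"]
        assert rec["interaction_sensitivity_B6"] >= 0.8
        assert rec["motif_partition_sensitivity"] == 1.0

    def test_rerun_reproduces_identical_tables(self, fixture_dir, tmp_path):
        cfg1 = sio.RunConfig(fixture_dir=fixture_dir,
                             out_dir=str(tmp_path / "o1"), seed=31)
        cfg2 = sio.RunConfig(fixture_dir=fixture_dir,
                             out_dir=str(tmp_path / "o2"), seed=31)
        r1, r2 = run_pipeline(cfg1), run_pipeline(cfg2)
        for name in r1.tables:
            p1 = os.path.join(r1.out_dir, f"{name}.tsv")
            p2 = os.path.join(r2.out_dir, f"{name}.tsv")
            assert open(p1, "rb").read() == open(p2, "rb").read()

    def test_missing_input_fails_fast_with_stage(self, fixture_dir, tmp_path):
        import shutil
        broken = tmp_path / "broken"
        shutil.copytree(fixture_dir, broken)
        os.remove(broken / "loops.bedpe")
        cfg = sio.RunConfig(fixture_dir=str(broken),
                            out_dir=str(tmp_path / "out"), seed=31)
        with pytest.raises(PipelineError, match="inputs"):
            run_pipeline(cfg)

    def test_invalid_threshold_rejected_before_compute(self, fixture_dir,
                                                       tmp_path):
        cfg = sio.RunConfig(fixture_dir=fixture_dir,
                            out_dir=str(tmp_path / "out"), atac_fdr=1.5)
        with pytest.raises(ValueError):
            run_pipeline(cfg)
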