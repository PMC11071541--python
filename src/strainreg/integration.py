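"""Composite regulatory analyses and the end-to-end pipeline.

Enhancers are induced accessibility peaks supported by >= 1 bp of H3K27ac
overlap; super-enhancers are stitched H3K27ac clusters above the slope-1
cutoff on the rank-ordered total-signal curve (ROSE-style: 12.5 kb
stitching, +/- 2 kb TSS exclusion).  Group comparisons (motif-partition
expression/induction, promoter-to-boundary distances) use Welch's unpaired
two-sided t-test.

``run_pipeline`` chains the whole analysis on a fixture directory and
writes deterministic TSV report tables plus a machine-readable run log.
"""

from __future__ import annotations

import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from . import chromatin, countmodels, intervals, motifs
from . import io as sio


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# enhancers
# ---------------------------------------------------------------------------

def call_enhancers(induced_peaks: pd.DataFrame,
                   h3k27ac: pd.DataFrame) -> pd.DataFrame:
    """Induced ATAC peaks with >= 1 bp H3K27ac support; peak geometry kept."""
    return intervals.intersect(induced_peaks, h3k27ac, min_bp=1)


@dataclass
class SuperEnhancer:
    chrom: str
    start: int
    end: int
    constituents: list
    total_signal: float
    rank: int = -1


def stitch_super_enhancers(h3k27ac: pd.DataFrame,
                           tss_positions: pd.DataFrame | None = None,
                           stitch: int = 12_500,
                           tss_exclusion: int = 2_000):
    """Stitch H3K27ac peaks and call super-enhancers at the slope-1 cutoff.

    Peaks within ``tss_exclusion`` bp of a TSS are dropped, the remainder
    merged when gaps are <= ``stitch``.  Stitched regions are ranked by
    total signal; with rank and signal both rescaled to [0, 1], regions
    beyond the point where the signal curve's tangent reaches slope 1 (the
    point farthest below the diagonal) are super-enhancers.

    Returns ``(super_enhancers, stitched)`` where both are lists of
    :class:`SuperEnhancer`; ``stitched`` is every region, rank-ordered by
    ascending signal.
    """
    peaks = h3k27ac.copy()
    if tss_positions is not None and len(tss_positions) and len(peaks):
        keep = []
        for row in peaks.itertuples(index=False):
            tss = tss_positions.loc[tss_positions["chrom"] == row.chrom, "tss"]
            if len(tss):
                gap = np.maximum(tss.to_numpy() - row.end,
                                 row.start - tss.to_numpy())
                gap = np.maximum(gap, 0)
                keep.append(bool((gap > tss_exclusion).all()))
            else:
                keep.append(True)
        peaks = peaks.loc[np.array(keep, dtype=bool)]
    if peaks.empty:
        return [], []

    peaks = peaks.sort_values(["chrom", "start", "end", "name"],
                              kind="stable")
    stitched: list[SuperEnhancer] = []
    for chrom, sub in peaks.groupby("chrom", sort=True):
        cur = None
        for row in sub.itertuples(index=False):
            if cur is None or row.start - cur.end > stitch:
                if cur is not None:
                    stitched.append(cur)
                cur = SuperEnhancer(chrom, int(row.start), int(row.end),
                                    [row.name], float(row.score))
            else:
                cur.end = max(cur.end, int(row.end))
                cur.constituents.append(row.name)
                cur.total_signal += float(row.score)
        if cur is not None:
            stitched.append(cur)

    # rank ascending by signal; deterministic tie-break on coordinates
    stitched.sort(key=lambda r: (r.total_signal, r.chrom, r.start, r.end))
    for i, r in enumerate(stitched):
        r.rank = i
    n = len(stitched)
    if n == 1:
        return list(stitched), stitched
    sig = np.array([r.total_signal for r in stitched])
    x = np.arange(n) / (n - 1)
    span = sig[-1] - sig[0]
    if span <= 0:
        return [], stitched  # flat curve: no point is above a slope-1 tangent
    y = (sig - sig[0]) / span
    cut = int(np.argmax(x - y))  # farthest below the diagonal = slope-1 point
    supers = [r for r in stitched[cut + 1:]]
    return supers, stitched


def link_enhancers_to_genes(elements, annotation: pd.DataFrame,
                            gene_set) -> dict:
    """Count genes in ``gene_set`` with >= 1 nearest-TSS-associated element.

    ``elements`` is a BED-like frame or a list of :class:`SuperEnhancer`.
    Returns ``{"genes_with_element": int, "by_gene": {gene: count},
    "assignments": frame}``.
    """
    if isinstance(elements, list):
        frame = pd.DataFrame(
            [(e.chrom, e.start, e.end) for e in elements],
            columns=["chrom", "start", "end"])
    else:
        frame = elements[["chrom", "start", "end"]].copy()
    gene_set = set(gene_set)
    by_gene: dict = {}
    assignments = []
    for row in frame.itertuples(index=False):
        gene, dist = intervals.nearest_tss(row, annotation)
        assignments.append((row.chrom, row.start, row.end, gene, dist))
        if gene in gene_set:
            by_gene[gene] = by_gene.get(gene, 0) + 1
    return {
        "genes_with_element": len(by_gene),
        "by_gene": by_gene,
        "assignments": pd.DataFrame(
            assignments,
            columns=["chrom", "start", "end", "gene_id", "distance"]),
    }


# ---------------------------------------------------------------------------
# group comparisons (Welch t-tests)
# ---------------------------------------------------------------------------

@dataclass
class PartitionComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_stat: float
    pvalue: float
    test: str = "Welch t-test, two-sided"
    degenerate: bool = False

    def summary(self) -> str:
        return (f"{self.label_a} (n={self.n_a}, mean={self.mean_a:.4g} "
                f"sd={self.sd_a:.4g}) vs {self.label_b} (n={self.n_b}, "
                f"mean={self.mean_b:.4g} sd={self.sd_b:.4g}): "
                f"t={self.t_stat:.3f}, p={self.pvalue:.3g} [{self.test}]")


def _welch(values_a, values_b, label_a, label_b) -> PartitionComparison:
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"degenerate group sizes ({len(a)}, {len(b)}); need >= 2 each")
    degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
    if degenerate:
        t, p = np.nan, np.nan
    else:
        t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
        p = float(min(max(p, np.finfo(float).tiny), 1.0))
        t = float(t)
    return PartitionComparison(label_a, label_b, len(a), len(b),
                               float(a.mean()), float(b.mean()),
                               float(a.std(ddof=1)), float(b.std(ddof=1)),
                               t, p, degenerate=degenerate)


def partition_expression_test(model: countmodels.StrainResponseModel,
                              partition: dict, strain,
                              treated: str = "IL4", control: str = "Ctrl",
                              pseudocount: float = 1.0):
    """Expression and induction of motif-bearing vs motif-lacking genes.

    Two Welch two-sided t-tests within one strain: (a) normalized
    expression in the treated condition; (b) per-gene log2 induction
    (treated vs control, pseudocount on normalized means).
    """
    bearing = list(partition["bearing"])
    lacking = list(partition["lacking"])
    mean_t = model.group_mean({"strain": strain, "treatment": treated})
    mean_c = model.group_mean({"strain": strain, "treatment": control})
    induction = np.log2(mean_t + pseudocount) - np.log2(mean_c + pseudocount)
    expr = _welch(mean_t.loc[bearing], mean_t.loc[lacking],
                  "bearing", "lacking")
    ind = _welch(induction.loc[bearing], induction.loc[lacking],
                 "bearing", "lacking")
    return expr, ind


def boundary_proximity_test(distances_a, distances_b,
                            label_a="group A",
                            label_b="group B") -> PartitionComparison:
    """Welch two-sided t-test on promoter-to-boundary distances (gaps >= 0)."""
    for name, vals in ((label_a, distances_a), (label_b, distances_b)):
        arr = np.asarray(vals, dtype=float)
        if (arr[np.isfinite(arr)] < 0).any():
            raise ValueError(f"{name}: negative distances are invalid gaps")
    return _welch(distances_a, distances_b, label_a, label_b)


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineReport:
    tables: dict
    run_log: dict
    out_dir: str


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


def _require(path, stage):
    if not os.path.exists(path):
        raise PipelineError(stage, f"required input missing: {path}")
    return path


def run_pipeline(config: sio.RunConfig) -> PipelineReport:
    """Execute the full analysis chain on a fixture directory.

    Stages: (simulate) -> normalize -> pairwise DE -> interaction LRT ->
    k-means profiles -> synergy -> peak classification -> enhancers and
    super-enhancers -> loop distal assignment -> motif partition ->
    boundary distances -> comparisons -> report tables.  Identical config
    and seed reproduce byte-identical tables.
    """
    from .simulate import (STRAINS, CohortSimulator, SimulationConfig,
                           load_fixture, write_fixture)

    config.validate()
    t0 = time.time()
    os.makedirs(config.out_dir, exist_ok=True)
    fixture_dir = config.fixture_dir

    if config.simulate:
        sim_cfg = SimulationConfig(seed=config.seed)
        cohort = CohortSimulator(sim_cfg).run()
        fixture_dir = fixture_dir or os.path.join(config.out_dir, "fixture")
        write_fixture(cohort, fixture_dir)
    else:
        if not fixture_dir:
            raise PipelineError("inputs", "fixture_dir not set and simulate=false")
        for fname in ("design.tsv", "rna_counts.tsv", "genes.tsv",
                      "atac_peaks.bed", "atac_counts.tsv", "h3k27ac.bed",
                      "loops.bedpe", "motifs.meme"):
            _require(os.path.join(fixture_dir, fname), "inputs")
        cohort = load_fixture(fixture_dir)

    tables: dict[str, pd.DataFrame] = {}
    log: dict = {
        "seed": config.seed,
        "thresholds": {
            "de_fdr": config.de_fdr, "de_lfc": config.de_lfc,
            "atac_fdr": config.atac_fdr, "scan_p": config.scan_p,
            "tad_flank": config.tad_flank, "stitch": config.stitch,
            "tss_exclusion": config.tss_exclusion,
            "reciprocal": config.reciprocal,
            "k_values": list(config.k_values),
        },
        "stages": [],
    }

    def done(stage):
        log["stages"].append(stage)

    # ---- expression statistics ------------------------------------------
    model = _stage("normalize")(countmodels.StrainResponseModel)(
        cohort.rna_counts, cohort.design)
    strains = model.strains
    done("normalize")

    @_stage("pairwise_de")
    def _de():
        rows = []
        induced = {}
        for strain in strains:
            de = model.fit_pairwise({"strain": strain, "treatment": config.control},
                                    {"strain": strain, "treatment": config.treated},
                                    config.de_fdr, config.de_lfc)
            up = de.frame.index[de.frame["pass"] & (de.frame["lfc"] > 0)]
            induced[strain] = set(up)
            rows.append((strain, len(up)))
        shared = len(induced[strains[0]] & induced[strains[1]])
        rows.append(("shared", shared))
        tables["pairwise_induced"] = pd.DataFrame(
            rows, columns=["group", "n_induced"])
        return induced
    induced_genes = _de()
    done("pairwise_de")

    @_stage("interaction_lrt")
    def _lrt():
        res = model.fit_interaction(config.de_fdr)
        specific = {s: res.strain_specific(s) for s in strains}
        tables["interaction_summary"] = pd.DataFrame(
            [(s, len(specific[s])) for s in strains] +
            [("significant_total",
              int((res.frame["fdr"] <= config.de_fdr).sum()))],
            columns=["group", "n_genes"])
        return res, specific
    lrt, strain_specific = _lrt()
    done("interaction_lrt")

    @_stage("kmeans_profiles")
    def _cluster():
        sig = lrt.frame.index[lrt.frame["fdr"] <= config.de_fdr]
        ctrl = {s: model.group_mean({"strain": s, "treatment": config.control})
                for s in strains}
        cols = {}
        for s in strains:
            for t in [t for t in model.treatments if t != config.control]:
                m = model.group_mean({"strain": s, "treatment": t})
                cols[f"{s}:{t}"] = (np.log2(m + 1)
                                    - np.log2(ctrl[s] + 1))
        profiles = pd.DataFrame(cols).loc[sig]
        rows = []
        for k in config.k_values:
            if len(profiles) < k:
                continue
            res = countmodels.kmeans_profiles(profiles, k, seed=config.seed)
            for c, size in res.sizes().items():
                rows.append((k, c, int(size)))
        tables["cluster_sizes"] = pd.DataFrame(
            rows, columns=["k", "cluster", "n_genes"])
    _cluster()
    done("kmeans_profiles")

    @_stage("synergy")
    def _synergy():
        rows = []
        for s in strains:
            if set(model.design.loc[model.design["strain"] == s, "treatment"]) \
                    >= {"Ctrl", "IL4", "LPS", "IL4+LPS"}:
                syn = model.synergy_scores(s)
                rows.append((s, int(syn["synergy"].sum()),
                             float(syn["score"].mean())))
        tables["synergy"] = pd.DataFrame(
            rows, columns=["strain", "n_synergy_genes", "mean_score"])
    _synergy()
    done("synergy")

    # ---- accessibility ---------------------------------------------------
    @_stage("peak_classification")
    def _peaks():
        classes = {}
        for s in strains:
            cls = intervals.classify_peaks(
                cohort.atac_counts, cohort.design,
                {"strain": s, "treatment": config.treated},
                {"strain": s, "treatment": config.control},
                config.atac_fdr)
            classes[s] = cls
        peaks = cohort.atac_peaks.set_index("name")
        rows = []
        sets = {}
        for label in ("constitutive", "induced"):
            per_strain = {}
            for s in strains:
                ids = classes[s].index[classes[s]["label"] == label]
                per_strain[s] = peaks.loc[ids].reset_index()
            shared_a, _, unique_a, unique_b = intervals.strain_peak_overlap(
                per_strain[strains[0]], per_strain[strains[1]])
            rows.append((label, len(shared_a), len(unique_a), len(unique_b)))
            sets[label] = per_strain
        tables["peak_overlap"] = pd.DataFrame(
            rows, columns=["class", "shared", f"unique_{strains[0]}",
                           f"unique_{strains[1]}"])
        return classes, sets
    peak_classes, peak_sets = _peaks()
    done("peak_classification")

    @_stage("enhancers")
    def _enhancers():
        rows = []
        enhancers = {}
        tss_frame = cohort.annotation[["chrom", "tss"]]
        supers, stitched = stitch_super_enhancers(
            cohort.h3k27ac, tss_frame, config.stitch, config.tss_exclusion)
        for s in strains:
            enh = call_enhancers(peak_sets["induced"][s], cohort.h3k27ac)
            enhancers[s] = enh
            linked = link_enhancers_to_genes(enh, cohort.annotation,
                                             strain_specific[s])
            se_linked = link_enhancers_to_genes(supers, cohort.annotation,
                                                strain_specific[s])
            rows.append((s, len(enh), len(strain_specific[s]),
                         linked["genes_with_element"],
                         se_linked["genes_with_element"]))
        tables["enhancer_association"] = pd.DataFrame(
            rows, columns=["strain", "n_enhancers", "n_specific_genes",
                           "genes_with_enhancer", "genes_with_super_enhancer"])
        tables["super_enhancers"] = pd.DataFrame(
            [(r.chrom, r.start, r.end, len(r.constituents), r.total_signal)
             for r in supers],
            columns=["chrom", "start", "end", "n_constituents", "total_signal"])
        return enhancers, supers
    _enh = _enhancers()
    done("enhancers")

    # ---- 3D genome -------------------------------------------------------
    designated = cohort.config.designated_strain \
        if hasattr(cohort.config, "designated_strain") else strains[0]
    chrom_lengths = cohort.chrom_lengths
    promoters = intervals.promoter_windows(cohort.annotation, chrom_lengths)

    @_stage("loop_assignment")
    def _loops():
        anchors = chromatin.promoter_loops(cohort.loops, promoters)
        distal = chromatin.accessible_distal_elements(anchors,
                                                      cohort.atac_peaks)
        return anchors, distal
    gene_anchors, gene_distal = _loops()
    done("loop_assignment")

    @_stage("motif_partition")
    def _partition():
        genome = cohort.genomes.get(designated)
        if genome is None:
            raise PipelineError("motif_partition",
                                f"no genome for strain {designated}")
        genes = list(strain_specific[designated])
        part = motifs.motif_partition(genes, promoters, gene_distal, genome,
                                      cohort.pwm, p_target=config.scan_p)
        expr, ind = partition_expression_test(
            model, part, designated, config.expression_condition,
            config.control)
        tables["partition_tests"] = pd.DataFrame([
            ("expression", expr.n_a, expr.n_b, expr.mean_a, expr.mean_b,
             expr.t_stat, expr.pvalue),
            ("induction", ind.n_a, ind.n_b, ind.mean_a, ind.mean_b,
             ind.t_stat, ind.pvalue),
        ], columns=["comparison", "n_bearing", "n_lacking", "mean_bearing",
                    "mean_lacking", "t_stat", "pvalue"])
        return part
    partition = _partition()
    done("motif_partition")

    @_stage("tad_boundaries")
    def _tads():
        tads = cohort.tads.get(designated)
        if tads is None or not len(cohort.tads):
            raise PipelineError("tad_boundaries", "no TAD input available")
        bounds = chromatin.tad_boundaries(tads, config.tad_flank,
                                          chrom_lengths)
        prom_by_gene = promoters.set_index("name")
        dist = {}
        for s in strains:
            rows = prom_by_gene.loc[[g for g in strain_specific[s]
                                     if g in prom_by_gene.index]]
            dist[s] = chromatin.boundary_distances(rows.reset_index(), bounds)
        comparison = boundary_proximity_test(
            dist[strains[0]].dropna(), dist[strains[1]].dropna(),
            strains[0], strains[1])
        tables["boundary_distance"] = pd.DataFrame([
            (strains[0], comparison.n_a, comparison.mean_a, comparison.sd_a),
            (strains[1], comparison.n_b, comparison.mean_b, comparison.sd_b),
        ], columns=["strain", "n_genes", "mean_distance", "sd_distance"])
        tables["boundary_distance_test"] = pd.DataFrame(
            [(comparison.t_stat, comparison.pvalue, comparison.test)],
            columns=["t_stat", "pvalue", "test"])
        # Fano factors of the strain-specific sets in the treated condition
        rows = []
        for s in strains:
            fano = model.fano_factor({"strain": s,
                                      "treatment": config.treated},
                                     features=[g for g in strain_specific[s]])
            rows.append((s, int(fano.notna().sum()),
                         float(fano.mean(skipna=True))))
        tables["fano"] = pd.DataFrame(
            rows, columns=["strain", "n_genes", "mean_fano"])
        if len(cohort.tads) == 2:
            a, b = (cohort.tads[s] for s in strains)
            shared_a, _, unique_a, unique_b = chromatin.compare_tads(
                a, b, config.reciprocal)
            tables["tad_sharing"] = pd.DataFrame(
                [(len(shared_a), len(unique_a), len(unique_b))],
                columns=["shared", f"unique_{strains[0]}",
                         f"unique_{strains[1]}"])
    _tads()
    done("tad_boundaries")

    # ---- ground-truth recovery ------------------------------------------
    @_stage("recovery")
    def _recovery():
        truth = cohort.truth
        if not truth.interaction_genes:
            return
        rows = []
        frame = lrt.frame
        planted = {s: [g for g, i in truth.interaction_genes.items()
                       if i["strain"] == s] for s in strains}
        for s in strains:
            ids = [g for g in planted[s] if g in frame.index]
            if not ids:
                continue
            sub = frame.loc[ids]
            hit = (sub["fdr"] <= config.de_fdr) & (sub["direction"] == s)
            rows.append((f"interaction_sensitivity_{s}",
                         float(hit.mean())))
        null_ids = [g for g in frame.index
                    if g not in truth.interaction_genes]
        if null_ids:
            rows.append(("interaction_null_fdr_rate",
                         float((frame.loc[null_ids, "fdr"]
                                <= config.de_fdr).mean())))
        cls = peak_classes[designated]
        planted_peaks = [p for p, s in truth.induced_peaks.items()
                         if s == designated and p in cls.index]
        if planted_peaks:
            rows.append(("peak_sensitivity",
                         float((cls.loc[planted_peaks, "label"]
                                == "induced").mean())))
        null_peaks = [p for p in cls.index if p not in truth.induced_peaks]
        if null_peaks:
            rows.append(("peak_null_mislabel_rate",
                         float((cls.loc[null_peaks, "label"]
                                != "constitutive").mean())))
        motif_genes = [g for g in truth.motif_genes
                       if g in set(partition["bearing"])
                       | set(partition["lacking"])]
        if motif_genes:
            rows.append(("motif_partition_sensitivity",
                         float(np.mean([g in set(partition["bearing"])
                                        for g in motif_genes]))))
        tables["recovery"] = pd.DataFrame(rows, columns=["metric", "value"])
    _recovery()
    done("recovery")

    # ---- write report ----------------------------------------------------
    for name, frame in sorted(tables.items()):
        sio.write_tsv(frame, os.path.join(config.out_dir, f"{name}.tsv"))
    log["tables"] = sorted(tables)
    log["wall_time_s"] = round(time.time() - t0, 3)
    sio.write_json(log, os.path.join(config.out_dir, "run_log.json"))
    return PipelineReport(tables, log, config.out_dir)
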