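"""Synthetic two-strain, four-condition multi-omics cohort with planted truth.

The generator emulates the study design the downstream statistics expect:
two inbred strains (B6, BALB) x four treatments (Ctrl, IL4, LPS, IL4+LPS)
with three replicates per cell.  It emits, deterministically from one
seed:

* a gene annotation with non-overlapping genes whose promoters are placed
  at controlled distances from TAD boundaries,
* per-strain genome FASTA differing only at logged SNP positions (placed
  outside planted motif sites by default),
* an RNA count matrix drawn from NB(mu, alpha) under
  ``log2 mu = baseline + strain + treatment (+ planted interaction,
  + planted synergy)`` with log-normal size factors,
* an ATAC peak set and peak count matrix with planted condition-gained
  peaks in the designated strain,
* H3K27ac regions (enhancer support and super-enhancer clusters with
  signal),
* chromatin loops connecting each planted gene's promoter to a distal
  anchor that carries an accessible peak with a planted motif occurrence,
* TADs tiling each chromosome, and
* a JSON ground-truth record of everything planted.

All randomness flows from one seeded generator, split into named
sub-streams so enlarging one component does not perturb the others.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io as sio
from .motifs import PWM

STRAINS = ("B6", "BALB")
TREATMENTS = ("Ctrl", "IL4", "LPS", "IL4+LPS")
NFKB_CONSENSUS = "GGGAATTTCC"
GENE_LENGTH = 2_000
PEAK_WIDTH = 500

_STREAMS = ("annotation", "sequence", "counts", "landscape", "peaks")


class SizingError(ValueError):
    """Raised when the requested genes do not fit on the chromosomes."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_genes: int = 1_000
    n_chromosomes: int = 2
    chrom_length: int = 4_000_000
    n_replicates: int = 3
    baseline_mean: float = 100.0
    baseline_sd: float = 0.5          # per-gene log2 spread of baselines
    strain_effect_sd: float = 0.25    # shared additive strain effect (log2)
    treatment_effect_sd: float = 0.5  # per-gene treatment effect (log2)
    dispersion: float = 0.05
    frac_interaction_genes: float = 0.2
    planted_lfc: float = 2.0
    frac_motif_genes: float = 0.5
    motif_extra_induction: float = 1.5
    frac_synergy_genes: float = 0.05
    synergy_offset: float = 1.5
    lfc_range: tuple = (1.0, 3.0)       # spread of non-planted treatment effects
    tad_size_range: tuple = (300_000, 500_000)
    loop_anchor_width: int = 5_000
    boundary_flank: int = 100_000
    peak_baseline: float = 50.0
    accessibility_fold: float = 4.0
    n_background_peaks: int = 300
    n_background_k27ac: int = 200
    n_se_genes: int = 20
    n_decoy_loops: int = 20
    snp_rate: float = 1e-3
    size_factor_sd: float = 0.1
    motif_consensus: str = NFKB_CONSENSUS
    plant_disrupting_snps: bool = False
    designated_strain: str = "B6"
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        for attr in ("n_genes", "n_chromosomes", "chrom_length",
                     "n_replicates", "loop_anchor_width"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        for attr in ("frac_interaction_genes", "frac_motif_genes",
                     "frac_synergy_genes"):
            if not 0 <= getattr(self, attr) <= 1:
                raise ValueError(f"{attr} must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.loop_anchor_width > self.tad_size_range[0]:
            raise ValueError("loop anchor width exceeds the smallest TAD")
        if self.designated_strain not in STRAINS:
            raise ValueError(f"designated_strain must be one of {STRAINS}")
        return self


@dataclass
class GroundTruth:
    """Record of every planted feature, exactly recoverable from the files."""

    interaction_genes: dict = field(default_factory=dict)   # gene -> {strain, lfc}
    synergy_genes: dict = field(default_factory=dict)       # gene -> offset
    motif_genes: list = field(default_factory=list)
    motif_sites: list = field(default_factory=list)         # dicts with intervals
    induced_peaks: dict = field(default_factory=dict)       # peak -> strain
    boundary_genes: list = field(default_factory=list)
    center_genes: list = field(default_factory=list)
    snp_positions: dict = field(default_factory=dict)       # chrom -> [pos]
    tads: list = field(default_factory=list)
    se_genes: list = field(default_factory=list)

    def to_json(self, path) -> None:
        sio.write_json(asdict(self), path)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**sio.read_json(path))


@dataclass
class Cohort:
    """Everything the generator produced, in memory."""

    config: SimulationConfig
    truth: GroundTruth
    annotation: pd.DataFrame
    genomes: dict                    # strain -> {chrom: sequence}
    rna_counts: pd.DataFrame
    design: pd.DataFrame
    atac_peaks: pd.DataFrame
    atac_counts: pd.DataFrame
    h3k27ac: pd.DataFrame
    loops: pd.DataFrame
    tads: dict                       # strain -> BED frame
    pwm: PWM

    @property
    def chrom_lengths(self) -> dict:
        genome = next(iter(self.genomes.values()))
        return {c: len(s) for c, s in genome.items()}


def _rng_streams(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss)
            for name, ss in zip(_STREAMS, children)}


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             alpha: float) -> np.ndarray:
    """NB(mu, alpha) with var = mu + alpha mu^2; alpha = 0 is Poisson."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

class CohortSimulator:
    """Deterministic generator for the full multi-omics fixture."""

    def __init__(self, config: SimulationConfig):
        self.config = config.validate()
        self.rngs = _rng_streams(config.seed)
        self.truth = GroundTruth()

    # -- gene sets ---------------------------------------------------------

    def _assign_gene_roles(self):
        cfg = self.config
        n = cfg.n_genes
        gene_ids = [f"g{i:05d}" for i in range(n)]
        n_inter = int(round(cfg.frac_interaction_genes * n))
        n_each = n_inter // 2
        designated = cfg.designated_strain
        other = [s for s in STRAINS if s != designated][0]
        inter_designated = gene_ids[:n_each]
        inter_other = gene_ids[n_each:2 * n_each]
        rest = gene_ids[2 * n_each:]
        n_motif = int(round(cfg.frac_motif_genes * len(inter_designated)))
        motif_genes = inter_designated[:n_motif]
        n_syn = int(round(cfg.frac_synergy_genes * n))
        synergy = rest[:n_syn]
        se_genes = inter_designated[:min(cfg.n_se_genes, len(inter_designated))]
        return (gene_ids, {designated: inter_designated, other: inter_other},
                motif_genes, synergy, se_genes)

    # -- annotation + TADs -------------------------------------------------

    def generate_annotation(self):
        """Place TADs and genes; boundary/center placement follows roles."""
        cfg = self.config
        rng = self.rngs["annotation"]
        (gene_ids, inter_by_strain, motif_genes, synergy_genes,
         se_genes) = self._assign_gene_roles()
        designated = cfg.designated_strain
        other = [s for s in STRAINS if s != designated][0]

        chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
        tad_rows = []
        junctions = {}
        for chrom in chroms:
            pos = 0
            edges = [0]
            while pos < cfg.chrom_length:
                size = int(rng.integers(cfg.tad_size_range[0],
                                        cfg.tad_size_range[1] + 1))
                end = min(pos + size, cfg.chrom_length)
                if end - pos < cfg.tad_size_range[0] // 2:
                    break
                tad_rows.append((chrom, pos, end))
                edges.append(end)
                pos = end
            junctions[chrom] = edges[1:-1]  # interior junctions only
        tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end"])

        # candidate TSS slots: boundary slots hug interior junctions (inside
        # the +/- flank), center slots sit mid-TAD, generic slots on a grid
        slot_gap = 6_000
        boundary_slots, center_slots = [], []
        margin = cfg.boundary_flank // 2 - GENE_LENGTH
        for chrom in chroms:
            for j in junctions[chrom]:
                for off in range(-margin, margin, slot_gap):
                    boundary_slots.append((chrom, j + off))
            for tad in tads[tads["chrom"] == chrom].itertuples(index=False):
                mid = (tad.start + tad.end) // 2
                half = (tad.end - tad.start) // 2 - cfg.boundary_flank \
                    - GENE_LENGTH
                span = min(half, 40_000)
                if span <= 0:
                    continue
                for off in range(-span, span, slot_gap):
                    center_slots.append((chrom, mid + off))

        n_boundary = len(inter_by_strain[designated])
        n_center = len(inter_by_strain[other])
        if n_boundary > len(boundary_slots):
            raise SizingError(
                f"{n_boundary} boundary genes requested but only "
                f"{len(boundary_slots)} slots fit; enlarge the chromosomes")
        if n_center > len(center_slots):
            raise SizingError(
                f"{n_center} center genes requested but only "
                f"{len(center_slots)} slots fit; enlarge the chromosomes")

        def spread(slots, k):
            idx = np.linspace(0, len(slots) - 1, num=k).astype(int)
            return [slots[i] for i in idx]

        chosen_boundary = spread(boundary_slots, n_boundary)
        chosen_center = spread(center_slots, n_center)
        used = set(p for p in chosen_boundary) | set(chosen_center)

        n_rest = cfg.n_genes - n_boundary - n_center
        grid = []
        for chrom in chroms:
            for pos in range(50_000, cfg.chrom_length - 50_000, slot_gap):
                near_used = any(c == chrom and abs(pos - p) < slot_gap
                                for c, p in used)
                if not near_used:
                    grid.append((chrom, pos))
        if n_rest > len(grid):
            raise SizingError(
                f"{cfg.n_genes} genes do not fit on "
                f"{cfg.n_chromosomes} x {cfg.chrom_length} bp")
        chosen_rest = spread(grid, n_rest) if n_rest else []

        placements = {}
        boundary_gene_ids = inter_by_strain[designated]
        center_gene_ids = inter_by_strain[other]
        rest_ids = [g for g in gene_ids
                    if g not in set(boundary_gene_ids) | set(center_gene_ids)]
        for gid, slot in zip(boundary_gene_ids, chosen_boundary):
            placements[gid] = slot
        for gid, slot in zip(center_gene_ids, chosen_center):
            placements[gid] = slot
        for gid, slot in zip(rest_ids, chosen_rest):
            placements[gid] = slot

        rows = []
        strands = rng.choice(["+", "-"], size=cfg.n_genes)
        for gid, strand in zip(gene_ids, strands):
            chrom, tss = placements[gid]
            if strand == "+":
                start, end = tss, tss + GENE_LENGTH
            else:
                start, end = tss - GENE_LENGTH + 1, tss + 1
            rows.append((gid, chrom, strand, tss, start, end))
        annotation = pd.DataFrame(
            rows, columns=sio.ANNOTATION_COLUMNS).sort_values(
            ["chrom", "start"], kind="stable").reset_index(drop=True)

        # record roles in the truth; a fixed planted_lfc is the default, a
        # per-gene uniform draw from lfc_range when planted_lfc is None
        lfc_lo, lfc_hi = cfg.lfc_range

        def draw_lfc():
            if cfg.planted_lfc is not None:
                return float(cfg.planted_lfc)
            return float(rng.uniform(lfc_lo, lfc_hi))

        self.truth.interaction_genes = {
            g: {"strain": designated, "lfc": draw_lfc()}
            for g in boundary_gene_ids}
        self.truth.interaction_genes.update({
            g: {"strain": other, "lfc": draw_lfc()}
            for g in center_gene_ids})
        self.truth.motif_genes = list(motif_genes)
        self.truth.synergy_genes = {g: cfg.synergy_offset
                                    for g in synergy_genes}
        self.truth.boundary_genes = list(boundary_gene_ids)
        self.truth.center_genes = list(center_gene_ids)
        self.truth.se_genes = list(se_genes)
        self.truth.tads = [list(t) for t in tads.itertuples(index=False)]
        self.annotation = annotation
        self.tads = tads
        return annotation

    # -- regulatory landscape ---------------------------------------------

    def generate_regulatory_landscape(self):
        """Loops, distal peaks with motif sites, K27ac, background peaks."""
        cfg = self.config
        rng = self.rngs["landscape"]
        ann = self.annotation.set_index("gene_id")
        designated = cfg.designated_strain
        half_anchor = cfg.loop_anchor_width // 2
        w = len(cfg.motif_consensus)

        tss_by_chrom = {c: sub["tss"].to_numpy()
                        for c, sub in self.annotation.groupby("chrom")}

        def clear_of_promoters(chrom, lo, hi):
            tss = tss_by_chrom[chrom]
            return not ((tss > lo - 600) & (tss < hi + 600)).any()

        peak_rows, loop_rows, k27_rows = [], [], []
        motif_sites = []
        induced = {}
        peak_id = 0

        interaction_items = sorted(self.truth.interaction_genes.items())
        motif_set = set(self.truth.motif_genes)
        for gene, info in interaction_items:
            g = ann.loc[gene]
            # distal anchor 60-120 kb from the TSS, toward chromosome center
            for _ in range(40):
                d = int(rng.integers(60_000, 120_000))
                pos = g.tss + d if g.tss < cfg.chrom_length // 2 else g.tss - d
                lo, hi = pos - half_anchor, pos + half_anchor
                if lo > 0 and hi < cfg.chrom_length and \
                        clear_of_promoters(g.chrom, lo, hi):
                    break
            anchor_a = (g.chrom, max(int(g.tss) - half_anchor, 0),
                        int(g.tss) + half_anchor)
            anchor_b = (g.chrom, lo, hi)
            loop_rows.append((*anchor_a, *anchor_b, f"loop_{gene}", 1.0))
            pid = f"peak{peak_id:05d}"
            peak_id += 1
            p_lo, p_hi = pos - PEAK_WIDTH // 2, pos + PEAK_WIDTH // 2
            peak_rows.append((g.chrom, p_lo, p_hi, pid, 0.0, "."))
            induced[pid] = info["strain"]
            if gene in motif_set:
                m_start = pos - w // 2
                strand = str(rng.choice(["+", "-"]))
                motif_sites.append({
                    "gene": gene, "peak": pid, "chrom": g.chrom,
                    "start": int(m_start), "end": int(m_start + w),
                    "strand": strand,
                    "offset": int(m_start - p_lo),
                })
            if gene in set(self.truth.se_genes):
                # cluster of 3 high-signal K27ac peaks 5-25 kb past the TSS
                base = int(g.tss) + 5_000
                for j in range(3):
                    s = base + j * 5_000
                    sig = float(rng.uniform(50, 100))
                    k27_rows.append((g.chrom, s, s + 1_000,
                                     f"k27_se_{gene}_{j}", sig, "."))
            if info["strain"] == designated:
                # enhancer support: K27ac region over the induced distal peak
                k27_rows.append((g.chrom, p_lo - 500, p_hi + 500,
                                 f"k27_{gene}", float(rng.uniform(10, 30)), "."))

        # promoter-proximal constitutive peaks (one per gene)
        for gene, g in ann.iterrows():
            pid = f"peak{peak_id:05d}"
            peak_id += 1
            peak_rows.append((g.chrom, max(int(g.tss) - PEAK_WIDTH // 2, 0),
                              int(g.tss) + PEAK_WIDTH // 2, pid, 0.0, "."))

        # background constitutive peaks and decoy loops in clear space
        occupied = np.array(sorted(r[1] for r in peak_rows))
        chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
        tries = 0
        added = 0
        while added < cfg.n_background_peaks and tries < 50 * cfg.n_background_peaks:
            tries += 1
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(10_000, cfg.chrom_length - 10_000))
            near = np.searchsorted(occupied, pos)
            window = occupied[max(near - 2, 0):near + 2]
            if len(window) and np.abs(window - pos).min() < 2_000:
                continue
            pid = f"peak{peak_id:05d}"
            peak_id += 1
            peak_rows.append((chrom, pos, pos + PEAK_WIDTH, pid, 0.0, "."))
            added += 1
        added = 0
        tries = 0
        while added < cfg.n_background_k27ac and tries < 50 * cfg.n_background_k27ac:
            tries += 1
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(10_000, cfg.chrom_length - 10_000))
            if not clear_of_promoters(chrom, pos, pos + 1_000):
                continue
            k27_rows.append((chrom, pos, pos + 1_000,
                             f"k27_bg_{added}", float(rng.uniform(1, 5)), "."))
            added += 1
        for i in range(cfg.n_decoy_loops):
            chrom = chroms[int(rng.integers(len(chroms)))]
            for _ in range(40):
                a = int(rng.integers(20_000, cfg.chrom_length - 200_000))
                b = a + int(rng.integers(80_000, 150_000))
                if clear_of_promoters(chrom, a, a + cfg.loop_anchor_width) and \
                        clear_of_promoters(chrom, b, b + cfg.loop_anchor_width):
                    loop_rows.append((chrom, a, a + cfg.loop_anchor_width,
                                      chrom, b, b + cfg.loop_anchor_width,
                                      f"decoy_{i}", 0.5))
                    break

        self.atac_peaks = pd.DataFrame(
            peak_rows, columns=sio.BED_COLUMNS).sort_values(
            ["chrom", "start"], kind="stable").reset_index(drop=True)
        self.loops = pd.DataFrame(loop_rows, columns=sio.BEDPE_COLUMNS)
        self.h3k27ac = pd.DataFrame(
            k27_rows, columns=sio.BED_COLUMNS).sort_values(
            ["chrom", "start"], kind="stable").reset_index(drop=True)
        self.truth.induced_peaks = induced
        self.truth.motif_sites = motif_sites

        # second strain's TADs: mostly shared, a few shrunk past the 50%
        # reciprocal-overlap threshold so they register as strain-unique
        tads_b = self.tads.copy()
        n_shift = max(len(tads_b) // 10, 1)
        shift_idx = rng.choice(len(tads_b), size=n_shift, replace=False)
        for i in shift_idx:
            length = tads_b.loc[i, "end"] - tads_b.loc[i, "start"]
            tads_b.loc[i, "start"] = tads_b.loc[i, "start"] + (6 * length) // 10
        other = [s for s in STRAINS if s != designated][0]
        self.tads_by_strain = {designated: self.tads, other: tads_b}

    # -- sequences ---------------------------------------------------------

    def generate_sequences(self):
        """Per-strain FASTA; strains differ only at logged SNP positions."""
        cfg = self.config
        rng = self.rngs["sequence"]
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
        genome_a = {}
        for chrom in chroms:
            seq = rng.integers(0, 4, size=cfg.chrom_length)
            genome_a[chrom] = seq.astype(np.uint8)

        # plant motif occurrences (identical in both strains by default)
        consensus = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b]
                              for b in cfg.motif_consensus], dtype=np.uint8)
        comp = np.array([3, 2, 1, 0], dtype=np.uint8)
        motif_mask = {c: np.zeros(cfg.chrom_length, dtype=bool) for c in chroms}
        for site in self.truth.motif_sites:
            word = consensus if site["strand"] == "+" else comp[consensus][::-1]
            genome_a[site["chrom"]][site["start"]:site["end"]] = word
            motif_mask[site["chrom"]][site["start"]:site["end"]] = True

        genome_b = {c: genome_a[c].copy() for c in chroms}
        snp_log = {}
        for chrom in chroms:
            n_snps = int(cfg.snp_rate * cfg.chrom_length)
            pos = rng.choice(cfg.chrom_length, size=n_snps, replace=False)
            if not cfg.plant_disrupting_snps:
                pos = pos[~motif_mask[chrom][pos]]
            pos = np.sort(pos)
            shift = rng.integers(1, 4, size=len(pos)).astype(np.uint8)
            genome_b[chrom][pos] = (genome_b[chrom][pos] + shift) % 4
            snp_log[chrom] = [int(p) for p in pos]

        def decode(genome):
            return {c: bases[v].tobytes().decode("ascii")
                    for c, v in genome.items()}

        designated = cfg.designated_strain
        other = [s for s in STRAINS if s != designated][0]
        self.genomes = {designated: decode(genome_a), other: decode(genome_b)}
        self.truth.snp_positions = snp_log

    # -- counts ------------------------------------------------------------

    def _design(self) -> pd.DataFrame:
        rows = []
        for strain in STRAINS:
            for treat in TREATMENTS:
                for rep in range(1, self.config.n_replicates + 1):
                    safe = treat.replace("+", "")
                    rows.append((f"{strain}_{safe}_r{rep}", strain, treat, rep))
        design = pd.DataFrame(rows, columns=sio.DESIGN_COLUMNS)
        return design.set_index("sample", drop=False)

    def generate_counts(self):
        """RNA counts under the NB strain x treatment model."""
        cfg = self.config
        rng = self.rngs["counts"]
        design = self._design()
        gene_ids = list(self.annotation["gene_id"])
        n = len(gene_ids)
        designated = cfg.designated_strain

        base = np.log2(cfg.baseline_mean) + rng.normal(0, cfg.baseline_sd, size=n)
        strain_eff = rng.normal(0, cfg.strain_effect_sd, size=n)  # B vs A
        t_il4 = rng.normal(0, cfg.treatment_effect_sd, size=n)
        t_lps = rng.normal(0, cfg.treatment_effect_sd, size=n)

        inter_il4 = {s: np.zeros(n) for s in STRAINS}
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        for gene, info in self.truth.interaction_genes.items():
            inter_il4[info["strain"]][gene_pos[gene]] += info["lfc"]
        for gene in self.truth.motif_genes:
            inter_il4[designated][gene_pos[gene]] += cfg.motif_extra_induction
        # synergy genes emulate the LPS-inducible cluster that IL-4 priming
        # amplifies: a clear LPS response, no standalone IL-4 response, and
        # the planted offset only on the combined treatment in one strain
        synergy = np.zeros(n)
        for gene, off in self.truth.synergy_genes.items():
            i = gene_pos[gene]
            synergy[i] += off
            t_il4[i] = 0.0
            t_lps[i] = 1.0 + abs(t_lps[i])

        size_factors = np.exp(rng.normal(0, cfg.size_factor_sd,
                                         size=len(design)))
        counts = np.zeros((n, len(design)), dtype=np.int64)
        for j, sample in enumerate(design.itertuples(index=False)):
            log2mu = base.copy()
            if sample.strain == STRAINS[1]:
                log2mu += strain_eff
            extra_il4 = inter_il4[sample.strain]
            if sample.treatment == "IL4":
                log2mu += t_il4 + extra_il4
            elif sample.treatment == "LPS":
                log2mu += t_lps
            elif sample.treatment == "IL4+LPS":
                log2mu += t_il4 + extra_il4 + t_lps
                if sample.strain == designated:
                    log2mu += synergy
            mu = (2.0 ** log2mu) * size_factors[j]
            counts[:, j] = _nb_draw(rng, mu, cfg.dispersion)
        self.rna_counts = pd.DataFrame(counts, index=pd.Index(gene_ids,
                                       name="feature_id"),
                                       columns=design.index)
        self.design = design
        self._rna_size_factors = size_factors

    def generate_peak_counts(self):
        """ATAC counts; planted peaks gain accessibility on IL4 in their strain."""
        cfg = self.config
        rng = self.rngs["peaks"]
        design = self.design
        peaks = self.atac_peaks
        n = len(peaks)
        base = np.log2(cfg.peak_baseline) + rng.normal(0, 0.3, size=n)
        gain = np.log2(cfg.accessibility_fold)
        induced_strain = pd.Series(peaks["name"].map(self.truth.induced_peaks))
        counts = np.zeros((n, len(design)), dtype=np.int64)
        for j, sample in enumerate(design.itertuples(index=False)):
            log2mu = base.copy()
            boost = (induced_strain == sample.strain).to_numpy() & \
                (sample.treatment in ("IL4", "IL4+LPS"))
            log2mu = log2mu + np.where(boost, gain, 0.0)
            counts[:, j] = _nb_draw(rng, 2.0 ** log2mu, cfg.dispersion)
        self.atac_counts = pd.DataFrame(
            counts, index=pd.Index(peaks["name"], name="feature_id"),
            columns=design.index)

    # -- assembly ----------------------------------------------------------

    def run(self) -> Cohort:
        self.generate_annotation()
        self.generate_regulatory_landscape()
        self.generate_sequences()
        self.generate_counts()
        self.generate_peak_counts()
        pwm = PWM.from_consensus("NFKB", self.config.motif_consensus)
        return Cohort(self.config, self.truth, self.annotation, self.genomes,
                      self.rna_counts, self.design, self.atac_peaks,
                      self.atac_counts, self.h3k27ac, self.loops,
                      self.tads_by_strain, pwm)


def simulate_cohort(config: SimulationConfig | None = None, **overrides) -> Cohort:
    if config is None:
        config = SimulationConfig(**overrides)
    return CohortSimulator(config).run()


# ---------------------------------------------------------------------------
# fixture files
# ---------------------------------------------------------------------------

def write_fixture(cohort: Cohort, out_dir) -> dict:
    """Write all fixture files; returns a manifest path -> sha256 checksum."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def emit(name, writer, *args):
        path = os.path.join(out_dir, name)
        writer(*args, path)
        paths[name] = path

    for strain, genome in cohort.genomes.items():
        emit(f"genome_{strain}.fa", sio.write_fasta, genome)
    emit("genes.tsv", sio.write_annotation, cohort.annotation)
    emit("rna_counts.tsv", sio.write_counts, cohort.rna_counts)
    emit("design.tsv", sio.write_design, cohort.design)
    emit("atac_peaks.bed", sio.write_bed, cohort.atac_peaks)
    emit("atac_counts.tsv", sio.write_counts, cohort.atac_counts)
    emit("h3k27ac.bed", sio.write_bed, cohort.h3k27ac)
    emit("loops.bedpe", sio.write_bedpe, cohort.loops)
    for strain, tads in cohort.tads.items():
        bed = tads.copy()
        bed["name"] = [f"tad{i}" for i in range(len(bed))]
        emit(f"tads_{strain}.bed", sio.write_bed, bed)
    emit("motifs.meme", lambda m, p: sio.write_meme(m, p), [cohort.pwm])
    cohort.truth.to_json(os.path.join(out_dir, "ground_truth.json"))
    paths["ground_truth.json"] = os.path.join(out_dir, "ground_truth.json")

    manifest = {name: sio.sha256_file(path) for name, path in sorted(paths.items())}
    sio.write_json(manifest, os.path.join(out_dir, "manifest.json"))
    return manifest


def load_fixture(fixture_dir) -> Cohort:
    """Read a written fixture back into a :class:`Cohort` (lossless)."""
    cfg = SimulationConfig()  # not recorded per-file; config travels separately
    truth = GroundTruth.from_json(os.path.join(fixture_dir, "ground_truth.json"))
    design = sio.read_design(os.path.join(fixture_dir, "design.tsv"))
    annotation = sio.read_annotation(os.path.join(fixture_dir, "genes.tsv"))
    rna = sio.read_counts(os.path.join(fixture_dir, "rna_counts.tsv"), design)
    atac_counts = sio.read_counts(os.path.join(fixture_dir, "atac_counts.tsv"),
                                  design)
    atac_peaks = sio.read_bed(os.path.join(fixture_dir, "atac_peaks.bed"))
    h3k27ac = sio.read_bed(os.path.join(fixture_dir, "h3k27ac.bed"))
    loops = sio.read_bedpe(os.path.join(fixture_dir, "loops.bedpe"))
    genomes, tads = {}, {}
    for strain in STRAINS:
        fa = os.path.join(fixture_dir, f"genome_{strain}.fa")
        if os.path.exists(fa):
            genomes[strain] = sio.read_fasta(fa)
        bed = os.path.join(fixture_dir, f"tads_{strain}.bed")
        if os.path.exists(bed):
            tads[strain] = sio.read_bed(bed)[["chrom", "start", "end"]]
    pwm = sio.read_meme(os.path.join(fixture_dir, "motifs.meme"))[0]
    return Cohort(cfg, truth, annotation, genomes, rna, design, atac_peaks,
                  atac_counts, h3k27ac, loops, tads, pwm)
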