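"""File formats and configuration.

Every on-disk format the package touches goes through this module so the
coordinate convention (0-based, half-open) is enforced in exactly one place.
BED/BEDPE are native to that convention; GTF (1-based, closed) is converted
on read.  Tabular output is TSV with a '#'-prefixed header row and empty
strings for missing values.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score",
]
DESIGN_COLUMNS = ["sample", "strain", "treatment", "replicate"]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# generic TSV tables
# ---------------------------------------------------------------------------

def write_tsv(frame: pd.DataFrame, path, index: bool = False,
              index_label: str | None = None, float_format: str = "%.6g") -> None:
    """Write a TSV with a '#'-prefixed header and '' for NA."""
    df = frame.reset_index() if index else frame.copy()
    if index and index_label is not None:
        df = df.rename(columns={df.columns[0]: index_label})
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(str(c) for c in df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, na_rep="",
                  float_format=float_format)


def read_tsv(path, index_col: str | None = None) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError(f"{path}: expected '#'-prefixed header line")
        columns = header[1:].rstrip("\n").split("\t")
        df = pd.read_csv(fh, sep="\t", header=None, names=columns,
                         na_values=[""], keep_default_na=False)
    if index_col is not None:
        df = df.set_index(index_col)
    return df


# ---------------------------------------------------------------------------
# BED / BEDPE
# ---------------------------------------------------------------------------

def _check_interval(chrom, start, end, path, lineno):
    if start < 0 or start >= end:
        raise FormatError(
            f"{path}:{lineno}: invalid interval {chrom}:{start}-{end} "
            "(need 0 <= start < end)")


def read_bed(path) -> pd.DataFrame:
    """Read BED3-BED6 into a frame with columns chrom,start,end,name,score,strand."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            _check_interval(parts[0], start, end, path, lineno)
            name = parts[3] if len(parts) > 3 else ""
            score = float(parts[4]) if len(parts) > 4 and parts[4] not in (".", "") else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((parts[0], start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(intervals: pd.DataFrame, path) -> None:
    df = intervals.copy()
    for col, default in (("name", ""), ("score", 0.0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    df = df[BED_COLUMNS]
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            score = f"{row.score:g}"
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t{score}\t{row.strand}\n")


def read_bedpe(path) -> pd.DataFrame:
    """Read BEDPE (6 coordinate columns + optional name/score)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: fewer than 6 BEDPE columns")
            try:
                s1, e1, s2, e2 = (int(parts[i]) for i in (1, 2, 4, 5))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            _check_interval(parts[0], s1, e1, path, lineno)
            _check_interval(parts[3], s2, e2, path, lineno)
            name = parts[6] if len(parts) > 6 else ""
            score = float(parts[7]) if len(parts) > 7 and parts[7] not in (".", "") else 0.0
            rows.append((parts[0], s1, e1, parts[3], s2, e2, name, score))
    return pd.DataFrame(rows, columns=BEDPE_COLUMNS)


def write_bedpe(loops: pd.DataFrame, path) -> None:
    df = loops.copy()
    if "name" not in df.columns:
        df["name"] = ""
    if "score" not in df.columns:
        df["score"] = 0.0
    df = df[BEDPE_COLUMNS]
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom1}\t{row.start1}\t{row.end1}\t{row.chrom2}\t"
                     f"{row.start2}\t{row.end2}\t{row.name}\t{row.score:g}\n")


# ---------------------------------------------------------------------------
# gene annotation (TSV or GTF)
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["gene_id", "chrom", "strand", "tss", "start", "end"]


def read_annotation(path) -> pd.DataFrame:
    ann = read_tsv(path)
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise FormatError(f"{path}: annotation missing columns {sorted(missing)}")
    return ann[ANNOTATION_COLUMNS].astype(
        {"tss": int, "start": int, "end": int})


def write_annotation(annotation: pd.DataFrame, path) -> None:
    write_tsv(annotation[ANNOTATION_COLUMNS], path)


def read_gtf(path) -> pd.DataFrame:
    """Extract gene records from a GTF; 1-based closed -> 0-based half-open.

    The TSS is the transcription start in genomic coordinates: the converted
    `start` for '+' genes and `end - 1` for '-' genes.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: fewer than 9 GTF columns")
            if parts[2] != "gene":
                continue
            try:
                start1, end1 = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            start, end = start1 - 1, end1  # to half-open
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{lineno}: invalid gene span")
            strand = parts[6]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: gene without strand")
            gene_id = ""
            for attr in parts[8].split(";"):
                attr = attr.strip()
                if attr.startswith("gene_id"):
                    gene_id = attr.split(None, 1)[1].strip('"')
                    break
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            tss = start if strand == "+" else end - 1
            rows.append((gene_id, parts[0], strand, tss, start, end))
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id, uppercased."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# counts + design
# ---------------------------------------------------------------------------

def read_design(path) -> pd.DataFrame:
    design = read_tsv(path)
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise FormatError(f"{path}: design missing columns {sorted(missing)}")
    design = design[DESIGN_COLUMNS].astype({"replicate": int})
    if design["sample"].duplicated().any():
        dupes = design.loc[design["sample"].duplicated(), "sample"].tolist()
        raise FormatError(f"{path}: duplicated sample ids {dupes}")
    return design.set_index("sample", drop=False)


def read_counts(counts_path, design: pd.DataFrame) -> pd.DataFrame:
    counts = read_tsv(counts_path, index_col="feature_id")
    unknown = [s for s in counts.columns if s not in design.index]
    if unknown:
        raise FormatError(
            f"{counts_path}: samples absent from the design: {unknown}")
    missing = [s for s in design.index if s not in counts.columns]
    if missing:
        raise FormatError(
            f"{counts_path}: design samples missing from counts: {missing}")
    counts = counts[list(design.index)]
    counts.columns = design.index.copy()
    values = counts.to_numpy()
    if (values < 0).any():
        raise FormatError(f"{counts_path}: negative counts")
    return counts.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    write_tsv(counts, path, index=True, index_label="feature_id")


def write_design(design: pd.DataFrame, path) -> None:
    write_tsv(design.reset_index(drop=True)[DESIGN_COLUMNS], path)


# ---------------------------------------------------------------------------
# minimal MEME motif format
# ---------------------------------------------------------------------------

def read_meme(path) -> list:
    """Parse a minimal MEME text file (MOTIF / letter-probability blocks)."""
    from .motifs import PWM  # local import to avoid a cycle

    motifs = []
    name = None
    rows: list[list[float]] = []
    expected_w = None

    def flush():
        nonlocal name, rows, expected_w
        if name is not None:
            if not rows:
                raise FormatError(f"{path}: motif {name} has no probability rows")
            if expected_w is not None and len(rows) != expected_w:
                raise FormatError(
                    f"{path}: motif {name}: expected {expected_w} rows, got {len(rows)}")
            motifs.append(PWM(name=name, matrix=np.array(rows).T))
        name, rows, expected_w = None, [], None

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                flush()
                parts = line.split()
                if len(parts) < 2:
                    raise FormatError(f"{path}: MOTIF line without a name")
                name = parts[1]
            elif line.startswith("letter-probability matrix"):
                compact = line.replace("w =", "w=")
                if "w=" in compact:
                    try:
                        expected_w = int(compact.split("w=")[1].split()[0])
                    except (ValueError, IndexError):
                        expected_w = None
            elif name is not None and line and (line[0].isdigit() or line[0] == "."):
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise FormatError(
                        f"{path}: motif {name}: probability row with {len(vals)} values")
                rows.append(vals)
    flush()
    if not motifs:
        raise FormatError(f"{path}: no MOTIF blocks found")
    return motifs


def write_meme(motifs, path, background=None) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        if background is not None:
            fh.write("Background letter frequencies\n")
            fh.write("A %.5f C %.5f G %.5f T %.5f\n\n" % tuple(background))
        for pwm in motifs:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                     f"nsites= 20 E= 0\n")
            for col in pwm.matrix.T:
                fh.write(" " + "  ".join(f"{p:.6f}" for p in col) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline configuration with the published default thresholds.

    de_fdr/de_lfc implement the expression filter (FDR <= 0.05, >= 2-fold);
    atac_fdr the accessibility filter (FDR <= 0.001); scan_p the motif scan
    p-value; tad_flank the 100-kb boundary flank; stitch the super-enhancer
    stitching gap; reciprocal the TAD-sharing reciprocal-overlap fraction.
    """

    fixture_dir: str = ""
    out_dir: str = "strainreg_out"
    seed: int = 0
    de_fdr: float = 0.05
    de_lfc: float = 1.0
    atac_fdr: float = 0.001
    scan_p: float = 1e-4
    tad_flank: int = 100_000
    stitch: int = 12_500
    tss_exclusion: int = 2_000
    reciprocal: float = 0.5
    k_values: tuple = (3, 6)
    treated: str = "IL4"
    control: str = "Ctrl"
    expression_condition: str = "IL4"
    simulate: bool = False

    def validate(self) -> "RunConfig":
        for attr in ("de_fdr", "atac_fdr", "scan_p"):
            v = getattr(self, attr)
            if not 0 < v <= 1:
                raise ValueError(f"{attr}={v} outside (0, 1]")
        if not 0 < self.reciprocal <= 1:
            raise ValueError(f"reciprocal={self.reciprocal} outside (0, 1]")
        if self.de_lfc < 0 or self.tad_flank < 0 or self.stitch < 0:
            raise ValueError("de_lfc, tad_flank and stitch must be non-negative")
        if any(k < 1 for k in self.k_values):
            raise ValueError("k_values must be >= 1")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "k_values" in raw:
            raw["k_values"] = tuple(raw["k_values"])
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------

def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
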