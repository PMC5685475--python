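"""Readers and writers for the pipeline's external formats.

Formats: gene-level count matrices as TSV with a sidecar sample-metadata
table, gene annotation TSV, BED3+ intervals (0-based half-open), FASTA
genomes, and JASPAR-style text PFM motif files.  Every reader/writer
pair round-trips losslessly on valid input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pwm import DEFAULT_PSEUDOCOUNT, PWMModel


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples, with per-sample day/replicate
    labels and per-gene transcript lengths."""

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    day: np.ndarray
    replicate: np.ndarray
    counts: np.ndarray
    gene_length_bp: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.day = np.asarray(self.day, dtype=int)
        self.replicate = np.asarray(self.replicate, dtype=int)
        self.counts = np.asarray(self.counts)
        self.gene_length_bp = np.asarray(self.gene_length_bp, dtype=int)
        n_genes, n_samples = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match counts rows")
        if len(self.sample_ids) != n_samples or len(self.day) != n_samples \
                or len(self.replicate) != n_samples:
            raise ValueError("sample metadata length does not match counts")
        if len(set(self.gene_ids)) != n_genes:
            dupes = pd.Series(self.gene_ids)
            dupes = dupes[dupes.duplicated()].iloc[0]
            raise ValueError(f"duplicate gene id: {dupes!r}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            frac = np.modf(np.asarray(self.counts, dtype=float))[0]
            if np.any(frac != 0):
                g, s = np.argwhere(frac != 0)[0]
                raise ValueError(
                    f"non-integer count at gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if np.any(self.gene_length_bp <= 0):
            raise ValueError("gene lengths must be positive")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class GeneAnnotation:
    """Per-gene genomic position plus TF / cone-specific / pathway labels."""

    table: pd.DataFrame  # index gene_id; chromosome, tss_bp, strand,
    #                      is_tf, is_cone_specific, pathways (set of str)

    REQUIRED = ("chromosome", "tss_bp", "strand", "is_tf",
                "is_cone_specific", "pathways")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate gene id in annotation: {dup!r}")
        bad = ~self.table["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(
                f"invalid strand for gene {self.table.index[bad][0]!r}")

    @property
    def gene_ids(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def pathway_sets(self) -> dict[str, set[str]]:
        """Mapping pathway name -> set of member gene ids."""
        out: dict[str, set[str]] = {}
        for gene, pws in self.table["pathways"].items():
            for pw in pws:
                out.setdefault(pw, set()).add(gene)
        return out

    def tss_by_chromosome(self) -> dict[str, np.ndarray]:
        out = {}
        for chrom, sub in self.table.groupby("chromosome"):
            out[str(chrom)] = np.sort(sub["tss_bp"].to_numpy())
        return out


@dataclass
class GenomicInterval:
    """0-based half-open genomic interval (BED convention)."""

    chromosome: str
    start_bp: int
    end_bp: int
    name: str = "."
    strand: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start_bp < self.end_bp:
            raise ValueError(
                f"invalid interval {self.chromosome}:{self.start_bp}-"
                f"{self.end_bp}")

    @property
    def width(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def midpoint(self) -> int:
        return (self.start_bp + self.end_bp) // 2


# ---------------------------------------------------------------- counts TSV

def read_count_matrix(path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a counts TSV (gene_id, length, sample columns) plus a sample
    metadata TSV (sample_id, day, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id" or "length" not in df.columns:
        raise ValueError("counts TSV must start with gene_id and carry a "
                         "'length' column")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    meta = meta.set_index("sample_id")
    sample_cols = [c for c in df.columns if c not in ("gene_id", "length")]
    missing = [s for s in sample_cols if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    counts = df[sample_cols].to_numpy()
    return CountMatrix(
        gene_ids=df["gene_id"].to_numpy(),
        sample_ids=np.array(sample_cols, dtype=object),
        day=meta.loc[sample_cols, "day"].to_numpy(),
        replicate=meta.loc[sample_cols, "replicate"].to_numpy(),
        counts=counts,
        gene_length_bp=df["length"].to_numpy(),
    )


def write_count_matrix(cm: CountMatrix, path: str | Path,
                       metadata_path: str | Path) -> None:
    df = pd.DataFrame(cm.counts, columns=cm.sample_ids)
    df.insert(0, "length", cm.gene_length_bp)
    df.insert(0, "gene_id", cm.gene_ids)
    df.to_csv(path, sep="\t", index=False)
    meta = pd.DataFrame({"sample_id": cm.sample_ids, "day": cm.day,
                         "replicate": cm.replicate})
    meta.to_csv(metadata_path, sep="\t", index=False)


# ------------------------------------------------------------- annotation TSV

def read_annotation(path: str | Path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    df["is_tf"] = df["is_tf"].astype(bool)
    df["is_cone_specific"] = df["is_cone_specific"].astype(bool)
    df["pathways"] = [
        set() if (pd.isna(p) or p == "") else set(str(p).split(";"))
        for p in df["pathways"]
    ]
    return GeneAnnotation(df)


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    df = ann.table.copy()
    df["pathways"] = [";".join(sorted(p)) for p in df["pathways"]]
    df.to_csv(path, sep="\t", index=True, index_label="gene_id")


# ----------------------------------------------------------------------- BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(
                    f"line {lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else None
            intervals.append(GenomicInterval(chrom, start, end, name, strand))
    return intervals


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chromosome, str(iv.start_bp), str(iv.end_bp), iv.name]
            if iv.strand is not None:
                fields += ["0", iv.strand]
            fh.write("\t".join(fields) + "\n")


# --------------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {name: upper-cased sequence}; duplicate headers and empty
    records are errors."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA header: {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence record: {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(sequences: dict[str, str], path: str | Path,
                width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------- JASPAR PFM

def read_jaspar_pfm(path: str | Path,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT,
                    background: np.ndarray | None = None) -> list[PWMModel]:
    """Parse JASPAR-style text PFMs.

    Blocks look like::

        >MA0139.1 CTCF
        A [ 87 167 281 ... ]
        C [291 145  49 ... ]
        G [ 76 414 449 ... ]
        T [459 187 134 ... ]

    Bare whitespace-separated rows without the base letter and brackets
    are accepted too.
    """
    if background is None:
        background = np.full(4, 0.25)
    models: list[PWMModel] = []
    motif_id = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal rows, motif_id
        if motif_id is None:
            return
        if len(rows) != 4:
            raise ValueError(f"{motif_id}: expected 4 base rows, got {len(rows)}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"{motif_id}: rows of unequal length")
        models.append(PWMModel(motif_id, np.array(rows),
                               background=background.copy(),
                               pseudocount=pseudocount))
        rows = []
        motif_id = None

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
                continue
            body = line
            if body[0] in "ACGTacgt" and ("[" in body or body[1:2].isspace()):
                body = body[1:]
            body = body.replace("[", " ").replace("]", " ")
            rows.append([float(x) for x in body.split()])
    flush()
    for m in models:
        if np.any(m.counts < 0):
            raise ValueError(f"{m.motif_id}: negative counts")
    return models


def write_jaspar_pfm(models: list[PWMModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.motif_id}\n")
            for base, row in zip("ACGT", m.counts):
                cells = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base} [ {cells} ]\n")
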