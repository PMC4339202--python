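"""Shared domain types, file formats, configuration and logging.

Internal coordinates are 0-based, half-open everywhere; the GFF3 reader/writer
converts from/to the 1-based inclusive convention at the boundary, so no other
module ever shifts coordinates.  "No hit" E-values are represented as ``+inf``
in memory and serialised as ``NA``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

DEFAULT_SEED = 20150224
NO_HIT = math.inf

DNA_COMPLEMENT = str.maketrans("ACGTNYRSWKMacgtnyrswkm", "TGCANRYSWMKtgcanryswmk")

#: IUPAC degenerate DNA codes used by the motif machinery.
IUPAC_CODES: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "Y": frozenset("CT"),
    "R": frozenset("AG"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "N": frozenset("ACGT"),
}

logger = logging.getLogger("lossmark")


def configure_logging(level: str = "INFO") -> None:
    """Initialise the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level.upper())


class FormatError(ValueError):
    """A file violates its declared format."""


class ConfigError(ValueError):
    """Inconsistent configuration or inputs."""


def reverse_complement(seq: str) -> str:
    return seq.translate(DNA_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence (genome contig or protein)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record requires a non-empty id")
        if not self.sequence:
            raise FormatError(f"sequence record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Gene:
    """One annotated gene: CDS union span in internal coordinates."""

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id!r}: strand required, got {self.strand!r}")
        if not (0 <= self.cds_start < self.cds_end):
            raise FormatError(
                f"gene {self.gene_id!r}: invalid span ({self.cds_start}, {self.cds_end})"
            )


@dataclass
class GenomeAnnotation:
    """Per-gene annotation keyed by gene id."""

    genes: dict[str, Gene] = field(default_factory=dict)

    def add(self, gene: Gene) -> None:
        if gene.gene_id in self.genes:
            raise FormatError(f"duplicate gene id {gene.gene_id!r}")
        self.genes[gene.gene_id] = gene

    def __iter__(self):
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]


@dataclass
class BlastHitTable:
    """Tabular BLAST hits with per-(query, taxon) best-hit retrieval.

    Best hit = minimum E-value, ties broken by maximum bitscore, then
    lexicographically smallest subject id, so outputs are deterministic.
    """

    hits: pd.DataFrame  # columns: query_id, subject_id, subject_taxon, evalue, bitscore, aln_len

    REQUIRED = ("query_id", "subject_id", "subject_taxon", "evalue", "bitscore", "aln_len")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.hits.columns]
        if missing:
            raise FormatError(f"BlastHitTable missing columns: {missing}")
        if (self.hits["evalue"] < 0).any():
            raise FormatError("negative E-value in hit table")

    def best_hit(self, query_id: str, taxon: str) -> pd.Series | None:
        sub = self.hits[
            (self.hits["query_id"] == query_id) & (self.hits["subject_taxon"] == taxon)
        ]
        if sub.empty:
            return None
        sub = sub.sort_values(
            ["evalue", "bitscore", "subject_id"], ascending=[True, False, True]
        )
        return sub.iloc[0]

    def best_evalue(self, query_id: str, taxon: str) -> float:
        row = self.best_hit(query_id, taxon)
        return NO_HIT if row is None else float(row["evalue"])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA records in file order, sequences upper-cased.

    Raises :class:`FormatError` naming the offending line for malformed
    headers or empty sequences (a contract plain ``Bio.SeqIO`` does not give).
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    seen: set[str] = set()

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"line {header_line}: record {header!r} has no sequence")
        records.append(SequenceRecord(header, seq.upper()))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                if header in seen:
                    raise FormatError(f"line {lineno}: duplicate record id {header!r}")
                seen.add(header)
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"line {lineno}: sequence before first header")
                chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff(path: str | Path) -> GenomeAnnotation:
    """Read gene/CDS features from GFF3 into one CDS-union span per gene.

    GFF3 1-based inclusive coordinates become internal 0-based half-open.
    Multiple CDS lines sharing a gene id are merged to their union span.
    """
    spans: dict[str, list] = {}  # gene_id -> [chrom, strand, start, end]
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"line {lineno}: expected 9 GFF columns, got {len(fields)}")
            chrom, _, ftype, start_s, end_s, _, strand, _, attrs_s = fields
            if ftype not in {"gene", "CDS", "mRNA"}:
                continue
            if ftype == "mRNA":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise FormatError(f"line {lineno}: end < start ({end1} < {start1})")
            if strand not in {"+", "-"}:
                raise FormatError(f"line {lineno}: strand required")
            attrs = _gff_attributes(attrs_s)
            gene_id = attrs.get("ID") or attrs.get("Parent")
            if not gene_id:
                raise FormatError(f"line {lineno}: missing ID attribute")
            start, end = start1 - 1, end1  # to 0-based half-open
            if gene_id not in spans:
                spans[gene_id] = [chrom, strand, start, end]
            else:
                rec = spans[gene_id]
                if rec[0] != chrom or rec[1] != strand:
                    raise FormatError(f"line {lineno}: gene {gene_id!r} spans chrom/strand")
                rec[2] = min(rec[2], start)
                rec[3] = max(rec[3], end)
    ann = GenomeAnnotation()
    for gene_id, (chrom, strand, start, end) in spans.items():
        ann.add(Gene(gene_id, chrom, strand, start, end))
    return ann


def write_gff(annotation: GenomeAnnotation, path: str | Path, source: str = "lossmark") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in annotation:
            fh.write(
                "\t".join(
                    [
                        gene.chrom,
                        source,
                        "gene",
                        str(gene.cds_start + 1),  # back to 1-based inclusive
                        str(gene.cds_end),
                        ".",
                        gene.strand,
                        ".",
                        f"ID={gene.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

_BLAST6_COLS = [
    "query_id", "subject_id", "pident", "aln_len", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(path: str | Path, taxon_map: Mapping[str, str]) -> BlastHitTable:
    """Read outfmt-6 BLAST hits, annotating each subject with its taxon.

    ``taxon_map`` maps subject ids to taxon names; a subject absent from the
    map is a configuration error.  Unparseable rows are dropped with a count
    logged rather than aborting the run.
    """
    rows = []
    n_bad = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                n_bad += 1
                continue
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
                aln_len = int(fields[3])
            except ValueError:
                n_bad += 1
                continue
            subject = fields[1]
            if subject not in taxon_map:
                raise ConfigError(f"subject {subject!r} absent from taxon map")
            rows.append(
                {
                    "query_id": fields[0],
                    "subject_id": subject,
                    "subject_taxon": taxon_map[subject],
                    "evalue": evalue,
                    "bitscore": bitscore,
                    "aln_len": aln_len,
                }
            )
    if n_bad:
        logger.warning("read_blast_tab: rejected %d unparseable rows in %s", n_bad, path)
    frame = pd.DataFrame(rows, columns=list(BlastHitTable.REQUIRED))
    return BlastHitTable(frame)


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def write_bed(hits, path: str | Path, chrom_sizes: Mapping[str, int] | None = None) -> None:
    """Write motif hits as BED6 (name = model id, score = match score × 1000).

    ``hits`` are any objects with chrom/start/end/strand/model_id/score
    attributes (see :class:`lossmark.motif_models.MotifHit`).
    """
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for hit in hits:
            if chrom_sizes is not None:
                size = chrom_sizes.get(hit.chrom)
                if size is not None and not (0 <= hit.start < hit.end <= size):
                    raise FormatError(
                        f"hit ({hit.chrom}, {hit.start}, {hit.end}) outside chromosome bounds"
                    )
            score = int(round(min(max(hit.score, 0.0), 1.0) * 1000))
            fh.write(
                f"{hit.chrom}\t{hit.start}\t{hit.end}\t{hit.model_id}\t{score}\t{hit.strand}\n"
            )


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED6 back into a DataFrame (intervals stay 0-based half-open)."""
    frame = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": int, "end": int, "name": str, "score": int, "strand": str},
    )
    return frame


# ---------------------------------------------------------------------------
# TSV matrices (gene × taxon E-values etc.)
# ---------------------------------------------------------------------------

def write_evalue_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Serialise an E-value matrix; +inf sentinels become "NA"."""
    out = matrix.replace(math.inf, float("nan"))
    # repr round-trips doubles exactly; fixed-width formats do not
    out.to_csv(path, sep="\t", index_label="gene", na_rep="NA",
               float_format=lambda v: repr(float(v)))


def read_evalue_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene×taxon E-value TSV; "NA" means no hit and becomes +inf."""
    matrix = pd.read_csv(
        path, sep="\t", index_col="gene", na_values=["NA"], float_precision="round_trip"
    )
    return matrix.fillna(math.inf)


def read_config(path: str | Path) -> dict[str, str]:
    """Read a flat ``key = value`` configuration document.

    Lines starting with '#' are comments; values are kept as strings and
    interpreted by the consumer.
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
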