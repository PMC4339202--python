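"""Heat-shock-element motif models and genome scanning.

Four model families describe the Hsf1-binding HSE signature upstream of the
two eukaryotic ClpB disaggregase genes (cytosolic HSP104, mitochondrial
HSP78): a degenerate IUPAC consensus, an additive position weight matrix with
pseudocount, an inverted-repeat nGAAn array with skipped/clipped triplets, and
(in :mod:`lossmark.promoter_architecture`) a composite HSE + STRE-cluster
architecture.  Scanning reports both strands; palindromic consensus patterns
(the perfect HSE4 is its own reverse complement) yield the same interval on
both strands and are collapsed to one '+' locus, since loci — not
strand-matches — are what the precision metric counts.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .io_core import (
    IUPAC_CODES,
    FormatError,
    Gene,
    GenomeAnnotation,
    SequenceRecord,
    logger,
    reverse_complement,
)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# IUPAC consensus motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IupacMotif:
    """A degenerate consensus pattern ('.' accepted as an alias for N)."""

    pattern: str
    name: str = ""

    def __post_init__(self) -> None:
        normalised = self.pattern.upper().replace(".", "N")
        object.__setattr__(self, "pattern", normalised)
        if len(normalised) < 4:
            raise FormatError(f"motif {normalised!r}: length must be >= 4")
        bad = set(normalised) - set(IUPAC_CODES)
        if bad:
            raise FormatError(f"motif {normalised!r}: invalid codes {sorted(bad)}")
        if not self.name:
            object.__setattr__(self, "name", normalised)

    def __len__(self) -> int:
        return len(self.pattern)

    def matches(self, window: str) -> bool:
        if len(window) != len(self.pattern):
            return False
        return all(b in IUPAC_CODES[c] for b, c in zip(window.upper(), self.pattern))

    def reverse_complement(self) -> "IupacMotif":
        return IupacMotif(reverse_complement(self.pattern), name=self.name)

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.pattern) == self.pattern

    def to_regex(self) -> re.Pattern:
        parts = []
        for code in self.pattern:
            chars = "".join(sorted(IUPAC_CODES[code]))
            parts.append(chars if len(chars) == 1 else f"[{chars}]")
        # lookahead so overlapping occurrences are all reported
        return re.compile(f"(?=({''.join(parts)}))")


@dataclass(frozen=True)
class MotifHit:
    """A genomic motif match (0-based half-open, stranded)."""

    chrom: str
    start: int
    end: int
    strand: str
    model_id: str
    score: float = 1.0

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def _as_records(genome) -> list[SequenceRecord]:
    if isinstance(genome, SequenceRecord):
        return [genome]
    return list(genome)


def scan_iupac(
    genome,
    motif: IupacMotif,
    both_strands: bool = True,
    collapse_palindromic: bool = True,
) -> list[MotifHit]:
    """All matches of a degenerate consensus, both strands, sorted by locus.

    Minus-strand hits are matches of the reverse-complement pattern reported
    in plus-strand coordinates.  When the pattern is self-reverse-complementary
    the two strands produce identical intervals; those pairs collapse to a
    single hit with strand '+'.
    """
    records = _as_records(genome)
    if records and all(len(r) < len(motif) for r in records):
        logger.warning("motif %s longer than every sequence; no hits possible", motif.name)
        return []
    hits: list[MotifHit] = []
    fwd = motif.to_regex()
    rev = motif.reverse_complement().to_regex() if both_strands else None
    for rec in records:
        seq = rec.sequence.upper()
        plus = {m.start() for m in fwd.finditer(seq)}
        minus: set[int] = set()
        if rev is not None:
            minus = {m.start() for m in rev.finditer(seq)}
        for pos in sorted(plus | minus):
            on_plus, on_minus = pos in plus, pos in minus
            if on_plus and on_minus and collapse_palindromic:
                strands = ["+"]
            else:
                strands = (["+"] if on_plus else []) + (["-"] if on_minus else [])
            for strand in strands:
                hits.append(MotifHit(rec.id, pos, pos + len(motif), strand, motif.name, 1.0))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def merge_nearby_hits(hits: Sequence[MotifHit], min_sep: int = 5) -> list[MotifHit]:
    """Merge same-model hits whose starts differ by < ``min_sep`` bp.

    Runs of N positions make a degenerate pattern match at several adjacent
    offsets; counting each would inflate locus counts, so a run collapses to
    one hit spanning the union interval (max score, '+' if strands mix).
    """
    merged: list[MotifHit] = []
    for hit in sorted(hits, key=lambda h: (h.chrom, h.model_id, h.start)):
        last = merged[-1] if merged else None
        if (
            last is not None
            and last.chrom == hit.chrom
            and last.model_id == hit.model_id
            and hit.start - last.start < min_sep
        ):
            strand = last.strand if last.strand == hit.strand else "+"
            merged[-1] = replace(
                last,
                end=max(last.end, hit.end),
                strand=strand,
                score=max(last.score, hit.score),
            )
        else:
            merged.append(hit)
    merged.sort(key=lambda h: (h.chrom, h.start))
    return merged


# ---------------------------------------------------------------------------
# Position weight matrices
# ---------------------------------------------------------------------------

@dataclass
class WeightMatrix:
    """Additive PWM: weight(b, i) = count(b, i) + pseudocount.

    A window scores the sum of its per-position weights; windows containing
    non-ACGT bases never match.  ``threshold`` is unset until calibrated.
    """

    weights: np.ndarray  # shape (4, L), rows in A,C,G,T order
    pseudocount: float
    threshold: float | None = None
    name: str = "pwm"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != 4:
            raise FormatError("weight matrix must have shape (4, L)")
        if self.pseudocount < 0:
            raise FormatError("pseudocount must be >= 0")
        if (self.weights < 0).any():
            raise FormatError("weights must be non-negative")

    def __len__(self) -> int:
        return self.weights.shape[1]

    def score(self, window: str) -> float:
        if len(window) != len(self):
            raise ValueError("window length mismatch")
        total = 0.0
        for i, base in enumerate(window.upper()):
            idx = _BASE_INDEX.get(base)
            if idx is None:
                return -math.inf
            total += self.weights[idx, i]
        return total


def build_pwm(sites: Sequence[str], pseudocount: float, name: str = "pwm") -> WeightMatrix:
    """Count matrix from aligned binding sites plus a uniform pseudocount."""
    if not sites:
        raise FormatError("build_pwm requires at least one site")
    length = len(sites[0])
    if any(len(s) != length for s in sites):
        raise FormatError("training sites must have equal length")
    counts = np.zeros((4, length))
    for site in sites:
        for i, base in enumerate(site.upper()):
            idx = _BASE_INDEX.get(base)
            if idx is None:
                raise FormatError(f"site {site!r}: non-ACGT base {base!r}")
            counts[idx, i] += 1
    return WeightMatrix(counts + pseudocount, pseudocount, name=name)


def calibrate_threshold(pwm: WeightMatrix, sites: Sequence[str]) -> WeightMatrix:
    """Set the match threshold to the minimum score over the training sites.

    With this rule every training site is recovered when its genome of origin
    is scanned; anything scoring at least as well as the weakest training
    example is reported.
    """
    if not sites:
        raise FormatError("calibration requires at least one site")
    theta = min(pwm.score(s) for s in sites)
    return WeightMatrix(pwm.weights.copy(), pwm.pseudocount, threshold=theta, name=pwm.name)


def scan_pwm(genome, pwm: WeightMatrix, both_strands: bool = True) -> list[MotifHit]:
    """Windows scoring >= the calibrated threshold, both strands."""
    if pwm.threshold is None:
        raise FormatError("calibrate first: PWM threshold unset")
    records = _as_records(genome)
    length = len(pwm)
    hits: list[MotifHit] = []
    for rec in records:
        seq = rec.sequence.upper()
        for strand in ("+", "-") if both_strands else ("+",):
            view = seq if strand == "+" else reverse_complement(seq)
            for i in range(len(view) - length + 1):
                s = pwm.score(view[i : i + length])
                if s >= pwm.threshold:
                    if strand == "+":
                        start = i
                    else:
                        start = len(seq) - i - length
                    hits.append(MotifHit(rec.id, start, start + length, strand, pwm.name, s))
    # identical interval matched on both strands counts once (locus semantics)
    seen: dict[tuple, MotifHit] = {}
    for hit in hits:
        key = hit.interval
        if key in seen:
            best = seen[key]
            seen[key] = replace(best, strand="+", score=max(best.score, hit.score))
        else:
            seen[key] = hit
    out = sorted(seen.values(), key=lambda h: (h.chrom, h.start))
    return out


def parse_pwm_text(text: str, pseudocount: float, name: str = "pwm") -> WeightMatrix:
    """Parse the compact "T:5555..., C:..., G:..., A:..." digit-row syntax.

    Each row is a string of single digits giving that base's weight at each
    position; the stated pseudocount is added to every cell.
    """
    rows: dict[str, list[float]] = {}
    for chunk in re.split(r"[,\s]+", text.strip()):
        if not chunk:
            continue
        if ":" not in chunk:
            raise FormatError(f"cannot parse PWM row {chunk!r}")
        base, digits = chunk.split(":", 1)
        base = base.strip().upper()
        digits = digits.strip().rstrip(".")
        if base not in _BASE_INDEX:
            raise FormatError(f"unknown PWM row base {base!r}")
        if not digits.isdigit():
            raise FormatError(f"PWM row for {base} is not a digit string: {digits!r}")
        rows[base] = [float(d) for d in digits]
    if set(rows) != set("ACGT"):
        raise FormatError(f"PWM text needs rows T, C, G, A; got {sorted(rows)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise FormatError("PWM rows have unequal lengths")
    weights = np.array([rows["A"], rows["C"], rows["G"], rows["T"]])
    return WeightMatrix(weights + pseudocount, pseudocount, name=name)


# ---------------------------------------------------------------------------
# Inverted-repeat HSE arrays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HseArrayModel:
    """An HSE as n_units alternating TTC/GAA triplets with 2-bp gaps.

    Unit i contributes triplet TTC (even i) or GAA (odd i) at offset 5*i.
    ``skips`` maps a unit index to how many leading bases of its triplet are
    kept (0 = fully skipped, i.e. NNN; 1 keeps only the first base, as in the
    skipped-HSE5 signature TTC..GAA..TTC..G....TTC).  ``end_clip`` trims
    (left, right) bases off the expanded pattern, producing end-clipped
    variants such as CnnGAAnnTTCnnG.  At least three intact triplets must
    remain.
    """

    n_units: int
    skips: dict = field(default_factory=dict)
    end_clip: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.n_units not in {4, 5, 6}:
            raise FormatError("HSE arrays have 4, 5 or 6 nGAAn units")
        raw = self.skips
        skips = dict(raw) if isinstance(raw, dict) else {i: 0 for i in raw}
        for unit, kept in skips.items():
            if not (0 <= unit < self.n_units):
                raise FormatError(f"skip unit {unit} out of range")
            if not (0 <= kept <= 2):
                raise FormatError("kept prefix of a skipped triplet must be 0..2")
        object.__setattr__(self, "skips", skips)
        intact = self.n_units - len(skips) - sum(1 for c in self.end_clip if c >= 3)
        if intact < 3:
            raise FormatError("skip mask leaves fewer than 3 intact triplets")


def expand_hse_array(model: HseArrayModel) -> list[IupacMotif]:
    """Explicit degenerate pattern(s) implied by an HSE array model."""
    parts: list[str] = []
    for unit in range(model.n_units):
        triplet = "TTC" if unit % 2 == 0 else "GAA"
        if unit in model.skips:
            kept = model.skips[unit]
            triplet = triplet[:kept] + "N" * (3 - kept)
        parts.append(triplet)
        if unit < model.n_units - 1:
            parts.append("NN")
    pattern = "".join(parts)
    left, right = model.end_clip
    if left or right:
        pattern = pattern[left : len(pattern) - right if right else None]
    return [IupacMotif(pattern)]


# ---------------------------------------------------------------------------
# Locus assignment and the precision metric
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusAssignment:
    """A hit assigned to a gene and zone (promoter / CDS / intergenic).

    ``distance`` is the gap in bp between the hit and the ORF start on the
    gene's upstream side (0 for an abutting hit); None for CDS/intergenic.
    """

    hit: MotifHit
    gene_id: str | None
    zone: str
    distance: int | None


def _upstream_gap(hit: MotifHit, gene: Gene) -> int | None:
    """Gap between hit and ORF start if the hit lies on the gene's upstream side."""
    if gene.strand == "+":
        if hit.end <= gene.cds_start:
            return gene.cds_start - hit.end
    else:
        if hit.start >= gene.cds_end:
            return hit.start - gene.cds_end
    return None


def assign_promoter(
    hits: Sequence[MotifHit],
    annotation: GenomeAnnotation,
    promoter_window: int = 1000,
) -> list[LocusAssignment]:
    """Assign each hit to a CDS, a promoter, or intergenic space.

    CDS overlap wins outright; otherwise the hit goes to the nearest gene
    whose strand-aware upstream window (``promoter_window`` bp before the ORF
    start) contains it.  Ties break by smaller distance, then lexicographic
    gene id.
    """
    if promoter_window <= 0:
        raise ValueError("promoter_window must be positive")
    by_chrom: dict[str, list[Gene]] = {}
    for gene in annotation:
        by_chrom.setdefault(gene.chrom, []).append(gene)
    out: list[LocusAssignment] = []
    for hit in hits:
        genes = by_chrom.get(hit.chrom, [])
        cds = sorted(
            (g for g in genes if hit.start < g.cds_end and hit.end > g.cds_start),
            key=lambda g: g.gene_id,
        )
        if cds:
            out.append(LocusAssignment(hit, cds[0].gene_id, "CDS", None))
            continue
        candidates: list[tuple[int, str]] = []
        for gene in genes:
            gap = _upstream_gap(hit, gene)
            if gap is not None and gap <= promoter_window:
                candidates.append((gap, gene.gene_id))
        if candidates:
            gap, gene_id = min(candidates)
            out.append(LocusAssignment(hit, gene_id, "promoter", gap))
        else:
            out.append(LocusAssignment(hit, None, "intergenic", None))
    return out


def regulon_precision(
    assignments: Sequence[LocusAssignment],
    annotation_set: Iterable[str],
) -> tuple[int, int, float]:
    """Fraction of matched loci whose gene is in the curated regulon set.

    Loci are distinct promoter-assigned genes plus each CDS hit (CDS hits are
    not listed by gene in reports but count in the denominator); intergenic
    hits are not loci.  Returns (numerator, denominator, precision); an empty
    locus set yields NaN precision.
    """
    known = set(annotation_set)
    promoter_genes = {a.gene_id for a in assignments if a.zone == "promoter"}
    n_cds = sum(1 for a in assignments if a.zone == "CDS")
    denominator = len(promoter_genes) + n_cds
    numerator = len(promoter_genes & known)
    if denominator == 0:
        logger.warning("regulon_precision: no matched loci; precision undefined")
        return (0, 0, math.nan)
    return (numerator, denominator, numerator / denominator)
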