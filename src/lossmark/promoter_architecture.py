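"""Composite promoter-architecture search and promoter dot plots.

The ClpB promoter signature combines an Hsf1-binding HSE with a cluster of
stress-response elements (STRE, 5'-CCCCT, bound by Msn2/Msn4): a window
qualifies when it holds at least ``min_stre`` STREs and one match to any of
the HSE alternative patterns.  The dot plot finds shared word blocks between
two promoters and tests whether the blocks form a serial (collinear)
alignment, the hallmark of a shared regulatory architecture.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

from .io_core import GenomeAnnotation, SequenceRecord, reverse_complement
from .motif_models import (
    HseArrayModel,
    IupacMotif,
    LocusAssignment,
    MotifHit,
    assign_promoter,
    expand_hse_array,
    scan_iupac,
)


def default_hse_alternatives() -> list[IupacMotif]:
    """Skipped HSE4 (internal triplet absent) and the end-clipped HSE4."""
    skipped = expand_hse_array(HseArrayModel(4, {2: 0}))[0]  # TTCNNGAANNNNNNNGAA
    clipped = expand_hse_array(HseArrayModel(4, end_clip=(2, 2)))[0]  # CNNGAANNTTCNNG
    return [skipped, clipped]


@dataclass
class CompositeModel:
    """HSE + STRE-cluster architecture searched in sliding windows."""

    window_len: int = 160
    stre_pattern: IupacMotif = field(default_factory=lambda: IupacMotif("CCCCT"))
    min_stre: int = 3
    hse_alternatives: list[IupacMotif] = field(default_factory=default_hse_alternatives)

    def __post_init__(self) -> None:
        if self.min_stre < 1:
            raise ValueError("min_stre must be >= 1")
        longest = max([len(self.stre_pattern)] + [len(m) for m in self.hse_alternatives])
        if self.window_len < longest:
            raise ValueError("window_len shorter than the longest component pattern")


def composite_scan(
    genome,
    model: CompositeModel,
    annotation: GenomeAnnotation,
    promoter_window: int = 1000,
) -> list[LocusAssignment]:
    """Loci whose window holds >= min_stre STREs plus an HSE alternative.

    The window slides by 1 bp; overlapping qualifying windows merge into one
    region, and each merged region is assigned to a locus via
    :func:`assign_promoter`.  STREs are counted on both strands at distinct
    start positions (overlapping occurrences each count).
    """
    records = [genome] if isinstance(genome, SequenceRecord) else list(genome)
    regions: list[tuple[str, int, int]] = []
    for rec in records:
        L = model.window_len
        seq_len = len(rec)
        if seq_len < L:
            continue
        stre_hits = scan_iupac(rec, model.stre_pattern, collapse_palindromic=True)
        stre_starts = sorted(h.start for h in stre_hits)
        stre_len = len(model.stre_pattern)
        hse_hits: list[MotifHit] = []
        for alt in model.hse_alternatives:
            hse_hits.extend(scan_iupac(rec, alt))
        spans: set[tuple[int, int]] = set()
        for hse in hse_hits:
            lo = max(0, hse.end - L)
            hi = min(hse.start, seq_len - L)
            for w in range(lo, hi + 1):
                # STREs fully inside [w, w+L)
                i0 = bisect_left(stre_starts, w)
                i1 = bisect_right(stre_starts, w + L - stre_len)
                if i1 - i0 >= model.min_stre:
                    # evidence span: the matched elements, not the whole
                    # window, so the locus interval never spills into a CDS
                    span_start = min(hse.start, stre_starts[i0])
                    span_end = max(hse.end, stre_starts[i1 - 1] + stre_len)
                    spans.add((span_start, span_end))
        for start, end in sorted(spans):
            if regions and regions[-1][0] == rec.id and start <= regions[-1][2]:
                regions[-1] = (rec.id, regions[-1][1], max(end, regions[-1][2]))
            else:
                regions.append((rec.id, start, end))
    region_hits = [MotifHit(c, s, e, "+", "composite", 1.0) for c, s, e in regions]
    return assign_promoter(region_hits, annotation, promoter_window)


# ---------------------------------------------------------------------------
# Dot plots
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DotPlotBlock:
    """Maximal diagonal run of word matches between two sequences.

    ``length`` counts word matches in the run; the spanned sequence length is
    ``length + word_size - 1`` bp.  Forward blocks run down-right; reverse
    blocks (word equals the reverse complement of the partner word) run
    down-left.
    """

    x_start: int
    y_start: int
    length: int
    orientation: str  # "forward" | "reverse"


def dotplot(
    seq_x: str,
    seq_y: str,
    word_size: int = 8,
    min_block: int = 10,
) -> list[DotPlotBlock]:
    """Word-match dot plot: maximal diagonal runs spanning >= min_block bp."""
    if word_size < 4:
        raise ValueError("word_size must be >= 4")
    x, y = seq_x.upper(), seq_y.upper()
    if len(x) < word_size or len(y) < word_size:
        return []
    y_index: dict[str, list[int]] = {}
    for j in range(len(y) - word_size + 1):
        y_index.setdefault(y[j : j + word_size], []).append(j)

    fwd: dict[int, list[int]] = {}  # diagonal i-j -> sorted i
    rev: dict[int, list[int]] = {}  # antidiagonal i+j -> sorted i
    for i in range(len(x) - word_size + 1):
        word = x[i : i + word_size]
        for j in y_index.get(word, ()):
            fwd.setdefault(i - j, []).append(i)
        for j in y_index.get(reverse_complement(word), ()):
            rev.setdefault(i + j, []).append(i)

    blocks: list[DotPlotBlock] = []

    def harvest(diags: dict[int, list[int]], orientation: str) -> None:
        for key, positions in diags.items():
            positions.sort()
            run_start = prev = positions[0]
            for i in positions[1:] + [None]:
                if i is not None and i == prev + 1:
                    prev = i
                    continue
                length = prev - run_start + 1
                if length + word_size - 1 >= min_block:
                    j0 = run_start - key if orientation == "forward" else key - run_start
                    blocks.append(DotPlotBlock(run_start, j0, length, orientation))
                if i is not None:
                    run_start = prev = i
    harvest(fwd, "forward")
    harvest(rev, "reverse")
    blocks.sort(key=lambda b: (b.x_start, b.y_start, b.orientation))
    return blocks


def serial_block_test(blocks) -> bool:
    """True iff >= 2 forward blocks form a collinear chain (x and y orders agree)."""
    forward = sorted((b for b in blocks if b.orientation == "forward"), key=lambda b: b.x_start)
    for i, a in enumerate(forward):
        for b in forward[i + 1 :]:
            if b.x_start > a.x_start and b.y_start > a.y_start:
                return True
    return False
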