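"""Synthetic inputs with the statistical structure each analysis stage assumes.

Every generator is deterministic given its seed and returns a machine-readable
truth table alongside the data, so the screen, the motif scanners, the
co-expression ranking and the residue analysis can all be tested for exact
planted-truth recovery without any genome downloads.

The genome generator guarantees by *construction*, not by probability
argument, that consensus-model scans recover exactly the planted motifs:
background windows that happen to spell a planted model's consensus (on
either strand) are redrawn until none remain.  Matches that are logically
implied by a planted instance itself — e.g. any perfect HSE4 instance
necessarily contains a match to the more degenerate skipped/end-clipped HSE
patterns — are sanctioned and left alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import IUPAC_CODES, ConfigError, Gene, GenomeAnnotation, SequenceRecord, reverse_complement
from .motif_models import HseArrayModel, IupacMotif, expand_hse_array
from .ortholog_screen import EvalueMatrix, TaxonPanel
from .coexpression import ExpressionCompendium
from .residue_analysis import LabeledAlignment

SCREEN_STATUSES = (
    "retained_everywhere",
    "lost_in_animals",
    "lost_in_animals_with_contaminant",
    "lost_in_choanos_too",
    "absent_in_fungi",
)

#: Non-opisthokont clades used to label synthetic contaminant hits.
CONTAMINANT_TAXA = ("gamma_proteobacteria", "flavobacteria", "alpha_proteobacteria")


# ---------------------------------------------------------------------------
# E-value matrices with retained/lost/contaminant structure
# ---------------------------------------------------------------------------

def _log10e_to_evalue(x: float) -> float:
    return 10.0**x


def gen_evalue_matrix(
    n_genes: int,
    taxon_panel: TaxonPanel | None = None,
    loss_fraction: float = 0.05,
    contaminant_rate: float = 0.2,
    paralog_rate: float = 0.05,
    seed: int = 0,
    choano_loss_fraction: float = 0.05,
    fungal_absence_fraction: float = 0.05,
) -> tuple[EvalueMatrix, pd.DataFrame]:
    """Gene × taxon E-value matrix with planted loss structure plus truth.

    Statuses: genes lost in animals carry strong matches (log10 E uniform in
    [-180, -40]) in all non-animal taxa and no animal hit; a
    ``contaminant_rate`` share of them additionally get one animal cell with
    log10 E in [-60, -20], flagged with a non-opisthokont full-database
    taxon.  The contaminant draw is truncated to stay strictly worse than the
    gene's best non-animal holozoan match, so screen recovery is exact for
    every seed rather than merely probable.  Smaller fractions of genes are
    lost in choanoflagellates too (fail the choanoflagellate E-value stage)
    or absent from a Dikarya taxon (fail the orthology stage); the remainder
    are retained everywhere.  ``paralog_rate`` duplicates rows with jitter
    into two-member paralog groups.
    """
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    for name, frac in [
        ("loss_fraction", loss_fraction),
        ("contaminant_rate", contaminant_rate),
        ("paralog_rate", paralog_rate),
        ("choano_loss_fraction", choano_loss_fraction),
        ("fungal_absence_fraction", fungal_absence_fraction),
    ]:
        if not 0.0 <= frac <= 1.0:
            raise ConfigError(f"{name} must lie in [0, 1]")
    panel = taxon_panel or TaxonPanel()
    rng = np.random.default_rng(seed)

    taxa = sorted(panel.all_taxa)
    flag_taxa = sorted(panel.dikarya | panel.bilateria_seed)
    non_animal = sorted(set(taxa) - set(panel.animals))
    holozoa = sorted(panel.non_animal_holozoa)

    n_lost = round(n_genes * loss_fraction)
    n_cont = round(n_lost * contaminant_rate)
    n_choano = round(n_genes * choano_loss_fraction)
    n_fungal = round(n_genes * fungal_absence_fraction)
    if n_lost + n_choano + n_fungal > n_genes:
        raise ConfigError("status fractions exceed the gene count")

    width = len(str(n_genes))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]
    statuses = (
        ["lost_in_animals_with_contaminant"] * n_cont
        + ["lost_in_animals"] * (n_lost - n_cont)
        + ["lost_in_choanos_too"] * n_choano
        + ["absent_in_fungi"] * n_fungal
    )
    statuses += ["retained_everywhere"] * (n_genes - len(statuses))
    order = rng.permutation(n_genes)
    status_by_gene = {gene_ids[i]: statuses[order[i]] for i in range(n_genes)}

    def strong() -> float:
        return _log10e_to_evalue(rng.uniform(-180.0, -40.0))

    def present_flag() -> str:
        return "one2many" if rng.random() < 0.1 else "one2one"

    ev_rows, flag_rows = {}, {}
    animal_hit_taxon: dict[str, str] = {}
    truth_rows = []
    for gene in gene_ids:
        status = status_by_gene[gene]
        ev = {t: math.inf for t in taxa}
        flags = {}
        if status == "retained_everywhere":
            for t in taxa:
                ev[t] = strong()
            flags = {t: present_flag() for t in flag_taxa}
        elif status in {"lost_in_animals", "lost_in_animals_with_contaminant"}:
            for t in non_animal:
                ev[t] = strong()
            flags = {t: present_flag() for t in sorted(panel.dikarya)}
            flags.update({t: "none" for t in sorted(panel.bilateria_seed)})
            if status == "lost_in_animals_with_contaminant":
                animal = rng.choice(sorted(panel.animals))
                best_holo_log10 = min(math.log10(ev[t]) for t in holozoa)
                lo = max(-60.0, best_holo_log10 + 1.0)
                ev[animal] = _log10e_to_evalue(rng.uniform(lo, -20.0))
                animal_hit_taxon[gene] = str(rng.choice(CONTAMINANT_TAXA))
        elif status == "lost_in_choanos_too":
            for t in sorted(panel.dikarya):
                ev[t] = strong()
            flags = {t: present_flag() for t in sorted(panel.dikarya)}
            flags.update({t: "none" for t in sorted(panel.bilateria_seed)})
        elif status == "absent_in_fungi":
            missing = rng.choice(sorted(panel.dikarya))
            for t in taxa:
                ev[t] = strong()
            ev[missing] = math.inf
            flags = {t: present_flag() for t in flag_taxa}
            flags[missing] = "none"
        ev_rows[gene] = ev
        flag_rows[gene] = flags
        truth_rows.append(
            {
                "gene": gene,
                "status": status,
                "paralog_group": gene,
                "contaminant_taxon": animal_hit_taxon.get(gene, ""),
            }
        )

    # duplicate rows with jitter into paralog pairs
    n_par = round(n_genes * paralog_rate)
    paralog_parents = [gene_ids[i] for i in rng.choice(n_genes, size=n_par, replace=False)]
    for parent in paralog_parents:
        dup = parent + "p"
        status = status_by_gene[parent]
        ev = {}
        for t, e in ev_rows[parent].items():
            if e == math.inf:
                ev[t] = math.inf
            else:
                ev[t] = _log10e_to_evalue(
                    float(np.clip(math.log10(e) + rng.uniform(-2.0, 2.0), -180.0, -20.0))
                )
        if parent in animal_hit_taxon:
            best_holo_log10 = min(math.log10(ev[t]) for t in holozoa)
            for t in sorted(panel.animals):
                if ev[t] != math.inf:
                    lo = max(-60.0, best_holo_log10 + 1.0)
                    ev[t] = _log10e_to_evalue(
                        float(np.clip(math.log10(ev[t]), lo, -20.0))
                    )
            animal_hit_taxon[dup] = animal_hit_taxon[parent]
        ev_rows[dup] = ev
        flag_rows[dup] = dict(flag_rows[parent])
        status_by_gene[dup] = status
        truth_rows.append(
            {
                "gene": dup,
                "status": status,
                "paralog_group": parent,
                "contaminant_taxon": animal_hit_taxon.get(dup, ""),
            }
        )
        for row in truth_rows:
            if row["gene"] == parent:
                row["paralog_group"] = parent

    all_ids = list(ev_rows)
    evalues = pd.DataFrame([ev_rows[g] for g in all_ids], index=all_ids)[taxa]
    flags = pd.DataFrame([flag_rows[g] for g in all_ids], index=all_ids)[flag_taxa]
    truth = pd.DataFrame(truth_rows).set_index("gene")
    matrix = EvalueMatrix(evalues, flags, animal_hit_taxon=animal_hit_taxon)
    return matrix, truth


def truth_paralog_groups(truth: pd.DataFrame) -> list[set[str]]:
    """Multi-member paralog groups implied by a screen truth table."""
    groups: dict[str, set[str]] = {}
    for gene, row in truth.iterrows():
        groups.setdefault(row["paralog_group"], set()).add(gene)
    return [g for g in groups.values() if len(g) > 1]


# ---------------------------------------------------------------------------
# Genomes with planted promoter motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantSpec:
    """One motif instance to plant: gene, model and upstream offset.

    ``offset`` is the gap in bp between the planted element's downstream end
    and the ORF start on the gene's upstream side.  ``model`` may be an
    IupacMotif, an HseArrayModel (first expanded pattern is planted) or a
    CompositeModel (one HSE alternative plus ``min_stre`` STREs are planted
    within the architecture window).
    """

    gene_id: str
    model: object
    offset: int


def _allowed(code: str) -> tuple[str, ...]:
    return tuple(sorted(IUPAC_CODES[code]))


def _pattern_subsumes(general: str, specific: str) -> bool:
    """True iff every sequence matching ``specific`` also matches ``general``."""
    if len(general) != len(specific):
        return False
    return all(IUPAC_CODES[s] <= IUPAC_CODES[g] for g, s in zip(general, specific))


def _rejection_patterns(plants: Sequence[PlantSpec]) -> list[IupacMotif]:
    out: dict[str, IupacMotif] = {}
    for plant in plants:
        model = plant.model
        if isinstance(model, IupacMotif):
            motifs = [model]
        elif isinstance(model, HseArrayModel):
            motifs = expand_hse_array(model)
        elif hasattr(model, "hse_alternatives"):  # CompositeModel
            motifs = list(model.hse_alternatives) + [model.stre_pattern]
        else:
            raise ConfigError(f"unsupported plant model {model!r}")
        for m in motifs:
            out.setdefault(m.pattern, m)
    return list(out.values())


def _sample_instance(pattern: str, rng, forbidden: list[str]) -> str:
    """A concrete sequence matching ``pattern`` containing no accidental
    internal match to any non-implied forbidden pattern (either strand)."""
    for _ in range(200):
        inst = "".join(rng.choice(_allowed(c)) for c in pattern)
        ok = True
        for q in forbidden:
            for view, pat in ((inst, pattern), (reverse_complement(inst), reverse_complement(pattern))):
                for a in range(len(view) - len(q) + 1):
                    if _pattern_subsumes(q, pat[a : a + len(q)]):
                        continue  # implied by the model itself; unavoidable
                    window = view[a : a + len(q)]
                    if all(b in IUPAC_CODES[c] for b, c in zip(window, q)):
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            return inst
    raise RuntimeError(f"could not sample a clean instance of {pattern}")


def gen_genome_with_motifs(
    n_genes: int,
    intergenic_len: int = 500,
    gc: float = 0.38,
    plants: Sequence[PlantSpec] = (),
    seed: int = 0,
    cds_len: int = 600,
    extra_reject: Sequence[IupacMotif] = (),
) -> tuple[list[SequenceRecord], GenomeAnnotation, pd.DataFrame]:
    """Single-contig genome with planted promoter motifs and exact truth.

    Genes alternate with intergenic stretches of ``intergenic_len`` bp on one
    chromosome; strands are random.  Background bases are i.i.d. at the given
    GC; any background window matching a planted model's consensus (either
    strand) is redrawn until the only matches left are the planted ones, so
    consensus scans equal the truth table exactly.  ``extra_reject`` adds
    models to the rejection set without planting them — useful for clean
    negative-control genomes.
    """
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    if not 0.0 < gc < 1.0:
        raise ConfigError("gc must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    chrom = "chr1"

    annotation = GenomeAnnotation()
    gene_ids = [f"g{i}" for i in range(1, n_genes + 1)]
    pos = 0
    for gid in gene_ids:
        pos += intergenic_len
        strand = "+" if rng.random() < 0.5 else "-"
        annotation.add(Gene(gid, chrom, strand, pos, pos + cds_len))
        pos += cds_len
    total_len = pos + intergenic_len

    bg_weights = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(["A", "C", "G", "T"])

    def draw_bg() -> str:
        return str(rng.choice(bases, p=bg_weights))

    letters: list[str] = [draw_bg() for _ in range(total_len)]
    allowed: list[tuple[str, ...] | None] = [None] * total_len  # None = background

    rejection = _rejection_patterns(plants)
    for motif in extra_reject:
        if motif.pattern not in {m.pattern for m in rejection}:
            rejection.append(motif)
    rejection_strings = [m.pattern for m in rejection]

    # --- plant the instances -------------------------------------------------
    truth_rows = []

    def place(pattern: str, gene: Gene, gap: int, model_id: str) -> tuple[int, int]:
        length = len(pattern)
        if gap < 0 or gap + length > intergenic_len:
            raise ConfigError(
                f"plant for {gene.gene_id}: offset {gap} + motif length {length} "
                f"exceeds intergenic_len {intergenic_len}"
            )
        if gene.strand == "+":
            start = gene.cds_start - gap - length
            genome_pattern = pattern
        else:
            start = gene.cds_end + gap
            genome_pattern = reverse_complement(pattern)
        instance = _sample_instance(genome_pattern, rng, rejection_strings)
        for i, (base, code) in enumerate(zip(instance, genome_pattern)):
            if allowed[start + i] is not None:
                raise ConfigError(f"plants overlap at {chrom}:{start + i}")
            letters[start + i] = base
            allowed[start + i] = _allowed(code)
        # palindromic consensus matches collapse to '+' when scanned
        palindromic = reverse_complement(genome_pattern) == genome_pattern
        truth_rows.append(
            {
                "gene_id": gene.gene_id,
                "model_id": model_id,
                "chrom": chrom,
                "start": start,
                "end": start + length,
                "strand": "+" if palindromic else gene.strand,
            }
        )
        return start, start + length

    for plant in plants:
        if plant.gene_id not in annotation.genes:
            raise ConfigError(f"plant references unknown gene {plant.gene_id!r}")
        gene = annotation[plant.gene_id]
        model = plant.model
        if isinstance(model, IupacMotif):
            place(model.pattern, gene, plant.offset, model.name)
        elif isinstance(model, HseArrayModel):
            place(expand_hse_array(model)[0].pattern, gene, plant.offset, "hse_array")
        elif hasattr(model, "hse_alternatives"):  # CompositeModel
            hse = model.hse_alternatives[0]
            stre = model.stre_pattern
            spacing = len(stre) + 8
            span = plant.offset + len(hse) + 6 + model.min_stre * spacing
            if span > model.window_len:
                raise ConfigError("architecture plant does not fit the model window")
            place(hse.pattern, gene, plant.offset, "composite")
            for k in range(model.min_stre):
                gap = plant.offset + len(hse) + 6 + k * spacing
                place(stre.pattern, gene, gap, f"composite_stre")
        else:
            raise ConfigError(f"unsupported plant model {model!r}")

    # --- rejection resampling ------------------------------------------------
    # sanctioned[pattern_string] = match starts implied by the plants
    plant_spans = [
        (row["start"], row["end"]) for row in truth_rows
    ]
    genome_patterns: list[tuple[int, str]] = []
    for (start, end) in plant_spans:
        genome_patterns.append((start, "".join(_code_of(allowed[i]) for i in range(start, end))))

    orientations: dict[str, object] = {}
    for motif in rejection:
        for pat in {motif.pattern, reverse_complement(motif.pattern)}:
            orientations[pat] = IupacMotif(pat).to_regex()

    sanctioned: dict[str, set[int]] = {pat: set() for pat in orientations}
    for pat in orientations:
        L = len(pat)
        for p_start, p_pattern in genome_patterns:
            for a in range(len(p_pattern) - L + 1):
                if _pattern_subsumes(pat, p_pattern[a : a + L]):
                    sanctioned[pat].add(p_start + a)

    for _ in range(500):
        genome_str = "".join(letters)
        offending: list[tuple[int, int]] = []
        for pat, regex in orientations.items():
            for m in regex.finditer(genome_str):
                if m.start() not in sanctioned[pat]:
                    offending.append((m.start(), len(pat)))
        if not offending:
            break
        for start, length in offending:
            redrawn = False
            for i in range(start, start + length):
                opts = allowed[i]
                if opts is None:
                    letters[i] = draw_bg()
                    redrawn = True
                elif len(opts) > 1:
                    letters[i] = str(rng.choice(opts))
                    redrawn = True
            if not redrawn:
                raise RuntimeError(
                    f"spurious match at {start} cannot be removed: all positions fixed"
                )
    else:
        raise RuntimeError("rejection resampling did not converge")

    genome = [SequenceRecord(chrom, "".join(letters))]
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "model_id", "chrom", "start", "end", "strand"]
    )
    return genome, annotation, truth


def _code_of(opts: tuple[str, ...] | None) -> str:
    """IUPAC code whose allowed set equals ``opts`` (background = N)."""
    if opts is None:
        return "N"
    target = frozenset(opts)
    for code, chars in IUPAC_CODES.items():
        if chars == target:
            return code
    raise ValueError(f"no IUPAC code for {opts}")


# ---------------------------------------------------------------------------
# Expression compendia with a planted regulon
# ---------------------------------------------------------------------------

def gen_expression_compendium(
    n_datasets: int,
    n_genes: int,
    regulon: Sequence[str],
    rho: float = 0.7,
    noise_sd: float = 1.0,
    samples_per_dataset: int = 10,
    seed: int = 0,
) -> tuple[ExpressionCompendium, list[str]]:
    """Datasets in which regulon genes share a latent per-dataset factor.

    Each regulon gene's profile is sqrt(rho)·f + sqrt(1-rho)·eps with f a
    dataset-specific standard-normal factor and eps independent noise of SD
    ``noise_sd``; at noise_sd = 1 the pairwise correlation between regulon
    members is rho.  Non-regulon genes are pure noise.
    """
    if samples_per_dataset < 3:
        raise ConfigError("samples_per_dataset must be >= 3 (correlation degenerate)")
    if not 0.0 <= rho < 1.0:
        raise ConfigError("rho must lie in [0, 1)")
    width = len(str(n_genes))
    gene_ids = [f"y{i:0{width}d}" for i in range(1, n_genes + 1)]
    unknown = [g for g in regulon if g not in gene_ids]
    if unknown:
        raise ConfigError(f"regulon genes outside the universe: {unknown}")
    rng = np.random.default_rng(seed)
    regulon_set = set(regulon)
    datasets = []
    for d in range(n_datasets):
        factor = rng.standard_normal(samples_per_dataset)
        data = np.empty((n_genes, samples_per_dataset))
        for i, gene in enumerate(gene_ids):
            eps = rng.standard_normal(samples_per_dataset) * noise_sd
            if gene in regulon_set:
                data[i] = math.sqrt(rho) * factor + math.sqrt(1.0 - rho) * eps
            else:
                data[i] = eps
        frame = pd.DataFrame(
            data, index=gene_ids, columns=[f"s{j}" for j in range(samples_per_dataset)]
        )
        datasets.append((f"ds{d:03d}", frame))
    return ExpressionCompendium(datasets), sorted(regulon_set)


# ---------------------------------------------------------------------------
# Two-family alignments with controlled family-specific columns
# ---------------------------------------------------------------------------

_HYDROPHOBIC = "VLIMFWC"
_NON_HYDROPHOBIC = "DEKRNQHTY"
_ALL_AA = "ACDEFGHIKLMNPQRSTVWY"


def gen_labeled_alignment(
    n_per_family: int,
    n_cols: int,
    n_specific: int,
    hydrophobic_frac: float = 0.5,
    seed: int = 0,
    families: tuple[str, str] = ("famA", "famB"),
) -> tuple[LabeledAlignment, pd.DataFrame]:
    """Two-family alignment with planted family-specific columns.

    ``n_specific`` columns are fixed within each family at differing
    residues; a ``hydrophobic_frac`` share of family-A consensus residues
    come from the hydrophobic set {V,L,I,M,F,W,C}, the rest from outside it.
    Remaining columns share one residue across both families (with sparse
    single-row substitutions that break conservation without creating
    family-specific columns).
    """
    if n_per_family < 2:
        raise ConfigError("n_per_family must be >= 2")
    if n_specific > n_cols:
        raise ConfigError("n_specific cannot exceed n_cols")
    if not 0.0 <= hydrophobic_frac <= 1.0:
        raise ConfigError("hydrophobic_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    fam_a, fam_b = families
    n_rows = 2 * n_per_family

    specific_cols = sorted(int(c) for c in rng.choice(n_cols, size=n_specific, replace=False))
    specific_set = set(specific_cols)
    n_hydro = round(n_specific * hydrophobic_frac)
    columns = np.empty((n_rows, n_cols), dtype="<U1")
    truth_rows = []
    for col in range(n_cols):
        shared = str(rng.choice(list(_ALL_AA)))
        columns[:, col] = shared
    for rank, col in enumerate(specific_cols):
        if rank < n_hydro:
            res_a = str(rng.choice(list(_HYDROPHOBIC)))
        else:
            res_a = str(rng.choice(list(_NON_HYDROPHOBIC)))
        choices_b = [c for c in _NON_HYDROPHOBIC if c != res_a]
        res_b = str(rng.choice(choices_b))
        columns[:n_per_family, col] = res_a
        columns[n_per_family:, col] = res_b
        truth_rows.append(
            {
                "column": col,
                "residue_a": res_a,
                "residue_b": res_b,
                "hydrophobic_a": res_a in _HYDROPHOBIC,
            }
        )
    # sparse substitutions in shared columns only
    for col in range(n_cols):
        if col in specific_set:
            continue
        if rng.random() < 0.15:
            row = int(rng.integers(n_rows))
            current = columns[row, col]
            columns[row, col] = str(rng.choice([c for c in _ALL_AA if c != current]))

    rows = []
    for i in range(n_per_family):
        rows.append((f"{fam_a}_{i}", fam_a, "".join(columns[i])))
    for i in range(n_per_family):
        rows.append((f"{fam_b}_{i}", fam_b, "".join(columns[n_per_family + i])))
    truth = pd.DataFrame(truth_rows, columns=["column", "residue_a", "residue_b", "hydrophobic_a"])
    return LabeledAlignment(rows), truth
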