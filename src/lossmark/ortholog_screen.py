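"""Staged phylogenetic-profiling screen for genes lost in animals.

The screen starts from a fungal reference proteome and asks which genes are
retained across fungi and the closest non-animal relatives of animals
(choanoflagellates and filastereans) yet undetectable in animals themselves:

1. orthology calls present in all Dikarya panel taxa, absent in two
   well-assembled bilaterians (lineage-specific duplications accepted);
2. a strong BLASTP match in the primary choanoflagellate (E < 1e-30, strict);
3. detectable matches in the secondary holozoans (E < 1e-10 in each, strict);
4. no animal match better than the best non-animal holozoan match.

Survivors collapse into genetic functions by merging lineage-specific
paralog pairs, residual animal hits are classified (contaminant/HGT,
non-ortholog, possible ortholog), and a PFAM-complement screen adds gene
families absent from the reference proteome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .io_core import NO_HIT, BlastHitTable, ConfigError, logger

PRESENT_FLAGS = {"one2one", "one2many", "many2many"}
ORTHOLOGY_FLAGS = PRESENT_FLAGS | {"none"}

#: Clades whose best-matching full-database taxon counts as opisthokont
#: (fungi + holozoa); a residual animal hit whose closest relative lies
#: outside this set is flagged as contamination or horizontal transfer.
DEFAULT_OPISTHOKONTS = frozenset(
    {
        "S_cerevisiae", "S_pombe", "C_neoformans", "P_graminis", "B_dendrobatidis",
        "M_brevicollis", "S_rosetta", "C_owczarzaki",
        "A_queenslandica", "M_leidyi", "T_adhaerens", "L_gigantea", "C_teleta",
        "H_robusta", "D_melanogaster", "H_sapiens",
        "Fungi", "Choanoflagellata", "Filasterea", "Metazoa",
    }
)


@dataclass(frozen=True)
class TaxonPanel:
    """The taxon roles the four screen stages compare against."""

    dikarya: frozenset = frozenset({"S_pombe", "C_neoformans", "P_graminis"})
    bilateria_seed: frozenset = frozenset({"D_melanogaster", "H_sapiens"})
    choano_primary: str = "M_brevicollis"
    holozoa_secondary: frozenset = frozenset({"S_rosetta", "C_owczarzaki"})
    animals: frozenset = frozenset(
        {
            "A_queenslandica", "M_leidyi", "T_adhaerens", "L_gigantea",
            "C_teleta", "H_robusta", "D_melanogaster", "H_sapiens",
        }
    )

    def __post_init__(self) -> None:
        non_animal = [self.dikarya, {self.choano_primary}, self.holozoa_secondary]
        for i, a in enumerate(non_animal):
            for b in non_animal[i + 1 :]:
                if set(a) & set(b):
                    raise ConfigError("panel taxon sets must be pairwise disjoint")
        if not self.bilateria_seed <= self.animals:
            raise ConfigError("bilateria_seed taxa must be among the animal taxa")

    @property
    def all_taxa(self) -> frozenset:
        return frozenset(
            set(self.dikarya) | {self.choano_primary} | set(self.holozoa_secondary) | set(self.animals)
        )

    @property
    def non_animal_holozoa(self) -> frozenset:
        return frozenset({self.choano_primary} | set(self.holozoa_secondary))


@dataclass
class EvalueMatrix:
    """Gene × taxon best E-values plus companion orthology flags.

    ``evalues`` holds best-hit E-values (+inf = no hit).  ``ortho_flags``
    covers the taxa where orthology calls rather than raw BLAST are used
    (stage 1).  ``animal_hit_taxon`` and ``reciprocal_family`` carry the
    precomputed full-database lookups consumed by residual-hit
    classification; they are inputs, not live queries.
    """

    evalues: pd.DataFrame
    ortho_flags: pd.DataFrame
    animal_hit_taxon: dict = field(default_factory=dict)
    reciprocal_family: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        finite = self.evalues.replace(math.inf, float("nan"))
        if (finite < 0).any().any():
            raise ConfigError("E-values must be >= 0")
        bad = ~self.ortho_flags.isin(ORTHOLOGY_FLAGS) & self.ortho_flags.notna()
        if bad.any().any():
            raise ConfigError("orthology flags must be one2one/one2many/many2many/none")

    @property
    def genes(self) -> list[str]:
        return list(self.evalues.index)

    def check_panel(self, panel: TaxonPanel) -> None:
        missing = panel.all_taxa - set(self.evalues.columns)
        if missing:
            raise ConfigError(f"matrix lacks panel taxa: {sorted(missing)}")


# ---------------------------------------------------------------------------
# The four screen stages
# ---------------------------------------------------------------------------

def stage1_dikarya_filter(matrix: EvalueMatrix, panel: TaxonPanel) -> set[str]:
    """Genes with an ortholog call in every Dikarya taxon and none in the
    two bilaterian seeds (one2many accepted: lineage-specific duplications
    of a single ancestral gene are not losses)."""
    flag_taxa = sorted(panel.dikarya | panel.bilateria_seed)
    for taxon in flag_taxa:
        if taxon not in matrix.ortho_flags.columns:
            raise ConfigError(f"missing orthology flags for taxon {taxon!r}")
    kept: set[str] = set()
    flags = matrix.ortho_flags
    for gene in matrix.genes:
        row = flags.loc[gene]
        for taxon in flag_taxa:
            if pd.isna(row[taxon]):
                raise ConfigError(f"missing orthology flag for ({gene!r}, {taxon!r})")
        if all(row[t] in PRESENT_FLAGS for t in panel.dikarya) and all(
            row[t] == "none" for t in panel.bilateria_seed
        ):
            kept.add(gene)
    return kept


def stage2_choano_filter(
    genes: Iterable[str],
    matrix: EvalueMatrix,
    panel: TaxonPanel,
    threshold: float = 1e-30,
) -> set[str]:
    """Keep genes with E strictly below ``threshold`` in the primary
    choanoflagellate (boundary equality fails: 'lower than')."""
    col = matrix.evalues[panel.choano_primary]
    return {g for g in genes if col[g] < threshold}


def stage3_holozoa_filter(
    genes: Iterable[str],
    matrix: EvalueMatrix,
    panel: TaxonPanel,
    threshold: float = 1e-10,
) -> set[str]:
    """Keep genes detectable (E strictly below threshold) in every secondary
    holozoan."""
    ev = matrix.evalues
    return {
        g
        for g in genes
        if all(ev.loc[g, t] < threshold for t in panel.holozoa_secondary)
    }


def stage4_animal_comparison(
    genes: Iterable[str],
    matrix: EvalueMatrix,
    panel: TaxonPanel,
    mode: str = "best",
) -> set[str]:
    """Drop genes whose best animal match beats the non-animal holozoans.

    ``mode='best'`` (default) compares against the single best of the three
    non-animal holozoans; ``mode='worst'`` against the worst, the alternative
    reading of "better than any".  A gene with no animal hits is always kept.
    """
    if mode not in {"best", "worst"}:
        raise ConfigError(f"stage4_mode must be 'best' or 'worst', got {mode!r}")
    ev = matrix.evalues
    kept: set[str] = set()
    for gene in genes:
        best_animal = min(ev.loc[gene, t] for t in panel.animals)
        holo = [ev.loc[gene, t] for t in panel.non_animal_holozoa]
        ref = min(holo) if mode == "best" else max(holo)
        if not best_animal < ref:
            kept.add(gene)
    return kept


@dataclass
class ScreenResult:
    """Stage trace, surviving genes, residual-hit classes and functions."""

    stage_sets: dict
    final: set
    classifications: dict
    functions: list


def run_screen(
    matrix: EvalueMatrix,
    panel: TaxonPanel | None = None,
    choano_threshold: float = 1e-30,
    holozoa_threshold: float = 1e-10,
    stage4_mode: str = "best",
    paralog_groups: Sequence[Iterable[str]] = (),
) -> ScreenResult:
    """Run all four stages, classify residual hits and collapse paralogs."""
    panel = panel or TaxonPanel()
    matrix.check_panel(panel)
    s1 = stage1_dikarya_filter(matrix, panel)
    s2 = stage2_choano_filter(s1, matrix, panel, choano_threshold)
    s3 = stage3_holozoa_filter(s2, matrix, panel, holozoa_threshold)
    s4 = stage4_animal_comparison(s3, matrix, panel, stage4_mode)
    classifications = {}
    for gene in sorted(s4):
        best_animal = min(matrix.evalues.loc[gene, t] for t in panel.animals)
        hit = None if best_animal == NO_HIT else best_animal
        classifications[gene] = classify_residual_hit(
            gene,
            hit,
            matrix.animal_hit_taxon.get(gene),
            matrix.reciprocal_family.get(gene),
        )
    functions = collapse_paralogs(s4, paralog_groups)
    return ScreenResult(
        stage_sets={1: s1, 2: s2, 3: s3, 4: s4},
        final=s4,
        classifications=classifications,
        functions=functions,
    )


# ---------------------------------------------------------------------------
# Paralog collapse and residual-hit classification
# ---------------------------------------------------------------------------

def collapse_paralogs(
    genes: Iterable[str],
    paralog_groups: Sequence[Iterable[str]],
) -> list[str]:
    """Merge lineage-specific duplicates into one genetic function each.

    Each group contributes a single function named by its surviving members
    joined with '/'; ungrouped genes are their own function.  Function ids
    come back sorted.
    """
    genes = set(genes)
    assigned: dict[str, int] = {}
    for gi, group in enumerate(paralog_groups):
        for g in group:
            if g in assigned:
                raise ConfigError(f"gene {g!r} appears in two paralog groups")
            assigned[g] = gi
    functions: dict[int, set[str]] = {}
    singletons: list[str] = []
    for gene in genes:
        if gene in assigned:
            functions.setdefault(assigned[gene], set()).add(gene)
        else:
            singletons.append(gene)
    names = ["/".join(sorted(members)) for members in functions.values()]
    return sorted(names + singletons)


def classify_residual_hit(
    gene: str,
    best_animal_hit: float | None,
    full_db_best_taxon: str | None,
    reciprocal_family: str | None,
    query_family: str | None = None,
    opisthokonts: frozenset = DEFAULT_OPISTHOKONTS,
) -> str:
    """Classify the best residual animal match of a surviving gene.

    - ``no_hit``: no animal match at all;
    - ``contaminant_or_hgt``: the animal sequence's closest full-database
      relative is non-opisthokont (environmental contamination or horizontal
      transfer, e.g. an endosymbiont ClpB fragment in a sponge assembly);
    - ``non_ortholog``: the reciprocal best match belongs to a different
      named family (e.g. a homoaconitase query recovering aconitase);
    - ``possible_ortholog``: none of the above.
    """
    if best_animal_hit is None:
        if full_db_best_taxon is not None:
            raise ConfigError(
                f"{gene}: no animal hit but a full-database taxon was supplied"
            )
        return "no_hit"
    if full_db_best_taxon is not None and full_db_best_taxon not in opisthokonts:
        return "contaminant_or_hgt"
    family = query_family if query_family is not None else gene
    if reciprocal_family is not None and reciprocal_family != family:
        return "non_ortholog"
    return "possible_ortholog"


# ---------------------------------------------------------------------------
# PFAM-complement secondary screen
# ---------------------------------------------------------------------------

def pfam_complement_screen(
    domain_table: pd.DataFrame,
    protein_hits: BlastHitTable,
    present_taxa: Iterable[str],
    absent_taxa: Iterable[str],
    domain_queries: Mapping[str, str],
    hit_taxa: Iterable[str],
    threshold: float = 1e-30,
) -> list[str]:
    """Domains present outside animals, absent in animals, and whose
    representative protein hits a choanoflagellate/filasterean proteome
    with E strictly below ``threshold``.

    ``domain_table`` is a boolean domain × taxon presence table;
    ``domain_queries`` maps each domain to its representative query protein
    in ``protein_hits``.  Domains with no representative are skipped with a
    warning.  The presence/absence E-value criterion the original taxonomy
    query used is not recorded anywhere, so the threshold is a stated choice.
    """
    present_taxa, absent_taxa = list(present_taxa), list(absent_taxa)
    hit_taxa = list(hit_taxa)
    out: list[str] = []
    for domain in domain_table.index:
        row = domain_table.loc[domain]
        if not all(bool(row[t]) for t in present_taxa):
            continue
        if any(bool(row[t]) for t in absent_taxa):
            continue
        query = domain_queries.get(domain)
        if query is None:
            logger.warning("pfam screen: domain %s has no representative protein; skipped", domain)
            continue
        best = min(protein_hits.best_evalue(query, t) for t in hit_taxa)
        if best < threshold:
            out.append(domain)
    return sorted(out)


def merge_screens(main_functions: Sequence[str], alternate_genes: Sequence[str]) -> list[str]:
    """Union of the main-screen function list with an alternate gene list.

    An alternate gene matches an existing function when it is one of the
    function's member genes (function ids are '/'-joined member lists);
    unmatched alternates are appended as new single-gene functions.
    """
    members = {m for f in main_functions for m in f.split("/")}
    merged = list(main_functions)
    for gene in alternate_genes:
        if gene not in members and gene not in merged:
            merged.append(gene)
            members.add(gene)
    return sorted(merged)


# ---------------------------------------------------------------------------
# Heat-map binning and enrichment
# ---------------------------------------------------------------------------

DEFAULT_BREAKPOINTS = (1e-100, 1e-30, 1e-20, 1e-10)


def evalue_bins(
    matrix: pd.DataFrame,
    breakpoints: Sequence[float] = DEFAULT_BREAKPOINTS,
) -> pd.DataFrame:
    """Ordinal heat-map bins: bin 0 strongest; boundary E falls in the
    stronger bin (E <= breakpoint); +inf maps to "absent"."""
    bp = list(breakpoints)
    if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
        raise ConfigError("breakpoints must be strictly monotone in E")

    def bin_one(e: float):
        if e == NO_HIT or pd.isna(e):
            return "absent"
        for i, b in enumerate(bp):
            if e <= b:
                return i
        return len(bp)

    return matrix.map(bin_one)


def category_enrichment(
    selected: Iterable[str],
    background: Iterable[str],
    category_members: Iterable[str],
) -> tuple[int, float]:
    """Upper-tail hypergeometric enrichment of a category in a selection.

    Returns (overlap count, P[overlap >= observed]) for drawing
    ``len(selected)`` genes without replacement from the background.
    """
    background = set(background)
    if not background:
        raise ConfigError("empty background")
    selected = set(selected)
    if not selected <= background:
        raise ConfigError("selected genes must be a subset of the background")
    category = set(category_members) & background
    overlap = len(selected & category)
    p = float(hypergeom.sf(overlap - 1, len(background), len(category), len(selected)))
    return overlap, p


def adjust_bh(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values for multi-category testing."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvalues[idx] * m / rank)
        adjusted[idx] = running
    return adjusted
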