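"""Family-specific residues and their hydrophobic fraction.

Given a multiple alignment whose rows are labelled with protein-family names
(e.g. homoaconitase Lys4 vs TCA-cycle aconitase Aco1), a column is
family-specific when each family is conserved at its own residue and the two
residues differ.  The hydrophobic fraction of those family-consensus
residues is the aggregation-propensity statistic: exposed hydrophobics are
what disaggregase chaperones recognise in heat-denatured clients.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io_core import ConfigError, logger

GAP = "-"


@dataclass(frozen=True)
class ResidueClassScheme:
    """Residue classes used in reports; hydrophobic and small-neutral must be
    disjoint (alanine is classed small-neutral, not hydrophobic)."""

    hydrophobic: frozenset = frozenset("VLIMFWC")
    small_neutral: frozenset = frozenset("GASP")

    def __post_init__(self) -> None:
        if self.hydrophobic & self.small_neutral:
            raise ConfigError("hydrophobic and small-neutral sets must be disjoint")


@dataclass
class LabeledAlignment:
    """Aligned rows carrying (sequence id, family label, gapped sequence)."""

    rows: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ConfigError("empty alignment")
        length = len(self.rows[0][2])
        if any(len(seq) != length for _, _, seq in self.rows):
            raise ConfigError("alignment rows must all have the same length")
        counts = Counter(family for _, family, _ in self.rows)
        if len(counts) < 2:
            raise ConfigError("alignment needs at least 2 families")
        small = [f for f, n in counts.items() if n < 2]
        if small:
            raise ConfigError(f"families need >= 2 rows each; too few in {small}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][2])

    def family_rows(self, family: str) -> list[str]:
        out = [seq for _, fam, seq in self.rows if fam == family]
        if not out:
            raise ConfigError(f"family {family!r} not present in alignment")
        return out


def _column_consensus(seqs: list[str], col: int, conservation: float) -> str | None:
    """Residue shared at >= conservation frequency (gaps excluded), else None."""
    residues = [s[col] for s in seqs if s[col] != GAP]
    if not residues:
        return None
    residue, count = Counter(residues).most_common(1)[0]
    return residue if count / len(residues) >= conservation else None


def family_specific_columns(
    alignment: LabeledAlignment,
    family_a: str,
    family_b: str,
    conservation: float = 1.0,
) -> dict[int, tuple[str, str]]:
    """Columns conserved within each family at different residues.

    Returns {column index: (family_a consensus, family_b consensus)}.
    ``conservation`` is the minimum within-family frequency of the consensus
    residue; the default 1.0 demands strict identity.
    """
    if not (0.5 < conservation <= 1.0):
        raise ConfigError("conservation must lie in (0.5, 1]")
    rows_a = alignment.family_rows(family_a)
    rows_b = alignment.family_rows(family_b)
    out: dict[int, tuple[str, str]] = {}
    for col in range(alignment.n_cols):
        res_a = _column_consensus(rows_a, col, conservation)
        res_b = _column_consensus(rows_b, col, conservation)
        if res_a is not None and res_b is not None and res_a != res_b:
            out[col] = (res_a, res_b)
    return out


def hydrophobic_fraction(
    columns_with_consensus: Mapping[int, str] | Iterable[str],
    scheme: ResidueClassScheme = ResidueClassScheme(),
) -> tuple[int, int, float]:
    """(hydrophobic count, total, fraction) over family-consensus residues.

    Accepts either a {column: residue} mapping or a plain residue iterable.
    An empty input is flagged and yields NaN.
    """
    if isinstance(columns_with_consensus, Mapping):
        residues = list(columns_with_consensus.values())
    else:
        residues = list(columns_with_consensus)
    total = len(residues)
    if total == 0:
        logger.warning("hydrophobic_fraction: no columns; fraction undefined")
        return (0, 0, math.nan)
    count = sum(1 for r in residues if r.upper() in scheme.hydrophobic)
    return (count, total, count / total)
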