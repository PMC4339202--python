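"""Fisher-z aggregated co-expression ranking across an expression compendium.

For a query gene (or the mean standardised profile of several), each dataset
contributes a Pearson correlation r with every other gene; r is
variance-stabilised with Fisher's z = atanh(r) and the per-dataset z values
are averaged into a combined score used for ranking.  Under independence,
z·sqrt(n-3) is approximately standard normal for a dataset with n samples,
which gives the null calibration the tests rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import ConfigError, logger

_R_CLIP = 1.0 - 1e-12


@dataclass
class ExpressionCompendium:
    """A list of (dataset id, genes × samples matrix) with a shared universe.

    Gene ids are harmonised across datasets; a gene may be missing from some
    datasets and is then simply skipped there.
    """

    datasets: list[tuple[str, pd.DataFrame]]

    def __post_init__(self) -> None:
        for ds_id, frame in self.datasets:
            if frame.shape[1] < 3:
                raise ConfigError(f"dataset {ds_id!r} has fewer than 3 samples")
            if frame.index.has_duplicates:
                raise ConfigError(f"dataset {ds_id!r} has duplicate gene ids")

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for _, frame in self.datasets:
            out.update(frame.index)
        return out


@dataclass
class CoexpressionScore:
    gene: str
    combined: float
    n_datasets_used: int
    per_dataset: dict = field(default_factory=dict)  # dataset id -> (r, z)


def fisher_z(r: float) -> float:
    """atanh with |r| clipped just inside 1 to avoid infinities."""
    return math.atanh(max(-_R_CLIP, min(_R_CLIP, r)))


def dataset_correlation(
    dataset: pd.DataFrame,
    query_profile: np.ndarray,
    gene: str,
) -> float | None:
    """Pearson r between a gene's profile and the query over shared finite
    samples; None (excluded, logged) when undefined."""
    if gene not in dataset.index:
        raise ConfigError(f"gene {gene!r} not in dataset")
    x = np.asarray(dataset.loc[gene], dtype=float)
    q = np.asarray(query_profile, dtype=float)
    mask = np.isfinite(x) & np.isfinite(q)
    if mask.sum() < 3:
        logger.debug("correlation for %s skipped: <3 shared finite samples", gene)
        return None
    x, q = x[mask], q[mask]
    if x.std() == 0 or q.std() == 0:
        logger.debug("correlation for %s skipped: zero variance", gene)
        return None
    return float(np.corrcoef(x, q)[0, 1])


def combine_scores(per_dataset_z: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Weighted mean of Fisher-z values (uniform by default)."""
    if len(per_dataset_z) == 0:
        raise ConfigError("no usable datasets: combined score undefined")
    z = np.asarray(per_dataset_z, dtype=float)
    if weights is None:
        return float(z.mean())
    w = np.asarray(weights, dtype=float)
    if w.shape != z.shape or w.sum() <= 0:
        raise ConfigError("weights must match z values and sum to > 0")
    return float((z * w).sum() / w.sum())


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _query_profile(frame: pd.DataFrame, query_genes: Sequence[str]) -> np.ndarray | None:
    present = [g for g in query_genes if g in frame.index]
    if not present:
        return None
    rows = [_standardise(np.asarray(frame.loc[g], dtype=float)) for g in present]
    return np.mean(rows, axis=0)


def rank_query(
    compendium: ExpressionCompendium,
    query_genes: Sequence[str] | str,
    weighting: str = "uniform",
) -> list[CoexpressionScore]:
    """Rank all non-query genes by combined Fisher-z co-expression score.

    Multi-gene queries use the mean of the standardised query profiles per
    dataset.  ``weighting='variance'`` weights datasets by the variance of
    the (standardised-mean) query profile, a crude informativeness proxy;
    the default is uniform.  Genes with no usable dataset are omitted.
    """
    if isinstance(query_genes, str):
        query_genes = [query_genes]
    universe = compendium.universe
    unknown = [g for g in query_genes if g not in universe]
    if unknown:
        raise ConfigError(f"query genes not in compendium: {unknown}")
    if weighting not in {"uniform", "variance"}:
        raise ConfigError(f"unknown weighting {weighting!r}")

    acc: dict[str, CoexpressionScore] = {}
    zs: dict[str, list[float]] = {}
    ws: dict[str, list[float]] = {}
    for ds_id, frame in compendium.datasets:
        q = _query_profile(frame, query_genes)
        if q is None:
            continue
        weight = float(np.var(q)) if weighting == "variance" else 1.0
        values = frame.to_numpy(dtype=float)
        finite_rows = np.isfinite(values).all(axis=1) & np.isfinite(q).all()
        sds = values.std(axis=1)
        qc = q - q.mean()
        qn = np.sqrt((qc**2).sum())
        for i, gene in enumerate(frame.index):
            if gene in query_genes:
                continue
            if finite_rows[i] and qn > 0 and sds[i] > 0:
                xc = values[i] - values[i].mean()
                r = float((xc @ qc) / (np.sqrt((xc**2).sum()) * qn))
            else:
                r = dataset_correlation(frame, q, gene)
                if r is None:
                    continue
            z = fisher_z(r)
            score = acc.setdefault(gene, CoexpressionScore(gene, 0.0, 0))
            score.per_dataset[ds_id] = (r, z)
            zs.setdefault(gene, []).append(z)
            ws.setdefault(gene, []).append(weight)

    out: list[CoexpressionScore] = []
    for gene, score in acc.items():
        score.combined = combine_scores(zs[gene], ws[gene] if weighting == "variance" else None)
        score.n_datasets_used = len(zs[gene])
        out.append(score)
    out.sort(key=lambda s: (-s.combined, s.gene))
    return out
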