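"""Transcriptome statistics: probe-set collapse, per-gene Welch tests with
Benjamini-Hochberg FDR, a fold-change filter, and hypergeometric category
over-representation.

The workflow mirrors a classic two-group oligonucleotide-array analysis:

1. collapse probe sets to genes by keeping each gene's 3'-most probe set;
2. per-gene Welch t-test on log2 abundances, Benjamini-Hochberg adjustment
   across all tested genes, and a dual cut-off (adjusted p <= 0.05 and
   at least 2-fold change on the linear scale);
3. partition of the passing genes into up- and down-regulated lists;
4. per-category upper-tail hypergeometric over-representation of the
   selected genes, dropping categories with fewer than two selected members
   and keeping those with p <= 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "ExpressionMatrix",
    "DifferentialResult",
    "CategoryResult",
    "benjamini_hochberg",
    "collapse_to_gene",
    "differential_expression",
    "hypergeometric_enrichment",
    "up_down_partition",
    "gene_to_category_map",
]


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValidationError("p_values: must be nonempty")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p_values: must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Probe-set (or gene) x sample abundances with two-group labels.

    ``values``: positive abundances, rows indexed by probe-set/gene id,
    columns by sample id. ``groups``: per-sample group label; exactly two
    distinct labels, each with n >= 2 samples.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not (self.values.to_numpy() > 0).all():
            raise ValidationError("values: all abundances must be > 0")
        if list(self.groups.index) != list(self.values.columns):
            raise ValidationError("groups: index must match the sample columns")
        counts = self.groups.value_counts()
        if len(counts) != 2 or (counts < 2).any():
            raise ValidationError("groups: need exactly two groups with n >= 2 each")

    @property
    def group_labels(self) -> tuple[str, str]:
        """The two group labels, first-appearance order (control first)."""
        seen = list(dict.fromkeys(self.groups))
        return seen[0], seen[1]

    def split(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        a, b = self.group_labels
        return (
            self.values.loc[:, self.groups[self.groups == a].index],
            self.values.loc[:, self.groups[self.groups == b].index],
        )


@dataclass
class DifferentialResult:
    """Per-gene two-group test result."""

    gene_id: str
    log2_fold_change: float
    t_stat: float
    p_value: float
    fdr_adjusted_p: float
    passes: bool
    flagged: bool = False


@dataclass
class CategoryResult:
    """Over-representation of one functional category.

    ``universe`` (N) genes total, ``n_category_genes`` (K) in the category,
    ``n_selected`` (n) selected, ``overlap`` (k) selected in the category;
    ``p_value`` is the upper tail P(X >= k). ``kept`` requires overlap >= 2
    and p <= 0.05.
    """

    category_id: str
    n_category_genes: int
    n_selected: int
    overlap: int
    universe: int
    p_value: float
    kept: bool


def collapse_to_gene(
    matrix: ExpressionMatrix, annotation: pd.DataFrame
) -> ExpressionMatrix:
    """Collapse probe sets to one row per gene via the 3'-most probe set.

    ``annotation`` needs columns ``probeset_id``, ``gene_id`` and
    ``three_prime_rank`` (1 = most 3'). Probe sets without annotation are
    dropped (the count is logged); a gene with two rank-1 probe sets is an
    error.
    """
    required = {"probeset_id", "gene_id", "three_prime_rank"}
    if not required.issubset(annotation.columns):
        raise ValidationError(f"annotation: needs columns {sorted(required)}")
    annot = annotation.set_index("probeset_id")
    known = matrix.values.index.intersection(annot.index)
    n_dropped = matrix.values.index.size - known.size
    if n_dropped:
        logger.info("collapse_to_gene: dropped %d unannotated probe sets", n_dropped)
    annot = annot.loc[known]
    rank1 = annot[annot["three_prime_rank"] == 1]
    dup = rank1["gene_id"].duplicated()
    if dup.any():
        genes = sorted(rank1.loc[dup, "gene_id"].unique())
        raise ValidationError(f"annotation: duplicate rank-1 probe sets for genes {genes}")
    collapsed = matrix.values.loc[rank1.index].copy()
    collapsed.index = pd.Index(rank1["gene_id"], name="gene_id")
    return ExpressionMatrix(values=collapsed, groups=matrix.groups)


def differential_expression(
    matrix: ExpressionMatrix,
    fdr_threshold: float = 0.05,
    fold_change_threshold: float = 2.0,
    fold_change_scale: str = "linear",
) -> list[DifferentialResult]:
    """Per-gene Welch t-test on log2 abundances with BH adjustment.

    The fold change is the ratio of group means — of the linear abundances
    by default (``fold_change_scale="linear"``) or of the geometric means
    (``"log"``). A gene passes with adjusted p <= ``fdr_threshold`` and a
    fold change of at least ``fold_change_threshold`` in either direction.
    Genes with zero variance in both groups get p = 1 and are flagged.
    """
    if fold_change_scale not in ("linear", "log"):
        raise ValidationError("fold_change_scale: must be 'linear' or 'log'")
    a, b = matrix.split()  # control, treated
    la, lb = np.log2(a.to_numpy()), np.log2(b.to_numpy())

    res = sps.ttest_ind(lb, la, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (la.var(axis=1, ddof=1) == 0.0) & (lb.var(axis=1, ddof=1) == 0.0)
    t[degenerate] = 0.0
    p[degenerate] = 1.0

    adj = benjamini_hochberg(p)

    if fold_change_scale == "linear":
        ratio = b.to_numpy().mean(axis=1) / a.to_numpy().mean(axis=1)
    else:
        ratio = np.power(2.0, lb.mean(axis=1) - la.mean(axis=1))
    log2fc = np.log2(ratio)
    passes = (adj <= fdr_threshold) & (np.abs(log2fc) >= np.log2(fold_change_threshold))

    return [
        DifferentialResult(
            gene_id=str(g),
            log2_fold_change=float(log2fc[i]),
            t_stat=float(t[i]),
            p_value=float(p[i]),
            fdr_adjusted_p=float(adj[i]),
            passes=bool(passes[i]),
            flagged=bool(degenerate[i]),
        )
        for i, g in enumerate(matrix.values.index)
    ]


def up_down_partition(
    results: Iterable[DifferentialResult],
) -> tuple[list[DifferentialResult], list[DifferentialResult]]:
    """Split the passing genes by the sign of their log2 fold change."""
    up = [r for r in results if r.passes and r.log2_fold_change > 0]
    down = [r for r in results if r.passes and r.log2_fold_change < 0]
    return up, down


def gene_to_category_map(
    categories: Mapping[str, Iterable[str]]
) -> dict[str, list[str]]:
    """Invert a category -> genes mapping (e.g. parsed GMT) to gene -> categories."""
    out: dict[str, list[str]] = {}
    for cat, genes in categories.items():
        for g in genes:
            out.setdefault(g, []).append(cat)
    return out


def hypergeometric_enrichment(
    selected: Iterable[str],
    category_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    p_threshold: float = 0.05,
    min_overlap: int = 2,
) -> list[CategoryResult]:
    """Upper-tail hypergeometric over-representation per category.

    ``category_map`` maps each gene to its category labels (see
    :func:`gene_to_category_map` to invert a GMT-style mapping);
    ``universe`` is the gene background N. For a category with K genes in
    the universe and an overlap of k with the n selected genes, the p-value
    is P(X >= k) for X ~ Hypergeometric(N, K, n). Categories are returned
    for every overlap, with ``kept`` true when overlap >= ``min_overlap``
    and p <= ``p_threshold``; callers drop the rest, matching the
    at-least-two-genes rule.
    """
    universe_set = set(universe)
    selected_set = set(selected)
    outside = selected_set - universe_set
    if outside:
        raise ValidationError(
            f"selected: genes outside the universe: {sorted(outside)[:5]}"
        )
    cat_members: dict[str, set[str]] = {}
    for gene, cats in category_map.items():
        if gene not in universe_set:
            continue
        for c in cats:
            cat_members.setdefault(c, set()).add(gene)

    n_univ = len(universe_set)
    n_sel = len(selected_set)
    results = []
    for cat in sorted(cat_members):
        members = cat_members[cat]
        big_k = len(members)
        k = len(members & selected_set)
        p = float(sps.hypergeom.sf(k - 1, n_univ, big_k, n_sel))
        results.append(
            CategoryResult(
                category_id=cat,
                n_category_genes=big_k,
                n_selected=n_sel,
                overlap=k,
                universe=n_univ,
                p_value=p,
                kept=bool(k >= min_overlap and p <= p_threshold),
            )
        )
    return results
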