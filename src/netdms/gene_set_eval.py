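"""SNP-resampling significance test for gene sets, with BH correction.

The observed quantity per category is the number of its genes that are
"significant" (carry at least one mapped SNP with P strictly below the
cutoff). Each resample draws SNPs uniformly without replacement from the
full pool; a drawn SNP stands in for a significant SNP, so every gene it
maps to joins the resampled significant-gene set regardless of the SNP's
own P — this preserves the gene-size and SNP-density bias of the real
selection. Drawing stops when the resampled set reaches the observed
genome-wide significant-gene count, and per-category counts are recorded.
The empirical category P is #{resamples with count >= observed}/B with a
1/B floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .formats_io import GeneSet
from .gene_score import SnpGeneMap


@dataclass
class ResampleNull:
    """Per-category significant-gene counts over B resamples."""

    B: int
    category_names: list
    counts: np.ndarray  # shape (B, n_categories)

    def __post_init__(self):
        if self.counts.shape != (self.B, len(self.category_names)):
            raise ValidationError("resample count matrix has wrong shape")


def significant_genes(
    pool: pd.DataFrame, snp_map: SnpGeneMap, p_cut: float = 0.05
) -> set:
    """Genes with at least one mapped SNP with P strictly below ``p_cut``."""
    pmap = dict(zip(pool["snp_id"], pool["p_value"]))
    out = set()
    for gene, snps in snp_map.genes.items():
        for s in snps:
            p = pmap.get(s)
            if p is not None and p < p_cut:
                out.add(gene)
                break
    return out


class _PoolIndex:
    """Array view of the pool for resampling.

    Gene-mapped SNPs are indexed with their gene lists; unmapped SNPs only
    dilute the draw order and are dropped, which leaves the resampled
    gene-set distribution unchanged (the relative order of mapped SNPs in a
    uniform permutation of the whole pool is itself uniform).
    """

    def __init__(self, pool: pd.DataFrame, snp_map: SnpGeneMap):
        snp_to_genes = snp_map.snp_to_genes
        genes = sorted({g for gl in snp_to_genes.values() for g in gl})
        self.gene_index = {g: i for i, g in enumerate(genes)}
        self.n_genes = len(genes)
        self.snp_genes = [
            np.array([self.gene_index[g] for g in snp_to_genes[s]], dtype=np.int64)
            for s in pool["snp_id"]
            if s in snp_to_genes
        ]
        self.n_snps = len(self.snp_genes)

    def walk(self, order: np.ndarray, target_count: int) -> np.ndarray:
        """Boolean gene mask after drawing SNPs in ``order`` until the
        resampled significant-gene count reaches ``target_count``."""
        mask = np.zeros(self.n_genes, dtype=bool)
        if target_count == 0:
            return mask
        hit = 0
        for idx in order:
            for g in self.snp_genes[idx]:
                if not mask[g]:
                    mask[g] = True
                    hit += 1
            if hit >= target_count:
                return mask
        raise ValidationError(
            f"SNP pool exhausted before reaching target {target_count}"
        )


def one_resample(
    pool: pd.DataFrame,
    snp_map: SnpGeneMap,
    target_count: int,
    p_cut: float = 0.05,
    rng: np.random.Generator | int = 0,
) -> set:
    """One resampled significant-gene set of size >= ``target_count``.

    Draws SNPs uniformly without replacement; every gene mapped by a drawn
    SNP joins the running set (the draw itself stands in for SNP
    significance, so ``p_cut`` does not filter draws). Stops as soon as the
    set size reaches ``target_count`` (one draw can push it past).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    index = _PoolIndex(pool, snp_map)
    order = rng.permutation(index.n_snps)
    mask = index.walk(order, target_count)
    inv = {i: g for g, i in index.gene_index.items()}
    return {inv[i] for i in np.flatnonzero(mask)}


def resample_null(
    pool: pd.DataFrame,
    snp_map: SnpGeneMap,
    categories: Sequence[GeneSet],
    target_count: int,
    B: int,
    p_cut: float = 0.05,
    seed: int = 0,
) -> ResampleNull:
    """B independent resamples; per-resample substreams from (seed, index)."""
    if B < 1:
        raise ValidationError("B must be >= 1")
    index = _PoolIndex(pool, snp_map)
    cat_idx = [
        np.array(
            sorted(index.gene_index[g] for g in c.genes if g in index.gene_index),
            dtype=np.int64,
        )
        for c in categories
    ]
    counts = np.zeros((B, len(categories)), dtype=np.int64)
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), b)))
        order = rng.permutation(index.n_snps)
        mask = index.walk(order, target_count)
        for c, idx in enumerate(cat_idx):
            counts[b, c] = int(mask[idx].sum()) if idx.size else 0
    return ResampleNull(B=B, category_names=[c.name for c in categories],
                        counts=counts)


def category_pvalues(
    categories: Sequence[GeneSet], real_set: set, nulls: ResampleNull
) -> pd.DataFrame:
    """Empirical per-category P with the 1/B floor.

    P = max(1, #{b : count_b >= x_C}) / B where x_C is the real
    significant-gene count of the category.
    """
    rows = []
    for c, cat in enumerate(categories):
        x = len(cat.genes & real_set)
        n_ge = int((nulls.counts[:, c] >= x).sum())
        rows.append(
            {
                "set": cat.name,
                "size": len(cat.genes),
                "real_count": x,
                "p": max(1, n_ge) / nulls.B,
            }
        )
    return pd.DataFrame(rows)


def bh_adjust(ps: Sequence[float], m_total: int) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjustment with total test count m_total.

    adj_i = min_{j >= i} (p_(j) * m_total / j), capped at 1; m_total may
    exceed the number of supplied p-values (unseen tests assumed larger).
    """
    ps = np.asarray(list(ps), dtype=float)
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    if m_total < ps.size:
        raise ValidationError("m_total must be >= the number of p-values")
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m_total / np.arange(1, ps.size + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def filter_gene_sets(
    sets: Iterable[GeneSet], min_size: int = 5, max_size: int = 300
) -> list:
    """Keep sets with min_size <= |genes| <= max_size (closed bounds)."""
    return [s for s in sets if min_size <= len(s.genes) <= max_size]


def evaluate_gene_sets(
    pool: pd.DataFrame,
    snp_map: SnpGeneMap,
    categories: Sequence[GeneSet],
    B: int = 10_000,
    p_cut: float = 0.05,
    m_total: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """End-to-end resampling evaluation of ``categories``.

    Returns a DataFrame (set, size, real_count, p, p_bh) ordered as given.
    ``m_total`` defaults to the number of categories tested.
    """
    real = significant_genes(pool, snp_map, p_cut)
    nulls = resample_null(pool, snp_map, categories, len(real), B, p_cut, seed)
    df = category_pvalues(categories, real, nulls)
    df["p_bh"] = bh_adjust(df["p"].to_numpy(), m_total or len(df))
    return df
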