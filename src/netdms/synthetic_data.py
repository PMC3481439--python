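"""Fully synthetic inputs with controlled statistical structure.

Generates LD-block genotypes, SNP association P-values (null, planted, or
drawn consistently with the realised genotype correlation), gene loci whose
length tracks SNP density, a preferential-attachment interaction network
with an optional planted dense module, and pathway-style gene sets. All
draws are deterministic in ``rng_seed``; every generator uses its own
substream so the pieces can be produced independently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .formats_io import GeneSet, GenotypeRef
from .gene_score import _repair_psd

_TAG_LAYOUT, _TAG_GENO, _TAG_ASSOC, _TAG_NET, _TAG_SETS = range(5)


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples: int = 200
    n_genes: int = 100
    snps_per_gene: tuple = (3, 6)  # inclusive range
    ld_block_rho: float = 0.3
    ld_model: str = "cs"  # 'cs' (exchangeable) or 'ar1'
    network_m: int = 2  # preferential-attachment parameter
    planted_module_size: int = 0
    planted_effect: float = 0.0  # mean shift of causal-SNP z statistics
    planted_chord_prob: float = 0.5
    background_null: bool = True
    background_signal_frac: float = 0.1
    background_effect: float = 1.5
    assoc_mode: str = "independent"  # or 'mvn' (LD-consistent statistics)
    missing_rate: float = 0.0
    bp_per_snp: int = 1500
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2 or self.n_genes < 1:
            raise ValidationError("sizes must be positive")
        if not 0 <= self.ld_block_rho < 1:
            raise ValidationError("ld_block_rho must lie in [0, 1)")
        if self.snps_per_gene[0] < 1 or self.snps_per_gene[0] > self.snps_per_gene[1]:
            raise ValidationError("invalid snps_per_gene range")
        if self.planted_module_size > self.n_genes:
            raise ValidationError("planted module larger than gene count")
        if self.ld_model not in ("cs", "ar1"):
            raise ValidationError("ld_model must be 'cs' or 'ar1'")
        if self.assoc_mode not in ("independent", "mvn"):
            raise ValidationError("assoc_mode must be 'independent' or 'mvn'")


@dataclass
class Layout:
    """Deterministic genomic arrangement shared by all generators."""

    loci: pd.DataFrame  # gene_id, chrom, start, end
    snps: pd.DataFrame  # snp_id, chrom, pos, gene_idx
    n_snps_per_gene: np.ndarray
    maf: np.ndarray  # per-SNP minor allele frequency
    planted_genes: tuple


def _rng(config: SyntheticConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(config.rng_seed), tag))
    )


def make_layout(config: SyntheticConfig) -> Layout:
    """Gene loci, SNP positions and planted-gene choice for a config.

    Genes are laid out round-robin over the 22 autosomes with >= 120 kb
    between consecutive flanked loci, so no SNP maps to two genes at the
    default 50 kb flank. Gene length is proportional to its SNP count.
    """
    rng = _rng(config, _TAG_LAYOUT)
    lo, hi = config.snps_per_gene
    n_snps = rng.integers(lo, hi + 1, size=config.n_genes)
    max_len = hi * config.bp_per_snp
    spacing = max_len + 150_000
    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    rows, snp_rows = [], []
    j = 0
    for i, gid in enumerate(gene_ids):
        chrom = str(i % 22 + 1)
        slot = i // 22
        start = 1_000_000 + slot * spacing
        length = int(n_snps[i]) * config.bp_per_snp
        end = start + length - 1
        rows.append({"gene_id": gid, "chrom": chrom, "start": start, "end": end})
        pos = np.sort(
            rng.choice(np.arange(start, end + 1), size=int(n_snps[i]),
                       replace=False)
        )
        for p in pos:
            snp_rows.append(
                {"snp_id": f"rs{j:06d}", "chrom": chrom, "pos": int(p),
                 "gene_idx": i}
            )
            j += 1
    planted = ()
    if config.planted_module_size:
        idx = rng.choice(config.n_genes, size=config.planted_module_size,
                         replace=False)
        planted = tuple(gene_ids[i] for i in sorted(idx))
    return Layout(
        loci=pd.DataFrame(rows),
        snps=pd.DataFrame(snp_rows),
        n_snps_per_gene=n_snps,
        maf=rng.uniform(0.05, 0.5, size=j),
        planted_genes=planted,
    )


def _block_latent(rng, n, m, rho, model) -> np.ndarray:
    if model == "cs":
        u = rng.standard_normal((n, 1))
        e = rng.standard_normal((n, m))
        return np.sqrt(rho) * u + np.sqrt(1 - rho) * e
    h = np.empty((n, m))
    h[:, 0] = rng.standard_normal(n)
    for jj in range(1, m):
        h[:, jj] = rho * h[:, jj - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    return h


def simulate_genotypes(
    config: SyntheticConfig, layout: Layout | None = None
) -> GenotypeRef:
    """Additive-coded genotypes with one LD block per gene.

    Two latent haplotype vectors per sample share the block correlation
    (exchangeable or AR(1)); alleles arise by thresholding at the normal
    quantile of each SNP's allele frequency, so genotypes are in
    Hardy-Weinberg proportions.
    """
    layout = layout or make_layout(config)
    rng = _rng(config, _TAG_GENO)
    n = config.n_samples
    total = len(layout.snps)
    geno = np.empty((n, total))
    col = 0
    for i in range(config.n_genes):
        m = int(layout.n_snps_per_gene[i])
        thr = stats.norm.ppf(layout.maf[col:col + m])
        g = np.zeros((n, m))
        for _hap in range(2):
            h = _block_latent(rng, n, m, config.ld_block_rho, config.ld_model)
            g += (h < thr).astype(float)
        geno[:, col:col + m] = g
        col += m
    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = np.nan
    return GenotypeRef(snp_ids=list(layout.snps["snp_id"]), matrix=geno)


def simulate_assoc(
    config: SyntheticConfig,
    geno: GenotypeRef | None = None,
    layout: Layout | None = None,
) -> pd.DataFrame:
    """SNP association table (snp_id, chrom, pos, p_value).

    ``independent`` mode draws one standard-normal statistic per SNP;
    ``mvn`` mode draws each gene block jointly from MVN(0, R) with R the
    realised genotype correlation (requires ``geno``), so downstream
    LD-aware combination is exactly calibrated. Causal SNPs — those inside
    planted-module genes — get their mean shifted by ``planted_effect``;
    when ``background_null`` is off, a random fraction of the remaining
    genes receives a milder shift. P-values are two-sided.
    """
    layout = layout or make_layout(config)
    rng = _rng(config, _TAG_ASSOC)
    total = len(layout.snps)
    if config.assoc_mode == "mvn":
        if geno is None:
            raise ValidationError("assoc_mode='mvn' requires genotypes")
        z = np.empty(total)
        col = 0
        for i in range(config.n_genes):
            m = int(layout.n_snps_per_gene[i])
            block = geno.matrix[:, col:col + m]
            if m == 1:
                z[col] = rng.standard_normal()
            else:
                r = _repair_psd(np.corrcoef(block, rowvar=False))
                w, v = np.linalg.eigh(r)
                factor = v * np.sqrt(np.clip(w, 0, None))
                z[col:col + m] = factor @ rng.standard_normal(m)
            col += m
    else:
        z = rng.standard_normal(total)

    gene_ids = list(layout.loci["gene_id"])
    effects = np.zeros(config.n_genes)
    planted_idx = [gene_ids.index(g) for g in layout.planted_genes]
    effects[planted_idx] = config.planted_effect
    if not config.background_null:
        candidates = [i for i in range(config.n_genes) if i not in planted_idx]
        n_signal = int(round(config.background_signal_frac * len(candidates)))
        if n_signal:
            chosen = rng.choice(candidates, size=n_signal, replace=False)
            effects[chosen] = config.background_effect
    z = z + effects[layout.snps["gene_idx"].to_numpy()]
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    return pd.DataFrame(
        {
            "snp_id": layout.snps["snp_id"],
            "chrom": layout.snps["chrom"],
            "pos": layout.snps["pos"],
            "p_value": p,
        }
    )


def simulate_network(
    config: SyntheticConfig,
    gene_ids: Sequence[str],
    planted_genes: Sequence[str] = (),
) -> list:
    """Scale-free raw pair list with the planted genes wired densely.

    A Barabasi-Albert graph is built over a shuffled copy of ``gene_ids``;
    planted genes are additionally joined in a ring (every planted gene
    adjacent to >= 2 planted genes, connected by construction) plus random
    chords.
    """
    gene_ids = list(gene_ids)
    if planted_genes and not set(planted_genes) <= set(gene_ids):
        raise ValidationError("planted genes must be a subset of gene_ids")
    rng = _rng(config, _TAG_NET)
    n = len(gene_ids)
    m = min(config.network_m, max(1, n - 1))
    ba = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    order = list(rng.permutation(n))
    label = {i: gene_ids[order[i]] for i in range(n)}
    pairs = [(label[u], label[v]) for u, v in ba.edges()]
    planted = list(planted_genes)
    if len(planted) >= 3:
        for i, g in enumerate(planted):
            pairs.append((g, planted[(i + 1) % len(planted)]))
        for i in range(len(planted)):
            for k in range(i + 2, len(planted)):
                if (i, k) != (0, len(planted) - 1) and (
                    rng.random() < config.planted_chord_prob
                ):
                    pairs.append((planted[i], planted[k]))
    elif len(planted) == 2:
        pairs.append((planted[0], planted[1]))
    return pairs


def simulate_pathways(
    config: SyntheticConfig,
    gene_ids: Sequence[str],
    planted_genes: Sequence[str] = (),
    n_sets: int = 20,
    size_range: tuple = (5, 50),
) -> list:
    """Random gene sets plus one set containing all planted genes (padded)."""
    gene_ids = list(gene_ids)
    rng = _rng(config, _TAG_SETS)
    lo, hi = size_range
    hi = min(hi, len(gene_ids), 300)
    lo = min(lo, hi)
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(gene_ids, size=size, replace=False)
        sets.append(GeneSet(f"P{i:04d}", "random", frozenset(genes)))
    if planted_genes:
        others = [g for g in gene_ids if g not in set(planted_genes)]
        pad = rng.choice(others, size=min(4, len(others)), replace=False)
        sets.append(
            GeneSet("planted_set", "planted",
                    frozenset(planted_genes) | frozenset(pad))
        )
    return sets


@dataclass
class SyntheticData:
    config: SyntheticConfig
    layout: Layout
    loci: pd.DataFrame
    assoc: pd.DataFrame
    genotypes: GenotypeRef
    edges: list
    gene_sets: list
    planted_genes: tuple


def generate(config: SyntheticConfig) -> SyntheticData:
    """Generate every input the pipeline consumes, deterministically."""
    layout = make_layout(config)
    geno = simulate_genotypes(config, layout)
    assoc = simulate_assoc(config, geno, layout)
    edges = simulate_network(config, list(layout.loci["gene_id"]),
                             layout.planted_genes)
    sets = simulate_pathways(config, list(layout.loci["gene_id"]),
                             layout.planted_genes)
    return SyntheticData(
        config=config,
        layout=layout,
        loci=layout.loci,
        assoc=assoc,
        genotypes=geno,
        edges=edges,
        gene_sets=sets,
        planted_genes=layout.planted_genes,
    )


def write_all(data: SyntheticData, outdir) -> dict:
    """Write every generated input in its pipeline format; returns paths."""
    import os

    from . import formats_io as fio

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "assoc": os.path.join(outdir, "assoc.tsv"),
        "loci": os.path.join(outdir, "loci.tsv"),
        "geno": os.path.join(outdir, "genotypes.tsv"),
        "edges": os.path.join(outdir, "edges.tsv"),
        "sets": os.path.join(outdir, "pathways.gmt"),
    }
    fio.write_assoc(data.assoc, paths["assoc"])
    fio.write_loci(data.loci, paths["loci"])
    fio.write_genotypes(data.genotypes, paths["geno"])
    fio.write_edge_list(data.edges, paths["edges"])
    fio.write_gmt(data.gene_sets, paths["sets"])
    if data.planted_genes:
        paths["planted"] = os.path.join(outdir, "planted_genes.txt")
        with open(paths["planted"], "w") as fh:
            fh.write("\n".join(data.planted_genes) + "\n")
    return paths
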