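"""Gene-wise P-values from SNP-level statistics.

Three combination strategies are provided:

- ``all``  : sum of 1-df chi-square quantiles over every mapped SNP, with an
  empirical P obtained from multivariate-normal simulation under the local
  LD correlation matrix;
- ``top``  : same machinery restricted to the top ``fraction`` (default 10%)
  most significant SNPs, with each null draw contributing the sum of its own
  largest chi-squares;
- ``minp`` : the smallest SNP P-value, taken as-is with no multiplicity
  correction.

Gene-wise P-values are transformed to node weights ``z = Phi^-1(1 - p)``
(clamped so the transform stays finite) for the network stages.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NumericalError, ValidationError
from .formats_io import AUTOSOMES, GenotypeRef

EPS_P = 1e-12
_CHUNK = 20_000


# ---------------------------------------------------------------------------
# SNP -> gene mapping
# ---------------------------------------------------------------------------

@dataclass
class SnpGeneMap:
    """Per-gene ordered SNP lists (order = genomic position).

    A SNP may map to multiple genes. ``n_snps_excluded`` / ``n_genes_excluded``
    count sex-chromosome records dropped when ``autosomes_only`` was set.
    """

    genes: dict
    flank_bp: int = 50_000
    n_snps_excluded: int = 0
    n_genes_excluded: int = 0
    _snp_to_genes: dict = field(default=None, repr=False)

    @property
    def snp_to_genes(self) -> dict:
        if self._snp_to_genes is None:
            inv: dict = {}
            for gene, snps in self.genes.items():
                for s in snps:
                    inv.setdefault(s, []).append(gene)
            self._snp_to_genes = inv
        return self._snp_to_genes


def map_snps_to_genes(
    snps: pd.DataFrame,
    loci: pd.DataFrame,
    flank_bp: int = 50_000,
    autosomes_only: bool = True,
) -> SnpGeneMap:
    """Map SNPs to genes within ``flank_bp`` of the gene boundaries.

    A SNP at position ``pos`` maps to a gene iff it is on the same chromosome
    and ``start - flank_bp <= pos <= end + flank_bp`` (closed interval,
    1-based coordinates). With ``autosomes_only`` (the default) SNPs and
    genes on non-autosomes are excluded and counted.
    """
    snps = snps.copy()
    loci = loci.copy()
    n_snps_excl = n_genes_excl = 0
    if autosomes_only:
        keep_s = snps["chrom"].isin(AUTOSOMES)
        keep_g = loci["chrom"].isin(AUTOSOMES)
        n_snps_excl = int((~keep_s).sum())
        n_genes_excl = int((~keep_g).sum())
        snps, loci = snps[keep_s], loci[keep_g]

    mapping: dict = {}
    for chrom, gsub in loci.groupby("chrom", sort=False):
        ssub = snps[snps["chrom"] == chrom]
        if ssub.empty:
            continue
        ssub = ssub.sort_values(["pos", "snp_id"], kind="stable")
        pos = ssub["pos"].to_numpy()
        ids = ssub["snp_id"].to_numpy()
        for gene, start, end in gsub[["gene_id", "start", "end"]].itertuples(
            index=False
        ):
            lo = np.searchsorted(pos, start - flank_bp, side="left")
            hi = np.searchsorted(pos, end + flank_bp, side="right")
            if hi > lo:
                mapping[gene] = tuple(ids[lo:hi])
    return SnpGeneMap(
        genes=mapping,
        flank_bp=flank_bp,
        n_snps_excluded=n_snps_excl,
        n_genes_excluded=n_genes_excl,
    )


# ---------------------------------------------------------------------------
# LD estimation
# ---------------------------------------------------------------------------

@dataclass
class LdMatrix:
    """Pairwise SNP correlation matrix, repaired to PSD with unit diagonal."""

    snp_ids: list
    values: np.ndarray

    def __post_init__(self):
        k = len(self.snp_ids)
        if self.values.shape != (k, k):
            raise ValidationError("LD matrix shape does not match snp_ids")

    @property
    def k(self) -> int:
        return len(self.snp_ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values).min())


def _repair_psd(r: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues at 0 and rescale back to unit diagonal."""
    r = (r + r.T) / 2.0
    w, v = np.linalg.eigh(r)
    if w.min() >= -1e-10:
        np.fill_diagonal(r, 1.0)
        return r
    w = np.clip(w, 0.0, None)
    r = (v * w) @ v.T
    d = np.sqrt(np.diag(r))
    d[d == 0] = 1.0
    r = r / np.outer(d, d)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return r


def estimate_ld(
    geno: GenotypeRef, snp_ids: Sequence[str], on_missing: str = "drop"
) -> tuple[LdMatrix, dict]:
    """Pairwise-complete Pearson correlation of additive genotype codes.

    SNPs absent from the reference are dropped (``on_missing='drop'``) or
    raise (``'error'``); monomorphic SNPs (zero variance on non-missing
    samples, or fewer than 2 non-missing samples) are always dropped. The
    correlation matrix is repaired to positive semi-definiteness by
    eigenvalue clipping followed by re-normalisation to unit diagonal.

    Returns ``(LdMatrix, report)`` where ``report`` lists dropped SNP ids
    under ``'absent'`` and ``'monomorphic'``.
    """
    report = {"absent": [], "monomorphic": []}
    present = []
    for s in snp_ids:
        if s in geno:
            present.append(s)
        else:
            if on_missing == "error":
                raise ValidationError(f"SNP {s!r} absent from genotype reference")
            report["absent"].append(s)
    kept = []
    for s in present:
        col = geno.columns([s])[:, 0]
        col = col[~np.isnan(col)]
        if col.size < 2 or np.nanstd(col) == 0.0:
            report["monomorphic"].append(s)
        else:
            kept.append(s)
    if not kept:
        return LdMatrix(snp_ids=[], values=np.empty((0, 0))), report
    sub = pd.DataFrame(geno.columns(kept), columns=kept)
    r = sub.corr(min_periods=2).to_numpy()
    if np.isnan(r).any():
        raise NumericalError(
            "undefined pairwise correlation (no overlapping samples)"
        )
    return LdMatrix(snp_ids=list(kept), values=_repair_psd(r)), report


# ---------------------------------------------------------------------------
# gene-wise P-values
# ---------------------------------------------------------------------------

def _mvn_factor(ld: LdMatrix) -> np.ndarray:
    w, v = np.linalg.eigh(ld.values)
    if w.min() < -1e-8:
        raise NumericalError(
            f"LD matrix not PSD after repair (min eigenvalue {w.min():.3g})"
        )
    return v * np.sqrt(np.clip(w, 0.0, None))


def _chi2_quantiles(snp_ps: np.ndarray) -> np.ndarray:
    if np.any(snp_ps <= 0) or np.any(snp_ps > 1):
        raise ValidationError("SNP p-values must lie in (0, 1]")
    return stats.chi2.isf(snp_ps, df=1)


def _empirical_p(
    stat_obs: float,
    factor: np.ndarray,
    stat_fn,
    rng: np.random.Generator,
    n_sims: int,
    adaptive: bool,
    max_sims: int,
) -> tuple[float, int]:
    """(1 + #{T* >= T}) / (1 + B) with the adaptive escalation schedule.

    Escalates B tenfold whenever the current estimate p < 100/B, up to
    ``max_sims`` (fresh draws each stage, same per-gene stream).
    """
    k = factor.shape[0]
    b = int(n_sims)
    while True:
        hits = 0
        done = 0
        while done < b:
            n = min(_CHUNK, b - done)
            z = rng.standard_normal((n, k)) @ factor.T
            hits += int((stat_fn(z) >= stat_obs).sum())
            done += n
        p = (1 + hits) / (1 + b)
        if not adaptive or b >= max_sims or p >= 100.0 / b:
            return p, b
        b = min(b * 10, max_sims)


def gene_p_all(
    snp_ps: Sequence[float],
    ld: LdMatrix,
    n_sims: int = 1000,
    rng_seed: int | np.random.Generator = 0,
    adaptive: bool = True,
    max_sims: int = 100_000,
) -> tuple[float, int]:
    """Empirical gene P from the sum of chi-squares over all mapped SNPs."""
    q = _chi2_quantiles(np.asarray(snp_ps, dtype=float))
    if q.size != ld.k:
        raise ValidationError("number of p-values does not match LD dimension")
    rng = _as_rng(rng_seed)
    return _empirical_p(
        float(q.sum()), _mvn_factor(ld), lambda z: (z * z).sum(axis=1),
        rng, n_sims, adaptive, max_sims,
    )


def gene_p_top(
    snp_ps: Sequence[float],
    ld: LdMatrix,
    fraction: float = 0.10,
    n_sims: int = 1000,
    rng_seed: int | np.random.Generator = 0,
    adaptive: bool = True,
    max_sims: int = 100_000,
) -> tuple[float, int]:
    """Empirical gene P from the top ``fraction`` of SNP chi-squares.

    ``m = max(1, ceil(fraction * k))``; the observed statistic sums the m
    largest chi-square quantiles, and each null draw contributes the sum of
    its own m largest squared components.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must lie in (0, 1]")
    q = _chi2_quantiles(np.asarray(snp_ps, dtype=float))
    if q.size != ld.k:
        raise ValidationError("number of p-values does not match LD dimension")
    k = q.size
    m = max(1, int(np.ceil(fraction * k)))
    stat_obs = float(np.sort(q)[k - m:].sum())

    def stat_fn(z):
        z2 = z * z
        if m == k:
            return z2.sum(axis=1)
        return np.partition(z2, k - m, axis=1)[:, k - m:].sum(axis=1)

    rng = _as_rng(rng_seed)
    return _empirical_p(stat_obs, _mvn_factor(ld), stat_fn, rng, n_sims,
                        adaptive, max_sims)


def gene_p_min(snp_ps: Sequence[float]) -> float:
    """The smallest SNP P-value, with no multiplicity correction."""
    ps = np.asarray(snp_ps, dtype=float)
    if ps.size == 0:
        raise ValidationError("gene_p_min requires a non-empty p-value list")
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValidationError("SNP p-values must lie in (0, 1]")
    return float(ps.min())


def p_to_z(p: float) -> float:
    """Node weight z = Phi^-1(1 - p), with p clamped into [1e-12, 1-1e-12]."""
    p = float(p)
    if p <= 0 or p > 1:
        raise ValidationError(f"p-value {p!r} outside (0, 1]")
    return float(stats.norm.isf(min(max(p, EPS_P), 1 - EPS_P)))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gene_rng(global_seed: int, gene_id: str) -> np.random.Generator:
    """Per-gene RNG stream derived from (global seed, CRC32 of the gene id).

    Makes gene-level results independent of processing order.
    """
    return np.random.default_rng(
        np.random.SeedSequence((int(global_seed), zlib.crc32(gene_id.encode())))
    )


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def score_genes(
    assoc: pd.DataFrame,
    loci: pd.DataFrame,
    geno: GenotypeRef | None,
    method: str = "all",
    flank_bp: int = 50_000,
    autosomes_only: bool = True,
    fraction: float = 0.10,
    n_sims: int = 1000,
    max_sims: int = 100_000,
    seed: int = 0,
    snp_map: SnpGeneMap | None = None,
) -> pd.DataFrame:
    """Compute one gene-wise P per mapped gene and its node weight z.

    Returns a DataFrame with columns ``gene_id, chrom, start, end, n_snps,
    p_<method>, z``. Genes whose mapped SNPs all fail LD QC are omitted.
    ``minp`` needs no genotype reference.
    """
    if method not in ("all", "top", "minp"):
        raise ValidationError(f"unknown gene-wise method {method!r}")
    if method != "minp" and geno is None:
        raise ValidationError(f"method {method!r} requires a genotype reference")
    if snp_map is None:
        snp_map = map_snps_to_genes(assoc, loci, flank_bp, autosomes_only)
    pmap = dict(zip(assoc["snp_id"], assoc["p_value"]))
    loci_idx = loci.set_index("gene_id")
    rows = []
    for gene, snps in snp_map.genes.items():
        ps = np.array([pmap[s] for s in snps if s in pmap])
        if ps.size == 0:
            continue
        if method == "minp":
            p_gene = gene_p_min(ps)
            n_used = ps.size
        else:
            snps_in = [s for s in snps if s in pmap]
            ld, rep = estimate_ld(geno, snps_in)
            if ld.k == 0:
                continue
            ps = np.array([pmap[s] for s in ld.snp_ids])
            rng = gene_rng(seed, gene)
            if method == "all":
                p_gene, _ = gene_p_all(ps, ld, n_sims, rng, True, max_sims)
            else:
                p_gene, _ = gene_p_top(ps, ld, fraction, n_sims, rng, True,
                                       max_sims)
            n_used = ld.k
        loc = loci_idx.loc[gene]
        rows.append(
            {
                "gene_id": gene,
                "chrom": loc["chrom"],
                "start": int(loc["start"]),
                "end": int(loc["end"]),
                "n_snps": int(n_used),
                f"p_{method}": p_gene,
                "z": p_to_z(p_gene),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "start", "end", "n_snps",
                 f"p_{method}", "z"],
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def length_bias_diagnostic(
    scores: pd.DataFrame,
    loci: pd.DataFrame,
    bin_size: int = 100,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Length-bias bins plus Q-Q coordinates for a gene score table.

    Genes are sorted by length (``end - start + 1``) and grouped into
    consecutive bins of ``bin_size`` genes (last bin may be smaller); each
    bin reports its mean length and the proportion of genes with
    ``p < alpha``. The second frame holds Q-Q coordinates:
    -log10 expected uniform order statistics vs -log10 observed p.
    """
    p_col = [c for c in scores.columns if c.startswith("p_")]
    if len(p_col) != 1:
        raise ValidationError("scores table must carry exactly one p_* column")
    p_col = p_col[0]
    merged = scores.merge(loci[["gene_id", "start", "end"]], on="gene_id",
                          how="left", suffixes=("", "_locus"))
    start = merged["start_locus"] if "start_locus" in merged else merged["start"]
    end = merged["end_locus"] if "end_locus" in merged else merged["end"]
    if start.isna().any():
        missing = merged.loc[start.isna(), "gene_id"].iloc[0]
        raise ValidationError(f"gene {missing!r} has no locus")
    merged["length"] = (end - start + 1).astype(int)
    merged = merged.sort_values(["length", "gene_id"], kind="stable")
    n = len(merged)
    bins = []
    for b, lo in enumerate(range(0, n, bin_size)):
        chunk = merged.iloc[lo:lo + bin_size]
        bins.append(
            {
                "bin": b,
                "n_genes": len(chunk),
                "mean_length": float(chunk["length"].mean()),
                "prop_significant": float((chunk[p_col] < alpha).mean()),
            }
        )
    p_obs = np.sort(scores[p_col].to_numpy())
    expected = (np.arange(1, n + 1)) / (n + 1)
    qq = pd.DataFrame(
        {
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(p_obs),
        }
    )
    return pd.DataFrame(bins), qq
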