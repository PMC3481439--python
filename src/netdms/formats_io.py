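"""Readers and writers for the plain-text formats the pipeline consumes.

Formats
-------
- SNP association table: whitespace- or tab-delimited with a header carrying
  at least the columns ``SNP CHR BP P`` (any order, PLINK ``.assoc`` style).
- Gene locus table: 4-column TSV ``gene  chrom  start  end`` (1-based, closed).
- PPI edge list: 2-column TSV, one interaction per line, no header.
- GMT gene sets: ``name<TAB>description<TAB>gene1<TAB>gene2...``.
- Genotype matrix: TSV; first row SNP ids, each following row one sample of
  additive codes in {0, 1, 2}, missing coded ``NA``.
- Module table: TSV written by :func:`write_modules`.

Every reader validates rather than coerces: malformed rows are either
rejected with a reported count (association P values) or raise
:class:`~netdms.errors.FormatError` / :class:`~netdms.errors.ValidationError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

ASSOC_COLUMNS = ("SNP", "CHR", "BP", "P")
AUTOSOMES = frozenset(str(i) for i in range(1, 23))


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (one GMT record)."""

    name: str
    description: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self):
        return len(self.genes)


@dataclass
class GenotypeRef:
    """Reference genotype matrix (samples x SNPs, additive coding).

    ``matrix`` is float with NaN for missing; column j corresponds to
    ``snp_ids[j]``.
    """

    snp_ids: list
    matrix: np.ndarray

    def __post_init__(self):
        if self.matrix.ndim != 2:
            raise ValidationError("genotype matrix must be 2-dimensional")
        if self.matrix.shape[1] != len(self.snp_ids):
            raise ValidationError("genotype column count != number of SNP ids")
        if self.matrix.shape[0] < 2:
            raise ValidationError("genotype reference needs >= 2 samples")
        self._index = {s: j for j, s in enumerate(self.snp_ids)}
        if len(self._index) != len(self.snp_ids):
            raise ValidationError("duplicate SNP ids in genotype reference")

    @property
    def sample_count(self) -> int:
        return self.matrix.shape[0]

    def columns(self, snp_ids: Sequence[str]) -> np.ndarray:
        idx = [self._index[s] for s in snp_ids]
        return self.matrix[:, idx]

    def __contains__(self, snp_id) -> bool:
        return snp_id in self._index


@dataclass
class ReadReport:
    """Counts describing what a reader kept and rejected."""

    n_read: int = 0
    n_rejected: int = 0
    messages: list = field(default_factory=list)


def format_float(x) -> str:
    """6 significant digits; scientific notation below 1e-4; NA for NaN."""
    if x is None:
        return "NA"
    x = float(x)
    if math.isnan(x):
        return "NA"
    if x != 0.0 and abs(x) < 1e-4:
        return f"{x:.5e}"
    return f"{x:.6g}"


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_assoc(path) -> tuple[pd.DataFrame, ReadReport]:
    """Read a PLINK ``.assoc``-like SNP association table.

    Returns a DataFrame with columns ``snp_id, chrom, pos, p_value`` plus a
    :class:`ReadReport`. Rows whose P is non-numeric or outside (0, 1], or
    whose BP is non-numeric, are rejected and counted. Duplicate SNP ids
    raise :class:`ValidationError`; a missing required column raises
    :class:`FormatError`.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    missing = [c for c in ASSOC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    report = ReadReport()
    p = pd.to_numeric(df["P"], errors="coerce")
    bp = pd.to_numeric(df["BP"], errors="coerce")
    bad = p.isna() | (p <= 0) | (p > 1) | bp.isna() | (bp < 1)
    report.n_rejected = int(bad.sum())
    if report.n_rejected:
        report.messages.append(
            f"rejected {report.n_rejected} row(s) with invalid P or BP"
        )
    out = pd.DataFrame(
        {
            "snp_id": df.loc[~bad, "SNP"].astype(str),
            "chrom": df.loc[~bad, "CHR"].astype(str),
            "pos": bp[~bad].astype(np.int64),
            "p_value": p[~bad].astype(float),
        }
    ).reset_index(drop=True)
    dup = out["snp_id"][out["snp_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate SNP id {dup.iloc[0]!r}")
    report.n_read = len(out)
    return out, report


def read_loci(path) -> pd.DataFrame:
    """Read a 4-column gene locus TSV (gene, chrom, start, end; 1-based)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["gene_id", "chrom", "start", "end"],
        dtype={"gene_id": str, "chrom": str},
    )
    try:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-integer gene coordinates ({exc})")
    if (df["start"] > df["end"]).any():
        bad = df.loc[df["start"] > df["end"], "gene_id"].iloc[0]
        raise ValidationError(f"{path}: start > end for gene {bad!r}")
    if (df["start"] < 1).any():
        raise ValidationError(f"{path}: gene coordinates must be >= 1")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate gene id {dup.iloc[0]!r}")
    return df


def read_edge_list(path) -> list:
    """Read a 2-column TSV interaction list; order preserved, no filtering.

    Self-pairs and duplicates are kept here; deduplication happens in
    :mod:`netdms.network_build`.
    """
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated fixtures
                fields = line.split()
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 fields, found {len(fields)}"
                )
            pairs.append((fields[0], fields[1]))
    return pairs


def read_gmt(path) -> list:
    """Read GMT gene sets; duplicates within a line are collapsed."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            sets.append(GeneSet(name, desc, frozenset(g for g in genes if g)))
    return sets


def read_genotypes(path) -> GenotypeRef:
    """Read the genotype TSV dialect (header of SNP ids, NA = missing)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype=float, header=0)
    snp_ids = [str(c) for c in df.columns]
    matrix = df.to_numpy(dtype=float)
    valid = np.isnan(matrix) | np.isin(matrix, (0.0, 1.0, 2.0))
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise FormatError(
            f"{path}: genotype code {matrix[i, j]!r} at sample {i + 1}, "
            f"SNP {snp_ids[j]!r} is not in {{0,1,2,NA}}"
        )
    return GenotypeRef(snp_ids=snp_ids, matrix=matrix)


MODULE_COLUMNS = ("module_id", "seed_gene", "k", "member_genes", "Zm", "ZS", "p_module")


def read_modules(path) -> pd.DataFrame:
    """Parse back a module TSV written by :func:`write_modules`."""
    df = pd.read_csv(path, sep="\t", dtype={"module_id": str, "seed_gene": str})
    missing = [c for c in MODULE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing module column(s) {missing}")
    return df


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_modules(modules: Iterable, path) -> None:
    """Write scored modules as TSV.

    Rows are ordered by descending Zm, ties broken by seed gene id; member
    genes are comma-joined and sorted. Accepts any objects exposing
    ``module_id, seed, members, k, zm`` and optionally ``zs, p_module``.
    """
    rows = sorted(modules, key=lambda m: (-m.zm, m.seed))
    with open(path, "w") as fh:
        fh.write("\t".join(MODULE_COLUMNS) + "\n")
        for m in rows:
            zs = getattr(m, "zs", None)
            pm = getattr(m, "p_module", None)
            fh.write(
                "\t".join(
                    [
                        str(m.module_id),
                        str(m.seed),
                        str(int(m.k)),
                        ",".join(sorted(m.members)),
                        format_float(m.zm),
                        format_float(zs),
                        format_float(pm),
                    ]
                )
                + "\n"
            )


def write_assoc(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "SNP": df["snp_id"],
            "CHR": df["chrom"],
            "BP": df["pos"],
            "P": [format_float(p) for p in df["p_value"]],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_loci(df: pd.DataFrame, path) -> None:
    df[["gene_id", "chrom", "start", "end"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def write_edge_list(pairs: Iterable, path) -> None:
    with open(path, "w") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description] + sorted(s.genes)) + "\n")


def write_genotypes(geno: GenotypeRef, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(geno.snp_ids) + "\n")
        for row in geno.matrix:
            fh.write(
                "\t".join("NA" if np.isnan(v) else str(int(v)) for v in row) + "\n"
            )


def write_gene_scores(df: pd.DataFrame, path) -> None:
    """Write the gene score table; float columns use :func:`format_float`."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = [format_float(v) for v in out[col]]
    out.to_csv(path, sep="\t", index=False)
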