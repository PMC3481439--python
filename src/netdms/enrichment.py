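"""Hypergeometric over-representation of module genes in pathway sets."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .errors import ValidationError
from .formats_io import GeneSet


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    set_size_in_universe: int
    overlap: int
    p: float
    p_bonferroni: float | None = None


def hypergeom_enrich(
    module_genes: set, gene_set: GeneSet, universe: set
) -> EnrichmentResult:
    """Upper-tail hypergeometric P of the module/set overlap.

    Population = universe, successes = |set ∩ universe|, draws =
    |module genes|; P = P(X >= overlap). Gene-set members outside the
    universe are discarded before testing; module genes must already lie
    inside the universe.
    """
    if not universe:
        raise ValidationError("universe must be non-empty")
    if not set(module_genes) <= set(universe):
        raise ValidationError("module genes must be a subset of the universe")
    in_univ = gene_set.genes & set(universe)
    overlap = len(set(module_genes) & in_univ)
    m = len(universe)
    p = float(stats.hypergeom.sf(overlap - 1, m, len(in_univ), len(module_genes)))
    return EnrichmentResult(
        set_name=gene_set.name,
        set_size_in_universe=len(in_univ),
        overlap=overlap,
        p=min(p, 1.0),
    )


def bonferroni(ps: Sequence[float], m: int) -> list:
    """Each p multiplied by m, capped at 1."""
    ps = list(ps)
    if m < len(ps):
        raise ValidationError("m must be >= the number of p-values")
    return [min(1.0, p * m) for p in ps]


def enrich_all(
    module_genes: set,
    sets: Iterable[GeneSet],
    universe: set,
    m: int | None = None,
) -> pd.DataFrame:
    """Test every set and attach Bonferroni-corrected P-values.

    ``m`` defaults to the number of sets tested.
    """
    results = [hypergeom_enrich(module_genes, s, universe) for s in sets]
    m = m if m is not None else len(results)
    corrected = bonferroni([r.p for r in results], m)
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "set_size_in_universe": [r.set_size_in_universe for r in results],
            "overlap": [r.overlap for r in results],
            "p": [r.p for r in results],
            "p_bonferroni": corrected,
        }
    )
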