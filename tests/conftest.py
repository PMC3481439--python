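import numpy as np
import pandas as pd
import pytest

from netdms.formats_io import GeneSet


@pytest.fixture
def assoc_file(tmp_path):
    def make(rows, header="SNP CHR BP P", sep=" "):
        path = tmp_path / "assoc.txt"
        lines = [header] + [sep.join(str(v) for v in r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return make


@pytest.fixture
def loci_file(tmp_path):
    def make(rows):
        path = tmp_path / "loci.tsv"
        path.write_text(
            "\n".join("\t".join(str(v) for v in r) for r in rows) + "\n"
        )
        return path

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_assoc_df(snp_ids, chroms, positions, pvals):
    return pd.DataFrame(
        {
            "snp_id": list(snp_ids),
            "chrom": [str(c) for c in chroms],
            "pos": list(positions),
            "p_value": list(pvals),
        }
    )


def make_loci_df(genes):
    """genes: iterable of (gene_id, chrom, start, end)."""
    return pd.DataFrame(
        [
            {"gene_id": g, "chrom": str(c), "start": s, "end": e}
            for g, c, s, e in genes
        ]
    )


@pytest.fixture
def gene_set_factory():
    def make(name, genes):
        return GeneSet(name, "test", frozenset(genes))

    return make
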