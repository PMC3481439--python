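import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netdms import gene_score as gs
from netdms.errors import ValidationError
from netdms.formats_io import GenotypeRef

from conftest import make_assoc_df, make_loci_df


def identity_ld(k):
    return gs.LdMatrix(snp_ids=[f"s{i}" for i in range(k)], values=np.eye(k))


class TestMapSnpsToGenes:
    def test_flank_boundary_inclusive(self):
        loci = make_loci_df([("G1", 1, 100_000, 110_000)])
        snps = make_assoc_df(["rs1"], [1], [50_000], [0.5])
        m = gs.map_snps_to_genes(snps, loci)
        assert m.genes == {"G1": ("rs1",)}

    def test_one_bp_outside_flank_excluded(self):
        loci = make_loci_df([("G1", 1, 100_000, 110_000)])
        snps = make_assoc_df(["rs1"], [1], [49_999], [0.5])
        m = gs.map_snps_to_genes(snps, loci)
        assert m.genes == {}

    def test_exhaustive_pairwise_oracle(self, rng):
        genes = [
            ("G1", 1, 1000, 5000), ("G2", 1, 4000, 9000),  # overlapping pair
            ("G3", 2, 1000, 2000), ("G4", 2, 100_000, 150_000),
            ("G5", 3, 50_000, 60_000),
        ]
        loci = make_loci_df(genes)
        chroms = rng.choice(["1", "2", "3"], size=20)
        pos = rng.integers(1, 200_000, size=20)
        snps = make_assoc_df(
            [f"rs{i}" for i in range(20)], chroms, pos, [0.5] * 20
        )
        flank = 2000
        m = gs.map_snps_to_genes(snps, loci, flank_bp=flank)
        expected = {}
        for g, c, s, e in genes:
            hits = [
                (p, f"rs{i}")
                for i, (sc, p) in enumerate(zip(chroms, pos))
                if sc == str(c) and s - flank <= p <= e + flank
            ]
            if hits:
                expected[g] = tuple(snp for _, snp in sorted(hits))
        assert m.genes == expected

    def test_autosome_exclusion_counts(self):
        loci = make_loci_df([("G1", 1, 100, 200), ("GX", "X", 100, 200)])
        snps = make_assoc_df(
            ["rs1", "rsX", "rsY"], [1, "X", "Y"], [150, 150, 150],
            [0.5, 0.5, 0.5],
        )
        m = gs.map_snps_to_genes(snps, loci, flank_bp=0)
        assert set(m.genes) == {"G1"}
        assert m.n_snps_excluded == 2
        assert m.n_genes_excluded == 1

    def test_snp_maps_to_both_overlapping_genes(self):
        loci = make_loci_df([("G1", 1, 100, 300), ("G2", 1, 200, 400)])
        snps = make_assoc_df(["rs1"], [1], [250], [0.5])
        m = gs.map_snps_to_genes(snps, loci, flank_bp=0)
        assert set(m.genes) == {"G1", "G2"}


class TestEstimateLd:
    def test_duplicated_column_r_one(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 1], dtype=float)
        geno = GenotypeRef(["a", "b"], np.column_stack([col, col]))
        ld, _ = gs.estimate_ld(geno, ["a", "b"])
        assert ld.values[0, 1] == pytest.approx(1.0)

    def test_independent_snps_low_r(self, rng):
        n = 1000
        geno = GenotypeRef(
            ["a", "b"],
            np.column_stack([
                rng.integers(0, 3, n).astype(float),
                rng.integers(0, 3, n).astype(float),
            ]),
        )
        ld, _ = gs.estimate_ld(geno, ["a", "b"])
        assert abs(ld.values[0, 1]) < 0.1

    def test_hand_computed_3x3(self):
        m = np.array(
            [[0, 0, 2], [1, 1, 1], [2, 2, 0], [0, 1, 2], [1, 0, 1]],
            dtype=float,
        )
        geno = GenotypeRef(["a", "b", "c"], m)
        ld, _ = gs.estimate_ld(geno, ["a", "b", "c"])
        expected = np.corrcoef(m, rowvar=False)
        # hand/oracle matrix is already PSD here, repair must not alter it
        np.testing.assert_allclose(ld.values, expected, atol=1e-10)

    def test_monomorphic_dropped(self):
        m = np.column_stack([
            np.array([1.0, 1.0, 1.0, 1.0]),
            np.array([0.0, 1.0, 2.0, 1.0]),
        ])
        geno = GenotypeRef(["mono", "ok"], m)
        ld, report = gs.estimate_ld(geno, ["mono", "ok"])
        assert ld.snp_ids == ["ok"]
        assert report["monomorphic"] == ["mono"]

    def test_absent_snp_dropped_or_raises(self):
        geno = GenotypeRef(
            ["a"], np.array([[0.0], [1.0], [2.0], [1.0]])
        )
        ld, report = gs.estimate_ld(geno, ["a", "zzz"])
        assert report["absent"] == ["zzz"]
        with pytest.raises(ValidationError):
            gs.estimate_ld(geno, ["zzz"], on_missing="error")

    def test_psd_repair_unit_diagonal(self):
        # pairwise-complete correlations can be indefinite; force repair
        r = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        repaired = gs._repair_psd(r)
        assert np.linalg.eigvalsh(repaired).min() >= -1e-10
        np.testing.assert_allclose(np.diag(repaired), 1.0)


class TestGenePAll:
    def test_single_snp_matches_chi2_1(self):
        p_in = 0.01
        p, b = gs.gene_p_all([p_in], identity_ld(1), n_sims=2000, rng_seed=0,
                             max_sims=100_000)
        tol = 3 * np.sqrt(p_in * (1 - p_in) / b)
        assert p == pytest.approx(p_in, abs=tol)

    def test_independent_k5_matches_chi2_5(self):
        rng = np.random.default_rng(3)
        ps = rng.uniform(0.01, 0.5, size=5)
        t_obs = stats.chi2.isf(ps, 1).sum()
        expected = stats.chi2.sf(t_obs, df=5)
        p, b = gs.gene_p_all(ps, identity_ld(5), n_sims=2000, rng_seed=1,
                             max_sims=100_000)
        tol = 4 * np.sqrt(expected * (1 - expected) / b) + 2 / b
        assert p == pytest.approx(expected, abs=tol)

    def test_perfect_ld_equals_single_snp(self):
        ld2 = gs.LdMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        p2, _ = gs.gene_p_all([0.02, 0.02], ld2, n_sims=20_000, rng_seed=5,
                              adaptive=False)
        p1, _ = gs.gene_p_all([0.02], identity_ld(1), n_sims=20_000,
                              rng_seed=5, adaptive=False)
        assert p2 == pytest.approx(p1, abs=0.01)

    def test_adaptive_escalation(self):
        # tiny p escalates to the cap
        p, b = gs.gene_p_all([1e-8], identity_ld(1), n_sims=1000, rng_seed=0,
                             max_sims=100_000)
        assert b == 100_000
        assert p == pytest.approx(1 / (1 + b))

    def test_monotone_in_p_under_fixed_seed(self):
        ld = identity_ld(4)
        ps = np.array([0.3, 0.5, 0.2, 0.8])
        p_hi, _ = gs.gene_p_all(ps, ld, n_sims=1000, rng_seed=9, adaptive=False)
        p_lo, _ = gs.gene_p_all(ps / 2, ld, n_sims=1000, rng_seed=9,
                                adaptive=False)
        assert p_lo <= p_hi


class TestGenePTop:
    def test_k5_fraction_default_uses_single_top(self):
        # m = ceil(0.1 * 5) = 1: statistic is the largest chi-square
        ps = [0.5, 0.04, 0.9, 0.7, 0.2]
        q_max = stats.chi2.isf(min(ps), 1)
        p, b = gs.gene_p_top(ps, identity_ld(5), n_sims=5000, rng_seed=2,
                             adaptive=False)
        # oracle: P(max of 5 iid chi2_1 >= q_max)
        expected = 1 - stats.chi2.cdf(q_max, 1) ** 5
        tol = 4 * np.sqrt(expected * (1 - expected) / b) + 2 / b
        assert p == pytest.approx(expected, abs=tol)

    def test_fraction_one_identical_to_all(self):
        ps = [0.3, 0.02, 0.6]
        ld = identity_ld(3)
        p_top, _ = gs.gene_p_top(ps, ld, fraction=1.0, n_sims=2000,
                                 rng_seed=7, adaptive=False)
        p_all, _ = gs.gene_p_all(ps, ld, n_sims=2000, rng_seed=7,
                                 adaptive=False)
        assert p_top == p_all

    def test_k20_brute_force_oracle(self, rng):
        # independent re-simulation with a different code path
        k, frac = 20, 0.10
        m = max(1, int(np.ceil(frac * k)))
        ps = rng.uniform(0.001, 0.9, size=k)
        q = stats.chi2.isf(ps, 1)
        obs = np.sort(q)[-m:].sum()
        draws = rng.standard_normal((100_000, k)) ** 2
        draws.sort(axis=1)
        null = draws[:, -m:].sum(axis=1)
        oracle = (1 + (null >= obs).sum()) / (1 + len(null))
        p, b = gs.gene_p_top(ps, identity_ld(k), fraction=frac, n_sims=20_000,
                             rng_seed=3, adaptive=False)
        tol = 4 * np.sqrt(oracle * (1 - oracle) * (1 / b + 1e-5)) + 2 / b
        assert p == pytest.approx(oracle, abs=max(tol, 0.01))

    def test_bad_fraction_raises(self):
        with pytest.raises(ValidationError):
            gs.gene_p_top([0.5], identity_ld(1), fraction=0.0)


class TestGenePMin:
    def test_examples(self):
        assert gs.gene_p_min([0.2, 0.05, 0.8]) == 0.05
        assert gs.gene_p_min([0.3]) == 0.3

    def test_sort_oracle(self, rng):
        ps = rng.uniform(size=100)
        assert gs.gene_p_min(ps) == np.sort(ps)[0]

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            gs.gene_p_min([])

    def test_expected_value_independent_null(self, rng):
        # min of k iid uniforms has mean 1/(k+1)
        k = 4
        sims = rng.uniform(size=(5000, k)).min(axis=1)
        assert sims.mean() == pytest.approx(1 / (k + 1), abs=0.01)


class TestPToZ:
    def test_half_is_zero(self):
        assert gs.p_to_z(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_normal_quantile(self):
        assert gs.p_to_z(0.0227501) == pytest.approx(2.000, abs=1e-3)

    def test_p_one_finite(self):
        z = gs.p_to_z(1.0)
        assert np.isfinite(z)
        assert z == pytest.approx(stats.norm.isf(1 - 1e-12))

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.1])
    def test_out_of_range_raises(self, bad):
        with pytest.raises(ValidationError):
            gs.p_to_z(bad)


class TestScoreGenes:
    def _toy(self, rng, n_genes=4, snps_per_gene=3):
        genes, snp_rows = [], []
        j = 0
        for i in range(n_genes):
            start = 1_000_000 + i * 500_000
            genes.append((f"G{i}", 1, start, start + 10_000))
            for _ in range(snps_per_gene):
                snp_rows.append((f"rs{j}", 1, start + 100 * (j % 90 + 1)))
                j += 1
        loci = make_loci_df(genes)
        assoc = make_assoc_df(
            [r[0] for r in snp_rows], [r[1] for r in snp_rows],
            [r[2] for r in snp_rows], rng.uniform(0.01, 0.99, size=j),
        )
        geno = GenotypeRef(
            [r[0] for r in snp_rows],
            rng.integers(0, 3, size=(50, j)).astype(float),
        )
        return assoc, loci, geno

    def test_minp_equals_per_gene_minimum(self, rng):
        assoc, loci, _ = self._toy(rng)
        scores = gs.score_genes(assoc, loci, None, method="minp")
        snp_map = gs.map_snps_to_genes(assoc, loci)
        pmap = dict(zip(assoc.snp_id, assoc.p_value))
        for row in scores.itertuples():
            expected = min(pmap[s] for s in snp_map.genes[row.gene_id])
            assert row.p_minp == expected

    def test_z_column_consistent(self, rng):
        assoc, loci, geno = self._toy(rng)
        scores = gs.score_genes(assoc, loci, geno, method="all", n_sims=500,
                                max_sims=500, seed=1)
        for row in scores.itertuples():
            assert row.z == pytest.approx(gs.p_to_z(row.p_all))

    def test_order_independent_given_seed(self, rng):
        assoc, loci, geno = self._toy(rng)
        s1 = gs.score_genes(assoc, loci, geno, method="all", n_sims=500,
                            max_sims=500, seed=5)
        shuffled = assoc.sample(frac=1, random_state=0).reset_index(drop=True)
        s2 = gs.score_genes(shuffled, loci, geno, method="all", n_sims=500,
                            max_sims=500, seed=5)
        merged = s1.merge(s2, on="gene_id", suffixes=("_a", "_b"))
        assert (merged["p_all_a"] == merged["p_all_b"]).all()


class TestLengthBiasDiagnostic:
    def _scores(self, ps, lengths):
        genes = [(f"G{i}", 1, 1000, 1000 + L - 1) for i, L in enumerate(lengths)]
        loci = make_loci_df(genes)
        scores = pd.DataFrame(
            {"gene_id": [g[0] for g in genes], "p_minp": ps}
        )
        return scores, loci

    def test_all_null_props_zero(self):
        scores, loci = self._scores([0.5] * 30, range(100, 130))
        bins, _ = gs.length_bias_diagnostic(scores, loci, bin_size=10)
        assert (bins["prop_significant"] == 0).all()

    def test_constructed_split(self):
        lengths = list(range(100, 300))
        ps = [0.01] * 100 + [0.5] * 100  # short genes significant
        scores, loci = self._scores(ps, lengths)
        bins, _ = gs.length_bias_diagnostic(scores, loci, bin_size=100)
        assert bins["prop_significant"].tolist() == [1.0, 0.0]
        assert bins["n_genes"].tolist() == [100, 100]

    def test_qq_null_within_band(self, rng):
        n = 400
        ps = rng.uniform(size=n)
        scores, loci = self._scores(ps, rng.integers(100, 10_000, size=n))
        _, qq = gs.length_bias_diagnostic(scores, loci)
        # 95% beta order-statistic band should contain ~95% of points
        i = np.arange(1, n + 1)
        lo = stats.beta.ppf(0.025, i, n - i + 1)
        hi = stats.beta.ppf(0.975, i, n - i + 1)
        obs = 10 ** (-qq["observed_neglog10"].to_numpy())
        inside = (obs >= lo) & (obs <= hi)
        # order statistics are strongly correlated, so the fraction inside a
        # pointwise 95% band fluctuates well below its 0.95 mean
        assert inside.mean() > 0.8
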