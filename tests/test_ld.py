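"""Pairwise LD, pruning, clumping and proxy search."""

import itertools

import numpy as np
import pytest

import condfdr as cf
from condfdr.ld import UndefinedLdError, _d_prime_from_freqs

from conftest import make_merged, make_panel


class TestR2:
    def test_identical_vectors_give_one(self):
        d = np.array([[0, 1], [1, 2], [2, 0], [1, 1], [0, 0], [2, 2]], float)
        panel = make_panel(np.column_stack([d[:, 0], d[:, 0]]))
        assert cf.compute_r2(panel, "rs0", "rs1") == pytest.approx(1.0)

    def test_zero_covariance_gives_zero(self):
        x = np.array([0, 0, 2, 2], float)
        y = np.array([0, 2, 0, 2], float)
        panel = make_panel(np.column_stack([x, y]))
        assert cf.compute_r2(panel, "rs0", "rs1") == pytest.approx(0.0)

    def test_matches_hand_computed_pearson(self):
        # 6-individual toy pair; expectation via the covariance formula
        x = np.array([0, 1, 2, 1, 0, 2], float)
        y = np.array([0, 1, 1, 1, 0, 2], float)
        num = np.mean((x - x.mean()) * (y - y.mean())) ** 2
        expect = num / (x.var() * y.var())
        panel = make_panel(np.column_stack([x, y]))
        assert cf.compute_r2(panel, "rs0", "rs1") == pytest.approx(expect, abs=1e-12)

    def test_symmetric_and_coding_invariant(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(30, 2)).astype(float)
        panel = make_panel(d)
        r_ij = cf.compute_r2(panel, "rs0", "rs1")
        r_ji = cf.compute_r2(panel, "rs1", "rs0")
        assert r_ij == pytest.approx(r_ji, abs=1e-12)
        flipped = make_panel(np.column_stack([2 - d[:, 0], d[:, 1]]))
        assert cf.compute_r2(flipped, "rs0", "rs1") == pytest.approx(r_ij, abs=1e-12)

    def test_zero_variance_raises(self):
        panel = make_panel(np.column_stack([np.ones(5), np.arange(5) % 3]))
        with pytest.raises(UndefinedLdError):
            cf.compute_r2(panel, "rs0", "rs1")


def phased_panel(hap_counts):
    """Panel from haplotype counts {(a, b): count} with a, b in {0, 1}."""
    haps = []
    for (a, b), k in hap_counts.items():
        haps += [(a, b)] * k
    haps = np.array(haps, dtype=np.int8)
    dosages = (haps[0::2] + haps[1::2]).astype(float)
    return make_panel(dosages, haplotypes=haps)


class TestDPrime:
    def test_perfect_coupling_gives_one(self):
        panel = phased_panel({(1, 1): 30, (0, 0): 30})
        assert cf.compute_d_prime(panel, "rs0", "rs1") == pytest.approx(1.0)

    def test_equilibrium_gives_zero(self):
        panel = phased_panel({(1, 1): 25, (1, 0): 25, (0, 1): 25, (0, 0): 25})
        assert cf.compute_d_prime(panel, "rs0", "rs1") == pytest.approx(0.0, abs=1e-12)

    def test_worked_haplotype_counts(self):
        # counts {AB: 40, Ab: 10, aB: 10, ab: 40}: D = 0.4 - 0.25 = 0.15,
        # Dmax = min(0.5*0.5, 0.5*0.5) = 0.25, D' = 0.6
        f = np.array([40, 10, 10, 40]) / 100
        assert _d_prime_from_freqs(f) == pytest.approx(0.6, abs=1e-12)
        panel = phased_panel({(1, 1): 40, (1, 0): 10, (0, 1): 10, (0, 0): 40})
        assert cf.compute_d_prime(panel, "rs0", "rs1") == pytest.approx(0.6, abs=1e-12)

    @pytest.mark.parametrize("zero_slot", range(4))
    def test_dprime_one_when_any_haplotype_frequency_zero(self, zero_slot):
        counts = [30, 20, 26, 24]
        counts[zero_slot] = 0
        keys = [(1, 1), (1, 0), (0, 1), (0, 0)]
        panel = phased_panel(dict(zip(keys, counts)))
        assert cf.compute_d_prime(panel, "rs0", "rs1") == pytest.approx(1.0)

    def test_em_on_unphased_matches_phased(self):
        rng = np.random.default_rng(11)
        # generate haplotypes with moderate LD, then discard phase
        f = np.array([0.35, 0.15, 0.10, 0.40])
        choice = rng.choice(4, size=2000, p=f)
        haps = np.array([[(1, 1), (1, 0), (0, 1), (0, 0)][c] for c in choice],
                        dtype=np.int8)
        phased = make_panel((haps[0::2] + haps[1::2]).astype(float),
                            haplotypes=haps)
        unphased = make_panel((haps[0::2] + haps[1::2]).astype(float))
        d_phased = cf.compute_d_prime(phased, "rs0", "rs1")
        d_em = cf.compute_d_prime(unphased, "rs0", "rs1")
        # EM cannot recover phase exactly; small sampling-phase gap allowed
        assert d_em == pytest.approx(d_phased, abs=0.05)


def prune_oracle(m, r2, threshold):
    """Fixed-point oracle: rescan all pairs and apply the removal rule until
    no pair exceeds the threshold.  ``r2[(i, j)]`` indexed by snp_id."""
    df = m.df.sort_values(["chrom", "pos", "snp_id"]).reset_index(drop=True)
    alive = {r.snp_id: (r.maf, r.p1) for r in df.itertuples()}
    changed = True
    while changed:
        changed = False
        ids = [r.snp_id for r in df.itertuples() if r.snp_id in alive]
        for i, j in itertools.combinations(ids, 2):
            if i not in alive or j not in alive:
                continue
            if r2.get((i, j), r2.get((j, i), 0.0)) > threshold:
                ki = (alive[i][0], -alive[i][1], i)
                kj = (alive[j][0], -alive[j][1], j)
                drop = i if (ki[0], ki[1]) < (kj[0], kj[1]) or (
                    (ki[0], ki[1]) == (kj[0], kj[1]) and i > j) else j
                del alive[drop]
                changed = True
                break
    return set(alive)


def chain_panel(rho_chain, n=400, seed=5):
    """Markov chain of haplotypes giving a known decreasing r2 ladder."""
    rng = np.random.default_rng(seed)
    k = len(rho_chain) + 1
    haps = np.empty((2 * n, k), dtype=np.int8)
    haps[:, 0] = rng.random(2 * n) < 0.5
    for j, rho in enumerate(rho_chain, start=1):
        stay = rng.random(2 * n) < rho
        haps[:, j] = np.where(stay, haps[:, j - 1], rng.random(2 * n) < 0.5)
    return make_panel((haps[0::2] + haps[1::2]).astype(float))


class TestPrune:
    def test_lower_maf_member_removed(self):
        panel = chain_panel([0.95])
        m = make_merged([0.5, 0.5], [0.5, 0.5], pos=[1000, 2000],
                        maf=[0.1, 0.4])
        out = cf.prune(m, panel, r2_threshold=0.2, window_kb=100)
        assert list(out.df["maf"]) == [0.4]

    def test_no_pair_above_threshold_is_identity(self):
        rng = np.random.default_rng(9)
        panel = make_panel(rng.integers(0, 3, size=(500, 5)).astype(float))
        m = make_merged([0.5] * 5, [0.5] * 5, maf=np.linspace(0.1, 0.4, 5))
        out = cf.prune(m, panel, r2_threshold=0.2, window_kb=100)
        assert len(out) == len(m)

    def test_chain_matches_fixed_point_oracle(self):
        panel = chain_panel([0.98, 0.9, 0.2, 0.95], n=500)
        maf = [0.25, 0.10, 0.30, 0.05, 0.40]
        m = make_merged([0.5] * 5, [0.5] * 5, maf=maf,
                        pos=[1000, 2000, 3000, 4000, 5000])
        r2 = {}
        for i, j in itertools.combinations(range(5), 2):
            r2[(f"rs{i}", f"rs{j}")] = cf.compute_r2(panel, f"rs{i}", f"rs{j}")
        expect = prune_oracle(m, r2, 0.2)
        out = cf.prune(m, panel, r2_threshold=0.2, window_kb=100)
        assert set(out.df["snp_id"]) == expect

    def test_postcondition_no_surviving_pair_in_ld(self, small_sim):
        m, panel = small_sim["merged"], small_sim["panel"]
        out = cf.prune(m, panel, r2_threshold=0.2, window_kb=200)
        assert len(out) < len(m)
        df = out.df
        for chrom in df["chrom"].unique():
            sub = df[df["chrom"] == chrom]
            ids = sub["snp_id"].to_numpy()
            pos = sub["pos"].to_numpy()
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    if pos[j] - pos[i] > 200_000:
                        break
                    r2 = cf.compute_r2(panel, ids[i], ids[j])
                    assert r2 <= 0.2, (ids[i], ids[j], r2)

    def test_repruning_is_fixed_point(self, small_sim):
        m, panel = small_sim["merged"], small_sim["panel"]
        once = cf.prune(m, panel, 0.2, 200)
        twice = cf.prune(once, panel, 0.2, 200)
        assert list(twice.df["snp_id"]) == list(once.df["snp_id"])
        assert set(once.df["snp_id"]) <= set(m.df["snp_id"])

    def test_uncovered_snps_pass_through(self):
        panel = chain_panel([0.95])
        m = make_merged([0.5] * 3, [0.5] * 3, pos=[1000, 2000, 3000],
                        maf=[0.1, 0.4, 0.2])
        m.df.loc[2, "snp_id"] = "rs_not_in_panel"
        out = cf.prune(m, panel, 0.2, 100)
        assert "rs_not_in_panel" in set(out.df["snp_id"])

    def test_bad_threshold(self, small_sim):
        with pytest.raises(ValueError):
            cf.prune(small_sim["merged"], small_sim["panel"], r2_threshold=0.0)


def clump_oracle(df, r2_lookup, p_threshold, r2_threshold, distance_bp):
    """Greedy order enumerated explicitly."""
    cand = df[df["p"] <= p_threshold].sort_values(
        ["p", "chrom", "pos", "snp_id"])
    kept = []
    for row in cand.itertuples():
        ok = True
        for k in kept:
            if k.chrom == row.chrom and abs(k.pos - row.pos) <= distance_bp:
                ok = False
                break
            if r2_lookup(row.snp_id, k.snp_id) > r2_threshold:
                ok = False
                break
        if ok:
            kept.append(row)
    return [k.snp_id for k in kept]


class TestClump:
    def _table(self, p, pos, chrom="1"):
        from conftest import make_sumstats
        ids = [f"rs{i}" for i in range(len(p))]
        return make_sumstats(ids, chrom=chrom, pos=pos, p=p)

    def test_distance_rule_keeps_most_significant(self):
        panel = make_panel(np.random.default_rng(1).integers(0, 3, (50, 2)).astype(float),
                           pos=[10_000, 15_000])
        t = self._table([1e-12, 1e-10], pos=[10_000, 15_000])
        out = cf.clump(t, panel, p_threshold=1e-8, r2_threshold=0.001,
                       distance_kb=10)
        assert list(out.df["snp_id"]) == ["rs0"]

    def test_single_qualifier_passes(self):
        panel = make_panel(np.random.default_rng(1).integers(0, 3, (50, 1)).astype(float))
        t = self._table([1e-9], pos=[1000])
        out = cf.clump(t, panel, 1e-8, 0.001, 10)
        assert list(out.df["snp_id"]) == ["rs0"]

    def test_eight_snp_toy_matches_greedy_oracle(self):
        pos = [10_000, 18_000, 40_000, 52_000, 90_000, 95_000, 200_000, 400_000]
        p = [1e-12, 1e-9, 1e-10, 1e-11, 1e-9, 1e-13, 1e-7, 1e-9]
        panel = chain_panel([0.9, 0.1, 0.95, 0.2, 0.99, 0.1, 0.05], n=500, seed=8)
        panel = make_panel(panel.dosages, pos=pos)
        t = self._table(p, pos=pos)

        def r2_lookup(i, j):
            return cf.compute_r2(panel, i, j)

        expect = clump_oracle(t.df, r2_lookup, 1e-8, 0.3, 10_000)
        out = cf.clump(t, panel, p_threshold=1e-8, r2_threshold=0.3,
                       distance_kb=10)
        assert list(out.df["snp_id"]) == expect
        assert len(expect) >= 2  # toy actually exercises both rules


class TestProxies:
    def test_index_not_its_own_proxy_and_perfect_partner_found(self):
        haps = np.array([[1, 1], [1, 1], [0, 0], [0, 0]] * 20, dtype=np.int8)
        panel = make_panel((haps[0::2] + haps[1::2]).astype(float),
                           haplotypes=haps)
        out = cf.find_proxies(panel, "rs0", window_kb=10)
        assert [p.snp_j for p in out] == ["rs1"]
        assert out[0].r2 == pytest.approx(1.0)
        assert out[0].d_prime == pytest.approx(1.0)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(21)
        f = np.array([0.45, 0.05, 0.05, 0.45])
        # 10-SNP block built from a shared pair distribution plus noise SNPs
        choice = rng.choice(4, size=1200, p=f)
        base = np.array([[(1, 1), (1, 0), (0, 1), (0, 0)][c] for c in choice],
                        dtype=np.int8)
        cols = [base[:, 0]]
        for k in range(9):
            flip = rng.random(1200) < 0.02 * (k + 1)
            cols.append(np.where(flip, 1 - base[:, 1], base[:, 1]).astype(np.int8))
        haps = np.column_stack(cols)
        panel = make_panel((haps[0::2] + haps[1::2]).astype(float),
                           haplotypes=haps)
        out = cf.find_proxies(panel, "rs0", r2_min=0.8, window_kb=100)
        got = {p.snp_j for p in out}
        expect = set()
        for j in range(1, 10):
            r2 = cf.compute_r2(panel, "rs0", f"rs{j}")
            dp = cf.compute_d_prime(panel, "rs0", f"rs{j}")
            if r2 > 0.8 and abs(dp - 1.0) <= 1e-6:
                expect.add(f"rs{j}")
        assert got == expect
        # sorted by descending r2
        r2s = [p.r2 for p in out]
        assert r2s == sorted(r2s, reverse=True)

    def test_absent_index_raises(self):
        panel = make_panel(np.random.default_rng(0).integers(0, 3, (20, 2)).astype(float))
        with pytest.raises(KeyError):
            cf.find_proxies(panel, "rs_missing")


class TestVcfPanel:
    def test_plain_vcf_round_trip(self, tmp_path):
        vcf = tmp_path / "panel.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
            "\tI1\tI2\tI3\n"
            "1\t1000\trsA\tA\tG\t.\tPASS\t.\tGT\t0|0\t0|1\t1|1\n"
            "1\t2000\trsB\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1\t1|1\n"
            "1\t3000\trsC\tG\tA\t.\tPASS\t.\tGT\t1|0\t0|0\t0|1\n")
        panel = cf.read_panel_vcf(vcf)
        assert list(panel.snp_ids) == ["rsA", "rsB", "rsC"]
        np.testing.assert_array_equal(panel.dosages[:, 0], [0, 1, 2])
        assert panel.haplotypes is not None  # phased GTs preserved
        assert cf.compute_r2(panel, "rsA", "rsB") == pytest.approx(1.0)
        assert cf.compute_d_prime(panel, "rsA", "rsB") == pytest.approx(1.0)
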