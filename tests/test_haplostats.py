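"""EHH/iHH/XP-EHH against the brute-force all-pairs oracle, plus LD decay."""



import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from gradsel.cohortpairs import build_pairs
from gradsel.genodata import GenotypeMatrix, MarkerMap
from gradsel.haplostats import (
    CUTOFF,
    DEGENERATE,
    EDGE,
    ehh_at,
    ehh_profile,
    ihh,
    ld_decay,
    ld_r2,
    xpehh,
    xpehh_scan,
)
from gradsel.simulate import SimConfig, simulate_cohort


def ehh_bruteforce(vals, core, j):
    """All-pairs identity count over the inclusive span — the independent oracle."""
    lo, hi = min(core, j), max(core, j)
    n = vals.shape[0]
    same = 0
    for a in range(n):
        for b in range(a + 1, n):
            if np.array_equal(vals[a, lo:hi + 1], vals[b, lo:hi + 1]):
                same += 1
    return same / (n * (n - 1) / 2)


def _map_for(m, spacing=1000, chrom="1"):
    return MarkerMap([f"m{j}" for j in range(m)], [chrom] * m,
                     (np.arange(m) + 1) * spacing, ["A"] * m, ["B"] * m)


class TestEhh:
    def test_identical_haplotypes_give_one(self):
        vals = np.zeros((6, 5), dtype=np.uint8)
        assert ehh_at(vals, 2, 4) == 1.0

    def test_all_distinct_give_zero(self):
        vals = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
        assert ehh_at(vals, 0, 1) == 0.0

    def test_single_identical_pair_of_four(self):
        vals = np.array([[0, 0, 0], [0, 0, 0], [0, 1, 0], [1, 0, 1]], dtype=np.uint8)
        assert ehh_at(vals, 0, 2) == pytest.approx(1 / 6)

    @given(st.integers(2, 12), st.integers(1, 10), st.data())
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_bruteforce_oracle(self, n, m, data):
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 2, size=(n, m)).astype(np.uint8)
        core = data.draw(st.integers(0, m - 1))
        j = data.draw(st.integers(0, m - 1))
        assert ehh_at(vals, core, j) == pytest.approx(ehh_bruteforce(vals, core, j))

    def test_monotone_non_increasing_with_span(self, rng):
        vals = rng.integers(0, 2, size=(20, 30)).astype(np.uint8)
        core = 15
        for direction in (+1, -1):
            prev = ehh_at(vals, core, core)
            j = core
            while 0 < j < 29:
                j += direction
                cur = ehh_at(vals, core, j)
                assert cur <= prev + 1e-12
                prev = cur

    def test_profile_core_value_is_site_homozygosity(self, rng):
        vals = rng.integers(0, 2, size=(12, 9)).astype(np.uint8)
        M = _map_for(9)
        prof = ehh_profile(vals, 4, M, cutoff=0.0)
        col = vals[:, 4]
        counts = np.bincount(col)
        hom = (counts * (counts - 1)).sum() / (12 * 11)
        assert prof.left_ehh[0] == prof.right_ehh[0] == pytest.approx(hom)


class TestIhh:
    def test_constant_ehh_integrates_full_span_with_edge_flags(self):
        vals = np.zeros((4, 5), dtype=np.uint8)
        M = _map_for(5, spacing=1000)
        val, flags = ihh(vals, 2, M)
        assert val == pytest.approx(4000.0)  # 2000 bp each side at EHH=1
        assert flags == {"left": EDGE, "right": EDGE}

    def test_hand_trapezoid_to_chromosome_edge(self):
        # core (middle marker): all allele 0 -> EHH 1.  Each 2-marker side span
        # splits the 4 haplotypes into two identical pairs -> EHH 2/6 = 1/3.
        vals = np.array([
            [0, 0, 0],
            [0, 0, 1],
            [1, 0, 0],
            [1, 0, 1],
        ], dtype=np.uint8)
        M = _map_for(3, spacing=1000)
        val, flags = ihh(vals, 1, M, cutoff=0.05)
        expect_side = 0.5 * (1.0 + 1 / 3) * 1000  # one trapezoid to the edge
        assert val == pytest.approx(2 * expect_side)
        assert flags == {"left": EDGE, "right": EDGE}

    def test_crossing_interpolation_single_trapezoid(self):
        # 2 markers, core at the left end; all 4 haplotypes share the core
        # allele (EHH0 = 1) but are split into two pairs at the flank, so the
        # right side walks (0 bp, 1.0) -> (1000 bp, 1/3); with cutoff 0.5 the
        # crossing is interpolated at d* = (1 - 0.5)/(1 - 1/3) * 1000 = 750 bp
        vals = np.array([[0, 0], [0, 0], [0, 1], [0, 1]], dtype=np.uint8)
        M = _map_for(2, spacing=1000)
        cutoff = 0.5
        val, flags = ihh(vals, 0, M, cutoff=cutoff)
        e1 = 1 / 3
        dstar = (1.0 - cutoff) / (1.0 - e1) * 1000
        area = 0.5 * (1.0 + cutoff) * dstar
        assert flags["right"] == CUTOFF
        assert flags["left"] == EDGE  # core is the chromosome's first marker
        assert val == pytest.approx(area)

    def test_distance_doubling_doubles_ihh(self, rng):
        vals = rng.integers(0, 2, size=(16, 21)).astype(np.uint8)
        M1 = _map_for(21, spacing=500)
        M2 = _map_for(21, spacing=1000)
        v1, _ = ihh(vals, 10, M1)
        v2, _ = ihh(vals, 10, M2)
        assert v2 == pytest.approx(2 * v1)

    def test_degenerate_core_flagged_zero(self):
        # 30 pairwise-distinct haplotypes at the core would need >1 allele;
        # use many haplotypes with balanced alleles so homozygosity < cutoff
        n = 10
        vals = (np.arange(n) % 2).astype(np.uint8)[:, None] * np.ones((1, 3), dtype=np.uint8)
        vals = np.ascontiguousarray(vals)
        M = _map_for(3)
        val, flags = ihh(vals, 1, M, cutoff=0.6)
        assert val == 0.0
        assert flags["left"] == flags["right"] == DEGENERATE


class TestXpehh:
    def test_identical_populations_zero(self, rng):
        vals = rng.integers(0, 2, size=(10, 11)).astype(np.uint8)
        M = _map_for(11)
        assert xpehh(vals, vals.copy(), 5, M) == 0.0

    def test_antisymmetry_under_swap(self, rng):
        M = _map_for(15)
        a = rng.integers(0, 2, size=(12, 15)).astype(np.uint8)
        b = rng.integers(0, 2, size=(14, 15)).astype(np.uint8)
        s = xpehh(a, b, 7, M)
        assert s == pytest.approx(-xpehh(b, a, 7, M))

    def test_global_allele_relabel_invariance(self, rng):
        M = _map_for(15)
        a = rng.integers(0, 2, size=(12, 15)).astype(np.uint8)
        b = rng.integers(0, 2, size=(12, 15)).astype(np.uint8)
        s = xpehh(a, b, 7, M)
        assert s == pytest.approx(xpehh(1 - a, 1 - b, 7, M), nan_ok=True)

    def test_sweep_in_high_population_gives_negative_score(self, rng):
        # high subpopulation shares one long haplotype; low is diverse
        m = 21
        M = _map_for(m)
        shared = rng.integers(0, 2, size=m).astype(np.uint8)
        high = np.tile(shared, (10, 1))
        low = rng.integers(0, 2, size=(10, m)).astype(np.uint8)
        s = xpehh(low, high, 10, M)
        assert s < 0

    def test_scan_matches_direct_call_and_is_deterministic(self, sim_cohort):
        cfg, H, M, P = sim_cohort
        from gradsel.cohortpairs import rank_by_trait
        gp = build_pairs(rank_by_trait(P, cfg.trait), trait=cfg.trait,
                         sizes=("half", 75, 45))
        sub = H.take_markers(np.arange(40))
        Msub = M.take(np.arange(40))
        out1 = xpehh_scan(sub, gp, Msub)
        out2 = xpehh_scan(sub, gp, Msub)
        np.testing.assert_array_equal(out1, out2)
        k = 1
        high, low = gp.levels[k]
        direct = xpehh(sub.subset_samples(low).values, sub.subset_samples(high).values,
                       20, Msub)
        assert out1[20, k] == pytest.approx(direct, nan_ok=True)

    def test_null_scan_centered_near_zero(self):
        cfg = SimConfig(n_individuals=120, n_snps=120, chrom_length=7_200_000,
                        qtls=((60, 0.0, (0,)),), seed=11)
        H, M, P = simulate_cohort(cfg)
        from gradsel.cohortpairs import rank_by_trait
        gp = build_pairs(rank_by_trait(P, cfg.trait), trait=cfg.trait,
                         sizes=("half", 40, 20))
        out = xpehh_scan(H, gp, M)
        for k in range(3):
            col = out[:, k]
            col = col[np.isfinite(col)]
            se = col.std() / np.sqrt(len(col))
            assert abs(col.mean()) < 3 * se + 0.05


class TestLd:
    def test_identical_and_mirror_columns(self):
        g = np.array([0, 1, 2, 1, 0, 2, 2, 0])
        assert ld_r2(g, g) == pytest.approx(1.0)
        assert ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        g1 = rng.integers(0, 3, size=500)
        g2 = rng.integers(0, 3, size=500)
        assert ld_r2(g1, g2) < 0.05

    def test_too_few_complete_obs_raises(self):
        with pytest.raises(ValueError):
            ld_r2(np.array([0, -1]), np.array([-1, 1]))

    def test_decay_two_perfect_adjacent_snps(self):
        vals = np.array([[0, 0], [1, 1], [2, 2], [1, 1]], dtype=np.int8)
        G = GenotypeMatrix(list("abcd"), vals)
        M = _map_for(2, spacing=600)
        df = ld_decay(G, M, bin_bp=1000, max_dist=2000)
        assert df.loc[0, "mean_r2"] == pytest.approx(1.0)
        assert df["n_pairs"].sum() == 1

    def test_pair_count_conserved_and_bins_half_open(self, rng):
        m, n = 30, 50
        vals = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        G = GenotypeMatrix([f"s{i}" for i in range(n)], vals)
        M = _map_for(m, spacing=400)
        df = ld_decay(G, M, bin_bp=1000, max_dist=4000)
        # oracle count of within-range pairs
        pos = M.pos
        expect = sum(
            1 for a in range(m) for b in range(a + 1, m) if pos[b] - pos[a] <= 4000
        )
        assert df["n_pairs"].sum() == expect

    def test_founder_mosaic_ld_decays_with_distance(self, sim_cohort):
        cfg, H, M, P = sim_cohort
        G = H.to_genotypes()
        df = ld_decay(G, M, bin_bp=60_000, max_dist=1_200_000)
        ok = df["n_pairs"] > 0
        rho = spearmanr(df.loc[ok, "bin_start"], df.loc[ok, "mean_r2"]).statistic
        assert rho < 0
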