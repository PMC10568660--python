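import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popvar.core_io import MISSING, AnalysisConfig, CalledVariants, ValidationError
from popvar.popgen import (
    HudsonComponents,
    bootstrap_ci,
    diversity,
    genome_wide_fst,
    harmonic_number,
    hudson_fst_components,
    hudson_fst_from_groups,
    inbreeding_coefficient,
    pbs,
    pbs_values,
    per_gene_fst,
    site_pairwise_diversity,
    windowed_diversity,
    windowed_fst,
)

from conftest import make_sheet


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_hudson(ac_a, ac_b):
    """Second, loop-based implementation of the per-site components."""
    nums, dens = [], []
    for (r1, a1), (r2, a2) in zip(ac_a, ac_b):
        n1, n2 = r1 + a1, r2 + a2
        if n1 < 2 or n2 < 2:
            nums.append(math.nan)
            dens.append(math.nan)
            continue
        p1, p2 = a1 / n1, a2 / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        nums.append(num)
        dens.append(den)
    return nums, dens


def oracle_pi(counts, length):
    """Brute-force mean pairwise Hamming distance over explicit haplotypes."""
    counts = np.asarray(counts)
    n = int(counts[0].sum())
    haps = []
    for h in range(n):
        hap = []
        for site in counts:
            # expand counts into an explicit allele list, deterministic order
            alleles = [a for a, c in enumerate(site) for _ in range(int(c))]
            hap.append(alleles[h])
        haps.append(hap)
    total = 0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(x != y for x, y in zip(haps[i], haps[j]))
            n_pairs += 1
    return total / n_pairs / length


# ---------------------------------------------------------------------------
# Hudson components
# ---------------------------------------------------------------------------

class TestHudsonComponents:
    def test_fixed_difference(self):
        comp = hudson_fst_components(np.array([[0, 10]]), np.array([[10, 0]]))
        assert comp.num[0] == pytest.approx(1.0)
        assert comp.den[0] == pytest.approx(1.0)
        assert comp.per_site_fst()[0] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # A=(8 ref, 2 alt), B=(3 ref, 7 alt), both n=10
        comp = hudson_fst_components(np.array([[8, 2]]), np.array([[3, 7]]))
        expected_num = 0.25 - 0.16 / 9 - 0.21 / 9
        assert comp.num[0] == pytest.approx(expected_num, abs=1e-12)
        assert comp.num[0] == pytest.approx(0.208889, abs=1e-6)
        assert comp.den[0] == pytest.approx(0.62, abs=1e-12)
        assert comp.per_site_fst()[0] == pytest.approx(0.33692, abs=1e-5)

    def test_monomorphic_site_masked_ratio(self):
        comp = hudson_fst_components(np.array([[10, 0]]), np.array([[10, 0]]))
        assert comp.num[0] <= 0
        assert comp.den[0] == 0
        assert np.isnan(comp.per_site_fst()[0])

    def test_insufficient_haplotypes(self):
        with pytest.raises(ValidationError, match="insufficient haplotypes"):
            hudson_fst_components(np.array([[1, 0]]), np.array([[5, 5]]))

    def test_low_n_site_masked(self):
        comp = hudson_fst_components(
            np.array([[1, 0], [5, 5]]), np.array([[5, 5], [5, 5]])
        )
        assert np.isnan(comp.num[0]) and np.isnan(comp.den[0])
        assert not np.isnan(comp.num[1])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_sites = rng.integers(1, 20)
        ac_a = rng.integers(0, 10, size=(n_sites, 2))
        ac_b = rng.integers(0, 10, size=(n_sites, 2))
        n1, n2 = ac_a.sum(1), ac_b.sum(1)
        if not ((n1 >= 2) & (n2 >= 2)).any():
            return
        comp = hudson_fst_components(ac_a, ac_b)
        nums, dens = oracle_hudson(ac_a, ac_b)
        np.testing.assert_allclose(comp.num, nums, atol=1e-12)
        np.testing.assert_allclose(comp.den, dens, atol=1e-12)


class TestWindowedFst:
    def test_single_fixed_site(self):
        comp = hudson_fst_components(
            np.array([[0, 10]]), np.array([[10, 0]]),
            chrom=np.array(["c1"], dtype=object), pos=np.array([50]),
        )
        out = windowed_fst(comp, window_size_bp=100)
        assert out["fst"].iloc[0] == pytest.approx(1.0)
        assert out["n_snps"].iloc[0] == 1

    def test_ratio_of_averages_two_sites(self):
        comp = HudsonComponents(
            chrom=np.array(["c1", "c1"], dtype=object),
            pos=np.array([10, 20]),
            num=np.array([0.2088888888888889, 1.0]),
            den=np.array([0.62, 1.0]),
        )
        out = windowed_fst(comp, window_size_bp=100)
        assert out["fst"].iloc[0] == pytest.approx(1.2088888888888889 / 1.62)
        assert out["fst"].iloc[0] == pytest.approx(0.74623, abs=1e-5)

    def test_empty_window_missing(self):
        comp = hudson_fst_components(
            np.array([[0, 10]]), np.array([[10, 0]]),
            chrom=np.array(["c1"], dtype=object), pos=np.array([150]),
        )
        out = windowed_fst(comp, window_size_bp=100)
        assert np.isnan(out["fst"].iloc[0]) and out["n_snps"].iloc[0] == 0
        assert out["fst"].iloc[1] == pytest.approx(1.0)

    def test_windows_tile_without_overlap(self):
        comp = hudson_fst_components(
            np.tile([[5, 5]], (10, 1)), np.tile([[5, 5]], (10, 1)),
            chrom=np.array(["c1"] * 10, dtype=object),
            pos=np.arange(1, 1000, 100),
        )
        out = windowed_fst(comp, window_size_bp=100)
        assert (out["start"].iloc[1:].to_numpy()
                == out["end"].iloc[:-1].to_numpy() + 1).all()
        assert out["n_snps"].sum() == 10

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_oracle_sum(self, seed):
        rng = np.random.default_rng(seed)
        n_sites = 20
        ac_a = rng.integers(0, 8, size=(n_sites, 2)) + 1
        ac_b = rng.integers(0, 8, size=(n_sites, 2)) + 1
        pos = np.sort(rng.choice(np.arange(1, 500), n_sites, replace=False))
        comp = hudson_fst_components(
            ac_a, ac_b, chrom=np.array(["c1"] * n_sites, dtype=object), pos=pos
        )
        out = windowed_fst(comp, window_size_bp=100)
        nums, dens = oracle_hudson(ac_a, ac_b)
        for _, w in out.iterrows():
            sel = [i for i, p in enumerate(pos) if w["start"] <= p <= w["end"]]
            d = sum(dens[i] for i in sel)
            if d > 0:
                expected = sum(nums[i] for i in sel) / d
                assert w["fst"] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# PBS
# ---------------------------------------------------------------------------

class TestPbs:
    def test_all_zero(self):
        assert pbs_values(0.0, 0.0, 0.0) == pytest.approx(0.0)

    def test_hand_computed(self):
        val = pbs_values(0.2, 0.3, 0.1)
        expected = (-math.log(0.8) - math.log(0.7) + math.log(0.9)) / 2
        assert val == pytest.approx(expected, abs=1e-12)
        assert val == pytest.approx(0.237229, abs=1e-6)

    def test_clipping_finite_and_flagged(self):
        wins = pd.DataFrame({"chrom": ["c1"], "start": [1], "end": [100]})
        ab = wins.assign(fst=[1.0])
        ac = wins.assign(fst=[0.5])
        bc = wins.assign(fst=[0.5])
        res = pbs(ab, ac, bc)
        assert np.isfinite(res.table["pbs"].iloc[0])
        assert bool(res.table["clipped"].iloc[0])

    def test_misaligned_windows_error(self):
        w1 = pd.DataFrame({"chrom": ["c1"], "start": [1], "end": [100], "fst": [0.1]})
        w2 = pd.DataFrame({"chrom": ["c1"], "start": [101], "end": [200], "fst": [0.1]})
        with pytest.raises(ValidationError, match="aligned"):
            pbs(w1, w2, w1)

    @given(st.floats(0, 0.9), st.floats(0, 0.9), st.floats(0, 0.9))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_in_nonfocal_groups(self, f_ab, f_ac, f_bc):
        # swapping B and C swaps fst_AB <-> fst_AC; fst_BC is symmetric
        assert pbs_values(f_ab, f_ac, f_bc) == pytest.approx(
            pbs_values(f_ac, f_ab, f_bc), abs=1e-12
        )


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

class TestDiversity:
    def test_single_snp_pi(self):
        counts = np.array([[5, 5]])
        out = windowed_diversity(
            counts, np.array(["c1"], dtype=object), np.array([500]),
            window_size_bp=1000,
        )
        assert out["pi"].iloc[0] == pytest.approx(25 / 45 / 1000)
        assert out["pi"].iloc[0] == pytest.approx(5.5556e-4, rel=1e-4)

    def test_pi_matches_brute_force(self):
        rng = np.random.default_rng(11)
        counts = np.column_stack([10 - (a := rng.integers(0, 11, 8)), a])
        out = windowed_diversity(
            counts, np.array(["c1"] * 8, dtype=object),
            np.arange(10, 90, 10), window_size_bp=1000,
        )
        assert out["pi"].iloc[0] == pytest.approx(oracle_pi(counts, 1000), abs=1e-15)

    def test_theta_hand_computed(self):
        # 5 segregating sites, n=10, 1 kb window
        counts = np.tile([[5, 5]], (5, 1))
        out = windowed_diversity(
            counts, np.array(["c1"] * 5, dtype=object),
            np.array([10, 20, 30, 40, 50]), window_size_bp=1000,
        )
        a9 = sum(1 / i for i in range(1, 10))
        assert a9 == pytest.approx(2.8289683, abs=1e-7)
        assert out["theta"].iloc[0] == pytest.approx(5 / (a9 * 1000), abs=1e-12)
        assert out["theta"].iloc[0] == pytest.approx(1.7674e-3, rel=1e-4)
        assert out["S"].iloc[0] == 5

    def test_monomorphic_window(self):
        counts = np.array([[10, 0], [0, 10]])  # zero-count alleles: not segregating
        out = windowed_diversity(
            counts, np.array(["c1"] * 2, dtype=object), np.array([10, 20]),
            window_size_bp=1000,
        )
        assert out["pi"].iloc[0] == 0.0
        assert out["theta"].iloc[0] == 0.0

    def test_multiallelic_pi(self):
        counts = np.array([[4, 3, 3]])
        out = windowed_diversity(
            counts, np.array(["c1"], dtype=object), np.array([5]),
            window_size_bp=100,
        )
        assert out["pi"].iloc[0] == pytest.approx(oracle_pi(counts, 100), abs=1e-15)

    def test_pi_invariant_under_sample_relabeling(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 2, size=(10, 4, 2)).astype(np.int16)
        samples = [f"g_{i}" for i in range(4)]
        v = CalledVariants(
            chrom=np.array(["c1"] * 10, dtype=object),
            pos=np.arange(1, 11, dtype=np.int64) * 10,
            ref=np.array(["A"] * 10, dtype=object), alt=[("G",)] * 10,
            qual=np.full(10, 60.0), genotypes=g, samples=samples,
        )
        sheet = make_sheet({"g": 4})
        cfg = AnalysisConfig(window_size_bp=1000)
        d1 = diversity(v, sheet, cfg, n_bootstrap=100, seed=0)
        perm = [2, 0, 3, 1]
        v2 = v.take_samples([samples[i] for i in perm])
        d2 = diversity(v2, sheet, cfg, n_bootstrap=100, seed=0)
        np.testing.assert_allclose(
            d1.windows["g"]["pi"], d2.windows["g"]["pi"], atol=1e-15
        )

    def test_downsampling_seeded(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 2, size=(20, 6, 2)).astype(np.int16)
        v = CalledVariants(
            chrom=np.array(["c1"] * 20, dtype=object),
            pos=np.arange(1, 21, dtype=np.int64) * 10,
            ref=np.array(["A"] * 20, dtype=object), alt=[("G",)] * 20,
            qual=np.full(20, 60.0), genotypes=g,
            samples=[f"g_{i}" for i in range(6)],
        )
        sheet = make_sheet({"g": 6})
        cfg = AnalysisConfig(window_size_bp=1000)
        d1 = diversity(v, sheet, cfg, n_downsample=4, n_bootstrap=100, seed=7)
        d2 = diversity(v, sheet, cfg, n_downsample=4, n_bootstrap=100, seed=7)
        pd.testing.assert_frame_equal(d1.windows["g"], d2.windows["g"])

    def test_single_haplotype_error(self):
        v = CalledVariants(
            chrom=np.array(["c1"], dtype=object), pos=np.array([10]),
            ref=np.array(["A"], dtype=object), alt=[("G",)],
            qual=np.array([60.0]),
            genotypes=np.zeros((1, 1, 1), dtype=np.int16), samples=["g_0"],
        )
        with pytest.raises(ValidationError, match="haplotype"):
            diversity(v, make_sheet({"g": 1}), AnalysisConfig(ploidy=1),
                      n_bootstrap=10)


def test_windowed_fst_median_monotone_in_simulated_f():
    """Increasing differentiation strictly increases the median windowed value."""
    from popvar.core_io import group_allele_counts
    from popvar.simulate import SimulationConfig, simulate_populations

    medians = []
    for f in (0.0, 0.05, 0.1, 0.2, 0.4):
        sim = simulate_populations(
            SimulationConfig(f_target=f, n_sites=2000, n_samples_per_pop=20, seed=99)
        )
        gac = group_allele_counts(sim.variants, sim.sheet)
        comp = hudson_fst_from_groups(gac, "pop0", "pop1")
        wins = windowed_fst(comp, window_size_bp=50_000)
        medians.append(float(wins["fst"].median()))
    assert all(a < b for a, b in zip(medians, medians[1:]))
    assert harmonic_number(0) == 0.0
    assert harmonic_number(1) == 1.0
    assert harmonic_number(9) == pytest.approx(sum(1 / i for i in range(1, 10)))


def test_bootstrap_ci_contains_mean():
    rng = np.random.default_rng(0)
    vals = rng.normal(5, 1, 200)
    mean, lo, hi = bootstrap_ci(vals, 2000, seed=1)
    assert lo <= mean <= hi
    assert mean == pytest.approx(vals.mean())


# ---------------------------------------------------------------------------
# inbreeding
# ---------------------------------------------------------------------------

class TestInbreeding:
    def _variants(self, genotypes):
        g = np.asarray(genotypes, dtype=np.int16)
        samples = [f"g_{i}" for i in range(g.shape[1])]
        return CalledVariants(
            chrom=np.array(["c1"] * g.shape[0], dtype=object),
            pos=np.arange(1, g.shape[0] + 1, dtype=np.int64),
            ref=np.array(["A"] * g.shape[0], dtype=object),
            alt=[("G",)] * g.shape[0],
            qual=np.full(g.shape[0], 60.0), genotypes=g, samples=samples,
        ), make_sheet({"g": g.shape[1]})

    def test_all_heterozygous(self):
        v, sheet = self._variants([[[0, 1], [0, 1], [0, 1], [0, 1]]])
        assert inbreeding_coefficient(v, sheet)["g"] == pytest.approx(-1.0)

    def test_no_heterozygotes(self):
        # half 0/0, half 1/1: H_obs = 0, H_exp = 0.5 -> F_IS = 1
        v, sheet = self._variants([[[0, 0], [0, 0], [1, 1], [1, 1]]])
        assert inbreeding_coefficient(v, sheet)["g"] == pytest.approx(1.0)

    def test_hardy_weinberg_simulation(self):
        rng = np.random.default_rng(1234)
        p = 0.3
        g = (rng.random((50, 1000, 2)) < p).astype(np.int16)
        v, sheet = self._variants(g)
        assert abs(inbreeding_coefficient(v, sheet)["g"]) < 0.05

    def test_monomorphic_nan_with_warning(self, caplog):
        v, sheet = self._variants([[[0, 0], [0, 0]]])
        with caplog.at_level("WARNING"):
            out = inbreeding_coefficient(v, sheet)
        assert np.isnan(out["g"])
        assert "monomorphic" in caplog.text

    def test_haploid_rejected(self):
        v, sheet = self._variants([[[0], [1]]])
        with pytest.raises(ValidationError, match="ploidy"):
            inbreeding_coefficient(v, sheet)


# ---------------------------------------------------------------------------
# per-gene F_ST
# ---------------------------------------------------------------------------

class TestPerGeneFst:
    def _annotation(self, genes):
        from popvar.core_io import GenomeAnnotation

        return GenomeAnnotation(
            genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end"]),
            exons={}, contig_lengths={},
        )

    def test_single_fixed_difference_gene(self):
        comp = hudson_fst_components(
            np.array([[0, 10]]), np.array([[10, 0]]),
            chrom=np.array(["c1"], dtype=object), pos=np.array([150]),
        )
        ann = self._annotation([("geneA", "c1", 100, 200)])
        out = per_gene_fst(comp, ann)
        assert out["fst"].iloc[0] == pytest.approx(1.0)
        assert out["percentile_rank"].iloc[0] == 100.0
        assert bool(out["top_percentile"].iloc[0])

    def test_exactly_five_of_hundred_flagged(self):
        rng = np.random.default_rng(0)
        n = 100
        # distinct per-gene values via distinct (num, den) pairs
        nums = np.linspace(0.01, 0.99, n)
        comp = HudsonComponents(
            chrom=np.array(["c1"] * n, dtype=object),
            pos=np.arange(n, dtype=np.int64) * 1000 + 500,
            num=nums, den=np.ones(n),
        )
        ann = self._annotation(
            [(f"g{i}", "c1", i * 1000 + 1, (i + 1) * 1000) for i in range(n)]
        )
        out = per_gene_fst(comp, ann, fst_top_percentile=5)
        assert int(out["top_percentile"].sum()) == 5
        flagged = set(out.loc[out["top_percentile"], "gene_id"])
        assert flagged == {f"g{i}" for i in range(95, 100)}

    def test_gene_without_variants_unranked(self):
        comp = hudson_fst_components(
            np.array([[0, 10]]), np.array([[10, 0]]),
            chrom=np.array(["c1"], dtype=object), pos=np.array([150]),
        )
        ann = self._annotation(
            [("geneA", "c1", 100, 200), ("empty", "c1", 300, 400)]
        )
        out = per_gene_fst(comp, ann)
        row = out[out["gene_id"] == "empty"].iloc[0]
        assert np.isnan(row["fst"]) and np.isnan(row["percentile_rank"])
        assert not row["top_percentile"]
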