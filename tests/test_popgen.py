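import itertools
import math

import numpy as np
import pandas as pd
import pytest

from haplopop import popgen
from haplopop.simulate import SimConfig, simulate_matrix
from haplopop.types import ALT, HET, MISSING, REF

from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracles (plain loops, no shared code with the implementation)
# ---------------------------------------------------------------------------

def wc_oracle(group_sizes, group_alt_counts):
    """Direct textbook evaluation of haploid Weir-Cockerham a and b at one site."""
    r = len(group_sizes)
    n = [float(x) for x in group_sizes]
    p = [a / s for a, s in zip(group_alt_counts, group_sizes)]
    nbar = sum(n) / r
    nc = (sum(n) - sum(x * x for x in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    b = nbar / (nbar - 1) * inner
    a = nbar / nc * (s2 - inner / (nbar - 1))
    return a, b


def pairwise_pi_oracle(haplotypes):
    """Mean pairwise difference over all haplotype pairs at one site."""
    pairs = list(itertools.combinations(haplotypes, 2))
    return sum(x != y for x, y in pairs) / len(pairs)


class TestDiversity:
    def test_monomorphic_pi_zero(self):
        gm = make_matrix(np.zeros((5, 10), dtype=np.int8),
                         populations=["p"] * 10, behaviors=["social"] * 10)
        res = popgen.nucleotide_diversity(gm, genome_length=100)
        assert res.pi_per_site == 0.0
        assert res.segregating_sites == 0

    def test_single_site_half_frequency(self):
        # 4 haplotypes {0,0,1,1}: brute-force over 6 pairs gives 4/6 = 2/3
        calls = np.array([[REF, REF, ALT, ALT]])
        gm = make_matrix(calls, populations=["p"] * 4, behaviors=["social"] * 4)
        res = popgen.nucleotide_diversity(gm, genome_length=1)
        assert res.pi_per_site == pytest.approx(pairwise_pi_oracle([0, 0, 1, 1]))
        assert res.pi_per_site == pytest.approx(2 / 3)

    def test_pi_matches_pairwise_oracle_with_missing(self):
        rng = np.random.default_rng(0)
        calls = rng.choice([REF, ALT, MISSING], size=(30, 12), p=[0.5, 0.4, 0.1])
        gm = make_matrix(calls, populations=["p"] * 12, behaviors=["social"] * 12)
        expected = 0.0
        for row in calls:
            haps = [c for c in row if c in (REF, ALT)]
            if len(haps) >= 2 and len(set(haps)) > 1:
                expected += pairwise_pi_oracle(haps)
        res = popgen.nucleotide_diversity(gm, genome_length=50)
        assert res.pi_per_site == pytest.approx(expected / 50, rel=1e-12)

    def test_watterson_examples(self):
        assert popgen.watterson_theta(0, 10, 100) == 0.0
        # a_4 = 1 + 1/2 + 1/3
        assert popgen.watterson_theta(3, 4, 100) == pytest.approx(3 / ((1 + 0.5 + 1 / 3) * 100))
        assert popgen.watterson_theta(3, 4, 100) == pytest.approx(0.016364, abs=5e-7)
        assert popgen.watterson_theta(7, 2, 100) == pytest.approx(7 / 100)  # a_2 = 1

    def test_watterson_domain_error(self):
        with pytest.raises(ValueError):
            popgen.watterson_theta(1, 1, 100)

    def test_pi_theta_agree_on_neutral_sfs(self):
        # infinite-sites-style calibration: both estimators target the same scale
        ratios = []
        for seed in range(3):
            cfg = SimConfig.for_target_diversity(
                0.002, seed=seed, fst_target=0.0,
                het_artifact_rate=0.0, missing_rate=0.0,
                scaffold_layout=[("s1", 500_000)],
            )
            gm, _ = simulate_matrix(cfg)
            res = popgen.nucleotide_diversity(
                gm.take_samples(gm.ingroup_mask), cfg.genome_length
            )
            ratios.append(res.pi_per_site / res.watterson_theta_per_site)
            assert res.pi_per_site == pytest.approx(0.002, rel=0.2)
        assert 0.8 <= np.mean(ratios) <= 1.25


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        calls = np.array([[REF] * 10 + [ALT] * 10] * 3)
        gm = make_matrix(calls, populations=["p1"] * 10 + ["p2"] * 10,
                         behaviors=["social"] * 10 + ["solitary"] * 10)
        res = popgen.weir_cockerham_fst(gm, gm.population_labels)
        assert np.allclose(res.per_site["fst"], 1.0)
        assert res.genome_wide == pytest.approx(1.0)

    def test_identical_sample_frequencies_give_nonpositive_fst(self):
        # exactly equal group frequencies: only the noise term remains
        rng = np.random.default_rng(1)
        base = rng.choice([REF, ALT], size=(50, 15))
        calls = np.concatenate([base, base[:, rng.permutation(15)]], axis=1)
        gm = make_matrix(calls, populations=["p1"] * 15 + ["p2"] * 15,
                         behaviors=["social"] * 30)
        res = popgen.weir_cockerham_fst(gm, gm.population_labels)
        assert (res.per_site["fst"].dropna() <= 0).all()

    def test_panmictic_sampling_near_zero_genome_wide(self):
        # two groups drawn independently from one frequency law
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, size=5000)
        calls = (rng.uniform(size=(5000, 30)) < p[:, None]).astype(np.int8)
        gm = make_matrix(calls, populations=["p1"] * 15 + ["p2"] * 15,
                         behaviors=["social"] * 30)
        res = popgen.weir_cockerham_fst(gm, gm.population_labels)
        assert abs(res.genome_wide) < 0.01

    def test_matches_oracle_on_random_configurations(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            r = rng.integers(2, 5)
            sizes = rng.integers(2, 12, size=r)
            alts = np.array([rng.integers(0, s + 1) for s in sizes])
            cols, pops = [], []
            for g, (s, a) in enumerate(zip(sizes, alts)):
                cols.extend([ALT] * a + [REF] * (s - a))
                pops.extend([f"g{g}"] * s)
            gm = make_matrix(np.array(cols)[None, :], populations=pops,
                             behaviors=["social"] * len(pops))
            res = popgen.weir_cockerham_fst(gm, gm.population_labels)
            a_exp, b_exp = wc_oracle(sizes, alts)
            assert res.per_site["a"][0] == pytest.approx(a_exp, abs=1e-12)
            assert res.per_site["d"][0] == pytest.approx(a_exp + b_exp, abs=1e-12)

    def test_explicit_textbook_case(self):
        # p1 = 0.8, p2 = 0.2, 10 haploids each
        calls = np.array([[ALT] * 8 + [REF] * 2 + [ALT] * 2 + [REF] * 8])
        gm = make_matrix(calls, populations=["p1"] * 10 + ["p2"] * 10,
                         behaviors=["social"] * 20)
        res = popgen.weir_cockerham_fst(gm, gm.population_labels)
        a_exp, b_exp = wc_oracle([10, 10], [8, 2])
        assert res.per_site["fst"][0] == pytest.approx(a_exp / (a_exp + b_exp), abs=1e-12)

    def test_group_with_too_few_calls_skipped(self):
        # p1 has a single call at this site -> excluded from the comparison
        calls = np.array([[REF, MISSING, MISSING, MISSING, REF, ALT, REF, ALT]])
        gm = make_matrix(calls, populations=["p1"] * 4 + ["p2"] * 4,
                         behaviors=["social"] * 8)
        res = popgen.weir_cockerham_fst(gm, gm.population_labels)
        assert np.isnan(res.per_site["fst"][0])

    def test_ratio_of_sums_not_mean_of_ratios(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([REF, ALT], size=(50, 20))
        gm = make_matrix(calls, populations=["p1"] * 10 + ["p2"] * 10,
                         behaviors=["social"] * 20)
        res = popgen.weir_cockerham_fst(gm, gm.population_labels)
        df = res.per_site.dropna()
        df = df[df["d"] != 0]
        assert res.genome_wide == pytest.approx(df["a"].sum() / df["d"].sum(), rel=1e-12)
        assert res.genome_wide != pytest.approx(np.nanmean(df["fst"]), rel=1e-6)


class TestPermutation:
    def test_fully_differentiated_minimum_p(self):
        calls = np.tile(np.array([REF] * 15 + [ALT] * 15, dtype=np.int8), (40, 1))
        gm = make_matrix(calls, populations=["p1"] * 15 + ["p2"] * 15,
                         behaviors=["social"] * 15 + ["solitary"] * 15)
        res = popgen.fst_permutation_test(gm, n_perm=1000, subset_size=40, seed=4)
        assert res.observed_fst == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1001)

    def test_exhaustive_enumeration_agreement(self):
        # 3 vs 3 labels: Monte-Carlo p agrees with the exhaustive 20-arrangement p
        rng = np.random.default_rng(5)
        calls = rng.choice([REF, ALT], size=(150, 6)).astype(np.int8)
        gm = make_matrix(calls, populations=["p1"] * 3 + ["p2"] * 3,
                         behaviors=["social"] * 3 + ["solitary"] * 3)
        labels = gm.behavior_labels
        observed = popgen.weir_cockerham_fst(gm, labels).genome_wide
        null = []
        for combo in itertools.combinations(range(6), 3):
            lab = np.array(["solitary"] * 6, dtype=object)
            lab[list(combo)] = "social"
            null.append(popgen.weir_cockerham_fst(gm, lab).genome_wide)
        p_exhaustive = sum(v >= observed for v in null) / len(null)
        res = popgen.fst_permutation_test(gm, n_perm=2000, subset_size=150, seed=6)
        assert abs(res.p_value - p_exhaustive) < 0.05

    def test_p_value_convention(self):
        assert popgen.fst_permutation_test(
            make_matrix(np.tile(np.array([REF] * 4 + [ALT] * 4, dtype=np.int8), (5, 1)),
                        populations=["p1"] * 4 + ["p2"] * 4,
                        behaviors=["social"] * 4 + ["solitary"] * 4),
            n_perm=10, subset_size=5, seed=0,
        ).p_value > 0

    def test_nperm_domain_error(self, default_sim):
        _, gm, _ = default_sim
        with pytest.raises(ValueError):
            popgen.fst_permutation_test(gm, n_perm=0)

    def test_fixed_subset_mode_reproducible(self):
        rng = np.random.default_rng(7)
        calls = rng.choice([REF, ALT], size=(100, 20)).astype(np.int8)
        gm = make_matrix(calls, populations=["p1"] * 10 + ["p2"] * 10,
                         behaviors=["social"] * 10 + ["solitary"] * 10)
        r1 = popgen.fst_permutation_test(gm, n_perm=50, subset_size=60, seed=8,
                                         fresh_subset=False)
        r2 = popgen.fst_permutation_test(gm, n_perm=50, subset_size=60, seed=8,
                                         fresh_subset=False)
        assert np.array_equal(r1.null_values, r2.null_values)


class TestLD:
    def _two_col_r2(self, x, y):
        calls = np.stack([x, y]).astype(np.int8)
        gm = make_matrix(calls, positions=[100, 150],
                         populations=["p"] * len(x), behaviors=["social"] * len(x))
        res = popgen.ld_r2(gm, window_bp=1000)
        return res.pairs["r2"].tolist()

    def test_identical_columns_r2_one(self):
        assert self._two_col_r2([0, 0, 1, 1], [0, 0, 1, 1]) == [pytest.approx(1.0)]

    def test_independent_columns_r2_zero(self):
        assert self._two_col_r2([0, 0, 1, 1], [0, 1, 0, 1]) == [pytest.approx(0.0, abs=1e-15)]

    def test_printed_third_case(self):
        # D = 0.25 - 0.5*0.25 = 0.125; r2 = D^2/(0.25 * 0.25*0.75) = 1/3
        assert self._two_col_r2([0, 0, 1, 1], [0, 0, 1, 0]) == [pytest.approx(1 / 3)]

    def test_zero_variance_pair_skipped(self):
        assert self._two_col_r2([0, 0, 0, 0], [0, 0, 1, 0]) == []

    def test_window_limits_pairs(self):
        calls = np.random.default_rng(9).choice([REF, ALT], size=(3, 10)).astype(np.int8)
        gm = make_matrix(calls, positions=[100, 200, 100_000],
                         populations=["p"] * 10, behaviors=["social"] * 10)
        res = popgen.ld_r2(gm, window_bp=1000)
        assert set(zip(res.pairs["pos_i"], res.pairs["pos_j"])) <= {(100, 200)}

    def test_jointly_missing_handling_matches_pearson(self):
        rng = np.random.default_rng(10)
        x = rng.choice([REF, ALT, MISSING], size=60, p=[0.45, 0.45, 0.1])
        y = rng.choice([REF, ALT, MISSING], size=60, p=[0.45, 0.45, 0.1])
        joint = (x >= 0) & (y >= 0)
        expected = np.corrcoef(x[joint], y[joint])[0, 1] ** 2
        assert self._two_col_r2(x, y) == [pytest.approx(expected, rel=1e-10)]

    def test_decay_curve_non_increasing_on_block_model(self):
        cfg = SimConfig(seed=22, n_snps=3000, scaffold_layout=[("s1", 300_000)],
                        recomb_block_bp=500, het_artifact_rate=0.0, missing_rate=0.0)
        gm, _ = simulate_matrix(cfg)
        res = popgen.ld_r2(gm, window_bp=5000)
        curve = res.binned_decay.dropna(subset=["mean_r2"])["mean_r2"].to_numpy()
        violations = np.sum(np.diff(curve) > 0.01)
        assert violations <= 1  # allow one-bin Monte-Carlo wobble


def brute_force_vifs(dosage, retained_window):
    """Oracle: VIF by explicit OLS regression of each SNP on the others."""
    vifs = []
    x = dosage[retained_window].T
    for j in range(x.shape[1]):
        others = np.delete(x, j, axis=1)
        others = others[:, others.std(axis=0) > 0]
        target = x[:, j]
        if target.std() == 0 or others.shape[1] == 0:
            vifs.append(1.0)
            continue
        design = np.column_stack([np.ones(len(target)), others])
        beta, *_ = np.linalg.lstsq(design, target, rcond=None)
        resid = target - design @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((target - target.mean()) ** 2).sum())
        r2 = 1 - ss_res / ss_tot
        vifs.append(1 / (1 - r2) if r2 < 1 else np.inf)
    return np.array(vifs)


class TestPrune:
    def test_independent_snps_untouched(self):
        rng = np.random.default_rng(11)
        calls = rng.choice([REF, ALT], size=(20, 200)).astype(np.int8)
        gm = make_matrix(calls, populations=["p"] * 200, behaviors=["social"] * 200)
        retained = popgen.ld_prune(gm, window_snps=10, step_snps=2, vif_threshold=10)
        assert len(retained) == 20

    def test_duplicate_column_removes_later(self):
        rng = np.random.default_rng(12)
        base = rng.choice([REF, ALT], size=50).astype(np.int8)
        other = rng.choice([REF, ALT], size=50).astype(np.int8)
        calls = np.stack([base, base, other])
        gm = make_matrix(calls, positions=[100, 200, 300],
                         populations=["p"] * 50, behaviors=["social"] * 50)
        retained = popgen.ld_prune(gm, window_snps=3, step_snps=1, vif_threshold=2)
        assert 0 in retained and 1 not in retained

    def test_correlated_block_pruned_to_hand_count(self):
        # 10 SNPs; SNPs 3,4,5 perfectly correlated -> 8 retained
        rng = np.random.default_rng(13)
        cols = [rng.choice([REF, ALT], size=60).astype(np.int8) for _ in range(8)]
        block = cols[3]
        calls = np.stack(cols[:3] + [block, block.copy(), block.copy()] + cols[4:])
        gm = make_matrix(calls, populations=["p"] * 60, behaviors=["social"] * 60)
        retained = popgen.ld_prune(gm, window_snps=10, step_snps=5, vif_threshold=2)
        assert len(retained) == 8
        assert {3, 4, 5} - set(retained.tolist()) != set()  # block reduced
        assert sum(j in retained for j in (3, 4, 5)) == 1

    def test_no_retained_window_vif_exceeds_threshold(self):
        cfg = SimConfig(seed=23, n_snps=600, scaffold_layout=[("s1", 60_000)],
                        recomb_block_bp=600, het_artifact_rate=0.0, missing_rate=0.0)
        gm, _ = simulate_matrix(cfg)
        window, step, thresh = 20, 5, 2.0
        retained = popgen.ld_prune(gm, window_snps=window, step_snps=step,
                                   vif_threshold=thresh)
        dosage = gm.take_samples(gm.ingroup_mask).dosage(impute_mean=True)
        retained_set = set(retained.tolist())
        m = gm.n_variants
        for lo in range(0, max(m - window, 0) + 1, step):
            live = [j for j in range(lo, min(lo + window, m)) if j in retained_set]
            if len(live) < 2:
                continue
            vifs = brute_force_vifs(dosage, live)
            assert (vifs < thresh + 1e-6).all()


class TestPCA:
    def test_two_fixed_populations_separate_on_pc1(self):
        calls = np.tile(np.array([REF] * 10 + [ALT] * 10, dtype=np.int8), (30, 1))
        gm = make_matrix(calls, populations=["p1"] * 10 + ["p2"] * 10,
                         behaviors=["social"] * 20)
        res = popgen.genotype_pca(gm, n_components=2)
        pc1 = res.coordinates[:, 0]
        assert np.std(pc1[:10]) == pytest.approx(0.0, abs=1e-9)
        assert np.std(pc1[10:]) == pytest.approx(0.0, abs=1e-9)
        assert abs(pc1[:10].mean() - pc1[10:].mean()) > 1.0

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(14)
        calls = rng.choice([REF, ALT], size=(100, 12)).astype(np.int8)
        gm = make_matrix(calls, populations=["p"] * 12, behaviors=["social"] * 12)
        perm = rng.permutation(12)
        res1 = popgen.genotype_pca(gm, n_components=3)
        res2 = popgen.genotype_pca(gm.take_samples(perm), n_components=3)
        # same subspace up to sign: compare absolute coordinates row-wise
        assert np.allclose(np.abs(res2.coordinates), np.abs(res1.coordinates[perm]),
                           atol=1e-8)

    def test_eigenvalues_descending_nonnegative(self, default_sim):
        _, gm, _ = default_sim
        res = popgen.genotype_pca(gm.take_variants(np.arange(2000)), n_components=6)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()
        assert (res.eigenvalues >= 0).all()

    def test_components_clipped_with_warning(self):
        calls = np.random.default_rng(15).choice([REF, ALT], size=(5, 4)).astype(np.int8)
        gm = make_matrix(calls, populations=["p"] * 4, behaviors=["social"] * 4)
        res = popgen.genotype_pca(gm, n_components=50)
        assert res.coordinates.shape[1] <= 4
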