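"""Diversity statistics, Fu's Fs via Ewens sampling, and AMOVA PhiST."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stepstone.alignment_io import (
    DifferenceMatrix,
    PopulationMap,
    SequenceAlignment,
    collapse_haplotypes,
    pairwise_differences,
)
from stepstone.errors import (
    InsufficientSampleError,
    IncomparablePairError,
    is_undefined,
)
from stepstone.popgen_stats import (
    ewens_k_distribution,
    fs_from_summary,
    fs_null_test,
    fus_fs,
    haplotype_diversity,
    nucleotide_diversity,
    pairwise_phi_st_matrix,
    phi_st,
    phi_st_permutation,
    region_comparison_ttest,
)


def ewens_oracle(n: int, theta: float) -> np.ndarray:
    """P(K=k) by exhaustive permutation cycle counting (n <= 8).

    The Ewens distribution of the haplotype count satisfies
    P(K=k) ∝ (#permutations of n with k cycles) θ^k, giving an oracle
    wholly independent of the Stirling-recurrence implementation.
    """
    cycle_counts = np.zeros(n + 1)
    for perm in itertools.permutations(range(n)):
        seen = [False] * n
        cycles = 0
        for start in range(n):
            if not seen[start]:
                cycles += 1
                j = start
                while not seen[j]:
                    seen[j] = True
                    j = perm[j]
        cycle_counts[cycles] += 1
    weights = cycle_counts[1:] * theta ** np.arange(1, n + 1)
    return weights / weights.sum()


class TestHaplotypeDiversity:
    def test_monomorphic_zero(self):
        assert haplotype_diversity([7]) == 0.0

    def test_all_distinct_one(self):
        assert haplotype_diversity([1, 1, 1, 1]) == pytest.approx(1.0)

    def test_hand_evaluated(self):
        # (4/3)(1 - (0.5^2 + 0.25^2 + 0.25^2)) = (4/3)(0.625)
        assert haplotype_diversity([2, 1, 1]) == pytest.approx(5 / 6, abs=1e-12)

    def test_needs_two_samples(self):
        with pytest.raises(InsufficientSampleError):
            haplotype_diversity([1])

    def test_permutation_invariant_and_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            counts = rng.integers(1, 10, size=rng.integers(1, 6))
            h = haplotype_diversity(counts)
            assert 0.0 <= h <= 1.0
            assert h == pytest.approx(
                haplotype_diversity(rng.permutation(counts))
            )


@settings(derandomize=True, max_examples=60)
@given(
    counts=st.lists(st.integers(1, 25), min_size=1, max_size=8).filter(
        lambda c: sum(c) >= 2
    )
)
def test_haplotype_diversity_bounded_and_order_free(counts):
    h = haplotype_diversity(counts)
    assert 0.0 <= h <= 1.0 + 1e-12
    assert h == pytest.approx(haplotype_diversity(sorted(counts)))


@settings(derandomize=True, max_examples=40)
@given(
    n=st.integers(1, 40),
    theta=st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False),
)
def test_ewens_distribution_normalized(n, theta):
    p = ewens_k_distribution(n, theta)
    assert len(p) == n
    assert np.all(p >= 0)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        aln = SequenceAlignment(ids=["a", "b"], sequences=["ACGT", "ACGT"])
        assert nucleotide_diversity(pairwise_differences(aln)) == 0.0

    def test_single_pair(self):
        dm = DifferenceMatrix(
            d=np.array([[0, 1], [1, 0]]),
            sites_compared=np.full((2, 2), 10),
        )
        assert nucleotide_diversity(dm) == pytest.approx(0.1)

    def test_mean_over_pairs(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        s = np.full((3, 3), 10)
        assert nucleotide_diversity(DifferenceMatrix(d, s)) == pytest.approx(0.2)

    def test_incomparable_pair_raises(self):
        aln = SequenceAlignment(ids=["a", "b"], sequences=["NNNN", "ACGT"])
        with pytest.raises(IncomparablePairError):
            nucleotide_diversity(pairwise_differences(aln))


class TestEwensDistribution:
    def test_two_lineages_closed_form(self):
        p = ewens_k_distribution(2, 1.0)
        assert p[1] == pytest.approx(1.0 / 2.0)  # P(K=2) = theta/(theta+1)

    def test_three_lineages_stirling(self):
        p = ewens_k_distribution(3, 1.0)
        assert p[0] == pytest.approx(1 / 3)  # |s(3,1)|=2 over 3! = 6

    def test_large_theta_limit(self):
        p = ewens_k_distribution(6, 1e9)
        assert p[-1] == pytest.approx(1.0, abs=1e-6)

    def test_sums_to_one(self):
        for n in (2, 5, 30):
            for theta in (0.1, 1.0, 10.0):
                assert ewens_k_distribution(n, theta).sum() == pytest.approx(
                    1.0, abs=1e-12
                )

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    @pytest.mark.parametrize("theta", [0.1, 1.0, 10.0])
    def test_matches_cycle_counting_oracle(self, n, theta):
        np.testing.assert_allclose(
            ewens_k_distribution(n, theta), ewens_oracle(n, theta), atol=1e-12
        )


class TestFusFs:
    def test_symmetric_point_is_zero(self):
        assert fs_from_summary(2, 2, 1.0) == pytest.approx(0.0)

    def test_three_sample_hand_value(self):
        # S' = P(K>=2 | theta=1, n=3) = 2/3, Fs = ln 2
        assert fs_from_summary(3, 2, 1.0) == pytest.approx(math.log(2))

    def test_undefined_for_monomorphic(self):
        assert is_undefined(fs_from_summary(10, 1, 0.5))
        assert is_undefined(fs_from_summary(10, 3, 0.0))

    @pytest.mark.parametrize("n", range(2, 9))
    @pytest.mark.parametrize("theta", [0.1, 1.0, 10.0])
    def test_direct_summation_oracle_full_grid(self, n, theta):
        """Log-space Fs agrees with plain-float Ewens summation to 1e-8."""
        probs = ewens_oracle(n, theta)
        for k in range(2, n + 1):
            s_prime = probs[k - 1 :].sum()
            if s_prime >= 1.0:
                continue
            expected = math.log(s_prime / (1.0 - s_prime))
            assert fs_from_summary(n, k, theta) == pytest.approx(
                expected, abs=1e-8
            )

    def test_from_spectrum_and_distances(self):
        aln = SequenceAlignment(
            ids=["a", "b", "c"], sequences=["AAAA", "AAAT", "AAAT"]
        )
        pm = PopulationMap({i: "P" for i in aln.ids})
        spec = collapse_haplotypes(aln, pm)
        dm = pairwise_differences(aln)
        # theta_hat = mean(1,1,0) = 2/3, k=2, n=3
        assert fus_fs(spec, dm) == pytest.approx(
            fs_from_summary(3, 2, 2 / 3)
        )


class TestFsNullTest:
    def test_extreme_low_attains_minimum(self):
        res = fs_null_test(-1e9, n=10, theta_hat=2.0, nsim=99, seed=1)
        assert res.p_value == pytest.approx(1 / 100)

    def test_extreme_high_attains_one(self):
        # theta large enough that no null replicate is monomorphic
        # (monomorphic replicates sit on the +inf side of the logit and
        # would never count as extreme)
        res = fs_null_test(1e9, n=10, theta_hat=20.0, nsim=99, seed=1)
        assert res.p_value == 1.0

    def test_null_calibration_conservative(self):
        """Under neutral data the alpha=0.02 test rejects at most ~5%.

        Fu's test is known-conservative, so the check is one-sided: the
        rejection rate over null replicates must not exceed 0.05 by
        more than binomial noise.
        """
        from stepstone.coalescent_sim import simulate_infinite_sites_population

        n, theta, reps = 20, 3.0, 120
        rejections = 0
        tested = 0
        for rep in range(reps):
            k, theta_hat, _ = simulate_infinite_sites_population(
                n, theta, seed=50_000 + rep
            )
            fs = fs_from_summary(n, k, theta_hat)
            if is_undefined(fs):
                continue
            tested += 1
            res = fs_null_test(fs, n, theta_hat, nsim=99, seed=60_000 + rep)
            if res.p_value < 0.02:
                rejections += 1
        # binomial(120, 0.05) has sd ~2.4; allow 3 sd above the bound
        assert tested > 100
        assert rejections <= 0.05 * tested + 3 * np.sqrt(0.05 * 0.95 * tested)


def amova_oracle(d: np.ndarray, labels: list[str]) -> float:
    """Term-by-term AMOVA evaluation with explicit loops."""
    n = len(labels)
    pops = sorted(set(labels))
    ss_t = sum(d[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    sizes = {}
    for pop in pops:
        idx = [i for i, l in enumerate(labels) if l == pop]
        sizes[pop] = len(idx)
        ss_w += (
            sum(d[i, j] for a, i in enumerate(idx) for j in idx[a + 1 :])
            / len(idx)
        )
    P = len(pops)
    ms_a = (ss_t - ss_w) / (P - 1)
    ms_w = ss_w / (n - P)
    n_prime = (n - sum(s**2 for s in sizes.values()) / n) / (P - 1)
    sigma_a = (ms_a - ms_w) / n_prime
    return sigma_a / (sigma_a + ms_w)


class TestPhiSt:
    def test_fixed_differences_give_one(self, fixed_difference_alignment):
        aln, pm = fixed_difference_alignment
        dm = pairwise_differences(aln)
        labels = [pm.assignment[i] for i in aln.ids]
        assert phi_st(dm, labels) == pytest.approx(1.0)

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = 6
            d = rng.integers(0, 8, size=(n, n)).astype(float)
            d = np.triu(d, 1)
            d = d + d.T
            labels = ["A"] * 3 + ["B"] * 3
            dm = DifferenceMatrix(d=d, sites_compared=np.full((n, n), 50))
            assert phi_st(dm, labels) == pytest.approx(
                amova_oracle(d, labels), abs=1e-12
            )

    def test_random_split_of_panmictic_sample_near_zero(self):
        rng = np.random.default_rng(5)
        from tests.conftest import random_alignment

        vals = []
        for _ in range(30):
            aln = random_alignment(rng, n=12, L=60)
            dm = pairwise_differences(aln)
            labels = rng.permutation(["A"] * 6 + ["B"] * 6)
            vals.append(phi_st(dm, labels))
        assert abs(np.mean(vals)) < 0.05
        assert max(vals) <= 1.0

    def test_duplicated_population_not_positive(self):
        rng = np.random.default_rng(9)
        from tests.conftest import random_alignment

        aln = random_alignment(rng, n=4, L=50)
        both = SequenceAlignment(
            ids=[f"x{i}" for i in range(8)],
            sequences=aln.sequences + aln.sequences,
        )
        dm = pairwise_differences(both)
        val = phi_st(dm, ["A"] * 4 + ["B"] * 4)
        assert is_undefined(val) or val <= 1e-12

    def test_undefined_when_no_variation(self):
        aln = SequenceAlignment(
            ids=list("abcd"), sequences=["AAAA"] * 4
        )
        dm = pairwise_differences(aln)
        assert is_undefined(phi_st(dm, ["A", "A", "B", "B"]))

    def test_small_population_raises(self, toy_alignment):
        dm = pairwise_differences(toy_alignment)
        with pytest.raises(InsufficientSampleError):
            phi_st(dm, ["A", "B", "B", "B"])


class TestPhiStPermutation:
    def test_undefined_statistic_propagates(self):
        aln = SequenceAlignment(ids=list("abcd"), sequences=["AAAA"] * 4)
        dm = pairwise_differences(aln)
        res = phi_st_permutation(dm, ["A", "A", "B", "B"], nperm=99, seed=0)
        assert is_undefined(res.phi_st) and is_undefined(res.p_value)

    def test_p_on_add_one_grid(self, fixed_difference_alignment):
        aln, pm = fixed_difference_alignment
        dm = pairwise_differences(aln)
        labels = [pm.assignment[i] for i in aln.ids]
        res = phi_st_permutation(dm, labels, nperm=199, seed=4)
        grid = [m / 200 for m in range(1, 201)]
        assert min(abs(res.p_value - g) for g in grid) < 1e-12

    def test_matches_exhaustive_enumeration_oracle(self):
        """Sampled permutation p agrees with exhaustive label-split p."""
        rng = np.random.default_rng(17)
        from tests.conftest import random_alignment

        aln = random_alignment(rng, n=8, L=60)
        dm = pairwise_differences(aln)
        labels = np.array(["A"] * 4 + ["B"] * 4)
        obs = phi_st(dm, labels)
        # exhaustive: all unordered assignments of 4 indices to pop A
        stats = []
        for idx in itertools.combinations(range(8), 4):
            lab = np.array(["B"] * 8)
            lab[list(idx)] = "A"
            stats.append(phi_st(dm, lab))
        exact = np.mean([s >= obs - 1e-15 for s in stats])
        res = phi_st_permutation(dm, labels, nperm=999, seed=2)
        se = np.sqrt(exact * (1 - exact) / 999)
        assert abs(res.p_value - exact) < 4 * se + 2 / 1000


class TestPairwiseMatrix:
    def test_three_populations_three_pairs(self):
        rng = np.random.default_rng(2)
        from tests.conftest import random_alignment

        aln = random_alignment(rng, n=9, L=40)
        pm = PopulationMap(
            {aln.ids[i]: f"P{i // 3}" for i in range(9)}
        )
        results = pairwise_phi_st_matrix(aln, pm, nperm=49, seed=0)
        assert len(results) == 3
        # per-cell equality with direct single-pair calls
        for (a, b), res in results.items():
            ids = pm.members(a) + pm.members(b)
            sub = aln.subset(ids)
            dm = pairwise_differences(sub)
            assert phi_st(dm, [pm.assignment[i] for i in ids]) == pytest.approx(
                res.phi_st
            )


class TestRegionTTest:
    def test_focal_at_mean_gives_t_zero(self):
        res = region_comparison_ttest(2.0, [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_t(self):
        vals = [0.1, 0.2, 0.3, 0.4]
        focal = 0.9
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(4)
        expected_t = (mean - focal) / se
        res = region_comparison_ttest(focal, vals)
        assert res.t == pytest.approx(expected_t)
        assert res.df == 3

    def test_zero_variance_degenerate(self):
        res = region_comparison_ttest(0.5, [0.2, 0.2, 0.2])
        assert res.degenerate
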