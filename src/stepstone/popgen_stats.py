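"""Diversity and differentiation statistics for haplotype data.

Implements the per-population summary statistics used throughout the
package — unbiased haplotype diversity ``h``, per-site nucleotide
diversity ``π``, Fu's Fs with a coalescent-simulation null — and the
AMOVA-based differentiation statistic ``ΦST`` with a label-permutation
significance test, plus the focal-vs-region two-sided t-test.

Fu's Fs is computed from the Ewens sampling formula: given the observed
number of haplotypes ``k`` in a sample of ``n`` sequences with mean
pairwise difference θ̂ (per locus), ``S' = P(K ≥ k | θ̂, n)`` and
``Fs = ln(S' / (1 − S'))``.  Strongly negative values mark an excess of
rare haplotypes relative to the neutral equilibrium expectation, the
classic footprint of demographic expansion or hitchhiking.

All permutation/simulation p-values use the add-one estimator
``(1 + #extreme) / (n_iter + 1)`` so a p-value of exactly zero cannot
occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp

from stepstone._rng import child_int_seed, child_rng
from stepstone.alignment_io import (
    DifferenceMatrix,
    HaplotypeSpectrum,
    PopulationMap,
    SequenceAlignment,
    collapse_haplotypes,
    pairwise_differences,
)
from stepstone.errors import (
    UNDEFINED,
    ConfigurationError,
    DomainError,
    IncomparablePairError,
    InsufficientSampleError,
    is_undefined,
)

FS_ALPHA = 0.02  # conventional significance level for Fu's Fs


@dataclass
class DiversityStats:
    """Per-population diversity summary."""

    n: int
    k: int
    h: float
    pi: float
    theta_pi: float
    Fs: float = UNDEFINED
    Fs_p: float = UNDEFINED

    @property
    def fs_defined(self) -> bool:
        return not is_undefined(self.Fs)


@dataclass
class PhiStResult:
    """ΦST with its permutation p-value."""

    phi_st: float
    p_value: float
    n_permutations: int

    @property
    def defined(self) -> bool:
        return not is_undefined(self.phi_st)


@dataclass
class TTestResult:
    t: float
    df: int
    p_value: float
    degenerate: bool = False


def haplotype_diversity(counts, n: int | None = None) -> float:
    """Unbiased haplotype diversity ``h = n/(n-1) (1 - Σ p_i²)``."""
    counts = np.asarray(counts, dtype=float)
    total = int(counts.sum())
    if n is None:
        n = total
    elif n != total:
        raise ConfigurationError("counts do not sum to n")
    if n < 2:
        raise InsufficientSampleError("haplotype diversity needs n >= 2")
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def nucleotide_diversity(dm: DifferenceMatrix) -> float:
    """Mean per-site pairwise difference over all sequence pairs."""
    n = dm.n
    if n < 2:
        raise InsufficientSampleError("nucleotide diversity needs n >= 2")
    iu = np.triu_indices(n, 1)
    sites = dm.sites_compared[iu]
    if np.any(sites == 0):
        raise IncomparablePairError("a sequence pair shares no scored sites")
    return float(np.mean(dm.d[iu] / sites))


def mean_pairwise_differences(dm: DifferenceMatrix) -> float:
    """Mean pairwise difference count per locus (θ̂ for Fu's Fs)."""
    iu = np.triu_indices(dm.n, 1)
    return float(dm.d[iu].mean())


def _log_stirling_first_kind(n: int) -> np.ndarray:
    """Row ``n`` of unsigned Stirling numbers of the first kind, in logs.

    Uses ``|s(n, k)| = |s(n-1, k-1)| + (n-1) |s(n-1, k)|`` entirely in
    log space; entry ``k`` of the result is ``ln |s(n, k)|`` for
    ``k = 0..n`` (``-inf`` where the number is zero).
    """
    row = np.full(n + 1, -np.inf)
    row[min(1, n)] = 0.0  # |s(1,1)| = 1 ; |s(0,0)| = 1
    if n == 0:
        row[0] = 0.0
        return row
    for m in range(2, n + 1):
        new = np.full(n + 1, -np.inf)
        # k from 1..m
        shifted = np.concatenate(([-np.inf], row[:-1]))  # |s(m-1, k-1)|
        with np.errstate(invalid="ignore"):
            new = np.logaddexp(shifted, np.log(m - 1) + row)
        row = new
    return row


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """Ewens sampling distribution of the number of distinct haplotypes.

    Returns ``P(K = k)`` for ``k = 1..n`` under the neutral
    infinite-alleles model at scaled mutation rate ``theta``:
    ``P(K=k) = |s(n,k)| θ^k / (θ (θ+1) ⋯ (θ+n-1))``.
    """
    if theta <= 0:
        raise DomainError("theta must be positive")
    if n < 1:
        raise DomainError("n must be >= 1")
    log_s = _log_stirling_first_kind(n)[1:]  # k = 1..n
    ks = np.arange(1, n + 1)
    log_rising = np.sum(np.log(theta + np.arange(n)))
    log_p = log_s + ks * np.log(theta) - log_rising
    p = np.exp(log_p - logsumexp(log_p))  # normalize away rounding
    return p


def fs_from_summary(n: int, k_obs: int, theta_hat: float) -> float:
    """Fu's Fs from sample size, observed haplotype count, and θ̂.

    ``S' = P(K ≥ k_obs | θ̂, n)`` under the Ewens sampling formula;
    ``Fs = ln(S'/(1-S'))`` evaluated in log space so values survive S'
    near 0 or 1.  Undefined (NaN) when ``k_obs = 1`` or ``θ̂ = 0``.
    """
    if k_obs <= 1 or theta_hat <= 0:
        return UNDEFINED
    log_s = _log_stirling_first_kind(n)[1:]
    ks = np.arange(1, n + 1)
    log_rising = np.sum(np.log(theta_hat + np.arange(n)))
    log_p = log_s + ks * np.log(theta_hat) - log_rising
    log_p -= logsumexp(log_p)
    log_tail = logsumexp(log_p[k_obs - 1 :])  # ln S'
    log_head = logsumexp(log_p[: k_obs - 1])  # ln (1 - S')
    return float(log_tail - log_head)


def fus_fs(spectrum: HaplotypeSpectrum, dm: DifferenceMatrix) -> float:
    """Fu's Fs for a single-population spectrum and its distance matrix.

    θ̂ is the mean pairwise difference count per locus.  Returns the
    undefined sentinel (NaN) for monomorphic samples.
    """
    n = dm.n
    if spectrum.n != n:
        raise ConfigurationError("spectrum and distance matrix sample sizes differ")
    theta_hat = mean_pairwise_differences(dm)
    return fs_from_summary(n, spectrum.k, theta_hat)


@dataclass
class FsTestResult:
    Fs: float
    p_value: float
    n_simulations: int
    alpha: float = FS_ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def fs_null_test(
    observed_fs: float,
    n: int,
    theta_hat: float,
    nsim: int = 1000,
    seed: int = 0,
) -> FsTestResult:
    """Simulation p-value for Fu's Fs under the neutral coalescent.

    Simulates ``nsim`` single-population neutral datasets of size ``n``
    at θ = θ̂ under infinite-sites mutation, recomputes Fs for each, and
    reports the lower-tail add-one p-value
    ``(1 + #{Fs_sim ≤ Fs_obs}) / (nsim + 1)``.  Simulated datasets that
    come out monomorphic have Fs on the +∞ side of the logit and never
    count as extreme.
    """
    from stepstone.coalescent_sim import simulate_infinite_sites_population

    if nsim < 1:
        raise ConfigurationError("nsim must be >= 1")
    extreme = 0
    for i in range(nsim):
        k_sim, theta_sim, _ = simulate_infinite_sites_population(
            n, theta_hat, seed=child_int_seed(seed, "fs_null", 0) + i
        )
        fs_sim = fs_from_summary(n, k_sim, theta_sim)
        if not is_undefined(fs_sim) and fs_sim <= observed_fs:
            extreme += 1
    p = (1 + extreme) / (nsim + 1)
    return FsTestResult(Fs=observed_fs, p_value=p, n_simulations=nsim)


def diversity_stats(
    aln: SequenceAlignment,
    pm: PopulationMap,
    population: str,
    nsim_fs: int = 0,
    seed: int = 0,
) -> DiversityStats:
    """All per-population diversity statistics in one call.

    With ``nsim_fs > 0`` the Fu's Fs simulation null is run and its
    p-value reported.
    """
    members = pm.members(population)
    if len(members) < 2:
        raise InsufficientSampleError(
            f"population {population!r} has fewer than 2 samples"
        )
    sub = aln.subset(members)
    sub_pm = PopulationMap({i: population for i in members})
    spectrum = collapse_haplotypes(sub, sub_pm)
    dm = pairwise_differences(sub)
    counts = spectrum.counts.sum(axis=0)
    h = haplotype_diversity(counts)
    pi = nucleotide_diversity(dm)
    theta_pi = mean_pairwise_differences(dm)
    fs = fus_fs(spectrum, dm)
    fs_p = UNDEFINED
    if nsim_fs > 0 and not is_undefined(fs):
        fs_p = fs_null_test(fs, dm.n, theta_pi, nsim=nsim_fs, seed=seed).p_value
    return DiversityStats(
        n=dm.n, k=spectrum.k, h=h, pi=pi, theta_pi=theta_pi, Fs=fs, Fs_p=fs_p
    )


def _amova_phi(d: np.ndarray, labels: np.ndarray) -> float:
    """Two-level AMOVA ΦST on a difference matrix (may be negative/NaN)."""
    pops, inverse = np.unique(labels, return_inverse=True)
    P = len(pops)
    N = len(labels)
    sizes = np.bincount(inverse)
    if np.any(sizes < 2):
        raise InsufficientSampleError("every population needs >= 2 samples")
    iu = np.triu_indices(N, 1)
    ss_t = d[iu].sum() / N
    ss_w = 0.0
    for p in range(P):
        idx = np.flatnonzero(inverse == p)
        sub = d[np.ix_(idx, idx)]
        ss_w += sub[np.triu_indices(len(idx), 1)].sum() / sizes[p]
    ss_a = ss_t - ss_w
    ms_a = ss_a / (P - 1)
    ms_w = ss_w / (N - P)
    n_prime = (N - np.sum(sizes**2) / N) / (P - 1)
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / n_prime
    denom = sigma_a + sigma_w
    if denom == 0:
        return UNDEFINED
    return float(sigma_a / denom)


def phi_st(dm: DifferenceMatrix, labels) -> float:
    """ΦST between populations from squared-distance AMOVA.

    ``labels`` assigns a population to each row of ``dm``.  Pairwise
    difference counts serve directly as the squared distances (no
    substitution-model correction).  Negative estimates are returned as
    computed; any zeroing is display-only.
    """
    labels = np.asarray(labels)
    if len(labels) != dm.n:
        raise ConfigurationError("labels do not match the distance matrix")
    if len(np.unique(labels)) < 2:
        raise ConfigurationError("need at least two populations")
    return _amova_phi(dm.d.astype(float), labels)


def phi_st_permutation(
    dm: DifferenceMatrix, labels, nperm: int = 1000, seed: int = 0
) -> PhiStResult:
    """Permutation test of ΦST against no-structure null.

    Individual-to-population labels are permuted with sizes held fixed;
    ``p = (1 + #{ΦST_perm ≥ ΦST_obs}) / (nperm + 1)``.
    """
    labels = np.asarray(labels)
    obs = phi_st(dm, labels)
    if is_undefined(obs):
        return PhiStResult(phi_st=UNDEFINED, p_value=UNDEFINED, n_permutations=nperm)
    rng = child_rng(seed, "phi_perm")
    d = dm.d.astype(float)
    extreme = 0
    for _ in range(nperm):
        perm = rng.permutation(labels)
        val = _amova_phi(d, perm)
        if not is_undefined(val) and val >= obs:
            extreme += 1
    p = (1 + extreme) / (nperm + 1)
    return PhiStResult(phi_st=obs, p_value=p, n_permutations=nperm)


def pairwise_phi_st_matrix(
    aln: SequenceAlignment,
    pm: PopulationMap,
    nperm: int = 1000,
    seed: int = 0,
) -> dict[tuple[str, str], PhiStResult]:
    """ΦST and permutation p-values for every unordered population pair.

    Populations with fewer than two samples yield flagged (NaN) cells
    rather than aborting the sweep.  Use :func:`phi_st_display_matrix`
    for the zero-corrected copy used in figures.
    """
    dm = pairwise_differences(aln)
    id_index = {s: i for i, s in enumerate(aln.ids)}
    results: dict[tuple[str, str], PhiStResult] = {}
    pops = pm.populations
    for a_i in range(len(pops)):
        for b_i in range(a_i + 1, len(pops)):
            a, b = pops[a_i], pops[b_i]
            ids = pm.members(a) + pm.members(b)
            rows = [id_index[i] for i in ids]
            sub = DifferenceMatrix(
                d=dm.d[np.ix_(rows, rows)],
                sites_compared=dm.sites_compared[np.ix_(rows, rows)],
                ids=ids,
            )
            labels = [pm.assignment[i] for i in ids]
            try:
                res = phi_st_permutation(
                    sub, labels, nperm=nperm,
                    seed=child_int_seed(seed, f"pair_{a}_{b}"),
                )
            except InsufficientSampleError:
                res = PhiStResult(UNDEFINED, UNDEFINED, nperm)
            results[(a, b)] = res
    return results


def phi_st_display_matrix(
    results: dict[tuple[str, str], PhiStResult], populations: list[str]
) -> np.ndarray:
    """Symmetric ΦST matrix with negative values corrected to zero.

    This is the visualization convention only; analytic consumers keep
    the signed estimates.
    """
    P = len(populations)
    out = np.zeros((P, P))
    index = {p: i for i, p in enumerate(populations)}
    for (a, b), res in results.items():
        val = res.phi_st
        disp = 0.0 if (is_undefined(val) or val < 0) else val
        out[index[a], index[b]] = out[index[b], index[a]] = disp
    return out


def region_comparison_ttest(focal_value: float, regional_values) -> TTestResult:
    """Two-sided one-sample t-test of regional values against the focal value.

    Tests whether the focal population's statistic differs from the
    mean of the surrounding sampled populations; the regional values are
    the sample, the focal value the null mean.
    """
    vals = np.asarray(regional_values, dtype=float)
    if len(vals) < 2:
        raise InsufficientSampleError("need >= 2 regional values")
    if np.allclose(vals, vals[0]):
        return TTestResult(t=UNDEFINED, df=len(vals) - 1, p_value=UNDEFINED,
                           degenerate=True)
    t, p = sps.ttest_1samp(vals, popmean=focal_value)
    return TTestResult(t=float(t), df=len(vals) - 1, p_value=float(p))
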