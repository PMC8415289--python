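"""Metapopulation model choice: panmixia vs n-island vs stepping-stone.

The decision engine is simulation-based (rejection ABC): parameters are
drawn from the windowed exponential priors, datasets simulated under
each candidate topology, reduced to a summary-statistic vector, and the
closest fraction of simulations to the observed vector retained.  The
per-model share of the accepted set gives relative model probabilities,
and the log acceptance rate at the common distance threshold serves as
a marginal-likelihood proxy.  Downstream arithmetic — relative
probabilities, 2 ln Bayes factors, odds, Kass–Raftery evidence labels,
and the replicate permutation t-test — is shared with likelihood-based
samplers and lives in :func:`bayes_factor_table`,
:func:`kass_raftery_label` and :func:`replicate_support_test`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from stepstone._rng import child_int_seed
from stepstone.alignment_io import (
    PopulationMap,
    SequenceAlignment,
    collapse_haplotypes,
    pairwise_differences,
)
from stepstone.coalescent_sim import (
    MetapopModel,
    MutationModel,
    PriorSpec,
    build_model,
    draw_truncated_exponential,
    simulate_dataset,
)
from stepstone.errors import ConfigurationError, InsufficientSampleError, is_undefined
from stepstone.popgen_stats import _amova_phi, haplotype_diversity
from stepstone._rng import child_rng


@dataclass
class SummaryStatVector:
    """Fixed-order summary statistics for one dataset.

    Per population: haplotype diversity ``h``, per-site nucleotide
    diversity ``π``, haplotype count ``k``; then all unordered pairwise
    ΦST values (undefined cells imputed as 0 and flagged); finally the
    global haplotype count.
    """

    values: np.ndarray
    names: list[str]
    imputed: list[str] = field(default_factory=list)


@dataclass
class ModelPosterior:
    """Model-choice output: probabilities, Bayes factors, odds."""

    labels: list[str]
    lnml: dict[str, float]
    probabilities: dict[str, float]
    two_ln_bf: np.ndarray  # antisymmetric, ordered as labels
    odds: float  # best vs second
    ranking: list[str]
    accepted: dict[str, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def best(self) -> str:
        return self.ranking[0]

    @property
    def second(self) -> str:
        if len(self.ranking) < 2:
            raise ConfigurationError("posterior has a single model")
        return self.ranking[1]

    @property
    def top_two_ln_bf(self) -> float:
        i = self.labels.index(self.best)
        j = self.labels.index(self.second)
        return float(self.two_ln_bf[i, j])


@dataclass
class ReplicateSupport:
    """Exhaustive permutation t-test over replicate lnML estimates."""

    values_first: list[float]
    values_second: list[float]
    p_value: float
    observed_diff: float
    n_relabelings: int


def summarize(aln: SequenceAlignment, pm: PopulationMap) -> SummaryStatVector:
    """Compute the ABC summary-statistic vector for a dataset."""
    dm = pairwise_differences(aln)
    spectrum = collapse_haplotypes(aln, pm)
    id_index = {s: i for i, s in enumerate(aln.ids)}
    values: list[float] = []
    names: list[str] = []
    imputed: list[str] = []
    pops = pm.populations
    for pop in pops:
        rows = [id_index[i] for i in pm.members(pop)]
        counts = spectrum.population_counts(pop)
        counts = counts[counts > 0]
        h = haplotype_diversity(counts) if len(rows) >= 2 else 0.0
        sub_d = dm.d[np.ix_(rows, rows)]
        sub_s = dm.sites_compared[np.ix_(rows, rows)]
        if len(rows) >= 2:
            iu = np.triu_indices(len(rows), 1)
            pi = float(np.mean(sub_d[iu] / sub_s[iu]))
        else:
            pi = 0.0
        values += [h, pi, float(len(counts))]
        names += [f"h[{pop}]", f"pi[{pop}]", f"k[{pop}]"]
    for a_i in range(len(pops)):
        for b_i in range(a_i + 1, len(pops)):
            a, b = pops[a_i], pops[b_i]
            rows = [id_index[i] for i in pm.members(a) + pm.members(b)]
            labels = [pm.assignment[aln.ids[r]] for r in rows]
            name = f"phi_st[{a},{b}]"
            try:
                val = _amova_phi(
                    dm.d[np.ix_(rows, rows)].astype(float), np.asarray(labels)
                )
            except InsufficientSampleError:
                val = float("nan")
            if is_undefined(val):
                val = 0.0
                imputed.append(name)
            values.append(val)
            names.append(name)
    values.append(float(spectrum.k))
    names.append("k[global]")
    return SummaryStatVector(np.asarray(values, float), names, imputed)


# Migrations per pairwise coalescence (M·Θ/2) beyond which a structured
# model is numerically indistinguishable from its pooled panmictic limit
# (expected ΦST below ~1%); stepping-stone chains mix slower, so the
# threshold scales with the squared chain length.
_POOLING_MIX_SCALE = 200.0


def _concrete_model(template: MetapopModel, theta: float, m: float) -> MetapopModel:
    """Instantiate a model template with drawn prior parameters.

    In the high-migration regime (``M·Θ`` beyond the mixing threshold)
    the structured coalescent converges to a single panmictic deme of
    pooled size ``n_demes × Θ``; that exact limit is simulated directly,
    which also caps the per-simulation event count.
    """
    if template.label == "panmixia":
        return build_model("panmixia", template.demes, theta=theta)
    k = template.n_demes
    boundary = _POOLING_MIX_SCALE * (
        (k - 1) ** 2 if template.label == "stepping_stone" else 1
    )
    if theta * m >= boundary:
        return build_model("panmixia", [template.demes[0]], theta=theta * k)
    return build_model(
        template.label,
        template.demes,
        neighbor_pairs=template.neighbor_pairs or None,
        theta=theta,
        m=m,
    )


def _simulation_sample_sizes(
    template: MetapopModel, observed_sizes: dict[str, int]
) -> dict[str, int]:
    if template.n_demes == 1:
        return {template.demes[0]: sum(observed_sizes.values())}
    missing = [d for d in template.demes if d not in observed_sizes]
    if missing:
        raise ConfigurationError(
            f"model demes not present in observed data: {missing}"
        )
    return {d: observed_sizes[d] for d in template.demes}


def _relabel_panmictic(
    aln: SequenceAlignment, observed_sizes: dict[str, int]
) -> PopulationMap:
    """Stratify a single-deme simulation by the observed population sizes.

    Under panmixia individuals are exchangeable, so assigning the
    observed strata in emission order is a valid draw of the labels.
    """
    labels: list[str] = []
    for pop, size in observed_sizes.items():
        labels += [pop] * size
    return PopulationMap(assignment=dict(zip(aln.ids, labels)))


def abc_model_choice(
    observed: SummaryStatVector,
    models: list[MetapopModel],
    priors: PriorSpec,
    observed_sizes: dict[str, int],
    L: int,
    mutation_model: MutationModel | None = None,
    nsim_per_model: int = 1000,
    accept_fraction: float = 0.01,
    seed: int = 0,
) -> ModelPosterior:
    """Rejection-ABC model choice over the candidate topologies.

    For each model, ``nsim_per_model`` datasets are simulated at prior
    parameter draws and summarized; all statistics are standardized by
    their median absolute deviation across the pooled reference table;
    the ``accept_fraction`` closest simulations to the observed vector
    (Euclidean distance) are accepted.  Relative model probability is
    the per-model share of the accepted set; the marginal-likelihood
    proxy is the log per-model acceptance rate at the common distance
    threshold.  A model with zero acceptances receives the probability
    floor ``1/(total accepted + number of models)`` and a flag.
    """
    if nsim_per_model < 100:
        raise ConfigurationError("nsim_per_model must be >= 100")
    if not (0 < accept_fraction <= 1):
        raise ConfigurationError("accept_fraction must be in (0, 1]")
    mutation_model = mutation_model or MutationModel()
    labels = [m.label for m in models]
    if len(set(labels)) != len(labels):
        labels = [f"{m.label}#{i}" for i, m in enumerate(models)]

    rng = child_rng(seed, "abc_priors")
    table: list[np.ndarray] = []
    model_of_sim: list[int] = []
    sim_counter = 0
    for mi, template in enumerate(models):
        sizes = _simulation_sample_sizes(template, observed_sizes)
        for _ in range(nsim_per_model):
            theta = float(
                draw_truncated_exponential(
                    priors.theta_lower, priors.theta_upper, priors.theta_mean, rng
                )
            )
            m_rate = float(
                draw_truncated_exponential(
                    priors.m_lower, priors.m_upper, priors.m_mean, rng
                )
            )
            concrete = _concrete_model(template, theta, m_rate)
            sim_sizes = (
                {concrete.demes[0]: sum(sizes.values())}
                if concrete.n_demes == 1
                else sizes
            )
            sim_seed = child_int_seed(seed, "abc_sim", 0) + sim_counter
            sim_counter += 1
            aln, pm = simulate_dataset(
                concrete, sim_sizes, L, mutation_model, seed=sim_seed
            )
            if concrete.n_demes == 1:
                pm = _relabel_panmictic(aln, observed_sizes)
            stats = summarize(aln, pm)
            table.append(stats.values)
            model_of_sim.append(mi)

    ref = np.vstack(table)
    model_of_sim = np.asarray(model_of_sim)
    mad = np.median(np.abs(ref - np.median(ref, axis=0)), axis=0)
    scale = np.where(mad > 0, mad, 1.0)
    dist = np.sqrt(np.sum(((ref - observed.values) / scale) ** 2, axis=1))
    n_accept = max(1, int(round(accept_fraction * len(dist))))
    threshold = np.partition(dist, n_accept - 1)[n_accept - 1]
    accepted_mask = dist <= threshold
    counts = {
        lab: int(np.sum(model_of_sim[accepted_mask] == i))
        for i, lab in enumerate(labels)
    }
    return posterior_from_acceptance(counts, nsim_per_model)


def posterior_from_acceptance(
    counts: dict[str, int], nsim_per_model: int
) -> ModelPosterior:
    """Posterior arithmetic from per-model acceptance counts.

    Relative probability is the per-model share of the accepted set;
    the lnML proxy is the log acceptance rate.  Zero-count models get
    the probability floor ``1/(total accepted + number of models)`` and
    a flag, keeping every Bayes factor finite.
    """
    labels = list(counts)
    total_accepted = sum(counts.values())
    flags: list[str] = []
    lnml: dict[str, float] = {}
    floor = 1.0 / (total_accepted + len(labels))
    weights: dict[str, float] = {}
    for lab in labels:
        c = counts[lab]
        if c == 0:
            flags.append(f"zero-acceptance floor applied to {lab}")
            weights[lab] = floor
            lnml[lab] = float(np.log(floor * total_accepted / nsim_per_model))
        else:
            weights[lab] = c / total_accepted
            lnml[lab] = float(np.log(c / nsim_per_model))
    z = sum(weights.values())
    probabilities = {lab: w / z for lab, w in weights.items()}

    post = bayes_factor_table(lnml)
    return ModelPosterior(
        labels=post.labels,
        lnml=lnml,
        probabilities=probabilities,
        two_ln_bf=post.two_ln_bf,
        odds=post.odds,
        ranking=post.ranking,
        accepted=dict(counts),
        flags=flags,
    )


def bayes_factor_table(lnml: dict[str, float]) -> ModelPosterior:
    """Convert per-model log marginal likelihoods to the reporting fields.

    Probabilities are the softmax of the lnML values; ``two_ln_bf`` is
    the antisymmetric matrix ``2 (lnML_i - lnML_j)``; ``odds`` is
    ``exp(lnML_best - lnML_second)``.
    """
    labels = list(lnml)
    vals = np.array([lnml[lab] for lab in labels], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ConfigurationError("lnML values must be finite")
    shifted = vals - vals.max()
    probs = np.exp(shifted) / np.exp(shifted).sum()
    two_ln_bf = 2.0 * (vals[:, None] - vals[None, :])
    order = np.argsort(-vals, kind="stable")
    ranking = [labels[i] for i in order]
    odds = float(np.exp(vals[order[0]] - vals[order[1]])) if len(vals) > 1 else np.inf
    return ModelPosterior(
        labels=labels,
        lnml=dict(lnml),
        probabilities={lab: float(p) for lab, p in zip(labels, probs)},
        two_ln_bf=two_ln_bf,
        odds=odds,
        ranking=ranking,
    )


def kass_raftery_label(two_ln_bf: float) -> str:
    """Kass–Raftery evidence category for a 2 ln BF value.

    ``> 6`` is "strong" (odds beyond 20:1), ``> 3`` "substantial",
    anything else "weak".
    """
    if not np.isfinite(two_ln_bf):
        raise ConfigurationError("2 ln BF must be finite")
    if two_ln_bf > 6:
        return "strong"
    if two_ln_bf > 3:
        return "substantial"
    return "weak"


def replicate_support_test(
    lnml_first, lnml_second
) -> ReplicateSupport:
    """Exhaustive permutation t-test comparing replicate lnML means.

    All ``C(m+n, m)`` relabelings of the pooled replicate values are
    enumerated; the one-tailed p-value is the proportion of relabelings
    whose mean difference (first minus second) is at least the observed
    one, the observed labeling included.  With 3 vs 3 replicates the
    attainable floor is ``1/20 = 0.05``.
    """
    a = [float(x) for x in lnml_first]
    b = [float(x) for x in lnml_second]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientSampleError("need >= 2 replicates per model")
    pooled = a + b
    observed = np.mean(a) - np.mean(b)
    m = len(a)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), m):
        grp_a = [pooled[i] for i in idx]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        diff = np.mean(grp_a) - np.mean(grp_b)
        if diff >= observed - 1e-12:
            count += 1
        total += 1
    return ReplicateSupport(
        values_first=a,
        values_second=b,
        p_value=count / total,
        observed_diff=float(observed),
        n_relabelings=total,
    )
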