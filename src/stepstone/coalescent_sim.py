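"""Structured-coalescent synthetic data under three metapopulation models.

This module is the package's synthetic-data engine.  It simulates
multi-deme mtDNA samples under the three migration topologies compared
throughout the package:

* ``panmixia`` — a single well-mixed deme;
* ``island`` — n demes of equal size exchanging migrants at one equal
  rate between every ordered pair;
* ``stepping_stone`` — migration restricted to neighboring demes.

Scaling follows the mutation-scaled convention used by coalescent
samplers for single-locus data: time is measured in expected mutations
per site, Θ = N_e·μ (per deme, inheritance-scaled — haploid maternal
for mtDNA) and M = m/μ is the backwards immigration rate of a lineage.
With these units a pair of lineages in a deme coalesces at rate 2/Θ and
the expected pairwise sequence divergence under panmixia is Θ per site.

Genealogy generation and sequence mutation are delegated to ``msprime``
(configured so its generation/size parameters realize exactly the rates
above); the analytic first-step-analysis oracle
:func:`expected_coalescence_times` is implemented independently here
and is used by the test-suite to validate that mapping.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import msprime
import numpy as np
import tskit
from scipy import stats as sps

from stepstone._rng import child_int_seed, child_rng
from stepstone.alignment_io import PopulationMap, SequenceAlignment
from stepstone.errors import (
    ConfigurationError,
    ModelInvariantError,
    NonCoalescingError,
)

PANMIXIA = "panmixia"
ISLAND = "island"
STEPPING_STONE = "stepping_stone"
MODEL_LABELS = (PANMIXIA, ISLAND, STEPPING_STONE)

_BASES = ("A", "C", "G", "T")


@dataclass
class MetapopModel:
    """A labelled metapopulation model with concrete parameters.

    ``theta`` holds per-deme Θ; ``M`` the deme×deme matrix of
    mutation-scaled backwards immigration rates (``M[i, j]`` is the rate
    at which a lineage currently in deme ``i`` jumps to deme ``j``
    looking backwards in time; zero diagonal).  ``neighbor_pairs`` is
    only meaningful for the stepping-stone topology.
    """

    label: str
    demes: list[str]
    theta: np.ndarray
    M: np.ndarray
    neighbor_pairs: frozenset[frozenset] = frozenset()
    inheritance_scalar: float = 1.0

    @property
    def n_demes(self) -> int:
        return len(self.demes)

    def deme_index(self, name: str) -> int:
        return self.demes.index(name)


@dataclass
class MutationModel:
    """HKY substitution model with discrete-gamma rate heterogeneity.

    ``kappa`` is the transition/transversion rate ratio, ``base_freqs``
    the equilibrium frequencies (A, C, G, T), ``alpha`` the gamma shape
    and ``n_categories`` the number of equal-probability discrete
    categories (category rates are conditional means, normalized to
    overall mean 1).
    """

    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    alpha: float = 0.5
    n_categories: int = 4

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.alpha <= 0 or self.n_categories < 1:
            raise ModelInvariantError("kappa, alpha must be > 0; n_categories >= 1")
        total = float(sum(self.base_freqs))
        if abs(total - 1.0) > 1e-12:
            raise ModelInvariantError("base frequencies must sum to 1")

    def category_rates(self) -> np.ndarray:
        """Equal-probability discrete-gamma category rates (mean 1).

        Rates are the conditional means of a Gamma(alpha, mean 1)
        between consecutive ``c/K`` quantiles, computed with the
        incomplete-gamma identity ``E[X; X<q] = F_{alpha+1}(q)`` for a
        unit-mean gamma.
        """
        k = self.n_categories
        if k == 1:
            return np.ones(1)
        a = self.alpha
        bounds = sps.gamma.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        upper = sps.gamma.cdf(bounds, a + 1, scale=1.0 / a)
        rates = k * np.diff(upper)
        return rates / rates.mean()

    def draw_site_rates(self, L: int, rng: np.random.Generator) -> np.ndarray:
        """Per-site rate multipliers: a uniform category per site."""
        cats = self.category_rates()
        return cats[rng.integers(0, len(cats), size=L)]


@dataclass
class Genealogy:
    """A single-locus genealogy with deme-aware tips.

    Wraps a one-tree ``tskit`` tree sequence produced by the structured
    coalescent; node times are in mutational units.  ``tip_demes`` gives
    the sampling deme of each tip in emission order.
    """

    ts: tskit.TreeSequence
    demes: list[str]
    tip_demes: list[str]
    migrations: list[tuple[int, float, str, str]] = field(default_factory=list)

    @property
    def n_tips(self) -> int:
        return self.ts.num_samples

    @property
    def n_coalescences(self) -> int:
        return self.ts.num_nodes - self.ts.num_samples

    @property
    def tmrca(self) -> float:
        tree = self.ts.first()
        return max(tree.time(r) for r in tree.roots)

    @property
    def total_branch_length(self) -> float:
        return self.ts.first().total_branch_length

    def node_times(self) -> np.ndarray:
        return self.ts.tables.nodes.time

    def to_newick(self, include_migrations: bool = True) -> str:
        """Newick string; migration events appended as ``#`` comment lines."""
        newick = self.ts.first().as_newick()
        if not include_migrations:
            return newick
        lines = [newick]
        for node, time, src, dst in self.migrations:
            lines.append(f"# migration node={node} time={time:.6g} {src}->{dst}")
        return "\n".join(lines)


@dataclass
class PriorSpec:
    """Windowed (truncated) exponential priors on Θ and M.

    The ``mean`` parameters are the means of the exponential before
    truncation to ``[lower, upper]``; draws are by inverse CDF on the
    truncated distribution.
    """

    theta_lower: float = 1e-5
    theta_upper: float = 1e-1
    theta_mean: float = 0.01
    m_lower: float = 1e-4
    m_upper: float = 1e6
    m_mean: float = 1e5

    def __post_init__(self) -> None:
        for lo, hi, mu in [
            (self.theta_lower, self.theta_upper, self.theta_mean),
            (self.m_lower, self.m_upper, self.m_mean),
        ]:
            if not (lo < hi and lo < mu < hi):
                raise ConfigurationError(
                    "prior requires lower < mean < upper"
                )


def truncated_exponential_mean(lower: float, upper: float, mean: float) -> float:
    """Analytic mean of an exponential(mean) truncated to [lower, upper]."""
    lam = 1.0 / mean
    num = (lower + mean) * np.exp(-lam * lower) - (upper + mean) * np.exp(-lam * upper)
    den = np.exp(-lam * lower) - np.exp(-lam * upper)
    return float(num / den)


def draw_truncated_exponential(
    lower: float, upper: float, mean: float, rng: np.random.Generator, size=None
):
    """Inverse-CDF draw(s) from the truncated exponential."""
    lam = 1.0 / mean
    flo = 1.0 - np.exp(-lam * lower)
    fhi = 1.0 - np.exp(-lam * upper)
    u = rng.uniform(flo, fhi, size=size)
    return -mean * np.log1p(-u)


def sample_priors(
    ps: PriorSpec, seed: int | np.random.Generator
) -> tuple[float, float]:
    """One (Θ, M) draw from the windowed exponential priors."""
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed, "priors")
    theta = float(draw_truncated_exponential(ps.theta_lower, ps.theta_upper,
                                             ps.theta_mean, rng))
    m = float(draw_truncated_exponential(ps.m_lower, ps.m_upper, ps.m_mean, rng))
    return theta, m


def _line_neighbors(demes: list[str]) -> frozenset:
    return frozenset(frozenset(p) for p in zip(demes[:-1], demes[1:]))


def build_model(
    label: str,
    demes: list[str],
    neighbor_pairs=None,
    theta=0.01,
    m=0.0,
) -> MetapopModel:
    """Construct and validate a metapopulation model.

    ``theta`` may be a scalar (replicated across demes) or a per-deme
    vector; ``m`` a scalar rate applied to every permitted deme pair or
    a full matrix.  Island models require equal Θ and equal migration;
    stepping-stone models require a connected neighbor graph with
    positive rates on exactly the neighboring pairs.
    """
    if label not in MODEL_LABELS:
        raise ModelInvariantError(f"unknown model label {label!r}")
    demes = list(demes)
    d = len(demes)
    theta_vec = np.broadcast_to(np.asarray(theta, dtype=float), (d,)).copy()
    if np.any(theta_vec <= 0):
        raise ModelInvariantError("theta must be positive")

    if label == PANMIXIA:
        if d != 1:
            raise ModelInvariantError("panmixia requires exactly one deme")
        m_arr = np.asarray(m, dtype=float)
        if np.any(m_arr != 0):
            raise ModelInvariantError("panmixia admits no migration rates")
        return MetapopModel(label, demes, theta_vec, np.zeros((1, 1)))

    M = np.zeros((d, d))
    m_in = np.asarray(m, dtype=float)
    if m_in.ndim == 2:
        M = m_in.copy()
        np.fill_diagonal(M, 0.0)
    else:
        rate = float(m_in)
        if label == ISLAND:
            M[:] = rate
            np.fill_diagonal(M, 0.0)
        else:
            if neighbor_pairs is None:
                neighbor_pairs = _line_neighbors(demes)
            for pair in neighbor_pairs:
                a, b = tuple(pair)
                ia, ib = demes.index(a), demes.index(b)
                M[ia, ib] = M[ib, ia] = rate

    if label == ISLAND:
        if d < 2:
            raise ModelInvariantError("island model requires >= 2 demes")
        off = M[~np.eye(d, dtype=bool)]
        if not (np.allclose(off, off[0]) and off[0] > 0):
            raise ModelInvariantError("island model requires equal positive migration")
        if not np.allclose(theta_vec, theta_vec[0]):
            raise ModelInvariantError("island model requires equal deme sizes")
        return MetapopModel(label, demes, theta_vec, M)

    # stepping stone
    if neighbor_pairs is None:
        neighbor_pairs = frozenset(
            frozenset((demes[i], demes[j]))
            for i in range(d)
            for j in range(i + 1, d)
            if M[i, j] > 0 or M[j, i] > 0
        )
    neighbor_pairs = frozenset(frozenset(p) for p in neighbor_pairs)
    for i in range(d):
        for j in range(d):
            if i == j:
                continue
            is_neighbor = frozenset((demes[i], demes[j])) in neighbor_pairs
            if is_neighbor and M[i, j] <= 0:
                raise ModelInvariantError(
                    f"neighbor pair {demes[i]}-{demes[j]} must have M > 0"
                )
            if not is_neighbor and M[i, j] != 0:
                raise ModelInvariantError(
                    f"non-neighbor pair {demes[i]}-{demes[j]} must have M = 0"
                )
    # connectivity of the neighbor graph
    adj = {name: set() for name in demes}
    for pair in neighbor_pairs:
        a, b = tuple(pair)
        adj[a].add(b)
        adj[b].add(a)
    seen = {demes[0]}
    stack = [demes[0]]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    if len(seen) != d:
        raise NonCoalescingError("stepping-stone neighbor graph is disconnected")
    return MetapopModel(label, demes, theta_vec, M, neighbor_pairs)


def _demography(model: MetapopModel) -> msprime.Demography:
    # Pair-coalescence rate in deme i must be 2/Theta_i; with ploidy 1 and
    # one time unit per generation, msprime gives rate 1/size, so
    # size = Theta/2.  Backwards migration rates transfer directly.
    dem = msprime.Demography()
    for i, name in enumerate(model.demes):
        dem.add_population(name=name, initial_size=model.theta[i] / 2.0)
    for i in range(model.n_demes):
        for j in range(model.n_demes):
            if i != j and model.M[i, j] > 0:
                dem.set_migration_rate(
                    source=model.demes[i], dest=model.demes[j],
                    rate=float(model.M[i, j]),
                )
    return dem


def _check_coalescible(model: MetapopModel, sample_sizes: dict[str, int]) -> None:
    occupied = [d for d in model.demes if sample_sizes.get(d, 0) > 0]
    if len(occupied) <= 1:
        return
    # undirected reachability over positive migration rates
    adj = {d: set() for d in model.demes}
    for i in range(model.n_demes):
        for j in range(model.n_demes):
            if i != j and (model.M[i, j] > 0 or model.M[j, i] > 0):
                adj[model.demes[i]].add(model.demes[j])
                adj[model.demes[j]].add(model.demes[i])
    seen = {occupied[0]}
    stack = [occupied[0]]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    if not set(occupied) <= seen:
        raise NonCoalescingError(
            "sampled demes are mutually unreachable (zero migration)"
        )


def simulate_genealogy(
    model: MetapopModel,
    sample_sizes: dict[str, int] | int,
    seed: int,
    record_migrations: bool = True,
) -> Genealogy:
    """Simulate one structured-coalescent genealogy.

    ``sample_sizes`` maps deme name to tip count (an integer is accepted
    for single-deme models).  Event dynamics: with ``k_i`` lineages in
    deme ``i``, coalescence occurs at rate ``k_i (k_i - 1) / Θ_i`` and
    each lineage jumps (backwards) from ``i`` to ``j`` at rate
    ``M[i, j]``; times are in mutational units.  Raises
    :class:`NonCoalescingError` when sampled demes cannot exchange
    lineages.
    """
    if isinstance(sample_sizes, int):
        sample_sizes = {model.demes[0]: sample_sizes}
    total = sum(sample_sizes.values())
    if total < 2:
        raise ConfigurationError("need at least 2 sampled lineages")
    _check_coalescible(model, sample_sizes)
    dem = _demography(model)
    ts = msprime.sim_ancestry(
        samples={d: n for d, n in sample_sizes.items() if n > 0},
        demography=dem,
        ploidy=1,
        sequence_length=1,
        discrete_genome=False,
        record_migrations=record_migrations,
        random_seed=child_int_seed(seed, "genealogy"),
    )
    pops = {p.id: p.metadata.get("name", str(p.id)) for p in ts.populations()}
    node_pops = ts.tables.nodes.population
    tip_demes = [pops[node_pops[u]] for u in ts.samples()]
    mig = ts.tables.migrations
    migrations = [
        (int(n), float(t), pops[s], pops[d])
        for n, t, s, d in zip(mig.node, mig.time, mig.source, mig.dest)
    ]
    return Genealogy(ts=ts, demes=list(model.demes), tip_demes=tip_demes,
                     migrations=migrations)


def expected_coalescence_times(model: MetapopModel, lineage_config: dict[str, int],
                               max_lineages: int = 4) -> float:
    """Expected time to the MRCA of a small lineage configuration.

    Solves the first-step-analysis linear system over lineage-location
    states exactly.  ``lineage_config`` maps deme name to the number of
    sampled lineages there (total ≤ ``max_lineages``).  Returns ``inf``
    when coalescence is unreachable (disconnected demes with zero
    migration).  With two lineages this is the expected pairwise
    coalescence time, e.g. Θ/2 within a single deme.
    """
    total = sum(lineage_config.values())
    if total < 2:
        raise ConfigurationError("need at least 2 lineages")
    if total > max_lineages:
        raise ConfigurationError(
            f"state space capped at {max_lineages} lineages, got {total}"
        )
    try:
        _check_coalescible(model, lineage_config)
    except NonCoalescingError:
        return float("inf")

    d = model.n_demes
    start = tuple(
        sorted(
            itertools.chain.from_iterable(
                [model.deme_index(name)] * k for name, k in lineage_config.items()
            )
        )
    )

    # enumerate reachable states (multisets of deme locations, >= 2 lineages)
    states: dict[tuple, int] = {}

    def transitions(state):
        out = []  # (next_state_or_None, rate); None = absorbed (1 lineage left)
        counts = np.bincount(state, minlength=d)
        for i in range(d):
            k = counts[i]
            if k >= 2:
                rate = k * (k - 1) / model.theta[i]
                nxt = list(state)
                nxt.remove(i)
                nxt = tuple(sorted(nxt))
                out.append((nxt if len(nxt) >= 2 else None, rate))
        for pos, i in enumerate(state):
            for j in range(d):
                if j != i and model.M[i, j] > 0:
                    nxt = list(state)
                    nxt[pos] = j
                    out.append((tuple(sorted(nxt)), model.M[i, j]))
        return out

    frontier = [start]
    states[start] = 0
    while frontier:
        s = frontier.pop()
        for nxt, _ in transitions(s):
            if nxt is not None and nxt not in states:
                states[nxt] = len(states)
                frontier.append(nxt)

    m = len(states)
    A = np.zeros((m, m))
    b = np.ones(m)
    for s, row in states.items():
        trans = transitions(s)
        total_rate = sum(r for _, r in trans)
        if total_rate == 0:
            return float("inf")
        A[row, row] = total_rate
        for nxt, r in trans:
            if nxt is not None:
                A[row, states[nxt]] -= r
    # E[T](s) * total_rate = 1 + sum rate * E[T](next)
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return float("inf")
    return float(sol[states[start]])


def _rescale_ts(ts: tskit.TreeSequence, L: int) -> tskit.TreeSequence:
    """Stretch a length-1, no-recombination tree sequence to L sites."""
    tables = ts.dump_tables()
    tables.sequence_length = float(L)
    edges = tables.edges
    # without recombination every edge spans the whole unit genome
    tables.edges.set_columns(
        left=edges.left * L,
        right=edges.right * L,
        parent=edges.parent,
        child=edges.child,
    )
    tables.sites.clear()
    tables.mutations.clear()
    tables.migrations.clear()
    return tables.tree_sequence()


def evolve_sequences(
    g: Genealogy, L: int, mm: MutationModel, seed: int
) -> SequenceAlignment:
    """Evolve sequences along a genealogy under HKY+G.

    The root sequence is drawn from the equilibrium base frequencies;
    each site gets a discrete-gamma rate multiplier (overall mean 1) and
    substitutions follow the HKY rate matrix along branches.  Tips are
    emitted in deme order as ``<deme>_<index>``.
    """
    if L <= 0:
        raise ConfigurationError("L must be positive")
    rng = child_rng(seed, "evolve")
    site_rates = mm.draw_site_rates(L, rng)
    rate_map = msprime.RateMap(
        position=np.arange(L + 1, dtype=float), rate=site_rates
    )
    ts = _rescale_ts(g.ts, L)
    mts = msprime.sim_mutations(
        ts,
        rate=rate_map,
        model=msprime.HKY(
            kappa=mm.kappa, equilibrium_frequencies=list(mm.base_freqs)
        ),
        random_seed=child_int_seed(seed, "mutations"),
    )
    base_idx = rng.choice(4, size=L, p=np.asarray(mm.base_freqs))
    ascii_bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    root = ascii_bases[base_idx].copy()
    n = g.n_tips
    seqs = np.tile(root, (n, 1))
    for var in mts.variants():
        pos = int(var.site.position)
        alleles = np.frombuffer(
            "".join(a[0] for a in var.alleles).encode(), dtype=np.uint8
        )
        seqs[:, pos] = alleles[var.genotypes]
    counters: dict[str, int] = {}
    ids = []
    for deme in g.tip_demes:
        counters[deme] = counters.get(deme, 0) + 1
        ids.append(f"{deme}_{counters[deme]}")
    aln = SequenceAlignment(
        ids=ids,
        sequences=[row.tobytes().decode("ascii") for row in seqs],
        locus_name="sim",
    )
    # pre-populate the integer encoding from the ASCII matrix
    lut = np.full(128, -1, dtype=np.int8)
    for code, byte in enumerate(b"ACGT"):
        lut[byte] = code
    aln._encoded = lut[seqs]
    return aln


def simulate_dataset(
    model: MetapopModel,
    sample_sizes: dict[str, int] | int,
    L: int,
    mm: MutationModel,
    seed: int,
    record_migrations: bool = False,
) -> tuple[SequenceAlignment, PopulationMap]:
    """Genealogy + sequences + deme labels; deterministic under a seed."""
    g = simulate_genealogy(model, sample_sizes, seed=child_int_seed(seed, "tree"),
                           record_migrations=record_migrations)
    aln = evolve_sequences(g, L, mm, seed=child_int_seed(seed, "seq"))
    pm = PopulationMap(assignment=dict(zip(aln.ids, g.tip_demes)))
    return aln, pm


def simulate_infinite_sites_population(
    n: int, theta: float, seed: int
) -> tuple[int, float, np.ndarray]:
    """One neutral single-deme dataset under infinite-sites mutation.

    ``theta`` is the per-locus mutation-scaled size (expected pairwise
    differences per locus).  Returns ``(k, theta_pi, d)``: the number of
    distinct haplotypes, the mean pairwise difference count, and the
    full pairwise-difference matrix.  Used by the Fu's Fs simulation
    null, where infinite sites keeps the θ̂ estimator exact.
    """
    if n < 2 or theta <= 0:
        raise ConfigurationError("need n >= 2 and theta > 0")
    ts = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        population_size=theta / 2.0,
        sequence_length=1,
        discrete_genome=False,
        random_seed=child_int_seed(seed, "fs_tree"),
    )
    mts = msprime.sim_mutations(
        ts, rate=1.0, discrete_genome=False,
        random_seed=child_int_seed(seed, "fs_mut"),
    )
    if mts.num_sites == 0:
        return 1, 0.0, np.zeros((n, n))
    G = mts.genotype_matrix()  # (sites, n)
    k = len({tuple(col) for col in G.T})
    diff = (G[:, :, None] != G[:, None, :]).sum(axis=0)
    iu = np.triu_indices(n, 1)
    theta_pi = float(diff[iu].mean())
    return k, theta_pi, diff
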