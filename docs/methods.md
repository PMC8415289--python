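# Methods

`stepstone` evaluates the role of a focal reef (a single marine
protected area) in regional connectivity for a panel of species, using
single-locus mtDNA samples and a coarse dispersal geography.  Four
stages mirror how such surveys are analyzed in practice: per-population
diversity statistics, metapopulation model choice, a reef-graph
centrality analysis, and a cross-species regression of model outcome on
pelagic larval duration (PLD).  This note records the models, the
parameters that matter, and the numerical and design choices behind
them.

## Diversity and differentiation statistics

For each population we report the unbiased haplotype diversity
`h = n/(n−1)·(1 − Σ p_i²)`, per-site nucleotide diversity `π` (mean
pairwise difference over jointly scored sites), the haplotype count
`k`, and the private-haplotype count and percentage (haplotypes seen in
the focal population and nowhere else in the sampled set).

**Missing data.** `N` and `-` are treated as missing throughout.  Two
sequences share a haplotype when they agree at every jointly scored
site; an ambiguous sequence compatible with several established
haplotypes joins the first-encountered one, which makes the collapse
deterministic in input order.  Pairwise differences use pairwise
deletion, and are raw mismatch counts with no substitution-model
correction — matching the default behavior of the standard R toolchain
for such data.  IUPAC ambiguity codes other than `N` become `N` with a
warning.

**Fu's Fs.** With `k` observed haplotypes in `n` sequences and
`θ̂` the mean pairwise difference count per locus, the Ewens sampling
formula gives `S′ = P(K ≥ k | θ̂, n)` and `Fs = ln(S′/(1−S′))`.
Unsigned Stirling numbers of the first kind are evaluated by their
recurrence entirely in log space, and both `ln S′` and `ln(1−S′)` are
log-sum-exp tail sums, so Fs survives `S′` near 0 or 1 (|Fs| up to
hundreds is representable).  Fs is undefined (NaN sentinel, never an
exception) when `k = 1` or `θ̂ = 0`.  Significance comes from
simulating neutral single-deme coalescent datasets at `θ = θ̂` under
infinite-sites mutation and recomputing Fs; the reported p-value is the
lower-tail add-one estimator `(1 + #{Fs_sim ≤ Fs_obs})/(nsim + 1)`
(default 1000 simulations) against the conventional α = 0.02.
Monomorphic null replicates have `S′ = 1`, i.e. Fs on the +∞ side of
the logit, and never count as extreme.  The infinite-sites choice keeps
the simulated θ̂ estimator exact; the finite-sites HKY machinery is
available but unnecessary for this null.

**ΦST.** A two-level AMOVA on the pairwise difference counts (used
directly as squared distances): from `SS_total` and within-population
`SS`, the variance components give `ΦST = σ²_a/(σ²_a + σ²_w)`.
Negative estimates are kept as computed; zeroing happens only in the
display/export copy, matching the visualization convention.  When the
total variance is zero the statistic is flagged undefined.
Significance uses label permutations with sizes held fixed and the
add-one upper-tail estimator (default 1000 permutations).  The add-one
rule differs from raw-proportion reporting by at most `1/(nperm+1)` and
cannot produce p = 0.

**Focal-vs-region comparison.** A two-sided one-sample t-test treats
the regional populations' statistic values as the sample and the focal
population's value as the null mean (degenerate when the regional
values have zero variance).

## Synthetic sequence data: structured coalescent + HKY+G

The generator defines the study conditions for every simulation-based
test.  Three metapopulation topologies are supported: a single
panmictic deme; an n-island model (equal deme sizes Θ, one equal
migration rate between every ordered pair); and a stepping-stone model
(migration only between neighboring demes; the neighbor graph must be
connected).

**Scaling.** Time is measured in expected mutations per site, the
convention of coalescent samplers for single-locus data: Θ = N_e·μ per
deme (the mtDNA inheritance scalar is absorbed into Θ and carried as
metadata), and M = m/μ is the backwards immigration rate of a lineage.
A pair of lineages in deme i coalesces at rate 2/Θ_i, and a lineage in
i jumps to j (backwards in time) at rate M[i,j]; expected pairwise
divergence under panmixia is Θ per site.  Genealogy generation uses
msprime configured to realize exactly these rates (deme size Θ/2,
ploidy 1, per-generation migration M); the mapping is validated against
an independent first-step-analysis oracle (below).  Demes that cannot
exchange lineages raise a non-coalescing error up front rather than
hanging.

**Sequence evolution.** HKY with transition/transversion ratio κ and
arbitrary base frequencies, with discrete-gamma rate heterogeneity:
four equal-probability categories whose rates are the conditional means
of a unit-mean gamma between consecutive quantiles (computed with the
incomplete-gamma identity), normalized to mean one; each site draws a
category independently.  The root sequence is drawn from the
equilibrium frequencies.  Defaults (κ = 2, equal frequencies,
α = 0.5) stand in for the per-species model fits a real analysis would
estimate; all are configurable.

**Analytic oracle.** `expected_coalescence_times` solves the
first-step-analysis linear system over lineage-location states exactly
for configurations of up to four lineages, returning the expected time
to the MRCA (infinite when coalescence is unreachable).  Closed-form
anchors used in tests: Θ/2 for a pair in one deme; for two demes with
equal Θ and symmetric M, `E[T|together] = Θ` and
`E[T|apart] = Θ + 1/(2M)`.

**Priors.** Windowed exponential priors follow the published analysis:
Θ on [1e−5, 1e−1] with pre-truncation mean 0.01; M on [1e−4, 1e6] with
mean 1e5.  The rate is fixed at 1/mean *before* truncation (the
parameterization is not stated in the source analysis; it is exposed in
`PriorSpec`).  Draws are inverse-CDF on the truncated distribution; the
analytic truncated mean is provided for calibration tests.  One shared
Θ and one M are drawn per simulated dataset (the island topology
requires equal values; stepping-stone is kept symmetric for
comparability).

## Metapopulation model choice

The published analysis ranked the three models by path-sampling
marginal likelihoods from an MCMC genealogy sampler.  That sampler is
out of scope here; the decision engine is rejection ABC over the same
model space and priors:

1. simulate `nsim_per_model` datasets per model at prior draws, with
   the observed per-population sample sizes and locus length;
2. reduce each dataset to a fixed-order summary vector — per-population
   `h`, `π`, `k`; all pairwise ΦST (undefined cells imputed 0 and
   flagged); global `k`;
3. standardize every statistic by its median absolute deviation across
   the pooled reference table (MAD 0 → scale 1);
4. accept the `accept_fraction` of simulations closest to the observed
   vector in Euclidean distance, at one common threshold.

The per-model share of the accepted set is its relative probability;
`ln(per-model acceptance rate)` serves as the marginal-likelihood
proxy.  A model with zero acceptances receives the probability floor
`1/(total accepted + number of models)` with a flag, keeping Bayes
factors finite.  Downstream arithmetic is exactly the likelihood-based
pipeline's: softmax probabilities, `2 ln BF = 2(lnML_1 − lnML_2)`,
odds `exp(lnML_1 − lnML_2)`, and the Kass–Raftery labels (>6 strong,
equivalently odds beyond ~20:1; >3 substantial).

**High-migration pooling.** The prior mean M = 1e5 puts most draws deep
in the strong-migration regime, where a structured model is
statistically indistinguishable from a single panmictic deme of pooled
size k·Θ but costs orders of magnitude more migration events to
simulate.  When M·Θ exceeds a mixing threshold (200 migrations per
pairwise coalescence, scaled by (k−1)² for stepping-stone chains, whose
end-to-end mixing is slower), the pooled limit is simulated directly;
expected ΦST at the boundary is below ~1%, far inside the acceptance
noise.  Under panmixia (and pooled limits) the observed population
labels are assigned to simulated individuals in emission order, a valid
label draw under exchangeability.

**Replicates and support.** As in the source design, the pipeline
repeats the estimate three times; replicate means feed the Bayes-factor
arithmetic, and an exhaustive permutation t-test over all C(6,3) = 20
relabelings of the replicate lnML values gives a one-tailed p for
"first-ranked mean exceeds second-ranked mean", observed labeling
included — so the attainable floor with 3 vs 3 replicates is 0.05.

**Budgets.** `nsim_per_model` and `accept_fraction` are config.  The
pipeline default is 1000 / 0.01.  The acceptance-style recovery
experiments run 150 per model with 30 accepted, the largest budget that
keeps 25 repeated recoveries plus the panmictic control near ten
minutes on one CPU; at that budget the strongly structured
stepping-stone truth (Θ = 0.01, M = 10, five demes in a line, 20
samples per deme, 500 bp) is recovered in ≥80% of repetitions, and
panmictic truth never yields strong stepping-stone support.  Because
the priors put roughly 1e−3 mass on migration rates as low as the
strongly structured truth, small acceptance sets behave noisily below
~100 simulations per model; larger budgets sharpen the probabilities
but do not change the ranking behavior.

## Reef graph

Rasters are square-cell grids (row 0 at top) holding a habitat mask and
a traversal-cost multiplier per cell: sea 1 (so distances are km over
water), land 10,000 — a heavy penalty rather than a hard barrier, so
paths may cross land at enormous cost.  Patches are 8-connected
habitat components of at least 25 ha (`cells × resolution² × 100`);
ids are assigned in row-major order of each component's first cell.
The linkset holds exact least-cost distances between all patch pairs:
multi-source Dijkstra over the 8-neighbor cell graph, a step costing
its length (resolution, √2·resolution diagonally) times the mean of
the two cells' costs, minimized edge-to-edge over patch cells (large
atolls make centroids misleading).  The candidate linkset is complete,
thresholded per species at `D_max = PLD × current speed` (default
18.7 km/day) to give the binary undirected dispersal graph.
Betweenness is unweighted shortest-path betweenness with equal
splitting among ties, endpoints excluded, normalized by
`(n−1)(n−2)/2`; focal rank is 1-based with ties sharing the best rank.
Diameter is the largest shortest-path step count; disconnected graphs
report the per-component maximum with a flag.

The synthetic seascape generator places square reef blobs and
rectangular land barriers on the grid with known centers, recording
straight-line distances as ground truth; grid distances on open water
are bounded between Euclidean and the octile (8-neighbor) metric, about
8% above Euclidean in the worst direction.  Raster I/O uses ESRI ASCII
grids; inputs are assumed already projected to a metric CRS.

## PLD logistic regression

Species whose data select the stepping-stone model are coded 1,
effective panmixia 0 (the island model was never selected in the study
this mirrors; a multinomial extension is out of scope).  The full
design is `stepping_stone ~ PLD + closest_km + furthest_km` with
great-circle distances (haversine, R = 6371 km).  Fitting is
maximum-likelihood IRLS (via statsmodels GLM; tolerance 1e−10, ≤100
iterations) with Wald standard errors; the PLD effect is reported as
the per-day percentage change in odds, `100·(1 − exp(β))`, with the
1.96·SE interval transformed the same way.  Backward BIC
(`BIC = −2 lnL + p·ln n`) drops the term whose removal most lowers BIC
until no removal helps.  Complete separation — easy at n = 9 — is
detected from divergent coefficients or exploded standard errors and
flagged; separated fits are inadmissible during backward elimination
(effective BIC = ∞), since their likelihood is degenerate.  No
penalization is added at n = 9, matching the analysis being mirrored;
the separation flag protects the general-purpose API.

The packaged nine-species table (PLDs, loci, selected models, printed
2 ln BF values) is input data for the worked example, not an output of
the package.

## Reproducibility

A single master seed fans out to named child streams (`fs_null`,
`phi_perm`, `abc_priors`, per-species and per-replicate streams), so
each stage is independently reproducible and identical configs give
byte-identical reports.  Integer seeds handed to msprime are derived
from the same streams and kept below 2³¹.

## What the synthetic data do and do not show

The generators emulate: neutral single-locus mtDNA variation under the
three migration topologies with realistic Θ (0.01) and locus lengths
(300–1000 bp); seascapes with patchy habitat and land barriers at km
resolution.  They do not emulate selection, demographic change
(growth/bottlenecks — precisely what makes empirical Fs strongly
negative), sequencing error, recombination (none expected for mtDNA),
real coastline geometry, or biophysical larval transport.  Passing
tests therefore demonstrate correctness of the statistics and the
internal consistency of the model-choice machinery under neutral
equilibrium conditions, not the field accuracy of any biological
conclusion.

## Known limitations

- The ABC lnML proxy is an acceptance rate, not a marginal likelihood;
  only its downstream arithmetic (probabilities, 2 ln BF, odds, labels)
  is comparable with likelihood-based samplers.
- At desk-scale simulation budgets the accepted set is small (~30), so
  relative probabilities carry multinomial noise of order ±0.1.
- The expected-coalescence-time oracle enumerates lineage-location
  states and is capped at four lineages.
- Least-cost distances depend on the 8-neighbor metric (≤8% octile
  inflation over Euclidean on open water).
- `pairwise_phi_st_matrix` and the diversity report treat populations
  with fewer than two samples as flagged cells, not errors.
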