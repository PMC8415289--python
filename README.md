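# stepstone

Tools for asking whether a single marine protected area acts as a
stepping-stone for regional connectivity.  Given single-locus mtDNA
samples from a focal reef and surrounding populations for a panel of
species, plus a coarse map of reef habitat, the package answers four
linked questions:

1. **How diverse is the focal population?**  Haplotype diversity
   *h* = n/(n−1)·(1 − Σ p²), per-site nucleotide diversity π, private
   haplotypes, and Fu's *Fs* — the Ewens-sampling statistic
   *Fs* = ln(S′/(1−S′)) with S′ = P(K ≥ k | θ̂, n) — with a
   coalescent-simulation null, plus pairwise Φ<sub>ST</sub> (AMOVA on
   sequence differences) with permutation tests.
2. **What metapopulation structure do the data support?**  Selection
   among panmixia, an n-island model, and a stepping-stone model by
   simulation-based inference (rejection ABC) over windowed-exponential
   priors on Θ = N<sub>e</sub>μ and M = m/μ, reported as relative
   probabilities, 2 ln Bayes factors, odds, Kass–Raftery evidence
   labels, and a replicate permutation *t*-test.
3. **How central is the focal reef?**  Habitat patches (≥25 ha) from a
   raster, least-cost overwater distances over a land-penalty cost
   grid, a binary dispersal graph thresholded at
   D<sub>max</sub> = PLD × 18.7 km/day, and the focal patch's
   betweenness-centrality rank and the graph diameter.
4. **Does larval duration predict structure?**  Logistic regression of
   the selected model (stepping-stone = 1) on maximum pelagic larval
   duration and sampling distances, with backward BIC selection and the
   PLD effect reported as the per-day percentage change in odds,
   100·(1 − e<sup>β</sup>).

Field samples and digitized reef maps are replaced by first-class
synthetic generators: a structured-coalescent simulator with HKY+Γ
sequence evolution over the three migration topologies, and a seascape
generator with known patch geometry.  See `docs/methods.md` for the
models, assumptions, and numerical choices.

## Worked example

The packaged nine-species table (maximum PLDs, loci, selected models,
and printed 2 ln Bayes factors) drives the cross-species arithmetic:

```python
>>> from stepstone import datasets
>>> from stepstone.model_selection import bayes_factor_table, kass_raftery_label
>>> from stepstone.pipeline import run_regress
>>> import numpy as np

>>> # 2 ln BF -> odds of the best model over the second best
>>> for sp, bf in [("Pearlscale angelfish", 4.90), ("Striated surgeonfish", 37.99)]:
...     print(sp, round(np.exp(bf / 2), 1), kass_raftery_label(bf))
Pearlscale angelfish 11.6 substantial
Striated surgeonfish 177592116.8 strong

>>> res = run_regress()
>>> print(res["selected_terms"])
['const', 'pld']
>>> print(round(res["odds_change_percent_per_day"], 1))
9.3
```

So a day of extra larval duration multiplies the odds of stepping-stone
structure by e<sup>β</sup> ≈ 0.907 — a 9.3% decrease per day — and the
sampling-distance covariates are pruned by BIC: larval duration alone
carries the signal.  Group summaries of the same table
(`datasets.pld_group_summary()`) show the panmictic species averaging
78 days of larval duration against 37 days (sd 15) for the
stepping-stone species.

A full synthetic analysis is driven by a YAML config through the CLI:

```sh
stepstone simulate  --config config.yaml --out-dir out   # FASTA + pop maps
stepstone stats     --config config.yaml --out-dir out   # diversity + PhiST tables
stepstone modelselect --config config.yaml --out-dir out # model choice table
stepstone graph     --config config.yaml --out-dir out   # centrality + diameter
stepstone regress   --out-dir out                        # PLD regression
```

Each command writes TSV tables and a `manifest.json` recording every
setting and derived seed; identical config + seed gives byte-identical
outputs.

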