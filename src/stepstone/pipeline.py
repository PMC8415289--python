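"""Config-driven orchestration of the full multi-species analysis.

A single YAML (or dict) run configuration lists the species — each with
either file inputs (aligned FASTA + population-map TSV) or a synthetic
simulation spec — alongside statistical settings and an optional
seascape block.  The stage runners (:func:`run_stats`,
:func:`run_model_selection`, :func:`run_graph`, :func:`run_regress`)
each produce a tidy table; per-species failures are quarantined and
logged so one malformed dataset does not abort a multi-species run.
All randomness fans out from the single master seed via named streams.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from stepstone import datasets
from stepstone._rng import child_int_seed
from stepstone.alignment_io import (
    PopulationMap,
    collapse_haplotypes,
    read_alignment,
    spectrum_report,
)
from stepstone.coalescent_sim import (
    MetapopModel,
    MutationModel,
    PriorSpec,
    build_model,
    simulate_dataset,
)
from stepstone.errors import ConfigurationError, is_undefined
from stepstone.model_selection import (
    abc_model_choice,
    bayes_factor_table,
    kass_raftery_label,
    replicate_support_test,
    summarize,
)
from stepstone.pld_regression import backward_bic, fit_logistic
from stepstone.popgen_stats import (
    diversity_stats,
    pairwise_phi_st_matrix,
    region_comparison_ttest,
)
from stepstone.reef_graph import (
    betweenness,
    build_species_graph,
    diameter,
    extract_patches,
    generate_synthetic_seascape,
    least_cost_linkset,
    rank_focal_patch,
)

log = logging.getLogger("stepstone")


@dataclass
class Settings:
    nperm: int = 1000
    nsim_fs: int = 1000
    abc_nsim_per_model: int = 1000
    abc_accept_fraction: float = 0.01
    n_replicates: int = 3
    min_area_ha: float = 25.0
    current_speed: float = 18.7
    land_cost: float = 10_000.0


@dataclass
class SpeciesConfig:
    name: str
    pld_days: float = 30.0
    focal_population: str | None = None
    alignment: str | None = None
    population_map: str | None = None
    synthetic: dict | None = None
    neighbor_pairs: list[tuple[str, str]] | None = None


@dataclass
class RunConfig:
    seed: int = 0
    settings: Settings = field(default_factory=Settings)
    species: list[SpeciesConfig] = field(default_factory=list)
    seascape: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        settings = Settings(**(raw.get("settings") or {}))
        for name in ("nperm", "nsim_fs", "abc_nsim_per_model", "n_replicates"):
            if getattr(settings, name) <= 0:
                raise ConfigurationError(f"setting {name} must be positive")
        species = [SpeciesConfig(**s) for s in raw.get("species", [])]
        for sp in species:
            for path_attr in ("alignment", "population_map"):
                p = getattr(sp, path_attr)
                if p is not None and not Path(p).exists():
                    raise ConfigurationError(f"{sp.name}: missing file {p}")
            if sp.alignment is None and sp.synthetic is None:
                raise ConfigurationError(
                    f"{sp.name}: needs an alignment or a synthetic spec"
                )
        return cls(
            seed=int(raw.get("seed", 0)),
            settings=settings,
            species=species,
            seascape=raw.get("seascape"),
        )


def _load_species_data(sp: SpeciesConfig, master_seed: int):
    """Alignment + population map for a species (file or simulated)."""
    if sp.alignment is not None:
        aln = read_alignment(sp.alignment)
        pm = PopulationMap.read_tsv(sp.population_map)
        return aln, pm
    spec = dict(sp.synthetic)
    label = spec.get("model", "stepping_stone")
    demes = list(spec.get("demes", ["D1", "D2", "D3"]))
    neighbor_pairs = (
        frozenset(frozenset(p) for p in sp.neighbor_pairs)
        if sp.neighbor_pairs
        else None
    )
    model = build_model(
        label,
        demes,
        neighbor_pairs=neighbor_pairs,
        theta=spec.get("theta", 0.01),
        m=spec.get("m", 0.0) if label != "panmixia" else 0.0,
    )
    samples = spec.get("samples_per_deme", 10)
    sizes = (
        {d: samples for d in demes}
        if isinstance(samples, int)
        else dict(samples)
    )
    mm = MutationModel(
        kappa=spec.get("kappa", 2.0), alpha=spec.get("alpha", 0.5)
    )
    aln, pm = simulate_dataset(
        model,
        sizes,
        int(spec.get("length", 400)),
        mm,
        seed=child_int_seed(master_seed, f"data_{sp.name}"),
    )
    strata = spec.get("strata")
    if strata and model.n_demes == 1:
        # panmictic individuals are exchangeable: label sampling sites
        # in emission order (sizes as even as possible)
        n = aln.n
        base, extra = divmod(n, len(strata))
        labels: list[str] = []
        for i, site in enumerate(strata):
            labels += [site] * (base + (1 if i < extra else 0))
        pm = PopulationMap(assignment=dict(zip(aln.ids, labels)))
    return aln, pm


def run_stats(config: RunConfig) -> pd.DataFrame:
    """Diversity report: one row per population per species.

    Columns mirror the standard diversity table — N, haplotype counts,
    private haplotypes and percentage, h and π with regional means,
    Fu's Fs with its simulation p-value for the focal population, and
    two-sided t-tests of the focal population against regional means.
    """
    rows = []
    st = config.settings
    for sp in config.species:
        try:
            aln, pm = _load_species_data(sp, config.seed)
            spectrum = collapse_haplotypes(aln, pm)
            priv = spectrum_report(spectrum).set_index("population")
            focal = sp.focal_population or pm.populations[0]
            per_pop = {}
            for pop in pm.populations:
                nsim = st.nsim_fs if pop == focal else 0
                per_pop[pop] = diversity_stats(
                    aln, pm, pop, nsim_fs=nsim,
                    seed=child_int_seed(config.seed, f"fs_{sp.name}_{pop}"),
                )
            regional = [p for p in pm.populations if p != focal]
            reg_h = [per_pop[p].h for p in regional]
            reg_pi = [per_pop[p].pi for p in regional]
            for pop in pm.populations:
                stats = per_pop[pop]
                row = {
                    "species": sp.name,
                    "population": pop,
                    "is_focal": pop == focal,
                    "n": stats.n,
                    "n_haplotypes": stats.k,
                    "private": int(priv.loc[pop, "private"]),
                    "pct_private": float(priv.loc[pop, "pct_private"]),
                    "h": stats.h,
                    "pi": stats.pi,
                    "Fs": stats.Fs,
                    "Fs_p": stats.Fs_p,
                }
                if pop == focal and len(regional) >= 2:
                    row["regional_mean_h"] = float(np.mean(reg_h))
                    row["regional_mean_pi"] = float(np.mean(reg_pi))
                    row["h_ttest_p"] = region_comparison_ttest(stats.h, reg_h).p_value
                    row["pi_ttest_p"] = region_comparison_ttest(
                        stats.pi, reg_pi
                    ).p_value
                rows.append(row)
        except Exception as exc:  # quarantine per species
            log.error("stats failed for %s: %s", sp.name, exc)
            rows.append({"species": sp.name, "error": str(exc)})
    return pd.DataFrame(rows)


def run_phi_st(config: RunConfig) -> pd.DataFrame:
    """Pairwise ΦST with permutation p-values for every species."""
    rows = []
    for sp in config.species:
        try:
            aln, pm = _load_species_data(sp, config.seed)
            results = pairwise_phi_st_matrix(
                aln, pm, nperm=config.settings.nperm,
                seed=child_int_seed(config.seed, f"phi_{sp.name}"),
            )
            for (a, b), res in results.items():
                phi = res.phi_st
                rows.append(
                    {
                        "species": sp.name,
                        "pop_a": a,
                        "pop_b": b,
                        "phi_st": phi,
                        "phi_st_display": 0.0
                        if (is_undefined(phi) or phi < 0)
                        else phi,
                        "p_value": res.p_value,
                    }
                )
        except Exception as exc:
            log.error("phi_st failed for %s: %s", sp.name, exc)
            rows.append({"species": sp.name, "error": str(exc)})
    return pd.DataFrame(rows)


def _model_templates(pm: PopulationMap, neighbor_pairs) -> list[MetapopModel]:
    pops = pm.populations
    templates = [build_model("panmixia", [pops[0]], theta=0.01)]
    if len(pops) >= 2:
        templates.append(build_model("island", pops, theta=0.01, m=1.0))
        templates.append(
            build_model(
                "stepping_stone",
                pops,
                neighbor_pairs=neighbor_pairs,
                theta=0.01,
                m=1.0,
            )
        )
    return templates


def run_model_selection(
    config: RunConfig, n_replicates: int | None = None
) -> pd.DataFrame:
    """Model-choice report: best/second models, probabilities, support.

    Each species gets ``n_replicates`` independent ABC estimates of the
    per-model marginal-likelihood proxy; replicate means feed the Bayes
    factor arithmetic, and the exhaustive permutation t-test compares
    the replicate values of the two top-ranked models.
    """
    st = config.settings
    n_replicates = n_replicates or st.n_replicates
    priors = PriorSpec()
    rows = []
    for sp in config.species:
        try:
            aln, pm = _load_species_data(sp, config.seed)
            if len(pm.populations) < 2:
                raise ConfigurationError(
                    f"{sp.name}: model selection needs >= 2 sampled "
                    "populations (add sampling strata)"
                )
            observed = summarize(aln, pm)
            sizes = pm.sample_sizes()
            neighbor_pairs = (
                frozenset(frozenset(p) for p in sp.neighbor_pairs)
                if sp.neighbor_pairs
                else None
            )
            templates = _model_templates(pm, neighbor_pairs)
            lnml_reps: dict[str, list[float]] = {t.label: [] for t in templates}
            for rep in range(n_replicates):
                post = abc_model_choice(
                    observed,
                    templates,
                    priors,
                    observed_sizes=sizes,
                    L=aln.length,
                    nsim_per_model=st.abc_nsim_per_model,
                    accept_fraction=st.abc_accept_fraction,
                    seed=child_int_seed(config.seed, f"abc_{sp.name}_{rep}"),
                )
                for lab, v in post.lnml.items():
                    lnml_reps[lab].append(v)
            mean_lnml = {lab: float(np.mean(v)) for lab, v in lnml_reps.items()}
            post = bayes_factor_table(mean_lnml)
            support = replicate_support_test(
                lnml_reps[post.best], lnml_reps[post.second]
            )
            two_ln_bf = post.top_two_ln_bf
            rows.append(
                {
                    "species": sp.name,
                    "model_1": post.best,
                    "prob_1": post.probabilities[post.best],
                    "model_2": post.second,
                    "prob_2": post.probabilities[post.second],
                    "perm_p": support.p_value,
                    "two_ln_bf": two_ln_bf,
                    "odds": post.odds,
                    "evidence": kass_raftery_label(two_ln_bf),
                }
            )
        except Exception as exc:
            log.error("model selection failed for %s: %s", sp.name, exc)
            rows.append({"species": sp.name, "error": str(exc)})
    return pd.DataFrame(rows)


def _build_seascape(config: RunConfig):
    spec = config.seascape or {}
    if "habitat_ascii" in spec:
        from stepstone.reef_graph import ReefRaster

        return ReefRaster.read_ascii(spec["habitat_ascii"], spec["cost_ascii"])
    return generate_synthetic_seascape(
        shape=tuple(spec.get("shape", (60, 120))),
        patch_specs=[tuple(p) for p in spec["patches"]]
        if "patches" in spec
        else None,
        n_patches=spec.get("n_patches", 8),
        land_rects=[tuple(r) for r in spec.get("land_rects", [])],
        resolution_km=spec.get("resolution_km", 1.0),
        land_cost=config.settings.land_cost,
        seed=child_int_seed(config.seed, "seascape"),
    )


def run_graph(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Graph report per species plus the per-patch betweenness table."""
    if config.seascape is None:
        raise ConfigurationError("config has no seascape block")
    rr = _build_seascape(config)
    patches = extract_patches(rr, min_area_ha=config.settings.min_area_ha)
    linkset = least_cost_linkset(patches, rr)
    focal = (config.seascape or {}).get("focal_patch", 0)
    species_rows = []
    bc_rows = []
    for sp in config.species:
        sg = build_species_graph(
            linkset, sp.pld_days, current_speed=config.settings.current_speed
        )
        bc = betweenness(sg)
        diam = diameter(sg)
        species_rows.append(
            {
                "species": sp.name,
                "pld_days": sp.pld_days,
                "d_max_km": sg.d_max_km,
                "n_patches": sg.graph.number_of_nodes(),
                "n_edges": sg.graph.number_of_edges(),
                "diameter": diam.steps,
                "connected": diam.connected,
                "focal_rank": rank_focal_patch(sg, focal),
            }
        )
        for pid, val in bc.items():
            bc_rows.append(
                {"species": sp.name, "patch": pid, "betweenness": val}
            )
    return pd.DataFrame(species_rows), pd.DataFrame(bc_rows)


def run_regress(profiles: pd.DataFrame | None = None) -> dict:
    """PLD logistic regression with backward BIC selection.

    ``profiles`` needs columns ``pld`` and ``stepping_stone`` and
    optionally ``closest_km`` / ``furthest_km``; the packaged
    nine-species table is used when omitted.
    """
    if profiles is None:
        profiles = datasets.regression_inputs()
    terms = [
        t for t in ("pld", "closest_km", "furthest_km") if t in profiles.columns
    ]
    y = profiles["stepping_stone"].to_numpy()
    selected = backward_bic(y, profiles, terms)
    pld_only = fit_logistic(y, profiles, ["pld"])
    return {
        "selected_terms": selected.terms,
        "bic_trace": selected.bic_trace,
        "selected": selected,
        "pld_only": pld_only,
        "odds_change_percent_per_day": pld_only.odds_change_percent("pld"),
        "odds_change_ci95": pld_only.odds_change_ci95("pld"),
    }


def write_manifest(config: RunConfig, out_dir: str | Path, stages: list[str]) -> Path:
    """Record every setting and derived seed used by a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "settings": vars(config.settings),
        "species": [sp.name for sp in config.species],
        "stages": stages,
        "derived_seeds": {
            f"abc_{sp.name}_0": child_int_seed(config.seed, f"abc_{sp.name}_0")
            for sp in config.species
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
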