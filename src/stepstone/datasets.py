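"""Published study inputs for the nine-species South China Sea survey.

Small literature-derived tables used as worked-example inputs: per
species, the maximum pelagic larval duration (days), the mtDNA locus
and its aligned length, the metapopulation model selected by the
original coalescent analysis, and the reported 2 ln Bayes factor of the
best over the second-best model.  These are inputs to the package's
arithmetic (odds conversion, group summaries, the PLD logistic
regression), not outputs of it.
"""

from __future__ import annotations

import pandas as pd

PANMIXIA = "panmixia"
STEPPING_STONE = "stepping_stone"

_SPECIES_ROWS = [
    # species, common name, max PLD (days), locus, bp, selected model, 2lnBF, perm p
    ("Acanthurus japonicus", "Japanese surgeonfish", 62, "CytB", 491,
     PANMIXIA, 9.55, 0.05),
    ("Centropyge vrolikii", "Pearlscale angelfish", 29, "CytB", 575,
     STEPPING_STONE, 4.90, 0.05),
    ("Chaetodon auriga", "Threadfin butterflyfish", 48, "CytB", 668,
     PANMIXIA, 19.29, 0.05),
    ("Chaetodon lunulatus", "Oval butterflyfish", 35, "CytB", 605,
     STEPPING_STONE, 44.83, 0.05),
    ("Ctenochaetus striatus", "Striated surgeonfish", 59, "CR", 316,
     STEPPING_STONE, 37.99, 0.05),
    ("Dascyllus aruanus", "Whitetail dascyllus", 26, "CytB", 1058,
     STEPPING_STONE, 2.96, 0.15),
    ("Lutjanus kasmira", "Bluestripe snapper", 60, "CytB", 446,
     PANMIXIA, 441.07, 0.05),
    ("Nerita plicata", "Whorled nerite", 180, "COI", 613,
     PANMIXIA, 15.92, 0.05),
    ("Pomacentrus coelestis", "Neon damselfish", 39, "CR", 337,
     PANMIXIA, 123.10, 0.05),
]


def species_profiles() -> pd.DataFrame:
    """The nine-species table: PLDs, loci, and selected models."""
    return pd.DataFrame(
        _SPECIES_ROWS,
        columns=[
            "species",
            "common_name",
            "pld_days",
            "locus",
            "locus_bp",
            "selected_model",
            "two_ln_bf",
            "perm_p",
        ],
    )


def regression_inputs() -> pd.DataFrame:
    """Design for the PLD logistic regression.

    Response ``stepping_stone`` is 1 for species whose data selected a
    stepping-stone model, 0 for effective panmixia.
    """
    df = species_profiles()
    df = df[["species", "pld_days"]].copy()
    df["pld"] = df["pld_days"].astype(float)
    df["stepping_stone"] = (
        species_profiles()["selected_model"] == STEPPING_STONE
    ).astype(int)
    return df


def pld_group_summary() -> pd.DataFrame:
    """Mean and sd of maximum PLD by selected metapopulation model."""
    df = species_profiles()
    out = (
        df.groupby("selected_model")["pld_days"]
        .agg(["count", "mean", "std"])
        .rename(columns={"count": "n_species", "mean": "mean_pld", "std": "sd_pld"})
        .reset_index()
    )
    return out
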