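"""Packaged reference tables from the underlying growing-pig calorimetry trial.

The trial fed 36 Duroc x Landrace x Yorkshire barrows (initial BW
28.1 +/- 0.8 kg) one of six diets — a corn–soybean meal basal diet (T1) and
five test diets substituting 27% corn starch (T2), 27% pea starch (T3),
27% tapioca starch (T4), 5% soybean oil (T5) or 11.8% casein (T6) — at a
feeding level of 1.92 MJ ME/kg BW^0.6/d, plus a companion 47-ingredient
deposition dataset.  The published treatment-level tables are transcribed
verbatim here as typed records; they serve as inputs for desk-scale
re-derivations and as reference surfaces for tests.  Per-pig replicates
were not published, so these are means (with pooled SEMs omitted).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .balance import DietFormulation
from .difference import InclusionScheme

__all__ = [
    "diet_nutrient_table",
    "diet_ingredient_table",
    "diet_formulations",
    "digestibility_nitrogen_table",
    "energy_balance_table",
    "nutrient_profile_table",
    "ingredient_table",
    "prediction_equation_table",
    "inclusion_schemes",
    "NESTED_MODEL_ESTIMATES",
    "BASAL_DIET",
    "TEST_NUTRIENTS",
]

#: published estimates of the nested-model parameters (reference only; the
#: per-pig data needed to re-derive them were not published).
NESTED_MODEL_ESTIMATES = {"k_br": 0.96, "ne_pd": 0.35}

BASAL_DIET = "T1"
#: test diet -> tested nutrient
TEST_NUTRIENTS = {
    "T2": "Corn starch",
    "T3": "Pea starch",
    "T4": "Tapioca starch",
    "T5": "Soybean oil",
    "T6": "Casein",
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("nepartition").joinpath("data", name).open() as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=None)
def diet_nutrient_table() -> pd.DataFrame:
    """Analyzed nutrient levels of the six diets (%, as-fed; GE in MJ/kg)."""
    return _read("diet_nutrients.csv")


@lru_cache(maxsize=None)
def diet_ingredient_table() -> pd.DataFrame:
    """Ingredient composition of the six diets (%, as-fed); columns sum to 100."""
    return _read("diet_ingredients.csv")


def diet_formulations() -> dict[str, DietFormulation]:
    """The six diets as typed :class:`~nepartition.balance.DietFormulation`."""
    nut = diet_nutrient_table().set_index("diet")
    ing = diet_ingredient_table().set_index("ingredient")
    out: dict[str, DietFormulation] = {}
    for diet, row in nut.iterrows():
        pct = {name: float(v) for name, v in ing[diet].items() if v > 0}
        out[diet] = DietFormulation(
            id=diet,
            ingredient_pct=pct,
            dm=row["dm"] / 100.0,
            ash=row["ash"],
            ee=row["ee"],
            ndf=row["ndf"],
            adf=row["adf"],
            cp=row["cp"],
            ge=row["ge"],
        )
    return out


@lru_cache(maxsize=None)
def digestibility_nitrogen_table() -> pd.DataFrame:
    """Treatment means: ATTD (%) of nutrients and nitrogen balance (g/d)."""
    return _read("digestibility_nitrogen.csv")


@lru_cache(maxsize=None)
def energy_balance_table() -> pd.DataFrame:
    """Treatment means: energy balance (kJ/kg BW^0.6/d), energy values
    (MJ/kg DM) and utilization ratios (%)."""
    return _read("energy_balance.csv")


@lru_cache(maxsize=None)
def nutrient_profile_table() -> pd.DataFrame:
    """Published nutrient-level energy values and efficiencies.

    Reference only: the dry-matter basis of the pure nutrients and the
    intake normalization behind the published values are unstated, so this
    table cannot be re-derived from the treatment means by differencing.
    """
    return _read("nutrient_profiles.csv")


@lru_cache(maxsize=None)
def ingredient_table() -> pd.DataFrame:
    """47-ingredient nutrient characteristics with measured PD and LD.

    19 energy ingredients, 7 lipids and 21 protein ingredients; the
    ``category`` column encodes that grouping (inferred from row order).
    """
    return _read("ingredients.csv")


@lru_cache(maxsize=None)
def prediction_equation_table() -> pd.DataFrame:
    """Published stepwise prediction-equation ladder with fit metrics.

    One row per equation; absent terms are NaN.  Where the running text and
    the table disagree (PD univariate RMSE 177.36 vs 173.36; intercept
    -23.37.62 vs -23.37) the table values are kept.
    """
    return _read("prediction_equations.csv")


def inclusion_schemes(basis: str = "as_fed") -> dict[str, InclusionScheme]:
    """Substitution proportions per test diet, from the formulation table.

    r0: corn + soybean meal share of the basal diet; r1: corn + soybean meal
    share of the test diet; r2: tested-nutrient inclusion.  The published
    proportions are on the as-fed basis; ``basis="dm"`` rescales all three
    by the diets' analyzed DM contents.
    """
    ing = diet_ingredient_table().set_index("ingredient")
    nut = diet_nutrient_table().set_index("diet")
    basal_frac = (ing.loc["Corn", BASAL_DIET] + ing.loc["Soybean meal", BASAL_DIET]) / 100.0
    out: dict[str, InclusionScheme] = {}
    for diet, nutrient in TEST_NUTRIENTS.items():
        r1 = (ing.loc["Corn", diet] + ing.loc["Soybean meal", diet]) / 100.0
        r2 = ing.loc[nutrient, diet] / 100.0
        r0 = basal_frac
        if basis == "dm":
            # proportions of DM rather than of as-fed mass.  The DM content
            # of the pure nutrients is not published, so it is approximated
            # by the test diet's own DM (leaving r2 unchanged); the basal
            # fraction is rescaled by the basal/test diet DM ratio.
            dm_b = nut.loc[BASAL_DIET, "dm"] / 100.0
            dm_t = nut.loc[diet, "dm"] / 100.0
            r1 = r1 * dm_b / dm_t
        out[diet] = InclusionScheme(r0=r0, r1=r1, r2=r2, basis=basis)
    return out
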