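"""Turn a molar amino-acid ratio into a weighable diet recipe.

A chemically defined (holidic) fly diet supplies each amino acid
individually. Given a molar-fraction profile p and a total amino-acid
concentration T (grams of free-base amino acid per litre of food), the
total molar amount is

    N = T / sum_i p_i * MW_i(free)        [mol/L]

and each amino acid contributes N * p_i moles, i.e. N * p_i * MW_i(free)
grams free-base. Lysine and arginine are commonly weighed as
monohydrochloride salts; the weighed amount then scales by
MW(salt)/MW(free) while the free-base and molar columns are unchanged
(counter-ion mass never counts toward the amino-acid total).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, ESSENTIAL_AAS, AAProfile

__all__ = [
    "MolecularWeightTable",
    "DietRecipe",
    "default_mw_table",
    "formulate",
    "stock_split",
    "DEFAULT_STOCK_PLAN",
]


@dataclass(frozen=True)
class MolecularWeightTable:
    """Free-base molecular weights (g/mol) plus optional salt forms."""

    free_mw: dict[str, float]
    salt_mw: dict[str, float] = field(default_factory=dict)
    salt_name: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for aa, mw in self.free_mw.items():
            if mw <= 0:
                raise ValueError(f"non-positive free MW for {aa}")
        for aa, smw in self.salt_mw.items():
            if aa not in self.free_mw:
                raise ValueError(f"salt MW given for {aa} without a free MW")
            if smw < self.free_mw[aa]:
                raise ValueError(f"salt MW below free MW for {aa}")

    def weighed_mw(self, aa: str, use_salt: bool) -> float:
        if use_salt and aa in self.salt_mw:
            return self.salt_mw[aa]
        return self.free_mw[aa]

    def form(self, aa: str, use_salt: bool) -> str:
        if use_salt and aa in self.salt_mw:
            return self.salt_name.get(aa, f"{aa} (salt)")
        return "free base"


def default_mw_table() -> MolecularWeightTable:
    """The packaged MW table (standard free AAs; Lys/Arg monohydrochlorides)."""
    from importlib.resources import files

    from .io import read_mw_table

    return read_mw_table(files("exomatch.data").joinpath("aa_weights.tsv"))


@dataclass(frozen=True)
class DietRecipe:
    """Weighable recipe for one litre of food.

    ``table`` has one row per amino acid with ``mmol_per_l``,
    ``free_g_per_l``, ``weighed_g_per_l`` and ``form``; the free-base gram
    column sums to ``total_g_per_l`` and the mmol column reproduces the
    input molar ratio exactly.
    """

    table: pd.DataFrame
    label: str
    total_g_per_l: float

    def __post_init__(self):
        total = float(self.table["free_g_per_l"].sum())
        if abs(total - self.total_g_per_l) > 1e-6:
            raise ValueError(
                f"free-base grams sum to {total}, expected {self.total_g_per_l}"
            )

    def grams(self, aa: str, weighed: bool = True) -> float:
        col = "weighed_g_per_l" if weighed else "free_g_per_l"
        return float(self.table.set_index("aa").loc[aa, col])

    def molar_fractions(self) -> np.ndarray:
        mmol = self.table["mmol_per_l"].to_numpy(float)
        return mmol / mmol.sum()


def formulate(
    profile: AAProfile,
    total_g_per_l: float,
    mw: MolecularWeightTable | None = None,
    use_salt_forms: bool = True,
    label: str | None = None,
) -> DietRecipe:
    """Convert a molar-fraction profile into grams per litre of food.

    ``total_g_per_l`` is interpreted on the free-base basis (dilution
    series of the same ratio scale linearly; salt counter-ions do not count
    toward the amino-acid mass). Missing molecular weights raise with the
    offending amino acid named.
    """
    if total_g_per_l <= 0:
        raise ValueError("total_g_per_l must be positive")
    mw = mw if mw is not None else default_mw_table()
    missing = [aa for aa in AMINO_ACIDS if profile[aa] > 0 and aa not in mw.free_mw]
    if missing:
        raise ValueError(f"no molecular weight for amino acid(s) {missing}")
    mean_mw = sum(profile[aa] * mw.free_mw[aa] for aa in AMINO_ACIDS if profile[aa] > 0)
    n_total = total_g_per_l / mean_mw  # mol/L
    rows = []
    for aa in AMINO_ACIDS:
        p = profile[aa]
        mol = n_total * p
        free_g = mol * mw.free_mw.get(aa, float("nan")) if p > 0 else 0.0
        salt_factor = mw.weighed_mw(aa, use_salt_forms) / mw.free_mw[aa] if p > 0 else 1.0
        rows.append(
            {
                "aa": aa,
                "mmol_per_l": 1000.0 * mol,
                "free_g_per_l": free_g,
                "_salt_factor": salt_factor,
                "form": mw.form(aa, use_salt_forms) if p > 0 else "free base",
            }
        )
    table = pd.DataFrame(rows)
    # absorb rounding so the invariant holds exactly; the weighed column is
    # the corrected free column scaled by MW(salt)/MW(free)
    table["free_g_per_l"] *= total_g_per_l / table["free_g_per_l"].sum()
    table["weighed_g_per_l"] = table["free_g_per_l"] * table.pop("_salt_factor")
    table = table[["aa", "mmol_per_l", "free_g_per_l", "weighed_g_per_l", "form"]]
    return DietRecipe(table=table, label=label or profile.label, total_g_per_l=total_g_per_l)


#: How the fly-diet protocol distributes amino acids across stock solutions:
#: poorly soluble Ile/Leu/Tyr go straight into the food before autoclaving,
#: Glu and Cys are dosed from their own solutions, the remaining essentials
#: and non-essentials from the EAA / NEAA stocks.
DEFAULT_STOCK_PLAN: dict[str, str] = {
    **{aa: "direct-to-food" for aa in "ILY"},
    "E": "glu-solution",
    "C": "cys-solution",
    **{aa: "eaa-stock" for aa in sorted(ESSENTIAL_AAS - set("IL"))},
    **{aa: "neaa-stock" for aa in sorted(set(AMINO_ACIDS) - ESSENTIAL_AAS - set("YEC"))},
}


def stock_split(recipe: DietRecipe, stock_plan: Mapping[str, str] | None = None) -> dict[str, pd.DataFrame]:
    """Split a recipe into per-stock gram listings.

    ``stock_plan`` maps each amino acid to a stock name; amino acids with
    zero amount may be omitted from the plan. The per-stock tables
    partition the recipe: summed over stocks they reproduce it exactly.
    """
    plan = dict(stock_plan) if stock_plan is not None else dict(DEFAULT_STOCK_PLAN)
    table = recipe.table
    active = table.loc[table["mmol_per_l"] > 0, "aa"]
    unassigned = [aa for aa in active if aa not in plan]
    if unassigned:
        raise ValueError(f"stock plan does not assign amino acid(s) {unassigned}")
    out: dict[str, pd.DataFrame] = {}
    assigned = table["aa"].map(lambda aa: plan.get(aa))
    for stock in sorted({plan[aa] for aa in active}):
        sub = table[assigned == stock].reset_index(drop=True)
        out[stock] = sub
    return out
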