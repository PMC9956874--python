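"""Diet-versus-demand comparison: coverage, limiting amino acid, gain.

A diet profile (molar fractions supplied by the food) is compared to a
demand profile (molar fractions the consumer is predicted to require, e.g.
a transcriptome-weighted profile). Per-AA coverage is

    coverage_i = 100 * diet_i / demand_i,

the limiting amino acid is the *essential* AA with the lowest coverage, and
the predicted gain is the relative increase in the limiting AA obtained by
rebalancing the diet to the demand ratio at fixed total AA — which, under
the single-limiting-AA model, equals the potential relative increase in
fecundity.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, ESSENTIAL_AAS, AAProfile

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoverageReport:
    """Per-AA coverage of a demand profile by a diet profile.

    ``coverage`` maps every reportable AA to percent coverage; ``inf``
    marks the sentinel case demand = 0 with diet > 0 (flagged, never
    limiting). AAs with demand = 0 and diet = 0 are listed in
    ``excluded``. ``tied_limiting`` lists all essential AAs sharing the
    minimal coverage (alphabetically first is the primary ``limiting_aa``).
    """

    diet_label: str
    demand_label: str
    coverage: dict[str, float]
    limiting_aa: str
    limiting_coverage: float
    tied_limiting: tuple[str, ...]
    excluded: tuple[str, ...] = ()
    unbounded: tuple[str, ...] = ()
    essentials: frozenset[str] = field(default_factory=lambda: ESSENTIAL_AAS)

    @property
    def predicted_gain(self) -> float:
        return predicted_gain(self)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "aa": aa,
                "essential": aa in self.essentials,
                "coverage_pct": self.coverage.get(aa, float("nan")),
                "limiting": aa == self.limiting_aa,
            }
            for aa in AMINO_ACIDS
        ]
        return pd.DataFrame(rows)


def coverage(
    diet: AAProfile,
    demand: AAProfile,
    essentials: frozenset[str] | None = None,
) -> CoverageReport:
    """Compute per-AA coverage and identify the limiting essential AA.

    Non-essential AAs are reported but never selected as limiting.
    ``essentials`` overrides the default fly set for cross-species use.
    Zero-demand AAs: with diet > 0 coverage is reported as ``inf`` and
    flagged; with diet = 0 the AA is excluded with a warning.
    """
    ess = frozenset(essentials) if essentials is not None else ESSENTIAL_AAS
    unknown = ess - set(AMINO_ACIDS)
    if unknown:
        raise ValueError(f"essentials outside the alphabet: {sorted(unknown)}")
    cov: dict[str, float] = {}
    excluded: list[str] = []
    unbounded: list[str] = []
    for aa in AMINO_ACIDS:
        d, q = diet[aa], demand[aa]
        if q > 0:
            cov[aa] = 100.0 * d / q
        elif d > 0:
            cov[aa] = math.inf
            unbounded.append(aa)
        else:
            excluded.append(aa)
            log.warning("amino acid %s absent from both diet and demand; excluded from coverage", aa)
    candidates = {aa: c for aa, c in cov.items() if aa in ess and math.isfinite(c)}
    if not candidates:
        raise ValueError("no essential amino acid with finite coverage; cannot identify a limiting AA")
    lim_cov = min(candidates.values())
    tied = tuple(sorted(aa for aa, c in candidates.items() if c == lim_cov))
    return CoverageReport(
        diet_label=diet.label,
        demand_label=demand.label,
        coverage=cov,
        limiting_aa=tied[0],
        limiting_coverage=lim_cov,
        tied_limiting=tied,
        excluded=tuple(excluded),
        unbounded=tuple(unbounded),
        essentials=ess,
    )


def predicted_gain(report: CoverageReport) -> float:
    """Relative increase (%) in the limiting AA from rebalancing to the demand ratio.

    gain = 100 * (100 / limiting_coverage - 1). A limiting coverage of 0
    (the essential AA is completely absent from the diet) gives an
    unbounded gain, returned as ``inf``.
    """
    if report.limiting_coverage == 0:
        log.warning(
            "limiting AA %s completely absent from diet %r; gain unbounded",
            report.limiting_aa,
            report.diet_label,
        )
        return math.inf
    return 100.0 * (100.0 / report.limiting_coverage - 1.0)


@dataclass(frozen=True)
class TissuePanel:
    """Limiting-AA summary of several diets against several tissue demands.

    ``summary`` has one row per (tissue, diet) with the limiting AA, its
    coverage, and the predicted gain; ``coverage_long`` is the full
    plot-ready long format (tissue, diet, aa, essential, coverage,
    limiting_flag) suitable for Cleveland plots.
    """

    summary: pd.DataFrame
    coverage_long: pd.DataFrame

    def gain_difference(self, diet_a: str, diet_b: str) -> pd.Series:
        """Per-tissue difference in predicted gain, diet_a minus diet_b."""
        s = self.summary.set_index(["tissue", "diet"])["predicted_gain_pct"]
        return (s.xs(diet_a, level="diet") - s.xs(diet_b, level="diet")).rename(
            f"gain({diet_a}) - gain({diet_b})"
        )


def tissue_panel(
    diets: Mapping[str, AAProfile],
    tissue_demands: Mapping[str, AAProfile],
    essentials: frozenset[str] | None = None,
) -> TissuePanel:
    """Compare each diet to each tissue's demand profile.

    Tissue demands are typically tissue-specific transcriptome-weighted
    profiles; the coverage of the limiting AA says how well each diet meets
    each tissue's predicted requirement (100 = perfectly matched).
    """
    if not diets or not tissue_demands:
        raise ValueError("tissue_panel requires at least one diet and one tissue demand")
    srows, lrows = [], []
    for tissue, demand in tissue_demands.items():
        for diet_name, diet in diets.items():
            rep = coverage(diet, demand, essentials=essentials)
            srows.append(
                {
                    "tissue": tissue,
                    "diet": diet_name,
                    "limiting_aa": rep.limiting_aa,
                    "limiting_coverage_pct": rep.limiting_coverage,
                    "predicted_gain_pct": rep.predicted_gain,
                }
            )
            for aa in AMINO_ACIDS:
                lrows.append(
                    {
                        "tissue": tissue,
                        "diet": diet_name,
                        "aa": aa,
                        "essential": aa in rep.essentials,
                        "coverage_pct": rep.coverage.get(aa, float("nan")),
                        "limiting_flag": aa == rep.limiting_aa,
                    }
                )
    return TissuePanel(pd.DataFrame(srows), pd.DataFrame(lrows))


def power_sample_size(
    z: float | None = None,
    sigma: float | None = None,
    e: float | None = None,
    n: float | None = None,
    solve_for: str = "n",
):
    """Solve the one-sample power relation n = (Z * sigma / E)^2.

    Exactly the three quantities other than ``solve_for`` must be given:
    ``z`` the confidence level, ``sigma`` the standard deviation of the
    fecundity measure, ``e`` the detectable difference (same units as
    sigma), ``n`` the sample size.
    """
    given = {"z": z, "sigma": sigma, "e": e, "n": n}
    if solve_for not in given:
        raise ValueError(f"solve_for must be one of {list(given)}")
    needed = [k for k in given if k != solve_for]
    missing = [k for k in needed if given[k] is None]
    if missing:
        raise ValueError(f"missing parameters: {missing}")
    for k in needed:
        if given[k] <= 0:
            raise ValueError(f"{k} must be positive")
    if solve_for == "n":
        return (z * sigma / e) ** 2
    if solve_for == "z":
        return e * math.sqrt(n) / sigma
    if solve_for == "e":
        return z * sigma / math.sqrt(n)
    return e * math.sqrt(n) / z  # sigma
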