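"""Permutation null for transcriptome-weighted amino-acid profiles.

Whether an observed profile (FLYAA, MALEAA, FEMALEAA, ...) is an extreme
example of amino-acid usage is judged against a null distribution built by
randomly reassigning the observed expression values to genes: each
permutation keeps the multiset of expression weightings but shuffles which
gene gets which weighting, yielding divergent but realistically-distributed
expression profiles. For every permutation a transcriptome-weighted profile
is computed; divergence is measured as the Euclidean distance from each
profile to the per-AA *median* of the permuted profiles, and an observed
profile is located in the null by the percentage of permuted profiles that
lie closer to the median than it does.

Permutation can act at gene level (default — all isoforms of a gene move
together, preserving the within-gene isoform expression structure) or at
isoform level.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, AAProfile, euclidean_distance, median_profile
from .profiles import ProteomeCounts, align_expression

__all__ = [
    "PermutationResult",
    "permute_null",
    "percentile_of",
    "per_aa_null_summary",
    "calibration_percentiles",
]


@dataclass(frozen=True)
class ObservedPlacement:
    profile: AAProfile
    distance: float
    percentile: float


@dataclass(frozen=True)
class PermutationResult:
    """Null distribution of expression-permuted profiles.

    ``profiles`` holds one permuted profile per row (alphabet order);
    ``median`` is the per-AA median over those rows (not renormalized);
    ``distances`` the Euclidean distance of each permuted profile to the
    median. ``observed`` maps labels of user-supplied profiles to their
    distance and percentile within the null.
    """

    n_perm: int
    level: str
    seed: int | None
    profiles: np.ndarray  # (n_perm, 20)
    median: np.ndarray  # (20,)
    distances: np.ndarray  # (n_perm,)
    observed: dict[str, ObservedPlacement] = field(default_factory=dict)

    def distance_quantile(self, q) -> float:
        return float(np.quantile(self.distances, q))


def _entity_matrix(
    pc: ProteomeCounts, expr: pd.DataFrame, level: str, replicate
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Collapse counts/expression to the permutation entities.

    Returns (C, e, names): C the (n_entities, 20) count matrix, e the
    expression vector whose values get permuted.

    At isoform level C holds the raw per-isoform counts. At gene level each
    gene's count vector is the expression-share-weighted mean of its
    isoforms' count vectors (uniform mean when the gene is unexpressed) and
    e its total FPKM, so a permutation moves a gene's whole expression
    budget while keeping its internal isoform usage fixed.
    """
    aligned = align_expression(pc, expr)
    if replicate is None or replicate == "mean":
        e_iso = aligned.mean(axis=1).to_numpy(float)
    else:
        if replicate not in aligned.columns:
            raise KeyError(f"replicate {replicate!r} not in expression table")
        e_iso = aligned[replicate].to_numpy(float)
    C_iso = pc.counts.to_numpy(float)
    if level == "isoform":
        return C_iso, e_iso, list(pc.counts.index)
    if level != "gene":
        raise ValueError(f"level must be 'gene' or 'isoform', got {level!r}")
    genes = pc.genes.to_numpy()
    names: list[str] = []
    C_rows, e_rows = [], []
    # stable first-appearance order keeps results reproducible
    seen: dict[str, int] = {}
    for g in genes:
        if g not in seen:
            seen[g] = len(names)
            names.append(g)
    for g in names:
        idx = np.flatnonzero(genes == g)
        e_g = e_iso[idx].sum()
        if e_g > 0:
            w = e_iso[idx] / e_g
        else:
            w = np.full(len(idx), 1.0 / len(idx))
        C_rows.append(w @ C_iso[idx])
        e_rows.append(e_g)
    return np.asarray(C_rows), np.asarray(e_rows), names


def _profiles_from_assignments(C: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Row-normalized weighted profiles for a batch of expression assignments E (n, entities)."""
    raw = E @ C
    totals = raw.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("a permutation produced an all-zero weighted profile")
    return raw / totals


def permute_null(
    pc: ProteomeCounts,
    expr: pd.DataFrame,
    n_perm: int = 20_000,
    seed: int | None = None,
    level: str = "gene",
    replicate=None,
    exhaustive: bool = False,
    observed: dict[str, AAProfile] | None = None,
) -> PermutationResult:
    """Build the permutation null and locate observed profiles within it.

    Parameters
    ----------
    pc, expr:
        Proteome counts and the expression table whose values are permuted.
        By default the per-isoform mean over replicate columns is used
        (``replicate`` selects a single column instead).
    n_perm:
        Number of random permutations (default 20,000).
    seed:
        Seed for the permutation RNG; required for reproducible nulls.
    level:
        ``"gene"`` (default) or ``"isoform"``.
    exhaustive:
        Enumerate all n! assignments in lexicographic order instead of
        sampling; ``n_perm`` is then ignored. Only sensible for tiny
        fixtures.
    observed:
        Label → profile map; each is placed in the null by distance to the
        null median (the observed profiles never contaminate the null).
    """
    C, e, names = _entity_matrix(pc, expr, level, replicate)
    n_ent = len(names)
    if n_ent < 2:
        raise ValueError("permutation needs at least two entities (it would be the identity)")
    if not (e > 0).any():
        raise ValueError("all expression values are zero")
    if exhaustive:
        assignments = np.asarray(list(itertools.permutations(e)), dtype=float)
        n_perm = len(assignments)
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        assignments = rng.permuted(np.tile(e, (n_perm, 1)), axis=1)
    profiles = _profiles_from_assignments(C, assignments)
    med = median_profile(profiles)
    distances = np.linalg.norm(profiles - med, axis=1)
    result = PermutationResult(
        n_perm=n_perm,
        level=level,
        seed=seed,
        profiles=profiles,
        median=med,
        distances=distances,
    )
    if observed:
        for label, prof in observed.items():
            d = euclidean_distance(prof.values, med)
            result.observed[label] = ObservedPlacement(
                profile=prof, distance=d, percentile=_percentile(distances, d)
            )
    return result


def _percentile(null_distances: np.ndarray, d: float) -> float:
    # strict inequality: ties count as not-exceeded
    return 100.0 * float(np.count_nonzero(null_distances < d)) / len(null_distances)


def percentile_of(result: PermutationResult, profile: AAProfile, label: str | None = None) -> float:
    """Percentage of permuted profiles strictly closer to the null median.

    A profile equal to the median scores 0; one farther than every
    permutation scores 100. When ``label`` is given the placement is also
    recorded on ``result.observed``.
    """
    d = euclidean_distance(profile.values, result.median)
    pct = _percentile(result.distances, d)
    if label is not None:
        result.observed[label] = ObservedPlacement(profile=profile, distance=d, percentile=pct)
    return pct


def per_aa_null_summary(result: PermutationResult) -> pd.DataFrame:
    """Box-plot summary of the null, per amino acid.

    One row per AA with the median, quartiles, 1.5*IQR fences and the
    min/max of the permuted proportions, plus one ``observed_<label>``
    column per placed observed profile. Long-format melt is left to the
    caller's plotting layer.
    """
    q1 = np.quantile(result.profiles, 0.25, axis=0)
    q3 = np.quantile(result.profiles, 0.75, axis=0)
    iqr = q3 - q1
    df = pd.DataFrame(
        {
            "aa": list(AMINO_ACIDS),
            "median": np.median(result.profiles, axis=0),
            "q1": q1,
            "q3": q3,
            "lower_fence": q1 - 1.5 * iqr,
            "upper_fence": q3 + 1.5 * iqr,
            "min": result.profiles.min(axis=0),
            "max": result.profiles.max(axis=0),
        }
    )
    for label, placement in result.observed.items():
        df[f"observed_{label}"] = placement.profile.values
    return df


def calibration_percentiles(
    pc: ProteomeCounts,
    expr: pd.DataFrame,
    n_trials: int,
    n_perm: int,
    seed: int,
    level: str = "gene",
    replicate=None,
) -> np.ndarray:
    """Percentiles of null-generated 'observed' profiles against fresh nulls.

    For each trial an independent null of ``n_perm`` permutations is built
    and one extra permutation plays the observed profile; its percentile is
    recorded. When the observed profile is itself an exchangeable draw from
    the null process these percentiles are approximately uniform on
    [0, 100] — the calibration property of the test.
    """
    C, e, names = _entity_matrix(pc, expr, level, replicate)
    if len(names) < 2:
        raise ValueError("permutation needs at least two entities")
    rng = np.random.default_rng(seed)
    out = np.empty(n_trials)
    base = np.tile(e, (n_perm + 1, 1))
    for t in range(n_trials):
        assignments = rng.permuted(base, axis=1)
        profiles = _profiles_from_assignments(C, assignments)
        null_profiles, obs_profile = profiles[:-1], profiles[-1]
        med = np.median(null_profiles, axis=0)
        null_d = np.linalg.norm(null_profiles - med, axis=1)
        d_obs = float(np.linalg.norm(obs_profile - med))
        out[t] = _percentile(null_d, d_obs)
    return out
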