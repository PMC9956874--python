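"""Amino-acid alphabet, composition profiles, and profile arithmetic.

Everything downstream — expression weighting, diet comparison, permutation
nulls, recipe formulation — operates on 20-dimensional molar-fraction
vectors over the canonical amino-acid alphabet defined here. The alphabet
order is fixed (alphabetical single-letter codes) so that serialized
profiles and internal numpy vectors always align.
"""
from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

#: Canonical amino acids, fixed alphabetical order.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: The ten amino acids Drosophila cannot synthesize de novo; only these can
#: be dietary-limiting.
ESSENTIAL_AAS: frozenset[str] = frozenset("FHIKLMRTVW")

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AAS: int = len(AMINO_ACIDS)

#: Sum-to-one tolerance for freshly constructed profiles.
SUM_TOL: float = 1e-9

_ESSENTIAL_MASK = np.array([aa in ESSENTIAL_AAS for aa in AMINO_ACIDS])


def essential_mask() -> np.ndarray:
    """Boolean mask over the fixed alphabet, True at essential positions."""
    return _ESSENTIAL_MASK.copy()


def as_vector(values) -> np.ndarray:
    """Coerce a profile-like object to a float vector over the alphabet.

    Accepts an :class:`AAProfile`, an :class:`AACountVector`, a mapping
    ``{symbol: value}`` (missing symbols are 0), or a length-20 sequence
    already in alphabet order.

    Raises
    ------
    ValueError
        If a mapping contains symbols outside the alphabet, or a sequence
        has the wrong length.
    """
    if isinstance(values, (AAProfile, AACountVector)):
        return values.values.astype(float, copy=True)
    if isinstance(values, Mapping):
        unknown = sorted(set(values) - set(AMINO_ACIDS))
        if unknown:
            raise ValueError(
                f"symbols outside the 20-letter amino-acid alphabet: {unknown}"
            )
        vec = np.zeros(N_AAS)
        for aa, v in values.items():
            vec[AA_INDEX[aa]] = float(v)
        return vec
    vec = np.asarray(values, dtype=float)
    if vec.shape != (N_AAS,):
        raise ValueError(
            f"expected a length-{N_AAS} vector in alphabet order, got shape {vec.shape}"
        )
    return vec.copy()


@dataclass(frozen=True)
class AACountVector:
    """Non-negative amino-acid counts (or expression-weighted counts).

    Entries may be real-valued: an expression-weighted count
    sum_j count_ij * E_j is still a "count" for profile purposes.
    """

    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        vec = as_vector(self.values) if not isinstance(self.values, np.ndarray) else self.values.astype(float)
        if vec.shape != (N_AAS,):
            vec = as_vector(self.values)
        if np.any(vec < 0) or not np.all(np.isfinite(vec)):
            raise ValueError(f"count vector {self.label!r} has negative or non-finite entries")
        object.__setattr__(self, "values", vec)

    @classmethod
    def from_mapping(cls, counts: Mapping[str, float], label: str = "") -> "AACountVector":
        return cls(as_vector(counts), label)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def __getitem__(self, aa: str) -> float:
        return float(self.values[AA_INDEX[aa]])


@dataclass(frozen=True)
class AAProfile:
    """A molar-fraction amino-acid profile: 20 non-negative proportions summing to 1."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        vec = as_vector(self.values)
        if np.any(vec < 0):
            raise ValueError(f"profile {self.label!r} has negative proportions")
        total = vec.sum()
        if abs(total - 1.0) > SUM_TOL:
            raise ValueError(
                f"profile {self.label!r} proportions sum to {total!r}, not 1 "
                f"(tolerance {SUM_TOL})"
            )
        object.__setattr__(self, "values", vec)

    @classmethod
    def from_mapping(cls, proportions: Mapping[str, float], label: str = "") -> "AAProfile":
        return cls(as_vector(proportions), label)

    @property
    def proportions(self) -> dict[str, float]:
        return {aa: float(v) for aa, v in zip(AMINO_ACIDS, self.values)}

    def __getitem__(self, aa: str) -> float:
        return float(self.values[AA_INDEX[aa]])

    def relabel(self, label: str) -> "AAProfile":
        return AAProfile(self.values, label)


def normalize(counts, label: str | None = None) -> AAProfile:
    """Normalize a count vector to a molar-fraction profile.

    This is the closing step of every profile computation: divide each
    amino acid's (possibly expression-weighted) count by the grand total so
    the proportions sum to one.

    Raises
    ------
    ValueError
        If the counts are all zero (there is nothing to normalize).
    """
    if label is None:
        label = getattr(counts, "label", "") or ""
    vec = as_vector(counts)
    if np.any(vec < 0):
        raise ValueError(f"count vector {label!r} has negative entries")
    total = vec.sum()
    if total <= 0:
        raise ValueError(f"cannot normalize all-zero count vector {label!r}")
    vec = vec / total
    # guard against accumulated rounding in the division itself
    vec = vec / vec.sum()
    return AAProfile(vec, label)


def euclidean_distance(p, q) -> float:
    """Euclidean distance between two profile-like vectors.

    Both arguments must cover the same 20-symbol alphabet (mappings are
    expanded over the full alphabet; sequences must be length 20 in
    alphabet order). For two normalized profiles the distance is bounded
    above by sqrt(2).
    """
    return float(np.linalg.norm(as_vector(p) - as_vector(q)))


def median_profile(profiles: Sequence | Iterable) -> np.ndarray:
    """Per-symbol median of a collection of profile-like vectors.

    The result is deliberately *not* renormalized: component-wise medians
    of normalized profiles do not themselves sum to one, and distances to
    this raw median are what the permutation null measures. Renormalizing
    would silently change every distance.
    """
    mat = np.asarray([as_vector(p) for p in profiles], dtype=float)
    if mat.size == 0:
        raise ValueError("median_profile requires at least one profile")
    return np.median(mat, axis=0)
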