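"""Exome-matched and transcriptome-weighted amino-acid profile builders.

Three distinct summaries of a proteome's amino-acid usage are provided, and
they genuinely differ on length- or expression-heterogeneous proteomes:

``exome_profile_protein_average``
    The original exome match: each protein's composition is normalized
    first, then proteins are averaged with equal weight. Protein length
    does not weight the result.

``exome_profile_pooled``
    Residues pooled across all isoforms, then normalized. Equivalent to the
    expression-weighted profile with equal expression for every isoform, so
    it isolates the effect of the weighting.

``weighted_profile``
    The transcriptome-weighted profile: each isoform's amino-acid counts
    AA_ij are multiplied by the isoform's expression E_j (FPKM), summed
    over isoforms (AA_i = sum_j AA_ij * E_j), and normalized
    (P(AA_i) = AA_i / sum_i AA_i).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, AAProfile, normalize
from .io import ProteinRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteomeCounts:
    """Per-isoform amino-acid counts (AA_ij) plus the isoform → gene map.

    ``counts`` is a DataFrame indexed by isoform id with one column per
    amino acid in fixed alphabet order; each row sums to the cleaned
    sequence length.
    """

    counts: pd.DataFrame
    genes: pd.Series  # isoform_id -> gene_id

    @property
    def isoform_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def lengths(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def n_isoforms(self) -> int:
        return len(self.counts)


def count_isoform_aas(records: Sequence[ProteinRecord]) -> ProteomeCounts:
    """Count each amino acid in each isoform sequence.

    Letters outside the canonical alphabet contribute nothing (the readers
    already strip them); records with zero canonical letters are excluded
    with a warning.
    """
    if not records:
        raise ValueError("count_isoform_aas requires at least one record")
    rows, index, genes = [], [], []
    for rec in records:
        row = np.zeros(len(AMINO_ACIDS), dtype=float)
        for i, aa in enumerate(AMINO_ACIDS):
            row[i] = rec.sequence.count(aa)
        if row.sum() == 0:
            log.warning("isoform %r has no canonical amino acids; excluded", rec.isoform_id)
            continue
        rows.append(row)
        index.append(rec.isoform_id)
        genes.append(rec.gene_id)
    if not rows:
        raise ValueError("no isoform with canonical amino acids")
    counts = pd.DataFrame(rows, index=pd.Index(index, name="isoform_id"), columns=list(AMINO_ACIDS))
    return ProteomeCounts(counts, pd.Series(genes, index=counts.index, name="gene_id"))


def exome_profile_protein_average(pc: ProteomeCounts, label: str = "exome-protein-average") -> AAProfile:
    """Unweighted exome match: average of per-protein composition vectors."""
    mat = pc.counts.to_numpy(float)
    per_protein = mat / mat.sum(axis=1, keepdims=True)
    return normalize(per_protein.mean(axis=0), label)


def exome_profile_pooled(pc: ProteomeCounts, label: str = "exome-pooled") -> AAProfile:
    """Length-weighted baseline: pool residues over all isoforms, then normalize."""
    return normalize(pc.counts.to_numpy(float).sum(axis=0), label)


def align_expression(pc: ProteomeCounts, expr: pd.DataFrame) -> pd.DataFrame:
    """Align an expression table to a proteome's isoform index.

    Isoforms missing from the table get 0 FPKM; isoforms in the table but
    absent from the proteome are dropped. Both situations are logged with
    counts so upstream id mismatches are visible.
    """
    missing = pc.counts.index.difference(expr.index)
    extra = expr.index.difference(pc.counts.index)
    if len(missing):
        log.warning("%d proteome isoforms missing from expression table; FPKM set to 0", len(missing))
    if len(extra):
        log.warning("%d expression rows have no matching isoform; ignored", len(extra))
    return expr.reindex(pc.counts.index, fill_value=0.0)


def _expression_vector(pc: ProteomeCounts, expr: pd.DataFrame, replicate) -> np.ndarray:
    aligned = align_expression(pc, expr)
    if replicate is None or replicate == "mean":
        return aligned.mean(axis=1).to_numpy(float)
    if replicate not in aligned.columns:
        raise KeyError(f"replicate {replicate!r} not in expression table columns {list(expr.columns)}")
    return aligned[replicate].to_numpy(float)


def weighted_profile(
    pc: ProteomeCounts,
    expr: pd.DataFrame,
    replicate=None,
    label: str = "transcriptome-weighted",
) -> AAProfile:
    """Transcriptome-weighted profile: normalize(sum_j AA_ij * E_j).

    ``replicate`` selects one FPKM column; ``None`` (or ``"mean"``) uses the
    per-isoform mean across replicate columns. Isoforms with zero
    expression contribute nothing; all-zero expression is an error.
    """
    e = _expression_vector(pc, expr, replicate)
    if not (e > 0).any():
        raise ValueError("all isoforms have zero expression in the chosen replicate")
    weighted = pc.counts.to_numpy(float).T @ e
    return normalize(weighted, label)


def weighted_profiles_by_replicate(pc: ProteomeCounts, expr: pd.DataFrame) -> list[AAProfile]:
    """One transcriptome-weighted profile per replicate column."""
    return [weighted_profile(pc, expr, replicate=c, label=str(c)) for c in expr.columns]


@dataclass(frozen=True)
class ReplicateAverage:
    """Mean profile across replicates plus the per-AA standard deviation."""

    mean: AAProfile
    sd: np.ndarray  # per-AA sd across replicate profiles, alphabet order

    def sd_of(self, aa: str) -> float:
        from .core import AA_INDEX

        return float(self.sd[AA_INDEX[aa]])


def average_replicate_profiles(profiles: Sequence[AAProfile], label: str = "replicate-average") -> ReplicateAverage:
    """Average replicate profiles element-wise and renormalize.

    Replicates are combined by building one weighted profile per replicate
    and then averaging the profiles (not by averaging FPKM first); the
    reported per-AA standard deviation is taken across the replicate
    profiles.
    """
    if not profiles:
        raise ValueError("average_replicate_profiles requires at least one profile")
    mat = np.asarray([p.values for p in profiles], dtype=float)
    mean = normalize(mat.mean(axis=0), label)
    sd = mat.std(axis=0, ddof=0)
    return ReplicateAverage(mean, sd)
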