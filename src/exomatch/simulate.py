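"""Synthetic proteomes and expression tables with known ground truth.

The generator emulates the statistical shape of a real insect
proteome/expression pair at adjustable scale: a multi-isoform proteome
whose sequences are drawn residue-by-residue from a target composition,
and right-skewed (log-normal) isoform expression with multiplicative
replicate noise — FPKM values in real tissue atlases span orders of
magnitude, hence the log-normal default. Sequences carry no positional
structure (pure multinomial residues); every downstream computation in
this package depends only on counts, so none is lost.

Every generated fixture ships a manifest holding the exact per-isoform
amino-acid counts, the expression values, and the analytically computed
transcriptome-weighted ground-truth profile — computed here with plain
Python loops, independently of the profile builders it is used to check.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, ESSENTIAL_AAS, AAProfile
from .io import ProteinRecord, write_expression, write_proteome


def _default_target() -> dict[str, float]:
    from .io import reference_diet_ratios

    return reference_diet_ratios()["FLYAA"].proportions


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic proteome/expression fixture.

    Defaults mirror the shape of whole-fly data at reduced scale: about two
    isoforms per gene, protein lengths of a few hundred residues, five
    replicates of log-normal FPKM (sigma 1.5 gives the several-decade
    spread typical of tissue atlases) with 20% multiplicative replicate
    noise, and the fly exome-matched composition as the sequence target.
    """

    seed: int
    n_genes: int = 500
    mean_extra_isoforms: float = 1.0  # isoforms per gene = 1 + Poisson(this)
    length_range: tuple[int, int] = (100, 1000)
    target_profile: dict[str, float] | None = None
    expression_mu: float = 1.0  # log-normal location of per-isoform FPKM
    expression_sigma: float = 1.5  # log-normal scale
    n_replicates: int = 5
    replicate_sd: float = 0.2  # sd of multiplicative log-normal replicate noise
    require_essentials: bool = False  # refuse targets unusable for diet tests

    def resolved_target(self) -> np.ndarray:
        mapping = self.target_profile if self.target_profile is not None else _default_target()
        vec = np.array([float(mapping.get(aa, 0.0)) for aa in AMINO_ACIDS])
        if (vec < 0).any() or vec.sum() <= 0:
            raise ValueError("target profile must be non-negative with positive total")
        vec = vec / vec.sum()
        if self.require_essentials and not any(
            vec[i] > 0 for i, aa in enumerate(AMINO_ACIDS) if aa in ESSENTIAL_AAS
        ):
            raise ValueError(
                "target profile has zero for every essential amino acid; "
                "unusable for diet comparisons"
            )
        return vec


@dataclass(frozen=True)
class Fixture:
    """A generated proteome/expression pair plus its ground-truth manifest."""

    records: list[ProteinRecord]
    expression: pd.DataFrame
    manifest: dict

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteome": outdir / "proteome.fasta",
            "expression": outdir / "expression.tsv",
            "manifest": outdir / "manifest.json",
        }
        write_proteome(self.records, paths["proteome"])
        write_expression(self.expression, paths["expression"])
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
        return paths


def generate(spec: FixtureSpec) -> Fixture:
    """Generate a fixture reproducibly from ``spec.seed``.

    The manifest records, per isoform: the gene, the exact amino-acid
    counts and the FPKM value per replicate; plus the analytic
    ground-truth profiles (pooled and replicate-mean transcriptome
    weighted) computed with independent plain-Python arithmetic.
    """
    rng = np.random.default_rng(spec.seed)
    target = spec.resolved_target()
    lo, hi = spec.length_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid length range {spec.length_range}")

    records: list[ProteinRecord] = []
    for g in range(spec.n_genes):
        gene_id = f"g{g + 1}"
        n_iso = 1 + rng.poisson(spec.mean_extra_isoforms)
        for k in range(n_iso):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=length, p=target))
            records.append(ProteinRecord(f"{gene_id}.i{k + 1}", gene_id, seq))

    n_iso_total = len(records)
    base = rng.lognormal(mean=spec.expression_mu, sigma=spec.expression_sigma, size=n_iso_total)
    noise = rng.lognormal(mean=0.0, sigma=spec.replicate_sd, size=(n_iso_total, spec.n_replicates))
    fpkm = base[:, None] * noise
    expression = pd.DataFrame(
        fpkm,
        index=pd.Index([r.isoform_id for r in records], name="isoform_id"),
        columns=[f"rep{i + 1}" for i in range(spec.n_replicates)],
    )

    # --- analytic ground truth, independent of the profile builders -------
    per_isoform = {}
    pooled = {aa: 0 for aa in AMINO_ACIDS}
    weighted = {aa: 0.0 for aa in AMINO_ACIDS}
    for i, rec in enumerate(records):
        counts = {aa: rec.sequence.count(aa) for aa in AMINO_ACIDS}
        e_mean = sum(fpkm[i]) / spec.n_replicates
        per_isoform[rec.isoform_id] = {
            "gene": rec.gene_id,
            "length": len(rec.sequence),
            "counts": counts,
            "fpkm": [float(x) for x in fpkm[i]],
        }
        for aa in AMINO_ACIDS:
            pooled[aa] += counts[aa]
            weighted[aa] += counts[aa] * e_mean
    total_residues = sum(pooled.values())
    pooled_profile = {aa: pooled[aa] / total_residues for aa in AMINO_ACIDS}
    wtot = sum(weighted.values())
    weighted_profile = {aa: weighted[aa] / wtot for aa in AMINO_ACIDS}

    manifest = {
        "spec": {
            **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(spec).items()
                if k != "target_profile"
            },
            "target_profile": {aa: float(t) for aa, t in zip(AMINO_ACIDS, target)},
        },
        "n_isoforms": n_iso_total,
        "total_residues": int(total_residues),
        "isoforms": per_isoform,
        "pooled_profile": pooled_profile,
        "weighted_profile_replicate_mean": weighted_profile,
    }
    return Fixture(records=records, expression=expression, manifest=manifest)


def worked_example() -> Fixture:
    """The fixed three-gene micro-dataset used throughout docs and tests.

    Proteome: g1.i1 = ``MW`` (FPKM 2), g2.i1 = ``MMMW`` (FPKM 1),
    g3.i1 = ``AAAG`` (FPKM 1). Every intermediate quantity can be done by
    hand:

    ====  =====  ======================  =============
    AA    pooled  expression-weighted    protein-average
          count   count (AA_i)           proportion
    ====  =====  ======================  =============
    M     4      1*2 + 3*1 = 5           (1/2 + 3/4 + 0)/3 = 5/12
    W     2      1*2 + 1*1 = 3           (1/2 + 1/4 + 0)/3 = 1/4
    A     3      3*1 = 3                 (0 + 0 + 3/4)/3 = 1/4
    G     1      1*1 = 1                 (0 + 0 + 1/4)/3 = 1/12
    ====  =====  ======================  =============

    so the transcriptome-weighted profile is {M: 5/12, W: 1/4, A: 1/4,
    G: 1/12} (total weighted count 12) and the pooled profile is
    {M: 0.4, W: 0.2, A: 0.3, G: 0.1} (10 residues). The manifest's
    ``expected`` block stores these as exact floats.
    """
    records = [
        ProteinRecord("g1.i1", "g1", "MW"),
        ProteinRecord("g2.i1", "g2", "MMMW"),
        ProteinRecord("g3.i1", "g3", "AAAG"),
    ]
    expression = pd.DataFrame(
        {"rep1": [2.0, 1.0, 1.0]},
        index=pd.Index([r.isoform_id for r in records], name="isoform_id"),
    )

    def prof(fracs: dict[str, Fraction]) -> dict[str, float]:
        return {aa: float(fracs.get(aa, Fraction(0))) for aa in AMINO_ACIDS}

    F = Fraction
    expected = {
        "weighted": prof({"M": F(5, 12), "W": F(1, 4), "A": F(1, 4), "G": F(1, 12)}),
        "pooled": prof({"M": F(2, 5), "W": F(1, 5), "A": F(3, 10), "G": F(1, 10)}),
        "protein_average": prof({"M": F(5, 12), "W": F(1, 4), "A": F(1, 4), "G": F(1, 12)}),
    }
    manifest = {
        "n_isoforms": 3,
        "total_residues": 10,
        "isoforms": {
            r.isoform_id: {
                "gene": r.gene_id,
                "length": len(r.sequence),
                "counts": {aa: r.sequence.count(aa) for aa in AMINO_ACIDS},
                "fpkm": [float(expression.loc[r.isoform_id, "rep1"])],
            }
            for r in records
        },
        "expected": expected,
    }
    return Fixture(records=records, expression=expression, manifest=manifest)


def expected_profile(fixture: Fixture, which: str) -> AAProfile:
    """An expected profile from a fixture manifest as an :class:`AAProfile`."""
    if "expected" in fixture.manifest:
        mapping = fixture.manifest["expected"][which]
    else:
        key = {"pooled": "pooled_profile", "weighted": "weighted_profile_replicate_mean"}[which]
        mapping = fixture.manifest[key]
    return AAProfile.from_mapping(mapping, label=f"manifest-{which}")
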