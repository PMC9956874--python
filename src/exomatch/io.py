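"""Readers and writers for the tool's tabular and sequence formats.

Formats handled here:

* protein FASTA (one record per isoform; configurable header rules for
  FlyBase-style and plain ``>id`` headers),
* isoform expression tables (TSV: ``isoform_id`` then one FPKM column per
  replicate),
* molar diet-ratio tables (TSV: ``aa`` then one column per diet),
* amino-acid molecular-weight tables,
* single-profile TSVs and coverage reports.

All tabular formats are tab-separated with ``#`` comment lines permitted
and a decimal point (no locale handling).
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import AA_INDEX, AMINO_ACIDS, AAProfile, normalize

log = logging.getLogger(__name__)

# Diet-ratio columns are printed rounded; a column sum outside this window
# means the column is not a molar-fraction profile (e.g. g/L by mistake).
RATIO_SUM_WINDOW = (0.98, 1.02)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein isoform: identifiers plus cleaned amino-acid sequence."""

    isoform_id: str
    gene_id: str
    sequence: str


# ---------------------------------------------------------------------------
# protein FASTA

_FLYBASE_PARENT = re.compile(r"parent=([^;\s]+)")
_GENE_KEY = re.compile(r"\bgene[=:]([\w.-]+)")
_FBGN = re.compile(r"(FBgn\d+)")

_CANONICAL = set(AMINO_ACIDS)


def _parse_header(header: str, rule) -> tuple[str, str | None]:
    """Extract (isoform_id, gene_id or None) from a FASTA description line."""
    isoform_id = header.split()[0]
    if callable(rule):
        return rule(header)
    if isinstance(rule, re.Pattern) or (isinstance(rule, str) and rule not in ("auto", "flybase", "plain")):
        pat = re.compile(rule) if isinstance(rule, str) else rule
        m = pat.search(header)
        if m is None:
            raise ValueError(f"header rule {pat.pattern!r} did not match record {isoform_id!r}")
        gd = m.groupdict()
        return gd.get("isoform", isoform_id), gd.get("gene")
    if rule == "flybase":
        m = _FLYBASE_PARENT.search(header)
        if m is None:
            raise ValueError(f"no 'parent=' field in FlyBase-style header of record {isoform_id!r}")
        genes = _FBGN.findall(m.group(1))
        if not genes:
            raise ValueError(f"no FBgn gene id in 'parent=' field of record {isoform_id!r}")
        return isoform_id, genes[0]
    if rule == "plain":
        m = _GENE_KEY.search(header)
        return isoform_id, m.group(1) if m else None
    # auto: FlyBase parent= field, then a gene=/gene: key, then FBgn anywhere
    m = _FLYBASE_PARENT.search(header)
    if m:
        genes = _FBGN.findall(m.group(1))
        if genes:
            return isoform_id, genes[0]
    m = _GENE_KEY.search(header)
    if m:
        return isoform_id, m.group(1)
    m = _FBGN.search(header)
    if m:
        return isoform_id, m.group(1)
    return isoform_id, None


def clean_sequence(raw: str) -> tuple[str, int]:
    """Uppercase, strip stop symbols, drop non-canonical letters.

    Returns the cleaned sequence and the number of non-canonical letters
    dropped (``*`` stops are stripped silently, not counted).
    """
    seq = str(raw).upper().replace("*", "")
    kept = [c for c in seq if c in _CANONICAL]
    return "".join(kept), len(seq) - len(kept)


def read_proteome(path, header_rule="auto") -> list[ProteinRecord]:
    """Read a protein FASTA into a list of :class:`ProteinRecord`.

    Parameters
    ----------
    path:
        FASTA file of translated isoform sequences.
    header_rule:
        ``"auto"`` (default) tries FlyBase ``parent=FBgn...`` fields, then a
        ``gene=`` key, then any FBgn token; ``"flybase"`` requires the
        ``parent=`` field; ``"plain"`` takes the first token as isoform id
        with an optional ``gene=`` key; a regex with named groups
        ``isoform``/``gene`` or a callable ``header -> (isoform, gene)`` may
        also be given. When no gene id is parseable the gene id defaults to
        the isoform id, so gene-level operations degrade gracefully to
        isoform level.

    Records whose sequence is empty after cleaning are dropped with a
    warning. Duplicate isoform ids and empty files are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    n_dropped_letters = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        isoform_id, gene_id = _parse_header(rec.description, header_rule)
        if isoform_id in seen:
            raise ValueError(f"duplicate isoform id {isoform_id!r} in {path}")
        seen.add(isoform_id)
        seq, dropped = clean_sequence(str(rec.seq))
        n_dropped_letters += dropped
        if not seq:
            log.warning("record %r has no canonical amino acids after cleaning; dropped", isoform_id)
            continue
        records.append(ProteinRecord(isoform_id, gene_id or isoform_id, seq))
    if n_dropped_letters:
        log.warning("dropped %d non-canonical letters while reading %s", n_dropped_letters, path)
    if not records and not seen:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_proteome(records, path) -> None:
    """Write records as plain protein FASTA with ``>isoform gene=<gene>`` headers."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.isoform_id} gene={rec.gene_id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# expression tables

def read_expression(path) -> pd.DataFrame:
    """Read an isoform expression table.

    TSV with a header row; first column is the isoform id, every further
    column one replicate of FPKM values. Returns a DataFrame indexed by
    isoform id. Missing cells are treated as 0 FPKM (with a warning);
    negative values, duplicate isoform ids, and all-zero replicate columns
    are errors.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"expression table {path} has no replicate columns")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated isoform ids in {path}: {dups[:5]}")
    df = df.apply(pd.to_numeric)
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        log.warning("%d missing FPKM cells in %s treated as 0", n_missing, path)
        df = df.fillna(0.0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative FPKM values in {path}")
    dead = [c for c in df.columns if not (df[c] > 0).any()]
    if dead:
        raise ValueError(f"replicate column(s) with no non-zero FPKM in {path}: {dead}")
    df.index = df.index.astype(str)
    df.index.name = "isoform_id"
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="isoform_id")


# ---------------------------------------------------------------------------
# profiles and diet-ratio tables

def write_profile(profile: AAProfile, path, header_lines=()) -> None:
    """Write one profile as a two-column TSV (``aa``, ``proportion``)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("aa\tproportion\n")
        for aa in AMINO_ACIDS:
            fh.write(f"{aa}\t{profile[aa]:.9g}\n")


def read_profile(path, label: str | None = None) -> AAProfile:
    """Read a two-column profile TSV written by :func:`write_profile`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns[:2]) != ["aa", "proportion"]:
        raise ValueError(f"{path} is not a profile TSV (expected columns aa, proportion)")
    vec = np.zeros(len(AMINO_ACIDS))
    for aa, v in zip(df["aa"], df["proportion"]):
        vec[AA_INDEX[str(aa)]] = float(v)
    return normalize(vec, label if label is not None else Path(str(path)).stem)


@dataclass(frozen=True)
class DietRatioTable:
    """Per-diet molar-ratio profiles plus bookkeeping from parsing.

    ``raw_column_sums`` records each column's sum before renormalization
    (printed tables are rounded, so sums like 1.001 are expected).
    """

    profiles: dict[str, AAProfile]
    raw_column_sums: dict[str, float]

    def __getitem__(self, diet: str) -> AAProfile:
        return self.profiles[diet]

    @property
    def diets(self) -> list[str]:
        return list(self.profiles)


def read_diet_ratios(path) -> DietRatioTable:
    """Read a diet-ratio TSV (``aa`` column, one molar-ratio column per diet).

    Each column must already be (close to) a molar-fraction profile: a
    pre-normalization sum outside [0.98, 1.02] is rejected, which catches
    columns accidentally given in g/L or percent. Accepted columns are
    renormalized to sum exactly to 1.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[0] != "aa":
        raise ValueError(f"{path}: first column must be 'aa'")
    df = df.set_index("aa")
    missing = set(AMINO_ACIDS) - set(df.index.astype(str))
    if missing:
        raise ValueError(f"{path}: missing amino acids {sorted(missing)}")
    profiles: dict[str, AAProfile] = {}
    sums: dict[str, float] = {}
    lo, hi = RATIO_SUM_WINDOW
    for diet in df.columns:
        col = df[diet].astype(float)
        s = float(col.sum())
        if not (lo <= s <= hi):
            raise ValueError(
                f"{path}: column {diet!r} sums to {s:.4g}, outside [{lo}, {hi}] — "
                "not a molar-ratio column (units mistake?)"
            )
        vec = np.array([col[aa] for aa in AMINO_ACIDS], dtype=float)
        profiles[diet] = normalize(vec, diet)
        sums[diet] = s
    return DietRatioTable(profiles, sums)


def reference_diet_ratios() -> DietRatioTable:
    """The packaged FLYAA / MALEAA / FEMALEAA molar-ratio table."""
    from importlib.resources import files

    return read_diet_ratios(files("exomatch.data").joinpath("diet_ratios.tsv"))


# ---------------------------------------------------------------------------
# molecular weights

def read_mw_table(path):
    """Read an amino-acid molecular-weight TSV (``aa free_mw [salt_mw salt_name]``)."""
    from .formulation import MolecularWeightTable

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"aa", "free_mw"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    free: dict[str, float] = {}
    salt: dict[str, float] = {}
    salt_name: dict[str, str] = {}
    for _, row in df.iterrows():
        aa = str(row["aa"])
        if aa not in AA_INDEX:
            raise ValueError(f"{path}: unknown amino acid {aa!r}")
        mw = float(row["free_mw"])
        if mw <= 0:
            raise ValueError(f"{path}: non-positive free MW for {aa}")
        free[aa] = mw
        if "salt_mw" in df.columns and pd.notna(row.get("salt_mw")):
            smw = float(row["salt_mw"])
            if smw < mw:
                raise ValueError(f"{path}: salt MW below free MW for {aa}")
            salt[aa] = smw
            if "salt_name" in df.columns and pd.notna(row.get("salt_name")):
                salt_name[aa] = str(row["salt_name"])
    return MolecularWeightTable(free_mw=free, salt_mw=salt, salt_name=salt_name)


# ---------------------------------------------------------------------------
# coverage reports

def write_coverage_report(report, path, header_lines=()) -> None:
    """Write a per-AA coverage report as TSV with a summary comment block."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"# diet={report.diet_label} demand={report.demand_label}\n")
        fh.write(
            f"# limiting_aa={report.limiting_aa} "
            f"limiting_coverage={report.limiting_coverage:.6g} "
            f"predicted_gain={report.predicted_gain:.6g}\n"
        )
        fh.write("aa\tessential\tcoverage_pct\tlimiting\n")
        for aa in AMINO_ACIDS:
            cov = report.coverage.get(aa, float("nan"))
            fh.write(
                f"{aa}\t{int(aa in report.essentials)}\t{cov:.9g}\t"
                f"{int(aa == report.limiting_aa)}\n"
            )
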