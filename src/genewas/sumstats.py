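"""Reading, validating, and filtering GWAS summary statistics.

Input files are whitespace/tab-delimited per-SNP association tables in the
PGC "daner" style (columns ``CHR SNP BP A1 A2 INFO OR SE P``); a column-name
mapping (:data:`DEFAULT_DIALECT`) makes other layouts readable.  Quality
control mirrors standard summary-statistic hygiene for LD-aware gene-based
testing: autosomes only, imputation INFO >= 0.9, biallelic single-base
alleles, no strand-ambiguous (A/T, C/G) pairs, no duplicated rsIDs.  The
per-variant Z statistic is ``log(OR) / SE(log OR)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

__all__ = [
    "VariantSummary",
    "DEFAULT_DIALECT",
    "QC_RULE_ORDER",
    "SumstatsConfigError",
    "InvalidRecordError",
    "read_sumstats",
    "write_sumstats",
    "qc_filter",
    "compute_z",
    "compute_z_all",
]

#: default column mapping for PGC daner-style headers
DEFAULT_DIALECT: dict[str, str] = {
    "chrom": "CHR",
    "rsid": "SNP",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "info": "INFO",
    "odds_ratio": "OR",
    "se": "SE",
    "pvalue": "P",
}

_REQUIRED_FIELDS = (
    "chrom",
    "rsid",
    "pos",
    "effect_allele",
    "other_allele",
    "odds_ratio",
    "se",
    "pvalue",
)

#: removal-attribution order: a dropped record is charged to the first rule
#: (in this order) that rejects it
QC_RULE_ORDER = ("non_autosomal", "non_acgt_biallelic", "strand_ambiguous", "low_info", "duplicate_rsid")

_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})
_BASES = {"A", "C", "G", "T"}


class SumstatsConfigError(KeyError):
    """A required column cannot be resolved through the dialect mapping."""


class InvalidRecordError(ValueError):
    """A record violates a hard precondition (e.g. non-positive OR or SE)."""


@dataclass(frozen=True)
class VariantSummary:
    """One GWAS summary-statistic record.

    ``chrom`` is kept as a (normalised) string so sex chromosomes survive
    parsing and are rejected explicitly by :func:`qc_filter`.  ``z`` is absent
    until :func:`compute_z` derives it from the odds ratio and its SE.
    """

    chrom: str
    pos: int
    rsid: str
    effect_allele: str
    other_allele: str
    odds_ratio: float
    se: float
    pvalue: float
    info: float | None = None
    z: float | None = None

    @property
    def is_autosomal(self) -> bool:
        c = self.chrom
        return c.isdigit() and 1 <= int(c) <= 22


def _normalise_chrom(raw: str) -> str:
    c = str(raw).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.endswith(".0"):  # pandas float-parsed chromosome column
        c = c[:-2]
    return c


def read_sumstats(
    path: str | Path, dialect: dict[str, str] | None = None
) -> tuple[list[VariantSummary], int]:
    """Read a delimited summary-statistics file.

    Returns the parsed records in input order together with the number of
    rows dropped because a numeric field could not be parsed.  A required
    column missing from the header raises :class:`SumstatsConfigError`.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    for field in _REQUIRED_FIELDS:
        if dialect[field] not in df.columns:
            raise SumstatsConfigError(
                f"required column {dialect[field]!r} (field {field!r}) not found in {path}"
            )
    has_info = dialect["info"] in df.columns

    records: list[VariantSummary] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        try:
            pos = int(float(row[dialect["pos"]]))
            odds_ratio = float(row[dialect["odds_ratio"]])
            se = float(row[dialect["se"]])
            pvalue = float(row[dialect["pvalue"]])
            info = float(row[dialect["info"]]) if has_info else None
            if any(math.isnan(v) for v in (odds_ratio, se, pvalue)):
                raise ValueError("missing numeric field")
            if info is not None and math.isnan(info):
                info = None
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        records.append(
            VariantSummary(
                chrom=_normalise_chrom(row[dialect["chrom"]]),
                pos=pos,
                rsid=str(row[dialect["rsid"]]).strip(),
                effect_allele=str(row[dialect["effect_allele"]]).strip().upper(),
                other_allele=str(row[dialect["other_allele"]]).strip().upper(),
                odds_ratio=odds_ratio,
                se=se,
                pvalue=pvalue,
                info=info,
            )
        )
    return records, n_dropped


def write_sumstats(
    records: list[VariantSummary], path: str | Path, dialect: dict[str, str] | None = None
) -> None:
    """Write records in daner layout, with a ``Z`` column when computed."""
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    rows = []
    for r in records:
        row = {
            dialect["chrom"]: r.chrom,
            dialect["rsid"]: r.rsid,
            dialect["pos"]: r.pos,
            dialect["effect_allele"]: r.effect_allele,
            dialect["other_allele"]: r.other_allele,
            dialect["info"]: r.info,
            dialect["odds_ratio"]: r.odds_ratio,
            dialect["se"]: r.se,
            dialect["pvalue"]: r.pvalue,
        }
        if r.z is not None:
            row["Z"] = r.z
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _is_strand_ambiguous(a1: str, a2: str) -> bool:
    return {a1, a2} in _AMBIGUOUS_PAIRS


def qc_filter(
    records: list[VariantSummary], info_min: float = 0.9
) -> tuple[list[VariantSummary], dict[str, int]]:
    """Apply the summary-statistic QC rules.

    Retained records are autosomal, single-base biallelic, not strand
    ambiguous, have INFO >= ``info_min`` (missing INFO fails, conservatively),
    and carry a unique rsID (every copy of a duplicated rsID is removed).
    Returns the retained records (input order preserved) and per-rule removal
    counts; ``retained + sum(counts) == len(records)``.
    """
    counts = dict.fromkeys(QC_RULE_ORDER, 0)
    survivors: list[VariantSummary] = []
    for r in records:
        if not r.is_autosomal:
            counts["non_autosomal"] += 1
        elif (
            r.effect_allele not in _BASES
            or r.other_allele not in _BASES
            or r.effect_allele == r.other_allele
        ):
            counts["non_acgt_biallelic"] += 1
        elif _is_strand_ambiguous(r.effect_allele, r.other_allele):
            counts["strand_ambiguous"] += 1
        elif r.info is None or r.info < info_min:
            counts["low_info"] += 1
        else:
            survivors.append(r)

    seen: dict[str, int] = {}
    for r in survivors:
        seen[r.rsid] = seen.get(r.rsid, 0) + 1
    kept = [r for r in survivors if seen[r.rsid] == 1]
    counts["duplicate_rsid"] = len(survivors) - len(kept)
    return kept, counts


def compute_z(record: VariantSummary) -> VariantSummary:
    """Attach ``z = log(OR) / SE`` (natural log) to a record."""
    if record.odds_ratio <= 0 or record.se <= 0:
        raise InvalidRecordError(
            f"{record.rsid}: odds_ratio and se must be positive "
            f"(got OR={record.odds_ratio}, SE={record.se})"
        )
    return replace(record, z=math.log(record.odds_ratio) / record.se)


def compute_z_all(records: list[VariantSummary]) -> list[VariantSummary]:
    """Vector convenience for :func:`compute_z` over a QC-passed collection."""
    return [compute_z(r) for r in records]
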