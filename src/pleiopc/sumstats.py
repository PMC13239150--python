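"""Reading, validation and harmonisation of GWAS summary statistics.

Per-trait association results are carried as :class:`pandas.DataFrame` objects
with one row per variant and the canonical columns listed in
:data:`SUMSTATS_COLUMNS`.  Effect sizes are always stored as ``beta``
(log odds ratio for case-control traits); odds-ratio input columns are
converted on read.  Signed Z-scores are ``beta / se`` oriented to the
record's effect allele.

Harmonisation aligns every record to a shared reference panel so that the
effect allele equals the panel's first allele.  Records whose alleles are
swapped relative to the panel have their effect sign and allele frequency
flipped; records matching only after strand complementation are
complemented first; strand-ambiguous variants (A/T, C/G) are dropped by
default because their orientation cannot be resolved from alleles alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order of a harmonisable summary-statistics frame.
SUMSTATS_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "p_value",
    "eaf",
    "n_case",
    "n_control",
]

#: Columns a row must carry valid values in to be kept.
MANDATORY_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "p_value",
]

VALID_BASES = frozenset("ACGT")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumstatsError(RuntimeError):
    """Fatal problem with a summary-statistics input."""


@dataclass
class HarmonisationReport:
    """Counts of harmonisation outcomes, suitable for a run log."""

    n_input: int = 0
    n_kept: int = 0
    n_flipped: int = 0
    n_complemented: int = 0
    n_dropped_absent: int = 0
    n_dropped_ambiguous: int = 0
    n_dropped_mismatch: int = 0

    def summary(self) -> str:
        return (
            f"harmonised {self.n_input} records: kept={self.n_kept} "
            f"(flipped={self.n_flipped}, complemented={self.n_complemented}); "
            f"dropped: absent={self.n_dropped_absent}, "
            f"ambiguous={self.n_dropped_ambiguous}, "
            f"mismatch={self.n_dropped_mismatch}"
        )


def read_sumstats(
    path,
    column_map: dict[str, str],
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a delimited summary-statistics file into canonical form.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Mapping from canonical names (``snp_id``, ``chrom``, ``pos``,
        ``effect_allele``, ``other_allele``, ``beta`` *or* ``odds_ratio``,
        ``se``, ``p_value``, optionally ``eaf``, ``n_case``, ``n_control``)
        to the column names present in the file.  Exactly one of ``beta``
        and ``odds_ratio`` must be mapped; no auto-detection of the effect
        scale is attempted.
    delimiter
        Field delimiter; default splits on any whitespace.

    Returns
    -------
    pandas.DataFrame
        Canonical columns; rows failing validation are dropped and counted
        in ``df.attrs["n_skipped"]``.

    Raises
    ------
    SumstatsError
        If the file is unreadable, a mapped column is missing, the effect
        scale is not declared unambiguously, or no valid row remains.
    """
    if ("beta" in column_map) == ("odds_ratio" in column_map):
        raise SumstatsError(
            "column_map must declare exactly one of 'beta' or 'odds_ratio'"
        )
    try:
        raw = pd.read_csv(path, sep=delimiter if delimiter else r"\s+", dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SumstatsError(f"cannot read sumstats file {path}: {exc}") from exc

    missing = [c for c in column_map.values() if c not in raw.columns]
    if missing:
        raise SumstatsError(f"{path}: mapped columns absent from header: {missing}")

    df = pd.DataFrame(index=raw.index)
    df["snp_id"] = raw[column_map["snp_id"]].astype(str)
    df["chrom"] = raw[column_map["chrom"]].astype(str)
    df["pos"] = pd.to_numeric(raw[column_map["pos"]], errors="coerce")
    df["effect_allele"] = raw[column_map["effect_allele"]].str.upper()
    df["other_allele"] = raw[column_map["other_allele"]].str.upper()
    if "odds_ratio" in column_map:
        orr = pd.to_numeric(raw[column_map["odds_ratio"]], errors="coerce")
        with np.errstate(divide="ignore", invalid="ignore"):
            df["beta"] = np.log(orr.where(orr > 0))
    else:
        df["beta"] = pd.to_numeric(raw[column_map["beta"]], errors="coerce")
    df["se"] = pd.to_numeric(raw[column_map["se"]], errors="coerce")
    df["p_value"] = pd.to_numeric(raw[column_map["p_value"]], errors="coerce")
    for opt in ("eaf", "n_case", "n_control"):
        if opt in column_map:
            df[opt] = pd.to_numeric(raw[column_map[opt]], errors="coerce")
        else:
            df[opt] = np.nan

    valid = (
        df["beta"].notna()
        & np.isfinite(df["beta"])
        & (df["se"] > 0)
        & (df["p_value"] > 0)
        & (df["p_value"] <= 1)
        & df["pos"].notna()
        & df["effect_allele"].isin(VALID_BASES)
        & df["other_allele"].isin(VALID_BASES)
        & (df["effect_allele"] != df["other_allele"])
    )
    n_skipped = int((~valid).sum())
    df = df[valid].reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    if df.empty:
        raise SumstatsError(f"{path}: no valid rows after validation")
    if n_skipped:
        logger.warning("%s: skipped %d invalid rows", path, n_skipped)
    df = df[SUMSTATS_COLUMNS]
    df.attrs["n_skipped"] = n_skipped
    return df


def read_panel(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a 5-column reference panel (snp_id, allele1, allele2, chrom, pos)."""
    panel = pd.read_csv(
        path,
        sep=delimiter if delimiter else r"\s+",
        dtype={"snp_id": str, "allele1": str, "allele2": str, "chrom": str},
    )
    required = {"snp_id", "allele1", "allele2", "chrom", "pos"}
    if not required.issubset(panel.columns):
        raise SumstatsError(f"panel {path} must have columns {sorted(required)}")
    return validate_panel(panel)


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    if panel["snp_id"].duplicated().any():
        dups = panel.loc[panel["snp_id"].duplicated(), "snp_id"].head(3).tolist()
        raise SumstatsError(f"duplicate snp_ids in reference panel, e.g. {dups}")
    for col in ("allele1", "allele2"):
        if not panel[col].isin(VALID_BASES).all():
            raise SumstatsError(f"invalid bases in panel column {col}")
    return panel.reset_index(drop=True)


def compute_z(records: pd.DataFrame) -> pd.Series:
    """Signed association Z-score, ``beta / se``, oriented to the effect allele."""
    return records["beta"] / records["se"]


def is_strand_ambiguous(a1: pd.Series, a2: pd.Series) -> pd.Series:
    """True for A/T and C/G allele pairs, whose strand cannot be resolved."""
    return a2 == a1.map(_COMPLEMENT)


def harmonise(
    records: pd.DataFrame,
    panel: pd.DataFrame,
    drop_ambiguous: bool = True,
) -> tuple[pd.DataFrame, HarmonisationReport]:
    """Align records to a reference panel's allele orientation.

    Output records have ``effect_allele == panel.allele1`` and
    ``other_allele == panel.allele2``.  Swapped records get ``beta``
    negated and ``eaf`` replaced by ``1 - eaf``; strand-complemented
    records are complemented before alignment; irreconcilable or
    (optionally) strand-ambiguous records are dropped and counted.
    """
    if panel.empty:
        raise SumstatsError("reference panel is empty")
    report = HarmonisationReport(n_input=len(records))
    merged = records.merge(
        panel[["snp_id", "allele1", "allele2"]], on="snp_id", how="left"
    )
    in_panel = merged["allele1"].notna()
    report.n_dropped_absent = int((~in_panel).sum())
    merged = merged[in_panel].copy()

    if drop_ambiguous:
        ambiguous = is_strand_ambiguous(
            merged["effect_allele"], merged["other_allele"]
        )
        report.n_dropped_ambiguous = int(ambiguous.sum())
        merged = merged[~ambiguous].copy()

    ea, oa = merged["effect_allele"], merged["other_allele"]
    ea_c, oa_c = ea.map(_COMPLEMENT), oa.map(_COMPLEMENT)
    a1, a2 = merged["allele1"], merged["allele2"]

    same = (ea == a1) & (oa == a2)
    swapped = (ea == a2) & (oa == a1)
    comp_same = ~same & ~swapped & (ea_c == a1) & (oa_c == a2)
    comp_swapped = ~same & ~swapped & (ea_c == a2) & (oa_c == a1)
    reconciled = same | swapped | comp_same | comp_swapped
    report.n_dropped_mismatch = int((~reconciled).sum())
    merged = merged[reconciled].copy()

    flip = (swapped | comp_swapped)[reconciled]
    comp = (comp_same | comp_swapped)[reconciled]
    report.n_flipped = int(flip.sum())
    report.n_complemented = int(comp.sum())

    merged.loc[flip, "beta"] = -merged.loc[flip, "beta"]
    merged.loc[flip, "eaf"] = 1.0 - merged.loc[flip, "eaf"]
    # After any flip/complement the orientation is by construction the panel's.
    merged["effect_allele"] = merged["allele1"]
    merged["other_allele"] = merged["allele2"]
    out = merged[SUMSTATS_COLUMNS].reset_index(drop=True)
    report.n_kept = len(out)
    logger.info(report.summary())
    return out, report
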