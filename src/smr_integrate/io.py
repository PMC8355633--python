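"""Readers and writers for GWAS and eQTL summary-statistics tables.

Tables are delimited text (TSV by default, gzip-transparent) with
configurable column names: real-world deposits disagree on headers, so a
``column_map`` translates source columns to the canonical names used
throughout the package.  Parsing is total: every input row is either kept
as a valid record or dropped with a counted reason — there is no silent
partial failure.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column order for GWAS tables
GWAS_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pvalue",
]
#: canonical column order for eQTL tables (adds the probe/gene annotation)
EQTL_COLUMNS = GWAS_COLUMNS + ["probe_id", "gene_name"]

#: identity mapping for files already using canonical headers
GENERIC_GWAS_MAP = {c: c for c in GWAS_COLUMNS}
GENERIC_EQTL_MAP = {c: c for c in EQTL_COLUMNS}

RESULT_COLUMNS = [
    "probe_id", "gene_name", "snp_id", "chrom", "z_gwas", "z_eqtl",
    "t_smr", "p_smr", "log_p_smr", "b_xy", "se_bxy", "significant",
]


class ConfigurationError(ValueError):
    """A column map names a column that the file does not contain."""


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's marginal association with the trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    n: int | None = None


@dataclass(frozen=True)
class EqtlRecord:
    """One SNP-probe pair's marginal association with expression."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    probe_id: str
    gene_name: str
    n: int | None = None


@dataclass
class StudyTable:
    """A parsed summary-statistics table with drop accounting.

    Parameters
    ----------
    df
        Records in canonical columns (``GWAS_COLUMNS`` or ``EQTL_COLUMNS``).
    study_label
        Human-readable label, e.g. ``"GUB"`` or ``"Cage"``.
    n_probes
        Distinct probe count (eQTL tables only; ``None`` for GWAS).  For
        thresholding, this may be overridden to the source panel's probe
        count rather than the probes present in the file.
    n_dropped
        Rows removed during parsing (invariant violations, unparseable
        numerics, duplicate collapses).
    drop_reasons
        Per-reason drop tally.
    """

    df: pd.DataFrame
    study_label: str
    n_probes: int | None = None
    n_dropped: int = 0
    drop_reasons: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def is_eqtl(self) -> bool:
        return "probe_id" in self.df.columns

    @property
    def records(self) -> Iterator[GwasRecord | EqtlRecord]:
        cls = EqtlRecord if self.is_eqtl else GwasRecord
        fields = EQTL_COLUMNS if self.is_eqtl else GWAS_COLUMNS
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            yield cls(**{k: d[k] for k in fields})


def _apply_column_map(raw: pd.DataFrame, column_map: dict, required: list[str],
                      path) -> pd.DataFrame:
    missing = [src for src in column_map.values() if src not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: mapped columns not found in file: {missing} "
            f"(available: {list(raw.columns)})"
        )
    df = pd.DataFrame({std: raw[src] for std, src in column_map.items()})
    absent = [c for c in required if c not in df.columns]
    if absent:
        raise ConfigurationError(f"{path}: column_map must map {absent}")
    return df


def _parse_common(df: pd.DataFrame, drop_reasons: Counter) -> pd.DataFrame:
    """Coerce numerics and enforce record invariants, tallying drops."""
    for col in ("beta", "se", "pvalue"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df.get("pos", np.nan), errors="coerce")
    df["chrom"] = df.get("chrom", pd.Series("NA", index=df.index)).astype(str)
    for col in ("snp_id", "effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip().str.upper()
    df["snp_id"] = df["snp_id"].str.lower()  # rsIDs are conventionally lower-case

    bad_numeric = df["beta"].isna() | df["se"].isna()
    drop_reasons["unparseable_beta_or_se"] += int(bad_numeric.sum())
    df = df[~bad_numeric]

    # missing p is tolerated: recompute from |Z| under a normal reference
    if "pvalue" not in df.columns:
        df["pvalue"] = np.nan
    missing_p = df["pvalue"].isna() & (df["se"] > 0)
    if missing_p.any():
        z = df.loc[missing_p, "beta"] / df.loc[missing_p, "se"]
        df.loc[missing_p, "pvalue"] = 2.0 * stats.norm.sf(np.abs(z))

    bad_se = df["se"] <= 0
    drop_reasons["nonpositive_se"] += int(bad_se.sum())
    df = df[~bad_se]

    bad_p = ~((df["pvalue"] > 0) & (df["pvalue"] <= 1))
    drop_reasons["pvalue_out_of_range"] += int(bad_p.sum())
    df = df[~bad_p]

    same_allele = df["effect_allele"] == df["other_allele"]
    drop_reasons["identical_alleles"] += int(same_allele.sum())
    df = df[~same_allele]

    df["pos"] = df["pos"].fillna(-1).astype(np.int64)
    return df


def read_gwas_table(path, column_map: dict | None = None, *,
                    delimiter: str = "\t", study_label: str = "GWAS") -> StudyTable:
    """Read a GWAS summary-statistics table.

    Rows violating record invariants (``se <= 0``, p outside (0, 1],
    identical alleles, unparseable numerics) are dropped and counted in
    :attr:`StudyTable.drop_reasons`.
    """
    column_map = dict(column_map or GENERIC_GWAS_MAP)
    raw = pd.read_csv(path, sep=delimiter, dtype=str, compression="infer")
    required = ["snp_id", "effect_allele", "other_allele", "beta", "se"]
    df = _apply_column_map(raw, column_map, required, path)
    reasons: Counter = Counter()
    df = _parse_common(df, reasons)
    df = df.reindex(columns=GWAS_COLUMNS).reset_index(drop=True)
    n_dropped = len(raw) - len(df)
    if n_dropped:
        logger.info("%s: dropped %d/%d GWAS rows (%s)", path, n_dropped,
                    len(raw), dict(reasons))
    return StudyTable(df=df, study_label=study_label, n_dropped=n_dropped,
                      drop_reasons=reasons)


def read_eqtl_table(path, column_map: dict | None = None, *,
                    delimiter: str = "\t", study_label: str = "eQTL",
                    n_probes: int | None = None) -> StudyTable:
    """Read an eQTL summary-statistics table.

    Duplicate ``(snp_id, probe_id)`` rows are collapsed to the row with the
    smallest p-value (the strongest signal); conflicts are logged.
    ``n_probes`` defaults to the distinct probe count of the parsed file
    but may be supplied to carry the source expression panel's probe count
    for downstream thresholding.
    """
    column_map = dict(column_map or GENERIC_EQTL_MAP)
    raw = pd.read_csv(path, sep=delimiter, dtype=str, compression="infer")
    required = ["snp_id", "effect_allele", "other_allele", "beta", "se",
                "probe_id", "gene_name"]
    df = _apply_column_map(raw, column_map, required, path)
    reasons: Counter = Counter()
    df["probe_id"] = df["probe_id"].astype(str).str.strip()
    df["gene_name"] = df["gene_name"].astype(str).str.strip()
    df = _parse_common(df, reasons)

    # smallest-p row wins among duplicate (snp, probe) keys; stable for exact dups
    before = len(df)
    df = df.sort_values(["pvalue"], kind="stable")
    df = df.drop_duplicates(subset=["snp_id", "probe_id"], keep="first")
    n_dup = before - len(df)
    if n_dup:
        reasons["duplicate_snp_probe"] += n_dup
        logger.info("%s: collapsed %d duplicate (snp, probe) rows", path, n_dup)
    df = df.sort_index().reindex(columns=EQTL_COLUMNS).reset_index(drop=True)

    n_dropped = len(raw) - len(df)
    inferred = int(df["probe_id"].nunique())
    return StudyTable(df=df, study_label=study_label,
                      n_probes=n_probes if n_probes is not None else inferred,
                      n_dropped=n_dropped, drop_reasons=reasons)


def write_study_table(table: StudyTable, path, *, delimiter: str = "\t") -> None:
    """Write a StudyTable back to delimited text in canonical columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = EQTL_COLUMNS if table.is_eqtl else GWAS_COLUMNS
    table.df.reindex(columns=cols).to_csv(path, sep=delimiter, index=False,
                                          float_format="%.15g")


def write_results_table(results: pd.DataFrame, path) -> None:
    """Write SMR results as TSV, lossless to 15 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = results.reindex(columns=[c for c in RESULT_COLUMNS
                                   if c in results.columns or c != "log_p_smr"])
    out.to_csv(path, sep="\t", index=False, float_format="%.15g")


def read_results_table(path) -> pd.DataFrame:
    """Re-read a results TSV written by :func:`write_results_table`."""
    df = pd.read_csv(path, sep="\t")
    if "significant" in df.columns:
        df["significant"] = df["significant"].astype(bool)
    for col in ("probe_id", "gene_name", "snp_id", "chrom"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return df
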