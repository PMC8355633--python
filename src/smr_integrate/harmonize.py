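"""SNP intersection and effect-allele alignment between a GWAS and an eQTL table.

The instrumental-variable step requires both studies to report effects on
the same allele.  The eQTL effect allele is taken as the reference: where
the GWAS reports the opposite allele its beta is sign-flipped, so the
downstream ratio beta_GWAS/beta_eQTL reads as trait change per unit
expression increase.  Matching is by rsID alone (build-agnostic).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import StudyTable

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of a harmonized pair table
PAIR_COLUMNS = [
    "snp_id", "chrom", "pos", "probe_id", "gene_name",
    "effect_allele", "other_allele",
    "beta_gwas", "se_gwas", "beta_eqtl", "se_eqtl",
    "pvalue_gwas", "pvalue_eqtl", "z_gwas", "z_eqtl", "flipped",
]


@dataclass
class MergedDataset:
    """SNP-intersected (and optionally allele-aligned) GWAS x eQTL dataset.

    ``n_probes`` is inherited from the source eQTL table (the multiple-
    testing denominator), not recomputed post-merge.
    """

    label: str
    pairs: pd.DataFrame
    n_probes: int
    aligned: bool = False
    drop_reasons: Counter = field(default_factory=Counter)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_snps(self) -> int:
        return int(self.pairs["snp_id"].nunique()) if len(self.pairs) else 0

    @property
    def n_genes(self) -> int:
        return int(self.pairs["gene_name"].nunique()) if len(self.pairs) else 0

    def gene_set(self) -> set[str]:
        return set(self.pairs["gene_name"]) if len(self.pairs) else set()


def intersect_snps(gwas: StudyTable, eqtl: StudyTable,
                   label: str | None = None) -> MergedDataset:
    """Join eQTL (snp, probe) rows with GWAS rows sharing the same rsID.

    Returns one pair per eQTL ``(snp_id, probe_id)`` whose SNP also occurs
    in the GWAS table, carrying both studies' beta/se and both allele
    codings (alignment happens in :func:`align_alleles`).  An empty
    intersection yields a valid empty dataset with a warning.
    """
    if label is None:
        label = f"{gwas.study_label}_{eqtl.study_label}"
    g = gwas.df.rename(columns={
        "effect_allele": "ea_gwas", "other_allele": "oa_gwas",
        "beta": "beta_gwas", "se": "se_gwas", "pvalue": "pvalue_gwas",
    })[["snp_id", "ea_gwas", "oa_gwas", "beta_gwas", "se_gwas", "pvalue_gwas"]]
    e = eqtl.df.rename(columns={
        "beta": "beta_eqtl", "se": "se_eqtl", "pvalue": "pvalue_eqtl",
    })
    merged = e.merge(g, on="snp_id", how="inner", sort=False)
    if merged.empty:
        logger.warning("%s: empty SNP intersection", label)
    merged["flipped"] = False
    n_probes = eqtl.n_probes if eqtl.n_probes is not None else int(
        e["probe_id"].nunique())
    return MergedDataset(label=label, pairs=merged.reset_index(drop=True),
                         n_probes=n_probes)


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.map(_COMPLEMENT).fillna("N")


def align_alleles(dataset: MergedDataset, policy: str = "strict") -> MergedDataset:
    """Align GWAS effects to the eQTL effect allele.

    Per pair: if the GWAS effect allele equals the eQTL effect allele the
    effect is kept; if it equals the eQTL *other* allele, beta_gwas is
    negated and ``flipped`` set; the same two checks are repeated on the
    strand-complemented GWAS alleles; anything else is irreconcilable and
    dropped.  Palindromic SNPs (A/T, C/G), whose strand cannot be resolved
    from labels, are dropped under ``policy="strict"`` and kept label-wise
    under ``policy="lenient"``.  Idempotent: aligning an aligned dataset
    changes nothing.
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"unknown ambiguity policy: {policy!r}")
    df = dataset.pairs.copy()
    reasons = Counter(dataset.drop_reasons)
    if dataset.aligned or df.empty or "ea_gwas" not in df.columns:
        # already aligned (or nothing to do): normalize columns and return
        out = df.reindex(columns=[c for c in PAIR_COLUMNS if c in df.columns]
                         if not df.empty else PAIR_COLUMNS)
        return MergedDataset(label=dataset.label, pairs=out,
                             n_probes=dataset.n_probes, aligned=True,
                             drop_reasons=reasons)

    ea_e, oa_e = df["effect_allele"], df["other_allele"]
    ea_g, oa_g = df["ea_gwas"], df["oa_gwas"]
    ea_gc, oa_gc = _complement(ea_g), _complement(oa_g)

    palindromic = ea_e == _complement(oa_e)
    same = (ea_g == ea_e) & (oa_g == oa_e)
    swap = (ea_g == oa_e) & (oa_g == ea_e)
    comp_same = (ea_gc == ea_e) & (oa_gc == oa_e)
    comp_swap = (ea_gc == oa_e) & (oa_gc == ea_e)

    keep = same | comp_same
    flip = (swap | comp_swap) & ~keep
    reconcilable = keep | flip
    if policy == "strict":
        ok = reconcilable & ~palindromic
        reasons["palindromic"] += int((reconcilable & palindromic).sum())
    else:
        # lenient: trust labels as-is; palindromic same/swap resolved literally
        ok = reconcilable
    reasons["irreconcilable_alleles"] += int((~reconcilable).sum())

    df = df[ok].copy()
    flip = flip[ok]
    df.loc[flip, "beta_gwas"] = -df.loc[flip, "beta_gwas"]
    df["flipped"] = flip
    df["z_gwas"] = df["beta_gwas"] / df["se_gwas"]
    df["z_eqtl"] = df["beta_eqtl"] / df["se_eqtl"]
    df = df.drop(columns=["ea_gwas", "oa_gwas"])
    df = df.reindex(columns=PAIR_COLUMNS).reset_index(drop=True)

    dropped = int((~ok).sum())
    if dropped:
        logger.info("%s: dropped %d pairs during allele alignment (%s)",
                    dataset.label, dropped, dict(reasons))
    return MergedDataset(label=dataset.label, pairs=df,
                         n_probes=dataset.n_probes, aligned=True,
                         drop_reasons=reasons)


def summarize_merge(dataset: MergedDataset) -> dict:
    """Counts for the merge report: pairs, distinct SNPs/genes/probes, drops."""
    df = dataset.pairs
    return {
        "label": dataset.label,
        "n_pairs": dataset.n_pairs,
        "n_snps": dataset.n_snps,
        "n_genes": dataset.n_genes,
        "n_probes_merged": int(df["probe_id"].nunique()) if len(df) else 0,
        "n_probes_source": dataset.n_probes,
        "n_dropped": int(sum(dataset.drop_reasons.values())),
        "drop_reasons": dict(dataset.drop_reasons),
        "aligned": dataset.aligned,
    }
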