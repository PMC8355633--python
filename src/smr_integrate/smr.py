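"""The SMR statistic and test: Z-scores, T_SMR, chi-square p-values,
probe-count Bonferroni thresholds, Wald-ratio effects, and risk-gene calls.

The test asks whether a SNP's trait association is mediated through gene
expression.  With Z = beta/se from each study, the statistic

    T_SMR = (Z_GWAS^2 * Z_eQTL^2) / (Z_GWAS^2 + Z_eQTL^2)

is referred to a chi-square distribution with one degree of freedom; a
pair is significant when P_SMR falls below alpha divided by the probe
count of the eQTL expression panel.  T_SMR equals half the harmonic mean
of the two squared Z-scores, hence is bounded by the weaker arm:
T_SMR <= min(Z_GWAS^2, Z_eQTL^2).

P-values are carried in log space internally (``log_p_smr``) so that
values far below the smallest positive double survive serialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import MergedDataset

RESULT_SORT_KEY = ["log_p_smr", "probe_id", "snp_id"]


@dataclass(frozen=True)
class SmrResult:
    """One SNP-probe pair's SMR test outcome."""

    snp_id: str
    probe_id: str
    gene_name: str
    z_gwas: float
    z_eqtl: float
    t_smr: float
    p_smr: float
    b_xy: float
    se_bxy: float
    significant: bool


@dataclass(frozen=True)
class ThresholdPolicy:
    """Family-wise Bonferroni control over the probes of one eQTL panel."""

    n_probes: int
    alpha: float = 0.05

    def __post_init__(self):
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.n_probes < 1:
            raise ValueError(f"n_probes must be >= 1, got {self.n_probes}")

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_probes


def z_score(beta, se):
    """Standardized association strength: beta divided by its standard error."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    out = beta / se
    return out if out.ndim else float(out)

def t_smr(z_gwas, z_eqtl):
    """T_SMR = (z1^2 z2^2)/(z1^2 + z2^2); 0 when both arms are 0.

    Symmetric in its arguments, invariant to the sign of either, and
    bounded above by min(z1^2, z2^2).
    """
    a2 = np.square(np.asarray(z_gwas, dtype=float))
    b2 = np.square(np.asarray(z_eqtl, dtype=float))
    denom = a2 + b2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, a2 * b2 / np.where(denom > 0, denom, 1.0), 0.0)
    return out if out.ndim else float(out)


def p_smr(t):
    """Upper-tail chi-square (df = 1) probability of the statistic."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("T_SMR must be non-negative")
    out = stats.chi2.sf(t, df=1)
    return out if out.ndim else float(out)


def log_p_smr(t):
    """Natural log of :func:`p_smr`, stable for very large statistics."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("T_SMR must be non-negative")
    # for df = 1, sf(t) = 2 * Phi-bar(sqrt(t)); the normal logsf stays
    # finite far beyond where the chi-square sf underflows
    out = np.log(2.0) + stats.norm.logsf(np.sqrt(t))
    return out if out.ndim else float(out)


def bonferroni_threshold(alpha: float, n_probes: int) -> float:
    """Significance threshold alpha / n_probes for one eQTL panel."""
    return ThresholdPolicy(n_probes=n_probes, alpha=alpha).threshold


def wald_ratio(beta_gwas, se_gwas, beta_eqtl, se_eqtl):
    """Two-stage ratio estimate b_xy = beta_GWAS / beta_eQTL and its SE.

    The standard error is first-order delta method,
    |b_xy| * sqrt((se_g/beta_g)^2 + (se_e/beta_e)^2); at beta_gwas = 0 the
    limit se_gwas/|beta_eqtl| is used.  Raises when beta_eqtl is 0 (scalar)
    or returns NaN element-wise (arrays).
    """
    bg = np.asarray(beta_gwas, dtype=float)
    sg = np.asarray(se_gwas, dtype=float)
    be = np.asarray(beta_eqtl, dtype=float)
    se = np.asarray(se_eqtl, dtype=float)
    scalar = bg.ndim == 0 and be.ndim == 0
    if scalar and be == 0:
        raise ZeroDivisionError("beta_eqtl is zero: Wald ratio undefined")
    if np.any(sg <= 0) or np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    with np.errstate(invalid="ignore", divide="ignore"):
        bxy = np.where(be != 0, bg / np.where(be != 0, be, 1.0), np.nan)
        rel = np.sqrt(
            np.where(bg != 0, np.square(sg / np.where(bg != 0, bg, 1.0)), 0.0)
            + np.square(se / np.where(be != 0, be, 1.0))
        )
        se_bxy = np.where(
            bg != 0, np.abs(bxy) * rel,
            np.where(be != 0, sg / np.abs(np.where(be != 0, be, 1.0)), np.nan),
        )
    if scalar:
        return float(bxy), float(se_bxy)
    return bxy, se_bxy


def select_instruments(dataset: MergedDataset, mode: str = "all_pairs",
                       p_cut: float = 5e-8) -> pd.DataFrame:
    """Choose the SNP-probe pairs to test.

    ``all_pairs`` tests every harmonized pair.  ``top_per_probe`` keeps,
    per probe, the single pair with the smallest eQTL p among those with
    p <= p_cut (ties broken by larger |z_eqtl|, then lexicographic rsID) —
    the canonical one-instrument-per-gene behaviour.
    """
    df = dataset.pairs
    if mode == "all_pairs":
        return df.copy()
    if mode != "top_per_probe":
        raise ValueError(f"unknown instrument mode: {mode!r}")
    eligible = df[df["pvalue_eqtl"] <= p_cut].copy()
    if eligible.empty:
        return eligible
    eligible["_absz"] = eligible["z_eqtl"].abs()
    eligible = eligible.sort_values(
        ["probe_id", "pvalue_eqtl", "_absz", "snp_id"],
        ascending=[True, True, False, True], kind="stable")
    top = eligible.groupby("probe_id", sort=False).head(1)
    return top.drop(columns="_absz").reset_index(drop=True)


def run_smr_dataset(dataset: MergedDataset, policy: ThresholdPolicy | None = None,
                    mode: str = "all_pairs", p_cut: float = 5e-8) -> pd.DataFrame:
    """Run the SMR test over one harmonized dataset.

    Returns one row per selected instrument pair with the statistic,
    p-value (plus log p), Wald-ratio effect, and the significance call at
    ``policy.threshold``, sorted by ascending p.
    """
    if not dataset.aligned:
        raise ValueError("dataset must be allele-aligned before testing")
    if policy is None:
        policy = ThresholdPolicy(n_probes=max(dataset.n_probes, 1))
    pairs = select_instruments(dataset, mode=mode, p_cut=p_cut)
    res = pairs.reindex(columns=["probe_id", "gene_name", "snp_id", "chrom"]).copy()
    if pairs.empty:
        for c in ("z_gwas", "z_eqtl", "t_smr", "p_smr", "log_p_smr",
                  "b_xy", "se_bxy"):
            res[c] = pd.Series(dtype=float)
        res["significant"] = pd.Series(dtype=bool)
        return res
    zg = pairs["z_gwas"].to_numpy()
    ze = pairs["z_eqtl"].to_numpy()
    t = t_smr(zg, ze)
    logp = log_p_smr(t)
    bxy, se_bxy = wald_ratio(pairs["beta_gwas"].to_numpy(),
                             pairs["se_gwas"].to_numpy(),
                             pairs["beta_eqtl"].to_numpy(),
                             pairs["se_eqtl"].to_numpy())
    res["z_gwas"] = zg
    res["z_eqtl"] = ze
    res["t_smr"] = t
    res["p_smr"] = np.exp(logp)
    res["log_p_smr"] = logp
    res["b_xy"] = bxy
    res["se_bxy"] = se_bxy
    # compare in log space so calls survive p-values that underflow to 0
    res["significant"] = logp < np.log(policy.threshold)
    res = res.sort_values(RESULT_SORT_KEY, kind="stable").reset_index(drop=True)
    return res


def call_risk_genes(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate significant pairs into gene-level risk calls.

    One row per distinct gene among significant results, with its best
    (smallest) p, the number of supporting SNPs, and their rsIDs.
    """
    cols = ["gene_name", "n_snps", "snp_ids", "best_p_smr"]
    if results.empty or not results["significant"].any():
        return pd.DataFrame(columns=cols)
    sig = results[results["significant"]]
    sig = sig.sort_values(RESULT_SORT_KEY, kind="stable")
    grouped = sig.groupby("gene_name", sort=False)
    out = pd.DataFrame({
        "gene_name": [g for g, _ in grouped],
        "n_snps": grouped["snp_id"].nunique().to_numpy(),
        "snp_ids": grouped["snp_id"].agg(
            lambda s: ",".join(dict.fromkeys(s))).to_numpy(),
        "best_p_smr": grouped["p_smr"].min().to_numpy(),
    })
    return out.sort_values(["best_p_smr", "gene_name"],
                           kind="stable").reset_index(drop=True)
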