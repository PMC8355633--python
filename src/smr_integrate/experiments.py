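"""Monte-Carlo experiments on the SMR test, run through the full pipeline.

Every replicate generates a fresh pair of summary tables from the
two-cohort model, harmonizes them, and runs the test — so these
experiments exercise the same code path real data would take.  They back
the calibration, power, and effect-recovery checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .harmonize import align_alleles, intersect_snps
from .simulate import SimulationConfig, generate_dataset_pair
from .smr import ThresholdPolicy, run_smr_dataset, wald_ratio, call_risk_genes


#: single strong instrument, null expression->trait effect; sized so the
#: eQTL arm is decisively significant (|Z| well above 6) in every replicate
CALIBRATION_CONFIG = SimulationConfig(
    m_snps=1, causal_index=0, ld_rho=0.0, b_zx=0.7, b_xy=0.0,
    n_eqtl=1000, n_gwas=1000, n_null_probes=0, n_probes_total=1000,
)

#: the power/recovery study conditions: 50-SNP cis region, strong
#: instrument, both cohorts at n = 5000
POWER_CONFIG = SimulationConfig(b_zx=0.5, n_eqtl=5000, n_gwas=5000)


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def run_replicate(config: SimulationConfig, policy: ThresholdPolicy | None = None
                  ) -> tuple[pd.DataFrame, dict]:
    """One full pipeline pass: simulate, harmonize, test.

    Returns the SMR result table (sorted by p) and the truth record.
    """
    gwas, eqtl, truth = generate_dataset_pair(config)
    merged = align_alleles(intersect_snps(gwas, eqtl))
    results = run_smr_dataset(merged, policy=policy)
    return results, truth


def _causal_row(results: pd.DataFrame, truth: dict) -> pd.Series:
    mask = ((results["probe_id"] == truth["causal_probe_id"])
            & (results["snp_id"] == truth["causal_snp_id"]))
    return results[mask].iloc[0]


def type_i_error(n_replicates: int = 2000, alpha: float = 0.05,
                 seed: int = 0, config: SimulationConfig = CALIBRATION_CONFIG
                 ) -> dict:
    """Empirical rejection rate of the causal-pair test under b_xy = 0.

    With a strong instrument the statistic is dominated by the GWAS arm,
    so under the null the rejection rate at nominal ``alpha`` should match
    ``alpha``.  Returns the rate, the binomial 95% interval, and the median
    eQTL |Z| (to confirm the strong-instrument regime).
    """
    assert config.b_xy == 0.0, "type-I error is defined under the null"
    seeds = _replicate_seeds(seed, n_replicates)
    rejected = 0
    abs_z = np.empty(n_replicates)
    for i, s in enumerate(seeds):
        results, truth = run_replicate(config.replace(seed=int(s)))
        row = _causal_row(results, truth)
        abs_z[i] = abs(row["z_eqtl"])
        rejected += bool(row["p_smr"] < alpha)
    rate = rejected / n_replicates
    half = 1.96 * np.sqrt(alpha * (1 - alpha) / n_replicates)
    return {
        "rate": rate,
        "n_replicates": n_replicates,
        "alpha": alpha,
        "binomial_ci95": (alpha - half, alpha + half),
        "median_abs_z_eqtl": float(np.median(abs_z)),
    }


def power_curve(b_xy_grid=(0.0, 0.1, 0.2, 0.4), n_replicates: int = 1000,
                seed: int = 0, config: SimulationConfig = POWER_CONFIG
                ) -> dict[float, float]:
    """Empirical power to call the causal gene, per expression->trait effect.

    A replicate counts as a discovery when the causal gene appears among
    the risk-gene calls at the probe-count Bonferroni threshold
    (alpha / n_probes_total).
    """
    policy = ThresholdPolicy(n_probes=config.n_probes_total)
    out: dict[float, float] = {}
    for b_xy in b_xy_grid:
        seeds = _replicate_seeds(seed + int(round(1000 * b_xy)) + 1, n_replicates)
        hits = 0
        for s in seeds:
            results, truth = run_replicate(
                config.replace(b_xy=float(b_xy), seed=int(s)), policy=policy)
            calls = call_risk_genes(results)
            hits += truth["causal_gene"] in set(calls["gene_name"])
        out[float(b_xy)] = hits / n_replicates
    return out


def bxy_recovery(n_replicates: int = 500, seed: int = 0,
                 config: SimulationConfig | None = None) -> dict:
    """Distribution of the causal-pair Wald ratio around the true b_xy."""
    if config is None:
        config = POWER_CONFIG.replace(b_xy=0.3)
    seeds = _replicate_seeds(seed + 97, n_replicates)
    estimates = np.empty(n_replicates)
    for i, s in enumerate(seeds):
        results, truth = run_replicate(config.replace(seed=int(s)))
        estimates[i] = _causal_row(results, truth)["b_xy"]
    return {
        "median_bxy_hat": float(np.median(estimates)),
        "true_b_xy": config.b_xy,
        "n_replicates": n_replicates,
        "estimates": estimates,
    }


def causal_rank_fraction(n_replicates: int = 200, seed: int = 0,
                         config: SimulationConfig | None = None) -> dict:
    """How often the causal probe tops the p-value ranking."""
    if config is None:
        config = POWER_CONFIG.replace(b_xy=0.3)
    seeds = _replicate_seeds(seed + 193, n_replicates)
    first = 0
    for s in seeds:
        results, truth = run_replicate(config.replace(seed=int(s)))
        first += results["probe_id"].iloc[0] == truth["causal_probe_id"]
    return {"fraction_ranked_first": first / n_replicates,
            "n_replicates": n_replicates}
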