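"""Two-cohort generative model for paired GWAS and eQTL summary statistics.

The model emulates the study design the pipeline consumes: two disjoint
cohorts genotyped at a shared panel of cis SNPs; an expression trait
driven by one causal SNP (plus optional pure-noise probes); and a
quantitative disease trait driven, optionally, by the genetic component of
that expression.  Each cohort is reduced to per-SNP marginal least-squares
beta/SE/p tables — exactly the summary statistics real deposits provide.

Genotypes: per-SNP allele frequencies are drawn once per configuration and
shared by both cohorts; linkage disequilibrium between adjacent SNPs comes
from a first-order autoregressive latent Gaussian per haplotype,
thresholded at the allele frequency, so dosages are Hardy-Weinberg with
tunable neighbour correlation.

The SNP panel itself (rsIDs, positions, allele labels) is a fixed
reference shared by every simulation, so tables generated under different
configurations still harmonize with each other; per-configuration
randomness covers frequencies, cohort draws, and which SNPs the GWAS
reports on the opposite allele (exercising downstream allele alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .io import StudyTable, EQTL_COLUMNS, GWAS_COLUMNS

_PANEL_SEED = 715_517          # fixed: the panel is a shared reference
_STRUCT_SALT = 8_316_427       # separates structural draws from cohort draws

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the two-cohort generative model.

    Parameters
    ----------
    m_snps
        Number of cis SNPs in the simulated region.
    maf_range
        Interval the per-SNP minor-allele frequencies are drawn from.
    ld_rho
        Adjacent-SNP latent correlation in [0, 1); 0 gives independent SNPs.
    causal_index
        Index of the SNP driving expression of the causal probe.
    b_zx
        SNP -> expression effect, per effect allele, in expression-SD units.
    b_xy
        Expression -> trait effect (trait SD per expression SD); 0 = null.
    n_eqtl, n_gwas
        Disjoint cohort sizes (two-sample design).
    n_probes_total
        Probe count of the emulated expression panel — the Bonferroni
        denominator — which may exceed the probes actually simulated.
    n_null_probes
        Extra probes with pure-noise expression (no causal SNP).
    flip_fraction
        Expected fraction of SNPs the GWAS table reports on the opposite
        effect allele (with beta negated), to exercise harmonization.
    palindromic_fraction
        Fraction of panel SNPs given A/T or C/G alleles.
    pleiotropy_beta
        Optional direct SNP -> trait effect at the causal SNP, bypassing
        expression; demonstrates that the test cannot separate causality
        from such pleiotropy.
    seed
        Seed for every random draw in the pair of studies.
    """

    m_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.5
    causal_index: int | None = None  # default: middle of the panel
    b_zx: float = 0.5
    b_xy: float = 0.0
    n_eqtl: int = 5000
    n_gwas: int = 5000
    n_probes_total: int = 1000
    n_null_probes: int = 9
    flip_fraction: float = 0.5
    palindromic_fraction: float = 0.0
    pleiotropy_beta: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.causal_index is None:
            object.__setattr__(self, "causal_index", self.m_snps // 2)
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (0 <= self.causal_index < self.m_snps):
            raise ValueError("causal_index must lie within the SNP panel")
        if self.n_eqtl < 10 or self.n_gwas < 10:
            raise ValueError("cohort sizes must be >= 10")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_probes_total < 1 + self.n_null_probes:
            raise ValueError("n_probes_total must cover the simulated probes")

    def replace(self, **kw) -> "SimulationConfig":
        d = asdict(self)
        d["maf_range"] = tuple(d["maf_range"])
        d.update(kw)
        return SimulationConfig(**d)


@dataclass
class CohortData:
    """Individual-level draws for one cohort (never leaves the generator
    except for testing: the pipeline sees only summary tables)."""

    genotypes: np.ndarray                  # individuals x SNPs, dosages 0/1/2
    expression: np.ndarray | None = None   # eQTL cohort only
    trait: np.ndarray | None = None        # GWAS cohort only


@lru_cache(maxsize=8)
def snp_panel(m_snps: int, palindromic_fraction: float = 0.0) -> pd.DataFrame:
    """The fixed reference panel: rsID, chrom, pos, effect/other alleles."""
    rng = np.random.default_rng(_PANEL_SEED)
    n_pal = int(round(palindromic_fraction * m_snps))
    pal_idx = set(rng.choice(m_snps, size=n_pal, replace=False)) if n_pal else set()
    rows = []
    for i in range(m_snps):
        pool = _PALINDROMIC if i in pal_idx else _NONPALINDROMIC
        ea, oa = pool[rng.integers(len(pool))]
        rows.append((f"rs{100000 + i}", "4", 90_600_000 + 1500 * i, ea, oa))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos",
                                       "effect_allele", "other_allele"])


def _structural_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STRUCT_SALT,)))


def allele_frequencies(config: SimulationConfig) -> np.ndarray:
    """Effect-allele frequencies, drawn once per configuration."""
    rng = _structural_rng(config)
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.m_snps)


def gwas_flip_mask(config: SimulationConfig) -> np.ndarray:
    """Which SNPs the GWAS table reports on the opposite allele."""
    rng = _structural_rng(config)
    rng.uniform(size=config.m_snps)  # skip the frequency draws
    return rng.uniform(size=config.m_snps) < config.flip_fraction


def simulate_genotypes(config: SimulationConfig, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw an n x m dosage matrix (0/1/2) with AR(1) latent LD.

    Each haplotype is an AR(1) standard-Gaussian sequence across SNPs
    (lag-one correlation ``ld_rho``) thresholded at Phi^-1(f_j), so every
    SNP is Hardy-Weinberg at its frequency and neighbours are correlated.
    """
    freqs = allele_frequencies(config)
    thresholds = stats.norm.ppf(freqs)
    m = config.m_snps
    scale = np.sqrt(1.0 - config.ld_rho ** 2)
    dosage = np.zeros((n, m), dtype=np.int8)
    for _hap in range(2):
        e = rng.standard_normal((n, m))
        z = np.empty((n, m))
        z[:, 0] = e[:, 0]
        for j in range(1, m):
            z[:, j] = config.ld_rho * z[:, j - 1] + scale * e[:, j]
        dosage += (z < thresholds).astype(np.int8)
    return dosage


def _marginal_regression(G: np.ndarray, y: np.ndarray):
    """Per-SNP simple least squares of y on dosage: beta, se, p (t test)."""
    n = len(y)
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    sxy = Gc.T @ yc
    syy = float(yc @ yc)
    poly = sxx <= 0  # monomorphic in this cohort: no slope estimable
    sxx_safe = np.where(poly, 1.0, sxx)
    beta = np.where(poly, 0.0, sxy / sxx_safe)
    rss = np.maximum(syy - beta * sxy, 0.0)
    sigma2 = rss / max(n - 2, 1)
    se = np.sqrt(sigma2 / sxx_safe)
    se = np.where(poly | (se <= 0), np.nan, se)
    with np.errstate(invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=max(n - 2, 1))
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)  # keep p in (0, 1]
    return beta, se, p


def _probe_names(k: int) -> tuple[str, str]:
    return f"PRB{k:05d}", f"GENE{k:04d}"


def simulate_eqtl_study(config: SimulationConfig,
                        rng: np.random.Generator,
                        genotypes: np.ndarray | None = None) -> StudyTable:
    """Simulate the eQTL cohort and reduce it to a summary table.

    Probe 0 is the causal probe (expression = b_zx * causal dosage + N(0,1));
    ``n_null_probes`` further probes are pure noise.  Every probe is
    regressed on every panel SNP, one row per (SNP, probe).  The reported
    ``n_probes`` is the emulated panel size ``n_probes_total``.
    """
    if genotypes is None:
        genotypes = simulate_genotypes(config, config.n_eqtl, rng)
    panel = snp_panel(config.m_snps, config.palindromic_fraction)
    n = genotypes.shape[0]
    blocks = []
    for k in range(1 + config.n_null_probes):
        if k == 0:
            expr = (config.b_zx * genotypes[:, config.causal_index]
                    + rng.standard_normal(n))
        else:
            expr = rng.standard_normal(n)
        beta, se, p = _marginal_regression(genotypes.astype(float), expr)
        probe_id, gene_name = _probe_names(k)
        block = panel.copy()
        block["beta"] = beta
        block["se"] = se
        block["pvalue"] = p
        block["probe_id"] = probe_id
        block["gene_name"] = gene_name
        blocks.append(block)
    df = pd.concat(blocks, ignore_index=True)
    ok = df["se"].notna()
    dropped = int((~ok).sum())
    df = df[ok].reindex(columns=EQTL_COLUMNS).reset_index(drop=True)
    return StudyTable(df=df, study_label="SimEqtl",
                      n_probes=config.n_probes_total, n_dropped=dropped)


def simulate_gwas_study(config: SimulationConfig,
                        rng: np.random.Generator,
                        genotypes: np.ndarray | None = None) -> StudyTable:
    """Simulate the independent GWAS cohort and reduce it to a summary table.

    The latent expression is regenerated in this cohort from the same
    genetic model; only its genetic component propagates to the trait
    (trait = b_xy * b_zx * causal dosage + noise, plus any direct
    pleiotropic effect).  SNPs in the configuration's flip mask are
    reported on the opposite allele with beta negated.
    """
    if genotypes is None:
        genotypes = simulate_genotypes(config, config.n_gwas, rng)
    panel = snp_panel(config.m_snps, config.palindromic_fraction)
    n = genotypes.shape[0]
    genetic_expr = config.b_zx * genotypes[:, config.causal_index]
    trait = (config.b_xy * genetic_expr
             + config.pleiotropy_beta * genotypes[:, config.causal_index]
             + rng.standard_normal(n))
    beta, se, p = _marginal_regression(genotypes.astype(float), trait)

    flip = gwas_flip_mask(config)
    df = panel.copy()
    ea = df["effect_allele"].to_numpy().copy()
    oa = df["other_allele"].to_numpy().copy()
    df["effect_allele"] = np.where(flip, oa, ea)
    df["other_allele"] = np.where(flip, ea, oa)
    df["beta"] = np.where(flip, -beta, beta)
    df["se"] = se
    df["pvalue"] = p
    ok = df["se"].notna()
    dropped = int((~ok).sum())
    df = df[ok].reindex(columns=GWAS_COLUMNS).reset_index(drop=True)
    return StudyTable(df=df, study_label="SimGwas", n_dropped=dropped)


def generate_dataset_pair(config: SimulationConfig
                          ) -> tuple[StudyTable, StudyTable, dict]:
    """Generate a matched (GWAS table, eQTL table, ground truth) triple.

    The two cohorts are disjoint draws seeded from ``config.seed``; the
    truth record identifies the causal SNP and probe and the generating
    effects, for recovery scoring.
    """
    ss = np.random.SeedSequence(config.seed)
    child_e, child_g = ss.spawn(2)
    eqtl = simulate_eqtl_study(config, np.random.default_rng(child_e))
    gwas = simulate_gwas_study(config, np.random.default_rng(child_g))
    panel = snp_panel(config.m_snps, config.palindromic_fraction)
    probe_id, gene_name = _probe_names(0)
    truth = {
        "causal_snp_id": panel["snp_id"].iloc[config.causal_index],
        "causal_probe_id": probe_id,
        "causal_gene": gene_name,
        "b_zx": config.b_zx,
        "b_xy": config.b_xy,
        "pleiotropy_beta": config.pleiotropy_beta,
        "n_flipped": int(gwas_flip_mask(config).sum()),
        "seed": config.seed,
    }
    return gwas, eqtl, truth
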