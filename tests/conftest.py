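import numpy as np
import pandas as pd
import pytest

from smr_integrate.harmonize import MergedDataset
from smr_integrate.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_config():
    """A seconds-scale simulation: 8 cis SNPs, 300 per cohort, 3 probes."""
    return SimulationConfig(m_snps=8, causal_index=3, n_eqtl=300, n_gwas=300,
                            n_null_probes=2, n_probes_total=50, b_zx=0.8,
                            b_xy=0.4, seed=11)


def write_tsv(path, header, rows, delimiter="\t"):
    lines = [delimiter.join(header)]
    lines += [delimiter.join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def gwas_file(tmp_path):
    header = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
              "beta", "se", "pvalue"]
    rows = [
        ["rs1", "4", 100, "A", "G", 0.30, 0.10, 0.0027],
        ["rs2", "4", 200, "T", "C", -0.05, 0.08, 0.53],
        ["rs3", "4", 300, "G", "A", 0.12, 0.05, 0.016],
    ]
    return write_tsv(tmp_path / "gwas.tsv", header, rows)


@pytest.fixture
def eqtl_file(tmp_path):
    header = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
              "beta", "se", "pvalue", "probe_id", "gene_name"]
    rows = [
        ["rs1", "4", 100, "A", "G", 0.9, 0.10, 1e-19, "p1", "SNCA"],
        ["rs2", "4", 200, "T", "C", 0.4, 0.09, 8.7e-6, "p1", "SNCA"],
        ["rs2", "4", 200, "T", "C", -0.2, 0.09, 0.026, "p2", "MTPAP"],
        ["rs4", "4", 400, "C", "T", 0.5, 0.11, 5.4e-6, "p2", "MTPAP"],
    ]
    return write_tsv(tmp_path / "eqtl.tsv", header, rows)


def make_merged(pairs: pd.DataFrame, n_probes=10, label="TEST",
                aligned=True) -> MergedDataset:
    defaults = {"chrom": "4", "pos": 1, "gene_name": "G1",
                "effect_allele": "A", "other_allele": "G",
                "pvalue_gwas": 0.5, "pvalue_eqtl": 1e-9, "flipped": False}
    df = pairs.copy()
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    if "z_gwas" not in df.columns:
        df["z_gwas"] = df["beta_gwas"] / df["se_gwas"]
    if "z_eqtl" not in df.columns:
        df["z_eqtl"] = df["beta_eqtl"] / df["se_eqtl"]
    return MergedDataset(label=label, pairs=df, n_probes=n_probes,
                         aligned=aligned)
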