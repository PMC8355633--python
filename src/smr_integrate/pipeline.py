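"""End-to-end workflow: N GWAS x M eQTL tables -> harmonized datasets ->
SMR results -> threshold, discovery, and overlap reports.

Every GWAS x eQTL combination becomes one dataset labelled
``<GWAS>_<eQTL>``.  Outputs are plain TSV plus one JSON manifest (row
counts and a config hash); reruns with identical inputs and config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .harmonize import align_alleles, intersect_snps, summarize_merge
from .overlap import overlap_rate_matrix, render_report
from .smr import ThresholdPolicy, call_risk_genes, run_smr_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative description of one full run.

    ``gwas_inputs`` and ``eqtl_inputs`` are lists of mappings with keys
    ``label`` and ``path`` (plus optional ``column_map``, ``delimiter``,
    and — for eQTL — ``n_probes``, either an integer carrying the source
    panel's probe count or ``"infer"`` to count probes in the file).
    """

    gwas_inputs: list[dict]
    eqtl_inputs: list[dict]
    out_dir: str = "smr_out"
    alpha: float = 0.05
    instrument_mode: str = "all_pairs"
    p_cut: float = 5e-8
    ambiguity_policy: str = "strict"
    overlap_definition: str = "min_fraction"
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        labels = ([g["label"] for g in self.gwas_inputs]
                  + [e["label"] for e in self.eqtl_inputs])
        if len(labels) != len(set(labels)):
            raise ValueError("input labels must be unique")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {k: raw.pop(k) for k in list(raw)
                 if k in cls.__dataclass_fields__}
        return cls(**known, **({"extra": raw} if raw else {}))

    def to_dict(self) -> dict:
        return {
            "gwas_inputs": self.gwas_inputs,
            "eqtl_inputs": self.eqtl_inputs,
            "out_dir": str(self.out_dir),
            "alpha": self.alpha,
            "instrument_mode": self.instrument_mode,
            "p_cut": self.p_cut,
            "ambiguity_policy": self.ambiguity_policy,
            "overlap_definition": self.overlap_definition,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _check_inputs(config: PipelineConfig) -> None:
    for entry in list(config.gwas_inputs) + list(config.eqtl_inputs):
        if not Path(entry["path"]).exists():
            raise FileNotFoundError(
                f"input '{entry['label']}' not found: {entry['path']}")


def _load_tables(config: PipelineConfig):
    gwas_tables, eqtl_tables = {}, {}
    for entry in config.gwas_inputs:
        gwas_tables[entry["label"]] = sio.read_gwas_table(
            entry["path"], entry.get("column_map"),
            delimiter=entry.get("delimiter", "\t"),
            study_label=entry["label"])
    for entry in config.eqtl_inputs:
        n_probes = entry.get("n_probes", "infer")
        n_probes = None if n_probes in (None, "infer") else int(n_probes)
        eqtl_tables[entry["label"]] = sio.read_eqtl_table(
            entry["path"], entry.get("column_map"),
            delimiter=entry.get("delimiter", "\t"),
            study_label=entry["label"], n_probes=n_probes)
    return gwas_tables, eqtl_tables


def write_demo_inputs(data_dir, seed: int = 0, *,
                      n_eqtl: int = 4000, n_gwas: int = 4000) -> "PipelineConfig":
    """Write a 2-GWAS x 4-eQTL synthetic input grid and its run config.

    Emulates the study layout of two disease GWAS integrated with four
    tissue eQTL panels of different probe counts.  Returns a
    :class:`PipelineConfig` whose ``run_all`` produces the full 8-dataset
    grid under ``data_dir/out``.
    """
    from .simulate import SimulationConfig, generate_dataset_pair

    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    eqtl_panels = {"BLOOD": 1000, "BRAIN": 800, "CD4": 500, "CD8": 400}
    base = dict(n_eqtl=n_eqtl, n_gwas=n_gwas, b_zx=0.5, b_xy=0.3)
    gwas_inputs, eqtl_inputs = [], []
    for i, g_label in enumerate(("GWA", "GWB")):
        config = SimulationConfig(seed=seed + i, **base)
        gwas, _, _ = generate_dataset_pair(config)
        path = data_dir / f"gwas.{g_label}.tsv"
        sio.write_study_table(gwas, path)
        gwas_inputs.append({"label": g_label, "path": str(path)})
    for j, (e_label, n_probes) in enumerate(eqtl_panels.items()):
        config = SimulationConfig(seed=seed + 10 + j,
                                  n_probes_total=n_probes, **base)
        _, eqtl, _ = generate_dataset_pair(config)
        path = data_dir / f"eqtl.{e_label}.tsv"
        sio.write_study_table(eqtl, path)
        eqtl_inputs.append({"label": e_label, "path": str(path),
                            "n_probes": n_probes})
    return PipelineConfig(gwas_inputs=gwas_inputs, eqtl_inputs=eqtl_inputs,
                          out_dir=str(data_dir / "out"), seed=seed)


def run_all(config: PipelineConfig) -> dict:
    """Run the full workflow; returns (and writes) the run manifest."""
    _check_inputs(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gwas_tables, eqtl_tables = _load_tables(config)

    manifest: dict = {"config_hash": config.config_hash(),
                      "config": config.to_dict(), "datasets": {},
                      "outputs": []}
    threshold_rows, discovery_rows = [], []
    gene_sets: dict[str, set] = {}

    for g_label, gwas in gwas_tables.items():
        for e_label, eqtl in eqtl_tables.items():
            label = f"{g_label}_{e_label}"
            merged = align_alleles(intersect_snps(gwas, eqtl, label=label),
                                   policy=config.ambiguity_policy)
            policy = ThresholdPolicy(n_probes=max(merged.n_probes, 1),
                                     alpha=config.alpha)
            results = run_smr_dataset(merged, policy=policy,
                                      mode=config.instrument_mode,
                                      p_cut=config.p_cut)
            calls = call_risk_genes(results)
            gene_sets[label] = merged.gene_set()

            merged_path = out_dir / f"merged.{label}.tsv"
            merged.pairs.to_csv(merged_path, sep="\t", index=False,
                                float_format="%.15g")
            results_path = out_dir / f"smr.{label}.tsv"
            sio.write_results_table(results, results_path)
            manifest["outputs"] += [str(merged_path), str(results_path)]

            threshold_rows.append({"dataset": label,
                                   "n_probes": policy.n_probes,
                                   "threshold": policy.threshold})
            if calls.empty:
                discovery_rows.append({"dataset": label, "n_genes": 0,
                                       "gene_name": "-", "best_p_smr": "-",
                                       "snp_ids": "-"})
            else:
                for _, row in calls.iterrows():
                    discovery_rows.append({
                        "dataset": label, "n_genes": len(calls),
                        "gene_name": row["gene_name"],
                        "best_p_smr": row["best_p_smr"],
                        "snp_ids": row["snp_ids"]})

            summary = summarize_merge(merged)
            summary.update(n_results=len(results),
                           n_significant=int(results["significant"].sum())
                           if len(results) else 0,
                           n_genes_called=len(calls))
            manifest["datasets"][label] = summary
            logger.info("%s: %d pairs, %d significant, %d genes called",
                        label, summary["n_pairs"], summary["n_significant"],
                        summary["n_genes_called"])

    thresholds = pd.DataFrame(threshold_rows)
    thresholds_path = out_dir / "thresholds.tsv"
    thresholds.to_csv(thresholds_path, sep="\t", index=False,
                      float_format="%.15g")
    discoveries = pd.DataFrame(discovery_rows)
    discoveries_path = out_dir / "discoveries.tsv"
    discoveries.to_csv(discoveries_path, sep="\t", index=False,
                       float_format="%.15g")
    manifest["outputs"] += [str(thresholds_path), str(discoveries_path)]

    # overlap matrices: eQTL sources compared under each fixed GWAS, and
    # the two GWAS compared on each shared eQTL source
    for g_label in gwas_tables:
        labels = [f"{g_label}_{e}" for e in eqtl_tables]
        if len(labels) >= 2:
            matrix = overlap_rate_matrix(
                {l: gene_sets[l] for l in labels},
                definition=config.overlap_definition)
            paths = render_report(matrix, out_dir / f"overlap.{g_label}")
            manifest["outputs"] += [str(paths["tsv"]), str(paths["png"])]
    if len(gwas_tables) >= 2:
        rows = []
        g_labels = list(gwas_tables)
        for e_label in eqtl_tables:
            for i in range(len(g_labels)):
                for j in range(i + 1, len(g_labels)):
                    a = gene_sets[f"{g_labels[i]}_{e_label}"]
                    b = gene_sets[f"{g_labels[j]}_{e_label}"]
                    rows.append({"eqtl": e_label,
                                 "dataset_a": f"{g_labels[i]}_{e_label}",
                                 "dataset_b": f"{g_labels[j]}_{e_label}",
                                 "n_overlap": len(a & b),
                                 "n_a": len(a), "n_b": len(b)})
        shared_path = out_dir / "overlap.same_eqtl.tsv"
        pd.DataFrame(rows).to_csv(shared_path, sep="\t", index=False)
        manifest["outputs"].append(str(shared_path))

    manifest["n_datasets"] = len(manifest["datasets"])
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
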