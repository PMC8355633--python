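"""Cross-dataset gene-overlap analyses: pairwise counts and rate matrices.

Two overlap-rate definitions are offered: ``min_fraction`` (intersection
over the smaller set — the default, reading as "what fraction of the
smaller gene list is shared") and ``jaccard`` (intersection over union).
Gene identity is exact symbol match; no aliasing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFINITIONS = ("min_fraction", "jaccard")


@dataclass
class OverlapMatrix:
    """Symmetric pairwise gene-overlap counts and rates for labelled sets."""

    labels: list[str]
    counts: np.ndarray   # int, counts[i, j] = |set_i & set_j|
    rates: np.ndarray    # float in [0, 1]
    sizes: np.ndarray    # int, |set_i|
    definition: str

    def to_frame(self, which: str = "rates") -> pd.DataFrame:
        arr = getattr(self, which)
        return pd.DataFrame(arr, index=self.labels, columns=self.labels)


def overlap_counts(a: set, b: set) -> tuple[int, int, int]:
    """Exact intersection cardinality plus both set sizes."""
    return len(a & b), len(a), len(b)


def _rate(n_common: int, n_a: int, n_b: int, definition: str) -> float:
    if definition == "jaccard":
        union = n_a + n_b - n_common
        if union == 0:
            warnings.warn("overlap rate of two empty sets defined as 0")
            return 0.0
        return n_common / union
    if definition == "min_fraction":
        smaller = min(n_a, n_b)
        if smaller == 0:
            if n_a == 0 and n_b == 0:
                warnings.warn("overlap rate of two empty sets defined as 0")
            return 0.0
        return n_common / smaller
    raise ValueError(f"unknown overlap definition: {definition!r}")


def overlap_rate_matrix(collection: dict[str, set],
                        definition: str = "min_fraction") -> OverlapMatrix:
    """Pairwise overlap rates over a labelled collection of gene sets."""
    if len(collection) < 2:
        raise ValueError("need at least two gene sets")
    if definition not in DEFINITIONS:
        raise ValueError(f"unknown overlap definition: {definition!r}")
    labels = list(collection)
    k = len(labels)
    counts = np.zeros((k, k), dtype=int)
    rates = np.zeros((k, k), dtype=float)
    sizes = np.array([len(collection[l]) for l in labels], dtype=int)
    for i in range(k):
        for j in range(i, k):
            n_common, n_a, n_b = overlap_counts(collection[labels[i]],
                                                collection[labels[j]])
            counts[i, j] = counts[j, i] = n_common
            r = _rate(n_common, n_a, n_b, definition)
            rates[i, j] = rates[j, i] = r
    return OverlapMatrix(labels=labels, counts=counts, rates=rates,
                         sizes=sizes, definition=definition)


def render_report(matrix: OverlapMatrix, out_prefix) -> dict:
    """Write the rate matrix as TSV and as a heatmap image.

    ``out_prefix`` gains ``.tsv`` and ``.png`` suffixes; returns the paths.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv_path = out_prefix.parent / (out_prefix.name + ".tsv")
    png_path = out_prefix.parent / (out_prefix.name + ".png")

    frame = matrix.to_frame("rates")
    frame.to_csv(tsv_path, sep="\t", float_format="%.15g",
                 index_label="dataset")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(matrix.labels) + 2,
                                    1.0 * len(matrix.labels) + 1.5))
    im = ax.imshow(matrix.rates, vmin=0.0, vmax=1.0, cmap="viridis")
    ax.set_xticks(range(len(matrix.labels)), matrix.labels,
                  rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.labels)), matrix.labels)
    for i in range(len(matrix.labels)):
        for j in range(len(matrix.labels)):
            ax.text(j, i, f"{matrix.rates[i, j]:.2f}\n({matrix.counts[i, j]})",
                    ha="center", va="center", fontsize=8,
                    color="w" if matrix.rates[i, j] < 0.6 else "k")
    ax.set_title(f"Gene overlap ({matrix.definition})")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return {"tsv": tsv_path, "png": png_path}


def read_rate_matrix(path) -> pd.DataFrame:
    """Round-trip reader for the TSV written by :func:`render_report`."""
    return pd.read_csv(path, sep="\t", index_col="dataset")
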