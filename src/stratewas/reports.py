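"""Figure-style outputs: p-value histograms and context-enrichment bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_pvalue_histogram(pvalues, path, title: str = "", bins: int = 50) -> None:
    """Density histogram of per-CpG p-values.

    The dashed line at density 1 is the Uniform(0, 1) distribution expected
    when methylation carries no association signal.
    """
    p = np.asarray(list(pvalues), dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(p, bins=bins, range=(0, 1), density=True, color="#4878CF",
            edgecolor="white", linewidth=0.3)
    ax.axhline(1.0, linestyle="--", color="black", linewidth=1.2)
    ax.set_xlabel("p-value")
    ax.set_ylabel("density")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_context_enrichment(tables: dict[str, pd.DataFrame], path, title: str = "") -> None:
    """Grouped bars of the percentage of probes per category for each set.

    ``tables`` maps a set label to a feature_enrichment table; query bars
    are annotated with '*' (significantly enriched) or '^' (significantly
    depleted).
    """
    fig, ax = plt.subplots(figsize=(7, 4))
    labels = list(tables)
    features = list(tables[labels[0]]["feature"])
    width = 0.8 / max(1, len(labels))
    x = np.arange(len(features))
    for i, label in enumerate(labels):
        tab = tables[label].set_index("feature").reindex(features)
        pct = 100.0 * tab["query_in"] / tab["query_total"]
        bars = ax.bar(x + i * width, pct, width=width, label=label)
        for bar, (_, row) in zip(bars, tab.iterrows()):
            if bool(row.get("significant", False)):
                mark = "*" if row["direction"] == "enriched" else "^"
                ax.text(bar.get_x() + bar.get_width() / 2, bar.get_height(),
                        mark, ha="center", va="bottom", fontsize=11)
    ax.set_xticks(x + width * (len(labels) - 1) / 2)
    ax.set_xticklabels(features, rotation=30, ha="right")
    ax.set_ylabel("% of probes in category")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
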