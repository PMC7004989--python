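"""Optional summary bar charts for protocol comparisons."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .metrics import ProtocolSummary, summary_frame


def plot_protocol_summary(summaries: Sequence[ProtocolSummary], path: str | Path) -> None:
    """One bar panel per metric, protocols on the x axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = summary_frame(summaries).set_index("protocol")
    panels = [
        ("total_mapping_rate_pct", "Total mapping rate (%)"),
        ("transcriptomic_mapping_ratio_pct", "Transcriptomic mapping ratio (%)"),
        ("mean_genes_detected", "Genes detected"),
        ("reproducibility", "Reproducibility (Pearson r)"),
        ("accuracy", "Accuracy vs bulk (Pearson r)"),
    ]
    fig, axes = plt.subplots(1, len(panels), figsize=(4 * len(panels), 3.5))
    for ax, (column, title) in zip(axes, panels):
        df[column].plot.bar(ax=ax, color="steelblue")
        ax.set_title(title, fontsize=9)
        ax.set_xlabel("")
        ax.tick_params(axis="x", rotation=45, labelsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
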