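"""Plot helpers: Bland–Altman agreement and per-group metric panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import AgreementResult

__all__ = ["bland_altman_plot", "group_metric_panel"]


def bland_altman_plot(
    values_a, values_b, agreement: AgreementResult, path: str | Path,
    label_a: str = "high_res", label_b: str = "bh", metric: str = "median T2 (ms)",
) -> None:
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    mean = (a + b) / 2.0
    diff = a - b
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=18, alpha=0.8)
    for y, style in ((agreement.bias, "-"), (agreement.loa_low, "--"), (agreement.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel(f"mean of {label_a} and {label_b}")
    ax.set_ylabel(f"{label_a} − {label_b}")
    ax.set_title(
        f"{metric}: bias {agreement.bias:.2f}, "
        f"Spearman r {agreement.spearman_r:.2f} (p={agreement.spearman_p:.3g})"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def group_metric_panel(
    records: pd.DataFrame, metric: str, path: str | Path, by: str = "subtype"
) -> None:
    """Box panels of one metric per group, one subplot per protocol."""
    protocols = sorted(records["protocol"].unique())
    fig, axes = plt.subplots(1, len(protocols), figsize=(5 * len(protocols), 4),
                             squeeze=False)
    for ax, proto in zip(axes[0], protocols):
        sub = records[records["protocol"] == proto]
        groups = sorted(sub[by].dropna().unique(), key=str)
        data = [sub.loc[sub[by] == g, metric].dropna() for g in groups]
        ax.boxplot(data, tick_labels=[str(g) for g in groups])
        ax.set_title(proto)
        ax.set_ylabel(metric)
        ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
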