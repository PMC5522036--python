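"""Figure helpers (matplotlib, Agg-safe): burden boxplots, volcano, MDS."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def burden_boxplot(groups: dict, path) -> None:
    """Boxplots of per-sample SEM totals per tissue group."""
    fig, ax = plt.subplots(figsize=(5, 4))
    names = list(groups)
    ax.boxplot([np.asarray(groups[g], dtype=float) for g in names], tick_labels=names)
    ax.set_ylabel("SEMs per sample")
    ax.set_yscale("symlog")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def volcano(site_result, path) -> None:
    """Delta (control - case) vs -log10 p per probe."""
    t = site_result.table
    fig, ax = plt.subplots(figsize=(5, 4))
    with np.errstate(divide="ignore"):
        y = -np.log10(np.maximum(t["p_value"].to_numpy(), 1e-300))
    ax.scatter(t["delta"], y, s=4, alpha=0.4, linewidths=0)
    ax.set_xlabel("mean methylation difference (control - case)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def mds_scatter(coords, labels, path) -> None:
    """First two MDS dimensions colored by tissue label."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab in labels.dropna().unique():
        sel = labels.reindex(coords.index) == lab
        ax.scatter(coords.loc[sel, "dim1"], coords.loc[sel, "dim2"], s=14, label=lab)
    ax.set_xlabel("MDS dim 1")
    ax.set_ylabel("MDS dim 2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
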