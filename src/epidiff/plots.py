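"""Optional matplotlib figures for the standard reports."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_density(density: pd.DataFrame, path: str | Path) -> None:
    """Allele-frequency density, full panel vs subset, one panel per population."""
    pops = density["population"].unique()
    fig, axes = plt.subplots(1, len(pops), figsize=(5 * len(pops), 4), squeeze=False)
    for ax, pop in zip(axes[0], pops):
        sub = density[density["population"] == pop]
        for snp_set, style in (("all", "-"), ("subset", "--")):
            s = sub[sub["snp_set"] == snp_set]
            centers = (s["bin_left"] + s["bin_right"]) / 2
            ax.plot(centers, s["density"], style, label=snp_set)
        ax.set_title(pop)
        ax.set_xlabel("allele-A frequency")
        ax.set_ylabel("density")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mds(coords: pd.DataFrame, path: str | Path) -> None:
    """Component-1/2 scatter coloured by population."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for pop, sub in coords.groupby("population"):
        ax.scatter(sub["component1"], sub["component2"], s=8, label=pop, alpha=0.6)
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ranking(ranking: pd.DataFrame, path: str | Path) -> None:
    """Gene-differentiation metric along the genome, deciles highlighted."""
    frame = ranking.sort_values(["chromosome", "gene_id"]).reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(8, 4))
    colors = frame.apply(
        lambda r: "tab:red" if r.top_decile else
        ("tab:blue" if r.bottom_decile else "0.6"),
        axis=1,
    )
    ax.scatter(frame.index, frame["metric"], c=colors, s=12)
    ax.set_xlabel("genes (genome order)")
    ax.set_ylabel("gene-differentiation metric")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
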