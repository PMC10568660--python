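"""Secondary plotting helpers. Every figure has a TSV twin; nothing asserts on images."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def genome_scan(table: pd.DataFrame, value_col: str, path: Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for chrom, sub in table.groupby("chrom", sort=False):
        mid = (sub["start"] + sub["end"]) / 2 + offset
        ax.scatter(mid, sub[value_col], s=6)
        ticks.append(float(mid.mean()))
        labels.append(str(chrom))
        offset += int(sub["end"].max())
    ax.set_xticks(ticks, labels)
    ax.set_ylabel(value_col)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pca_scatter(coords: pd.DataFrame, groups: dict[str, str], path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for group in sorted(set(groups.values())):
        sel = coords[coords["sample"].map(groups) == group]
        ax.scatter(sel["PC1"], sel["PC2"], label=group)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def balance_heatmap(per_group: pd.DataFrame, path: Path) -> None:
    pivot = per_group.pivot(index="name", columns="group", values="frequency")
    fig, ax = plt.subplots(figsize=(4 + 0.5 * pivot.shape[1], 1 + 0.4 * pivot.shape[0]))
    im = ax.imshow(pivot.to_numpy(), cmap="viridis", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    fig.colorbar(im, ax=ax, label="allele frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
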