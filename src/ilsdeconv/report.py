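"""Deterministic figure tables and plots for the pipeline's outputs.

Every figure is backed by a plain TSV table computed here (tests assert on
the tables); rendering to PNG is a thin matplotlib layer with no RNG.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .diffexpr import NormalizationFactors, cpm


@dataclass(frozen=True)
class VolcanoSpec:
    lfc_threshold: float = 0.6
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0 or self.fdr_threshold <= 0:
            raise ValueError("volcano thresholds must be positive")


@dataclass(frozen=True)
class HeatmapSpec:
    top_n: int = 50

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


def volcano_classify(
    de_table: pd.DataFrame, spec: VolcanoSpec = VolcanoSpec()
) -> pd.Series:
    """Classify genes as up / down / ns for volcano colouring.

    up iff log2FC > threshold and FDR < threshold (strict inequalities);
    down symmetric; everything else ns. The classes partition the genes.
    """
    sig = de_table["FDR"] < spec.fdr_threshold
    up = sig & (de_table["log2FC"] > spec.lfc_threshold)
    down = sig & (de_table["log2FC"] < -spec.lfc_threshold)
    out = pd.Series("ns", index=de_table.index, name="class")
    out[up] = "up"
    out[down] = "down"
    return out


def top50_heatmap_matrix(
    de_table: pd.DataFrame,
    counts: pd.DataFrame,
    norm: NormalizationFactors,
    groups: Sequence[str],
    spec: HeatmapSpec = HeatmapSpec(),
    fdr: float = 0.05,
) -> Tuple[pd.DataFrame, Dict]:
    """Z-scored log2 CPM matrix of the top-N DEGs.

    Genes ranked by ascending FDR (ties: ascending p, then gene_id);
    rows z-scored (constant rows guarded to zeros); columns ordered
    controls first, then the comparison group. Returns (matrix, meta).
    """
    sig = de_table[de_table["FDR"] < fdr]
    if sig.empty:
        raise ValueError("no significant genes to draw")
    ranked = sig.assign(_gene=sig.index).sort_values(
        ["FDR", "p_value", "_gene"], kind="mergesort"
    )
    top = list(ranked.index[: spec.top_n])
    meta = {"n_requested": spec.top_n, "n_used": len(top)}

    order = np.argsort([0 if g == groups[0] else 1 for g in groups], kind="stable")
    cols = [counts.columns[i] for i in order]
    log_cpm = np.log2(cpm(counts, norm).loc[top, cols] + 0.5)
    values = log_cpm.to_numpy()
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=top, columns=cols), meta


def deg_count_bars(
    de_tables: Mapping[str, pd.DataFrame], fdr: float = 0.05
) -> pd.DataFrame:
    """Up/down DEG counts per contrast at the FDR threshold."""
    rows = []
    for name, table in de_tables.items():
        sig = table["FDR"] < fdr
        rows.append(
            {
                "contrast": name,
                "up": int((sig & (table["log2FC"] > 0)).sum()),
                "down": int((sig & (table["log2FC"] < 0)).sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rendering


def render_volcano(
    de_table: pd.DataFrame, spec: VolcanoSpec, path: Path, title: str
) -> None:
    classes = volcano_classify(de_table, spec)
    colors = {"up": "#c0392b", "down": "#2980b9", "ns": "#bbbbbb"}
    fig, ax = plt.subplots(figsize=(5, 4))
    with np.errstate(divide="ignore"):
        neglog = -np.log10(np.maximum(de_table["FDR"], 1e-300))
    for cls in ("ns", "down", "up"):
        mask = classes == cls
        ax.scatter(
            de_table.loc[mask, "log2FC"], neglog[mask], s=6,
            c=colors[cls], label=cls, linewidths=0,
        )
    ax.axhline(-np.log10(spec.fdr_threshold), ls=":", c="k", lw=0.7)
    for x in (-spec.lfc_threshold, spec.lfc_threshold):
        ax.axvline(x, ls=":", c="k", lw=0.7)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 FDR")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_heatmap(matrix: pd.DataFrame, path: Path, title: str) -> None:
    fig, ax = plt.subplots(
        figsize=(4.5, max(3.0, 0.09 * len(matrix) + 1.0))
    )
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(matrix.columns)))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, label="row z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_deg_bars(bars: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    x = np.arange(len(bars))
    ax.bar(x - 0.2, bars["up"], width=0.4, color="#c0392b", label="up")
    ax.bar(x + 0.2, bars["down"], width=0.4, color="#2980b9", label="down")
    ax.set_xticks(x)
    ax.set_xticklabels(bars["contrast"], rotation=30, ha="right", fontsize=7)
    ax.set_ylabel("significant DEGs (FDR < 0.05)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_venn2(
    unique_a: int, shared: int, unique_b: int,
    label_a: str, label_b: str, path: Path, title: str,
) -> None:
    """Two-set Venn from precomputed counts, drawn with circle patches."""
    fig, ax = plt.subplots(figsize=(4, 3.2))
    for cx, color in ((-0.35, "#c0392b"), (0.35, "#2980b9")):
        ax.add_patch(
            plt.Circle((cx, 0), 0.75, alpha=0.35, color=color)
        )
    ax.text(-0.75, 0, str(unique_a), ha="center", va="center")
    ax.text(0, 0, str(shared), ha="center", va="center")
    ax.text(0.75, 0, str(unique_b), ha="center", va="center")
    ax.text(-0.55, 0.9, label_a, ha="center", fontsize=8)
    ax.text(0.55, 0.9, label_b, ha="center", fontsize=8)
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.1, 1.2)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_top_pathways(top: pd.DataFrame, path: Path, title: str) -> None:
    if top.empty:
        return
    fig, ax = plt.subplots(figsize=(5, max(2.5, 0.25 * len(top))))
    with np.errstate(divide="ignore"):
        vals = -np.log10(np.maximum(top["adj_p"].to_numpy(), 1e-300))
    ax.barh(np.arange(len(top)), vals, color="#27ae60")
    ax.set_yticks(np.arange(len(top)))
    ax.set_yticklabels(top["pathway_name"], fontsize=6)
    ax.invert_yaxis()
    ax.set_xlabel("-log10 adjusted p")
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_qpcr_panel(panel: pd.DataFrame, path: Path) -> None:
    genes = list(dict.fromkeys(panel["gene"]))
    genotypes = list(dict.fromkeys(panel["genotype"]))
    x = np.arange(len(genes))
    width = 0.8 / max(len(genotypes), 1)
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(genes)), 3.5))
    for i, genotype in enumerate(genotypes):
        sub = panel[panel["genotype"] == genotype].set_index("gene")
        vals = [sub["fold_change"].get(g, np.nan) for g in genes]
        bars = ax.bar(
            x + (i - (len(genotypes) - 1) / 2) * width, vals,
            width=width, label=genotype,
        )
        for j, g in enumerate(genes):
            if bool(sub["significant"].get(g, False)):
                ax.annotate(
                    "*", (x[j] + (i - (len(genotypes) - 1) / 2) * width,
                          vals[j]),
                    ha="center", fontsize=10,
                )
    ax.axhline(1.0, ls=":", c="k", lw=0.7)
    ax.set_yscale("log", base=2)
    ax.set_xticks(x)
    ax.set_xticklabels(genes, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("fold change (2^-ddCt)")
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
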