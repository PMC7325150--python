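"""Static diagnostic plots for multi-contrast enrichment results.

All output is vector PDF (one multi-page file per call).  The same figure
builders are reused by the HTML report, which embeds them as raster images.
Plotting is refused above 20 contrasts: pairwise panels grow quadratically
and stop being readable well before that.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.backends.backend_pdf import PdfPages
from scipy.stats import gaussian_kde

from .enrichment import ResultTable
from .exceptions import PlotLimitError, ValidationError

__all__ = ["plot_global", "plot_set_detail", "kde_grid", "MAX_PLOT_CONTRASTS"]

MAX_PLOT_CONTRASTS = 20

_SIG_COLOR = "#1f77b4"  # significance-selected sets (blue)
_EFF_COLOR = "#d62728"  # effect-size-selected sets (red)


def _check_contrasts(k: int) -> None:
    if k > MAX_PLOT_CONTRASTS:
        raise PlotLimitError(
            f"plotting supports at most {MAX_PLOT_CONTRASTS} contrasts, got {k}"
        )


def kde_grid(
    x: np.ndarray,
    y: np.ndarray,
    gridsize: int = 80,
    pad: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian KDE (Scott bandwidth) of 2-D points on a regular grid.

    The grid extends *pad* marginal bandwidths beyond the data range so the
    density mass is essentially all on the grid (it integrates to 1 within
    about a percent).  Returns (xs, ys, Z) with Z indexed [iy, ix].
    """
    pts = np.vstack([x, y])
    kde = gaussian_kde(pts, bw_method="scott")
    bw = np.sqrt(np.diag(kde.covariance))
    xs = np.linspace(x.min() - pad * bw[0], x.max() + pad * bw[0], gridsize)
    ys = np.linspace(y.min() - pad * bw[1], y.max() + pad * bw[1], gridsize)
    X, Y = np.meshgrid(xs, ys)
    Z = kde(np.vstack([X.ravel(), Y.ravel()])).reshape(X.shape)
    return xs, ys, Z


def _fig_score_scatter(profile: pd.DataFrame, a: str, b: str) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(profile[a], profile[b], s=2, alpha=0.3, color="0.3", rasterized=True)
    ax.axhline(0, lw=0.5, color="0.6")
    ax.axvline(0, lw=0.5, color="0.6")
    ax.set_xlabel(f"DE score: {a}")
    ax.set_ylabel(f"DE score: {b}")
    ax.set_title("Per-gene DE scores")
    return fig


def _fig_rank_contour(ranked: pd.DataFrame, a: str, b: str) -> plt.Figure:
    xs, ys, Z = kde_grid(ranked[a].to_numpy(), ranked[b].to_numpy())
    fig, ax = plt.subplots(figsize=(5.4, 5))
    cs = ax.contourf(xs, ys, Z, levels=12, cmap="viridis")
    fig.colorbar(cs, ax=ax, label="density")
    ax.set_xlabel(f"centred rank: {a}")
    ax.set_ylabel(f"centred rank: {b}")
    ax.set_title("Ranked profile density")
    return fig


def _fig_size_histogram(result: ResultTable) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(result.table["setSize"], bins=30, color="0.4")
    ax.set_xlabel("effective set size")
    ax.set_ylabel("gene sets")
    ax.set_title("Gene set sizes")
    return fig


def _fig_effect_significance(result: ResultTable) -> plt.Figure:
    tab = result.table
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    sig = -np.log10(tab["p.manovaFDR"].clip(lower=np.finfo(float).tiny))
    called = tab["p.manovaFDR"] < 0.05
    ax.scatter(tab.loc[~called, "S"], sig[~called], s=8, color="0.6", label="FDR >= 0.05")
    ax.scatter(tab.loc[called, "S"], sig[called], s=8, color=_EFF_COLOR, label="FDR < 0.05")
    ax.set_xlabel("effect size S")
    ax.set_ylabel(r"$-\log_{10}$(FDR)")
    ax.set_title("Effect size vs significance")
    ax.legend(frameon=False, fontsize=8)
    return fig


def _fig_s_pairs(result: ResultTable) -> plt.Figure:
    cols = [f"s.{c}" for c in result.contrasts]
    k = len(cols)
    fig, axes = plt.subplots(k, k, figsize=(1.9 * k + 1, 1.9 * k + 1), squeeze=False)
    tab = result.table
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            ax = axes[i][j]
            if i == j:
                ax.hist(tab[ci], bins=25, color="0.4")
            else:
                ax.scatter(tab[cj], tab[ci], s=4, alpha=0.5, color="0.3")
                ax.axhline(0, lw=0.4, color="0.7")
                ax.axvline(0, lw=0.4, color="0.7")
            if i == k - 1:
                ax.set_xlabel(cj, fontsize=8)
            if j == 0:
                ax.set_ylabel(ci, fontsize=8)
            ax.tick_params(labelsize=6)
    fig.suptitle("Enrichment scores s across contrasts")
    return fig


def global_figures(
    result: ResultTable,
    ranked: pd.DataFrame,
    profile: pd.DataFrame | None = None,
) -> list[tuple[str, plt.Figure]]:
    """Build the global diagnostic figures as (label, figure) pairs."""
    _check_contrasts(ranked.shape[1])
    figs: list[tuple[str, plt.Figure]] = []
    for a, b in itertools.combinations(ranked.columns, 2):
        if profile is not None:
            figs.append((f"scores_{a}_vs_{b}", _fig_score_scatter(profile, a, b)))
        figs.append((f"rank_density_{a}_vs_{b}", _fig_rank_contour(ranked, a, b)))
    figs.append(("set_sizes", _fig_size_histogram(result)))
    figs.append(("effect_vs_significance", _fig_effect_significance(result)))
    if len(result.contrasts) >= 2:
        figs.append(("s_pairs", _fig_s_pairs(result)))
    return figs


def plot_global(
    result: ResultTable,
    ranked: pd.DataFrame,
    path,
    profile: pd.DataFrame | None = None,
) -> list[str]:
    """Write the global diagnostics to a multi-page PDF; returns page labels."""
    figs = global_figures(result, ranked, profile)
    with PdfPages(path) as pdf:
        for _, fig in figs:
            pdf.savefig(fig)
            plt.close(fig)
    return [label for label, _ in figs]


def set_detail_figures(
    ranked: pd.DataFrame,
    members: Iterable[str],
    name: str,
) -> list[tuple[str, plt.Figure]]:
    """Member-vs-background figures for one gene set.

    Per contrast pair: background density contour with member genes overlaid
    as a scatter; plus one violin panel of member centred ranks per contrast
    against the grey background distribution.
    """
    mask = ranked.index.isin(set(members))
    figs: list[tuple[str, plt.Figure]] = []
    for a, b in itertools.combinations(ranked.columns, 2):
        xs, ys, Z = kde_grid(ranked[a].to_numpy(), ranked[b].to_numpy())
        fig, ax = plt.subplots(figsize=(5.2, 5))
        ax.contourf(xs, ys, Z, levels=10, cmap="Greys")
        ax.scatter(
            ranked.loc[mask, a], ranked.loc[mask, b],
            s=14, color=_EFF_COLOR, edgecolor="white", linewidth=0.3,
            label=f"{name} ({mask.sum()} genes)",
        )
        ax.set_xlabel(f"centred rank: {a}")
        ax.set_ylabel(f"centred rank: {b}")
        ax.legend(frameon=False, fontsize=8)
        ax.set_title(name, fontsize=10)
        figs.append((f"{name}_{a}_vs_{b}", fig))

    fig, ax = plt.subplots(figsize=(1.2 * ranked.shape[1] + 2, 4))
    positions = np.arange(1, ranked.shape[1] + 1)
    n = len(ranked)
    background = [ranked[c].to_numpy() for c in ranked.columns]
    member_vals = [ranked.loc[mask, c].to_numpy() for c in ranked.columns]
    bg = ax.violinplot(background, positions=positions, widths=0.8, showextrema=False)
    for body in bg["bodies"]:
        body.set_facecolor("0.85")
        body.set_alpha(1.0)
    mv = ax.violinplot(member_vals, positions=positions, widths=0.5, showmedians=True)
    for body in mv["bodies"]:
        body.set_facecolor("0.2")
        body.set_alpha(0.8)
    ax.axhline(0, lw=0.5, color="0.6")
    ax.set_xticks(positions)
    ax.set_xticklabels(ranked.columns, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("centred rank")
    ax.set_ylim(-n / 2 * 1.05, n / 2 * 1.05)
    ax.set_title(f"{name}: members vs background", fontsize=10)
    figs.append((f"{name}_violin", fig))
    return figs


def plot_set_detail(
    result: ResultTable,
    ranked: pd.DataFrame,
    library,
    path,
    set_names: Sequence[str] | None = None,
) -> list[str]:
    """Write per-set detail plots (contour, scatter, violin) to a PDF.

    *set_names* defaults to the sets selected by the result's priority mode
    (top N).  An empty selection writes nothing and succeeds.
    """
    _check_contrasts(ranked.shape[1])
    if set_names is None:
        set_names = result.detailed_sets
    tested = set(result.table["set"])
    unknown = [s for s in set_names if s not in tested]
    if unknown:
        raise ValidationError(f"unknown gene sets in selection: {unknown[:5]}")
    if not set_names:
        return []
    labels: list[str] = []
    with PdfPages(path) as pdf:
        for name in set_names:
            for label, fig in set_detail_figures(ranked, library[name].members, name):
                pdf.savefig(fig)
                plt.close(fig)
                labels.append(label)
    return labels
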