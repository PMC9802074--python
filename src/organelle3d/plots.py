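"""Summary figures for a dark/light comparison report.

Figures mirror the standard presentation for this kind of analysis:
per-class volume and sphericity distributions with median/quartile lines,
surface-area-vs-volume scatter against the theoretical sphere curve,
per-site proximity-area histograms with an all-sites inset, and per-cell
bar-with-points summaries of site counts and total areas.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .io import CONTACT_CLASSES
from .morphometry import sphere_surface_area

_COLORS = {"dark": "#3b6fb6", "light": "#e8882f"}


def _median_quartiles(ax, values, x, color):
    if len(values) == 0:
        return
    med = np.median(values)
    q1, q3 = np.percentile(values, [25, 75])
    ax.hlines(med, x - 0.3, x + 0.3, color=color, lw=2, linestyles="dashed")
    ax.hlines([q1, q3], x - 0.2, x + 0.2, color=color, lw=1,
              linestyles="dotted")


def violin_by_condition(ax, df, metric, title):
    for i, cond in enumerate(("dark", "light")):
        v = df.loc[df["condition"] == cond, metric].dropna().to_numpy()
        if len(v) == 0:
            continue
        jitter = (np.arange(len(v)) % 7 - 3) * 0.03
        ax.plot(np.full(len(v), i) + jitter, v, "o", ms=2.5, alpha=0.5,
                color=_COLORS[cond])
        _median_quartiles(ax, v, i, "black")
    ax.set_xticks([0, 1], ["dark", "light"])
    ax.set_title(title, fontsize=9)


def sa_vs_volume(ax, df, title):
    v = np.geomspace(max(df["volume_um3"].min(), 1e-4),
                     df["volume_um3"].max() * 1.2, 100)
    ax.plot(v, sphere_surface_area(v), "k-", lw=1, label="sphere")
    for cond in ("dark", "light"):
        sub = df[df["condition"] == cond]
        ax.plot(sub["volume_um3"], sub["surface_area_um2"], "o", ms=3,
                alpha=0.6, color=_COLORS[cond], label=cond)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("V (um^3)")
    ax.set_ylabel("SA (um^2)")
    ax.set_title(title, fontsize=9)
    ax.legend(fontsize=7)


def site_area_histogram(ax, sites, pair):
    sub = sites[sites["pair"] == pair]
    if len(sub) == 0:
        return
    hi = np.percentile(sub["area_um2"], 95)
    bins = np.linspace(0, max(hi, 1e-3), 20)
    for cond in ("dark", "light"):
        v = sub.loc[sub["condition"] == cond, "area_um2"].to_numpy()
        if len(v):
            ax.hist(v, bins=bins, density=True, alpha=0.5,
                    color=_COLORS[cond], label=cond)
    ax.set_title(pair, fontsize=8)
    ax.set_xlabel("site area (um^2)")
    ax.legend(fontsize=7)
    inset = ax.inset_axes([0.55, 0.45, 0.42, 0.5])
    for i, cond in enumerate(("dark", "light")):
        v = sub.loc[sub["condition"] == cond, "area_um2"].to_numpy()
        if len(v):
            inset.plot(np.full(len(v), i), v, "o", ms=2, alpha=0.5,
                       color=_COLORS[cond])
            _median_quartiles(inset, v, i, "black")
    inset.set_xticks([0, 1], ["D", "L"])
    inset.tick_params(labelsize=6)


def per_cell_bars(ax, pair_cells, pair, metric):
    sub = pair_cells[pair_cells["pair"] == pair]
    for i, cond in enumerate(("dark", "light")):
        v = sub.loc[sub["condition"] == cond, metric].to_numpy(dtype=float)
        if len(v) == 0:
            continue
        ax.bar(i, v.mean(), yerr=v.std(ddof=1) if len(v) > 1 else 0,
               color=_COLORS[cond], alpha=0.4, width=0.6, capsize=3)
        ax.plot(np.full(len(v), i), v, "o", mfc="none", color="black", ms=4)
    ax.set_xticks([0, 1], ["dark", "light"])
    ax.set_title(f"{pair}\n{metric}", fontsize=8)


def report_figures(summary, out_dir: str | Path) -> list[Path]:
    """Write all report figures as PNG; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    fig, axes = plt.subplots(2, 3, figsize=(10, 6))
    for j, cls in enumerate(CONTACT_CLASSES):
        sub = summary.instances[summary.instances["organelle_class"] == cls]
        violin_by_condition(axes[0, j], sub, "volume_um3", f"{cls} volume")
        violin_by_condition(axes[1, j], sub, "sphericity", f"{cls} sphericity")
    fig.tight_layout()
    p = out / "morphometry_distributions.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.5))
    for j, cls in enumerate(CONTACT_CLASSES):
        sub = summary.instances[summary.instances["organelle_class"] == cls]
        sa_vs_volume(axes[j], sub, cls)
    fig.tight_layout()
    p = out / "surface_area_vs_volume.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    pairs = sorted(summary.sites["pair"].unique())
    if pairs:
        fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 3.2))
        axes = np.atleast_1d(axes)
        for ax, pair in zip(axes, pairs):
            site_area_histogram(ax, summary.sites, pair)
        fig.tight_layout()
        p = out / "site_area_histograms.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

        fig, axes = plt.subplots(2, len(pairs), figsize=(3 * len(pairs), 6))
        for j, pair in enumerate(pairs):
            per_cell_bars(axes[0, j], summary.pair_cells, pair, "n_sites")
            per_cell_bars(axes[1, j], summary.pair_cells, pair,
                          "total_area_um2")
        fig.tight_layout()
        p = out / "per_cell_contacts.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
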