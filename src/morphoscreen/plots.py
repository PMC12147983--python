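"""Matplotlib figures for screen read-outs (stacked yield bars, per-object
area strip plots, dose-response lines)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from morphoscreen.screen import CLASS_COLUMNS

_CLASS_COLORS = {
    "XEnEpiC": "#2c7fb8",
    "XEnEpiRosette": "#7fcdbb",
    "XEnNonPolarizedEpi": "#fec44f",
    "EBLike": "#fc8d59",
    "AmorphousXEn": "#d7301f",
}


def yield_stacked_bars(summary: pd.DataFrame, path: str | Path) -> None:
    """Stacked phenotype yield% per condition x dose (mean over wells)."""
    labels = [f"{r.condition}\n{r.dose:g}" for r in summary.itertuples()]
    fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(labels)), 4))
    bottom = None
    for c in CLASS_COLUMNS:
        vals = summary[f"yield_{c}_mean"].to_numpy()
        ax.bar(labels, vals, bottom=bottom, label=c, color=_CLASS_COLORS[c])
        bottom = vals if bottom is None else bottom + vals
    ax.set_ylabel("yield (%)")
    ax.legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def area_strip(merged: pd.DataFrame, path: str | Path,
               target_class: str = "XEnEpiC") -> None:
    """One dot per object of the target class: projected area by condition."""
    sel = merged[merged["pred_class"] == target_class]
    fig, ax = plt.subplots(figsize=(6, 4))
    groups = list(sel.groupby(["condition", "dose"], sort=True))
    for i, ((cond, dose), grp) in enumerate(groups):
        y = grp["Area_um2"].to_numpy()
        x = i + (pd.Series(range(len(y))) % 7 - 3) * 0.03
        ax.plot(x, y, ".", ms=3, alpha=0.6)
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels([f"{c}\n{d:g}" for (c, d), _ in groups], fontsize=7)
    ax.set_ylabel(f"{target_class} area (µm²)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def dose_response(wells: pd.DataFrame, path: str | Path,
                  endpoint: str = "yield_XEnEpiC") -> None:
    """Endpoint mean ± SD over replicate wells vs dose, one line per condition."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, grp in wells.groupby("condition"):
        agg = grp.groupby("dose")[endpoint].agg(["mean", "std"]).reset_index()
        ax.errorbar(agg["dose"], agg["mean"], yerr=agg["std"], marker="o",
                    capsize=3, label=cond)
    ax.set_xlabel("dose")
    ax.set_ylabel(endpoint)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
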