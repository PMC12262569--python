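"""Tabular and graphical summaries of diagnostics and simulation output.

All tables go out as TSV with a ``# seed=`` provenance comment line; the
figures (a bias/error heat map over the simulation grid and a cVIF bar
summary) degrade gracefully to tables alone if the plotting backend is
unavailable.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .diagnostics import CVIF_EXCESSIVE, CVIF_INSPECT, VifReport

__all__ = ["write_tsv", "read_tsv", "bias_heatmap", "cvif_barplot", "render_vif_report"]


def write_tsv(frame: pd.DataFrame, path, seed=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def render_vif_report(report: VifReport, out_dir, seed=None) -> list[Path]:
    """Write the contrast table, per-column tVIFs and any warnings."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contrast_path = out_dir / "contrast_diagnostics.tsv"
    frame = report.to_frame()
    frame.attrs["thresholds"] = (CVIF_INSPECT, CVIF_EXCESSIVE)
    with open(contrast_path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        fh.write(f"# flag legend: inspect if cVIF > {CVIF_INSPECT:g}; "
                 f"excessive if cVIF > {CVIF_EXCESSIVE:g}\n")
        frame.to_csv(fh, sep="\t", index=False)
    tvif_path = out_dir / "column_tvifs.tsv"
    write_tsv(report.tvif_frame(), tvif_path, seed=seed)
    written = [contrast_path, tvif_path]
    if report.warnings:
        warn_path = out_dir / "warnings.txt"
        warn_path.write_text("\n".join(report.warnings) + "\n")
        written.append(warn_path)
    return written


def _pyplot():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        return plt
    except Exception as exc:  # pragma: no cover - depends on backend state
        warnings.warn(f"plotting unavailable ({exc}); writing tables only", RuntimeWarning)
        return None


def bias_heatmap(summary: pd.DataFrame, path) -> Path | None:
    """Grid of average bias t statistics per (scenario, model) x contrast.

    Solid gray cells carry true signal (no error rate defined); outlined
    cells have a significantly inflated type-I error rate.
    """
    plt = _pyplot()
    if plt is None:
        return None
    scenarios = list(dict.fromkeys(summary["scenario"]))
    models = list(dict.fromkeys(summary["model"]))
    contrasts = list(dict.fromkeys(summary["contrast"]))
    fig, axes = plt.subplots(
        len(models), 1, figsize=(1.1 * len(contrasts) + 3, 0.5 * len(scenarios) * len(models) + 2),
        squeeze=False,
    )
    vmax = max(2.0, float(np.nanmax(np.abs(summary["bias_t"]))))
    for ax, model in zip(axes.ravel(), models):
        sub = summary[summary["model"] == model]
        grid = np.full((len(scenarios), len(contrasts)), np.nan)
        for _, row in sub.iterrows():
            grid[scenarios.index(row["scenario"]), contrasts.index(row["contrast"])] = row["bias_t"]
        mesh = ax.pcolormesh(grid, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        for _, row in sub.iterrows():
            i, j = scenarios.index(row["scenario"]), contrasts.index(row["contrast"])
            if not row["null_cell"]:
                ax.add_patch(plt.Rectangle((j, i), 1, 1, color="0.6"))
            elif row["inflated"]:
                ax.add_patch(plt.Rectangle((j, i), 1, 1, fill=False, edgecolor="0.3", lw=2.5))
        ax.set_xticks(np.arange(len(contrasts)) + 0.5, contrasts, rotation=30, ha="right")
        ax.set_yticks(np.arange(len(scenarios)) + 0.5, scenarios)
        ax.set_title(f"{model}: average bias t (gray = signal cell, outline = inflated error)")
        fig.colorbar(mesh, ax=ax)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def cvif_barplot(report: VifReport, path) -> Path | None:
    """Bar chart of contrast cVIFs with the 5 / 20 working thresholds."""
    plt = _pyplot()
    if plt is None:
        return None
    names = list(report.cvif)
    values = [report.cvif[n] for n in names]
    fig, ax = plt.subplots(figsize=(1.0 * len(names) + 3, 4))
    ax.bar(names, values, color="steelblue")
    ax.axhline(CVIF_INSPECT, color="orange", ls="--", label=f"inspect ({CVIF_INSPECT:g})")
    ax.axhline(CVIF_EXCESSIVE, color="red", ls="--", label=f"excessive ({CVIF_EXCESSIVE:g})")
    ax.set_ylabel("cVIF")
    ax.legend()
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
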