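"""Group-level summary reports: box-plot statistics and figures.

Consumes one or more completed run directories (each holding a
``session_summary.tsv`` and ``shell_profiles.tsv`` written by the pipeline)
and produces group tables across sessions plus a box-plot figure.  Box-plot
convention: box = quartiles with linear interpolation between order
statistics, whiskers = extent of the first and fourth quartiles (min/max).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["make_report", "boxplot_stats"]


def boxplot_stats(values: np.ndarray) -> dict[str, float]:
    """Median, quartiles (linear interpolation) and whisker extents."""
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no defined values")
    return {
        "median": float(np.median(vals)),
        "q1": float(np.percentile(vals, 25)),
        "q3": float(np.percentile(vals, 75)),
        "whisker_lo": float(vals.min()),
        "whisker_hi": float(vals.max()),
        "mean": float(vals.mean()),
        "n": int(vals.size),
    }


def make_report(run_dirs: list, out_dir, make_figure: bool = True) -> dict:
    """Summarize one or more completed runs into group tables and a figure.

    Returns a small report manifest.  Metrics undefined in every session are
    omitted with a logged warning, never fabricated as zeros.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sessions = []
    shell_tables = []
    for i, d in enumerate(sorted(str(p) for p in run_dirs)):
        d = Path(d)
        summary_path = d / "session_summary.tsv"
        if not summary_path.exists():
            raise FileNotFoundError(f"{d}: no session_summary.tsv (incomplete run?)")
        df = pd.read_csv(summary_path, sep="\t")
        df["session"] = i
        sessions.append(df)
        shells_path = d / "shell_profiles.tsv"
        if shells_path.exists():
            sh = pd.read_csv(shells_path, sep="\t")
            sh["session"] = i
            shell_tables.append(sh)
    per_session = pd.concat(sessions, ignore_index=True)

    rows = []
    for (cat, metric), g in per_session.groupby(["category", "metric"]):
        vals = g["value"].to_numpy()
        if np.isnan(vals).all():
            logger.warning("metric %s/%s undefined in every session; omitted", cat, metric)
            continue
        rows.append({"category": cat, "metric": metric, **boxplot_stats(vals)})
    box = pd.DataFrame(rows)
    box.to_csv(out / "report_boxplot.tsv", sep="\t", index=False,
               float_format="%.12g", lineterminator="\n")

    files = ["report_boxplot.tsv"]
    if shell_tables:
        shells = pd.concat(shell_tables, ignore_index=True)
        grp = (
            shells.groupby(["vessel_type", "distance", "metric"])["value"]
            .agg(["mean", "median", "count"])
            .reset_index()
        )
        grp.to_csv(out / "report_shell_profiles.tsv", sep="\t", index=False,
                   float_format="%.12g", lineterminator="\n")
        files.append("report_shell_profiles.tsv")

    if make_figure and not box.empty:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plot_metrics = [m for m in ("D", "S_pos", "S_neg", "var_pos", "var_neg", "D_ratio")
                        if m in set(box["metric"])]
        fig, axes = plt.subplots(
            1, max(len(plot_metrics), 1), figsize=(3.2 * max(len(plot_metrics), 1), 3.6)
        )
        axes = np.atleast_1d(axes)
        for ax, metric in zip(axes, plot_metrics):
            sub = per_session[per_session["metric"] == metric]
            cats = sorted(sub["category"].unique())
            data = [sub[sub["category"] == c]["value"].dropna().to_numpy() for c in cats]
            keep = [(c, v) for c, v in zip(cats, data) if v.size]
            if not keep:
                continue
            ax.boxplot([v for _, v in keep], tick_labels=[c for c, _ in keep], whis=(0, 100))
            ax.set_title(metric)
            ax.tick_params(axis="x", rotation=75, labelsize=7)
        fig.suptitle("Session-mean connectivity metrics by category")
        fig.tight_layout()
        fig.savefig(out / "report_boxplots.png", dpi=120)
        plt.close(fig)
        files.append("report_boxplots.png")

    manifest = {"n_sessions": len(sessions), "files": files}
    (out / "report_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
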