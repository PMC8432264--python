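"""Summary figures: per-group boxplots of ptp-amplitude and the indices.

Boxplot convention follows the study figures: whiskers at 1.5 x IQR, mild
outliers (1.5-3 x IQR) as open circles, extreme outliers (>3 x IQR) as
stars; the stenotic segment is highlighted.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .segments import SEGMENTS, segment_index

log = logging.getLogger("cordmotion")


def _split_outliers(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    mild = x[((x < q1 - 1.5 * iqr) & (x >= q1 - 3 * iqr))
             | ((x > q3 + 1.5 * iqr) & (x <= q3 + 3 * iqr))]
    extreme = x[(x < q1 - 3 * iqr) | (x > q3 + 3 * iqr)]
    return mild, extreme


def _group_box(ax, data_by_segment: dict[str, np.ndarray], positions, color):
    segs = list(data_by_segment)
    vals = [data_by_segment[s] for s in segs]
    bp = ax.boxplot(vals, positions=positions, widths=0.32, whis=1.5,
                    showfliers=False, patch_artist=True)
    for box in bp["boxes"]:
        box.set_facecolor(color)
        box.set_alpha(0.6)
    for pos, x in zip(positions, vals):
        mild, extreme = _split_outliers(np.asarray(x))
        ax.plot(np.full(mild.size, pos), mild, "o", mfc="none", mec="k", ms=4)
        ax.plot(np.full(extreme.size, pos), extreme, "*", color="k", ms=6)
    return bp


def plot_group_boxplots(metrics: pd.DataFrame, metric: str, outdir: str | Path,
                        ylabel: str, prefix: str) -> list[Path]:
    """One figure per stenosis group: patients vs controls across segments."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    if "group" not in metrics.columns or not len(metrics):
        log.info("no metrics to plot for %s", metric)
        return paths
    for group in sorted(metrics["group"].dropna().unique(), key=segment_index):
        gm = metrics[metrics["group"] == group]
        fig, ax = plt.subplots(figsize=(7, 4))
        any_data = False
        for role, color, shift in (("patient", "tab:red", -0.2),
                                   ("control", "tab:blue", 0.2)):
            data = {}
            for seg in SEGMENTS:
                x = gm[(gm["role"] == role) & (gm["segment"] == seg)][metric].dropna()
                if len(x):
                    data[seg] = x.to_numpy()
            if not data:
                continue
            any_data = True
            positions = [segment_index(s) + shift for s in data]
            _group_box(ax, data, positions, color)
        if not any_data:
            plt.close(fig)
            log.info("group %s has no data for %s; skipped", group, metric)
            continue
        si = segment_index(group)
        ax.axvspan(si - 0.45, si + 0.45, color="gold", alpha=0.25, zorder=0)
        ax.set_xticks(range(len(SEGMENTS)))
        ax.set_xticklabels(SEGMENTS, rotation=45)
        ax.set_ylabel(ylabel)
        ax.set_title(f"Stenosis {group}: {ylabel} (patients red, controls blue)")
        fig.tight_layout()
        path = outdir / f"{prefix}_{group.replace('/', '')}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(path)
    return paths


def plot_summaries(metrics: pd.DataFrame, outdir: str | Path) -> list[Path]:
    """Boxplots of ptp-amplitude and both indices for every group."""
    paths = []
    paths += plot_group_boxplots(metrics, "ptp_mm_s", outdir,
                                 "ptp-amplitude (mm/s)", "ptp")
    paths += plot_group_boxplots(metrics, "c2_pai", outdir, "C2-pAI", "c2pai")
    paths += plot_group_boxplots(metrics, "c7_pai", outdir, "C7-pAI", "c7pai")
    return paths
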