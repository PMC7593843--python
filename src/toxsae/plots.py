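"""Two-panel selection figure: class-mean reconstruction errors per SNP
(top) and the per-SNP Delta with the percentile thresholds (bottom)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .selection import DeltaProfile, SelectionReport


def render_selection_figure(
    profile: DeltaProfile,
    report: SelectionReport,
    endpoint: str,
    path: str | Path,
) -> None:
    j = len(profile.rsids)
    x = np.arange(j)
    fig, (ax_top, ax_bot) = plt.subplots(
        2, 1, figsize=(max(10, j * 0.28), 7), sharex=True,
        gridspec_kw={"hspace": 0.12},
    )
    width = 0.4
    ax_top.bar(x - width / 2, profile.unhealthy_mean, width, color="crimson",
               label="with toxicity")
    ax_top.bar(x + width / 2, profile.healthy_mean, width, color="steelblue",
               label="without toxicity")
    ax_top.set_ylabel("mean RE")
    ax_top.set_title(f"{endpoint}: class-mean reconstruction errors")
    ax_top.legend(frameon=False)

    ax_bot.bar(x, profile.delta, color="gray")
    ax_bot.axhline(0.0, color="red", lw=1)
    styles = {70: ":", 80: "-.", 90: "--", 95: "-"}
    for p, cut in sorted(report.thresholds.items()):
        ax_bot.axhline(cut, color="black", lw=0.8,
                       linestyle=styles.get(p, "--"), label=f"{p}th pct")
    ax_bot.set_ylabel(r"$\Delta$ mean RE")
    ax_bot.set_xticks(x)
    ax_bot.set_xticklabels(profile.rsids, rotation=90, fontsize=6)
    ax_bot.legend(frameon=False, fontsize=7)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def identification_matrix(report: SelectionReport) -> "np.ndarray":
    """Table-style matrix: per SNP, Identified / Not validated per tier."""
    import pandas as pd

    cols = [f"p{p}" for p in sorted(report.thresholds)]
    out = report.table[cols].replace({True: "Identified", False: "Not validated"})
    out.columns = [f"{p}th percentile" for p in sorted(report.thresholds)]
    return out
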