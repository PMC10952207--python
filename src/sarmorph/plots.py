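"""Optional figure export (Bland-Altman, percent-difference histogram)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .stats import ComparisonReport, bland_altman, percent_diff_histogram


def plot_bland_altman(report: ComparisonReport, path: str | Path) -> None:
    ba = bland_altman(report.a, report.b, k=report.ba_k)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(ba["mean"], ba["diff"], ".", ms=2, alpha=0.5)
    ax.axhline(ba["mean_diff"], color="k", lw=1)
    for y in (ba["upper_line"], ba["lower_line"]):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel("mean max10gSAR (W/kg)")
    ax.set_ylabel(f"{report.label_a} - {report.label_b} (W/kg)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_percent_diff_histogram(report: ComparisonReport, path: str | Path,
                                bin_width_pct: float = 1.0) -> None:
    counts, edges = percent_diff_histogram(report.a, report.b, report.convention,
                                           bin_width_pct)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(edges[:-1], counts, width=bin_width_pct, align="edge")
    ax.set_xlabel("percent difference in max10gSAR (%)")
    ax.set_ylabel("shim sets")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
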