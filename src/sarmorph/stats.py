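"""Agreement statistics: Bland-Altman, percent differences, B1+ RMSE.

Per-shim maximum 10g SAR series from two models are compared pairwise; the
percent-difference denominator defaults to the target-model value (the
series treated as ground truth), with a pairwise-mean alternative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "bland_altman",
    "percent_diff_summary",
    "b1_rmse",
    "percent_diff_histogram",
    "ComparisonReport",
    "uncertainty_comparison",
]


def bland_altman(a: np.ndarray, b: np.ndarray, k: float = 1.0) -> dict:
    """Difference-vs-mean summary: d_i = a_i - b_i against (a_i + b_i)/2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 paired values")
    d = a - b
    m = (a + b) / 2.0
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    return {
        "mean": m,
        "diff": d,
        "mean_diff": mean_d,
        "sd_diff": sd_d,
        "upper_line": mean_d + k * sd_d,
        "lower_line": mean_d - k * sd_d,
        "k": k,
    }


def percent_diff_summary(a: np.ndarray, b: np.ndarray, reference: str = "target") -> dict:
    """Summaries of 100*|a-b|/ref per pair.

    ``reference='target'`` divides by b (the target-model series);
    ``'pairwise_mean'`` divides by (a+b)/2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if reference == "target":
        ref = b
    elif reference == "pairwise_mean":
        ref = (a + b) / 2.0
    else:
        raise ValueError("reference must be 'target' or 'pairwise_mean'")
    if np.any(ref <= 0):
        raise ValueError("nonpositive reference values")
    pct = 100.0 * np.abs(a - b) / ref
    return {
        "mean_abs_pct": float(pct.mean()),
        "p95_pct": float(np.percentile(pct, 95)),
        "p99_pct": float(np.percentile(pct, 99)),
        "full_range_pct": float(pct.max()),
        "reference": reference,
    }


def percent_diff_histogram(a, b, reference: str = "target", bin_width_pct: float = 1.0):
    """Signed percent-difference histogram over a symmetric range."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ref = b if reference == "target" else (a + b) / 2.0
    pct = 100.0 * (a - b) / ref
    lim = np.ceil(max(np.abs(pct).max(), bin_width_pct) / bin_width_pct) * bin_width_pct
    edges = np.arange(-lim, lim + bin_width_pct / 2, bin_width_pct)
    counts, edges = np.histogram(pct, bins=edges)
    return counts, edges


def b1_rmse(map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray) -> float:
    """RMS of |B1+_a| - |B1+_b| over the mask, in the maps' units (uT)."""
    if map_a.shape != map_b.shape or map_a.shape != mask.shape:
        raise ValueError("B1+ maps/mask are not on the same grid")
    if not mask.any():
        raise ValueError("empty mask")
    d = np.abs(map_a)[mask] - np.abs(map_b)[mask]
    return float(np.sqrt(np.mean(d * d)))


@dataclass
class ComparisonReport:
    """Per-shim max10gSAR pairs plus all derived agreement statistics.

    ``a`` is the candidate series (e.g. warped-reference model) and ``b``
    the target-model series used as the percent-difference denominator.
    """

    a: np.ndarray
    b: np.ndarray
    label_a: str = "candidate"
    label_b: str = "target"
    convention: str = "target"
    ba_k: float = 1.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape:
            raise ValueError("paired series must have equal length")

    def summaries(self) -> dict:
        ba = bland_altman(self.a, self.b, k=self.ba_k)
        out = {
            "n_pairs": int(self.a.size),
            "label_a": self.label_a,
            "label_b": self.label_b,
            "mean_abs_diff_w_per_kg": float(np.abs(self.a - self.b).mean()),
            "bland_altman_mean_diff": ba["mean_diff"],
            "bland_altman_sd_diff": ba["sd_diff"],
            "bland_altman_upper": ba["upper_line"],
            "bland_altman_lower": ba["lower_line"],
        }
        out.update(percent_diff_summary(self.a, self.b, self.convention))
        for key, val in self.extras.items():
            out[key] = val
        return out

    # serialisation ---------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summaries(), indent=2, default=float))

    def pairs_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"shim_id": np.arange(self.a.size), self.label_a: self.a, self.label_b: self.b}
        ).to_csv(path, index=False)

    @classmethod
    def pairs_from_csv(cls, path: str | Path, **kwargs) -> "ComparisonReport":
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c != "shim_id"]
        return cls(df[cols[0]].to_numpy(), df[cols[1]].to_numpy(),
                   label_a=cols[0], label_b=cols[1], **kwargs)


def uncertainty_comparison(qset_v1, qset_v2, shims) -> ComparisonReport:
    """Compare two segmentation variants of one morphometry under shared shims."""
    from .shimming import max10g_exact

    if qset_v1.n_channels != qset_v2.n_channels:
        raise ValueError("Q-matrix sets have different channel counts")
    s1 = max10g_exact(qset_v1, shims)
    s2 = max10g_exact(qset_v2, shims)
    return ComparisonReport(
        s1, s2, label_a="variant", label_b="original",
        extras={"morphometry_identical": True, "registration_skipped": True},
    )
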