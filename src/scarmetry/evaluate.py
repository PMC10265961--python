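"""Accuracy and agreement statistics for length measurements.

Relative error against a reference value, summary statistics over a batch of
errors (mean / sample std / max / min), Pearson correlation and Bland-Altman
limits of agreement between automatic and manual measurements. A bundled CSV
of 30 published clinical measurement pairs (manual vs automatic, with their
relative errors) ships with the package as a worked reference dataset.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ErrorSummary",
    "AgreementSummary",
    "relative_error",
    "summarize_errors",
    "agreement_stats",
    "load_clinical_table",
    "bland_altman_plot",
    "correlation_plot",
]


@dataclass
class ErrorSummary:
    mean: float
    std: float   # sample std (ddof=1); NaN when n == 1
    max: float
    min: float
    n: int


@dataclass
class AgreementSummary:
    pearson_r: float          # NaN when either side has zero variance
    bias: float               # mean(auto - manual), same units as inputs
    loa_low: float            # bias - 1.96 * sample SD of differences
    loa_high: float           # bias + 1.96 * sample SD of differences
    n: int


def relative_error(x_auto: float, x_ref: float) -> float:
    """Relative error in percent: ``|x_auto - x_ref| / x_ref * 100``."""
    if x_ref == 0:
        raise ValueError("reference value must be nonzero")
    return abs(x_auto - x_ref) / abs(x_ref) * 100.0


def summarize_errors(res) -> ErrorSummary:
    """Mean, sample standard deviation (n-1 denominator), max and min of a
    non-empty list of relative errors (percent). With a single value the
    std is undefined and returned as NaN."""
    res = np.asarray(res, dtype=float)
    if res.size == 0:
        raise ValueError("no errors to summarize")
    std = float(np.std(res, ddof=1)) if res.size > 1 else float("nan")
    return ErrorSummary(
        mean=float(res.mean()), std=std, max=float(res.max()), min=float(res.min()),
        n=int(res.size),
    )


def agreement_stats(pairs) -> AgreementSummary:
    """Pearson correlation and Bland-Altman agreement for (auto, manual)
    measurement pairs. Differences are automatic minus manual; limits of
    agreement are bias +/- 1.96 sample SD. Correlation is NaN (flagged
    undefined) when either side is constant."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (auto, manual) pairs")
    auto, manual = arr[:, 0], arr[:, 1]
    if np.std(auto) == 0 or np.std(manual) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(auto, manual).statistic)
    d = auto - manual
    bias = float(d.mean())
    sd = float(np.std(d, ddof=1))
    return AgreementSummary(
        pearson_r=r, bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        n=len(d),
    )


def load_clinical_table() -> pd.DataFrame:
    """The bundled table of 30 published clinical scar measurements:
    columns ``id, n_views, manual_cm, auto_cm, re_percent``."""
    ref = importlib.resources.files("scarmetry.data") / "clinical_lengths.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def correlation_plot(pairs, path=None):
    """Scatter of automatic vs manual lengths with the identity line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = np.asarray(pairs, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(arr[:, 1], arr[:, 0], s=20)
    lim = [0, 1.05 * arr.max()]
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel("manual length (cm)")
    ax.set_ylabel("automatic length (cm)")
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    s = agreement_stats(arr)
    ax.set_title(f"Pearson r = {s.pearson_r:.4f} (n = {s.n})")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def bland_altman_plot(pairs, path=None):
    """Bland-Altman diagram: differences vs means, with bias and 1.96 SD
    limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = np.asarray(pairs, dtype=float)
    s = agreement_stats(arr)
    mean = arr.mean(axis=1)
    diff = arr[:, 0] - arr[:, 1]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, diff, s=20)
    for y, style in ((s.bias, "-"), (s.loa_low, "--"), (s.loa_high, "--")):
        ax.axhline(y, color="k", ls=style, lw=1)
    ax.set_xlabel("mean of automatic and manual (cm)")
    ax.set_ylabel("automatic - manual (cm)")
    ax.set_title(f"bias {s.bias:+.3f} cm, LoA [{s.loa_low:+.3f}, {s.loa_high:+.3f}]")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
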