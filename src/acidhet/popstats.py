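"""Population-level statistics of reporter heterogeneity.

ON/OFF calling, Pearson correlation between channels, chi-square
comparison of intensity histograms, skewness-based shape classification,
and luminescence-reporter (RLU) normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["OnOffCall", "CorrelationResult", "HistogramComparison",
           "LuminescenceResult", "call_on_off", "pearson",
           "chi_square_compare", "chi_square_from_counts", "skewness",
           "classify_distribution", "rlu_normalize"]


@dataclass
class OnOffCall:
    """Result of thresholding a population into ON and OFF cells."""

    threshold: float
    rule: str
    on_fraction: float
    n_on: int
    n_off: int


@dataclass
class CorrelationResult:
    channel_x: str
    channel_y: str
    r: float
    p_value: float
    n: int


@dataclass
class HistogramComparison:
    """Chi-square homogeneity test of two binned samples."""

    bin_edges: np.ndarray
    counts_a: np.ndarray
    counts_b: np.ndarray
    chi2: float
    dof: int
    p_value: float


@dataclass
class LuminescenceResult:
    records: pd.DataFrame
    t_max: float
    rlu_max: float


def call_on_off(values, control_values, k: float = 3.0) -> OnOffCall:
    """Call ON cells against a non-fluorescent control population.

    The threshold is ``mean(control) + k · sd(control)`` (sample sd);
    a cell is ON iff its value exceeds the threshold. The default k = 3
    admits ~0.1% false ON calls for a Gaussian control.
    """
    values = np.asarray(values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if values.size == 0 or control.size < 2:
        raise ValueError("need nonempty values and a control with n >= 2")
    threshold = float(control.mean() + k * control.std(ddof=1))
    n_on = int((values > threshold).sum())
    n_off = values.size - n_on
    return OnOffCall(threshold=threshold,
                     rule=f"mean(control) + {k:g} sd(control)",
                     on_fraction=n_on / values.size, n_on=n_on, n_off=n_off)


def pearson(x, y, channel_x: str = "x", channel_y: str = "y") -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 for a p-value")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the inputs")
    res = stats.pearsonr(x, y)
    return CorrelationResult(channel_x=channel_x, channel_y=channel_y,
                             r=float(res.statistic), p_value=float(res.pvalue),
                             n=x.size)


def chi_square_from_counts(counts_a, counts_b,
                           bin_edges=None) -> HistogramComparison:
    """Chi-square test of homogeneity on a 2 x B count table (no pooling)."""
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if counts_a.shape != counts_b.shape or counts_a.ndim != 1:
        raise ValueError("count vectors must be 1-D and equal length")
    if counts_a.size < 2:
        raise ValueError("need at least 2 bins")
    nonzero = (counts_a + counts_b) > 0
    if nonzero.sum() < 2:
        raise ValueError("fewer than 2 non-empty bins: test degenerate")
    counts_a, counts_b = counts_a[nonzero], counts_b[nonzero]
    table = np.vstack([counts_a, counts_b])
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    if bin_edges is None:
        bin_edges = np.arange(counts_a.size + 1, dtype=float)
    return HistogramComparison(bin_edges=np.asarray(bin_edges),
                               counts_a=counts_a.astype(int),
                               counts_b=counts_b.astype(int),
                               chi2=float(chi2), dof=int(dof), p_value=float(p))


def _pool_tails(counts_a: np.ndarray, counts_b: np.ndarray,
                edges: np.ndarray, min_expected: float = 5.0):
    """Merge tail bins inward until every expected count is >= min_expected."""
    a, b, e = counts_a.astype(float), counts_b.astype(float), edges.copy()

    def expected(a, b):
        table = np.vstack([a, b])
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        return row * col / table.sum()

    while a.size > 2:
        exp = expected(a, b)
        if exp.min() >= min_expected:
            break
        # merge whichever outermost bin has the smaller expected mass
        left = exp[:, 0].min()
        right = exp[:, -1].min()
        if left <= right:
            a[1] += a[0]; b[1] += b[0]
            a, b, e = a[1:], b[1:], np.r_[e[0], e[2:]]
        else:
            a[-2] += a[-1]; b[-2] += b[-1]
            a, b, e = a[:-1], b[:-1], np.r_[e[:-2], e[-1]]
    return a, b, e


def chi_square_compare(values_a, values_b, n_bins: int = 20,
                       min_expected: float = 5.0) -> HistogramComparison:
    """Compare two intensity distributions with a chi-square homogeneity test.

    Both samples are binned on shared equal-width bins over their pooled
    range; tail bins are merged inward until every expected count reaches
    ``min_expected``. Raises ``ValueError`` if fewer than 2 usable bins
    remain.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    counts_a, _ = np.histogram(a, bins=edges)
    counts_b, _ = np.histogram(b, bins=edges)
    ca, cb, edges = _pool_tails(counts_a, counts_b, edges, min_expected)
    if ca.size < 2:
        raise ValueError("fewer than 2 usable bins after pooling")
    return chi_square_from_counts(ca, cb, edges)


def skewness(values) -> float:
    """Population (biased) moment skewness g1 = m3 / m2^(3/2)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need n >= 3")
    if values.std() == 0:
        raise ValueError("zero variance: skewness undefined")
    return float(stats.skew(values, bias=True))


def classify_distribution(values, cutoff: float = 0.5) -> str:
    """Label a sample ``"right-skewed"`` (g1 > cutoff) or ``"symmetric"``."""
    return "right-skewed" if skewness(values) > cutoff else "symmetric"


def rlu_normalize(timecourse: pd.DataFrame) -> LuminescenceResult:
    """Normalize a luminescence time course to relative light units.

    ``rlu = counts_per_s / (volume_ml · od600)`` — counts per second per
    milliliter per OD600. Requires columns ``time_min``, ``counts_per_s``,
    ``volume_ml``, ``od600``; returns the table with an ``rlu`` column and
    the time/value of the maximum.
    """
    required = ["time_min", "counts_per_s", "volume_ml", "od600"]
    missing = [c for c in required if c not in timecourse.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    if (timecourse["od600"] <= 0).any():
        raise ValueError("od600 must be > 0 at all time points")
    if (timecourse["volume_ml"] <= 0).any():
        raise ValueError("volume_ml must be > 0")
    out = timecourse.copy()
    out["rlu"] = out["counts_per_s"] / (out["volume_ml"] * out["od600"])
    i_max = out["rlu"].idxmax()
    return LuminescenceResult(records=out,
                              t_max=float(out.loc[i_max, "time_min"]),
                              rlu_max=float(out.loc[i_max, "rlu"]))
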