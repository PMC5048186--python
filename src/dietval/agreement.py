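"""Agreement, calibration and ranking statistics for paired methods.

Covers the standard toolkit for comparing a dietary instrument against a
reference (or against a second instrument): Bland-Altman limits of
agreement with a proportional-bias trend test, the calibration slope of
measured expenditure on reported intake, Wilcoxon signed-rank paired
comparison, crude Spearman and energy-adjusted Pearson correlations, and
quantile-based cross-classification with Cohen's weighted kappa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["BlandAltmanResult", "CalibrationResult", "PairedTestResult",
           "CorrelationResult", "CrossClassResult",
           "bland_altman", "calibration_slope", "paired_compare",
           "correlate", "quantile_bins", "cross_classify", "weighted_kappa",
           "bland_altman_plot"]


@dataclass
class BlandAltmanResult:
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    pct_outside_loa: float
    trend_slope: float
    trend_p: float
    n: int


@dataclass
class CalibrationResult:
    slope: float
    ci_lower: float
    ci_upper: float
    intercept: float
    n: int


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    n_nonzero: int
    n_zero: int
    degenerate: bool


@dataclass
class CorrelationResult:
    pair: str
    coefficient: float
    p_value: float
    mode: str           # "crude_spearman" | "adjusted_pearson"
    transformation: str = "none"


@dataclass
class CrossClassResult:
    n_bins: int
    table: np.ndarray
    pct_same: float
    pct_adjacent: float
    pct_opposite: float
    kappa_weighted: float
    weight_scheme: str


def _paired(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} pairs")
    return x, y


def bland_altman(x, y) -> BlandAltmanResult:
    """Limits of agreement for paired measurements x and y.

    Differences are x - y; limits are mean ± 1.96 SD (sample SD);
    proportional bias is the OLS slope of difference on pairwise mean with
    its two-sided p-value ("P for trend").
    """
    x, y = _paired(x, y)
    diff = x - y
    mean_pair = (x + y) / 2.0
    md = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    loa_lower, loa_upper = md - 1.96 * sd, md + 1.96 * sd
    outside = np.sum((diff < loa_lower) | (diff > loa_upper))
    if np.var(mean_pair) == 0 or sd == 0:
        slope, p = 0.0, 1.0
    else:
        fit = stats.linregress(mean_pair, diff)
        slope, p = float(fit.slope), float(fit.pvalue)
    return BlandAltmanResult(md, sd, loa_lower, loa_upper,
                             100.0 * outside / len(diff), slope, p, len(diff))


def calibration_slope(ei, tee, alpha: float = 0.05) -> CalibrationResult:
    """Slope of measured TEE regressed on reported EI, with 95% CI.

    The CI uses the slope's standard error and the t quantile at n-2
    degrees of freedom.
    """
    ei, tee = _paired(ei, tee)
    if np.var(ei) == 0:
        raise ValueError("reported EI has zero variance")
    fit = stats.linregress(ei, tee)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, len(ei) - 2)
    half = t_crit * fit.stderr
    return CalibrationResult(float(fit.slope), float(fit.slope - half),
                             float(fit.slope + half), float(fit.intercept),
                             len(ei))


def paired_compare(x, y) -> PairedTestResult:
    """Wilcoxon signed-rank test of paired x vs y.

    Zero differences are dropped before ranking; the exact null
    distribution is used for n <= 25 non-zero untied differences, the
    tie-corrected normal approximation with continuity correction
    otherwise. An all-zero difference vector is flagged degenerate.
    """
    x, y = _paired(x, y, min_n=1)
    diff = x - y
    nonzero = diff[diff != 0]
    n_zero = len(diff) - len(nonzero)
    if len(nonzero) == 0:
        return PairedTestResult(0.0, 1.0, 0, n_zero, True)
    has_ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (len(nonzero) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(nonzero, zero_method="wilcox", correction=True,
                         method=method, alternative="two-sided")
    return PairedTestResult(float(res.statistic), float(res.pvalue),
                            len(nonzero), n_zero, False)


def correlate(x, y, mode: str = "crude_spearman", pair: str = "",
              transformation: str = "none") -> CorrelationResult:
    """Spearman (crude intakes) or Pearson (energy-adjusted) correlation."""
    x, y = _paired(x, y)
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("undefined correlation: zero variance input")
    if mode == "crude_spearman":
        r, p = stats.spearmanr(x, y)
    elif mode == "adjusted_pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError("mode must be 'crude_spearman' or 'adjusted_pearson'")
    return CorrelationResult(pair, float(r), float(p), mode, transformation)


def quantile_bins(values, k: int) -> np.ndarray:
    """Assign 1..k quantile-bin labels (tertiles k=3, quartiles k=4).

    Boundaries are the sample quantiles i/k (linear interpolation); a
    value exactly on a boundary goes to the lower bin. A constant series
    yields a single bin with a warning.
    """
    values = np.asarray(values, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(values) < k:
        raise ValueError("need at least k values")
    if np.ptp(values) == 0:
        warnings.warn("degenerate bins: all values identical", stacklevel=2)
        return np.ones(len(values), dtype=int)
    boundaries = np.quantile(values, np.arange(1, k) / k)
    return np.searchsorted(boundaries, values, side="left").astype(int) + 1


def weighted_kappa(table, scheme: str = "linear") -> float:
    """Cohen's weighted kappa from a k x k contingency table.

    kappa_w = 1 - sum(w * p_obs) / sum(w * p_exp), with disagreement
    weights w_ij = |i-j|/(k-1) (linear) or ((i-j)/(k-1))^2 (quadratic)
    and expected proportions from the margin products.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError("table must be square")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    total = table.sum()
    if total == 0:
        raise ValueError("table total must be positive")
    k = table.shape[0]
    idx = np.arange(k)
    dist = np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    if scheme == "linear":
        w = dist
    elif scheme == "quadratic":
        w = dist ** 2
    else:
        raise ValueError("scheme must be 'linear' or 'quadratic'")
    p_obs = table / total
    rows = p_obs.sum(axis=1)
    cols = p_obs.sum(axis=0)
    p_exp = np.outer(rows, cols)
    expected_disagreement = float(np.sum(w * p_exp))
    if expected_disagreement == 0:
        return 1.0      # no expected disagreement and hence none observed
    return 1.0 - float(np.sum(w * p_obs)) / expected_disagreement


def cross_classify(bins_a, bins_b, scheme: str = "linear") -> CrossClassResult:
    """Cross-tabulate two quantile-bin labelings and summarise agreement.

    Same = diagonal share; adjacent = |bin difference| of 1; opposite =
    the two extreme corner cells (1,k) and (k,1); weighted kappa per
    ``weighted_kappa``.
    """
    a = np.asarray(bins_a, dtype=int)
    b = np.asarray(bins_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("bin label arrays must have equal length")
    k = int(max(a.max(), b.max()))
    if a.min() < 1 or b.min() < 1:
        raise ValueError("bin labels must be 1..k")
    table = np.zeros((k, k))
    np.add.at(table, (a - 1, b - 1), 1.0)
    n = table.sum()
    same = float(np.trace(table))
    adjacent = float(sum(table[i, j] for i in range(k) for j in range(k)
                         if abs(i - j) == 1))
    opposite = float(table[0, k - 1] + table[k - 1, 0]) if k >= 2 else 0.0
    return CrossClassResult(
        n_bins=k, table=table,
        pct_same=100.0 * same / n,
        pct_adjacent=100.0 * adjacent / n,
        pct_opposite=100.0 * opposite / n,
        kappa_weighted=weighted_kappa(table, scheme),
        weight_scheme=scheme)


def bland_altman_plot(x, y, labels: tuple[str, str] = ("method A", "method B"),
                      path: str | None = None):
    """Draw the Bland-Altman scatter with mean difference and LoA lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((x + y) / 2.0, x - y, s=18, alpha=0.7)
    for value, style in ((res.mean_difference, "-"),
                         (res.loa_lower, "--"), (res.loa_upper, "--")):
        ax.axhline(value, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel(f"mean of {labels[0]} and {labels[1]}")
    ax.set_ylabel(f"{labels[0]} - {labels[1]}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return res
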