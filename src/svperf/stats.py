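"""Reproducibility statistics for paired perfusion measurements.

Repeated perfusion acquisitions under an unchanged flow condition are
compared pairwise with the field's standard repeatability battery:
ordinary least-squares regression of the second measurement on the first
(with t-based 95% CIs), Spearman rank correlation (Fisher-z CI),
root-mean-square error about the regression line, root-mean-square
deviation within pairs (RMSD = sqrt(sum(d^2) / 2n), the repeatability
deviation), Bland-Altman bias with 1.96-SD limits of agreement, and the
two-sided Wilcoxon signed-rank test.

The Wilcoxon p-value uses the exact tie-aware null distribution for up to
25 non-zero differences (dynamic programming over signed average ranks) and
a normal approximation with continuity and tie corrections beyond that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateRegressionError,
    InvalidParameterError,
    UndefinedCorrelationError,
)

__all__ = [
    "PairedData",
    "PairedStats",
    "RegressionResult",
    "paired_regression",
    "spearman_ci",
    "rmse_rmsd",
    "bland_altman",
    "wilcoxon_signed_rank",
    "analyze_pairs",
    "read_pairs_csv",
]


@dataclass(frozen=True)
class PairedData:
    """Matched first/second measurement sequences with optional tags."""

    first: np.ndarray
    second: np.ndarray
    labels: "Sequence[str] | None" = None

    def __post_init__(self):
        a = np.asarray(self.first, dtype=float)
        b = np.asarray(self.second, dtype=float)
        object.__setattr__(self, "first", a)
        object.__setattr__(self, "second", b)
        if a.shape != b.shape or a.ndim != 1:
            raise InvalidParameterError("first and second must be matching 1-D sequences")
        if a.size < 3:
            raise InvalidParameterError("need at least 3 pairs")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise InvalidParameterError("measurements must be finite")
        if self.labels is not None and len(self.labels) != a.size:
            raise InvalidParameterError("labels must match the number of pairs")

    @property
    def n(self) -> int:
        return int(self.first.size)

    @property
    def differences(self) -> np.ndarray:
        return self.second - self.first


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_ci: tuple
    intercept_ci: tuple

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class PairedStats:
    """Full repeatability summary of one paired comparison."""

    slope: float
    intercept: float
    slope_ci: tuple
    intercept_ci: tuple
    spearman_rho: float
    spearman_ci: tuple
    rmse: float
    rmsd: float
    bias: float
    loa_low: float
    loa_high: float
    wilcoxon_p: float
    n: int

    def __post_init__(self):
        if not self.loa_low <= self.bias <= self.loa_high:
            raise InvalidParameterError("limits of agreement must bracket the bias")
        if not -1.0 <= self.spearman_rho <= 1.0:
            raise InvalidParameterError("rho out of [-1, 1]")
        if self.rmse < 0 or self.rmsd < 0:
            raise InvalidParameterError("rmse/rmsd must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("slope_ci", "intercept_ci", "spearman_ci"):
            d[k] = list(d[k])
        return d


def paired_regression(data: PairedData, alpha: float = 0.05) -> RegressionResult:
    """OLS of the second measurement on the first, with t-based CIs.

    CIs use the t distribution with n-2 degrees of freedom.
    """
    x, y = data.first, data.second
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("predictor is constant")
    fit = sps.linregress(x, y)
    tcrit = sps.t.ppf(1 - alpha / 2, data.n - 2)
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        slope_ci=(float(fit.slope - tcrit * fit.stderr),
                  float(fit.slope + tcrit * fit.stderr)),
        intercept_ci=(float(fit.intercept - tcrit * fit.intercept_stderr),
                      float(fit.intercept + tcrit * fit.intercept_stderr)))


def spearman_ci(data: PairedData, alpha: float = 0.05) -> tuple:
    """Spearman rank correlation with a Fisher-z confidence interval.

    Average ranks resolve ties; the CI uses the Fisher transform with
    standard error 1/sqrt(n-3).  Returns ``(rho, (lo, hi))``.
    """
    if data.n < 4:
        raise InvalidParameterError("Spearman CI needs n >= 4")
    if np.ptp(data.first) == 0 or np.ptp(data.second) == 0:
        raise UndefinedCorrelationError("correlation undefined on an all-tied margin")
    rho = float(sps.spearmanr(data.first, data.second).statistic)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    half = sps.norm.ppf(1 - alpha / 2) / np.sqrt(data.n - 3)
    return rho, (float(np.tanh(z - half)), float(np.tanh(z + half)))


def rmse_rmsd(data: PairedData, regression: RegressionResult) -> tuple:
    """RMSE about the regression line and within-pair RMSD.

    ``rmse = sqrt(sum((y - yhat)^2) / n)`` measures scatter about the fitted
    line; ``rmsd = sqrt(sum((y - x)^2) / (2n))`` is the repeatability
    deviation of a single measurement.
    """
    resid = data.second - regression.predict(data.first)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    d = data.differences
    rmsd = float(np.sqrt(np.sum(d ** 2) / (2 * data.n)))
    return rmse, rmsd


def bland_altman(data: PairedData) -> tuple:
    """Bias and 1.96-SD limits of agreement of the paired differences.

    Returns ``(bias, loa_low, loa_high)``; the SD uses the n-1 denominator.
    """
    d = data.differences
    if d.size < 2:
        raise InvalidParameterError("need at least 2 pairs")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def _exact_signed_rank_p(ranks2: np.ndarray, w2: float) -> float:
    """Exact two-sided p over all 2^n sign assignments, by DP.

    ``ranks2`` are average ranks doubled to integers (so tied ranks stay
    exact); ``w2`` the doubled positive-rank sum.  Counts of achievable sums
    come from the subset-sum polynomial.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        counts[r:] += counts[:total + 1 - r].copy()
    counts /= counts.sum()
    w2 = int(round(w2))
    cdf = counts[:w2 + 1].sum()
    sf = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(data: PairedData, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value for the paired differences.

    Zero differences are dropped.  With <= ``exact_max_n`` non-zero
    differences the exact tie-aware null distribution is enumerated;
    otherwise a normal approximation with continuity and tie corrections is
    used.  All differences zero yields p = 1 with a warning.
    """
    d = data.differences
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    if n < 5:
        raise InvalidParameterError(
            "need >= 5 non-zero differences for the signed-rank test")

    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        return _exact_signed_rank_p(2.0 * ranks, 2.0 * w_pos)

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts ** 3 - tie_counts) / 48.0
    if var == 0:
        warnings.warn("degenerate signed-rank variance; p = 1",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    # continuity correction shrinks |W - mu| by 0.5
    z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def analyze_pairs(data: PairedData) -> PairedStats:
    """Run the full repeatability battery on one paired dataset."""
    reg = paired_regression(data)
    rho, rho_ci = spearman_ci(data)
    rmse, rmsd = rmse_rmsd(data, reg)
    bias, lo, hi = bland_altman(data)
    p = wilcoxon_signed_rank(data)
    return PairedStats(slope=reg.slope, intercept=reg.intercept,
                       slope_ci=reg.slope_ci, intercept_ci=reg.intercept_ci,
                       spearman_rho=rho, spearman_ci=rho_ci,
                       rmse=rmse, rmsd=rmsd, bias=bias, loa_low=lo,
                       loa_high=hi, wilcoxon_p=p, n=data.n)


def read_pairs_csv(path) -> pd.DataFrame:
    """Read a paired-measurement table.

    Expected columns: ``pair_id, region, condition, p_first, p_second``.
    """
    df = pd.read_csv(path)
    missing = {"p_first", "p_second"} - set(df.columns)
    if missing:
        raise InvalidParameterError(f"pairs CSV missing columns {sorted(missing)}")
    return df


def pairs_from_frame(df: pd.DataFrame) -> PairedData:
    labels = df["region"].astype(str).tolist() if "region" in df else None
    return PairedData(first=df["p_first"].to_numpy(dtype=float),
                      second=df["p_second"].to_numpy(dtype=float),
                      labels=labels)


def plot_bland_altman(data: PairedData, path) -> None:
    """Bland-Altman scatter (mean vs difference) with bias and LoA lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bias, lo, hi = bland_altman(data)
    mean = (data.first + data.second) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, data.differences, s=18)
    for yv, style, lab in ((bias, "-", f"bias {bias:.3f}"),
                           (lo, "--", f"LoA {lo:.3f}"),
                           (hi, "--", f"LoA {hi:.3f}")):
        ax.axhline(yv, linestyle=style, color="k", linewidth=1)
        ax.annotate(lab, (0.02, yv), xycoords=("axes fraction", "data"),
                    fontsize=8, va="bottom")
    ax.set_xlabel("mean of pair (mL/min/g)")
    ax.set_ylabel("second - first (mL/min/g)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_regression(data: PairedData, path) -> None:
    """First-vs-second scatter with the OLS line and identity."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    reg = paired_regression(data)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(data.first, data.second, s=18)
    xs = np.linspace(data.first.min(), data.first.max(), 50)
    ax.plot(xs, reg.predict(xs), "k-",
            label=f"y = {reg.slope:.2f}x + {reg.intercept:+.2f}")
    ax.plot(xs, xs, "k:", linewidth=1, label="identity")
    ax.set_xlabel("first measurement (mL/min/g)")
    ax.set_ylabel("second measurement (mL/min/g)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
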