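"""Statistical battery for spine-morphometry comparisons.

Two-sample Kolmogorov-Smirnov comparisons between fixation conditions,
Spearman rank correlations between morphometric pairs, log-normal
distribution fits with a binned goodness-of-fit R^2, ordinary-least-squares
R^2, the four-group (condition x ER) ANOVA/Tukey comparison, and condition
summary tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "DistributionFit",
    "ks_two_sample",
    "spearman",
    "fit_lognormal",
    "linear_r2",
    "tukey_er_comparison",
    "summarize_condition",
]


@dataclass
class GroupComparison:
    labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sds: tuple[float, float]
    medians: tuple[float, float]
    ks_d: float
    ks_p: float


@dataclass
class CorrelationResult:
    variables: tuple[str, str]
    rho: float
    p: float
    n: int
    flags: list[str] = field(default_factory=list)


@dataclass
class DistributionFit:
    log_mean: float
    log_sd: float
    bin_edges: np.ndarray
    observed: np.ndarray       # relative frequency per bin
    expected: np.ndarray       # fitted bin probability
    r_squared: float


def ks_two_sample(x: np.ndarray, y: np.ndarray,
                  labels: tuple[str, str] = ("x", "y"),
                  method: str = "asymp") -> GroupComparison:
    """Unpaired two-sample Kolmogorov-Smirnov comparison.

    D is the exact supremum ECDF difference; the two-sided p-value is
    asymptotic by default (``method='exact'`` for small samples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    res = sps.ks_2samp(x, y, method=method)
    return GroupComparison(
        labels=labels, n=(len(x), len(y)),
        means=(float(x.mean()), float(y.mean())),
        sds=(float(x.std(ddof=1)), float(y.std(ddof=1))),
        medians=(float(np.median(x)), float(np.median(y))),
        ks_d=float(res.statistic), ks_p=float(min(res.pvalue, 1.0)))


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided permutation p-value by exhaustive enumeration (small n)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = abs(rho)
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        count += abs(r) >= obs - 1e-12
        total += 1
    return count / total


def spearman(x: np.ndarray, y: np.ndarray,
             variables: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    The p-value is by exhaustive permutation for n <= 9 and by the
    t-approximation otherwise.  Constant input yields rho = NaN and a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(variables, np.nan, np.nan, len(x),
                                 flags=["constant_input"])
    rho = float(sps.spearmanr(x, y).statistic)
    if len(x) <= 9:
        p = float(_spearman_exact_p(x, y, rho))
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return CorrelationResult(variables, rho, p, len(x))


def fit_lognormal(x: np.ndarray, bin_edges: np.ndarray | None = None,
                  binning_rule: str = "fd") -> DistributionFit:
    """Maximum-likelihood log-normal fit with a binned R^2.

    log_mean/log_sd are the mean and (ML) SD of ln x.  R^2 compares the
    observed relative bin frequencies with the fitted distribution's bin
    probabilities: R^2 = 1 - SS_res / SS_tot.  Bin edges default to the
    Freedman-Diaconis rule on the sample; pass shared edges to compare
    conditions on a common binning.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("log-normal fit requires positive data")
    if len(x) < 10:
        raise ValueError("need n >= 10 for a distribution fit")
    lx = np.log(x)
    mu = float(lx.mean())
    sd = float(lx.std(ddof=0))
    if bin_edges is None:
        bin_edges = np.histogram_bin_edges(x, bins=binning_rule)
    counts, edges = np.histogram(x, bins=bin_edges)
    observed = counts / counts.sum()
    cdf = sps.lognorm.cdf(edges, s=max(sd, 1e-12), scale=np.exp(mu))
    expected = np.diff(cdf)
    ss_res = float(((observed - expected) ** 2).sum())
    ss_tot = float(((observed - observed.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return DistributionFit(mu, sd, np.asarray(edges), observed, expected, r2)


def linear_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Ordinary-least-squares R^2 (squared Pearson correlation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    return float(sps.linregress(x, y).rvalue ** 2)


def tukey_er_comparison(records: pd.DataFrame, response: str,
                        log_transform: bool = False) -> pd.DataFrame:
    """One-way ANOVA + Tukey HSD across the four condition x ER groups.

    ``records`` needs columns ``condition``, ``er_in_neck`` and the response.
    Returns the pairwise table with adjusted p-values; the rows comparing
    +ER with -ER within one condition carry ``within_condition=True``.
    """
    df = records.dropna(subset=[response])
    groups: dict[str, np.ndarray] = {}
    for cond in sorted(df["condition"].unique()):
        for er in (False, True):
            key = f"{cond}{'+ER' if er else '-ER'}"
            vals = df[(df["condition"] == cond)
                      & (df["er_in_neck"] == er)][response].to_numpy(float)
            if log_transform:
                vals = np.log(vals)
            if len(vals) < 2:
                raise ValueError(f"group {key} has fewer than 2 spines")
            groups[key] = vals
    names = list(groups)
    res = sps.tukey_hsd(*groups.values())
    anova_p = float(sps.f_oneway(*groups.values()).pvalue)
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        gi, gj = names[i], names[j]
        rows.append({
            "group_a": gi, "group_b": gj,
            "n_a": len(groups[gi]), "n_b": len(groups[gj]),
            "mean_a": float(np.mean(groups[gi])),
            "mean_b": float(np.mean(groups[gj])),
            "p_adj": float(res.pvalue[i, j]),
            "anova_p": anova_p,
            "within_condition": gi[:-3] == gj[:-3],
        })
    return pd.DataFrame(rows)


def summarize_condition(records: pd.DataFrame,
                        measurands: list[str] | None = None) -> pd.DataFrame:
    """Per-condition mean, sample SD, median, IQR, min, max per measurand."""
    if measurands is None:
        numeric = records.select_dtypes("number")
        measurands = [c for c in numeric.columns if c != "seed"]
    rows = []
    for cond, sub in records.groupby("condition"):
        for m in measurands:
            v = sub[m].dropna().to_numpy(float)
            if len(v) == 0:
                continue
            rows.append({
                "condition": cond, "measurand": m, "n": len(v),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
                "median": float(np.median(v)),
                "iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
                "min": float(v.min()), "max": float(v.max()),
            })
    return pd.DataFrame(rows)
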