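"""Correlation screening and group-level statistics for drift features.

Covers the three statistical layers of the drift analysis:

* Kendall tau-b correlation / significance matrices over the 11-column
  feature matrix X, used to pick the features driving the rest-phase
  gaze-error SD (and hence the form of the correction polynomial);
* Pearson correlations between peak head velocity and eye drift with
  Fisher z-transform confidence intervals and R^2;
* per-protocol drift summaries (mean, SD, normal-approximation CI) and
  nonparametric group comparisons (Kruskal-Wallis, pairwise Mann-Whitney
  with Bonferroni correction).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .drift_metrics import X_COLUMNS, feature_matrix
from .errors import InputError, UndefinedCorrelationError

#: Significance display threshold for the tau-b p-value matrix.
SIGNIFICANCE_LEVEL = 0.05


@dataclass
class KendallResult:
    """Pairwise Kendall tau-b and p-value matrices over feature columns."""

    tau: pd.DataFrame
    pvals: pd.DataFrame


@dataclass
class GroupSummary:
    """Per-protocol drift summary (mean, SD, 95% CI, mean peak velocity)."""

    protocol: str
    n: int
    mean_drift: float
    drift_sd: float
    ci_low: float
    ci_high: float
    mean_head_vel: float


@dataclass
class CorrelationReport:
    """Pearson correlation with Fisher-z CI and R^2 for one group."""

    protocol: str | None
    n: int
    r: float
    r_ci_low: float
    r_ci_high: float
    r_squared: float
    p_value: float


def kendall_tau_b(x, y) -> tuple[float, float]:
    """Kendall tau-b rank correlation with tie correction.

    Returns (tau_b, p). tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)) where
    C/D count concordant/discordant pairs and n1/n2 are the tie
    corrections of x and y. The p-value follows scipy's policy: exact
    enumeration for small tie-free samples, normal approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-d arrays of equal length")
    if len(x) < 2:
        raise InputError("need at least 2 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("tau-b undefined for constant input")
    res = stats.kendalltau(x, y, variant="b")
    return float(res.statistic), float(res.pvalue)


def kendall_matrix(features: pd.DataFrame) -> KendallResult:
    """Pairwise tau-b / p matrices over the 11 X columns of a feature table.

    Constant columns are flagged undefined (NaN row/column); all other
    pairs are computed. Matrices are symmetric with unit tau diagonal.
    """
    X = feature_matrix(features) if set(X_COLUMNS) <= set(features.columns) else features
    cols = list(X.columns)
    if len(X) < 3:
        raise InputError("need at least 3 rows for a correlation matrix")
    k = len(cols)
    tau = np.full((k, k), np.nan)
    pv = np.full((k, k), np.nan)
    constant = [np.all(X[c].to_numpy() == X[c].to_numpy()[0]) for c in cols]
    for i in range(k):
        if constant[i]:
            continue
        tau[i, i] = 1.0
        pv[i, i] = 0.0
        for j in range(i + 1, k):
            if constant[j]:
                continue
            t, p = kendall_tau_b(X[cols[i]].to_numpy(), X[cols[j]].to_numpy())
            tau[i, j] = tau[j, i] = t
            pv[i, j] = pv[j, i] = p
    return KendallResult(
        tau=pd.DataFrame(tau, index=cols, columns=cols),
        pvals=pd.DataFrame(pv, index=cols, columns=cols),
    )


def fisher_ci_from_r(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a Pearson coefficient.

    CI = tanh(atanh(r) +/- z_crit / sqrt(n - 3)). Requires |r| < 1 and
    n >= 4 so that the standard error 1/sqrt(n-3) is defined.
    """
    if not -1.0 < r < 1.0:
        raise InputError("|r| must be < 1 for the Fisher transform")
    if n < 4:
        raise InputError("need n >= 4 for a Fisher-z interval")
    z = np.arctanh(r)
    z_crit = stats.norm.ppf(0.5 + level / 2.0)
    half = z_crit / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def pearson_with_fisher_ci(
    x, y, level: float = 0.95, protocol: str | None = None
) -> CorrelationReport:
    """Pearson r with Fisher-z CI, R^2 and two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 4:
        raise InputError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("Pearson r undefined for constant input")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    lo, hi = fisher_ci_from_r(r, n, level=level)
    return CorrelationReport(
        protocol=protocol,
        n=n,
        r=r,
        r_ci_low=lo,
        r_ci_high=hi,
        r_squared=r * r,
        p_value=float(res.pvalue),
    )


def drift_velocity_correlation(
    features: pd.DataFrame,
    protocol: str | None = None,
    signed: bool = False,
    level: float = 0.95,
) -> CorrelationReport:
    """Correlate peak head velocity with eye drift within one protocol.

    By default the drift magnitude |d_e| is used (drift offsets are
    negative while slippage severity grows with velocity, so the
    magnitude is the monotone quantity); ``signed=True`` correlates the
    signed drift instead.
    """
    df = features if protocol is None else features[features["protocol"] == protocol]
    if df.empty:
        raise InputError(f"no impulses for protocol {protocol!r}")
    drift = df["d_e"].to_numpy()
    if not signed:
        drift = np.abs(drift)
    return pearson_with_fisher_ci(
        df["v_max"].to_numpy(), drift, level=level, protocol=protocol
    )


def group_summary(
    features: pd.DataFrame,
    protocol: str,
    level: float = 0.95,
    drift_col: str = "d_e",
) -> GroupSummary:
    """Mean drift, sample SD, normal-approximation CI and mean v_max.

    The CI is mean +/- z_crit * sd / sqrt(n) with the normal critical
    value (not Student's t).
    """
    df = features[features["protocol"] == protocol]
    n = len(df)
    if n < 2:
        raise InputError(f"need at least 2 impulses in group {protocol!r}")
    drift = df[drift_col].to_numpy()
    mean = float(drift.mean())
    sd = float(drift.std(ddof=1))
    z_crit = stats.norm.ppf(0.5 + level / 2.0)
    half = z_crit * sd / np.sqrt(n)
    return GroupSummary(
        protocol=protocol,
        n=n,
        mean_drift=mean,
        drift_sd=sd,
        ci_low=mean - half,
        ci_high=mean + half,
        mean_head_vel=float(df["v_max"].mean()),
    )


def normal_ci(mean: float, sd: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI mean +/- z_crit * sd / sqrt(n)."""
    if n < 1 or sd < 0:
        raise InputError("need n >= 1 and sd >= 0")
    z_crit = stats.norm.ppf(0.5 + level / 2.0)
    half = z_crit * sd / np.sqrt(n)
    return float(mean - half), float(mean + half)


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df)."""
    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise InputError("every group needs at least 1 value")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        raise UndefinedCorrelationError(
            "Kruskal-Wallis undefined when all values are identical"
        )
    H, p = stats.kruskal(*arrays)
    return float(H), float(p)


def pairwise_mann_whitney(
    groups: dict[str, np.ndarray], alpha_family: float = 0.05
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U tests for every group pair.

    The Bonferroni-corrected significance threshold is
    ``alpha_family / number_of_pairs`` (0.05 / 3 = 0.0167 for three
    groups). The p-value uses exact enumeration for small tie-free
    samples and the tie-corrected normal approximation otherwise.
    """
    names = list(groups)
    if len(names) < 2:
        raise InputError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(len(a) == 0 for a in arrays.values()):
        raise InputError("every group needs at least 1 value")
    pairs = list(itertools.combinations(names, 2))
    threshold = alpha_family / len(pairs)
    rows = []
    for a, b in pairs:
        res = stats.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided")
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "U": float(res.statistic),
                "p": float(res.pvalue),
                "alpha_corrected": threshold,
                "significant": bool(res.pvalue < threshold),
            }
        )
    return pd.DataFrame(rows)
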