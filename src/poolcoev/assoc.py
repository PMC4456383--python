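"""Genotype-phenotype and treatment association statistics.

Genomic features of the evolved populations (variant frequencies, copy
numbers, HGT fragment frequencies, window statistics) are related to
phenotypes and experimental treatments with:

* weighted least-squares regression of a feature on a phenotype, weighted
  by log10 coverage (read depth controls the variance of pooled frequency
  estimates) or by inverse variance;
* a nested ANOVA with transfer, treatment (replicate populations nested
  within treatment as a fixed blocking factor), and the
  transfer x treatment interaction, using Type-II sums of squares to
  tolerate mild unbalance from extinct replicates;
* Spearman's rank correlation with an exact permutation p-value at small n;
* Benjamini-Hochberg step-up FDR adjustment across features;
* the candidate-region screen: variation in at least four replicate
  populations, a treatment effect without transfer or interaction
  effects, the >0.04 treatment-variance rule for HGT fragments, and a
  functional-consequence annotation flag.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = [
    "WlsResult",
    "SpearmanResult",
    "weighted_least_squares",
    "nested_anova",
    "spearman_correlation",
    "bh_fdr",
    "candidate_region_filter",
]

logger = logging.getLogger(__name__)


class SingularDesignError(ValueError):
    pass


@dataclass
class WlsResult:
    slope: float
    intercept: float
    t: float
    p: float
    r_squared: float


@dataclass
class SpearmanResult:
    rho: float
    p: float
    method: str  # "permutation" or "t-approximation"


def weighted_least_squares(x, y, weights) -> WlsResult:
    """Closed-form weighted least squares of y on x.

    Solves the weighted normal equations for slope and intercept and
    tests the slope with a two-sided t-test on n - 2 df. Estimates and
    p-values are invariant to rescaling all weights.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    W = w.sum()
    xbar = np.sum(w * x) / W
    ybar = np.sum(w * y) / W
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx == 0:
        raise SingularDesignError("x has no weighted spread")
    sxy = np.sum(w * (x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    df = x.size - 2
    s2 = np.sum(w * resid**2) / df
    se = np.sqrt(s2 / sxx)
    t = slope / se if se > 0 else np.inf * np.sign(slope)
    p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
    syy = np.sum(w * (y - ybar) ** 2)
    r2 = 1.0 - np.sum(w * resid**2) / syy if syy > 0 else 1.0
    return WlsResult(float(slope), float(intercept), float(t), float(p), float(r2))


def nested_anova(data: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effects nested ANOVA of a feature across the experiment.

    ``data`` columns: ``value``, ``transfer``, ``treatment``,
    ``replicate`` (replicate labels nested within treatment). The model
    is value ~ transfer + treatment + replicate-within-treatment +
    transfer:treatment, all fixed, with Type-II sums of squares and
    F-tests against the residual mean square. Terms rendered inestimable
    by empty cells are reported with NaN.

    Returns a DataFrame indexed by term (``transfer``, ``treatment``,
    ``replicate(treatment)``, ``transfer:treatment``) with columns
    ``df, sum_sq, F, p``.
    """
    for col in ("value", "transfer", "treatment", "replicate"):
        if col not in data:
            raise ValueError(f"missing column {col!r}")
    df = data.copy()
    for col in ("transfer", "treatment", "replicate"):
        df[col] = df[col].astype(str)
    if df["transfer"].nunique() < 2 or df["treatment"].nunique() < 2:
        raise ValueError("need >= 2 levels of transfer and treatment")
    # re-label replicates within treatment so nested labels are crossed-coded
    df["replicate"] = (
        df.groupby("treatment")["replicate"]
        .transform(lambda s: pd.factorize(s)[0])
        .astype(str)
    )
    model = ols(
        "value ~ C(transfer) + C(treatment) + C(treatment):C(replicate)"
        " + C(transfer):C(treatment)",
        data=df,
    ).fit()
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # nan F on zero-SS terms, handled below
        table = anova_lm(model, typ=2)
    rename = {
        "C(transfer)": "transfer",
        "C(treatment)": "treatment",
        "C(treatment):C(replicate)": "replicate(treatment)",
        "C(transfer):C(treatment)": "transfer:treatment",
    }
    out = table.rename(index=rename).rename(
        columns={"sum_sq": "sum_sq", "PR(>F)": "p"}
    )
    out = out.loc[[t for t in rename.values() if t in out.index] + ["Residual"]]
    out = out[["df", "sum_sq", "F", "p"]].copy()
    # degenerate designs: a term with zero SS has F = 0, p = 1 by convention;
    # with zero residual variance any term with positive SS is infinitely
    # significant
    tol = 1e-12 * max(1.0, float(np.abs(df["value"]).max()) ** 2)
    if np.ptp(df["value"].to_numpy()) == 0:
        # constant response: anova_lm emits NaN SS; every SS is exactly 0
        out["sum_sq"] = out["sum_sq"].fillna(0.0)
    zero_resid = out.loc["Residual", "sum_sq"] <= tol
    for term in out.index[:-1]:
        if out.loc[term, "sum_sq"] <= tol:
            out.loc[term, ["F", "p"]] = [0.0, 1.0]
        elif zero_resid:
            out.loc[term, ["F", "p"]] = [np.inf, 0.0]
    return out


def spearman_correlation(x, y) -> SpearmanResult:
    """Spearman's rank correlation with small-sample exact inference.

    rho is the Pearson correlation of fractional (tie-averaged) ranks.
    For n < 10 the two-sided p-value is exact, from full enumeration of
    all n! rank permutations; for n >= 10 the usual t approximation on
    n - 2 df is used. Constant input yields rho = NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(float("nan"), float("nan"), "undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n < 10:
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = np.sqrt(np.sum(rx_c**2) * np.sum(ry_c**2))
        obs = abs(np.sum(rx_c * ry_c) / denom)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.sum(rx_c * ry_c[list(perm)]) / denom
            count += abs(r) >= obs - 1e-12
            total += 1
        return SpearmanResult(rho, count / total, "permutation")
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return SpearmanResult(rho, float(p), "t-approximation")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped at
    1, returned in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def candidate_region_filter(
    results: pd.DataFrame,
    q_threshold: float = 0.05,
    min_replicates: int = 4,
    hgt_variance_threshold: float = 0.04,
) -> pd.DataFrame:
    """Flag candidate regions for host-adaptation relevance.

    ``results`` must carry, per feature row: ``n_replicates_with_variation``,
    ``q_treatment``, ``q_transfer``, ``q_interaction``,
    ``functional_consequence`` (bool), ``is_hgt`` (bool) and, for HGT
    rows, ``treatment_variance``. A feature is flagged when it varies in
    at least ``min_replicates`` replicate populations; shows a treatment
    effect (q < 0.05) but neither a transfer nor an interaction effect
    (both q >= 0.05); if it is an HGT fragment, its treatment variance
    strictly exceeds 0.04; and it has a functional consequence.

    Returns ``results`` with a boolean ``candidate`` column added.
    """
    r = results.copy()
    flag = (
        (r["n_replicates_with_variation"] >= min_replicates)
        & (r["q_treatment"] < q_threshold)
        & (r["q_transfer"] >= q_threshold)
        & (r["q_interaction"] >= q_threshold)
        & r["functional_consequence"].astype(bool)
    )
    if "is_hgt" in r:
        hgt = r["is_hgt"].astype(bool)
        var_ok = r.get("treatment_variance", pd.Series(0.0, index=r.index)).fillna(0.0)
        flag &= ~hgt | (var_ok > hgt_variance_threshold)
    r["candidate"] = flag
    return r
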