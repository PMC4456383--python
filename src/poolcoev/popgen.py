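"""Windowed population-genetic statistics for pooled sequencing data.

For pool-seq data the number of chromosomes sampled at a site is unknown;
read depth is used as a proxy for the sample size, so the estimators must
allow the sample size to vary from site to site:

* Watterson's theta per bp:  theta_W = sum_seg 1/a1(n_i) / L, where
  a1(n) = sum_{i<n} 1/i and n_i is the site's coverage;
* Tajima's pi per bp:  pi = sum_seg [n_i/(n_i - 1)] * 2 p_i (1 - p_i) / L,
  the per-site unbiased heterozygosity;
* Tajima's D uses the classical variance constants evaluated at the
  rounded mean coverage of the window's retained sites (median and
  harmonic-mean alternatives are exposed).

At constant coverage n these reduce exactly to the classical n-sample
estimators. Only polymorphisms with frequency strictly above the minor
allele threshold (default 0.05) are counted. Windows are
coordinate-anchored, half-open, default 10 kb wide with 5 kb steps;
trailing partial windows are emitted with their true length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WindowStats",
    "harmonic_numbers",
    "window_theta_w",
    "window_theta_pi",
    "tajima_d",
    "sliding_windows",
]

logger = logging.getLogger(__name__)


def harmonic_numbers(n: int) -> tuple[float, float]:
    """(a1, a2) = (sum_{i=1}^{n-1} 1/i, sum_{i=1}^{n-1} 1/i^2)."""
    if n < 2:
        raise ValueError("sample size must be >= 2")
    i = np.arange(1, n)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i**2))


@dataclass
class WindowStats:
    """Per-window summary; ``tajimas_d`` is NaN when S = 0 or the variance
    term degenerates."""

    contig: str
    start: int
    end: int
    theta_w: float
    pi: float
    tajimas_d: float
    s: int
    mean_coverage: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _retained(sites: pd.DataFrame, maf: float) -> pd.DataFrame:
    """Segregating sites passing coverage and frequency thresholds.

    Sites need coverage >= 2 and minor-allele frequency strictly above
    ``maf`` (so fixed and near-fixed sites drop out on both sides).
    """
    n = sites["coverage"].to_numpy(dtype=float)
    p = sites["freq"].to_numpy(dtype=float)
    minor = np.minimum(p, 1.0 - p)
    return sites[(n >= 2) & (minor > maf)]


def window_theta_w(sites: pd.DataFrame, window_length: float, maf: float = 0.05) -> float:
    """Coverage-adjusted Watterson's theta per bp over one window."""
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    kept = _retained(sites, maf)
    if len(kept) == 0:
        return 0.0
    a1 = np.array([harmonic_numbers(int(n))[0] for n in kept["coverage"]])
    return float(np.sum(1.0 / a1) / window_length)


def window_theta_pi(sites: pd.DataFrame, window_length: float, maf: float = 0.05) -> float:
    """Coverage-adjusted Tajima's pi per bp over one window."""
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    kept = _retained(sites, maf)
    if len(kept) == 0:
        return 0.0
    n = kept["coverage"].to_numpy(dtype=float)
    p = kept["freq"].to_numpy(dtype=float)
    return float(np.sum(n / (n - 1.0) * 2.0 * p * (1.0 - p)) / window_length)


def _tajima_constants(n: int) -> tuple[float, float]:
    a1, a2 = harmonic_numbers(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return c1 / a1, c2 / (a1**2 + a2)


def tajima_d(pi_total: float, theta_w_total: float, s: int, n_bar: float) -> float:
    """Classical Tajima's D from un-normalized window totals.

    ``pi_total`` and ``theta_w_total`` are the window sums before division
    by window length; the variance constants e1, e2 are evaluated at
    ``n = round(n_bar)``. Returns NaN when S = 0, n < 2, or the variance
    term is non-positive.
    """
    if s < 1:
        return float("nan")
    n = int(round(n_bar))
    if n < 2:
        logger.warning("Tajima's D undefined at mean coverage %.2f", n_bar)
        return float("nan")
    e1, e2 = _tajima_constants(n)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        logger.warning("non-positive variance term in Tajima's D (S=%d, n=%d)", s, n)
        return float("nan")
    return float((pi_total - theta_w_total) / np.sqrt(var))


def sliding_windows(
    sites: pd.DataFrame,
    contig_lengths: dict[str, int],
    window: int = 10_000,
    step: int = 5_000,
    maf: float = 0.05,
    coverage_summary: str = "mean",
) -> pd.DataFrame:
    """Compute theta_W, pi, and Tajima's D in sliding windows.

    ``sites`` columns: ``contig, position, coverage, freq`` (derived/alt
    frequency). Windows are [k*step, k*step + window) per contig for
    k*step < contig length, the trailing partials truncated to the contig
    end and normalized by their true length. ``coverage_summary`` selects
    how the window's Tajima-constant sample size is summarized from the
    retained sites: "mean" (default), "median", or "harmonic".
    """
    if window < step:
        raise ValueError("window must be >= step")
    summarize = {
        "mean": np.mean,
        "median": np.median,
        "harmonic": lambda x: len(x) / np.sum(1.0 / np.asarray(x, dtype=float)),
    }[coverage_summary]
    rows = []
    for contig, length in contig_lengths.items():
        on_contig = sites[sites["contig"] == contig]
        for start in range(0, length, step):
            end = min(start + window, length)
            in_win = on_contig[
                (on_contig["position"] >= start) & (on_contig["position"] < end)
            ]
            kept = _retained(in_win, maf)
            L = end - start
            tw = window_theta_w(in_win, L, maf)
            pi = window_theta_pi(in_win, L, maf)
            s = len(kept)
            n_bar = float(summarize(kept["coverage"].to_numpy())) if s else float("nan")
            rows.append(
                {
                    "contig": contig,
                    "start": start,
                    "end": end,
                    "theta_w": tw,
                    "pi": pi,
                    "tajimas_d": tajima_d(pi * L, tw * L, s, n_bar) if s else float("nan"),
                    "s": s,
                    "mean_coverage": n_bar,
                }
            )
    return pd.DataFrame(rows)
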