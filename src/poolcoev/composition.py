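"""Strain composition of pooled samples from diagnostic-site frequencies.

Each strain's relative abundance in a pooled sample is estimated from the
distribution of substitution frequencies at its diagnostic sites. Because
these distributions are typically asymmetric (read sampling, residual
mapping bias), the point estimate is the mode of the distribution rather
than the mean or median; we use the half-sample mode (HSM), a robust,
deterministic, bandwidth-free estimator, with a kernel-density mode
available as an alternative. Estimates are deliberately not renormalised
to sum to one: each strain's diagnostic sites give an independent
estimate, and the residual ``1 - sum`` is reported as a diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "StrainFrequencyProfile",
    "diagnostic_allele_frequencies",
    "estimate_mode",
    "half_sample_mode",
    "compose_population",
]

logger = logging.getLogger(__name__)


class NoDataError(ValueError):
    """Raised when an estimate is requested from an empty sample."""


@dataclass
class StrainFrequencyProfile:
    """Per-strain abundance estimates for one pooled sample."""

    estimates: dict[str, float]
    n_sites: dict[str, int]
    frequency_samples: dict[str, np.ndarray] = field(default_factory=dict)
    low_support: set[str] = field(default_factory=set)

    @property
    def unexplained(self) -> float:
        """1 minus the summed estimates: the mixture mass not attributed
        to any panel strain (sampling noise, unplaced strains)."""
        return 1.0 - float(sum(self.estimates.values()))

    def to_frame(self, sample_id: str = "sample") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": sample_id,
                "strain": list(self.estimates),
                "estimate": list(self.estimates.values()),
                "n_sites": [self.n_sites[s] for s in self.estimates],
                "low_support": [s in self.low_support for s in self.estimates],
                "residual": self.unexplained,
            }
        )


def diagnostic_allele_frequencies(
    pileup: pd.DataFrame,
    sites: pd.DataFrame,
    min_depth: int = 10,
) -> dict[str, np.ndarray]:
    """Per-strain vectors of diagnostic-allele frequencies.

    ``pileup`` columns: ``contig, position, depth, A, C, G, T``; ``sites``
    is a diagnostic-site table. At each site the frequency is the
    diagnostic-allele count over total depth; sites below ``min_depth``
    or absent from the pileup are dropped (counted, logged, not an error).
    """
    merged = sites.merge(pileup, on=["contig", "position"], how="left", indicator=True)
    n_missing = int((merged["_merge"] == "left_only").sum())
    if n_missing:
        logger.info("%d diagnostic sites absent from pileup, dropped", n_missing)
    merged = merged[merged["_merge"] == "both"]
    shallow = merged["depth"] < min_depth
    if shallow.any():
        logger.info("%d diagnostic sites below depth %d, dropped", int(shallow.sum()), min_depth)
    merged = merged[~shallow]
    out: dict[str, np.ndarray] = {}
    for strain, grp in merged.groupby("diagnostic_strain"):
        counts = np.array(
            [row[row["diagnostic_allele"]] for _, row in grp.iterrows()], dtype=float
        )
        out[str(strain)] = counts / grp["depth"].to_numpy(dtype=float)
    for strain in sites["diagnostic_strain"].unique():
        out.setdefault(str(strain), np.array([]))
    return out


def half_sample_mode(values: np.ndarray) -> float:
    """Half-sample mode: recursively keep the densest half of the sorted
    sample (the minimum-width window of ceil(n/2) points; ties broken by
    the leftmost window) until at most three points remain, then return
    the midpoint of the two closest remaining points."""
    x = np.sort(np.asarray(values, dtype=float))
    while x.size > 3:
        w = int(np.ceil(x.size / 2))
        widths = x[w - 1 :] - x[: x.size - w + 1]
        lo = int(np.argmin(widths))
        x = x[lo : lo + w]
    if x.size == 1:
        return float(x[0])
    if x.size == 2:
        return float(x.mean())
    return float(x[:2].mean()) if x[1] - x[0] < x[2] - x[1] else float(x[1:].mean())


def estimate_mode(frequencies: np.ndarray, method: str = "hsm") -> float:
    """Modal value of a vector of proportions, clipped to [0, 1].

    ``method="hsm"`` (default) uses the half-sample mode; ``method="kde"``
    maximises a Gaussian kernel density estimate on a fine grid
    (Scott bandwidth), falling back to HSM for degenerate samples.
    """
    x = np.asarray(frequencies, dtype=float)
    if x.size == 0:
        raise NoDataError("cannot estimate the mode of an empty sample")
    if method == "hsm":
        m = half_sample_mode(x)
    elif method == "kde":
        if np.ptp(x) == 0 or x.size < 3:
            m = half_sample_mode(x)
        else:
            kde = gaussian_kde(x)
            grid = np.linspace(x.min(), x.max(), 512)
            m = float(grid[np.argmax(kde(grid))])
    else:
        raise ValueError(f"unknown mode method {method!r}")
    return float(np.clip(m, 0.0, 1.0))


def compose_population(
    pileup: pd.DataFrame,
    sites: pd.DataFrame,
    min_depth: int = 10,
    min_sites: int = 20,
    method: str = "hsm",
) -> StrainFrequencyProfile:
    """Estimate every panel strain's abundance in one pooled sample.

    Strains with fewer than ``min_sites`` usable diagnostic sites are
    still estimated but flagged as low-support; a strain with no usable
    site at all receives estimate 0 with ``n_sites`` 0.
    """
    freqs = diagnostic_allele_frequencies(pileup, sites, min_depth=min_depth)
    estimates: dict[str, float] = {}
    n_sites: dict[str, int] = {}
    low_support: set[str] = set()
    for strain in sorted(freqs):
        v = freqs[strain]
        n_sites[strain] = int(v.size)
        if v.size == 0:
            estimates[strain] = 0.0
            low_support.add(strain)
            continue
        if v.size < min_sites:
            low_support.add(strain)
            logger.warning(
                "strain %s estimated from only %d diagnostic sites (< %d)",
                strain, v.size, min_sites,
            )
        estimates[strain] = estimate_mode(v, method=method)
    return StrainFrequencyProfile(
        estimates=estimates,
        n_sites=n_sites,
        frequency_samples=freqs,
        low_support=low_support,
    )
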