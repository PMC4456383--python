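"""Rank-based copy-number-variation detection for pooled samples.

Standard read-depth CNV callers assume each sample is an individual, so a
duplication carried by only part of a pooled population — which shifts
coverage by a factor between 1 and the copy number — falls below their
detection model. The approach here targets exactly that signature:

1. within each sample, transform per-position depth to fractional ranks
   (tie-averaged, divided by the number of positions), which removes
   between-sample differences in sequencing depth;
2. compute the sample variance (n-1 denominator) of each position's
   normalized rank across samples — positions where some populations
   carry a CNV and others do not have unusually variable ranks;
3. extract right-tail outliers of the variance distribution by fitting a
   normal to its central quantile band via QQ regression and flagging
   values whose expected count under the fit is below ``rho``;
4. merge flagged positions closer than 100 bp into "coverage
   singularities" and estimate each sample's copy number as the region's
   median depth over the median depth of chromosomal contigs.

Contig-level copy number (e.g. plasmid amplification) is the ratio of a
contig's mean depth to the chromosomal mean, with a positional bootstrap
variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "CoverageMatrix",
    "CnvCall",
    "rank_transform",
    "rank_variance",
    "detect_outlier_positions",
    "merge_adjacent",
    "estimate_copy_number",
    "contig_copy_number",
    "call_cnvs",
]

logger = logging.getLogger(__name__)


class NoVarianceError(ValueError):
    """Variance across samples requested with fewer than two samples."""


class UndefinedRatioError(ZeroDivisionError):
    """Copy-number ratio with a zero chromosomal-median denominator."""


@dataclass
class CoverageMatrix:
    """Per-position depth for several samples on a shared coordinate system.

    ``depths`` is a DataFrame indexed by (contig, position) with one
    integer column per sample; ``roles`` maps contig to "chromosomal" or
    "plasmid".
    """

    depths: pd.DataFrame
    roles: dict[str, str]

    def __post_init__(self) -> None:
        if (self.depths.to_numpy() < 0).any():
            raise ValueError("depths must be non-negative")

    @classmethod
    def from_samples(cls, samples, roles: dict[str, str]) -> "CoverageMatrix":
        """Assemble from PooledSample objects (shared contigs assumed)."""
        cols = {}
        index = None
        for s in samples:
            parts = []
            for contig, track in sorted(s.depth.items()):
                parts.append(
                    pd.Series(
                        track,
                        index=pd.MultiIndex.from_product(
                            [[contig], range(len(track))], names=["contig", "position"]
                        ),
                    )
                )
            col = pd.concat(parts)
            cols[s.sample_id] = col
            index = col.index if index is None else index
        return cls(depths=pd.DataFrame(cols, index=index), roles=roles)

    @property
    def samples(self) -> list[str]:
        return list(self.depths.columns)

    def chromosomal_mask(self) -> np.ndarray:
        contigs = self.depths.index.get_level_values("contig")
        chrom = {c for c, r in self.roles.items() if r == "chromosomal"}
        return contigs.isin(chrom)


@dataclass
class CnvCall:
    """One coverage singularity with per-sample copy-number estimates."""

    contig: str
    start: int
    end: int
    copy_number: dict[str, float]
    n_positions: int
    peak_rank_variance: float

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("CNV region must span at least one position")


def rank_transform(matrix: CoverageMatrix) -> pd.DataFrame:
    """Within-sample fractional ranks of depth, normalized by position count.

    Ties receive the average rank; dividing by the number of positions
    maps ranks into (0, 1] so samples of unequal breadth are comparable.
    Ranks are computed genome-wide across all contigs.
    """
    if len(matrix.depths) < 2:
        raise ValueError("need at least 2 positions to rank")
    ranks = matrix.depths.apply(lambda col: rankdata(col, method="average"), axis=0)
    return ranks / len(matrix.depths)


def rank_variance(ranks: pd.DataFrame) -> pd.Series:
    """Sample variance (ddof=1) of each position's normalized rank across
    samples."""
    if ranks.shape[1] < 2:
        raise NoVarianceError("rank variance needs at least 2 samples")
    return ranks.var(axis=1, ddof=1)


def detect_outlier_positions(
    variances: pd.Series | np.ndarray,
    rho: float = 1.0,
    band: tuple[float, float] = (0.1, 0.9),
) -> np.ndarray:
    """Right-tail outliers of the rank-variance distribution.

    A normal distribution is fitted to the central quantile band of the
    sorted variances by least-squares regression of observed values on
    theoretical normal quantiles (QQ regression). An observation ``y`` is
    flagged when the expected number of values >= y under the fitted
    normal, ``N * (1 - Phi((y - mu)/sigma))``, is below ``rho`` —
    equivalently when ``y > mu + sigma * Phi^-1(1 - rho/N)``. Only the
    right tail is considered (CNVs raise rank variance). Degenerate
    (zero-spread) inputs yield no outliers.

    Returns the integer positions (into the input ordering) of flagged
    values.
    """
    v = np.asarray(variances, dtype=float)
    N = v.size
    if N < 100:
        logger.warning("outlier fit on only %d positions; unstable", N)
    if N < 3 or np.ptp(v) == 0:
        return np.array([], dtype=int)
    order = np.argsort(v, kind="stable")
    y = v[order]
    lo = int(np.floor(band[0] * N))
    hi = int(np.ceil(band[1] * N))
    sel = np.arange(lo, hi)
    if sel.size < 2:
        return np.array([], dtype=int)
    q = norm.ppf((sel + 0.5) / N)
    yy = y[sel]
    sigma, mu = np.polyfit(q, yy, 1)
    if sigma <= 0 or np.ptp(yy) == 0:
        return np.array([], dtype=int)
    threshold = mu + sigma * norm.ppf(1 - min(rho / N, 1.0))
    return np.nonzero(v > threshold)[0]


def merge_adjacent(
    positions: pd.DataFrame | list[tuple[str, int]], max_gap: int = 100
) -> list[tuple[str, int, int]]:
    """Merge outlier positions closer than ``max_gap`` bp (strict) on the
    same contig into half-open regions.

    ``positions`` rows are (contig, position). Successive positions with
    distance < ``max_gap`` join the same region; distance exactly
    ``max_gap`` starts a new one.
    """
    if isinstance(positions, pd.DataFrame):
        items = list(positions[["contig", "position"]].itertuples(index=False, name=None))
    else:
        items = list(positions)
    items.sort()
    regions: list[tuple[str, int, int]] = []
    for contig, pos in items:
        if regions and regions[-1][0] == contig and pos - (regions[-1][2] - 1) < max_gap:
            regions[-1] = (contig, regions[-1][1], pos + 1)
        else:
            regions.append((contig, pos, pos + 1))
    return regions


def estimate_copy_number(
    region: tuple[str, int, int], matrix: CoverageMatrix
) -> dict[str, float]:
    """Per-sample copy number of a region: median depth inside the region
    over the median depth across all chromosomal-role positions."""
    contig, start, end = region
    chrom = matrix.chromosomal_mask()
    if not chrom.any():
        raise UndefinedRatioError("no chromosomal contigs in matrix")
    idx = matrix.depths.index
    in_region = (idx.get_level_values("contig") == contig) & (
        (idx.get_level_values("position") >= start)
        & (idx.get_level_values("position") < end)
    )
    out: dict[str, float] = {}
    for sample in matrix.samples:
        denom = float(matrix.depths.loc[chrom, sample].median())
        if denom == 0:
            raise UndefinedRatioError(f"zero chromosomal median for sample {sample}")
        out[sample] = float(matrix.depths.loc[in_region, sample].median()) / denom
    return out


def contig_copy_number(
    matrix: CoverageMatrix, seed: int = 0, n_boot: int = 10_000
) -> pd.DataFrame:
    """Contig-level copy number per sample with a positional bootstrap.

    The ratio is a contig's mean depth over the mean depth of all
    chromosomal contigs; its variance is estimated from ``n_boot``
    positions sampled with replacement from the contig (all positions if
    fewer), each contributing the per-position ratio depth/chromosomal
    mean.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chrom = matrix.chromosomal_mask()
    rows = []
    contigs = matrix.depths.index.get_level_values("contig")
    for contig in matrix.depths.index.unique("contig"):
        sub = matrix.depths[contigs == contig]
        for sample in matrix.samples:
            denom = float(matrix.depths.loc[chrom, sample].mean())
            if denom == 0:
                ratio, var = np.nan, np.nan
            else:
                depths = sub[sample].to_numpy(dtype=float)
                ratio = float(depths.mean()) / denom
                take = rng.integers(0, depths.size, size=min(n_boot, max(depths.size, 1)))
                var = float(np.var(depths[take] / denom, ddof=1)) if take.size > 1 else np.nan
            rows.append(
                {"contig": contig, "sample": sample, "ratio": ratio, "variance": var}
            )
    return pd.DataFrame(rows)


def call_cnvs(
    matrix: CoverageMatrix,
    rho: float = 1.0,
    max_gap: int = 100,
    band: tuple[float, float] = (0.1, 0.9),
) -> list[CnvCall]:
    """Full detector: rank transform, rank variance, outlier extraction,
    merging, and per-sample copy-number estimation."""
    ranks = rank_transform(matrix)
    variances = rank_variance(ranks)
    flagged = detect_outlier_positions(variances, rho=rho, band=band)
    pos_df = pd.DataFrame(
        {
            "contig": variances.index.get_level_values("contig")[flagged],
            "position": variances.index.get_level_values("position")[flagged],
        }
    )
    calls = []
    var_lookup = variances
    for contig, start, end in merge_adjacent(pos_df, max_gap=max_gap):
        region_vars = var_lookup.loc[contig].loc[start : end - 1]
        calls.append(
            CnvCall(
                contig=contig,
                start=start,
                end=end,
                copy_number=estimate_copy_number((contig, start, end), matrix),
                n_positions=int(
                    ((pos_df["contig"] == contig)
                     & (pos_df["position"] >= start)
                     & (pos_df["position"] < end)).sum()
                ),
                peak_rank_variance=float(region_vars.max()),
            )
        )
    return calls
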