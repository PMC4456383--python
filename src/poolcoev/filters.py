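"""Post-calling filters for pooled-sample variant tables.

Variant callers on pooled bacterial data emit many artefactual records at
anomalous-coverage positions (collapsed repeats, deletions), on single
strands (library artefacts), at indel-disturbed alignments, and at
frequencies indistinguishable from sequencing error. Four filters are
applied, in order:

(i)   coverage-quantile — drop records below the 2% or above the 98%
      quantile of the per-sample depth distribution;
(ii)  strand bias — drop records with a significant two-sided Fisher's
      exact test on the [[alt_fwd, alt_rev], [ref_fwd, ref_rev]] table;
(iii) indel collision — drop SNPs sharing a position with an indel;
(iv)  minimum allele frequency — keep records with alt/depth strictly
      above the threshold (default 5%).

Variant tables are pandas DataFrames with columns ``sample, contig,
position, type, ref, alt, depth, alt_count, alt_fwd, alt_rev, ref_fwd,
ref_rev`` (``type`` in {"SNP", "indel"}; positions 0-based internally).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

__all__ = [
    "coverage_quantile_filter",
    "strand_bias_filter",
    "indel_collision_filter",
    "maf_filter",
    "apply_all",
    "VARIANT_COLUMNS",
]

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = [
    "sample", "contig", "position", "type", "ref", "alt",
    "depth", "alt_count", "alt_fwd", "alt_rev", "ref_fwd", "ref_rev",
]

MIN_RECORDS_FOR_QUANTILES = 50


class InvalidRecordError(ValueError):
    pass


def _validate(variants: pd.DataFrame) -> None:
    if len(variants) == 0:
        return
    counts = variants[["alt_fwd", "alt_rev", "ref_fwd", "ref_rev"]]
    if (counts.to_numpy() < 0).any():
        raise InvalidRecordError("negative strand counts")
    if (variants["alt_count"] > variants["depth"]).any():
        raise InvalidRecordError("alt count exceeds depth")


def coverage_quantile_filter(
    variants: pd.DataFrame, low: float = 0.02, high: float = 0.98
) -> pd.DataFrame:
    """Drop records at extreme depths of the per-sample coverage distribution.

    Quantiles are empirical with linear interpolation, computed per sample
    on the depths of that sample's records; a record is dropped when its
    depth is strictly below the low or strictly above the high quantile.
    Samples with fewer than 50 records pass through unfiltered (quantiles
    would be meaningless), with a warning.
    """
    if len(variants) == 0:
        return variants
    keep = np.ones(len(variants), dtype=bool)
    for sample, grp in variants.groupby("sample"):
        depths = grp["depth"].to_numpy(dtype=float)
        if depths.size < MIN_RECORDS_FOR_QUANTILES:
            logger.warning(
                "sample %s: only %d records, coverage-quantile filter skipped",
                sample, depths.size,
            )
            continue
        q_lo, q_hi = np.quantile(depths, [low, high], method="linear")
        bad = (depths < q_lo) | (depths > q_hi)
        keep[variants.index.get_indexer(grp.index)] &= ~bad
    return variants[keep].copy()

def strand_bias_filter(variants: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Drop records whose alt/ref read counts are significantly unbalanced
    between strands (two-sided Fisher's exact test, p < alpha)."""
    _validate(variants)
    if len(variants) == 0:
        return variants
    pvals = np.array(
        [
            fisher_exact(
                [[r.alt_fwd, r.alt_rev], [r.ref_fwd, r.ref_rev]],
                alternative="two-sided",
            )[1]
            for r in variants.itertuples()
        ]
    )
    return variants[pvals >= alpha].copy()


def indel_collision_filter(variants: pd.DataFrame) -> pd.DataFrame:
    """Drop SNPs at positions where the same sample also has an indel call
    (the indel is retained)."""
    if len(variants) == 0:
        return variants
    indel_keys = set(
        map(
            tuple,
            variants.loc[variants["type"] == "indel", ["sample", "contig", "position"]]
            .itertuples(index=False, name=None),
        )
    )
    if not indel_keys:
        return variants
    is_colliding_snp = variants.apply(
        lambda r: r["type"] == "SNP"
        and (r["sample"], r["contig"], r["position"]) in indel_keys,
        axis=1,
    )
    return variants[~is_colliding_snp].copy()


def maf_filter(variants: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Keep records whose allele frequency alt/depth is strictly above the
    threshold. Zero-depth records are dropped with a warning."""
    if len(variants) == 0:
        return variants
    zero = variants["depth"] <= 0
    if zero.any():
        logger.warning("%d zero-depth records dropped in MAF filter", int(zero.sum()))
    v = variants[~zero]
    freq = v["alt_count"] / v["depth"]
    return v[freq > threshold].copy()


def apply_all(
    variants: pd.DataFrame,
    low: float = 0.02,
    high: float = 0.98,
    alpha: float = 0.05,
    maf: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the four filters in order (i)-(iv) and audit per-filter drops.

    The coverage quantiles are computed on the pre-filter depth
    distribution (the filter order matters only through this step).
    Returns the surviving records and a dict of records dropped per filter.
    """
    counts: dict[str, int] = {}
    stages = [
        ("coverage_quantile", lambda v: coverage_quantile_filter(v, low, high)),
        ("strand_bias", lambda v: strand_bias_filter(v, alpha)),
        ("indel_collision", indel_collision_filter),
        ("maf", lambda v: maf_filter(v, maf)),
    ]
    out = variants
    for name, fn in stages:
        before = len(out)
        out = fn(out)
        counts[name] = before - len(out)
        logger.info("filter %s: %d -> %d records", name, before, len(out))
    return out, counts
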