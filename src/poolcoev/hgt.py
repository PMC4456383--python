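"""Horizontal gene transfer detection by competitive read mapping.

In a population dominated by the focal strain, reads that map uniquely and
best (strictly lowest edit distance) to one of the *other* panel strains
indicate DNA acquired from that strain. A transferred fragment is called
when such donor-assigned coverage runs continuously over at least 1 kb of
the donor genome; short internal coverage gaps (default <= 100 bp, the
same distance used to merge CNV outliers) are tolerated because read
sampling at low fragment frequency would otherwise shatter true
fragments. The fragment's within-population frequency is the ratio of its
median donor-assigned depth to the median depth over the focal strain's
chromosomal contigs — a ratio that may exceed 1 for multicopy elements
(e.g. transferred phage) and is deliberately not clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .panel import ReadAssignment

__all__ = [
    "HgtFragment",
    "nonfocal_coverage",
    "call_fragments",
    "fragment_frequency",
    "treatment_variance_screen",
]

logger = logging.getLogger(__name__)


class UndefinedRatioError(ZeroDivisionError):
    """Fragment frequency with a zero focal chromosomal median."""


@dataclass
class HgtFragment:
    """A putative horizontally transferred fragment on donor coordinates."""

    donor: str
    contig: str
    start: int
    end: int
    frequency: dict[str, float] = field(default_factory=dict)
    median_depth: dict[str, float] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start


def nonfocal_coverage(
    assignments: list[ReadAssignment],
    donor: str,
    contig_lengths: dict[str, int],
    read_length: int = 100,
    contig_of: dict[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """Depth track of reads uniquely best assigned to ``donor``.

    Each assigned read contributes 1x coverage over ``read_length``
    positions from its mapped position. Reads excluded by the tie rule
    contribute nothing. ``contig_of`` maps read id to donor contig when
    assignments carry flat positions on a multi-contig donor; with a
    single contig it may be omitted.
    """
    tracks = {c: np.zeros(n, dtype=int) for c, n in contig_lengths.items()}
    single = next(iter(contig_lengths)) if len(contig_lengths) == 1 else None
    for rec in assignments:
        if rec.assigned != donor or rec.position is None:
            continue
        contig = (contig_of or {}).get(rec.read_id, single)
        if contig is None:
            raise ValueError(f"no contig for read {rec.read_id!r} on multi-contig donor")
        track = tracks[contig]
        lo = max(0, rec.position)
        hi = min(track.size, rec.position + read_length)
        if lo < hi:
            track[lo:hi] += 1
    return tracks


def call_fragments(
    tracks: dict[str, np.ndarray],
    donor: str,
    min_length: int = 1000,
    max_gap: int = 100,
    min_depth: int = 1,
) -> list[HgtFragment]:
    """Call HGT fragments from a donor-assigned depth track.

    Maximal runs of positions with depth >= ``min_depth`` are extended
    across internal sub-threshold gaps of <= ``max_gap`` positions, then
    retained iff the resulting half-open span is >= ``min_length`` bp.
    """
    fragments: list[HgtFragment] = []
    for contig, track in tracks.items():
        covered = np.nonzero(np.asarray(track) >= min_depth)[0]
        if covered.size == 0:
            continue
        run_start = prev = int(covered[0])
        for pos in covered[1:]:
            pos = int(pos)
            if pos - prev - 1 > max_gap:
                if prev + 1 - run_start >= min_length:
                    fragments.append(HgtFragment(donor, contig, run_start, prev + 1))
                run_start = pos
            prev = pos
        if prev + 1 - run_start >= min_length:
            fragments.append(HgtFragment(donor, contig, run_start, prev + 1))
    return fragments


def fragment_frequency(
    fragment: HgtFragment,
    donor_track: np.ndarray,
    focal_chromosomal_depths: np.ndarray,
) -> float:
    """Within-population frequency of a transferred fragment.

    Median donor-assigned depth inside the fragment divided by the median
    depth across the focal strain's chromosomal contigs. A fragment with
    no donor-assigned coverage in a sample has frequency 0.
    """
    denom = float(np.median(focal_chromosomal_depths))
    if denom == 0:
        raise UndefinedRatioError("zero focal chromosomal median depth")
    return float(np.median(donor_track[fragment.start : fragment.end])) / denom


def treatment_variance_screen(
    frequencies_by_treatment: dict[str, list[float]], threshold: float = 0.04
) -> bool:
    """Flag a fragment whose frequency varies among treatment groups.

    The screen passes (returns True) when the sample variance (ddof=1) of
    the per-treatment mean frequencies strictly exceeds ``threshold``.
    """
    if len(frequencies_by_treatment) < 2:
        raise ValueError("need at least 2 treatment groups")
    means = np.array([np.mean(v) for v in frequencies_by_treatment.values()])
    return bool(np.var(means, ddof=1) > threshold)
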