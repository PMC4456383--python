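"""Strain reference panel: metareference construction, diagnostic sites, read assignment.

A :class:`ReferencePanel` holds a multiple alignment of the strain genomes
that founded a pooled population (for the system this package was built
around: five *Bacillus thuringiensis* strains, with BT-679 as the focal
strain). From the panel we derive

* a *metareference* — a single consensus sequence in which polymorphic
  columns are collapsed to IUPAC ambiguity codes, so that strain variants
  are not scored as mismatches during mapping;
* a table of *diagnostic sites* — alignment columns where exactly one
  strain carries a substitution, whose pooled read frequency estimates
  that strain's abundance;
* competitive *read assignments* — each read is credited to the strain
  against which it has the strictly lowest edit distance (SAM ``NM``),
  with all ties excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReferencePanel",
    "ReadAssignment",
    "build_metareference",
    "find_diagnostic_sites",
    "assign_reads",
    "IUPAC_TO_BASES",
    "BASES_TO_IUPAC",
]

# IUPAC nucleotide ambiguity codes <-> base sets
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

GAP = "-"


class PanelError(ValueError):
    """Invalid reference panel or panel-derived input."""


@dataclass
class ReferencePanel:
    """Aligned strain genomes plus contig metadata.

    Parameters
    ----------
    strain_ids
        Strain labels, one per aligned sequence.
    aligned_sequences
        Equal-length nucleotide strings (gap ``-`` allowed), one per strain,
        in the order of ``strain_ids``.
    contig_table
        DataFrame with columns ``contig``, ``start``, ``end`` (0-based
        half-open alignment coordinates) and ``role`` in
        ``{"chromosomal", "plasmid"}``. Spans must be disjoint and cover
        the alignment.
    focal_strain
        The strain whose genome anchors the fine-scale analysis.
    """

    strain_ids: list[str]
    aligned_sequences: list[str]
    contig_table: pd.DataFrame
    focal_strain: str

    def __post_init__(self) -> None:
        if len(self.strain_ids) != len(self.aligned_sequences):
            raise PanelError("one aligned sequence required per strain")
        lengths = {len(s) for s in self.aligned_sequences}
        if len(lengths) > 1:
            raise PanelError(f"aligned sequences differ in length: {sorted(lengths)}")
        if self.focal_strain not in self.strain_ids:
            raise PanelError(f"focal strain {self.focal_strain!r} not in panel")
        ct = self.contig_table.sort_values("start").reset_index(drop=True)
        L = self.alignment_length
        if len(ct):
            spans = list(zip(ct["start"], ct["end"]))
            if spans[0][0] != 0 or spans[-1][1] != L:
                raise PanelError("contig spans must cover the alignment")
            for (s0, e0), (s1, _) in zip(spans, spans[1:]):
                if e0 != s1:
                    raise PanelError("contig spans must be disjoint and contiguous")
        bad = set(ct["role"]) - {"chromosomal", "plasmid"}
        if bad:
            raise PanelError(f"unknown contig roles: {bad}")
        self.contig_table = ct

    @property
    def alignment_length(self) -> int:
        return len(self.aligned_sequences[0])

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    def sequence(self, strain: str) -> str:
        return self.aligned_sequences[self.strain_ids.index(strain)]

    def contig_of(self, position: int) -> str:
        """Contig containing an alignment position."""
        row = self.contig_table[
            (self.contig_table["start"] <= position) & (position < self.contig_table["end"])
        ]
        if row.empty:
            raise PanelError(f"position {position} outside alignment")
        return row.iloc[0]["contig"]

    def to_local(self, position: int) -> tuple[str, int]:
        """Map an alignment position to (contig, within-contig position)."""
        contig = self.contig_of(position)
        start = int(
            self.contig_table.loc[self.contig_table["contig"] == contig, "start"].iloc[0]
        )
        return contig, position - start


@dataclass
class ReadAssignment:
    """Competitive assignment of one read across the strain panel.

    ``distances`` maps strain id to edit distance (``NM``), with strains the
    read did not map to absent. ``assigned`` is the uniquely-best strain or
    ``"excluded"`` when the minimum is tied or no distance is available.
    """

    read_id: str
    distances: dict[str, int]
    assigned: str = "excluded"
    position: int | None = None
    positions: dict[str, int] = field(default_factory=dict)


def _column_bases(chars: tuple[str, ...], position: int) -> set[str]:
    bases: set[str] = set()
    for c in chars:
        c = c.upper()
        if c == GAP:
            continue
        if c not in IUPAC_TO_BASES:
            raise PanelError(f"invalid character {c!r} at column {position}")
        bases |= IUPAC_TO_BASES[c]
    return bases


def build_metareference(panel: ReferencePanel) -> str:
    """Collapse the panel alignment into a single IUPAC-coded consensus.

    Each column becomes the IUPAC code for the union of bases observed in
    it; gap characters are dropped from the union (indel columns are kept
    without gaps), and a column consisting only of gaps is omitted.
    """
    out: list[str] = []
    for i, chars in enumerate(zip(*panel.aligned_sequences)):
        bases = _column_bases(chars, i)
        if not bases:
            continue  # all-gap column: nothing to represent
        out.append(BASES_TO_IUPAC[frozenset(bases)])
    return "".join(out)


def find_diagnostic_sites(panel: ReferencePanel) -> pd.DataFrame:
    """Identify strain-diagnostic alignment columns.

    A column is diagnostic when it is a biallelic substitution in which
    exactly one strain carries the minority allele and every other strain
    carries the shared background allele. Columns containing gaps, N or
    other ambiguity codes, or more than two alleles are excluded, as are
    panels of fewer than three strains (the 1-vs-rest pattern is then
    undefined).

    Returns
    -------
    DataFrame with columns ``contig``, ``position`` (0-based, within
    contig), ``aln_position`` (alignment column), ``diagnostic_strain``,
    ``diagnostic_allele``, ``background_allele``, sorted by
    (contig, position).
    """
    rows: list[dict] = []
    k = panel.n_strains
    if k < 3:
        return _empty_sites_table()
    seqs = [s.upper() for s in panel.aligned_sequences]
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(k, -1)
    acgt = np.isin(arr, [b"A", b"C", b"G", b"T"]).all(axis=0)
    # candidate columns: pure ACGT and polymorphic
    poly = ~(arr == arr[0]).all(axis=0)
    for col in np.nonzero(acgt & poly)[0]:
        column = arr[:, col]
        alleles, counts = np.unique(column, return_counts=True)
        if len(alleles) != 2:
            continue
        minority = int(np.argmin(counts))
        if counts[minority] != 1 or counts[1 - minority] != k - 1:
            continue
        strain_idx = int(np.nonzero(column == alleles[minority])[0][0])
        contig, local = panel.to_local(int(col))
        rows.append(
            {
                "contig": contig,
                "position": local,
                "aln_position": int(col),
                "diagnostic_strain": panel.strain_ids[strain_idx],
                "diagnostic_allele": alleles[minority].decode(),
                "background_allele": alleles[1 - minority].decode(),
            }
        )
    if not rows:
        return _empty_sites_table()
    return (
        pd.DataFrame(rows)
        .sort_values(["contig", "position"])
        .reset_index(drop=True)
    )


def _empty_sites_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "contig",
            "position",
            "aln_position",
            "diagnostic_strain",
            "diagnostic_allele",
            "background_allele",
        ]
    )


def assign_reads(
    alignments: list[ReadAssignment] | list[dict],
    strains: list[str],
    focal: str | None = None,
) -> list[ReadAssignment]:
    """Competitively assign reads to their uniquely best-matching strain.

    A read is assigned to a strain iff that strain's edit distance is
    strictly lower than every other strain's (strains the read did not map
    to count as infinitely distant). Any tie for the minimum excludes the
    read. ``focal`` is validated against ``strains`` but does not change
    the rule; the same uniquely-best semantics serve both the focal-strain
    variant analysis and non-focal HGT read extraction.
    """
    if focal is not None and focal not in strains:
        raise PanelError(f"unknown strain label {focal!r}")
    known = set(strains)
    out: list[ReadAssignment] = []
    for rec in alignments:
        if isinstance(rec, dict):
            rec = ReadAssignment(
                read_id=rec["read_id"],
                distances=rec["distances"],
                positions=rec.get("positions", {}),
            )
        unknown = set(rec.distances) - known
        if unknown:
            raise PanelError(f"unknown strain label(s) {sorted(unknown)}")
        if not rec.distances:
            raise PanelError(f"read {rec.read_id!r} has no distances")
        full = {s: rec.distances.get(s, math.inf) for s in strains}
        best = min(full.values())
        winners = [s for s, d in full.items() if d == best]
        if len(winners) == 1 and math.isfinite(best):
            rec.assigned = winners[0]
            rec.position = rec.positions.get(winners[0])
        else:
            rec.assigned = "excluded"
            rec.position = None
        out.append(rec)
    return out
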