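"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython, SAM through pysam (plain-text SAM works, no
index needed); every binary/standard format has a TSV twin so the whole
pipeline can run on plain text. Coordinates are 0-based half-open
internally, 1-based in VCF output, 0-based half-open in BED — the writers
own those conversions. Output files carry provenance comment headers
(tool version, config hash, seed) but no timestamps, so reruns are
bit-reproducible.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .panel import ReadAssignment

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_alignment_summaries",
    "read_assignment_tsv",
    "write_bed",
    "write_vcf",
    "read_vcf",
    "write_tsv",
    "read_tsv",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    pass


def _provenance(extra: dict | None = None, comment: str = "#") -> list[str]:
    lines = [f"{comment} poolcoev {__version__}"]
    for k, v in (extra or {}).items():
        lines.append(f"{comment} {k}: {v}")
    return lines


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as (id, sequence) pairs; empty file yields an empty list."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: list[tuple[str, str]], width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_alignment_summaries(
    path: str | Path, strain: str | None = None
) -> tuple[list[dict], int]:
    """Read per-read edit-distance records from SAM/BAM or a TSV twin.

    SAM/BAM: each mapped record contributes
    ``{read_id, strain, position, nm}`` with ``strain`` the reference name
    (or the ``strain`` argument when the file holds one strain's
    alignments). Records without an NM tag are skipped and counted.
    TSV: columns ``read_id, strain, position, nm``.

    Returns (records, n_skipped_missing_nm).
    """
    path = Path(path)
    if path.suffix.lower() in {".sam", ".bam"}:
        records: list[dict] = []
        skipped = 0
        mode = "rb" if path.suffix.lower() == ".bam" else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
            for aln in fh.fetch(until_eof=True):
                if aln.is_unmapped:
                    continue
                if not aln.has_tag("NM"):
                    skipped += 1
                    continue
                records.append(
                    {
                        "read_id": aln.query_name,
                        "strain": strain or aln.reference_name,
                        "position": aln.reference_start,
                        "nm": int(aln.get_tag("NM")),
                    }
                )
        if skipped:
            logger.warning("%d alignments without NM tag skipped in %s", skipped, path)
        return records, skipped
    if path.suffix.lower() in {".tsv", ".txt"}:
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"read_id", "strain", "position", "nm"}
        if not required <= set(df.columns):
            raise FormatError(f"TSV twin missing columns {required - set(df.columns)}")
        return df.to_dict("records"), 0
    raise FormatError(f"unknown alignment format: {path.suffix!r}")


def read_assignment_tsv(paths: list[str | Path]) -> list[ReadAssignment]:
    """Combine per-strain alignment summaries into ReadAssignment inputs."""
    by_read: dict[str, ReadAssignment] = {}
    for path in paths:
        records, _ = read_alignment_summaries(path)
        for rec in records:
            ra = by_read.setdefault(
                rec["read_id"], ReadAssignment(read_id=rec["read_id"], distances={})
            )
            ra.distances[rec["strain"]] = int(rec["nm"])
            ra.positions[rec["strain"]] = int(rec["position"])
    return list(by_read.values())


def write_bed(
    path: str | Path,
    intervals: list[tuple],
    provenance: dict | None = None,
) -> None:
    """Write (contig, start, end[, name[, score]]) as BED (0-based half-open)."""
    lines = _provenance(provenance)
    for iv in intervals:
        contig, start, end, *rest = iv
        if end <= start:
            raise FormatError(f"inverted interval {contig}:{start}-{end}")
        lines.append("\t".join(str(x) for x in (contig, start, end, *rest)))
    Path(path).write_text("\n".join(lines) + "\n")


def write_vcf(
    path: str | Path,
    variants: pd.DataFrame,
    provenance: dict | None = None,
) -> None:
    """Write a variant table as minimal VCF (positions converted to 1-based).

    Expects the internal variant-table columns; emits DP, AD and
    strand-depth fields in INFO.
    """
    header = [
        "##fileformat=VCFv4.2",
        f"##source=poolcoev {__version__}",
        *[f"##{k}={v}" for k, v in (provenance or {}).items()],
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt depth">',
        '##INFO=<ID=SB,Number=4,Type=Integer,Description="Strand counts alt_fwd,alt_rev,ref_fwd,ref_rev">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Pooled sample id">',
        '##INFO=<ID=TYPE,Number=1,Type=String,Description="SNP or indel">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    lines = header[:]
    for r in variants.itertuples():
        if r.position < 0:
            raise FormatError("negative position")
        info = (
            f"DP={r.depth};AD={r.alt_count};"
            f"SB={r.alt_fwd},{r.alt_rev},{r.ref_fwd},{r.ref_rev};"
            f"SAMPLE={r.sample};TYPE={r.type}"
        )
        lines.append(
            f"{r.contig}\t{r.position + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF written by :func:`write_vcf` back into the internal table."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        chrom, pos, _id, ref, alt, _q, _f, info = line.split("\t")[:8]
        fields = dict(kv.split("=", 1) for kv in info.split(";"))
        sb = [int(x) for x in fields["SB"].split(",")]
        rows.append(
            {
                "sample": fields.get("SAMPLE", "sample"),
                "contig": chrom,
                "position": int(pos) - 1,
                "type": fields.get("TYPE", "SNP"),
                "ref": ref,
                "alt": alt,
                "depth": int(fields["DP"]),
                "alt_count": int(fields["AD"]),
                "alt_fwd": sb[0],
                "alt_rev": sb[1],
                "ref_fwd": sb[2],
                "ref_rev": sb[3],
            }
        )
    from .filters import VARIANT_COLUMNS

    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_tsv(
    path: str | Path, df: pd.DataFrame, provenance: dict | None = None
) -> None:
    """Write a DataFrame as TSV with provenance comment headers."""
    with open(path, "w") as fh:
        for line in _provenance(provenance):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
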