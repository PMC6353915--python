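"""Readers and writers for the formats the pipeline consumes.

Conventions enforced at every module boundary:

* fragment coordinates are 0-based half-open on the circular reference
  (``start < L``; ``end`` may exceed ``L``, meaning the fragment wraps
  through the origin);
* fragment sequences are stored as aligned, reference-forward bases; the
  read orientation of minus-strand fragments is recovered by reverse
  complementing (see :mod:`paleomito.damage`);
* SAM/BAM 1-based inclusive positions are converted on ingestion.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .radiocarbon import CalibrationCurve

logger = logging.getLogger(__name__)

_FRAGMENT_ALPHABET = set("ACGTN")

TSV_COLUMNS = ["id", "library", "start", "end", "strand", "sequence", "truth_label"]


@dataclass
class AlignedFragment:
    """One mapped molecule on the circular mitochondrial reference.

    ``sequence`` holds aligned (reference-forward) bases; ``truth_label``
    ("endogenous"/"contaminant") is carried only by simulated data.
    """

    id: str
    library: str
    start: int
    end: int
    strand: str
    sequence: str
    truth_label: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.sequence:
            raise ValueError("fragment sequence must be non-empty")
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"fragment {self.id}: end - start = {self.end - self.start} "
                f"!= sequence length {len(self.sequence)}"
            )
        bad = set(self.sequence) - _FRAGMENT_ALPHABET
        if bad:
            raise ValueError(f"fragment {self.id}: invalid bases {sorted(bad)}")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered name → sequence mapping.

    Sequences are upper-cased. Empty files and duplicate record names are
    rejected.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record name {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Fragment TSV (internal dialect)


def write_fragments_tsv(frags: Iterable[AlignedFragment], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for f in frags:
            writer.writerow(
                [f.id, f.library, f.start, f.end, f.strand, f.sequence,
                 f.truth_label or ""]
            )


def read_fragments_tsv(path: str | Path) -> list[AlignedFragment]:
    frags: list[AlignedFragment] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(TSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"fragment TSV {path} missing columns {sorted(missing)}")
        for row in reader:
            frags.append(
                AlignedFragment(
                    id=row["id"],
                    library=row["library"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    sequence=row["sequence"],
                    truth_label=row["truth_label"] or None,
                )
            )
    return frags


# ---------------------------------------------------------------------------
# SAM/BAM ingestion


def read_alignments(
    path: str | Path,
    format: str = "sam",
    ref_name: str | None = None,
    default_library: str = "default",
) -> list[AlignedFragment]:
    """Ingest mapped reads from SAM/BAM (or the internal TSV dialect).

    Unmapped, secondary and supplementary records are dropped; soft-clipped
    bases are trimmed from the stored sequence. Reads whose CIGAR contains
    indels or skips are excluded (gapless substitution model) with a logged
    count.
    """
    if format == "tsv":
        return read_fragments_tsv(path)
    if format not in ("sam", "bam"):
        raise ValueError(f"unknown alignment format {format!r}")

    mode = "rb" if format == "bam" else "r"
    frags: list[AlignedFragment] = []
    n_indel = 0
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if ref_name is not None and read.reference_name != ref_name:
                continue
            cigar = read.cigartuples or []
            # ops other than M/=/X/S break the gapless model
            if any(op not in (0, 4, 7, 8) for op, _ in cigar):
                n_indel += 1
                continue
            seq = read.query_alignment_sequence
            if not seq:
                continue
            library = (
                str(read.get_tag("RG")) if read.has_tag("RG") else default_library
            )
            frags.append(
                AlignedFragment(
                    id=read.query_name,
                    library=library,
                    start=read.reference_start,
                    end=read.reference_start + len(seq),
                    strand="-" if read.is_reverse else "+",
                    sequence=seq.upper(),
                )
            )
    if n_indel:
        logger.info("read_alignments: skipped %d indel-containing records", n_indel)
    return frags


# ---------------------------------------------------------------------------
# FASTQ (unaligned simulator output)


def write_fastq(frags: Iterable[AlignedFragment], path: str | Path,
                quality_char: str = "I") -> None:
    with open(path, "w") as handle:
        for f in frags:
            handle.write(f"@{f.id}\n{f.sequence}\n+\n{quality_char * len(f.sequence)}\n")


# ---------------------------------------------------------------------------
# Radiocarbon calibration curves (.14c CSV dialect)

_NUMBER = re.compile(r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?")


def read_calibration_curve(path: str | Path) -> CalibrationCurve:
    """Parse a tabulated calibration curve.

    Accepts comma- or whitespace-separated rows whose first three numeric
    columns are calendar age (cal BP), conventional radiocarbon age (BP) and
    the 1-sigma curve error. Lines starting with ``#`` and blank lines are
    skipped. Rows are returned sorted by calendar age ascending; duplicate
    calendar ages are rejected.
    """
    theta, mu, tau = [], [], []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(",") if "," in line else line.split()
            numbers = []
            for tok in fields:
                tok = tok.strip()
                if _NUMBER.fullmatch(tok):
                    numbers.append(float(tok))
                if len(numbers) == 3:
                    break
            if len(numbers) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 numeric columns, got {line!r}"
                )
            theta.append(numbers[0])
            mu.append(numbers[1])
            tau.append(numbers[2])
    if not theta:
        raise ValueError(f"no data rows in calibration curve {path}")
    order = sorted(range(len(theta)), key=lambda i: theta[i])
    theta_s = [theta[i] for i in order]
    for a, b in zip(theta_s, theta_s[1:]):
        if a == b:
            raise ValueError(f"duplicate calendar age {a} in calibration curve {path}")
    return CalibrationCurve(
        theta=[theta[i] for i in order],
        mu_curve=[mu[i] for i in order],
        tau_curve=[tau[i] for i in order],
    )
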