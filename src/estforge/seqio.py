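"""Core domain types and FASTA/FASTQ/GFF3/TSV readers and writers.

All coordinates held in memory are 0-based half-open; the only places a
1-based inclusive convention appears are the GFF3 writer/reader, which
convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

LIBRARIES = ("seed", "seedling", "tiller", "flower", "other")

_DNA = set("ACGTN")


class FastxFormatError(ValueError):
    """Raised for malformed FASTA/FASTQ/GFF3 input."""


@dataclass
class Read:
    """A single sequencing read with its library of origin."""

    id: str
    seq: str
    qual: Optional[Sequence[int]] = None
    library: str = "other"

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: qual length {len(self.qual)} != seq length {len(self.seq)}"
            )
        if self.library not in LIBRARIES:
            raise ValueError(f"read {self.id!r}: unknown library {self.library!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Contig:
    """Consensus sequence plus read layout and per-column depth.

    ``members`` lists ``(read_id, offset, strand)`` with the offset giving the
    0-based start of the (oriented) read on the consensus.  A contig with one
    member is by definition a singleton.
    """

    id: str
    consensus: str
    members: list  # [(read_id, offset, strand)]
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if len(self.depth) != len(self.consensus):
            raise ValueError(f"contig {self.id!r}: depth length != consensus length")
        if not self.members:
            raise ValueError(f"contig {self.id!r}: no members")
        for rid, off, strand in self.members:
            if not (0 <= off < max(1, len(self.consensus))):
                raise ValueError(f"contig {self.id!r}: member {rid!r} offset {off} out of range")
            if strand not in "+-":
                raise ValueError(f"contig {self.id!r}: member {rid!r} bad strand {strand!r}")

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1

    @property
    def mean_depth(self) -> float:
        return float(np.mean(self.depth)) if len(self.depth) else 0.0


@dataclass
class Cluster:
    """A multi-membership group of overlapping reads destined for joint assembly.

    The same read id may appear in several clusters; that is the point.
    """

    id: str
    seed: str
    members: set

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.id!r}: empty")
        if self.seed not in self.members:
            raise ValueError(f"cluster {self.id!r}: seed {self.seed!r} not a member")


@dataclass
class AlignmentHit:
    """A local alignment between a query and a target.

    Query and target intervals are 0-based half-open on the *forward* strand
    of each sequence; ``strand`` records whether the query was
    reverse-complemented.  For translated hits, ``aln_len`` and ``matches``
    count amino-acid columns.
    """

    query_id: str
    target_id: str
    qstart: int
    qend: int
    tstart: int
    tend: int
    strand: str
    matches: int
    aln_len: int
    score: float
    evalue: float

    @property
    def identity(self) -> float:
        return self.matches / self.aln_len if self.aln_len else 0.0


@dataclass
class SSRLocus:
    """A perfect tandem repeat (microsatellite) on one sequence.

    ``unit_count`` counts full units only; ``end - start`` always equals
    ``unit_len * unit_count``.
    """

    seq_id: str
    start: int
    end: int
    motif: str
    canonical: str
    unit_len: int
    unit_count: int

    def __post_init__(self) -> None:
        if self.end - self.start != self.unit_len * self.unit_count:
            raise ValueError(
                f"SSR at {self.seq_id}:{self.start}-{self.end}: span != unit_len * unit_count"
            )

    @property
    def total_len(self) -> int:
        return self.end - self.start


@dataclass
class ExpressionRecord:
    """Per-library mapped-fragment counts and RPKM for one contig."""

    contig_id: str
    length_bp: int
    counts: Mapping[str, int]
    rpkm: Mapping[str, float]


@dataclass
class CleanReport:
    """Bookkeeping for one cleaning run: raw = kept + all removals."""

    raw: int
    kept: int
    removed_short: int = 0
    removed_contaminant: int = 0
    removed_empty: int = 0

    def __post_init__(self) -> None:
        if self.raw != self.kept + self.removed_short + self.removed_contaminant + self.removed_empty:
            raise ValueError(
                f"clean report does not balance: raw={self.raw} != "
                f"kept={self.kept} + removed={self.total_removed}"
            )

    @classmethod
    def tally(cls, raw: int, removed_short: int = 0, removed_contaminant: int = 0,
              removed_empty: int = 0) -> "CleanReport":
        """Build a balanced report from the raw count and per-reason removals."""
        kept = raw - removed_short - removed_contaminant - removed_empty
        return cls(raw=raw, kept=kept, removed_short=removed_short,
                   removed_contaminant=removed_contaminant, removed_empty=removed_empty)

    @property
    def total_removed(self) -> int:
        return self.removed_short + self.removed_contaminant + self.removed_empty


@dataclass
class BinnedCoverage:
    """Fixed-width binned alignment counts and depth for one chromosome.

    Per (strand, track) the object stores the number of assignments whose
    interval midpoint falls in each bin and the exact count of aligned bases
    per bin; mean per-base depth is derived from the latter so the
    "sum of depth x span equals total aligned bases" identity is exact.
    """

    chrom: str
    chrom_len: int
    bin_width: int = 500_000
    counts: dict = field(default_factory=dict)        # (strand, track) -> int array
    aligned_bases: dict = field(default_factory=dict)  # (strand, track) -> int array

    @property
    def n_bins(self) -> int:
        return -(-self.chrom_len // self.bin_width)

    def bin_span(self, b: int) -> int:
        return min(self.bin_width, self.chrom_len - b * self.bin_width)

    def mean_depth(self, strand: str, track: str) -> np.ndarray:
        bases = self.aligned_bases.get((strand, track), np.zeros(self.n_bins, dtype=np.int64))
        spans = np.array([self.bin_span(b) for b in range(self.n_bins)], dtype=np.int64)
        return bases / spans


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Sequences are uppercased; duplicate ids and empty sequences are rejected.
    """
    path = Path(path)
    records: dict = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if rec.id == "":
            raise FastxFormatError(f"{path}: record {i}: empty header")
        seq = str(rec.seq).upper()
        if not seq:
            raise FastxFormatError(f"{path}: record {i} ({rec.id!r}): empty sequence")
        if rec.id in records:
            raise FastxFormatError(f"{path}: record {i}: duplicate id {rec.id!r}")
        records[rec.id] = seq
    return records


def write_fasta(records, path, width: int = 70) -> None:
    """Write an ``{id: seq}`` mapping (or iterable of pairs) as FASTA."""
    items = records.items() if hasattr(records, "items") else records
    with open(path, "w") as fh:
        for rid, seq in items:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path, library: str = "other") -> list:
    """Read Sanger(+33)-encoded FASTQ into a list of :class:`Read`."""
    path = Path(path)
    reads = []
    seen = set()
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq"), start=1):
            if rec.id in seen:
                raise FastxFormatError(f"{path}: record {i}: duplicate id {rec.id!r}")
            seen.add(rec.id)
            quals = rec.letter_annotations.get("phred_quality")
            reads.append(Read(id=rec.id, seq=str(rec.seq).upper(),
                              qual=list(quals) if quals is not None else None,
                              library=library))
    except ValueError as exc:
        if isinstance(exc, FastxFormatError):
            raise
        raise FastxFormatError(f"{path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else [30] * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n")
            fh.write("".join(chr(q + 33) for q in qual) + "\n")


# ---------------------------------------------------------------------------
# GFF3 (microsatellite loci)
# ---------------------------------------------------------------------------

def write_gff3(loci: Iterable[SSRLocus], path, source: str = "estforge") -> None:
    """Write SSR loci as GFF3 ``microsatellite`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            attrs = (f"motif={loc.motif};canonical={loc.canonical};"
                     f"unit_len={loc.unit_len};unit_count={loc.unit_count}")
            fh.write("\t".join([
                loc.seq_id, source, "microsatellite",
                str(loc.start + 1), str(loc.end), ".", "+", ".", attrs,
            ]) + "\n")


def read_gff3(path) -> list:
    """Read back ``microsatellite`` features written by :func:`write_gff3`."""
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FastxFormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
            loci.append(SSRLocus(
                seq_id=fields[0],
                start=int(fields[3]) - 1,
                end=int(fields[4]),
                motif=attrs["motif"],
                canonical=attrs["canonical"],
                unit_len=int(attrs["unit_len"]),
                unit_count=int(attrs["unit_count"]),
            ))
    return loci


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

def write_tsv_report(records, path, float_format: str = "%.4f") -> None:
    """Write records as a TSV with a header row and fixed float precision.

    Accepts a DataFrame, a list of :class:`ExpressionRecord`, or a list of
    dicts.  Column order is stable (insertion order).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for rec in records:
            if isinstance(rec, ExpressionRecord):
                row = {"contig_id": rec.contig_id, "length_bp": rec.length_bp}
                for lib in rec.counts:
                    row[f"count_{lib}"] = rec.counts[lib]
                for lib in rec.rpkm:
                    row[f"rpkm_{lib}"] = rec.rpkm[lib]
                rows.append(row)
            else:
                rows.append(dict(rec))
        df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
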