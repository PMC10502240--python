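"""Genome sequences, windows and variants.

The data model follows the DeepSEA convention: the genome is tiled into
non-overlapping 200-bp bins, each described by a fixed-length neighbourhood
(1 kb by default) centred on the bin, sampled on both strands.  This module
reads assemblies and intervals, builds and one-hot-encodes such windows, and
applies variants to produce reference/alternate window pairs.

Coordinates are 0-based, half-open throughout (BED convention); VCF-style
1-based positions are converted on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from Bio import SeqIO

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed; names the offending line."""


class RefMismatchError(ValueError):
    """Variant REF allele does not match the assembly."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` with a strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def shift(self, delta: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + delta, self.end + delta, self.strand)


@dataclass
class GenomeAssembly:
    """An ordered set of chromosomes with uppercase ACGTN sequences.

    Chromosome order is fixed at construction and reused everywhere
    downstream (global Hi-C bin indexing depends on it).
    """

    chrom_names: list[str]
    chrom_seqs: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for name in self.chrom_names:
            seq = self.chrom_seqs[name]
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"{name}: invalid characters {sorted(bad)}")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(self.chrom_seqs[c]) for c in self.chrom_names}

    def fetch(self, interval: GenomicInterval) -> str:
        """Return the (strand-aware) sequence of an interval."""
        length = self.chrom_lengths.get(interval.chrom)
        if length is None:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > length:
            raise ValueError(
                f"interval {interval.chrom}:[{interval.start},{interval.end}) "
                f"exceeds chromosome length {length}"
            )
        seq = self.chrom_seqs[interval.chrom][interval.start:interval.end]
        return reverse_complement(seq) if interval.strand == "-" else seq


@dataclass(frozen=True)
class VariantRecord:
    """A sequence variant; ``pos`` is 0-based after ingest."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"variant {self.id or ''} has ref == alt ({self.ref})")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")


@dataclass
class SequenceWindow:
    """A fixed-length window with its one-hot encoding (rows A,C,G,T)."""

    interval: GenomicInterval
    sequence: str
    onehot: np.ndarray = field(repr=False)

    @classmethod
    def from_assembly(cls, assembly: GenomeAssembly, interval: GenomicInterval) -> "SequenceWindow":
        seq = assembly.fetch(interval)
        return cls(interval=interval, sequence=seq, onehot=one_hot(seq))


def _clean(seq: str) -> str:
    seq = seq.upper()
    return "".join(c if c in _VALID else "N" for c in seq)


def read_fasta(path) -> GenomeAssembly:
    """Read a FASTA file into a :class:`GenomeAssembly`.

    Sequences are uppercased and any non-ACGTN character (IUPAC ambiguity
    codes included) is mapped to ``N``.
    """
    with open(path) as fh:
        first = None
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = (lineno, line)
                break
        if first is None:
            raise FastaParseError(f"{path}: empty file (line 1)")
        if not first[1].startswith(">"):
            raise FastaParseError(
                f"{path}: line {first[0]} does not start a FASTA record ('>')"
            )
    names: list[str] = []
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise FastaParseError(f"{path}: duplicate record {record.id!r}")
        names.append(record.id)
        seqs[record.id] = _clean(str(record.seq))
    return GenomeAssembly(chrom_names=names, chrom_seqs=seqs)


def write_fasta(assembly: GenomeAssembly, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in assembly.chrom_names:
            fh.write(f">{name}\n")
            seq = assembly.chrom_seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def one_hot(sequence: str) -> np.ndarray:
    """One-hot encode a sequence as a 4 x L float matrix (rows A,C,G,T).

    ``N`` bases give all-zero columns, so each column sums to 1 for a real
    base and 0 for N.
    """
    L = len(sequence)
    out = np.zeros((4, L), dtype=np.float64)
    idx = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    for base, row in _BASE_INDEX.items():
        out[row, idx == ord(base)] = 1.0
    return out


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement over the ACGTN alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


def window_around_bin(
    bin_interval: GenomicInterval,
    window_length: int,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Centre a ``window_length`` interval on a bin.

    The flanks are split evenly; an out-of-bounds window raises instead of
    being silently clipped.
    """
    bin_len = len(bin_interval)
    if bin_len > window_length:
        raise ValueError(f"bin length {bin_len} exceeds window length {window_length}")
    flank = (window_length - bin_len) // 2
    start = bin_interval.start - flank
    end = start + window_length
    if start < 0 or (chrom_length is not None and end > chrom_length):
        raise ValueError(
            f"window [{start},{end}) around bin "
            f"{bin_interval.chrom}:[{bin_interval.start},{bin_interval.end}) "
            "overruns the chromosome"
        )
    return GenomicInterval(bin_interval.chrom, start, end, bin_interval.strand)


def tile_bins(
    assembly: GenomeAssembly, bin_length: int = 200, window_length: int = 1000
) -> list[GenomicInterval]:
    """Non-overlapping bins tiling each chromosome, keeping only bins whose
    centred window fits inside the chromosome."""
    bins: list[GenomicInterval] = []
    for chrom, length in assembly.chrom_lengths.items():
        for start in range(0, length - bin_length + 1, bin_length):
            b = GenomicInterval(chrom, start, start + bin_length)
            try:
                window_around_bin(b, window_length, chrom_length=length)
            except ValueError:
                continue
            bins.append(b)
    return bins


def windows_both_strands(
    assembly: GenomeAssembly,
    bins: Iterable[GenomicInterval],
    window_length: int = 1000,
    max_n_fraction: float = 0.10,
) -> list[SequenceWindow]:
    """Windows around bins on both strands (reverse-complement doubling).

    Windows whose N fraction exceeds ``max_n_fraction`` are excluded.
    The reverse-strand window shares the forward window's label vector
    downstream; it is emitted immediately after its forward partner.
    """
    out: list[SequenceWindow] = []
    lengths = assembly.chrom_lengths
    for b in bins:
        iv = window_around_bin(b, window_length, chrom_length=lengths[b.chrom])
        seq = assembly.fetch(iv)
        if seq.count("N") > max_n_fraction * len(seq):
            continue
        out.append(SequenceWindow(iv, seq, one_hot(seq)))
        rc = reverse_complement(seq)
        iv_rc = GenomicInterval(iv.chrom, iv.start, iv.end, "-")
        out.append(SequenceWindow(iv_rc, rc, one_hot(rc)))
    return out


def apply_variant(
    assembly: GenomeAssembly, variant: VariantRecord, window_length: int = 1000
) -> tuple[SequenceWindow, SequenceWindow]:
    """Build the reference and alternate windows for a variant.

    Both windows have exactly ``window_length`` bases and are centred on the
    variant's first reference base (the anchor).  For indels the edited
    chromosome is re-windowed around the same anchor, so downstream sequence
    is pulled in (deletion) or pushed out (insertion) at the right edge.
    """
    chrom_seq = assembly.chrom_seqs.get(variant.chrom)
    if chrom_seq is None:
        raise KeyError(f"unknown chromosome {variant.chrom!r}")
    found = chrom_seq[variant.pos : variant.pos + len(variant.ref)]
    if found != variant.ref:
        raise RefMismatchError(
            f"{variant.chrom}:{variant.pos}: expected REF {variant.ref!r}, "
            f"assembly has {found!r}"
        )
    flank = window_length // 2
    start = variant.pos - flank
    end = start + window_length
    if start < 0 or end > len(chrom_seq):
        raise ValueError(
            f"window around {variant.chrom}:{variant.pos} overruns the chromosome"
        )
    ref_seq = chrom_seq[start:end]
    edited = chrom_seq[: variant.pos] + variant.alt + chrom_seq[variant.pos + len(variant.ref) :]
    alt_seq = edited[start : start + window_length]
    if len(alt_seq) < window_length:
        raise ValueError("edited chromosome too short for the requested window")
    iv = GenomicInterval(variant.chrom, start, end)
    return (
        SequenceWindow(iv, ref_seq, one_hot(ref_seq)),
        SequenceWindow(iv, alt_seq, one_hot(alt_seq)),
    )


# --- interval / variant file formats ---------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read a BED (3+strand) file; columns beyond 6 are ignored."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 BED columns")
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "+"
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_vcf(path) -> list[VariantRecord]:
    """Read a minimal 5-column VCF (CHROM POS ID REF ALT); INFO/FORMAT and
    anything past column 5 are ignored.  Positions convert 1-based -> 0-based.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}: line {lineno}: expected >=5 VCF columns")
            chrom, pos, vid, ref, alt = parts[:5]
            out.append(
                VariantRecord(
                    chrom=chrom,
                    pos=int(pos) - 1,
                    ref=ref.upper(),
                    alt=alt.upper(),
                    id=None if vid in (".", "") else vid,
                )
            )
    return out


def write_vcf(variants: Iterable[VariantRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos + 1}\t{v.id or '.'}\t{v.ref}\t{v.alt}\n")
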