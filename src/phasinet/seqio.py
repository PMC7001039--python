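"""Sequence containers, collapsed-read FASTA I/O, abundance filters and
exact-match read mapping with fractional multimapper counting.

Small RNA libraries are handled as *collapsed* reads: one record per
distinct sequence carrying an integer copy number.  The collapsed-FASTA
header dialect is ``>name_x<count>`` (e.g. ``>sim_0001_x87``).

Mapping is exact and full-length on both genomic strands.  A read seen at
``n`` genomic locations contributes ``count / n`` at each location; the
fraction is kept as an exact :class:`fractions.Fraction` so count
conservation is testable bit-exactly.  Coordinates are 1-based inclusive
and the *leftmost* coordinate is reported for both strands (GFF3
convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")
_COUNT_RE = re.compile(r"_x(\d+)$")

VALID_ALPHABET = frozenset("ACGTUN")


def revcomp(seq: str) -> str:
    """Reverse complement (U pairs with A; case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_u(seq: str) -> str:
    """Uppercase and rewrite U -> T for mapping/search purposes."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class UniqueRead:
    """One distinct sequence with its raw collapsed copy number."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        if not set(self.sequence.upper()) <= VALID_ALPHABET:
            bad = set(self.sequence.upper()) - VALID_ALPHABET
            raise ValueError(f"invalid characters in read: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SrnaLibrary:
    """A collapsed sRNA-seq library: unique sequences with counts."""

    library_id: str
    reads: dict[str, UniqueRead] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __iter__(self) -> Iterator[UniqueRead]:
        return iter(self.reads.values())

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def n_unique(self) -> int:
        return len(self.reads)

    @property
    def total_reads(self) -> int:
        return sum(r.count for r in self.reads.values())

    def add(self, sequence: str, count: int = 1) -> None:
        prev = self.reads.get(sequence)
        if prev is None:
            self.reads[sequence] = UniqueRead(sequence, count)
        else:
            self.reads[sequence] = UniqueRead(sequence, prev.count + count)

    def to_fasta(self, path: str | Path, prefix: str = "read") -> None:
        with open(path, "w") as fh:
            for i, read in enumerate(sorted(self, key=lambda r: (-r.count, r.sequence))):
                fh.write(f">{prefix}_{i:06d}_x{read.count}\n{read.sequence}\n")

    @classmethod
    def from_fasta(cls, path: str | Path, library_id: str | None = None) -> "SrnaLibrary":
        """Read a collapsed-FASTA file; headers lacking ``_x<count>`` count as 1."""
        lib = cls(library_id or Path(path).stem)
        for rec in SeqIO.parse(str(path), "fasta"):
            m = _COUNT_RE.search(rec.id)
            lib.add(str(rec.seq).upper(), int(m.group(1)) if m else 1)
        return lib


# A degradome library has the same container shape: collapsed 5'-end tags.
DegradomeLibrary = SrnaLibrary


@dataclass(frozen=True)
class ReadAlignment:
    """One exact placement of a read on the reference."""

    read: UniqueRead
    reference_id: str
    start: int  # 1-based leftmost
    strand: str  # '+' or '-'
    n_locations: int
    fractional_count: Fraction

    @property
    def end(self) -> int:
        return self.start + self.read.length - 1

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the biological 5' end."""
        return self.start if self.strand == "+" else self.end

    @property
    def effective_five_prime(self) -> int:
        """Duplex-corrected coordinate used for 21-nt phase binning.

        Minus-strand reads are shifted by -2 from their leftmost coordinate
        so that the two members of a dicer duplex (2-nt 3' overhangs at both
        ends) fall at the same effective position as the sense partner's 5'
        end, for both 21- and 22-nt reads.
        """
        return self.start if self.strand == "+" else self.start - 2


def collapse_reads(
    sequences: Iterable[str], library_id: str = "lib", merge_u: bool = False
) -> SrnaLibrary:
    """Collapse raw sequences to unique reads with counts.

    With ``merge_u`` True, U and T are treated as the same base (sequences
    are normalized to DNA before collapsing); otherwise they stay distinct.
    """
    lib = SrnaLibrary(library_id)
    for seq in sequences:
        lib.add(normalize_u(seq) if merge_u else seq)
    return lib


def filter_library(
    lib: SrnaLibrary, min_count: int = 50, min_len: int = 20, max_len: int = 40
) -> SrnaLibrary:
    """Keep reads with min_len <= length <= max_len and count >= min_count.

    The count boundary is inclusive: "fewer than min_count" are removed.
    """
    out = SrnaLibrary(lib.library_id, metadata=dict(lib.metadata))
    for read in lib:
        if min_len <= read.length <= max_len and read.count >= min_count:
            out.reads[read.sequence] = read
    return out


def qc_library(lib: SrnaLibrary, min_unique: int = 100) -> bool:
    """True iff the library is informative (>= min_unique unique reads)."""
    return lib.n_unique >= min_unique


def trim_adapter3(lib: SrnaLibrary, adapter: str, min_len: int = 1) -> SrnaLibrary:
    """Optional exact-match 3' adapter trimmer (inputs are normally pre-trimmed).

    The read is cut at the first occurrence of ``adapter``; reads without the
    adapter or trimming to fewer than ``min_len`` nt are dropped.
    """
    out = SrnaLibrary(lib.library_id, metadata=dict(lib.metadata))
    for read in lib:
        idx = read.sequence.find(adapter)
        if idx >= min_len:
            out.add(read.sequence[:idx], read.count)
    return out


def clip5(lib: SrnaLibrary, n: int = 0) -> SrnaLibrary:
    """Remove the first ``n`` nt of every read (library-prep artifacts)."""
    if n == 0:
        return lib
    out = SrnaLibrary(lib.library_id, metadata=dict(lib.metadata))
    for read in lib:
        if read.length > n:
            out.add(read.sequence[n:], read.count)
    return out


def _find_all(haystack: str, needle: str) -> list[int]:
    """All 0-based occurrence offsets of needle in haystack (overlapping)."""
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def map_reads(
    lib: SrnaLibrary,
    reference: Mapping[str, str],
    allowed_lengths: frozenset[int] | set[int] = frozenset({21, 22}),
    max_locations: int = 10,
    merge_u: bool = True,
) -> list[ReadAlignment]:
    """Exact full-length mapping of a library against both reference strands.

    Reads of disallowed length are dropped before mapping; reads hitting
    more than ``max_locations`` sites are dropped entirely; every retained
    read's count is divided equally between its locations.
    """
    if not reference:
        raise ValueError("empty reference")
    refs = {rid: normalize_u(seq) for rid, seq in reference.items()}
    alignments: list[ReadAlignment] = []
    for read in lib:
        if allowed_lengths and read.length not in allowed_lengths:
            continue
        seq = normalize_u(read.sequence) if merge_u else read.sequence
        rc = revcomp(seq)
        hits: list[tuple[str, int, str]] = []
        for rid in refs:
            chrom = refs[rid]
            hits.extend((rid, off + 1, "+") for off in _find_all(chrom, seq))
            hits.extend((rid, off + 1, "-") for off in _find_all(chrom, rc))
        n = len(hits)
        if n == 0 or n > max_locations:
            continue
        frac = Fraction(read.count, n)
        for rid, start, strand in hits:
            alignments.append(ReadAlignment(read, rid, start, strand, n, frac))
    alignments.sort(key=lambda a: (a.reference_id, a.start, a.strand, a.read.sequence))
    return alignments


def write_alignment_tsv(alignments: Iterable[ReadAlignment], path: str | Path, library_id: str) -> None:
    with open(path, "w") as fh:
        fh.write("library_id\tsequence\treference\tstart\tstrand\tn_locations\tfractional_count\n")
        for a in alignments:
            fh.write(
                f"{library_id}\t{a.read.sequence}\t{a.reference_id}\t{a.start}\t"
                f"{a.strand}\t{a.n_locations}\t{float(a.fractional_count):.6g}\n"
            )


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Reference genome FASTA -> {chrom: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
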