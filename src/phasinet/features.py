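"""Genome features: a light GFF3-backed annotation layer.

Genes carry optional exon / CDS / UTR children.  Transcript sequences are
spliced from exons (whole gene span when no exons are annotated) and
transcript coordinates convert to genomic coordinates honouring splicing
and strand.  Reading goes through :mod:`gffutils`; writing is plain GFF3.

Coordinates are 1-based inclusive throughout.  Interval overlap lengths
follow the end-minus-start convention (a locus spanning [s, e] has length
e - s), matching how published locus/feature overlaps are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils

from .seqio import revcomp


@dataclass
class Feature:
    feature_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    ftype: str = "gene"
    parent: str | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """A flat feature set with parent/child links (genes own exons/CDS/UTRs)."""

    features: list[Feature] = field(default_factory=list)

    def genes(self) -> list[Feature]:
        return [f for f in self.features if f.parent is None]

    def children(self, feature_id: str, ftype: str | None = None) -> list[Feature]:
        out = [f for f in self.features if f.parent == feature_id]
        if ftype is not None:
            out = [f for f in out if f.ftype == ftype]
        return sorted(out, key=lambda f: f.start)

    def by_id(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def exons(self, gene: Feature) -> list[Feature]:
        """Exon children in genomic order; the gene span itself if none."""
        ex = self.children(gene.feature_id, "exon")
        return ex if ex else [gene]

    # -- transcript arithmetic ------------------------------------------------

    def transcript_length(self, gene: Feature) -> int:
        return sum(e.length for e in self.exons(gene))

    def transcript_sequence(self, genome: Mapping[str, str], gene: Feature) -> str:
        chrom = genome[gene.chrom]
        spliced = "".join(chrom[e.start - 1 : e.end] for e in self.exons(gene))
        return revcomp(spliced) if gene.strand == "-" else spliced

    def transcript_to_genomic(self, gene: Feature, tpos: int) -> int:
        """Map a 1-based transcript position to its genomic coordinate."""
        if tpos < 1:
            raise ValueError(f"transcript position {tpos} < 1")
        exons = self.exons(gene)
        order = exons if gene.strand == "+" else list(reversed(exons))
        offset = tpos - 1
        for exon in order:
            if offset < exon.length:
                return exon.start + offset if gene.strand == "+" else exon.end - offset
            offset -= exon.length
        raise ValueError(
            f"position {tpos} beyond transcript of {gene.feature_id} "
            f"(length {self.transcript_length(gene)})"
        )

    def genomic_to_transcript(self, gene: Feature, gpos: int) -> int:
        exons = self.exons(gene)
        order = exons if gene.strand == "+" else list(reversed(exons))
        walked = 0
        for exon in order:
            if exon.start <= gpos <= exon.end:
                within = gpos - exon.start if gene.strand == "+" else exon.end - gpos
                return walked + within + 1
            walked += exon.length
        raise ValueError(f"genomic position {gpos} not exonic in {gene.feature_id}")

    def region_label(self, gene: Feature, gpos: int) -> str:
        """Feature-region label (5'UTR / CDS / 3'UTR / gene type) at a position."""
        for ftype, label in (
            ("five_prime_UTR", "5'UTR"),
            ("CDS", "CDS"),
            ("three_prime_UTR", "3'UTR"),
        ):
            for child in self.children(gene.feature_id, ftype):
                if child.start <= gpos <= child.end:
                    return label
        return gene.attributes.get("biotype", gene.ftype)

    # -- I/O ------------------------------------------------------------------

    def to_gff3(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for line in header_lines:
                fh.write(f"#{line}\n")
            for f in self.features:
                attrs = [f"ID={f.feature_id}"]
                if f.parent:
                    attrs.append(f"Parent={f.parent}")
                attrs.extend(f"{k}={v}" for k, v in sorted(f.attributes.items()))
                fh.write(
                    f"{f.chrom}\tphasinet\t{f.ftype}\t{f.start}\t{f.end}\t.\t"
                    f"{f.strand}\t.\t{';'.join(attrs)}\n"
                )

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GenomeAnnotation":
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        ann = cls()
        for rec in db.all_features():
            parents = list(db.parents(rec, level=1))
            attrs = {
                k: v[0]
                for k, v in rec.attributes.items()
                if k not in ("ID", "Parent") and v
            }
            ann.features.append(
                Feature(
                    feature_id=rec.id,
                    chrom=rec.seqid,
                    start=rec.start,
                    end=rec.end,
                    strand=rec.strand,
                    ftype=rec.featuretype,
                    parent=parents[0].id if parents else None,
                    attributes=attrs,
                )
            )
        return ann


def overlap_length(start1: int, end1: int, start2: int, end2: int) -> int:
    """Interval overlap under the end-minus-start convention (>= 0)."""
    return max(0, min(end1, end2) - max(start1, start2))
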