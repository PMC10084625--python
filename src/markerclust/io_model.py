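"""Ingestion of SAM/BAM marker alignments into the canonical alignment table.

Reference sequence names are expected to encode ``taxon<delim>marker``; the
delimiter (or an arbitrary capture pattern) is configurable because marker
reference FASTA dialects vary.  All downstream stages consume the
:class:`AlignmentRecord` list produced here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam

__all__ = [
    "AlignmentRecord",
    "MarkerNaming",
    "MarkerReference",
    "parse_marker_taxon",
    "read_alignments",
    "count_total_reads",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-marker alignment.

    ``read_id`` is the query name plus a ``/1`` / ``/2`` mate tag for paired
    reads (mates count as distinct reads).  ``identity`` is the fraction of
    bases agreeing between query and reference, ``coverage_fraction`` the
    fraction of the marker covered by the alignment.
    """

    read_id: str
    marker_id: str
    taxon_id: str
    aln_length: int
    identity: float
    coverage_fraction: float
    mapq: Optional[int] = None

    def __post_init__(self) -> None:
        if self.aln_length < 1:
            raise ValueError(f"aln_length must be >= 1, got {self.aln_length}")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity must be in [0, 1], got {self.identity}")
        if not (0.0 < self.coverage_fraction <= 1.0):
            raise ValueError(
                f"coverage_fraction must be in (0, 1], got {self.coverage_fraction}"
            )


@dataclass(frozen=True)
class MarkerNaming:
    """How reference sequence names encode (taxon, marker).

    Either a delimiter (split at the first occurrence) or a regex with two
    capture groups ``(taxon, marker)``.  The delimiter dialect is the default
    and matches the fixture generator.
    """

    delimiter: str = "|"
    pattern: Optional[str] = None

    def parse(self, sequence_name: str) -> tuple[str, str]:
        if self.pattern is not None:
            m = re.fullmatch(self.pattern, sequence_name)
            if m is None or len(m.groups()) < 2:
                raise ValueError(
                    f"sequence name {sequence_name!r} does not match pattern {self.pattern!r}"
                )
            return m.group(1), m.group(2)
        taxon, sep, marker = sequence_name.partition(self.delimiter)
        if not sep or not taxon or not marker:
            raise ValueError(
                f"sequence name {sequence_name!r} does not contain delimiter {self.delimiter!r}"
            )
        return taxon, marker


def parse_marker_taxon(
    sequence_name: str, naming: MarkerNaming | None = None
) -> tuple[str, str]:
    """Split a reference sequence name into ``(taxon_id, marker_id)``.

    With the delimiter dialect the split happens at the *first* delimiter, so
    ``"taxA|m1|extra"`` parses as ``("taxA", "m1|extra")``.
    """
    return (naming or MarkerNaming()).parse(sequence_name)


class MarkerReference:
    """marker_id -> (taxon_id, marker_length) lookup.

    Marker ids must be unique across the reference (each maps to exactly one
    taxon); a duplicate id under a different taxon is a hard error.
    """

    def __init__(self, naming: MarkerNaming | None = None) -> None:
        self.naming = naming or MarkerNaming()
        self._taxon: dict[str, str] = {}
        self._length: dict[str, int] = {}

    def add(self, sequence_name: str, length: int) -> str:
        if length < 1:
            raise ValueError(
                f"marker length must be >= 1 for {sequence_name!r}, got {length}"
            )
        taxon_id, marker_id = self.naming.parse(sequence_name)
        if marker_id in self._taxon and self._taxon[marker_id] != taxon_id:
            raise ValueError(
                f"marker id {marker_id!r} maps to both {self._taxon[marker_id]!r} "
                f"and {taxon_id!r}"
            )
        self._taxon[marker_id] = taxon_id
        self._length[marker_id] = length
        return marker_id

    def taxon_of(self, marker_id: str) -> str:
        return self._taxon[marker_id]

    def length_of(self, marker_id: str) -> int:
        return self._length[marker_id]

    @property
    def marker_ids(self) -> list[str]:
        return list(self._taxon)

    @property
    def marker_lengths(self) -> dict[str, int]:
        return dict(self._length)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._taxon

    def __len__(self) -> int:
        return len(self._taxon)

    @classmethod
    def from_sam_header(
        cls, header: pysam.AlignmentHeader, naming: MarkerNaming | None = None
    ) -> "MarkerReference":
        ref = cls(naming)
        for sq in header.get("SQ", []):
            name = sq.get("SN")
            length = sq.get("LN")
            if name is None or length is None:
                raise ValueError(f"@SQ entry without SN/LN: {sq!r}")
            ref.add(name, int(length))
        return ref

    @classmethod
    def from_fasta(
        cls, fasta_path: str, naming: MarkerNaming | None = None
    ) -> "MarkerReference":
        from Bio import SeqIO

        ref = cls(naming)
        for rec in SeqIO.parse(fasta_path, "fasta"):
            ref.add(rec.id, len(rec.seq))
        return ref


def _mate_tagged_read_id(rec: pysam.AlignedSegment) -> str:
    if rec.is_paired:
        return f"{rec.query_name}/{'1' if rec.is_read1 else '2'}"
    return rec.query_name


def _iter_sam(sam_source) -> Iterator[pysam.AlignedSegment]:
    yield from sam_source


def read_alignments(
    sam_source: str | pysam.AlignmentFile,
    reference: MarkerReference | None = None,
    naming: MarkerNaming | None = None,
) -> list[AlignmentRecord]:
    """Read a SAM/BAM file into the canonical alignment table.

    One record per (read, marker) pair: when a read aligns to the same marker
    more than once (secondary/supplementary alignments are retained), only the
    highest-identity alignment is kept.  Unmapped records are skipped.
    Identity is ``(aln_length - NM) / aln_length`` from the edit-distance tag;
    a missing NM tag is a hard error.  Marker lengths come from ``reference``
    or, by default, from the @SQ header lines.
    """
    owns_handle = isinstance(sam_source, str)
    af = (
        pysam.AlignmentFile(sam_source, check_sq=False)
        if owns_handle
        else sam_source
    )
    try:
        ref = reference or MarkerReference.from_sam_header(af.header.to_dict(), naming)
        best: dict[tuple[str, str], AlignmentRecord] = {}
        order: list[tuple[str, str]] = []
        for rec in _iter_sam(af):
            if rec.is_unmapped:
                continue
            seq_name = rec.reference_name
            taxon_id, marker_id = ref.naming.parse(seq_name)
            if marker_id not in ref:
                raise ValueError(
                    f"no @SQ length for aligned marker {seq_name!r}"
                )
            read_id = _mate_tagged_read_id(rec)
            aln_length = rec.query_alignment_length
            if aln_length < 1:
                continue
            try:
                nm = rec.get_tag("NM")
            except KeyError:
                raise ValueError(
                    f"alignment of read {read_id!r} to {seq_name!r} lacks the NM tag"
                ) from None
            identity = max(0.0, (aln_length - nm) / aln_length)
            marker_length = ref.length_of(marker_id)
            ref_span = rec.reference_length or 0
            coverage = min(1.0, ref_span / marker_length) if ref_span else 0.0
            if coverage <= 0.0:
                continue
            record = AlignmentRecord(
                read_id=read_id,
                marker_id=marker_id,
                taxon_id=taxon_id,
                aln_length=aln_length,
                identity=identity,
                coverage_fraction=coverage,
                mapq=rec.mapping_quality,
            )
            key = (read_id, marker_id)
            if key not in best:
                best[key] = record
                order.append(key)
            elif record.identity > best[key].identity:
                best[key] = record
        return [best[k] for k in order]
    finally:
        if owns_handle:
            af.close()


def count_total_reads(sam_source: str) -> int:
    """Count distinct reads (mate-tagged) in the file, mapped or not.

    Used as the default sequencing-depth denominator for quantification; a
    SAM restricted to marker alignments under-counts true depth, so callers
    may override it.
    """
    seen: set[str] = set()
    with pysam.AlignmentFile(sam_source, check_sq=False) as af:
        for rec in af:
            seen.add(_mate_tagged_read_id(rec))
    return len(seen)
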