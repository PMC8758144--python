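"""PAR-CLIP read processing: barcode deduplication, conversion calling, filters.

PAR-CLIP libraries carry a random barcode in the 3' adapter so that PCR
duplicates can be collapsed.  Crosslinked 4-thiouridine leaves a diagnostic
T->C substitution in the read; every other substitution is treated as noise.
This module deduplicates reads, flags each mismatch as conversion vs other,
applies the read-level filters (minimum length, maximum non-conversion
mismatches), and accumulates per-position conversion profiles.

Reads live in transcript space ('+' strand).  Genome-space '-' alignments are
supported through the complement rule: a T->C conversion on a '-' strand read
appears as A->G in transcript-space coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import TranscriptModel

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class MismatchRecord:
    """One substitution in a read, transcript coordinates."""

    pos: int
    ref_base: str
    read_base: str
    is_conversion: bool | None = None  # None until classified

    def __post_init__(self) -> None:
        if self.ref_base == self.read_base:
            raise ValueError(f"mismatch at {self.pos} has identical ref/read base")


@dataclass
class AlignedRead:
    """One aligned PAR-CLIP read (0-based half-open, transcript space)."""

    transcript_id: str
    start: int
    end: int
    strand: str = "+"
    barcode: str = ""
    mismatches: list[MismatchRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(f"read on {self.transcript_id} has length < 1")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        for mm in self.mismatches:
            if not self.start <= mm.pos < self.end:
                raise ValueError(
                    f"mismatch position {mm.pos} outside read "
                    f"[{self.start}, {self.end}) on {self.transcript_id}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def conversion_count(self) -> int:
        return sum(1 for mm in self.mismatches if mm.is_conversion)

    def other_mismatch_count(self) -> int:
        return sum(1 for mm in self.mismatches if mm.is_conversion is False)


def _sort_key(read: AlignedRead):
    return (read.transcript_id, read.start, read.end, read.strand, read.barcode)


def collapse_barcodes(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Collapse PCR duplicates: one representative per
    (transcript, start, end, strand, barcode) key.

    The representative is the first read in sorted order, so the result is
    deterministic and the operation idempotent.  Output is sorted by
    coordinates then barcode.
    """
    reads = list(reads)
    for r in reads:
        if not r.barcode:
            raise ValueError(f"read on {r.transcript_id} [{r.start},{r.end}) has empty barcode")
    out: list[AlignedRead] = []
    seen_key = object()
    for r in sorted(reads, key=_sort_key):
        key = _sort_key(r)
        if key != seen_key:
            out.append(r)
            seen_key = key
    return out


def classify_mismatches(
    read: AlignedRead, conversion: tuple[str, str] = ("T", "C")
) -> AlignedRead:
    """Set ``is_conversion`` on every mismatch of ``read``.

    On the '+' strand a (ref, read) pair equal to ``conversion`` (default
    T->C) is a conversion; on the '-' strand the transcript-space appearance
    is the complement pair (A->G for T->C).  Everything else is "other".
    """
    ref_c, alt_c = conversion
    if read.strand == "-":
        ref_c, alt_c = COMPLEMENT[ref_c], COMPLEMENT[alt_c]
    for mm in read.mismatches:
        if mm.ref_base not in VALID_BASES or mm.read_base not in VALID_BASES:
            raise ValueError(
                f"invalid base in mismatch {mm.ref_base}>{mm.read_base} at {mm.pos}"
            )
        mm.is_conversion = (mm.ref_base == ref_c) and (mm.read_base == alt_c)
    return read


def filter_reads(
    reads: Iterable[AlignedRead], min_len: int = 20, max_other_mm: int = 1
) -> list[AlignedRead]:
    """Apply the read-level filters: length >= ``min_len`` and at most
    ``max_other_mm`` non-conversion mismatches (conversions are exempt)."""
    out = []
    for r in reads:
        for mm in r.mismatches:
            if mm.is_conversion is None:
                raise ValueError("filter_reads requires classified mismatches")
        if r.length >= min_len and r.other_mismatch_count() <= max_other_mm:
            out.append(r)
    return out


@dataclass
class ConversionProfile:
    """Per-position coverage and mismatch tallies over one transcript."""

    transcript_id: str
    coverage: np.ndarray
    conversion_count: np.ndarray
    other_mismatch_count: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n = len(self.coverage)
        return pd.DataFrame(
            {
                "transcript_id": [self.transcript_id] * n,
                "pos": np.arange(n),
                "coverage": self.coverage,
                "conversions": self.conversion_count,
                "other_mismatches": self.other_mismatch_count,
            }
        )


def conversion_profile(
    reads: Iterable[AlignedRead], model: TranscriptModel | int, transcript_id: str = ""
) -> ConversionProfile:
    """Accumulate coverage / conversion / other-mismatch counts per position.

    ``model`` may be a :class:`TranscriptModel` or a plain transcript length.
    """
    if isinstance(model, TranscriptModel):
        length = model.length
        transcript_id = transcript_id or model.transcript_id
    else:
        length = int(model)
    cov = np.zeros(length, dtype=np.int64)
    conv = np.zeros(length, dtype=np.int64)
    other = np.zeros(length, dtype=np.int64)
    for r in reads:
        if r.start < 0 or r.end > length:
            raise ValueError(
                f"read [{r.start},{r.end}) on {r.transcript_id} outside transcript "
                f"bounds [0,{length})"
            )
        cov[r.start : r.end] += 1
        for mm in r.mismatches:
            if mm.is_conversion:
                conv[mm.pos] += 1
            else:
                other[mm.pos] += 1
    return ConversionProfile(transcript_id, cov, conv, other)


# ---------------------------------------------------------------------------
# I/O: tab-delimited read tables and SAM (MD-tag dialect)

TABLE_COLUMNS = ["transcript_id", "start", "end", "strand", "barcode", "mismatches"]


def _encode_mismatches(mms: Sequence[MismatchRecord]) -> str:
    if not mms:
        return "."
    return ",".join(f"{m.pos}:{m.ref_base}>{m.read_base}" for m in mms)


def _decode_mismatches(text: str) -> list[MismatchRecord]:
    if text == "." or text == "":
        return []
    out = []
    for tok in text.split(","):
        pos, bases = tok.split(":")
        ref, alt = bases.split(">")
        out.append(MismatchRecord(int(pos), ref, alt))
    return out


def write_read_table(reads: Iterable[AlignedRead], path: str | Path) -> None:
    rows = [
        (r.transcript_id, r.start, r.end, r.strand, r.barcode, _encode_mismatches(r.mismatches))
        for r in reads
    ]
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_read_table(path: str | Path) -> list[AlignedRead]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != TABLE_COLUMNS:
        raise ValueError(f"read table must have columns {TABLE_COLUMNS}")
    return [
        AlignedRead(
            transcript_id=row.transcript_id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            barcode=row.barcode,
            mismatches=_decode_mismatches(row.mismatches),
        )
        for row in df.itertuples()
    ]


def reads_from_sam(path: str | Path) -> list[AlignedRead]:
    """Ingest transcript-space alignments from SAM.

    Mismatches are recovered from the MD tag via the aligned-pairs machinery;
    a record without an MD tag is a hard error.  The random barcode is taken
    from the read name suffix after the last underscore.
    """
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if not rec.has_tag("MD"):
                raise ValueError(f"SAM record {rec.query_name} lacks an MD tag")
            if "_" not in (rec.query_name or ""):
                raise ValueError(f"SAM record {rec.query_name}: no barcode suffix in name")
            barcode = rec.query_name.rsplit("_", 1)[1]
            qseq = rec.query_sequence
            mms = []
            for qpos, rpos, ref in rec.get_aligned_pairs(matches_only=True, with_seq=True):
                if ref is not None and ref.islower():  # lowercase marks a mismatch
                    mms.append(MismatchRecord(rpos, ref.upper(), qseq[qpos].upper()))
            reads.append(
                AlignedRead(
                    transcript_id=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    barcode=barcode,
                    mismatches=mms,
                )
            )
    return reads


def preprocess_reads(
    reads: Iterable[AlignedRead],
    conversion: tuple[str, str] = ("T", "C"),
    min_len: int = 20,
    max_other_mm: int = 1,
) -> list[AlignedRead]:
    """Standard preprocessing chain: collapse, classify, filter."""
    collapsed = collapse_barcodes(reads)
    classified = [classify_mismatches(r, conversion) for r in collapsed]
    return filter_reads(classified, min_len=min_len, max_other_mm=max_other_mm)
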