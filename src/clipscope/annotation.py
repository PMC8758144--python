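"""Transcript feature models: GTF parsing, isoform selection, feature lookup.

A :class:`TranscriptModel` describes one protein-coding transcript in
transcript coordinates (exons already spliced) as five ordered features:
5'-UTR, start codon, coding, stop codon, 3'-UTR.  Coordinates are 0-based,
half-open.  The start and stop codons are modeled as the first and last 3 nt
of the coding span, which is the standard GTF convention; ``lenC`` therefore
includes both codons.

One representative isoform per gene is chosen by transcript abundance (TPM),
because short crosslinking reads cannot resolve which isoform was bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

FIVE_PRIME_UTR = "five_prime_utr"
START_CODON = "start_codon"
CODING = "coding"
STOP_CODON = "stop_codon"
THREE_PRIME_UTR = "three_prime_utr"

#: feature kinds in 5'->3' order
FEATURE_KINDS = (FIVE_PRIME_UTR, START_CODON, CODING, STOP_CODON, THREE_PRIME_UTR)


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; the message names the line number."""


@dataclass(frozen=True)
class FeatureInterval:
    """One transcript feature span, 0-based half-open."""

    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.end > self.start:
            raise ValueError(f"empty interval for {self.kind}: [{self.start}, {self.end})")


@dataclass(frozen=True)
class TranscriptModel:
    """Feature geometry of one transcript.

    ``len5 + lenC + len3`` equals the transcript length; ``lenC`` includes the
    start and stop codons (3 nt each), so ``lenC >= 6``.  Zero-length UTRs are
    permitted; genes whose selected isoform lacks a 5'- or 3'-UTR are flagged
    unclassifiable downstream rather than silently dropped.
    """

    gene_id: str
    transcript_id: str
    len5: int
    lenC: int
    len3: int

    def __post_init__(self) -> None:
        if self.len5 < 0 or self.len3 < 0:
            raise ValueError(f"{self.transcript_id}: negative UTR length")
        if self.lenC < 6:
            raise ValueError(f"{self.transcript_id}: coding span {self.lenC} < 6 nt")

    @property
    def length(self) -> int:
        return self.len5 + self.lenC + self.len3

    @property
    def intervals(self) -> tuple[FeatureInterval, ...]:
        """Ordered non-empty feature intervals covering [0, length)."""
        l5, lc = self.len5, self.lenC
        spans = [
            (FIVE_PRIME_UTR, 0, l5),
            (START_CODON, l5, l5 + 3),
            (CODING, l5 + 3, l5 + lc - 3),
            (STOP_CODON, l5 + lc - 3, l5 + lc),
            (THREE_PRIME_UTR, l5 + lc, self.length),
        ]
        return tuple(FeatureInterval(k, s, e) for k, s, e in spans if e > s)


def locate_feature(model: TranscriptModel, pos: int) -> str:
    """Return the feature kind containing transcript position ``pos``."""
    if not 0 <= pos < model.length:
        raise ValueError(
            f"position {pos} outside transcript {model.transcript_id} [0, {model.length})"
        )
    for iv in model.intervals:
        if iv.start <= pos < iv.end:
            return iv.kind
    raise AssertionError("intervals do not partition the transcript")  # pragma: no cover


@dataclass
class AbundanceTable:
    """Transcript abundance (TPM) plus transcript -> gene mapping."""

    tpm: dict[str, float] = field(default_factory=dict)
    gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tx, v in self.tpm.items():
            if v < 0:
                raise ValueError(f"negative TPM for {tx}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbundanceTable":
        """Read a TSV with header ``transcript_id  gene_id  tpm``."""
        df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
        required = {"transcript_id", "gene_id", "tpm"}
        if not required.issubset(df.columns):
            raise ValueError(f"abundance TSV must have columns {sorted(required)}")
        return cls(
            tpm=dict(zip(df["transcript_id"], df["tpm"].astype(float))),
            gene=dict(zip(df["transcript_id"], df["gene_id"])),
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = [(tx, self.gene.get(tx, ""), v) for tx, v in sorted(self.tpm.items())]
        pd.DataFrame(rows, columns=["transcript_id", "gene_id", "tpm"]).to_csv(
            path, sep="\t", index=False
        )


def parse_gtf(source: str | Path | IO[str]) -> list[TranscriptModel]:
    """Parse a GENCODE-dialect GTF in transcript space into transcript models.

    The seqname column names the transcript; exon/CDS (and optionally
    stop_codon and UTR) features are given in 1-based transcript coordinates.
    Transcripts without an annotated CDS are skipped with a warning.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()

    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    stops: dict[str, list[tuple[int, int]]] = {}
    genes: dict[str, str] = {}
    order: list[str] = []

    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            feat = feature_from_line(line)
        except Exception as exc:
            raise GtfParseError(f"malformed GTF line {lineno}: {exc}") from exc
        if feat.start is None or feat.end is None or feat.start < 1 or feat.end < feat.start:
            raise GtfParseError(f"malformed GTF line {lineno}: bad coordinates")
        try:
            tx = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except (KeyError, IndexError) as exc:
            raise GtfParseError(
                f"malformed GTF line {lineno}: missing transcript_id/gene_id"
            ) from exc
        if tx not in genes:
            genes[tx] = gid
            order.append(tx)
        span = (feat.start - 1, feat.end)  # to 0-based half-open
        if feat.featuretype == "exon":
            exons.setdefault(tx, []).append(span)
        elif feat.featuretype == "CDS":
            cds.setdefault(tx, []).append(span)
        elif feat.featuretype == "stop_codon":
            stops.setdefault(tx, []).append(span)

    models: list[TranscriptModel] = []
    for tx in order:
        if tx not in cds:
            logger.warning("transcript %s has no CDS feature; skipped", tx)
            continue
        if tx in exons:
            length = sum(e - s for s, e in exons[tx])
        else:
            length = max(e for _, e in cds[tx] + stops.get(tx, []))
        cds_start = min(s for s, _ in cds[tx])
        cds_end = max(e for _, e in cds[tx])
        if tx in stops:
            cds_end = max(cds_end, max(e for _, e in stops[tx]))
        if cds_end > length:
            raise GtfParseError(f"transcript {tx}: CDS extends past transcript end")
        models.append(
            TranscriptModel(
                gene_id=genes[tx],
                transcript_id=tx,
                len5=cds_start,
                lenC=cds_end - cds_start,
                len3=length - cds_end,
            )
        )
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript-space GTF (1-based, GENCODE-style attributes)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'

            def row(ftype: str, start0: int, end0: int) -> str:
                return (
                    f"{m.transcript_id}\tclipscope\t{ftype}\t{start0 + 1}\t{end0}"
                    f"\t.\t+\t.\t{attrs}\n"
                )

            fh.write(row("transcript", 0, m.length))
            fh.write(row("exon", 0, m.length))
            if m.len5 > 0:
                fh.write(row("five_prime_utr", 0, m.len5))
            fh.write(row("CDS", m.len5, m.len5 + m.lenC - 3))
            fh.write(row("stop_codon", m.len5 + m.lenC - 3, m.len5 + m.lenC))
            if m.len3 > 0:
                fh.write(row("three_prime_utr", m.len5 + m.lenC, m.length))


def select_primary_isoform(
    gene_id: str,
    abundance: AbundanceTable,
    models: Iterable[TranscriptModel],
) -> TranscriptModel:
    """Pick the gene's representative isoform: highest TPM, ties broken by
    transcript length then lexicographic transcript_id.

    All-zero TPM across isoforms falls back to the longest transcript with a
    warning.  A gene with no isoform in the abundance table is an error.
    """
    candidates = [m for m in models if m.gene_id == gene_id]
    if not candidates:
        raise KeyError(f"gene {gene_id}: no transcript models")
    scored = [m for m in candidates if m.transcript_id in abundance.tpm]
    if not scored:
        raise KeyError(f"gene {gene_id}: absent from abundance table")
    if all(abundance.tpm[m.transcript_id] == 0.0 for m in scored):
        logger.warning("gene %s: all isoform TPMs are zero; using longest transcript", gene_id)
    # max TPM, then longest, then lexicographically smallest id
    return min(
        scored,
        key=lambda m: (-abundance.tpm[m.transcript_id], -m.length, m.transcript_id),
    )


def models_to_frame(models: Iterable[TranscriptModel]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.gene_id, m.transcript_id, m.len5, m.lenC, m.len3) for m in models],
        columns=["gene_id", "transcript_id", "len5", "lenC", "len3"],
    )


def write_models_tsv(models: Iterable[TranscriptModel], path: str | Path) -> None:
    models_to_frame(models).to_csv(path, sep="\t", index=False)


def group_models_by_gene(
    models: Iterable[TranscriptModel],
) -> Mapping[str, list[TranscriptModel]]:
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    return by_gene
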