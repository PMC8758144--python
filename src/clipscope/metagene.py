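"""Metagene profiling and 5'-UTR-enrichment classification.

Each read is assigned to one of three transcript regions — 5'-UTR together
with the start codon, coding region together with the stop codon, or 3'-UTR —
by majority overlap of its aligned bases.  Its position is then rescaled to a
common metagene axis: −1..0 across the 5'-UTR (−1 at the cap, 0 at the start
codon), 0..1 across the coding region, 1..2 across the 3'-UTR.  Region read
counts are normalized by region length to reads/nt, and a gene whose 5'-UTR
density is at least 20x its 3'-UTR density is called "5'-UTR enriched";
everything else is a "pan-mRNA" with crosslinking spread along the transcript.
Gene ranking by 5'-UTR density over genes with >= 100 total reads feeds
downstream pathway analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .readproc import AlignedRead

logger = logging.getLogger(__name__)

Region = Literal["utr5", "coding", "utr3"]

UTR5_ENRICHED = "utr5_enriched"
PAN_MRNA = "pan_mRNA"
UNCLASSIFIABLE = "unclassifiable"


def _region_spans(model: TranscriptModel) -> dict[str, tuple[int, int]]:
    # start codon counts with the 5'-UTR, stop codon with the coding region
    l5, lc = model.len5, model.lenC
    return {
        "utr5": (0, l5 + 3),
        "coding": (l5 + 3, l5 + lc),
        "utr3": (l5 + lc, model.length),
    }


def assign_read_feature(read: AlignedRead, model: TranscriptModel) -> Region:
    """Assign a read to utr5 / coding / utr3 by majority base overlap.

    Ties go to the 5'-most region.  The start codon belongs to utr5 and the
    stop codon to coding, matching the length-normalization convention.
    """
    if read.start < 0 or read.end > model.length:
        raise ValueError(
            f"read [{read.start},{read.end}) outside transcript "
            f"{model.transcript_id} [0,{model.length})"
        )
    best: Region = "utr5"
    best_ov = -1
    for region, (s, e) in _region_spans(model).items():
        ov = max(0, min(read.end, e) - max(read.start, s))
        if ov > best_ov:  # strict: first (5'-most) region wins ties
            best, best_ov = region, ov
    return best


def relative_position_of_midpoint(
    model: TranscriptModel, m: float, region: Region
) -> float:
    """Map a transcript-space midpoint to the metagene axis for its region.

    utr5: −(len5 − m)/len5 (cap → −1, start codon → 0); coding:
    (m − len5)/lenC; utr3: 1 + (m − len5 − lenC)/len3.  The value is clamped
    to the region's interval so the axis endpoints meet at −1, 0, 1, 2.
    """
    l5, lc, l3 = model.len5, model.lenC, model.len3
    if region == "utr5":
        if l5 == 0:
            raise ValueError(f"{model.transcript_id}: 5'-UTR has zero length")
        v = -(l5 - m) / l5
        lo, hi = -1.0, 0.0
    elif region == "coding":
        v = (m - l5) / lc
        lo, hi = 0.0, 1.0
    elif region == "utr3":
        if l3 == 0:
            raise ValueError(f"{model.transcript_id}: 3'-UTR has zero length")
        v = 1.0 + (m - l5 - lc) / l3
        lo, hi = 1.0, 2.0
    else:
        raise ValueError(f"unknown region {region!r}")
    return min(max(v, lo), hi)


def relative_position(
    read: AlignedRead, model: TranscriptModel, region: Region | None = None
) -> float:
    """Metagene relative position of a read (by its midpoint)."""
    if region is None:
        region = assign_read_feature(read, model)
    return relative_position_of_midpoint(model, read.midpoint, region)


@dataclass
class EcdfCurve:
    """Right-continuous empirical CDF: step locations and cumulative levels."""

    x: np.ndarray
    y: np.ndarray

    def __call__(self, q: float | np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.x, q, side="right")
        y = np.concatenate([[0.0], self.y])
        return y[idx]


def metagene_ecdf(positions: Sequence[float]) -> EcdfCurve:
    """ECDF of metagene positions (multiset semantics)."""
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        raise ValueError("metagene_ecdf requires at least one position")
    x, counts = np.unique(pos, return_counts=True)
    y = np.cumsum(counts) / pos.size
    return EcdfCurve(x, y)


@dataclass
class GeneReadSummary:
    """Per-gene region read counts, length-normalized densities and label."""

    gene_id: str
    reads5: int
    readsC: int
    reads3: int
    total_reads: int
    dens5: float
    densC: float
    dens3: float
    ratio: float  # dens5/dens3; inf when dens3 == 0 and reads5 > 0; nan if undefined
    label: str | None = None


def summarize_gene(
    reads: Iterable[AlignedRead], model: TranscriptModel
) -> GeneReadSummary:
    """Count reads per region and derive the length-normalized densities.

    reads5 covers the 5'-UTR plus start codon, normalized by 5'-UTR length;
    readsC covers coding plus stop codon, normalized by coding length; reads3
    covers the 3'-UTR, normalized by its length.  Genes with a missing UTR or
    no reads at all are flagged unclassifiable rather than dropped.
    """
    counts = {"utr5": 0, "coding": 0, "utr3": 0}
    for r in reads:
        counts[assign_read_feature(r, model)] += 1
    reads5, readsC, reads3 = counts["utr5"], counts["coding"], counts["utr3"]
    total = reads5 + readsC + reads3
    dens5 = reads5 / model.len5 if model.len5 > 0 else math.nan
    densC = readsC / model.lenC
    dens3 = reads3 / model.len3 if model.len3 > 0 else math.nan
    label = None
    if model.len5 == 0 or model.len3 == 0 or total == 0:
        label = UNCLASSIFIABLE
        ratio = math.nan
    elif dens3 == 0:
        ratio = math.inf if reads5 > 0 else math.nan
        if reads5 == 0:
            label = UNCLASSIFIABLE
    else:
        ratio = dens5 / dens3
    return GeneReadSummary(
        gene_id=model.gene_id,
        reads5=reads5,
        readsC=readsC,
        reads3=reads3,
        total_reads=total,
        dens5=dens5,
        densC=densC,
        dens3=dens3,
        ratio=ratio,
        label=label,
    )


def classify_gene(summary: GeneReadSummary, threshold: float = 20.0) -> str:
    """Label a gene 5'-UTR enriched (ratio >= threshold, inclusive) or
    pan-mRNA; an unclassifiable summary keeps its label."""
    if summary.label == UNCLASSIFIABLE:
        return UNCLASSIFIABLE
    if math.isnan(summary.ratio):
        summary.label = UNCLASSIFIABLE
    elif summary.ratio >= threshold:
        summary.label = UTR5_ENRICHED
    else:
        summary.label = PAN_MRNA
    return summary.label


def rank_and_select(
    summaries: Iterable[GeneReadSummary],
    min_total_reads: int = 100,
    top_n: int = 500,
) -> list[str]:
    """Rank genes for pathway analysis: keep genes with at least
    ``min_total_reads`` total reads, sort by 5'-UTR read density (descending;
    ties by total reads then gene_id), return the top ``top_n`` gene ids."""
    eligible = [
        s
        for s in summaries
        if s.total_reads >= min_total_reads and not math.isnan(s.dens5)
    ]
    eligible.sort(key=lambda s: (-s.dens5, -s.total_reads, s.gene_id))
    if len(eligible) < top_n:
        logger.warning(
            "only %d genes qualify (requested top %d); returning all", len(eligible), top_n
        )
    return [s.gene_id for s in eligible[:top_n]]


def summaries_to_frame(summaries: Iterable[GeneReadSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.gene_id, s.reads5, s.readsC, s.reads3, s.total_reads,
             s.dens5, s.densC, s.dens3, s.ratio, s.label)
            for s in summaries
        ],
        columns=["gene_id", "reads5", "readsC", "reads3", "total",
                 "dens5", "densC", "dens3", "ratio", "label"],
    )
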