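"""Synthetic data generators with ground-truth bookkeeping.

Two generators provide every input the pipeline consumes, so the full
analysis can be exercised and scored without external downloads:

* a PAR-CLIP read simulator: a transcriptome of protein-coding genes (1-3
  isoforms each, TPM-ranked), and crosslinking reads whose positions are
  either concentrated in the 5'-UTR or uniform along the transcript
  ("pan-mRNA"), carrying T->C conversions near the crosslink site,
  substitution noise, random 3'-adapter barcodes and PCR duplicates;
* a microscopy simulator: matched bead and cell 3-channel z-stacks of
  anisotropic Gaussian spots with known per-channel chromatic shifts, a known
  colocalized spot fraction, and Poisson-plus-Gaussian noise.

Every generator is deterministic given its config (the seed is part of the
config), and each returns a truth record sufficient to score downstream
parameter-recovery tests.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import AbundanceTable, TranscriptModel
from .coloc import ImageStack, Vector
from .readproc import AlignedRead, MismatchRecord

BASES = np.array(list("ACGT"))

# ---------------------------------------------------------------------------
# PAR-CLIP read simulation


@dataclass
class ReadSimConfig:
    """Configuration of the PAR-CLIP read simulator.

    Feature lengths are gamma-distributed (shape ``length_shape``) around the
    configured means, floored at small minima; coding lengths are rounded to
    codon multiples.  ``conversion_model`` selects where T->C conversions are
    planted: ``"crosslink"`` converts covered Ts within ``conversion_window``
    nt of each read's crosslink position (the PAR-CLIP signature), while
    ``"per_t"`` converts every covered reference T independently.
    """

    seed: int
    n_genes: int = 200
    frac_utr5_peaked: float = 0.5
    len5_mean: float = 150.0
    lenC_mean: float = 900.0
    len3_mean: float = 450.0
    length_shape: float = 4.0
    max_isoforms: int = 3
    reads_per_gene: int = 500
    read_len_min: int = 25
    read_len_max: int = 35
    conversion_rate: float = 0.25
    conversion_model: str = "crosslink"  # or "per_t"
    conversion_window: int = 3
    other_mismatch_rate: float = 0.002
    duplication_rate: float = 0.4
    barcode_length: int = 8
    utr5_leak: float = 0.1
    crosslink_sites_per_gene: int | None = None

    def __post_init__(self) -> None:
        for name in ("frac_utr5_peaked", "conversion_rate", "other_mismatch_rate",
                     "duplication_rate", "utr5_leak"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if min(self.len5_mean, self.lenC_mean, self.len3_mean) <= 0:
            raise ValueError("feature length means must be positive")
        if self.conversion_model not in ("crosslink", "per_t"):
            raise ValueError(f"unknown conversion_model {self.conversion_model!r}")
        if self.read_len_min < 1 or self.read_len_max < self.read_len_min:
            raise ValueError("invalid read length range")


@dataclass
class SimulatedTranscriptome:
    """Transcript models, abundances, reference sequences and gene truth."""

    models: list[TranscriptModel]
    abundance: AbundanceTable
    sequences: dict[str, np.ndarray]  # primary transcript_id -> base array
    truth: pd.DataFrame  # gene_id, transcript_id (primary), class_label

    def primary_model(self, gene_id: str) -> TranscriptModel:
        tx = self.truth.set_index("gene_id").loc[gene_id, "transcript_id"]
        return next(m for m in self.models if m.transcript_id == tx)


def _sample_length(rng: np.random.Generator, mean: float, shape: float,
                   minimum: int) -> int:
    return max(minimum, int(round(rng.gamma(shape, mean / shape))))


def simulate_transcriptome(config: ReadSimConfig) -> SimulatedTranscriptome:
    """Sample gene models (1-3 isoforms, TPM-ranked) and class labels."""
    rng = np.random.default_rng(config.seed)
    models: list[TranscriptModel] = []
    tpm: dict[str, float] = {}
    gene_of: dict[str, str] = {}
    sequences: dict[str, np.ndarray] = {}
    rows = []
    n_peaked = int(round(config.n_genes * config.frac_utr5_peaked))
    for i in range(config.n_genes):
        gid = f"G{i:04d}"
        label = "utr5_peaked" if i < n_peaked else "pan_uniform"
        n_iso = int(rng.integers(1, config.max_isoforms + 1))
        iso_models = []
        for k in range(n_iso):
            tx = f"{gid}.{k + 1}"
            m = TranscriptModel(
                gene_id=gid,
                transcript_id=tx,
                len5=_sample_length(rng, config.len5_mean, config.length_shape, 20),
                lenC=3 * max(20, int(round(
                    rng.gamma(config.length_shape, config.lenC_mean / config.length_shape) / 3
                ))),
                len3=_sample_length(rng, config.len3_mean, config.length_shape, 30),
            )
            iso_models.append(m)
            tpm[tx] = float(rng.gamma(2.0, 5.0))
            gene_of[tx] = gid
        primary = max(iso_models, key=lambda m: tpm[m.transcript_id])
        sequences[primary.transcript_id] = rng.choice(BASES, size=primary.length)
        models.extend(iso_models)
        rows.append((gid, primary.transcript_id, label))
    truth = pd.DataFrame(rows, columns=["gene_id", "transcript_id", "class_label"])
    return SimulatedTranscriptome(
        models=models,
        abundance=AbundanceTable(tpm=tpm, gene=gene_of),
        sequences=sequences,
        truth=truth,
    )


@dataclass
class ReadSimTruth:
    """Ground truth of one read-simulation run."""

    genes: pd.DataFrame  # gene_id, transcript_id, class_label, n_molecules, n_reads
    sites: dict[str, np.ndarray] = field(default_factory=dict)
    n_molecules: int = 0
    n_reads: int = 0
    n_distinct_keys: int = 0


def _random_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    codes = rng.integers(0, 4, size=(n, length))
    return ["".join(BASES[row]) for row in codes]


def _crosslink_positions(
    rng: np.random.Generator, model: TranscriptModel, label: str, n: int, leak: float
) -> np.ndarray:
    """Per-read crosslink positions under the gene's positional law."""
    total = model.length
    if label == "pan_uniform":
        return rng.integers(0, total, size=n)
    # 5'-UTR peaked: Beta(2,2) hump across the UTR with a uniform leak
    pos = np.floor(rng.beta(2.0, 2.0, size=n) * model.len5).astype(np.int64)
    pos = np.minimum(pos, max(model.len5 - 1, 0))
    leak_mask = rng.random(n) < leak
    pos[leak_mask] = rng.integers(0, total, size=int(leak_mask.sum()))
    return pos


def simulate_parclip_reads(
    transcriptome: SimulatedTranscriptome, config: ReadSimConfig
) -> tuple[list[AlignedRead], ReadSimTruth]:
    """Emit PAR-CLIP reads over each gene's primary isoform.

    Each unique molecule gets a random barcode; PCR duplicates (exact copies,
    same barcode and mismatches) are re-emitted at ``duplication_rate``.  When
    ``crosslink_sites_per_gene`` is set, each gene receives that many fixed
    crosslink sites (forced to contain Ts) and all reads pile on them;
    otherwise crosslink positions follow the gene's positional class.
    """
    if not transcriptome.models:
        raise ValueError("empty transcriptome")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    reads: list[AlignedRead] = []
    rows = []
    sites_truth: dict[str, np.ndarray] = {}
    total_molecules = 0
    w = config.conversion_window
    for gene in transcriptome.truth.itertuples():
        model = transcriptome.primary_model(gene.gene_id)
        seq = transcriptome.sequences[model.transcript_id]
        total = model.length
        n = config.reads_per_gene
        if config.crosslink_sites_per_gene:
            margin = min(config.read_len_max, total // 2)
            sites = rng.integers(margin, max(total - margin, margin + 1),
                                 size=config.crosslink_sites_per_gene)
            for s in sites:  # guarantee convertible uridines at the site
                seq[s] = "T"
                if s + 2 < total:
                    seq[s + 2] = "T"
            sites_truth[gene.gene_id] = sites
            xs = sites[rng.integers(0, len(sites), size=n)]
        else:
            xs = _crosslink_positions(rng, model, gene.class_label, n, config.utr5_leak)
        lens = rng.integers(config.read_len_min, config.read_len_max + 1, size=n)
        offsets = rng.integers(0, lens)
        starts = np.clip(xs - offsets, 0, np.maximum(total - lens, 0))
        barcodes = _random_barcodes(rng, n, config.barcode_length)
        dup_flags = rng.random(n) < config.duplication_rate
        gene_reads = 0
        for x, start, length, barcode, dup in zip(xs, starts, lens, barcodes, dup_flags):
            start = int(start)
            end = min(start + int(length), total)
            window = seq[start:end]
            t_pos = start + np.flatnonzero(window == "T")
            if config.conversion_model == "crosslink":
                t_pos = t_pos[(t_pos >= x - w) & (t_pos <= x + w)]
            conv_pos = t_pos[rng.random(t_pos.size) < config.conversion_rate]
            mms = [MismatchRecord(int(p), "T", "C", None) for p in conv_pos]
            converted = set(int(p) for p in conv_pos)
            noise = start + np.flatnonzero(rng.random(end - start) < config.other_mismatch_rate)
            for p in noise:
                p = int(p)
                if p in converted:
                    continue
                ref = str(seq[p])
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                mms.append(MismatchRecord(p, ref, alt, None))
            mms.sort(key=lambda m: m.pos)
            read = AlignedRead(
                transcript_id=model.transcript_id,
                start=start,
                end=end,
                strand="+",
                barcode=barcode,
                mismatches=mms,
            )
            reads.append(read)
            gene_reads += 1
            if dup:
                reads.append(copy.deepcopy(read))
                gene_reads += 1
        total_molecules += n
        rows.append((gene.gene_id, model.transcript_id, gene.class_label, n, gene_reads))
    genes = pd.DataFrame(
        rows, columns=["gene_id", "transcript_id", "class_label", "n_molecules", "n_reads"]
    )
    keys = {(r.transcript_id, r.start, r.end, r.strand, r.barcode) for r in reads}
    truth = ReadSimTruth(
        genes=genes,
        sites=sites_truth,
        n_molecules=total_molecules,
        n_reads=len(reads),
        n_distinct_keys=len(keys),
    )
    return reads, truth


def write_sam(
    reads: list[AlignedRead],
    sequences: Mapping[str, np.ndarray],
    path: str | Path,
) -> None:
    """Write reads as transcript-space SAM with MD/NM tags.

    The read sequence is reconstructed from the reference with the read's
    substitutions applied; the barcode is appended to the read name.
    """
    import pysam

    tx_ids = sorted({r.transcript_id for r in reads})
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": tx, "LN": int(len(sequences[tx]))} for tx in tx_ids],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, r in enumerate(reads):
            ref = sequences[r.transcript_id][r.start : r.end].copy()
            md_parts = []
            run = 0
            mms = {m.pos: m for m in r.mismatches}
            for p in range(r.start, r.end):
                if p in mms:
                    md_parts.append(f"{run}{mms[p].ref_base}")
                    run = 0
                    ref[p - r.start] = mms[p].read_base
                else:
                    run += 1
            md_parts.append(str(run))
            a = pysam.AlignedSegment()
            a.query_name = f"mol{i}_{r.barcode}"
            a.query_sequence = "".join(ref)
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = tx_ids.index(r.transcript_id)
            a.reference_start = r.start
            a.mapping_quality = 255
            a.cigarstring = f"{r.end - r.start}M"
            a.set_tag("MD", "".join(md_parts))
            a.set_tag("NM", len(r.mismatches))
            out.write(a)


# ---------------------------------------------------------------------------
# Microscopy simulation


@dataclass
class ImageSimConfig:
    """Configuration of the bead/cell z-stack simulator.

    Spots are anisotropic 3D Gaussians at roughly the deconvolved confocal
    resolution (~150 nm lateral, ~500 nm axial FWHM); the per-channel
    chromatic shift is a subvoxel 3D translation shared by the bead and cell
    fields of a sample.  Noise is Poisson shot noise plus an additive
    Gaussian floor.
    """

    seed: int
    shape: tuple[int, int, int] = (24, 96, 96)  # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (35.0, 35.0, 190.0)  # (x, y, z) nm
    n_spots: int = 150
    n_beads: int = 25
    spot_sigma_lateral_nm: float = 64.0
    spot_sigma_axial_nm: float = 212.0
    colocalized_fraction: float = 0.5
    channel_shifts: dict[str, Vector] = field(
        default_factory=lambda: {
            "ch0": (0.0, 0.0, 0.0),
            "ch1": (0.3, 1.6, -2.1),
            "ch2": (-0.5, -1.2, 0.8),
        }
    )
    amplitude: float = 150.0
    bead_amplitude: float = 400.0
    background: float = 10.0
    read_noise_sigma: float = 2.0
    poisson_noise: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.colocalized_fraction <= 1.0:
            raise ValueError("colocalized_fraction must be in [0,1]")
        if any(s <= 0 for s in self.shape):
            raise ValueError("stack shape must be positive")
        if min(self.sigma_voxels) < 1.0:
            raise ValueError(
                f"spot sigma {self.sigma_voxels} below 1 voxel in some axis: unresolvable"
            )

    @property
    def sigma_voxels(self) -> tuple[float, float, float]:
        """Spot sigma in (z, y, x) voxel units."""
        vx, vy, vz = self.voxel_size
        return (
            self.spot_sigma_axial_nm / vz,
            self.spot_sigma_lateral_nm / vy,
            self.spot_sigma_lateral_nm / vx,
        )


@dataclass
class ImageSimTruth:
    """Planted shifts, colocalized fraction and spot/bead positions."""

    channel_shifts: dict[str, Vector]
    colocalized_fraction: float
    bead_positions: np.ndarray
    cell_positions: dict[str, np.ndarray]


def _render_spots(
    shape: tuple[int, int, int],
    centers: np.ndarray,
    sigma: tuple[float, float, float],
    amplitude: float,
) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    if centers.size == 0:
        return img
    radii = [int(np.ceil(4 * s)) for s in sigma]
    for c in centers:
        lo = [max(int(np.floor(c[d])) - radii[d], 0) for d in range(3)]
        hi = [min(int(np.ceil(c[d])) + radii[d] + 1, shape[d]) for d in range(3)]
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        g = np.exp(
            -((zz - c[0]) ** 2) / (2 * sigma[0] ** 2)
            - ((yy - c[1]) ** 2) / (2 * sigma[1] ** 2)
            - ((xx - c[2]) ** 2) / (2 * sigma[2] ** 2)
        )
        img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * g
    return img


def _add_noise(img: np.ndarray, config: ImageSimConfig, rng: np.random.Generator) -> np.ndarray:
    out = img + config.background
    if config.poisson_noise:
        out = rng.poisson(np.maximum(out, 0.0)).astype(float)
    if config.read_noise_sigma > 0:
        out = out + rng.normal(0.0, config.read_noise_sigma, size=img.shape)
    return np.maximum(out, 0.0)


def _uniform_positions(
    rng: np.random.Generator, n: int, shape: tuple[int, int, int],
    sigma: tuple[float, float, float],
) -> np.ndarray:
    margins = [min(4 * s, dim / 4) for s, dim in zip(sigma, shape)]
    return np.column_stack(
        [rng.uniform(m, dim - m, size=n) for m, dim in zip(margins, shape)]
    )


def simulate_bead_and_cell_stacks(
    config: ImageSimConfig,
) -> tuple[ImageStack, ImageStack, ImageSimTruth]:
    """Matched bead and cell stacks with a shared planted chromatic shift.

    Beads are a single spot field rendered in every channel; cells share a
    fraction ``colocalized_fraction`` of spot positions across all channels,
    with the remainder independent per channel.  Each channel is displaced by
    its chromatic shift at render time (continuous, hence band-limited).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    sigma = config.sigma_voxels
    shifts = {k: np.asarray(v, dtype=float) for k, v in config.channel_shifts.items()}

    bead_pos = _uniform_positions(rng, config.n_beads, config.shape, sigma)
    bead_channels = {}
    for name, s in shifts.items():
        img = _render_spots(config.shape, bead_pos + s, sigma, config.bead_amplitude)
        bead_channels[name] = _add_noise(img, config, rng)

    n_shared = int(round(config.colocalized_fraction * config.n_spots))
    shared = _uniform_positions(rng, n_shared, config.shape, sigma)
    cell_channels = {}
    cell_positions = {}
    for name, s in shifts.items():
        own = _uniform_positions(rng, config.n_spots - n_shared, config.shape, sigma)
        pos = np.vstack([shared, own]) if own.size or shared.size else shared
        cell_positions[name] = pos
        img = _render_spots(config.shape, pos + s, sigma, config.amplitude)
        cell_channels[name] = _add_noise(img, config, rng)

    bead = ImageStack(bead_channels, config.voxel_size)
    cell = ImageStack(cell_channels, config.voxel_size)
    truth = ImageSimTruth(
        channel_shifts={k: tuple(v) for k, v in shifts.items()},
        colocalized_fraction=config.colocalized_fraction,
        bead_positions=bead_pos,
        cell_positions=cell_positions,
    )
    return bead, cell, truth
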