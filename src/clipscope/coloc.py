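"""Bead-registered fluorescence colocalization.

Multi-fluorescent beads (e.g. TetraSpeck microspheres) imaged alongside the
cells provide a per-channel estimate of the chromatic shift: each channel of
the bead z-stack is registered to a reference channel by cross-correlation
(subvoxel, translation-only), and the same vectors are applied to the cell
z-stack.  Channels are background-thresholded (Otsu by default) and
colocalization of each channel pair is quantified as the Pearson correlation
coefficient (PCC) of raw intensities over the union of the two masks inside
the registration validity region.  Samples whose bead channels correlate
below 0.45 for any pair are excluded from analysis (insufficient dynamic
range).  Groups of PCC values are compared with an exact two-sided Wilcoxon
rank-sum test.

Registration vectors are expressed in voxel units (z, y, x); anisotropic
voxel sizes are metadata used only for physical-unit reporting.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

logger = logging.getLogger(__name__)

Vector = tuple[float, float, float]  # (dz, dy, dx) in voxels


class DegenerateInputError(ValueError):
    """Raised when an image or evaluation set cannot support the operation."""


@dataclass
class ImageStack:
    """Named 3D channels (z, y, x) sharing one shape, plus voxel size in nm."""

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float] = (35.0, 35.0, 190.0)  # (x, y, z) nm

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)


def read_stack(
    paths: Mapping[str, str | Path],
    voxel_size: tuple[float, float, float] = (35.0, 35.0, 190.0),
) -> ImageStack:
    """Load one TIFF per channel (z-stack pages) into an :class:`ImageStack`."""
    channels = {name: tifffile.imread(str(p)).astype(float) for name, p in paths.items()}
    return ImageStack(channels, voxel_size)


def write_stack(stack: ImageStack, directory: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write each channel as a 32-bit TIFF z-stack; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for name, arr in stack.channels.items():
        p = directory / f"{prefix}{name}.tif"
        tifffile.imwrite(str(p), arr.astype(np.float32))
        out[name] = p
    return out


def estimate_registration(
    bead_stack: ImageStack,
    reference: str,
    upsample_factor: int = 50,
) -> dict[str, Vector]:
    """Per-channel chromatic shift relative to ``reference``, in voxels.

    The returned vector is the displacement of the channel's features with
    respect to the reference (a channel translated by +v yields vector v),
    estimated by cross-correlation with subvoxel refinement.  The reference
    channel maps to the zero vector.
    """
    if reference not in bead_stack.channels:
        raise KeyError(f"reference channel {reference!r} not in stack")
    ref = bead_stack.channels[reference]
    if np.ptp(ref) == 0:
        raise DegenerateInputError(f"reference channel {reference!r} has zero variance")
    vectors: dict[str, Vector] = {}
    for name, chan in bead_stack.channels.items():
        if name == reference:
            vectors[name] = (0.0, 0.0, 0.0)
            continue
        if np.ptp(chan) == 0:
            raise DegenerateInputError(f"channel {name!r} has zero variance")
        shift, _, _ = phase_cross_correlation(
            ref, chan, upsample_factor=upsample_factor, normalization=None
        )
        # phase_cross_correlation returns the shift that aligns the moving
        # channel onto the reference, i.e. minus the chromatic displacement
        vectors[name] = tuple((-shift).tolist())
    return vectors


@dataclass
class RegisteredStack:
    """A translated stack plus the validity mask of in-frame voxels."""

    channels: dict[str, np.ndarray]
    validity: np.ndarray


def apply_registration(stack: ImageStack, reg: Mapping[str, Vector]) -> RegisteredStack:
    """Undo each channel's chromatic shift by linear-interpolated translation.

    Out-of-frame voxels are filled with 0 and removed from the joint validity
    mask so they never enter a correlation.
    """
    if set(reg) != set(stack.channels):
        raise ValueError(
            f"registration channels {sorted(reg)} do not match stack {sorted(stack.channels)}"
        )
    out: dict[str, np.ndarray] = {}
    validity = np.ones(stack.shape, dtype=bool)
    for name, chan in stack.channels.items():
        v = np.asarray(reg[name], dtype=float)
        if np.all(v == 0):
            out[name] = chan.copy()
            continue
        out[name] = ndimage.shift(chan, -v, order=1, mode="constant", cval=0.0)
        ones = ndimage.shift(np.ones_like(chan), -v, order=1, mode="constant", cval=0.0)
        validity &= ones > 0.999
    return RegisteredStack(out, validity)


def threshold_channel(
    channel: np.ndarray, method: str = "otsu"
) -> tuple[np.ndarray, float]:
    """Background-removal mask for one channel; returns (mask, threshold).

    An all-background channel (no separation between the two Otsu classes)
    yields an empty mask with a warning; a constant channel is an error.
    """
    if np.ptp(channel) == 0:
        raise DegenerateInputError("constant channel cannot be thresholded")
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    thr = float(threshold_otsu(channel))
    mask = channel > thr
    if mask.any() and (~mask).any():
        fg, bg = channel[mask], channel[~mask]
        # no real foreground: the split is just carving up the noise floor
        if fg.mean() - bg.mean() < 4.0 * bg.std():
            warnings.warn("channel appears to be all background; returning empty mask")
            logger.warning("threshold %.3g separates no foreground; empty mask", thr)
            return np.zeros_like(mask), thr
    logger.info("threshold (%s) = %.6g, foreground fraction %.4f", method, thr, mask.mean())
    return mask, thr


def pearson_pcc(
    chan_a: np.ndarray,
    chan_b: np.ndarray,
    mask_a: np.ndarray | None = None,
    mask_b: np.ndarray | None = None,
    validity: np.ndarray | None = None,
) -> float:
    """Pearson correlation of raw intensities over the evaluation set.

    The evaluation set is the union of the two masks intersected with the
    validity region; with no masks it is the whole (valid) volume.  At least
    2 voxels and nonzero variance in both channels are required.
    """
    if mask_a is None and mask_b is None:
        sel = np.ones(chan_a.shape, dtype=bool)
    else:
        sel = np.zeros(chan_a.shape, dtype=bool)
        if mask_a is not None:
            sel |= mask_a
        if mask_b is not None:
            sel |= mask_b
    if validity is not None:
        sel &= validity
    a, b = chan_a[sel], chan_b[sel]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        raise DegenerateInputError(
            f"degenerate PCC evaluation set ({a.size} voxels)"
        )
    return float(np.corrcoef(a, b)[0, 1])


def pcc_matrix(
    channels: Mapping[str, np.ndarray],
    masks: Mapping[str, np.ndarray] | None = None,
    validity: np.ndarray | None = None,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise PCCs (diagonal 1)."""
    names = list(channels)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        pcc = pearson_pcc(
            channels[a],
            channels[b],
            masks[a] if masks else None,
            masks[b] if masks else None,
            validity,
        )
        mat.loc[a, b] = mat.loc[b, a] = pcc
    return mat


@dataclass
class ColocSample:
    """Per-sample colocalization result with the bead QC decision."""

    bead_pcc: pd.DataFrame
    cell_pcc: pd.DataFrame
    qc_pass: bool
    registration: dict[str, Vector] = field(default_factory=dict)

    def min_bead_pcc(self) -> float:
        m = self.bead_pcc.to_numpy()
        off = m[~np.eye(m.shape[0], dtype=bool)]
        return float(off.min())

    def cell_pair_pcc(self, a: str, b: str) -> float:
        return float(self.cell_pcc.loc[a, b])


def qc_filter(sample: ColocSample, qc_threshold: float = 0.45) -> bool:
    """Bead-based QC: exclude the sample iff any off-diagonal bead PCC is
    strictly below ``qc_threshold``.  Returns (and stores) the pass flag."""
    min_pcc = sample.min_bead_pcc()
    sample.qc_pass = not (min_pcc < qc_threshold)
    logger.info(
        "bead QC: min pair PCC %.4f vs threshold %.2f -> %s",
        min_pcc, qc_threshold, "retained" if sample.qc_pass else "excluded",
    )
    return sample.qc_pass


def analyze_sample(
    bead_stack: ImageStack,
    cell_stack: ImageStack,
    reference: str,
    qc_threshold: float = 0.45,
    threshold_method: str = "otsu",
    whole_image: bool = False,
) -> ColocSample:
    """Full per-sample pipeline: bead registration, registration transfer to
    the cell stack, thresholding, pairwise PCCs and bead QC.

    With ``whole_image=True`` the PCC is computed over the entire validity
    region instead of the union of thresholded masks.
    """
    reg = estimate_registration(bead_stack, reference)
    bead_reg = apply_registration(bead_stack, reg)
    cell_reg = apply_registration(cell_stack, reg)

    def masks_for(rs: RegisteredStack) -> dict[str, np.ndarray] | None:
        if whole_image:
            return None
        return {n: threshold_channel(c, threshold_method)[0] for n, c in rs.channels.items()}

    bead = pcc_matrix(bead_reg.channels, masks_for(bead_reg), bead_reg.validity)
    cell = pcc_matrix(cell_reg.channels, masks_for(cell_reg), cell_reg.validity)
    sample = ColocSample(bead_pcc=bead, cell_pcc=cell, qc_pass=True, registration=reg)
    qc_filter(sample, qc_threshold)
    return sample


def _rank_sum_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[: len(x)].sum())


def ranksum_exact(
    group1: Sequence[float], group2: Sequence[float], exact_max_n: int = 20
) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    For n1 + n2 <= ``exact_max_n`` the p-value is exact: the rank-sum statistic
    is evaluated over every assignment of the pooled values to the two groups
    (midranks for ties) and the two-sided p is twice the smaller one-sided
    tail, capped at 1.  Larger samples use the tie-corrected normal
    approximation.  Identical pooled values give p = 1.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    if x.size + y.size <= exact_max_n:
        ps = []
        for alternative in ("less", "greater"):
            res = stats.permutation_test(
                (x, y),
                _rank_sum_statistic,
                permutation_type="independent",
                alternative=alternative,
                n_resamples=np.inf,
            )
            ps.append(res.pvalue)
        return float(min(1.0, 2.0 * min(ps)))
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def samples_to_frame(samples: Mapping[str, ColocSample]) -> pd.DataFrame:
    """Long-format per-sample report: one row per channel pair."""
    rows = []
    for name, s in samples.items():
        chans = list(s.bead_pcc.columns)
        for a, b in itertools.combinations(chans, 2):
            rows.append(
                (name, f"{a}:{b}", float(s.bead_pcc.loc[a, b]),
                 float(s.cell_pcc.loc[a, b]), s.qc_pass)
            )
    return pd.DataFrame(
        rows, columns=["sample", "channel_pair", "bead_pcc", "cell_pcc", "qc_pass"]
    )
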