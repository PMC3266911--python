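"""Absolute integer copy number from LRR/BAF with aneuploidy correction.

Per chromosome, LRR is split by greedy binary segmentation (a split is
kept when it lowers the within-segment sum of squares by more than a
penalty).  Each segment's mean LRR and mean mirrored BAF are then matched
against the grid of integer copy number / minor-allele count expectations,
sample ploidy is the probe-weighted modal copy number, and segments are
labelled gained / lost / normal relative to that ploidy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "CopyNumberProfile",
    "segment_profile",
    "default_penalty",
    "fit_segment_cn",
    "estimate_ploidy",
    "label_segments",
    "call_profile",
]

#: mirrored-BAF below this is treated as homozygous and carries no
#: allelic-imbalance information for the segment mean
MBAF_MIN = 0.05

LABELS = ("normal", "gained", "lost")


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int  # probe index within chromosome, half-open
    end: int
    start_bp: int
    end_bp: int
    mean_lrr: float
    mean_mbaf: float
    cn: int
    b: int
    label: str = "normal"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment end must exceed start ({self.start}, {self.end})")
        if not 0 <= self.b <= self.cn // 2 and self.cn > 0:
            raise ValueError(f"minor-allele count {self.b} invalid for CN {self.cn}")

    @property
    def n_probes(self) -> int:
        return self.end - self.start


@dataclass
class CopyNumberProfile:
    sample: str
    segments: list[Segment]
    per_probe_cn: np.ndarray  # aligned with the genome-wide probe table
    ploidy: int


def _sse(cs: np.ndarray, css: np.ndarray, lo: int, hi: int) -> float:
    n = hi - lo
    s = cs[hi] - cs[lo]
    return float(css[hi] - css[lo] - s * s / n)


def _best_split(cs: np.ndarray, css: np.ndarray, lo: int, hi: int) -> tuple[float, int]:
    """Largest SSE reduction over all split points of [lo, hi), and its index."""
    k = np.arange(lo + 1, hi)
    n_left = k - lo
    n_right = hi - k
    s_left = cs[k] - cs[lo]
    s_right = cs[hi] - cs[k]
    sse_split = (
        (css[k] - css[lo]) - s_left * s_left / n_left
        + (css[hi] - css[k]) - s_right * s_right / n_right
    )
    best = int(np.argmin(sse_split))
    gain = _sse(cs, css, lo, hi) - float(sse_split[best])
    return gain, int(k[best])


def default_penalty(lrr: np.ndarray) -> float:
    """BIC-like penalty ``2 * sigma^2 * log(n)``.

    sigma is estimated from median absolute successive differences,
    scaled for Gaussian noise (a successive difference has sd
    ``sigma * sqrt(2)`` and the median absolute deviate is 0.6745 sd).
    """
    lrr = np.asarray(lrr, dtype=float)
    n = lrr.size
    if n < 2:
        return 0.0
    sigma = np.median(np.abs(np.diff(lrr))) / (math.sqrt(2.0) * 0.6745)
    return 2.0 * sigma * sigma * math.log(n)


def segment_profile(
    lrr: Sequence[float],
    penalty: float | None = None,
    probe_ids: Sequence[str] | None = None,
) -> list[int]:
    """Breakpoints (sorted probe indices) from greedy binary segmentation.

    A split is accepted iff it reduces the within-segment SSE by more than
    ``penalty`` (default: :func:`default_penalty`).  Deterministic.
    """
    lrr = np.asarray(lrr, dtype=float)
    if lrr.size < 2:
        raise ValueError(f"need >= 2 probes per chromosome, got {lrr.size}")
    bad = ~np.isfinite(lrr)
    if bad.any():
        ids = (
            [probe_ids[i] for i in np.flatnonzero(bad)]
            if probe_ids is not None
            else np.flatnonzero(bad).tolist()
        )
        raise ValueError(f"non-finite LRR at probes: {ids}")
    if penalty is None:
        penalty = default_penalty(lrr)
    if penalty < 0:
        raise ValueError(f"penalty must be >= 0, got {penalty}")

    cs = np.concatenate(([0.0], np.cumsum(lrr)))
    css = np.concatenate(([0.0], np.cumsum(lrr * lrr)))
    breakpoints: list[int] = []
    stack = [(0, lrr.size)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2:
            continue
        gain, k = _best_split(cs, css, lo, hi)
        if gain > penalty:
            breakpoints.append(k)
            stack.append((lo, k))
            stack.append((k, hi))
    return sorted(breakpoints)


def fit_segment_cn(
    mean_lrr: float,
    mean_mbaf: float,
    c_max: int = 12,
    w_lrr: float = 1.0,
    w_baf: float = 1.0,
) -> tuple[int, int]:
    """Integer (copy number, minor-allele count) best matching a segment.

    Minimises ``w_lrr * (mean_lrr - log2(max(c, 0.5)/2))^2 +
    w_baf * (mean_mbaf - b/c)^2`` over c in 0..c_max and b in 0..c//2
    (b/c taken as 0.5 for c = 0).  Ties resolve to the smaller c, then the
    smaller b.
    """
    if c_max < 2:
        raise ValueError(f"c_max must be >= 2, got {c_max}")
    best: tuple[int, int] | None = None
    best_cost = math.inf
    for c in range(c_max + 1):
        lrr_model = math.log2(max(c, 0.5) / 2.0)
        lrr_cost = w_lrr * (mean_lrr - lrr_model) ** 2
        for b in range(c // 2 + 1) if c > 0 else (0,):
            baf_model = b / c if c > 0 else 0.5
            cost = lrr_cost + w_baf * (mean_mbaf - baf_model) ** 2
            if cost < best_cost:
                best_cost = cost
                best = (c, b)
    assert best is not None
    return best


def estimate_ploidy(profile: CopyNumberProfile) -> int:
    """Probe-weighted modal copy number across all segments (ties: smaller)."""
    if not profile.segments:
        raise ValueError(f"profile {profile.sample!r} has no segments")
    weights: dict[int, int] = {}
    for seg in profile.segments:
        weights[seg.cn] = weights.get(seg.cn, 0) + seg.n_probes
    return min(sorted(weights), key=lambda c: (-weights[c], c))


def label_segments(profile: CopyNumberProfile, ploidy: int | None = None) -> CopyNumberProfile:
    """Label every segment gained / lost / normal relative to sample ploidy."""
    if ploidy is None:
        ploidy = profile.ploidy
    if ploidy < 1:
        raise ValueError(f"ploidy must be >= 1, got {ploidy}")
    labelled = []
    for seg in profile.segments:
        if seg.cn > ploidy:
            label = "gained"
        elif seg.cn < ploidy:
            label = "lost"
        else:
            label = "normal"
        labelled.append(replace(seg, label=label))
    profile.segments = labelled
    profile.ploidy = ploidy
    return profile


def call_profile(
    sample: str,
    probes: pd.DataFrame,
    lrr: Sequence[float],
    baf: Sequence[float],
    c_max: int = 12,
    penalty: float | None = None,
    mbaf_min: float = MBAF_MIN,
    w_lrr: float = 1.0,
    w_baf: float = 1.0,
) -> CopyNumberProfile:
    """Segment, fit and label one sample's genome.

    ``probes`` must be position-sorted within chromosome and aligned with
    the LRR/BAF vectors.  Mirrored BAF = min(BAF, 1 - BAF); probes below
    ``mbaf_min`` (effectively homozygous) are excluded from a segment's
    mirrored-BAF mean, falling back to all probes if none remain.
    """
    lrr = np.asarray(lrr, dtype=float)
    baf = np.asarray(baf, dtype=float)
    if not (len(probes) == lrr.size == baf.size):
        raise ValueError("probe table and LRR/BAF vectors differ in length")
    mbaf = np.minimum(baf, 1.0 - baf)

    segments: list[Segment] = []
    per_probe_cn = np.empty(lrr.size, dtype=int)
    for chrom in probes["chrom"].unique():
        idx = np.flatnonzero((probes["chrom"] == chrom).to_numpy())
        pos = probes["pos"].to_numpy()[idx]
        chrom_lrr = lrr[idx]
        chrom_mbaf = mbaf[idx]
        bps = segment_profile(
            chrom_lrr, penalty=penalty, probe_ids=probes["probe_id"].to_numpy()[idx]
        )
        edges = [0, *bps, idx.size]
        for lo, hi in zip(edges[:-1], edges[1:]):
            seg_mbaf_vals = chrom_mbaf[lo:hi]
            informative = seg_mbaf_vals[seg_mbaf_vals >= mbaf_min]
            mean_mbaf = float(informative.mean() if informative.size else seg_mbaf_vals.mean())
            mean_lrr = float(chrom_lrr[lo:hi].mean())
            cn, b = fit_segment_cn(mean_lrr, mean_mbaf, c_max=c_max, w_lrr=w_lrr, w_baf=w_baf)
            segments.append(
                Segment(
                    chrom=str(chrom),
                    start=lo,
                    end=hi,
                    start_bp=int(pos[lo]),
                    end_bp=int(pos[hi - 1]) + 1,
                    mean_lrr=mean_lrr,
                    mean_mbaf=mean_mbaf,
                    cn=cn,
                    b=b,
                )
            )
            per_probe_cn[idx[lo:hi]] = cn

    profile = CopyNumberProfile(sample=sample, segments=segments,
                                per_probe_cn=per_probe_cn, ploidy=2)
    ploidy = estimate_ploidy(profile)
    return label_segments(profile, ploidy)
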