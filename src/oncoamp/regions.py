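"""Recurrently amplified regions scored across a sample set.

Per-marker amplification amplitude is copy number above sample ploidy; the
G-score averages amplitude over samples, so it rises with both the
frequency and the magnitude of amplification.  Significance comes from a
cyclic-shift permutation null (each sample's amplitude vector is rotated
independently within each chromosome), with permuted G values pooled
across markers, Benjamini-Hochberg q-values, and maximal runs of q below
a cutoff reported as regions with a single peak marker each.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from oncoamp.cncall import CopyNumberProfile

__all__ = [
    "AmplitudeMatrix",
    "GScoreProfile",
    "RegionPeak",
    "build_amplitude_matrix",
    "gscore",
    "permutation_null",
    "fdr_q",
    "significant_regions",
]

Q_CUTOFF = 0.25


@dataclass
class AmplitudeMatrix:
    """Markers x samples amplification amplitudes, max(0, CN - ploidy)."""

    values: np.ndarray  # (n_markers, n_samples), >= 0
    probes: pd.DataFrame  # probe_id, chrom, pos
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probes), len(self.samples)):
            raise ValueError(
                f"amplitude matrix shape {self.values.shape} does not match "
                f"{len(self.probes)} probes x {len(self.samples)} samples"
            )
        if (self.values < 0).any():
            raise ValueError("amplitudes must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class GScoreProfile:
    probes: pd.DataFrame
    g: np.ndarray
    p: np.ndarray
    q: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        out = self.probes.copy()
        out["g_score"] = self.g
        out["p_value"] = self.p
        out["q_value"] = self.q
        return out


@dataclass(frozen=True)
class RegionPeak:
    chrom: str
    start_bp: int
    end_bp: int
    peak_probe: str
    peak_pos: int
    peak_g: float
    peak_q: float
    n_markers: int


def build_amplitude_matrix(
    profiles: Sequence[CopyNumberProfile], probes: pd.DataFrame
) -> AmplitudeMatrix:
    """Stack per-sample amplitudes max(0, CN - ploidy) over a shared probe list."""
    n = len(probes)
    cols = []
    samples = []
    for prof in profiles:
        if prof.per_probe_cn.size != n:
            raise ValueError(
                f"sample {prof.sample!r} has {prof.per_probe_cn.size} probes, expected {n}"
            )
        cols.append(np.maximum(0, prof.per_probe_cn - prof.ploidy))
        samples.append(prof.sample)
    values = np.column_stack(cols).astype(float)
    return AmplitudeMatrix(values=values, probes=probes.reset_index(drop=True), samples=samples)


def gscore(a: AmplitudeMatrix | np.ndarray) -> np.ndarray:
    """Per-marker mean amplitude over samples."""
    values = a.values if isinstance(a, AmplitudeMatrix) else np.asarray(a, dtype=float)
    if values.ndim != 2 or values.shape[1] < 1:
        raise ValueError("amplitude matrix must be 2-D with >= 1 sample")
    return values.mean(axis=1)


def _chrom_blocks(probes: pd.DataFrame) -> list[np.ndarray]:
    return [
        np.flatnonzero((probes["chrom"] == chrom).to_numpy())
        for chrom in probes["chrom"].unique()
    ]


def permutation_null(
    a: AmplitudeMatrix, n_perm: int, seed: int, return_null: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Empirical per-marker p-values from a cyclic-shift null.

    Each permutation rotates every sample's amplitude vector independently
    within each chromosome by a uniform offset, preserving each sample's
    amplitude magnitudes and within-chromosome spatial structure while
    destroying cross-sample alignment.  Permuted G values are pooled over
    all markers, giving p resolution finer than 1/n_perm:
    ``p(m) = (1 + #{null G >= G_obs(m)}) / (1 + n_perm * M)``.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    rng = np.random.default_rng(seed)
    g_obs = gscore(a)
    m, n = a.values.shape
    blocks = _chrom_blocks(a.probes)
    null = np.empty((n_perm, m))
    for it in range(n_perm):
        perm_sum = np.empty(m)
        for idx in blocks:
            block = a.values[idx, :]
            size = idx.size
            offsets = rng.integers(0, size, n)
            rows = (np.arange(size)[:, None] + offsets[None, :]) % size
            perm_sum[idx] = block[rows, np.arange(n)].sum(axis=1)
        null[it] = perm_sum / n
    null_sorted = np.sort(null.ravel())
    n_null = null_sorted.size
    # count of null values >= each observed G
    n_ge = n_null - np.searchsorted(null_sorted, g_obs, side="left")
    p = (1.0 + n_ge) / (1.0 + n_null)
    if return_null:
        return p, null
    return p


def fdr_q(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def significant_regions(
    profile: GScoreProfile, cutoff: float = Q_CUTOFF
) -> list[RegionPeak]:
    """Maximal runs of consecutive markers with q < cutoff, one peak each.

    Runs never span a chromosome boundary.  The peak is the marker of
    maximal G within the run (ties: leftmost).
    """
    probes = profile.probes
    regions: list[RegionPeak] = []
    for idx in _chrom_blocks(probes):
        sig = profile.q[idx] < cutoff
        if not sig.any():
            continue
        # run boundaries within this chromosome
        edges = np.flatnonzero(np.diff(np.concatenate(([0], sig.view(np.int8), [0]))))
        for lo, hi in zip(edges[::2], edges[1::2]):
            run = idx[lo:hi]
            g_run = profile.g[run]
            peak = run[int(np.argmax(g_run))]
            regions.append(
                RegionPeak(
                    chrom=str(probes["chrom"].iloc[run[0]]),
                    start_bp=int(probes["pos"].iloc[run[0]]),
                    end_bp=int(probes["pos"].iloc[run[-1]]) + 1,
                    peak_probe=str(probes["probe_id"].iloc[peak]),
                    peak_pos=int(probes["pos"].iloc[peak]),
                    peak_g=float(profile.g[peak]),
                    peak_q=float(profile.q[peak]),
                    n_markers=int(hi - lo),
                )
            )
    return regions
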