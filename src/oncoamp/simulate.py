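"""Seeded synthetic cohorts of SNP-array and expression data with known truth.

Each sample carries an integer ploidy drawn from a configurable
distribution, plus focal amplicons of fixed integer copy number planted in
a configurable fraction of samples.  Per-probe LRR is ``log2(CN/2)`` plus
Gaussian noise; BAF is centred on ``b/CN`` for the sampled allele split.
Expression responds to dosage through a per-gene-per-sample coupling flag,
so the fraction of amplified samples that overexpress a gene is a known
quantity the downstream ranking can be checked against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from oncoamp.integrate import GeneModel, gene_copy_number

__all__ = [
    "AmpliconSpec",
    "SimConfig",
    "SimTruth",
    "CohortDataset",
    "simulate_cohort",
    "simulate_expression",
]

# LRR emitted for zero-copy probes, where log2(CN/2) is undefined.
LRR_FLOOR = -5.0


@dataclass(frozen=True)
class AmpliconSpec:
    """A focal amplified segment planted in a fraction of samples."""

    chrom: str
    center: int
    width: int
    copy_number: int
    penetrance: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"amplicon width must be > 0, got {self.width}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError(f"penetrance must be in [0, 1], got {self.penetrance}")
        if self.copy_number < 3:
            raise ValueError(f"amplicon copy_number must be >= 3, got {self.copy_number}")

    @property
    def start(self) -> int:
        return self.center - self.width // 2

    @property
    def end(self) -> int:
        return self.start + self.width


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of a synthetic cohort."""

    n_tumours: int
    chrom_layout: tuple[tuple[str, int, int], ...]  # (chrom, n_probes, length bp)
    ploidy_dist: tuple[tuple[int, float], ...] = ((2, 1.0),)
    amplicons: tuple[AmpliconSpec, ...] = ()
    lrr_sd: float = 0.15
    baf_sd: float = 0.03
    pop_allele_freq: float = 0.5
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 1.0
    dosage_slope: float = 1.0
    dosage_coupling: float = 1.0
    expr_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom_layout", tuple(tuple(c) for c in self.chrom_layout))
        object.__setattr__(self, "ploidy_dist", tuple(tuple(p) for p in self.ploidy_dist))
        object.__setattr__(self, "amplicons", tuple(self.amplicons))
        if self.n_tumours < 1:
            raise ValueError("n_tumours must be >= 1")
        total = sum(p for _, p in self.ploidy_dist)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ploidy probabilities must sum to 1, got {total}")
        for sd_name in ("lrr_sd", "baf_sd", "expr_baseline_sd", "expr_sd"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be >= 0")
        if not 0.0 < self.pop_allele_freq < 1.0:
            raise ValueError("pop_allele_freq must be in (0, 1)")
        if not 0.0 <= self.dosage_coupling <= 1.0:
            raise ValueError("dosage_coupling must be in [0, 1]")
        for chrom, n_probes, length in self.chrom_layout:
            if n_probes < 2:
                raise ValueError(f"chromosome {chrom} needs >= 2 probes, got {n_probes}")
            if length < n_probes:
                raise ValueError(f"chromosome {chrom} length {length} < n_probes {n_probes}")
        bounds = {chrom: length for chrom, _, length in self.chrom_layout}
        for amp in self.amplicons:
            if amp.chrom not in bounds:
                raise ValueError(f"amplicon on unknown chromosome {amp.chrom!r}: {amp}")
            if amp.start < 0 or amp.end > bounds[amp.chrom]:
                raise ValueError(
                    f"amplicon outside chromosome bounds "
                    f"(chrom {amp.chrom} length {bounds[amp.chrom]}): {amp}"
                )


@dataclass
class SimTruth:
    """Ground truth emitted alongside the observable matrices."""

    ploidy: "pd.Series[int]"  # per sample
    cn: pd.DataFrame  # probes x samples, integer copy number
    minor: pd.DataFrame  # probes x samples, minor-allele count
    carriers: pd.DataFrame  # amplicon x samples, bool
    # filled by simulate_expression
    coupled: pd.DataFrame | None = None  # genes x samples, bool
    baseline: "pd.Series[float] | None" = None  # per gene, log2 scale
    gene_cn: pd.DataFrame | None = None  # genes x samples

    def to_dict(self) -> dict:
        out = {
            "ploidy": self.ploidy.to_dict(),
            "cn": {s: self.cn[s].tolist() for s in self.cn.columns},
            "minor": {s: self.minor[s].tolist() for s in self.minor.columns},
            "carriers": {s: self.carriers[s].astype(bool).tolist() for s in self.carriers.columns},
        }
        if self.coupled is not None:
            out["coupled"] = {s: self.coupled[s].astype(bool).tolist() for s in self.coupled.columns}
        if self.baseline is not None:
            out["baseline"] = self.baseline.to_dict()
        if self.gene_cn is not None:
            out["gene_cn"] = {s: self.gene_cn[s].tolist() for s in self.gene_cn.columns}
        return out


@dataclass
class CohortDataset:
    """Observable synthetic data: probe annotation plus LRR/BAF matrices."""

    probes: pd.DataFrame  # columns probe_id, chrom, pos
    lrr: pd.DataFrame  # probes x samples
    baf: pd.DataFrame  # probes x samples

    @property
    def samples(self) -> list[str]:
        return list(self.lrr.columns)


def _sample_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    # fixed-arithmetic child seeds: cohorts reproduce under sample subsetting
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream, index)))


def _probe_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for chrom, n_probes, length in config.chrom_layout:
        step = length / n_probes
        for i in range(n_probes):
            rows.append((f"{chrom}_p{i:05d}", chrom, int(i * step)))
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])


def simulate_cohort(config: SimConfig) -> tuple[CohortDataset, SimTruth]:
    """Draw a full cohort of LRR/BAF matrices plus its ground truth.

    Per sample, in order: ploidy, amplicon carrier flags, germline
    genotypes (B-allele count from two Binomial(1, pop_allele_freq)
    haplotypes), the amplified haplotype per probe, then LRR and BAF noise.
    Deterministic for a fixed config (including seed).
    """
    probes = _probe_table(config)
    n_probes = len(probes)
    chrom_arr = probes["chrom"].to_numpy()
    pos_arr = probes["pos"].to_numpy()
    samples = [f"S{i + 1:03d}" for i in range(config.n_tumours)]

    ploidies = np.array([p for p, _ in config.ploidy_dist], dtype=int)
    probs = np.array([w for _, w in config.ploidy_dist], dtype=float)

    lrr = np.empty((n_probes, config.n_tumours))
    baf = np.empty((n_probes, config.n_tumours))
    cn = np.empty((n_probes, config.n_tumours), dtype=int)
    minor = np.empty((n_probes, config.n_tumours), dtype=int)
    ploidy_out = np.empty(config.n_tumours, dtype=int)
    carriers = np.zeros((len(config.amplicons), config.n_tumours), dtype=bool)

    for s in range(config.n_tumours):
        rng = _sample_rng(config.seed, 0, s)
        ploidy = int(rng.choice(ploidies, p=probs))
        ploidy_out[s] = ploidy
        c = np.full(n_probes, ploidy, dtype=int)
        for a, amp in enumerate(config.amplicons):
            carrier = bool(rng.random() < amp.penetrance)
            carriers[a, s] = carrier
            if carrier:
                mask = (chrom_arr == amp.chrom) & (pos_arr >= amp.start) & (pos_arr < amp.end)
                c[mask] = amp.copy_number
        # germline: two independent haplotypes carrying the B allele or not
        hap_b = rng.random((n_probes, 2)) < config.pop_allele_freq
        g = hap_b.sum(axis=1)  # germline B count in {0, 1, 2}
        amp_hap = rng.integers(0, 2, size=n_probes)  # which haplotype the extra copies come from
        extra = np.maximum(c - 2, 0)
        bcount = np.where(
            c >= 2,
            g + extra * hap_b[np.arange(n_probes), amp_hap],
            # c in {0, 1}: keep the chosen haplotype's allele
            c * hap_b[np.arange(n_probes), amp_hap],
        )
        bcount = np.minimum(bcount, c)
        cn[:, s] = c
        minor[:, s] = np.minimum(bcount, c - bcount)

        lrr_mean = np.where(c > 0, np.log2(np.maximum(c, 1) / 2.0), LRR_FLOOR)
        lrr[:, s] = lrr_mean + rng.normal(0.0, config.lrr_sd, n_probes)
        with np.errstate(invalid="ignore", divide="ignore"):
            baf_mean = np.where(c > 0, bcount / np.maximum(c, 1), 0.5)
        noisy = baf_mean + rng.normal(0.0, config.baf_sd, n_probes)
        noisy = np.where(c > 0, noisy, rng.uniform(0.0, 1.0, n_probes))
        baf[:, s] = np.clip(noisy, 0.0, 1.0)

    index = pd.Index(probes["probe_id"], name="probe_id")
    dataset = CohortDataset(
        probes=probes,
        lrr=pd.DataFrame(lrr, index=index, columns=samples),
        baf=pd.DataFrame(baf, index=index, columns=samples),
    )
    truth = SimTruth(
        ploidy=pd.Series(ploidy_out, index=samples, name="ploidy"),
        cn=pd.DataFrame(cn, index=index, columns=samples),
        minor=pd.DataFrame(minor, index=index, columns=samples),
        carriers=pd.DataFrame(
            carriers, index=[f"amplicon_{i}" for i in range(len(config.amplicons))], columns=samples
        ),
    )
    return dataset, truth


def simulate_expression(
    config: SimConfig,
    truth: SimTruth,
    genes: Sequence[GeneModel],
    probes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Expression matrices for the tumours plus a single osteoblast reference.

    ``log2 expr(g, s) = baseline(g) + dosage_slope * log2(CN(g, s)/2) *
    coupled(g, s) + Normal(0, expr_sd)``; the reference column is
    ``baseline(g)`` plus noise.  Both outputs are returned on linear scale.
    Gene copy number is read from truth via the same within-or-nearest probe
    rule the integration stage uses.  Fills ``truth.coupled``,
    ``truth.baseline`` and ``truth.gene_cn`` as a side effect.
    """
    if probes is None:
        probes = _probe_table(config)
    chrom_bounds = {chrom: length for chrom, _, length in config.chrom_layout}
    for gene in genes:
        if gene.chrom not in chrom_bounds or gene.end > chrom_bounds[gene.chrom]:
            raise ValueError(f"gene outside chromosome layout: {gene}")

    samples = list(truth.cn.columns)
    gene_names = [g.name for g in genes]

    rng_genes = _sample_rng(config.seed, 1, 0)
    baseline = rng_genes.normal(config.expr_baseline_mean, config.expr_baseline_sd, len(genes))
    ref_noise = rng_genes.normal(0.0, config.expr_sd, len(genes))

    gene_cn = np.empty((len(genes), len(samples)), dtype=float)
    for j, s in enumerate(samples):
        cn_s = truth.cn[s].to_numpy()
        for i, gene in enumerate(genes):
            gene_cn[i, j] = gene_copy_number(gene, cn_s, probes)

    log_expr = np.empty((len(genes), len(samples)))
    coupled = np.empty((len(genes), len(samples)), dtype=bool)
    for j in range(len(samples)):
        rng = _sample_rng(config.seed, 2, j)
        coupled[:, j] = rng.random(len(genes)) < config.dosage_coupling
        dosage = config.dosage_slope * np.log2(np.maximum(gene_cn[:, j], 0.5) / 2.0)
        log_expr[:, j] = (
            baseline
            + dosage * coupled[:, j]
            + rng.normal(0.0, config.expr_sd, len(genes))
        )

    index = pd.Index(gene_names, name="gene")
    truth.coupled = pd.DataFrame(coupled, index=index, columns=samples)
    truth.baseline = pd.Series(baseline, index=index, name="baseline")
    truth.gene_cn = pd.DataFrame(gene_cn, index=index, columns=samples)

    expr = pd.DataFrame(np.exp2(log_expr), index=index, columns=samples)
    reference = pd.Series(np.exp2(baseline + ref_noise), index=index, name="osteoblast")
    return expr, reference
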