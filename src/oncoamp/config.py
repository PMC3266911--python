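"""Pipeline configuration: thresholds, paths and the default demo cohort."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from oncoamp.integrate import GeneModel
from oncoamp.simulate import AmpliconSpec, SimConfig

__all__ = ["PipelineConfig", "default_sim_config", "default_genes"]


@dataclass
class PipelineConfig:
    """Flat key-value configuration for the end-to-end pipeline."""

    # inputs
    probes: str = "probes.tsv"
    lrr: str = "lrr.tsv"
    baf: str = "baf.tsv"
    genes: str = "genes.bed"
    expression: str = "expression.tsv"
    reference: str = "reference.tsv"
    ct_table: str | None = None  # enables the qPCR screen stage
    out_dir: str = "results"
    # thresholds (published decision rules)
    amplification_cn: float = 3.5
    overexpression_fc: float = 2.0
    q_cutoff: float = 0.25
    min_pct: float = 50.0
    alpha: float = 0.05
    min_r: float = 0.0
    # algorithm knobs
    n_perm: int = 1000
    seed: int = 0
    c_max: int = 12
    penalty: float | None = None  # None -> per-chromosome BIC-like default

    def __post_init__(self) -> None:
        for name in ("amplification_cn", "overexpression_fc", "min_pct"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("q_cutoff", "alpha"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.c_max < 2:
            raise ValueError("c_max must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
        return path


def default_sim_config(seed: int = 0, n_tumours: int = 20,
                       probes_per_chrom: int = 2000) -> SimConfig:
    """A small two-chromosome demo cohort with two focal amplicons.

    Chromosome "17" spans 20 Mb with two planted amplicons; chromosome "2"
    is amplicon-free and serves as a negative control.
    """
    return SimConfig(
        n_tumours=n_tumours,
        chrom_layout=(("17", probes_per_chrom, 20_000_000),
                      ("2", probes_per_chrom, 20_000_000)),
        ploidy_dist=((2, 0.7), (3, 0.3)),
        amplicons=(
            AmpliconSpec(chrom="17", center=13_500_000, width=1_500_000,
                         copy_number=6, penetrance=0.6),
            AmpliconSpec(chrom="17", center=17_200_000, width=1_000_000,
                         copy_number=8, penetrance=0.5),
        ),
        lrr_sd=0.15,
        baf_sd=0.03,
        dosage_slope=1.0,
        dosage_coupling=0.7,
        expr_sd=0.2,
        seed=seed,
    )


def default_genes() -> list[GeneModel]:
    """Gene models inside and outside the demo amplicons."""
    inside_1 = [13_000_000, 13_400_000, 13_900_000]
    inside_2 = [16_900_000, 17_150_000, 17_500_000]
    outside = [2_000_000, 6_000_000, 10_000_000, 19_000_000]
    genes = []
    for i, start in enumerate(inside_1 + inside_2 + outside):
        genes.append(GeneModel(name=f"G17_{i + 1:02d}", chrom="17",
                               start=start, end=start + 50_000))
    for i, start in enumerate([3_000_000, 9_000_000, 15_000_000]):
        genes.append(GeneModel(name=f"G2_{i + 1:02d}", chrom="2",
                               start=start, end=start + 50_000))
    return genes
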