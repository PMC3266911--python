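"""Candidate-oncogene scoring from copy number and expression.

Per gene and tumour: copy number from the SNP probes within (or nearest
to) the gene body, amplification at CN > 3.5, overexpression at a fold
change of 2 or more versus the osteoblast reference.  Genes are then
ranked by the fraction of amplified tumours that also overexpress them
(the O/A percentage), kept at >= 50%, and finally filtered on a positive,
significant Pearson correlation between copy number and expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneModel",
    "GeneSampleStatus",
    "OverAmpSummary",
    "CorrelationResult",
    "gene_copy_number",
    "status_matrix",
    "summarize_oa",
    "expand_counts",
    "rank_candidates",
    "pearson_filter",
    "apply_table2_filter",
    "AMPLIFICATION_CN",
    "OVEREXPRESSION_FC",
]

#: copy number strictly above this is called amplified
AMPLIFICATION_CN = 3.5
#: fold change at or above this is called overexpressed
OVEREXPRESSION_FC = 2.0


@dataclass(frozen=True)
class GeneModel:
    """A gene body as a 0-based half-open interval."""

    name: str
    chrom: str
    start: int
    end: int
    band: str | None = None
    mb: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.name}: end must exceed start ({self.start}, {self.end})")


@dataclass(frozen=True)
class GeneSampleStatus:
    gene: str
    sample: str
    copy_number: float
    amplified: bool
    fold_change: float
    overexpressed: bool


@dataclass(frozen=True)
class OverAmpSummary:
    """Per-gene counts of amplified (A), overexpressed (O) and both (OA)."""

    gene: str
    a: int
    o: int
    oa: int

    def __post_init__(self) -> None:
        if self.oa > min(self.a, self.o):
            raise ValueError(f"{self.gene}: OA={self.oa} exceeds min(A={self.a}, O={self.o})")

    @property
    def pct(self) -> float | None:
        """100 * OA / A at full precision; None when A = 0."""
        if self.a == 0:
            return None
        return 100.0 * self.oa / self.a

    @property
    def pct_display(self) -> float | None:
        """pct rounded to one decimal for reporting."""
        return None if self.pct is None else round(self.pct, 1)


@dataclass(frozen=True)
class CorrelationResult:
    gene: str
    r: float
    p: float
    n: int
    passes: bool
    constant_input: bool = False


def gene_copy_number(
    gene: GeneModel,
    cn: np.ndarray | pd.Series,
    probes: pd.DataFrame,
) -> float:
    """Copy number of a gene from the probes within or nearest to it.

    Probes overlapping ``[start, end)`` contribute their lower median CN
    (the lower of the two central values for an even count, so integer
    inputs stay integral).  With no overlap the probe minimising the
    distance to the nearer gene boundary is used; ties resolve to the
    lower coordinate.
    """
    if len(probes) == 0:
        raise ValueError("empty probe list")
    cn = np.asarray(cn, dtype=float)
    on_chrom = probes["chrom"].to_numpy() == gene.chrom
    if not on_chrom.any():
        raise ValueError(f"no probes on chromosome {gene.chrom!r} for gene {gene.name}")
    pos = probes["pos"].to_numpy()
    inside = on_chrom & (pos >= gene.start) & (pos < gene.end)
    if inside.any():
        vals = np.sort(cn[inside])
        return float(vals[(len(vals) - 1) // 2])
    # distance to the nearer boundary of the half-open interval
    dist = np.where(pos < gene.start, gene.start - pos, pos - (gene.end - 1))
    dist = np.where(on_chrom, dist, np.iinfo(np.int64).max)
    order = np.lexsort((pos, dist))
    return float(cn[order[0]])


def _collapse_probes(expr: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    # multiple expression probes per gene: arithmetic mean of linear signals
    if expr.index.has_duplicates:
        return expr.groupby(level=0, sort=False).mean()
    return expr


def status_matrix(
    genes: Sequence[GeneModel],
    cn: pd.DataFrame | Mapping[str, np.ndarray],
    probes: pd.DataFrame,
    expr: pd.DataFrame,
    reference: pd.Series,
    amp_threshold: float = AMPLIFICATION_CN,
    fc_threshold: float = OVEREXPRESSION_FC,
) -> pd.DataFrame:
    """Per gene x sample copy-number and expression status.

    ``cn`` is a per-probe CN matrix (probes x samples) aligned with
    ``probes``; ``expr`` holds linear tumour signals (genes or expression
    probes x samples) and ``reference`` the osteoblast signal per gene.
    Only samples present in both the CN and expression data are scored.

    Returns a tidy frame with columns gene, sample, copy_number,
    amplified, fold_change, overexpressed.
    """
    if not isinstance(cn, pd.DataFrame):
        cn = pd.DataFrame(dict(cn), index=probes["probe_id"].to_numpy())
    if len(cn) != len(probes):
        raise ValueError(f"CN matrix has {len(cn)} rows but probe table has {len(probes)}")
    expr = _collapse_probes(expr)
    reference = _collapse_probes(reference)
    samples = [s for s in cn.columns if s in expr.columns]
    if not samples:
        raise ValueError("no shared samples between CN and expression matrices")

    rows = []
    for gene in genes:
        if gene.name not in expr.index:
            raise ValueError(f"gene {gene.name} missing from expression matrix")
        ref = float(reference[gene.name])
        if not ref > 0:
            raise ValueError(f"non-positive reference signal for gene {gene.name}: {ref}")
        for s in samples:
            g_cn = gene_copy_number(gene, cn[s].to_numpy(), probes)
            fc = float(expr.at[gene.name, s]) / ref
            rows.append(
                (gene.name, s, g_cn, g_cn > amp_threshold, fc, fc >= fc_threshold)
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "sample", "copy_number", "amplified", "fold_change", "overexpressed"],
    )


def summarize_oa(gene: str, statuses: Iterable[GeneSampleStatus] | pd.DataFrame) -> OverAmpSummary:
    """Count amplified (A), overexpressed (O) and both (OA) tumours for one gene."""
    if isinstance(statuses, pd.DataFrame):
        sub = statuses[statuses["gene"] == gene] if "gene" in statuses.columns else statuses
        if len(sub) == 0:
            raise ValueError(f"no statuses for gene {gene}")
        amplified = sub["amplified"].to_numpy(dtype=bool)
        over = sub["overexpressed"].to_numpy(dtype=bool)
    else:
        statuses = [st for st in statuses if st.gene == gene]
        if not statuses:
            raise ValueError(f"no statuses for gene {gene}")
        amplified = np.array([st.amplified for st in statuses])
        over = np.array([st.overexpressed for st in statuses])
    return OverAmpSummary(
        gene=gene,
        a=int(amplified.sum()),
        o=int(over.sum()),
        oa=int((amplified & over).sum()),
    )


def expand_counts(gene: str, a: int, o: int, oa: int, n_samples: int) -> list[GeneSampleStatus]:
    """Materialise a status list realising given (A, O, OA) counts.

    Lets count-level records (published summary tables) flow through the
    same ``summarize_oa`` path as full status matrices.
    """
    if oa > min(a, o) or a + o - oa > n_samples:
        raise ValueError(f"counts A={a}, O={o}, OA={oa} infeasible for n={n_samples}")
    statuses = []
    for i in range(n_samples):
        amplified = i < a
        over = i < oa or a <= i < a + (o - oa)
        statuses.append(
            GeneSampleStatus(
                gene=gene,
                sample=f"T{i + 1:02d}",
                copy_number=6.0 if amplified else 2.0,
                amplified=amplified,
                fold_change=3.0 if over else 1.0,
                overexpressed=over,
            )
        )
    return statuses


def rank_candidates(
    summaries: Iterable[OverAmpSummary], min_pct: float = 50.0
) -> list[OverAmpSummary]:
    """Keep genes overexpressed-through-amplification in >= min_pct of
    amplified tumours, ordered by pct descending (ties: larger OA, then
    gene name).  Genes with A = 0 have no defined pct and are dropped.
    """
    eligible = [s for s in summaries if s.pct is not None and s.pct >= min_pct]
    return sorted(eligible, key=lambda s: (-s.pct, -s.oa, s.gene))


def pearson_filter(
    cn: Sequence[float],
    expr: Sequence[float],
    gene: str = "",
    alpha: float = 0.05,
    min_r: float = 0.0,
) -> CorrelationResult:
    """Pearson correlation of per-sample copy number against expression.

    Two-sided P from the t transform with n - 2 degrees of freedom.  A
    gene passes when R > min_r and P <= alpha.  Constant input yields an
    undefined R, reported as non-passing rather than raised.
    """
    cn = np.asarray(cn, dtype=float)
    expr = np.asarray(expr, dtype=float)
    if cn.shape != expr.shape:
        raise ValueError("copy-number and expression vectors differ in length")
    n = cn.size
    if n < 3:
        raise ValueError(f"need >= 3 paired observations, got {n}")
    if np.ptp(cn) == 0 or np.ptp(expr) == 0:
        return CorrelationResult(gene=gene, r=float("nan"), p=float("nan"), n=n,
                                 passes=False, constant_input=True)
    r, p = stats.pearsonr(cn, expr)
    r = float(r)
    if abs(r) == 1.0:
        p = 0.0
    passes = bool(r > min_r and p <= alpha)
    return CorrelationResult(gene=gene, r=r, p=float(p), n=n, passes=passes)


def apply_table2_filter(
    results: Sequence[CorrelationResult],
) -> tuple[list[CorrelationResult], list[CorrelationResult]]:
    """Partition correlation results into (passing, discarded), preserving order."""
    passing = [r for r in results if r.passes]
    discarded = [r for r in results if not r.passes]
    return passing, discarded


def correlation_from_published(gene: str, r: float, p: float, n: int = 20,
                               alpha: float = 0.05, min_r: float = 0.0) -> CorrelationResult:
    """Wrap an already-computed (R, P) pair in the pass/fail rule."""
    if not (math.isfinite(r) and math.isfinite(p)):
        raise ValueError(f"non-finite R or P for {gene}")
    return CorrelationResult(gene=gene, r=r, p=p, n=n, passes=bool(r > min_r and p <= alpha))
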