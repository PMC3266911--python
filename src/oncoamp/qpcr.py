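"""Relative-quantification gene dosage and expression from Ct values.

Dosage assays normalise a target gene against a reference gene and a
calibrator sample; a normalised ratio of 1 corresponds to two copies, and
copy number strictly above 3.5 is called amplified.  Expression assays use
the same ratio against an osteoblast calibrator, with overexpression at a
fold change of 2 or more.  The cohort screen keeps every sample amplified
for at least one marker-panel gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CtMeasurement",
    "DosageCall",
    "MARKER_PANEL",
    "normalized_ratio",
    "call_dosage",
    "screen_cohort",
    "expression_fold_change_qpcr",
    "calls_from_ct_table",
]

#: dosage marker genes across the screened region with Mb positions
MARKER_PANEL: tuple[tuple[str, float], ...] = (
    ("SCO1", 10.6),
    ("MAP2K4", 11.9),
    ("MYOCD", 12.6),
    ("COX10", 14.0),
    ("PMP22", 15.1),
    ("NCOR1", 16.1),
    ("COPS3", 17.2),
    ("TOM1L2", 17.8),
)

_EFF_RANGE = (1.0, 2.2)


@dataclass(frozen=True)
class CtMeasurement:
    """Ct quadruple for one sample/gene assay plus its calibrator.

    ``efficiency_target``/``efficiency_reference`` are per-cycle
    amplification factors (2.0 = ideal doubling).
    """

    sample: str
    gene: str
    ct_target: float
    ct_reference: float
    calibrator_ct_target: float
    calibrator_ct_reference: float
    efficiency_target: float = 2.0
    efficiency_reference: float = 2.0

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference", "calibrator_ct_target", "calibrator_ct_reference"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{self.sample}/{self.gene}: non-finite {name}")
        for name in ("efficiency_target", "efficiency_reference"):
            eff = getattr(self, name)
            if not _EFF_RANGE[0] <= eff <= _EFF_RANGE[1]:
                raise ValueError(
                    f"{self.sample}/{self.gene}: {name}={eff} outside {_EFF_RANGE}"
                )


@dataclass(frozen=True)
class DosageCall:
    normalized_ratio: float
    copy_number: float
    amplified: bool


def normalized_ratio(m: CtMeasurement) -> float:
    """Efficiency-corrected relative quantity versus the calibrator.

    ``E_t^-(Ct_t - Ct_t,cal) / E_r^-(Ct_r - Ct_r,cal)``; with both
    efficiencies at 2 this reduces to ``2^-ddCt``.
    """
    d_target = m.ct_target - m.calibrator_ct_target
    d_reference = m.ct_reference - m.calibrator_ct_reference
    return float(
        m.efficiency_target ** (-d_target) / m.efficiency_reference ** (-d_reference)
    )


def call_dosage(ratio: float, threshold: float = 3.5) -> DosageCall:
    """Copy number = 2 x ratio; amplified iff strictly above the threshold."""
    if ratio < 0:
        raise ValueError(f"normalized ratio must be >= 0, got {ratio}")
    cn = 2.0 * ratio
    return DosageCall(normalized_ratio=float(ratio), copy_number=cn, amplified=cn > threshold)


def screen_cohort(
    calls: Mapping[str, Mapping[str, DosageCall]],
    panel: Iterable[str] | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Select samples amplified for one or more marker-panel genes.

    ``calls`` maps sample -> marker gene -> DosageCall and must cover the
    whole panel for every sample.  Returns the selected sample set plus a
    per-sample summary (amplified marker count, selected flag).
    """
    markers = [g for g, _ in MARKER_PANEL] if panel is None else list(panel)
    rows = []
    selected: set[str] = set()
    for sample in sorted(calls):
        sample_calls = calls[sample]
        for marker in markers:
            if marker not in sample_calls:
                raise ValueError(f"sample {sample!r} is missing a call for marker {marker!r}")
        n_amp = sum(sample_calls[m].amplified for m in markers)
        if n_amp >= 1:
            selected.add(sample)
        rows.append((sample, n_amp, n_amp >= 1))
    summary = pd.DataFrame(rows, columns=["sample", "n_amplified_markers", "selected"])
    return selected, summary


def expression_fold_change_qpcr(m: CtMeasurement, threshold: float = 2.0) -> tuple[float, bool]:
    """Fold change versus the osteoblast calibrator; overexpressed at >= threshold."""
    fc = normalized_ratio(m)
    return fc, fc >= threshold


def calls_from_ct_table(table: pd.DataFrame, threshold: float = 3.5) -> pd.DataFrame:
    """Dosage calls from a long-format Ct table.

    Expected columns: sample, gene, role (target|reference),
    context (test|calibrator), ct, efficiency.  Replicate wells (triplicate
    reactions) are averaged on the Ct scale before the ratio.
    """
    required = {"sample", "gene", "role", "context", "ct", "efficiency"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")

    rows = []
    for (sample, gene), grp in table[table["context"] == "test"].groupby(
        ["sample", "gene"], sort=True
    ):
        cal = table[(table["context"] == "calibrator") & (table["gene"] == gene)]
        if cal.empty:
            raise ValueError(f"no calibrator rows for gene {gene!r}")

        def _mean_ct(frame: pd.DataFrame, role: str, where: str) -> float:
            sel = frame[frame["role"] == role]
            if sel.empty:
                raise ValueError(f"{where}: no {role} Ct rows for {sample}/{gene}")
            return float(sel["ct"].mean())

        def _eff(frame: pd.DataFrame, role: str) -> float:
            sel = frame[frame["role"] == role]
            return float(sel["efficiency"].iloc[0]) if len(sel) else 2.0

        m = CtMeasurement(
            sample=str(sample),
            gene=str(gene),
            ct_target=_mean_ct(grp, "target", "test"),
            ct_reference=_mean_ct(grp, "reference", "test"),
            calibrator_ct_target=_mean_ct(cal, "target", "calibrator"),
            calibrator_ct_reference=_mean_ct(cal, "reference", "calibrator"),
            efficiency_target=_eff(grp, "target"),
            efficiency_reference=_eff(grp, "reference"),
        )
        call = call_dosage(normalized_ratio(m), threshold=threshold)
        rows.append(
            (m.sample, m.gene, call.normalized_ratio, call.copy_number, call.amplified)
        )
    return pd.DataFrame(
        rows, columns=["sample", "gene", "normalized_ratio", "copy_number", "amplified"]
    )
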