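"""End-to-end orchestration: screen -> CN calling -> regions -> integration.

Each stage reads/writes the on-disk TSV formats, so stages can also be run
individually from the CLI.  A manifest JSON listing every artifact with
its checksum is written at the end; stage failures propagate with the
stage name attached.
"""

from __future__ import annotations

import logging
import math
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from oncoamp import io
from oncoamp.cncall import call_profile
from oncoamp.config import PipelineConfig
from oncoamp.integrate import (
    GeneModel,
    apply_table2_filter,
    pearson_filter,
    rank_candidates,
    status_matrix,
    summarize_oa,
)
from oncoamp.qpcr import calls_from_ct_table, screen_cohort, call_dosage
from oncoamp.regions import (
    build_amplitude_matrix,
    fdr_q,
    gscore,
    permutation_null,
    significant_regions,
    GScoreProfile,
)
from oncoamp.simulate import CohortDataset, SimConfig, SimTruth, simulate_cohort, simulate_expression

__all__ = ["StageError", "run_pipeline", "write_simulated_inputs"]

logger = logging.getLogger("oncoamp")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: started", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", stage, dt)
                return False
            if isinstance(exc, StageError):
                return False
            raise StageError(stage, exc)

    return _Timer()


def write_simulated_inputs(
    sim: SimConfig, genes: Sequence[GeneModel], out_dir: str | Path
) -> dict[str, Path]:
    """Simulate a cohort and write every pipeline input format to out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, truth = simulate_cohort(sim)
    expr, reference = simulate_expression(sim, truth, genes, probes=dataset.probes)

    paths = {
        "probes": io.write_probes(dataset.probes, out / "probes.tsv"),
        "lrr": io.write_matrix(dataset.lrr, out / "lrr.tsv"),
        "baf": io.write_matrix(dataset.baf, out / "baf.tsv"),
        "genes": io.write_genes_bed(genes, out / "genes.bed"),
        "expression": io.write_matrix(expr, out / "expression.tsv", index_name="gene"),
        "reference": io.write_matrix(reference.to_frame(), out / "reference.tsv", index_name="gene"),
        "truth": io.write_json(truth.to_dict(), out / "truth.json"),
        "ct_table": _write_ct_table(truth, out / "ct_dosage.tsv"),
    }
    return paths


def _write_ct_table(truth: SimTruth, path: Path) -> Path:
    # ideal-efficiency Ct values consistent with true gene copy number:
    # calibrator (normal blood, CN 2) at Ct 25, reference gene unchanged
    if truth.gene_cn is None:
        raise ValueError("truth has no gene copy numbers; run simulate_expression first")
    rows = []
    for gene in truth.gene_cn.index:
        rows.append((  # one calibrator per gene
            "calibrator", gene, "target", "calibrator", 25.0, 2.0))
        rows.append(("calibrator", gene, "reference", "calibrator", 25.0, 2.0))
        for sample in truth.gene_cn.columns:
            cn = max(float(truth.gene_cn.at[gene, sample]), 0.5)
            rows.append((sample, gene, "target", "test", 25.0 - math.log2(cn / 2.0), 2.0))
            rows.append((sample, gene, "reference", "test", 25.0, 2.0))
    table = pd.DataFrame(
        rows, columns=["sample", "gene", "role", "context", "ct", "efficiency"]
    )
    table.to_csv(path, sep="\t", index=False)
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on the configured inputs; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    manifest: dict = {"stages": [], "outputs": {}}

    selected_samples: set[str] | None = None
    if config.ct_table is not None:
        with _timed("screen"):
            ct = pd.read_csv(config.ct_table, sep="\t")
            calls_df = calls_from_ct_table(ct, threshold=config.amplification_cn)
            calls = {
                s: {
                    row.gene: call_dosage(row.normalized_ratio, threshold=config.amplification_cn)
                    for row in grp.itertuples()
                }
                for s, grp in calls_df.groupby("sample")
            }
            panel = sorted(calls_df["gene"].unique())
            selected_samples, summary = screen_cohort(calls, panel=panel)
            calls_df.to_csv(out / "dosage_calls.tsv", sep="\t", index=False)
            summary.to_csv(out / "screen_summary.tsv", sep="\t", index=False)
            artifacts["dosage_calls"] = out / "dosage_calls.tsv"
            artifacts["screen_summary"] = out / "screen_summary.tsv"
            manifest["stages"].append("screen")
            logger.info("screen: selected %d samples", len(selected_samples))

    with _timed("callcn"):
        probes = io.read_probes(config.probes)
        lrr = io.read_matrix(config.lrr)
        baf = io.read_matrix(config.baf)
        samples = list(lrr.columns)
        if selected_samples is not None:
            samples = [s for s in samples if s in selected_samples]
        profiles = [
            call_profile(
                s,
                probes,
                lrr[s].to_numpy(),
                baf[s].to_numpy(),
                c_max=config.c_max,
                penalty=config.penalty,
            )
            for s in samples
        ]
        cn_matrix = pd.DataFrame(
            {p.sample: p.per_probe_cn for p in profiles},
            index=pd.Index(probes["probe_id"], name="probe_id"),
        )
        ploidy = pd.DataFrame(
            {"sample": [p.sample for p in profiles], "ploidy": [p.ploidy for p in profiles]}
        )
        artifacts["segments"] = io.write_segments(profiles, out / "segments.tsv")
        artifacts["cn_matrix"] = io.write_matrix(cn_matrix, out / "cn_matrix.tsv")
        ploidy.to_csv(out / "ploidy.tsv", sep="\t", index=False)
        artifacts["ploidy"] = out / "ploidy.tsv"
        manifest["stages"].append("callcn")

    with _timed("regions"):
        amp = build_amplitude_matrix(profiles, probes)
        g = gscore(amp)
        p = permutation_null(amp, n_perm=config.n_perm, seed=config.seed)
        q = fdr_q(p)
        gprofile = GScoreProfile(probes=amp.probes, g=g, p=p, q=q)
        peaks = significant_regions(gprofile, cutoff=config.q_cutoff)
        artifacts["gscore"] = io.write_matrix(
            gprofile.to_frame().set_index("probe_id"), out / "gscore.tsv"
        )
        regions_df = pd.DataFrame([vars(r) for r in peaks])
        regions_df.to_csv(out / "regions.tsv", sep="\t", index=False)
        artifacts["regions"] = out / "regions.tsv"
        manifest["stages"].append("regions")
        logger.info("regions: %d significant region(s)", len(peaks))

    with _timed("integrate"):
        genes = io.read_genes_bed(config.genes)
        expr = io.read_matrix(config.expression)
        reference = io.read_matrix(config.reference).iloc[:, 0]
        statuses = status_matrix(
            genes,
            cn_matrix,
            probes,
            expr,
            reference,
            amp_threshold=config.amplification_cn,
            fc_threshold=config.overexpression_fc,
        )
        statuses["status_code"] = np.select(
            [
                statuses["amplified"] & statuses["overexpressed"],
                statuses["amplified"],
                statuses["overexpressed"],
            ],
            ["AO", "A", "O"],
            default="none",
        )
        summaries = [summarize_oa(g.name, statuses) for g in genes]
        ranked = rank_candidates(summaries, min_pct=config.min_pct)
        corr = []
        for s in ranked:
            sub = statuses[statuses["gene"] == s.gene]
            corr.append(
                pearson_filter(
                    sub["copy_number"].to_numpy(),
                    sub["fold_change"].to_numpy(),
                    gene=s.gene,
                    alpha=config.alpha,
                    min_r=config.min_r,
                )
            )
        passing, discarded = apply_table2_filter(corr)

        statuses.to_csv(out / "status_matrix.tsv", sep="\t", index=False)
        summary_df = pd.DataFrame(
            [
                (s.gene, s.a, s.o, s.oa, s.pct_display if s.pct is not None else "")
                for s in sorted(summaries, key=lambda x: (-(x.pct or -1), x.gene))
            ],
            columns=["gene", "A", "O", "OA", "pct"],
        )
        summary_df.to_csv(out / "oa_summary.tsv", sep="\t", index=False)
        corr_df = pd.DataFrame(
            [(c.gene, c.r, c.p, c.n, c.passes) for c in corr],
            columns=["gene", "R", "P", "n", "passes"],
        )
        corr_df.to_csv(out / "correlation.tsv", sep="\t", index=False)
        candidates = {
            "candidates": [c.gene for c in passing],
            "discarded": [c.gene for c in discarded],
            "ranked": [
                {"gene": s.gene, "A": s.a, "O": s.o, "OA": s.oa, "pct": s.pct_display}
                for s in ranked
            ],
        }
        artifacts["status_matrix"] = out / "status_matrix.tsv"
        artifacts["oa_summary"] = out / "oa_summary.tsv"
        artifacts["correlation"] = out / "correlation.tsv"
        artifacts["candidates"] = io.write_json(candidates, out / "candidates.json")
        manifest["stages"].append("integrate")
        logger.info("integrate: %d candidate(s) after correlation filter", len(passing))

    manifest["outputs"] = {
        name: {"path": str(path), "sha256": io.file_checksum(path)}
        for name, path in artifacts.items()
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest
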