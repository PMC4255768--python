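"""End-to-end analysis stages tying the modules together.

``simulate_stage`` generates a cohort (probes, intensities, truth, assay
runs); ``boundary_stage`` estimates per-sample copy number from the PRT
runs, correlates every probe with it and calls the CNV block;
``hmm_stage`` segments the cohort-mean log2 track; ``calling_stage`` fuses
aCGH, PRT and ddPCR into integer copy-number calls. ``run_all`` chains all
four and writes every output with provenance headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assays, boundary, integration, io, synthetic
from .config import config_hash
from .errors import DataError
from .genome import IntensityMatrix, ProbeSet
from .synthetic import CohortConfig, CohortTruth


@dataclass
class SimulatedCohort:
    config: CohortConfig
    seed: int
    probes: ProbeSet
    intensities: IntensityMatrix
    truth: CohortTruth
    prt_runs: dict[str, assays.PRTRun] = field(default_factory=dict)
    ddpcr_runs: dict[str, list[assays.DdpcrRun]] = field(default_factory=dict)

    @property
    def meta(self) -> dict:
        return {"seed": self.seed, "config": config_hash(self.config)}


def simulate_stage(
    config: CohortConfig, seed: int, n_ddpcr_replicates: int = 4
) -> SimulatedCohort:
    """Generate a cohort and its assay measurements from one top-level seed."""
    streams = synthetic.substreams(seed)
    probes = synthetic.make_probe_set(
        config.region, config.mean_spacing, seed=streams["cohort"]
    )
    intensities, truth = synthetic.simulate_cohort(
        probes, config, rng=streams["cohort"]
    )
    prt_runs: dict[str, assays.PRTRun] = {}
    ddpcr_runs: dict[str, list[assays.DdpcrRun]] = {}
    nm = config.noise
    for sample in truth.sample_ids:
        cn = int(truth.cn[sample])
        if "prt" in config.assay_names:
            prt_runs[sample] = synthetic.simulate_prt(
                cn,
                n_replicates=5,
                noise_cv=nm.prt_cv,
                rng=streams["prt"],
                reference_cn=config.reference_cn,
                sample_id=sample,
            )
        if "ddpcr" in config.assay_names:
            ddpcr_runs[sample] = [
                synthetic.simulate_ddpcr(
                    cn,
                    n_droplets=nm.ddpcr_droplets,
                    molecules_per_droplet_ref=nm.ddpcr_lambda_ref,
                    rng=streams["ddpcr"],
                    reference_cn=config.reference_cn,
                    sample_id=sample,
                )
                for _ in range(n_ddpcr_replicates)
            ]
    return SimulatedCohort(
        config=config,
        seed=seed,
        probes=probes,
        intensities=intensities,
        truth=truth,
        prt_runs=prt_runs,
        ddpcr_runs=ddpcr_runs,
    )


def assay_estimates(cohort: SimulatedCohort) -> pd.DataFrame:
    """Per-sample continuous copy-number estimates from the raw assay runs."""
    columns: dict[str, pd.Series] = {}
    if cohort.prt_runs:
        columns["prt"] = pd.Series(
            {s: assays.prt_relative_cn(r) for s, r in cohort.prt_runs.items()}
        )
    if cohort.ddpcr_runs:
        columns["ddpcr"] = pd.Series(
            {s: assays.ddpcr_cn(runs) for s, runs in cohort.ddpcr_runs.items()}
        )
    if not columns:
        raise DataError("cohort carries no assay measurements")
    return pd.DataFrame(columns)


def combined_cn(estimates: pd.DataFrame) -> pd.Series:
    """The per-sample copy-number estimate used for the correlation track:
    the mean over available assay estimates (all on the diploid scale)."""
    return estimates.mean(axis=1)


@dataclass
class BoundaryResult:
    track: boundary.CorrelationTrack
    calls: list[boundary.BlockCall]
    cn_estimates: pd.Series


def boundary_stage(
    probes: ProbeSet,
    intensities: IntensityMatrix,
    cn: pd.Series,
    r2_threshold: float = boundary.R2_THRESHOLD,
    min_probes: int = boundary.MIN_PROBES,
    max_gap_probes: int = boundary.MAX_GAP_PROBES,
) -> BoundaryResult:
    track = boundary.probe_cn_r2(intensities, cn)
    calls = boundary.call_block(
        track,
        probes,
        r2_threshold=r2_threshold,
        min_probes=min_probes,
        max_gap_probes=max_gap_probes,
    )
    return BoundaryResult(track=track, calls=calls, cn_estimates=cn)


def hmm_stage(
    probes: ProbeSet,
    intensities: IntensityMatrix,
    model: boundary.HMMModel | None = None,
) -> pd.DataFrame:
    """Segment the cohort-mean log2 track; one row per breakpoint."""
    mean_track = np.nanmean(intensities.values, axis=1)
    seg = boundary.hmm_segment(mean_track, model=model, probes=probes)
    rows = [
        {
            "left_state": bp.left_state,
            "right_state": bp.right_state,
            "left_probe": probes.probe_ids[bp.left_index],
            "right_probe": probes.probe_ids[bp.right_index],
            "interval_start": bp.interval[0] if bp.interval else "",
            "interval_end": bp.interval[1] if bp.interval else "",
        }
        for bp in seg.breakpoints
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "left_state", "right_state", "left_probe", "right_probe",
            "interval_start", "interval_end",
        ],
    )


@dataclass
class CallingResult:
    block: boundary.BlockCall
    method_matrix: pd.DataFrame
    concordance: pd.DataFrame
    integrated: pd.Series
    callset: integration.IntegerCallSet


def calling_stage(
    probes: ProbeSet,
    intensities: IntensityMatrix,
    block: boundary.BlockCall,
    estimates: pd.DataFrame,
    anchor_method: str = "ddpcr",
) -> CallingResult:
    from .genome import Interval

    mask = probes.in_interval(Interval(block.chrom, block.start, block.end))
    pc1 = integration.block_pc1(intensities.subset_probes(mask))
    method_matrix = estimates.copy()
    method_matrix["acgh"] = pc1
    concordance = integration.method_concordance(method_matrix)
    integrated = integration.integrate_methods(method_matrix)
    callset = integration.call_integers(
        integrated, method_matrix, anchor_method=anchor_method
    )
    return CallingResult(
        block=block,
        method_matrix=method_matrix,
        concordance=concordance,
        integrated=integrated,
        callset=callset,
    )


def run_all(config: CohortConfig, seed: int, outdir: str | Path) -> dict:
    """Simulate, map the block, segment, call integers; write all outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_stage(config, seed)
    meta = cohort.meta

    io.write_probes_bed(cohort.probes, outdir / "probes.bed", meta)
    io.write_intensities_tsv(cohort.intensities, outdir / "intensities.tsv", meta)
    io.write_truth_json(cohort.truth, outdir / "truth.json", meta)
    io.write_assays_tsv(
        cohort.prt_runs, cohort.ddpcr_runs, outdir / "assays.tsv", meta
    )

    estimates = assay_estimates(cohort)
    cn_for_r2 = combined_cn(estimates)
    io.write_cn_tsv(cn_for_r2, outdir / "cn.tsv", meta)

    result = boundary_stage(cohort.probes, cohort.intensities, cn_for_r2)
    io.write_blocks_bed(result.calls, outdir / "blocks.bed", meta)
    io.write_bedgraph(
        cohort.probes, np.nan_to_num(result.track.r2),
        outdir / "r2_track.bedgraph", meta,
    )

    model = boundary.HMMModel(
        sds=np.full(3, max(config.noise.sd, 0.05))
    )
    breakpoints = hmm_stage(cohort.probes, cohort.intensities, model)
    io.write_breakpoints_tsv(breakpoints, outdir / "breakpoints.tsv", meta)

    long_estimates = (
        estimates.rename_axis("sample")
        .reset_index()
        .melt(id_vars="sample", var_name="method", value_name="estimate")
    )
    long_estimates["qc_flag"] = "pass"
    io.write_results_tsv(long_estimates, outdir / "results.tsv", meta)

    calls = None
    if result.calls:
        calls = calling_stage(
            cohort.probes,
            cohort.intensities,
            result.calls[0],
            estimates,
            anchor_method=config.anchor_method,
        )
        io.write_calls_tsv(
            calls.callset, outdir / "calls.tsv",
            methods_used=list(calls.method_matrix.columns), meta=meta,
        )
        io.write_concordance_tsv(calls.concordance, outdir / "concordance.tsv", meta)

    return {
        "cohort": cohort,
        "boundary": result,
        "breakpoints": breakpoints,
        "calls": calls,
    }
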