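"""File formats: BED/bedgraph probe tracks, TSV matrices, FASTA haplotypes,
JSON reports.

Every tabular output begins with a ``#`` header comment carrying the tool
version, config hash and seed; readers skip comment lines. Coordinates are
0-based half-open (BED convention). Write-then-read round-trips are exact
on valid files; malformed input raises :class:`~cnvblock.errors.DataError`
naming the offending line.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .assays import DdpcrRun, PRTRun
from .boundary import BlockCall
from .dating import InsertionMatrix
from .errors import DataError
from .genome import IntensityMatrix, Interval, ProbeSet
from .integration import IntegerCallSet
from .selection import HaplotypeSet
from .synthetic import CohortTruth, DropoutSpec


def meta_header(meta: Mapping[str, object] | None = None) -> str:
    parts = [f"cnvblock v{__version__}"]
    for key, value in (meta or {}).items():
        parts.append(f"{key}={value}")
    return "# " + " ".join(parts)


def _write_table(
    df: pd.DataFrame,
    path: str | Path,
    meta: Mapping[str, object] | None,
    header: bool,
    index: bool = False,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(meta_header(meta) + "\n")
        df.to_csv(fh, sep="\t", header=header, index=index)


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, sep="\t", comment="#", float_precision="round_trip", **kwargs
        )
    except pd.errors.ParserError as exc:
        raise DataError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# probes / intensities / copy numbers
# ---------------------------------------------------------------------------


def write_probes_bed(
    probes: ProbeSet, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    _write_table(probes.to_frame(), path, meta, header=False)


def read_probes_bed(path: str | Path) -> ProbeSet:
    df = _read_table(
        path, header=None, names=["chrom", "start", "end", "probe_id"],
        dtype={"chrom": str, "probe_id": str},
    )
    if df.empty:
        raise DataError(f"{path}: no probes")
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        if row.end <= row.start:
            raise DataError(
                f"{path}, record {lineno}: end {row.end} <= start {row.start}"
            )
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise DataError(f"{path}: duplicate probe id {dup!r}")
    return ProbeSet.from_frame(df)


def write_intensities_tsv(
    matrix: IntensityMatrix,
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    _write_table(matrix.to_frame(), path, meta, header=True, index=True)


def read_intensities_tsv(path: str | Path) -> IntensityMatrix:
    df = _read_table(path, index_col=0)
    return IntensityMatrix.from_frame(df)


def write_cn_tsv(
    cn: pd.Series, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    df = cn.rename("cn").rename_axis("sample").reset_index()
    _write_table(df, path, meta, header=True)


def read_cn_tsv(path: str | Path) -> pd.Series:
    df = _read_table(path, dtype={"sample": str})
    return df.set_index("sample")["cn"].astype(float)


# ---------------------------------------------------------------------------
# assay runs
# ---------------------------------------------------------------------------


def write_assays_tsv(
    prt_runs: Mapping[str, PRTRun] | None,
    ddpcr_runs: Mapping[str, Sequence[DdpcrRun]] | None,
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    """One row per sample x assay x replicate.

    PRT rows carry peak areas in (test, reference); ddPCR rows carry
    positive-droplet counts plus the total droplet count.
    """
    rows = []
    for sample, run in (prt_runs or {}).items():
        for rep, (t, r) in enumerate(run.replicates, start=1):
            rows.append(
                {"sample": sample, "assay": "prt", "replicate": rep,
                 "test": t, "reference": r, "n_droplets": ""}
            )
    for sample, runs in (ddpcr_runs or {}).items():
        for rep, run in enumerate(runs, start=1):
            rows.append(
                {"sample": sample, "assay": "ddpcr", "replicate": rep,
                 "test": run.n_test_positive, "reference": run.n_ref_positive,
                 "n_droplets": run.n_droplets}
            )
    _write_table(pd.DataFrame(rows), path, meta, header=True)


def read_assays_tsv(
    path: str | Path,
) -> tuple[dict[str, PRTRun], dict[str, list[DdpcrRun]]]:
    df = _read_table(path, dtype={"sample": str, "assay": str})
    prt: dict[str, PRTRun] = {}
    ddpcr: dict[str, list[DdpcrRun]] = {}
    for (sample, assay), group in df.groupby(["sample", "assay"], sort=True):
        group = group.sort_values("replicate")
        if assay == "prt":
            prt[sample] = PRTRun(
                sample_id=sample,
                replicates=[
                    (float(t), float(r))
                    for t, r in zip(group["test"], group["reference"])
                ],
            )
        elif assay == "ddpcr":
            ddpcr[sample] = [
                DdpcrRun(
                    sample_id=sample,
                    n_droplets=int(row.n_droplets),
                    n_test_positive=int(row.test),
                    n_ref_positive=int(row.reference),
                )
                for row in group.itertuples(index=False)
            ]
        else:
            raise DataError(f"{path}: unknown assay {assay!r}")
    return prt, ddpcr


def write_results_tsv(
    estimates: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    """Long-format per-sample method estimates: sample, method, estimate."""
    _write_table(estimates, path, meta, header=True)


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return _read_table(path, dtype={"sample": str, "method": str})


# ---------------------------------------------------------------------------
# blocks / tracks / breakpoints / calls
# ---------------------------------------------------------------------------


def write_blocks_bed(
    calls: Sequence[BlockCall],
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    """BED6 with the mean in-block r2 scaled to 0-1000 as the score."""
    df = pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "start": [c.start for c in calls],
            "end": [c.end for c in calls],
            "name": [f"block_{i + 1}" for i in range(len(calls))],
            "score": [int(round(1000 * c.mean_r2)) for c in calls],
            "strand": ["." for _ in calls],
        }
    )
    _write_table(df, path, meta, header=False)


def read_blocks_bed(path: str | Path) -> pd.DataFrame:
    df = _read_table(
        path, header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        if row.end <= row.start:
            raise DataError(
                f"{path}, record {lineno}: end {row.end} <= start {row.start}"
            )
    return df


def write_bedgraph(
    probes: ProbeSet,
    values: np.ndarray,
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    df = pd.DataFrame(
        {
            "chrom": probes.chroms,
            "start": probes.starts,
            "end": probes.ends,
            "value": np.asarray(values, dtype=float),
        }
    )
    _write_table(df, path, meta, header=False)


def write_breakpoints_tsv(
    rows: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    _write_table(rows, path, meta, header=True)


def write_calls_tsv(
    callset: IntegerCallSet,
    path: str | Path,
    methods_used: Sequence[str] = (),
    meta: Mapping[str, object] | None = None,
) -> None:
    df = callset.to_frame()
    df["methods_used"] = ",".join(methods_used)
    _write_table(df, path, meta, header=True)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    return _read_table(path, dtype={"sample": str})


def write_concordance_tsv(
    concordance: pd.DataFrame, path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    _write_table(concordance.rename_axis("method"), path, meta, header=True, index=True)


# ---------------------------------------------------------------------------
# truth / haplotypes / dating
# ---------------------------------------------------------------------------


def write_truth_json(
    truth: CohortTruth, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    payload = {
        "_meta": meta_header(meta).lstrip("# "),
        "block": asdict(truth.block),
        "reference_cn": truth.reference_cn,
        "sample_ids": truth.sample_ids,
        "cn": {s: int(v) for s, v in truth.cn.items()},
        "decoy_blocks": [asdict(iv) for iv in truth.decoy_blocks],
        "decoy_cn": [
            {s: int(v) for s, v in series.items()} for series in truth.decoy_cn
        ],
        "dropout": (
            {
                "interval": asdict(truth.dropout.interval),
                "n_carriers": truth.dropout.n_carriers,
                "delta": truth.dropout.delta,
            }
            if truth.dropout
            else None
        ),
        "dropout_carriers": truth.dropout_carriers,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_truth_json(path: str | Path) -> CohortTruth:
    payload = json.loads(Path(path).read_text())
    dropout = None
    if payload.get("dropout"):
        d = payload["dropout"]
        dropout = DropoutSpec(
            interval=Interval(**d["interval"]),
            n_carriers=d["n_carriers"],
            delta=d["delta"],
        )
    return CohortTruth(
        block=Interval(**payload["block"]),
        sample_ids=list(payload["sample_ids"]),
        cn=pd.Series(payload["cn"]),
        reference_cn=payload["reference_cn"],
        decoy_blocks=[Interval(**iv) for iv in payload["decoy_blocks"]],
        decoy_cn=[pd.Series(d) for d in payload["decoy_cn"]],
        dropout=dropout,
        dropout_carriers=list(payload.get("dropout_carriers", [])),
    )


def write_haplotypes_fasta(h: HaplotypeSet, path: str | Path) -> None:
    """Headers are ``variantLabel|haplotypeID|paralogPosition``."""
    records = []
    for (hap, pos), seq in sorted(h.sequences.items()):
        label = h.labels.get((hap, pos), hap)
        records.append(
            SeqRecord(Seq(seq), id=f"{label}|{hap}|{pos}", description="")
        )
    SeqIO.write(records, str(path), "fasta")


def read_haplotypes_fasta(path: str | Path) -> HaplotypeSet:
    sequences: dict[tuple[str, str], str] = {}
    labels: dict[tuple[str, str], str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        fields = record.id.split("|")
        if len(fields) != 3:
            raise DataError(
                f"{path}: header {record.id!r} is not 'label|haplotype|position'"
            )
        label, hap, pos = fields
        key = (hap, pos)
        if key in sequences:
            raise DataError(f"{path}: duplicate haplotype/position {key}")
        sequences[key] = str(record.seq)
        labels[key] = label
    if not sequences:
        raise DataError(f"{path}: no sequences")
    return HaplotypeSet(sequences=sequences, labels=labels)


def read_markers_tsv(
    markers_path: str | Path, meta_path: str | Path | None = None
) -> InsertionMatrix:
    """markers.tsv: lineage, divergence_Ma, marker, status;
    marker_meta.tsv: marker, subfamily_age_Ma."""
    df = _read_table(markers_path, dtype={"lineage": str, "marker": str, "status": str})
    divergence: dict[str, float] = {}
    status: dict[tuple[str, str], str] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        t = float(row.divergence_Ma)
        if row.lineage in divergence and divergence[row.lineage] != t:
            raise DataError(
                f"{markers_path}, record {lineno}: conflicting divergence time "
                f"for {row.lineage!r}"
            )
        divergence[row.lineage] = t
        status[(row.marker, row.lineage)] = row.status
    ages: dict[str, float] = {}
    if meta_path is not None:
        meta_df = _read_table(meta_path, dtype={"marker": str})
        ages = {
            row.marker: float(row.subfamily_age_Ma)
            for row in meta_df.itertuples(index=False)
            if pd.notna(row.subfamily_age_Ma)
        }
    return InsertionMatrix(
        divergence_ma=divergence, status=status, subfamily_age_ma=ages
    )


def write_markers_tsv(
    m: InsertionMatrix,
    markers_path: str | Path,
    meta_path: str | Path | None = None,
    meta: Mapping[str, object] | None = None,
) -> None:
    _write_table(m.to_frame(), markers_path, meta, header=True)
    if meta_path is not None:
        df = pd.DataFrame(
            {
                "marker": list(m.subfamily_age_ma),
                "subfamily_age_Ma": list(m.subfamily_age_ma.values()),
            }
        )
        _write_table(df, meta_path, meta, header=True)


def write_bracket_json(
    bracket, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    payload = {
        "_meta": meta_header(meta).lstrip("# "),
        "min_age_Ma": bracket.min_age,
        "max_age_Ma": bracket.max_age,
        "evidence": bracket.evidence,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")
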