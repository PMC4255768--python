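"""Copy-number estimation from raw PRT, ddPCR and qPCR measurements.

PRT (paralog ratio test): one primer pair co-amplifies a test locus inside
the CNV and a reference locus outside it; the ratio of peak areas estimates
the relative copy number, and the average over replicate ratios is scaled by
the reference locus's diploid copy number (2).

ddPCR: droplet positivity follows Poisson loading, so the mean number of
molecules per droplet is recovered from the negative fraction as
``lambda = -ln(n_negative / n_droplets)``; copy number is
``2 * lambda_test / lambda_ref``. Reads must have more than ``min_droplets``
droplets to pass QC (strict inequality), and a sample estimate averages its
QC-passing replicate reads.

qPCR: a standard curve (Ct vs log10 input quantity) per amplicon yields the
amplification efficiency ``E = 10^(-1/slope)``; relative quantities are
``E^-Ct`` and the test/reference quantity ratio, normalized by the same
ratio on a calibrator of known diploid copy number, gives the estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, MeasurementError, SaturationError

#: default diploid copy number of the reference locus
REFERENCE_CN = 2.0

#: reads with at most this many droplets fail QC (strict: "> 10,000")
MIN_DROPLETS = 10000


@dataclass
class PRTRun:
    """Replicated PRT measurement: (test, reference) peak-area pairs."""

    sample_id: str
    replicates: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.replicates) < 1:
            raise DataError(f"PRT run {self.sample_id!r} has no replicates")
        for t, r in self.replicates:
            if t < 0 or r < 0:
                raise DataError(
                    f"PRT run {self.sample_id!r} has a negative peak area"
                )


@dataclass
class DdpcrRun:
    """One ddPCR read: droplet counts for test and reference channels."""

    sample_id: str
    n_droplets: int
    n_test_positive: int
    n_ref_positive: int
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise DataError(f"ddPCR run {self.sample_id!r} has no droplets")
        for n in (self.n_test_positive, self.n_ref_positive):
            if n < 0 or n > self.n_droplets:
                raise DataError(
                    f"ddPCR run {self.sample_id!r}: positive count {n} outside "
                    f"[0, {self.n_droplets}]"
                )


@dataclass
class QpcrRun:
    """One qPCR measurement with per-amplicon standard-curve points.

    ``curves`` maps "test" and "ref" to lists of (log10 quantity, Ct).
    """

    sample_id: str
    ct_test: float
    ct_ref: float
    curves: Mapping[str, Sequence[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ct_test <= 0 or self.ct_ref <= 0:
            raise DataError(f"qPCR run {self.sample_id!r} has non-positive Ct")


class StandardCurve(NamedTuple):
    slope: float
    intercept: float
    efficiency: float


def prt_relative_cn(run: PRTRun, reference_cn: float = REFERENCE_CN) -> float:
    """Diploid-scale copy number: reference_cn times the mean replicate ratio.

    Replicates with a zero reference peak are rejected; if every replicate is
    rejected the run is unusable.
    """
    ratios = [t / r for t, r in run.replicates if r > 0]
    if not ratios:
        raise MeasurementError(
            f"PRT run {run.sample_id!r}: all replicates have zero reference area"
        )
    return reference_cn * float(np.mean(ratios))


def ddpcr_lambda(n_negative: int, n_droplets: int) -> float:
    """Mean molecules per droplet by Poisson inversion of the negative fraction."""
    if n_droplets < 1:
        raise DataError("n_droplets must be >= 1")
    if n_negative < 0 or n_negative > n_droplets:
        raise DataError(f"n_negative {n_negative} outside [0, {n_droplets}]")
    if n_negative == 0:
        raise SaturationError(
            "no negative droplets: concentration unbounded (saturated read)"
        )
    return -math.log(n_negative / n_droplets)


def _single_run_cn(run: DdpcrRun, reference_cn: float) -> float:
    lam_test = ddpcr_lambda(run.n_droplets - run.n_test_positive, run.n_droplets)
    lam_ref = ddpcr_lambda(run.n_droplets - run.n_ref_positive, run.n_droplets)
    if lam_ref == 0:
        raise MeasurementError(
            f"ddPCR run {run.sample_id!r}: reference channel empty, ratio undefined"
        )
    return reference_cn * lam_test / lam_ref


def ddpcr_cn(
    run: DdpcrRun | Sequence[DdpcrRun],
    min_droplets: int = MIN_DROPLETS,
    reference_cn: float = REFERENCE_CN,
) -> float:
    """Copy number ``reference_cn * lambda_test / lambda_ref``.

    Accepts a single read or a list of replicate reads; reads with
    ``n_droplets <= min_droplets`` fail QC and are excluded from the average.
    """
    runs = [run] if isinstance(run, DdpcrRun) else list(run)
    if not runs:
        raise MeasurementError("no ddPCR reads supplied")
    passing = [r for r in runs if r.n_droplets > min_droplets]
    if not passing:
        raise MeasurementError(
            f"all {len(runs)} ddPCR read(s) failed the droplet-count QC "
            f"(need > {min_droplets})"
        )
    return float(np.mean([_single_run_cn(r, reference_cn) for r in passing]))


def qpcr_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares Ct vs log10(quantity) line and the implied efficiency."""
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if len(np.unique(x)) < 2:
        raise DataError("standard curve needs >= 2 distinct input quantities")
    slope, intercept = np.polyfit(x, y, 1)
    if slope == 0:
        raise DataError("standard curve slope is zero; efficiency undefined")
    return StandardCurve(float(slope), float(intercept), float(10.0 ** (-1.0 / slope)))


class QpcrEstimate(NamedTuple):
    value: float
    calibrated: bool


def qpcr_cn(
    run: QpcrRun,
    calibrator: QpcrRun | None = None,
    reference_cn: float = REFERENCE_CN,
) -> QpcrEstimate:
    """Efficiency-corrected ddCt copy number.

    The test/reference relative-quantity ratio ``E_test^-Ct_test /
    E_ref^-Ct_ref`` is normalized by the same ratio on a calibrator of known
    diploid copy number. Without a calibrator the raw ratio (times
    ``reference_cn``) is returned flagged un-calibrated.
    """

    def ratio(r: QpcrRun) -> float:
        if "test" not in r.curves or "ref" not in r.curves:
            raise DataError(
                f"qPCR run {r.sample_id!r} lacks 'test'/'ref' standard curves"
            )
        e_test = qpcr_standard_curve(r.curves["test"]).efficiency
        e_ref = qpcr_standard_curve(r.curves["ref"]).efficiency
        return e_test**-r.ct_test / e_ref**-r.ct_ref

    if calibrator is None:
        warnings.warn(
            f"qPCR run {run.sample_id!r}: no calibrator; returning raw ratio",
            stacklevel=2,
        )
        return QpcrEstimate(reference_cn * ratio(run), calibrated=False)
    return QpcrEstimate(reference_cn * ratio(run) / ratio(calibrator), calibrated=True)


def calibrate_to_integer_scale(
    values: pd.Series | Mapping[str, float],
    anchors: Mapping[str, int] | pd.Series,
) -> pd.Series:
    """Affine-map continuous estimates onto anchor samples' asserted integers.

    A least-squares line from the anchor samples' values to their integers is
    applied to every sample. With fewer than two distinct anchor values the
    identity map is returned with a warning.
    """
    values = pd.Series(values, dtype=float)
    anchors = pd.Series(anchors, dtype=float)
    shared = values.index.intersection(anchors.index)
    x = values.loc[shared]
    if len(np.unique(x.to_numpy())) < 2:
        warnings.warn(
            "fewer than 2 distinct anchor values; returning values unchanged",
            stacklevel=2,
        )
        return values.copy()
    a, b = np.polyfit(x.to_numpy(), anchors.loc[shared].to_numpy(), 1)
    return a * values + b
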