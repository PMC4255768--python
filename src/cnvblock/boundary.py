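"""CNV block boundary mapping.

A tandem CNV embedded in repeat-rich flanks cannot be called from the
diploid-to-variable intensity transition alone, because the flanks are
themselves copy-number variable. Instead, each tiling probe's log2 ratio is
correlated across samples with an independently assayed copy number: probes
measuring the same CNV are strongly correlated with it, probes in unrelated
CNVs or diploid sequence are not. The contiguous run of high-r2 probes is
the block, and a Gaussian-emission hidden Markov model over an ordered log2
track places copy-number state transitions between informative probes.

Boundaries are always reported as intervals between probes, never point
estimates: the data cannot localize a breakpoint more finely than the probe
spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .genome import IntensityMatrix, ProbeSet

#: default probe-level r2 threshold for block membership
R2_THRESHOLD = 0.5
#: minimum supporting (above-threshold) probes per called block
MIN_PROBES = 10
#: tolerated run of consecutive sub-threshold probes inside a block
#: (accommodates an internally embedded low-correlation core duplicon)
MAX_GAP_PROBES = 20
#: conservative probability of switching copy-number state between probes
HMM_TRANSITION_P = 1e-6


@dataclass
class CorrelationTrack:
    """Per-probe squared Pearson correlation with copy number."""

    probe_ids: np.ndarray
    r2: np.ndarray  # NaN where fewer than 3 informative samples
    n_samples: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.r2 = np.asarray(self.r2, dtype=float)
        self.n_samples = np.asarray(self.n_samples, dtype=np.int64)
        if not (len(self.probe_ids) == len(self.r2) == len(self.n_samples)):
            raise DataError("correlation track arrays have mismatched lengths")
        finite = self.r2[np.isfinite(self.r2)]
        if ((finite < -1e-9) | (finite > 1 + 1e-9)).any():
            raise DataError("r2 values must lie in [0, 1]")


@dataclass
class BlockCall:
    """A called CNV block with interval-style boundary uncertainty."""

    chrom: str
    start: int
    end: int
    n_probes: int  # probes spanned by the call
    n_support: int  # above-threshold probes among them
    mean_r2: float
    left_boundary: tuple[int, int]
    right_boundary: tuple[int, int]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError(f"block end must exceed start: {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def probe_cn_r2(
    intensities: IntensityMatrix, cn: pd.Series | Mapping[str, float]
) -> CorrelationTrack:
    """Squared Pearson correlation of each probe's log2 ratios with copy number.

    Computed across the samples shared between the matrix and the copy-number
    vector; probes with fewer than 3 informative samples are recorded as
    missing (NaN); probes with zero intensity variance get r2 = 0 (they carry
    no supporting evidence). r2 is invariant to affine rescaling of either
    variable.
    """
    cn = pd.Series(cn, dtype=float).dropna()
    shared = [s for s in intensities.sample_ids if s in cn.index]
    if len(shared) < 3:
        raise DataError(
            f"need >= 3 samples with both intensities and copy number, got {len(shared)}"
        )
    col_idx = [list(intensities.sample_ids).index(s) for s in shared]
    x = intensities.values[:, col_idx]
    y = cn.loc[shared].to_numpy()

    valid = np.isfinite(x)
    n = valid.sum(axis=1)
    xz = np.where(valid, x, 0.0)
    sx = xz.sum(axis=1)
    sxx = (xz**2).sum(axis=1)
    sy = valid @ y
    syy = valid @ (y**2)
    sxy = xz @ y

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        var_x = sxx - sx**2 / n
        var_y = syy - sy**2 / n
        r2 = cov**2 / (var_x * var_y)
    # degenerate probes (or a constant copy-number vector) support nothing
    r2 = np.where((var_x <= 0) | (var_y <= 0), 0.0, r2)
    r2 = np.clip(r2, 0.0, 1.0)
    r2 = np.where(n < 3, np.nan, r2)
    return CorrelationTrack(intensities.probe_ids, r2, n)


def call_block(
    track: CorrelationTrack,
    probes: ProbeSet,
    r2_threshold: float = R2_THRESHOLD,
    min_probes: int = MIN_PROBES,
    max_gap_probes: int = MAX_GAP_PROBES,
) -> list[BlockCall]:
    """Call CNV blocks as maximal runs of probes with r2 >= threshold.

    Runs tolerate up to ``max_gap_probes`` consecutive sub-threshold probes
    (bridging internally embedded low-correlation sections); block edges are
    the outermost qualifying probes, with the flanking probe gaps reported
    as boundary-uncertainty intervals. Calls supported by fewer than
    ``min_probes`` qualifying probes are discarded. Sorted by size
    descending.
    """
    if len(track.probe_ids) != len(probes):
        raise DataError("correlation track is not aligned to the probe set")
    if not np.array_equal(track.probe_ids, probes.probe_ids):
        raise DataError("correlation track probe ids do not match the probe set")

    qualifying = np.isfinite(track.r2) & (track.r2 >= r2_threshold)
    calls: list[BlockCall] = []
    for chrom in pd.unique(probes.chroms):
        idx = np.nonzero(probes.chroms == chrom)[0]
        q_idx = idx[qualifying[idx]]
        if len(q_idx) == 0:
            continue
        # group qualifying probes separated by <= max_gap_probes others
        runs: list[list[int]] = [[int(q_idx[0])]]
        for i in q_idx[1:]:
            if int(i) - runs[-1][-1] - 1 <= max_gap_probes:
                runs[-1].append(int(i))
            else:
                runs.append([int(i)])
        for run in runs:
            if len(run) < min_probes:
                continue
            first, last = run[0], run[-1]
            span = np.arange(first, last + 1)
            prev_i = first - 1 if first - 1 in idx else None
            next_i = last + 1 if last + 1 in idx else None
            left = (
                (int(probes.ends[prev_i]), int(probes.starts[first]))
                if prev_i is not None
                else (int(probes.starts[first]), int(probes.starts[first]))
            )
            right = (
                (int(probes.ends[last]), int(probes.starts[next_i]))
                if next_i is not None
                else (int(probes.ends[last]), int(probes.ends[last]))
            )
            calls.append(
                BlockCall(
                    chrom=str(chrom),
                    start=int(probes.starts[first]),
                    end=int(probes.ends[last]),
                    n_probes=len(span),
                    n_support=len(run),
                    mean_r2=float(np.nanmean(track.r2[span])),
                    left_boundary=left,
                    right_boundary=right,
                )
            )
    calls.sort(key=lambda c: c.length, reverse=True)
    return calls


# ---------------------------------------------------------------------------
# HMM segmentation
# ---------------------------------------------------------------------------


@dataclass
class HMMModel:
    """Gaussian-emission copy-number-state HMM over an ordered probe track.

    States are ordered copy-number levels (by default loss / neutral / gain
    with log2-ratio means -1, 0 and log2(3/2)); the probability of switching
    between distinct states at each probe step is ``transition_p`` --
    deliberately conservative so that isolated outlier probes do not open a
    segment.
    """

    states: tuple[str, ...] = ("loss", "neutral", "gain")
    means: np.ndarray = field(
        default_factory=lambda: np.array([-1.0, 0.0, np.log2(1.5)])
    )
    sds: np.ndarray = field(default_factory=lambda: np.array([0.25, 0.25, 0.25]))
    transition_p: float = HMM_TRANSITION_P

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        k = len(self.states)
        if len(self.means) != k or len(self.sds) != k:
            raise ConfigurationError("means/sds must match the number of states")
        if (self.sds <= 0).any():
            raise ConfigurationError("emission sds must be > 0")
        if len(np.unique(self.means)) != k:
            raise ConfigurationError(
                "degenerate emission model: state means must be distinct"
            )
        if not 0 < self.transition_p < 1 / max(k - 1, 1):
            raise ConfigurationError(
                f"transition_p must be in (0, 1/(k-1)), got {self.transition_p}"
            )

    def log_transition(self) -> np.ndarray:
        k = len(self.states)
        t = np.full((k, k), self.transition_p)
        np.fill_diagonal(t, 1.0 - (k - 1) * self.transition_p)
        return np.log(t)

    def log_emission(self, values: np.ndarray) -> np.ndarray:
        """log N(value | mean_s, sd_s) for every probe x state."""
        v = values[:, None]
        return (
            -0.5 * ((v - self.means[None, :]) / self.sds[None, :]) ** 2
            - np.log(self.sds[None, :] * np.sqrt(2 * np.pi))
        )


@dataclass
class Breakpoint:
    """A state change localized to the interval between informative probes."""

    left_state: str
    right_state: str
    left_index: int
    right_index: int
    interval: tuple[int, int] | None = None  # genomic span probe[i]..probe[i+1]


@dataclass
class Segmentation:
    states: tuple[str, ...]
    path: np.ndarray  # state index per probe
    breakpoints: list[Breakpoint]

    @property
    def state_path(self) -> list[str]:
        return [self.states[i] for i in self.path]


def hmm_segment(
    values: Sequence[float] | np.ndarray,
    model: HMMModel | None = None,
    probes: ProbeSet | None = None,
) -> Segmentation:
    """Viterbi maximum-likelihood segmentation of one ordered log2 track.

    Each state change is reported as a breakpoint spanning from the last
    probe of the left-hand state to the first probe of the right-hand state
    (a genomic interval when ``probes`` is given).
    """
    model = model or HMMModel()
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise DataError("need a 1-D track of >= 2 probe values")
    if not np.isfinite(values).all():
        raise DataError("track contains non-finite values")
    if probes is not None and len(probes) != len(values):
        raise DataError("probe set does not match track length")

    k = len(model.states)
    log_e = model.log_emission(values)
    log_t = model.log_transition()
    log_init = np.full(k, -np.log(k))

    n = len(values)
    score = np.empty((n, k))
    back = np.zeros((n, k), dtype=np.int64)
    score[0] = log_init + log_e[0]
    for i in range(1, n):
        cand = score[i - 1][:, None] + log_t  # prev state x next state
        back[i] = np.argmax(cand, axis=0)
        score[i] = cand[back[i], np.arange(k)] + log_e[i]
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(score[-1]))
    for i in range(n - 2, -1, -1):
        path[i] = back[i + 1][path[i + 1]]

    breakpoints = []
    for i in np.nonzero(np.diff(path) != 0)[0]:
        interval = None
        if probes is not None:
            interval = (int(probes.starts[i]), int(probes.ends[i + 1]))
        breakpoints.append(
            Breakpoint(
                left_state=model.states[path[i]],
                right_state=model.states[path[i + 1]],
                left_index=int(i),
                right_index=int(i + 1),
                interval=interval,
            )
        )
    return Segmentation(states=model.states, path=path, breakpoints=breakpoints)


# ---------------------------------------------------------------------------
# internal-heterogeneity (dropout) scan
# ---------------------------------------------------------------------------


@dataclass
class DropoutCall:
    """A sub-interval of a block where a sample subset loses signal."""

    first_index: int
    last_index: int
    carriers: list[str]
    mean_delta: float
    interval: tuple[int, int] | None = None


def dropout_scan(
    intensities: IntensityMatrix,
    probes: ProbeSet | None = None,
    delta: float = 0.5,
    min_carriers: int = 2,
    max_carrier_frac: float = 0.5,
    min_run: int = 2,
) -> list[DropoutCall]:
    """Scan a block-restricted matrix for internal bimodal signal loss.

    Per-sample deviations from that sample's block-wide median are computed
    (removing the copy-number signal); probes where a subset of
    ``min_carriers``..``max_carrier_frac * n`` samples deviates below
    ``-delta`` are flagged, and runs of >= ``min_run`` consecutive flagged
    probes are reported with their carrier samples. Returns an empty list
    for a homogeneous block.
    """
    if intensities.n_probes < min_run:
        return []
    baseline = np.nanmedian(intensities.values, axis=0)
    dev = intensities.values - baseline[None, :]
    low = dev < -delta
    n_low = low.sum(axis=1)
    max_carriers = int(max_carrier_frac * intensities.n_samples)
    flagged = (n_low >= min_carriers) & (n_low <= max_carriers)

    calls: list[DropoutCall] = []
    i = 0
    n = intensities.n_probes
    while i < n:
        if not flagged[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flagged[j + 1]:
            j += 1
        if j - i + 1 >= min_run:
            run_low = low[i : j + 1]
            frac = run_low.mean(axis=0)
            carrier_mask = frac > 0.5
            n_car = int(carrier_mask.sum())
            if min_carriers <= n_car <= max_carriers:
                interval = None
                if probes is not None:
                    interval = (int(probes.starts[i]), int(probes.ends[j]))
                calls.append(
                    DropoutCall(
                        first_index=i,
                        last_index=j,
                        carriers=[
                            str(s)
                            for s, m in zip(intensities.sample_ids, carrier_mask)
                            if m
                        ],
                        mean_delta=float(-dev[i : j + 1, carrier_mask].mean()),
                        interval=interval,
                    )
                )
        i = j + 1
    return calls
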