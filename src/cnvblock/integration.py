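"""Fusing aCGH, PRT and ddPCR estimates into integer copy-number calls.

The aCGH intensities over a called block are reduced to one score per
sample (the first principal component of the probe x sample matrix); the
continuous estimates of every method are then combined as the first
principal component of the standardized sample x method matrix, anchored
back onto the most accurate method's scale (ddPCR by default, whose
estimates cluster about integers) by a least-squares affine map, and
rounded. The confidence of each call is ``1 - 2 |score - round(score)|``:
1 when the mapped score sits exactly on an integer, 0 exactly halfway
between two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .genome import IntensityMatrix


@dataclass
class IntegerCallSet:
    """Per-sample integer copy numbers with calibrated confidences."""

    sample_ids: list[str]
    cn: np.ndarray
    confidence: np.ndarray
    anchor_method: str | None
    mapped_score: np.ndarray
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if (self.cn < 0).any():
            raise DataError("integer copy numbers must be >= 0")
        if ((self.confidence < -1e-9) | (self.confidence > 1 + 1e-9)).any():
            raise DataError("confidences must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_ids,
                "integer_cn": self.cn,
                "confidence": self.confidence,
                "mapped_score": self.mapped_score,
            }
        )


def _pc1_scores(x: np.ndarray) -> np.ndarray:
    """First-principal-component score per row of ``x`` (columns as variables)."""
    centered = x - x.mean(axis=0, keepdims=True)
    if not np.any(centered):
        raise DataError("zero total variance: PC1 undefined")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    return u[:, 0] * s[0]


def block_pc1(intensities: IntensityMatrix) -> pd.Series:
    """Per-sample PC1 score of the block-restricted intensity matrix.

    Probes are the variables; missing values are imputed with the probe
    mean. The sign is oriented so the score correlates positively with each
    sample's mean intensity (higher copy number -> higher score).
    """
    if intensities.n_samples < 2 or intensities.n_probes < 2:
        raise DataError("need >= 2 samples and >= 2 probes for PC1")
    x = intensities.values.T.copy()  # samples x probes
    if np.isnan(x).any():
        probe_means = np.nanmean(x, axis=0)
        probe_means = np.where(np.isfinite(probe_means), probe_means, 0.0)
        nan_r, nan_c = np.nonzero(np.isnan(x))
        x[nan_r, nan_c] = probe_means[nan_c]
    scores = _pc1_scores(x)
    sample_mean = x.mean(axis=1)
    if np.cov(scores, sample_mean)[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=intensities.sample_ids, name="acgh_pc1")


def method_concordance(m: pd.DataFrame) -> pd.DataFrame:
    """Pairwise r2 between method columns (pairwise-complete samples).

    Symmetric with unit diagonal; a pair sharing fewer than 3 samples is
    recorded missing. Note r2 is sign-blind: perfectly anticorrelated
    methods score 1.
    """
    methods = list(m.columns)
    out = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            pair = m[[a, b]].dropna()
            if len(pair) < 3:
                r2 = np.nan
            else:
                x, y = pair[a].to_numpy(), pair[b].to_numpy()
                if x.std() == 0 or y.std() == 0:
                    r2 = 0.0
                else:
                    r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
            out.loc[a, b] = out.loc[b, a] = r2
    return out


def integrate_methods(m: pd.DataFrame) -> pd.Series:
    """Single integrated copy-number score per sample.

    Each method column is standardized (so the result is invariant to
    per-method affine rescaling) after mean imputation of missing values;
    the first principal component of the sample x method matrix is the
    integrated score, sign-oriented to correlate positively with the ddPCR
    column (falling back to the first column). With a single method, the
    standardized values are returned unchanged.
    """
    if m.shape[0] < 2:
        raise DataError("need >= 2 samples to integrate")
    work = m.copy().astype(float)
    dropped = [c for c in work.columns if work[c].std(skipna=True) == 0
               or work[c].dropna().empty]
    if dropped:
        warnings.warn(
            f"constant/empty method(s) dropped from integration: {dropped}",
            stacklevel=2,
        )
        work = work.drop(columns=dropped)
    if work.shape[1] == 0:
        raise DataError("no usable methods to integrate")
    work = work.fillna(work.mean())
    z = (work - work.mean()) / work.std()
    if z.shape[1] == 1:
        return pd.Series(z.iloc[:, 0].to_numpy(), index=m.index, name="integrated")
    scores = _pc1_scores(z.to_numpy())
    anchor_col = "ddpcr" if "ddpcr" in z.columns else z.columns[0]
    if np.cov(scores, z[anchor_col].to_numpy())[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=m.index, name="integrated")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def call_integers(
    score: pd.Series,
    m: pd.DataFrame | None = None,
    anchor_method: str = "ddpcr",
) -> IntegerCallSet:
    """Integer copy-number calls from an integrated score.

    The score is affine-mapped onto the anchor method's scale by least
    squares and rounded to the nearest integer (ties round half away from
    zero). Without the anchor column, the score is rounded as-is and the
    call set is flagged low-confidence.
    """
    score = score.astype(float)
    low_confidence = False
    if m is not None and anchor_method in m.columns:
        anchor = m[anchor_method].astype(float)
        shared = score.index.intersection(anchor.dropna().index)
        if len(shared) < 2:
            raise DataError("need >= 2 samples with anchor values")
        a, b = np.polyfit(
            score.loc[shared].to_numpy(), anchor.loc[shared].to_numpy(), 1
        )
        mapped = a * score + b
        used_anchor: str | None = anchor_method
    else:
        warnings.warn(
            f"anchor method {anchor_method!r} unavailable; rounding the "
            "integrated score directly (low confidence)",
            stacklevel=2,
        )
        mapped = score
        used_anchor = None
        low_confidence = True
    mapped_values = mapped.to_numpy()
    rounded = _round_half_away(mapped_values)
    rounded = np.maximum(rounded, 0.0)
    confidence = 1.0 - 2.0 * np.abs(mapped_values - _round_half_away(mapped_values))
    confidence = np.clip(confidence, 0.0, 1.0)
    return IntegerCallSet(
        sample_ids=[str(s) for s in score.index],
        cn=rounded.astype(np.int64),
        confidence=confidence,
        anchor_method=used_anchor,
        mapped_score=mapped_values,
        low_confidence=low_confidence,
    )
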