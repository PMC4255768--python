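"""Genomic intervals, tiling-probe sets and probe-by-sample intensity matrices.

Coordinates are 0-based half-open throughout (BED convention). Human-facing
reports elsewhere in the package print 1-based inclusive coordinates with an
explicit label; these containers never do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise DataError(f"negative interval start: {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_point(self, pos: float) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class ProbeSet:
    """Tiling-array probes, sorted by (chrom, start), with unique ids.

    Stored as parallel arrays; ``to_frame`` gives the equivalent BED4 table.
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    probe_ids: np.ndarray

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        n = len(self.probe_ids)
        if not (len(self.chroms) == len(self.starts) == len(self.ends) == n):
            raise DataError("probe arrays have mismatched lengths")
        if np.any(self.ends <= self.starts):
            bad = int(np.nonzero(self.ends <= self.starts)[0][0])
            raise DataError(
                f"probe {self.probe_ids[bad]!r} has end <= start "
                f"({self.starts[bad]}..{self.ends[bad]})"
            )
        if len(set(self.probe_ids)) != n:
            raise DataError("probe ids are not unique")
        order = np.lexsort((self.starts, self.chroms.astype(str)))
        if not np.array_equal(order, np.arange(n)):
            raise DataError("probes must be sorted by (chrom, start)")

    def __len__(self) -> int:
        return len(self.probe_ids)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "probe_id": self.probe_ids,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeSet":
        df = df.sort_values(["chrom", "start"], kind="stable")
        return cls(
            df["chrom"].to_numpy(),
            df["start"].to_numpy(),
            df["end"].to_numpy(),
            df["probe_id"].to_numpy(),
        )

    def in_interval(self, interval: Interval) -> np.ndarray:
        """Boolean mask of probes whose midpoint lies inside ``interval``."""
        mid = self.midpoints
        return (
            (self.chroms == interval.chrom)
            & (mid >= interval.start)
            & (mid < interval.end)
        )

    def subset(self, mask: np.ndarray) -> "ProbeSet":
        return ProbeSet(
            self.chroms[mask], self.starts[mask], self.ends[mask], self.probe_ids[mask]
        )


@dataclass
class IntensityMatrix:
    """Per-probe, per-sample log2(test/reference) ratios; NaN marks missing."""

    probe_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise DataError(
                f"intensity matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if np.isinf(self.values).any():
            raise DataError("intensity matrix contains non-finite (inf) values")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.probe_ids, name="probe_id"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IntensityMatrix":
        return cls(df.index.to_numpy(), df.columns.to_numpy(), df.to_numpy(float))

    def subset_probes(self, mask: np.ndarray) -> "IntensityMatrix":
        return IntensityMatrix(self.probe_ids[mask], self.sample_ids, self.values[mask])
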