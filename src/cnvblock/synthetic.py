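"""Synthetic cohorts with the statistical structure of multiallelic tandem CNVs.

This module generates everything the downstream stages consume, so the whole
pipeline is testable without any array download: tiling probe sets, aCGH-like
log2-ratio matrices over a cohort carrying one contiguous CNV block (plus
decoy CNVs in the flanks whose copy numbers are independent of the block's),
replicated PRT and droplet-digital PCR runs, and tandem-paralog haplotype
pairs with separate paralog-divergence and allelic-diversity substitution
processes.

All randomness flows from one top-level integer seed through named
substreams (``cohort``, ``prt``, ``ddpcr``, ``sequences``); identical seed
and configuration reproduce cohorts bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assays import DdpcrRun, PRTRun
from .errors import ConfigurationError, DataError
from .genome import IntensityMatrix, Interval, ProbeSet
from .selection import (
    GENETIC_CODE,
    HaplotypeSet,
    PROXIMAL,
    DISTAL,
)

#: pseudocount used when a sample carries zero copies, so the emitted
#: log2 ratio is a large negative floor rather than -inf (arrays saturate;
#: the exact value is never used quantitatively downstream).
ZERO_CN_PSEUDOCOUNT = 0.05

_SUBSTREAMS = ("cohort", "prt", "ddpcr", "sequences")


def substreams(seed: int) -> dict[str, np.random.Generator]:
    """Named, independent random substreams derived from one top-level seed."""
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class NoiseModel:
    """Noise parameters of the simulated platforms.

    ``sd`` is the per-probe Gaussian noise of the log2 ratio; ``attenuation``
    scales the probe response to the underlying copy-number ratio (1.0 =
    fully responsive probes); ``prt_cv`` is the coefficient of variation of a
    single PRT replicate ratio; ``ddpcr_lambda_ref`` and ``ddpcr_droplets``
    set the reference-channel Poisson loading and droplets per read.
    """

    sd: float = 0.15
    attenuation: float = 1.0
    prt_cv: float = 0.05
    ddpcr_lambda_ref: float = 0.8
    ddpcr_droplets: int = 15000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError(f"noise sd must be >= 0, got {self.sd}")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ConfigurationError(
                f"attenuation must be in [0, 1], got {self.attenuation}"
            )
        if self.prt_cv < 0 or self.ddpcr_lambda_ref < 0:
            raise ConfigurationError("assay noise parameters must be >= 0")


@dataclass(frozen=True)
class DecoySpec:
    """A flanking CNV whose per-sample copy numbers are drawn independently
    of the main block's, emulating the repeat-rich flanks around a tandem
    CNV: probe-level correlation with block copy number is low there by
    construction."""

    interval: Interval
    cn_range: tuple[int, int] = (1, 4)


@dataclass(frozen=True)
class DropoutSpec:
    """A polymorphic internal sub-interval (e.g. a retroelement present in
    the reference but absent in some individuals) where a subset of carriers
    lose signal by ``delta`` log2 units."""

    interval: Interval
    n_carriers: int
    delta: float = 1.0


@dataclass(frozen=True)
class CohortConfig:
    """Full generative configuration of one cohort."""

    name: str
    region: Interval
    mean_spacing: float
    block: Interval
    cn_range: tuple[int, int]
    n_samples: int
    noise: NoiseModel = NoiseModel()
    decoys: tuple[DecoySpec, ...] = ()
    dropout: DropoutSpec | None = None
    reference_cn: int = 2
    assay_names: tuple[str, ...] = ("prt", "ddpcr")
    anchor_method: str = "ddpcr"

    def __post_init__(self) -> None:
        lo, hi = self.cn_range
        if lo < 0 or hi < lo:
            raise ConfigurationError(f"invalid copy-number range {self.cn_range}")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.reference_cn < 1:
            raise ConfigurationError("reference_cn must be >= 1")
        intervals = [self.block] + [d.interval for d in self.decoys]
        for i, a in enumerate(intervals):
            for b in intervals[i + 1 :]:
                if a.overlaps(b):
                    raise ConfigurationError(
                        f"block/decoy intervals overlap: {a} vs {b}"
                    )
        if self.dropout is not None:
            d = self.dropout.interval
            if not (self.block.start <= d.start and d.end <= self.block.end):
                raise ConfigurationError("dropout interval must lie inside the block")
            if self.dropout.n_carriers > self.n_samples:
                raise ConfigurationError("more dropout carriers than samples")


@dataclass
class CohortTruth:
    """Ground truth returned alongside a simulated cohort."""

    block: Interval
    sample_ids: list[str]
    cn: pd.Series  # diploid copy number at the block, per sample
    reference_cn: int = 2
    decoy_blocks: list[Interval] = field(default_factory=list)
    decoy_cn: list[pd.Series] = field(default_factory=list)
    dropout: DropoutSpec | None = None
    dropout_carriers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.cn < 0).any():
            raise DataError("copy numbers must be >= 0")


def make_probe_set(
    region: Interval,
    mean_spacing: float,
    seed=0,
    probe_length: int = 60,
    jitter_frac: float = 0.25,
    prefix: str = "probe",
) -> ProbeSet:
    """Tile ``region`` with probes at jittered ``mean_spacing``.

    With ``jitter_frac=0`` the tiling is exactly regular: ``n = floor(length
    / spacing)`` probes at starts ``region.start + i * spacing``.
    """
    if mean_spacing <= 0:
        raise ConfigurationError(f"mean_spacing must be positive, got {mean_spacing}")
    if not 0.0 <= jitter_frac <= 0.45:
        raise ConfigurationError("jitter_frac must be in [0, 0.45]")
    if region.length < 2 * mean_spacing:
        raise ConfigurationError(
            f"region length {region.length} too short for spacing {mean_spacing}"
        )
    rng = _as_rng(seed)
    n = int(region.length // mean_spacing)
    starts = region.start + np.arange(n) * mean_spacing
    if jitter_frac > 0:
        starts = starts + rng.uniform(
            -jitter_frac * mean_spacing, jitter_frac * mean_spacing, size=n
        )
    starts = np.sort(np.round(starts).astype(np.int64))
    starts = np.clip(starts, region.start, region.end - 1)
    length = min(probe_length, int(mean_spacing))
    ends = np.minimum(starts + length, region.end)
    ids = np.array([f"{prefix}_{i:06d}" for i in range(n)], dtype=object)
    return ProbeSet(np.full(n, region.chrom, dtype=object), starts, ends, ids)


def _expected_log2(cn: np.ndarray, reference_cn: int, attenuation: float) -> np.ndarray:
    cn = np.asarray(cn, dtype=float)
    num = np.where(cn == 0, cn + ZERO_CN_PSEUDOCOUNT, cn)
    den = float(reference_cn) if reference_cn > 0 else reference_cn + ZERO_CN_PSEUDOCOUNT
    den = np.where(cn == 0, reference_cn + ZERO_CN_PSEUDOCOUNT, den)
    return attenuation * np.log2(num / den)


def simulate_cohort(
    probes: ProbeSet, config: CohortConfig, rng=None
) -> tuple[IntensityMatrix, CohortTruth]:
    """Simulate a cohort of aCGH-like log2-ratio profiles.

    Probes whose midpoint falls in the true block respond with expectation
    ``attenuation * log2(cn_sample / cn_reference)``; probes in decoys with
    the decoy's independent copy numbers; all other probes have expectation
    zero. Gaussian noise of the configured sd is added everywhere.
    """
    rng = _as_rng(rng if rng is not None else config.noise.seed)
    nm = config.noise
    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    lo, hi = config.cn_range
    cn = pd.Series(
        rng.integers(lo, hi + 1, size=config.n_samples), index=sample_ids, name="cn"
    )

    expected = np.zeros((len(probes), config.n_samples))
    in_block = probes.in_interval(config.block)
    expected[in_block, :] = _expected_log2(
        cn.to_numpy(), config.reference_cn, nm.attenuation
    )[None, :]

    decoy_cns: list[pd.Series] = []
    for decoy in config.decoys:
        dlo, dhi = decoy.cn_range
        dcn = pd.Series(
            rng.integers(dlo, dhi + 1, size=config.n_samples),
            index=sample_ids,
            name="cn",
        )
        decoy_cns.append(dcn)
        mask = probes.in_interval(decoy.interval)
        expected[mask, :] = _expected_log2(
            dcn.to_numpy(), config.reference_cn, nm.attenuation
        )[None, :]

    carriers: list[str] = []
    if config.dropout is not None and config.dropout.n_carriers > 0:
        idx = rng.choice(
            config.n_samples, size=config.dropout.n_carriers, replace=False
        )
        carriers = [sample_ids[i] for i in sorted(idx)]
        mask = probes.in_interval(config.dropout.interval)
        expected[np.ix_(mask, sorted(idx))] -= config.dropout.delta

    values = expected
    if nm.sd > 0:
        values = values + rng.normal(0.0, nm.sd, size=expected.shape)

    matrix = IntensityMatrix(probes.probe_ids, np.array(sample_ids, dtype=object), values)
    truth = CohortTruth(
        block=config.block,
        sample_ids=sample_ids,
        cn=cn,
        reference_cn=config.reference_cn,
        decoy_blocks=[d.interval for d in config.decoys],
        decoy_cn=decoy_cns,
        dropout=config.dropout,
        dropout_carriers=carriers,
    )
    return matrix, truth


def simulate_prt(
    true_cn: int,
    n_replicates: int = 5,
    noise_cv: float = 0.05,
    rng=None,
    reference_cn: int = 2,
    sample_id: str = "sample",
    reference_area: float = 10000.0,
) -> PRTRun:
    """Simulate one PRT run of replicate test/reference peak-area pairs.

    Replicate ratios are ``true_cn / reference_cn`` times multiplicative
    lognormal noise with unit mean and coefficient of variation ``noise_cv``,
    so the expectation of each replicate ratio is exactly the true ratio.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    if noise_cv < 0:
        raise ConfigurationError("noise_cv must be >= 0")
    rng = _as_rng(rng)
    base = true_cn / reference_cn
    if noise_cv == 0:
        ratios = np.full(n_replicates, base)
    else:
        sigma = math.sqrt(math.log1p(noise_cv**2))
        ratios = base * rng.lognormal(-0.5 * sigma**2, sigma, size=n_replicates)
    replicates = [(reference_area * r, reference_area) for r in ratios]
    return PRTRun(sample_id=sample_id, replicates=replicates)


def simulate_ddpcr(
    true_cn: int,
    n_droplets: int = 15000,
    molecules_per_droplet_ref: float = 0.8,
    rng=None,
    reference_cn: int = 2,
    sample_id: str = "sample",
) -> DdpcrRun:
    """Simulate one duplex ddPCR read under Poisson droplet loading.

    The test channel is loaded at ``lambda_ref * true_cn / reference_cn``;
    droplet positivity in each channel is Binomial(n_droplets, 1 - e^-lambda).
    A read in which every droplet is positive in a channel is flagged
    saturated (its concentration is unbounded below by the data).
    """
    if n_droplets < 1:
        raise ConfigurationError("n_droplets must be >= 1")
    if molecules_per_droplet_ref < 0:
        raise ConfigurationError("lambda_ref must be >= 0")
    rng = _as_rng(rng)
    lam_ref = molecules_per_droplet_ref
    lam_test = lam_ref * true_cn / reference_cn
    p_test = 1.0 - math.exp(-lam_test)
    p_ref = 1.0 - math.exp(-lam_ref)
    n_test = int(rng.binomial(n_droplets, p_test))
    n_ref = int(rng.binomial(n_droplets, p_ref))
    return DdpcrRun(
        sample_id=sample_id,
        n_droplets=n_droplets,
        n_test_positive=n_test,
        n_ref_positive=n_ref,
        saturated=(n_test == n_droplets or n_ref == n_droplets),
    )


# ---------------------------------------------------------------------------
# paralog / allele haplotype generator
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


def random_cds(n_codons: int, rng=None) -> str:
    """A random in-frame coding sequence with no stop codons."""
    rng = _as_rng(rng)
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon not in _STOPS:
            codons.append(codon)
    return "".join(codons)


def _single_changes(codon: str) -> list[tuple[int, str, bool]]:
    """All (position, alt_base, is_nonsynonymous) single-nucleotide changes
    of ``codon`` that do not create a stop codon."""
    aa = GENETIC_CODE[codon]
    out = []
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutated = codon[:pos] + alt + codon[pos + 1 :]
            if mutated in _STOPS:
                continue
            out.append((pos, alt, GENETIC_CODE[mutated] != aa))
    return out


@dataclass
class SubstitutionRecord:
    """One placed substitution with its truth labels."""

    kind: str  # "paralog" (divergence) or "allele" (diversity)
    codon_index: int
    site: int  # 0-based nucleotide position in the CDS
    ref_base: str
    alt_base: str
    nonsynonymous: bool


@dataclass
class HaplotypeTruth:
    """Truth labels of a simulated haplotype set.

    ``expected_divergence`` / ``expected_diversity`` give the (nonsyn, syn)
    cell values the partitioning convention recovers at zero homoplasy:
    divergence is the per-haplotype paralog difference count averaged over
    haplotypes, so each polymorphic site (carried by one haplotype at one
    position) also contributes 1/2 to divergence; diversity is the
    between-haplotype difference count summed over paralog positions.
    """

    records: list[SubstitutionRecord]

    @property
    def paralog_counts(self) -> tuple[int, int]:
        n = sum(1 for r in self.records if r.kind == "paralog" and r.nonsynonymous)
        s = sum(1 for r in self.records if r.kind == "paralog" and not r.nonsynonymous)
        return n, s

    @property
    def allele_counts(self) -> tuple[int, int]:
        n = sum(1 for r in self.records if r.kind == "allele" and r.nonsynonymous)
        s = sum(1 for r in self.records if r.kind == "allele" and not r.nonsynonymous)
        return n, s

    @property
    def expected_divergence(self) -> tuple[float, float]:
        pn, ps = self.paralog_counts
        an, asyn = self.allele_counts
        return pn + 0.5 * an, ps + 0.5 * asyn

    @property
    def expected_diversity(self) -> tuple[float, float]:
        return self.allele_counts


def simulate_paralog_haplotypes(
    ancestral_cds: str,
    paralog_subs: int,
    allelic_subs: int,
    nonsyn_fraction_paralog: float = 0.5,
    nonsyn_fraction_allele: float = 0.5,
    seed=0,
    haplotype_ids: Sequence[str] = ("hap1", "hap2"),
) -> tuple[HaplotypeSet, HaplotypeTruth]:
    """Two haplotypes each carrying a proximal and a distal tandem paralog.

    Paralog-divergence substitutions are fixed differences: they are applied
    to the distal copy of both haplotypes. Allelic-diversity substitutions
    are polymorphisms: each is applied to the second haplotype at the
    proximal copy only (mirroring data where all allelic variation is
    between the proximal copies and the distal copies are identical). Each
    substitution occupies its own codon and its synonymous/nonsynonymous
    class is drawn Bernoulli(nonsyn_fraction); realized classes are returned
    as truth labels.
    """
    cds = ancestral_cds.upper()
    if len(cds) % 3 != 0:
        raise DataError("ancestral CDS length must be divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if any(c in _STOPS for c in codons[:-1]):
        raise DataError("ancestral CDS contains an internal stop codon")
    rng = _as_rng(seed)

    free = set(range(len(codons)))
    if codons[-1] in _STOPS:
        free.discard(len(codons) - 1)
    records: list[SubstitutionRecord] = []

    def place(kind: str, nonsyn: bool) -> SubstitutionRecord:
        candidates = []
        for ci in free:
            for pos, alt, is_nonsyn in _single_changes(codons[ci]):
                if is_nonsyn == nonsyn:
                    candidates.append((ci, pos, alt))
        if not candidates:
            cls = "nonsynonymous" if nonsyn else "synonymous"
            raise ConfigurationError(
                f"requested substitution count exceeds available {cls} sites"
            )
        ci, pos, alt = candidates[rng.integers(len(candidates))]
        free.discard(ci)
        rec = SubstitutionRecord(
            kind=kind,
            codon_index=ci,
            site=3 * ci + pos,
            ref_base=codons[ci][pos],
            alt_base=alt,
            nonsynonymous=nonsyn,
        )
        records.append(rec)
        return rec

    for _ in range(paralog_subs):
        place("paralog", bool(rng.random() < nonsyn_fraction_paralog))
    for _ in range(allelic_subs):
        place("allele", bool(rng.random() < nonsyn_fraction_allele))

    def apply(seq: str, recs: list[SubstitutionRecord]) -> str:
        chars = list(seq)
        for r in recs:
            chars[r.site] = r.alt_base
        return "".join(chars)

    paralog_recs = [r for r in records if r.kind == "paralog"]
    allele_recs = [r for r in records if r.kind == "allele"]
    h1, h2 = haplotype_ids
    distal_seq = apply(cds, paralog_recs)
    sequences = {
        (h1, PROXIMAL): cds,
        (h1, DISTAL): distal_seq,
        (h2, PROXIMAL): apply(cds, allele_recs),
        (h2, DISTAL): distal_seq,
    }
    return HaplotypeSet(sequences=sequences), HaplotypeTruth(records=records)


def simulate_method_matrix(
    truth_cn: Mapping[str, int] | pd.Series,
    methods: Sequence[str] = ("acgh", "prt", "ddpcr"),
    noise_sd: float = 0.15,
    rng=None,
) -> pd.DataFrame:
    """Noisy continuous copy-number estimates per sample x method, for
    integration tests: each method reports truth plus independent Gaussian
    noise on the diploid copy-number scale."""
    rng = _as_rng(rng)
    cn = pd.Series(truth_cn, dtype=float)
    data = {
        m: cn + rng.normal(0.0, noise_sd, size=len(cn)) for m in methods
    }
    return pd.DataFrame(data, index=cn.index)
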