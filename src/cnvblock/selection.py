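"""Paralog-vs-allele selection analysis of tandem-duplicate coding sequences.

When a gene exists as two tandem paralogs carried in cis on a haplotype,
coding variation partitions into divergence (differences between the two
paralog positions within a haplotype) and diversity (differences between
haplotypes at the same paralog position). A McDonald-Kreitman 2x2 table of
{divergence, diversity} x {nonsynonymous, synonymous} counts, corrected for
multiple hits with the Jukes-Cantor model, tests whether amino-acid-changing
divergence between the paralogs is in excess of neutral expectation -- the
signature of positive selection acting after the duplication.

Codon differences are counted Nei-Gojobori style: multi-difference codons
are classified by averaging over all minimal substitution pathways, and
synonymous/nonsynonymous site totals come from the per-codon degeneracy
tally on the reference sequence.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from Bio import Align
from Bio.Data.CodonTable import standard_dna_table

from .errors import DataError, SaturationError

PROXIMAL = "proximal"
DISTAL = "distal"

#: codon -> amino acid (one letter), stops mapped to "*"
GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    GENETIC_CODE[_stop] = "*"

_BASES = "ACGT"


@dataclass
class HaplotypeSet:
    """Coding sequences keyed by (haplotype_id, paralog_position).

    Paralog positions are "proximal" and "distal"; optional ``labels`` carry
    a variant name per sequence (e.g. a named protein variant).
    """

    sequences: dict[tuple[str, str], str]
    labels: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise DataError("empty haplotype set")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise DataError(f"sequences have unequal lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise DataError(f"sequence length {length} not divisible by 3")
        self.sequences = {
            key: seq.upper() for key, seq in self.sequences.items()
        }
        for key, seq in self.sequences.items():
            codons = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
            if any(GENETIC_CODE.get(c, "X") == "*" for c in codons):
                raise DataError(f"sequence {key} contains an internal stop codon")

    @property
    def haplotype_ids(self) -> list[str]:
        return sorted({h for h, _ in self.sequences})

    def positions_of(self, haplotype_id: str) -> list[str]:
        return [p for h, p in self.sequences if h == haplotype_id]

    def complete_haplotypes(self) -> list[str]:
        """Haplotypes carrying both paralog positions."""
        return [
            h
            for h in self.haplotype_ids
            if {PROXIMAL, DISTAL} <= set(self.positions_of(h))
        ]


# ---------------------------------------------------------------------------
# codon difference classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonDiff:
    codon_index: int
    codon_a: str
    codon_b: str
    nonsyn: float
    syn: float


def _codon_paths(codon_a: str, codon_b: str) -> list[list[tuple[str, str]]]:
    """All minimal substitution pathways from codon_a to codon_b, as lists of
    (from_codon, to_codon) single-base steps."""
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    paths = []
    for order in itertools.permutations(diff_positions):
        steps = []
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            steps.append((current, nxt))
            current = nxt
        paths.append(steps)
    return paths


def _classify_codon(codon_a: str, codon_b: str, index: int) -> CodonDiff:
    paths = _codon_paths(codon_a, codon_b)
    # exclude pathways passing through a stop codon unless every pathway does
    no_stop = [
        p
        for p in paths
        if all(GENETIC_CODE[b] != "*" for _, b in p[:-1])
    ]
    usable = no_stop or paths
    nonsyn = syn = 0.0
    for path in usable:
        for frm, to in path:
            if GENETIC_CODE[frm] == GENETIC_CODE[to]:
                syn += 1.0
            else:
                nonsyn += 1.0
    k = len(usable)
    return CodonDiff(index, codon_a, codon_b, nonsyn / k, syn / k)


def classify_nuc_diffs(
    cds_a: str, cds_b: str
) -> tuple[float, float, list[CodonDiff]]:
    """Pathway-averaged (nonsynonymous, synonymous) difference counts.

    Codons with one difference are classified directly; codons with several
    are averaged over all minimal substitution pathways (pathways through
    stop codons are excluded when an alternative exists), contributing
    fractional counts. Symmetric in its arguments.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise DataError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    if len(a) % 3 != 0:
        raise DataError(f"length {len(a)} breaks the reading frame")
    records = []
    nonsyn = syn = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if ca == cb:
            continue
        if ca not in GENETIC_CODE or cb not in GENETIC_CODE:
            raise DataError(f"non-ACGT codon at codon {i // 3}: {ca!r}/{cb!r}")
        rec = _classify_codon(ca, cb, i // 3)
        records.append(rec)
        nonsyn += rec.nonsyn
        syn += rec.syn
    return nonsyn, syn, records


def count_sites(cds: str) -> tuple[float, float]:
    """Nei-Gojobori (nonsynonymous, synonymous) site totals for ``cds``.

    Per codon position, the synonymous site fraction is the fraction of the
    three possible base changes that preserve the amino acid; changes to
    stop codons count as nonsynonymous.
    """
    seq = cds.upper()
    if len(seq) % 3 != 0:
        raise DataError(f"length {len(seq)} not divisible by 3")
    syn_sites = 0.0
    n_codons = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon not in GENETIC_CODE:
            raise DataError(f"non-ACGT codon {codon!r} at codon {i // 3}")
        if GENETIC_CODE[codon] == "*":
            continue  # terminal stop carries no protein-coding sites
        n_codons += 1
        aa = GENETIC_CODE[codon]
        for pos in range(3):
            syn_here = sum(
                1
                for alt in _BASES
                if alt != codon[pos]
                and GENETIC_CODE[codon[:pos] + alt + codon[pos + 1 :]] == aa
            )
            syn_sites += syn_here / 3.0
    total = 3.0 * n_codons
    return total - syn_sites, syn_sites


def jc_correct(raw_count: float, sites: float) -> float:
    """Jukes-Cantor multiple-hit correction, scaled back to a count.

    With ``p = raw_count / sites``, the corrected per-site distance is
    ``d = -(3/4) ln(1 - (4/3) p)`` and the corrected count is ``sites * d``.
    Diverges as p approaches 3/4.
    """
    if sites <= 0:
        raise DataError(f"site total must be positive, got {sites}")
    if raw_count < 0:
        raise DataError("raw count must be >= 0")
    p = raw_count / sites
    if p >= 0.75:
        raise SaturationError(
            f"difference proportion {p:.3f} >= 3/4: Jukes-Cantor correction diverges"
        )
    return sites * (-0.75 * math.log1p(-4.0 * p / 3.0))


# ---------------------------------------------------------------------------
# partitioning and the McDonald-Kreitman test
# ---------------------------------------------------------------------------


@dataclass
class MKCounts:
    """The 2x2 divergence/diversity x nonsyn/syn table, raw and JC-corrected.

    Divergence cells average the within-haplotype paralog comparisons over
    haplotypes; diversity cells average the between-haplotype comparisons
    within each paralog position and sum over positions. Each cell is
    corrected on its own class site denominator.
    """

    divergence_nonsyn: float
    divergence_syn: float
    diversity_nonsyn: float
    diversity_syn: float
    nonsyn_sites: float
    syn_sites: float
    divergence_nonsyn_corrected: float = 0.0
    divergence_syn_corrected: float = 0.0
    diversity_nonsyn_corrected: float = 0.0
    diversity_syn_corrected: float = 0.0

    def raw_table(self) -> np.ndarray:
        return np.array(
            [
                [self.divergence_nonsyn, self.divergence_syn],
                [self.diversity_nonsyn, self.diversity_syn],
            ]
        )

    def corrected_table(self) -> np.ndarray:
        return np.array(
            [
                [self.divergence_nonsyn_corrected, self.divergence_syn_corrected],
                [self.diversity_nonsyn_corrected, self.diversity_syn_corrected],
            ]
        )


def partition_variation(h: HaplotypeSet, jc: bool = True) -> MKCounts:
    """Partition coding variation into the MK divergence/diversity table.

    Haplotypes missing a paralog position are excluded with a warning. Site
    denominators are tallied on the first complete haplotype's proximal
    sequence; the JC correction is applied per cell when ``jc`` is true.
    """
    complete = h.complete_haplotypes()
    skipped = set(h.haplotype_ids) - set(complete)
    if skipped:
        warnings.warn(
            f"haplotypes missing a paralog position excluded: {sorted(skipped)}",
            stacklevel=2,
        )
    if len(complete) < 2:
        raise DataError(
            "need >= 2 haplotypes carrying both paralog positions, "
            f"got {len(complete)}"
        )

    div_n = div_s = 0.0
    for hap in complete:
        n, s, _ = classify_nuc_diffs(
            h.sequences[(hap, PROXIMAL)], h.sequences[(hap, DISTAL)]
        )
        div_n += n
        div_s += s
    div_n /= len(complete)
    div_s /= len(complete)

    pol_n = pol_s = 0.0
    for position in (PROXIMAL, DISTAL):
        pairs = list(itertools.combinations(complete, 2))
        pn = ps = 0.0
        for ha, hb in pairs:
            n, s, _ = classify_nuc_diffs(
                h.sequences[(ha, position)], h.sequences[(hb, position)]
            )
            pn += n
            ps += s
        pol_n += pn / len(pairs)
        pol_s += ps / len(pairs)

    ref = h.sequences[(complete[0], PROXIMAL)]
    nonsyn_sites, syn_sites = count_sites(ref)

    counts = MKCounts(
        divergence_nonsyn=div_n,
        divergence_syn=div_s,
        diversity_nonsyn=pol_n,
        diversity_syn=pol_s,
        nonsyn_sites=nonsyn_sites,
        syn_sites=syn_sites,
    )
    if jc:
        counts.divergence_nonsyn_corrected = jc_correct(div_n, nonsyn_sites)
        counts.divergence_syn_corrected = jc_correct(div_s, syn_sites)
        counts.diversity_nonsyn_corrected = jc_correct(pol_n, nonsyn_sites)
        counts.diversity_syn_corrected = jc_correct(pol_s, syn_sites)
    else:
        counts.divergence_nonsyn_corrected = div_n
        counts.divergence_syn_corrected = div_s
        counts.diversity_nonsyn_corrected = pol_n
        counts.diversity_syn_corrected = pol_s
    return counts


@dataclass
class MKResult:
    table: np.ndarray  # integer 2x2 actually tested
    p_value: float
    neutrality_index: float | None
    direction: str  # "positive", "negative", or "neutral"
    informative: bool


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def mk_test(counts: MKCounts | np.ndarray, use_corrected: bool = True) -> MKResult:
    """Two-sided Fisher exact test on the MK 2x2 table.

    Corrected (real-valued) cells are rounded half away from zero to
    integers before testing. The neutrality index is
    ``(diversity_N / diversity_S) / (divergence_N / divergence_S)``; NI < 1
    (excess nonsynonymous divergence) flags positive selection, NI > 1
    negative/balancing. An all-zero row or column is uninformative: p = 1.
    """
    if isinstance(counts, MKCounts):
        raw = counts.corrected_table() if use_corrected else counts.raw_table()
    else:
        raw = np.asarray(counts, dtype=float)
        if raw.shape != (2, 2):
            raise DataError(f"MK table must be 2x2, got shape {raw.shape}")
    table = np.array([[_round_half_away(v) for v in row] for row in raw])
    if (table < 0).any():
        raise DataError("MK table cells must be >= 0")

    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return MKResult(
            table=table, p_value=1.0, neutrality_index=None,
            direction="neutral", informative=False,
        )

    _, p = stats.fisher_exact(table, alternative="two-sided")
    (dn, ds), (pn, ps) = table
    ni = None
    if ds > 0 and dn > 0 and ps > 0:
        ni = (pn / ps) / (dn / ds)
    if ni is None or math.isclose(ni, 1.0):
        direction = "neutral"
    elif ni < 1.0:
        direction = "positive"
    else:
        direction = "negative"
    return MKResult(
        table=table, p_value=float(min(p, 1.0)), neutrality_index=ni,
        direction=direction, informative=True,
    )


# ---------------------------------------------------------------------------
# variant naming and pairwise identity
# ---------------------------------------------------------------------------


def translate(cds: str) -> str:
    seq = cds.upper()
    if len(seq) % 3 != 0:
        raise DataError(f"length {len(seq)} not divisible by 3")
    return "".join(GENETIC_CODE[seq[i : i + 3]] for i in range(0, len(seq), 3))


def diff_aa(cds_variant: str, cds_reference: str) -> list[str]:
    """Amino-acid change labels like "G45R" (reference residue first,
    1-based numbering from the initiator Met of the reference).

    A premature stop in the variant is labelled with "X" at its position and
    a warning is issued.
    """
    if len(cds_variant) != len(cds_reference):
        raise DataError("variant and reference CDS lengths differ")
    prot_var = translate(cds_variant)
    prot_ref = translate(cds_reference)
    labels = []
    for i, (ref_aa, var_aa) in enumerate(zip(prot_ref, prot_var), start=1):
        if ref_aa == var_aa:
            continue
        if var_aa == "*" and i < len(prot_ref):
            labels.append(f"{ref_aa}{i}X")
            warnings.warn(
                f"premature stop at residue {i} in variant", stacklevel=2
            )
        elif ref_aa == "*" or var_aa == "*":
            continue  # difference at the terminal stop codon is not a residue change
        else:
            labels.append(f"{ref_aa}{i}{var_aa}")
    return labels


#: declared default global-alignment parameters: match/mismatch/open/extend
ALIGN_MATCH = 1.0
ALIGN_MISMATCH = -1.0
ALIGN_GAP_OPEN = -5.0
ALIGN_GAP_EXTEND = -1.0


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = ALIGN_MATCH
    aligner.mismatch_score = ALIGN_MISMATCH
    aligner.open_gap_score = ALIGN_GAP_OPEN
    aligner.extend_gap_score = ALIGN_GAP_EXTEND
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent nucleotide identity from a global affine-gap alignment.

    Identity = matched columns / aligned columns (gap columns count as
    non-matches), as a percent rounded to one decimal place.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if not a or not b:
        raise DataError("cannot align an empty sequence")
    alignment = _aligner().align(a, b)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return round(100.0 * counts.identities / columns, 1)
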