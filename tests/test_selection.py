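"""Codon difference classification, Jukes-Cantor correction, variation
partitioning, the McDonald-Kreitman test (against an exact-Fraction
hypergeometric enumeration oracle) and pairwise identity (against an
independent affine-gap dynamic-programming oracle)."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from cnvblock.errors import DataError, SaturationError
from cnvblock.selection import (
    DISTAL,
    GENETIC_CODE,
    PROXIMAL,
    HaplotypeSet,
    classify_nuc_diffs,
    count_sites,
    diff_aa,
    jc_correct,
    mk_test,
    pairwise_identity,
    partition_variation,
)
from cnvblock.synthetic import random_cds, simulate_paralog_haplotypes


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def oracle_codon_counts(ca, cb):
    """Independent pathway-averaging: enumerate substitution orders."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    paths = []
    for order in itertools.permutations(diffs):
        cur, steps = ca, []
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            steps.append((cur, nxt))
            cur = nxt
        if all(GENETIC_CODE[c] != "*" for _, c in steps[:-1]):
            paths.append(steps)
    if not paths:
        return None  # all pathways pass through stops; implementation keeps them
    n = s = 0.0
    for p in paths:
        for frm, to in p:
            if GENETIC_CODE[frm] == GENETIC_CODE[to]:
                s += 1
            else:
                n += 1
    return n / len(paths), s / len(paths)


def oracle_fisher_two_sided(table):
    """Exact two-sided Fisher probability by rational hypergeometric
    enumeration: sum of P(t) over tables with P(t) <= P(observed)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k):
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1))

    p_obs = pmf(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = pmf(k)
        if p <= p_obs:
            total += p
    return float(total)


def oracle_affine_alignment_identity(a, b, match=1, mismatch=-1, open_=-5, ext=-1):
    """Gotoh affine-gap global alignment with traceback; returns
    (score, percent identity over aligned columns)."""
    neg = float("-inf")
    la, lb = len(a), len(b)
    M = [[neg] * (lb + 1) for _ in range(la + 1)]
    X = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in b (consume a)
    Y = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = open_ + ext * (i - 1)
    for j in range(1, lb + 1):
        Y[0][j] = open_ + ext * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + ext, Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + ext, X[i][j - 1] + open_)
    # traceback counting matches and columns
    i, j = la, lb
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][i][j])
    score = {"M": M, "X": X, "Y": Y}[state][la][lb]
    matches = columns = 0
    while i > 0 or j > 0:
        columns += 1
        if state == "M":
            sub = match if a[i - 1] == b[j - 1] else mismatch
            if a[i - 1] == b[j - 1]:
                matches += 1
            prev = M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]
            target = M[i][j] - sub
            state = ("M", "X", "Y")[max(range(3), key=lambda k: (abs(prev[k] - target) < 1e-9, prev[k]))]
            i, j = i - 1, j - 1
        elif state == "X":
            val = X[i][j]
            if abs(val - (X[i - 1][j] + ext)) < 1e-9:
                state = "X"
            elif abs(val - (M[i - 1][j] + open_)) < 1e-9:
                state = "M"
            else:
                state = "Y"
            i -= 1
        else:
            val = Y[i][j]
            if abs(val - (Y[i][j - 1] + ext)) < 1e-9:
                state = "Y"
            elif abs(val - (M[i][j - 1] + open_)) < 1e-9:
                state = "M"
            else:
                state = "X"
            j -= 1
    return score, round(100.0 * matches / columns, 1)


# ---------------------------------------------------------------------------
# classify_nuc_diffs
# ---------------------------------------------------------------------------


class TestClassifyNucDiffs:
    def test_identical_sequences(self):
        n, s, recs = classify_nuc_diffs("ATGGCT", "ATGGCT")
        assert (n, s) == (0.0, 0.0) and recs == []

    def test_single_nonsynonymous_change(self):
        n, s, _ = classify_nuc_diffs("GGA", "AGA")  # Gly -> Arg
        assert (n, s) == (1.0, 0.0)

    def test_two_difference_codon_pathway_average(self):
        # TTA (Leu) vs CTG (Leu): both orders pass through Leu codons
        n, s, _ = classify_nuc_diffs("TTA", "CTG")
        expected = oracle_codon_counts("TTA", "CTG")
        assert (n, s) == expected == (0.0, 2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_codons_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bases = "ACGT"
        for _ in range(50):
            ca = "".join(rng.choice(list(bases), 3))
            cb = "".join(rng.choice(list(bases), 3))
            if "*" in (GENETIC_CODE[ca], GENETIC_CODE[cb]) or ca == cb:
                continue
            expected = oracle_codon_counts(ca, cb)
            if expected is None:
                continue
            n, s, _ = classify_nuc_diffs(ca, cb)
            assert (n, s) == pytest.approx(expected)
            # symmetry and conservation of the difference count
            n2, s2, _ = classify_nuc_diffs(cb, ca)
            assert (n2, s2) == pytest.approx((n, s))
            assert n + s == sum(x != y for x, y in zip(ca, cb))

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            classify_nuc_diffs("ATG", "ATGGCT")
        with pytest.raises(DataError):
            classify_nuc_diffs("ATGG", "ATGC")


class TestJukesCantor:
    def test_zero_raw_is_zero(self):
        assert jc_correct(0, 100) == 0.0

    def test_closed_form_example(self):
        assert jc_correct(10, 100) == pytest.approx(
            100 * (-0.75 * math.log(1 - 0.4 / 3)), rel=1e-12
        )
        assert round(jc_correct(10, 100), 2) == 10.73

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            jc_correct(75, 100)

    def test_correction_exceeds_raw_and_vanishes_at_low_p(self):
        assert jc_correct(20, 100) > 20
        raw = 1e-4 * 300
        assert jc_correct(raw, 300) / raw == pytest.approx(1.0, abs=1e-3)


# ---------------------------------------------------------------------------
# partition_variation
# ---------------------------------------------------------------------------


class TestPartitionVariation:
    def test_identical_sequences_yield_zero_table(self, ancestral_cds):
        h, _ = simulate_paralog_haplotypes(ancestral_cds, 0, 0, seed=0)
        counts = partition_variation(h)
        assert np.allclose(counts.raw_table(), 0.0)
        assert np.allclose(counts.corrected_table(), 0.0)

    @pytest.mark.parametrize("seed", [1, 7, 23])
    def test_generator_truth_round_trip(self, ancestral_cds, seed):
        h, truth = simulate_paralog_haplotypes(
            ancestral_cds, 6, 4,
            nonsyn_fraction_paralog=2 / 3, nonsyn_fraction_allele=0.25, seed=seed,
        )
        counts = partition_variation(h)
        assert (counts.divergence_nonsyn, counts.divergence_syn) == pytest.approx(
            truth.expected_divergence
        )
        assert (counts.diversity_nonsyn, counts.diversity_syn) == pytest.approx(
            truth.expected_diversity
        )

    def test_bac_style_haplotype_pair_partitioned(self, ancestral_cds):
        # two phase-resolved haplotypes, each carrying two tandem copies:
        # one haplotype pairs a 4-change variant with the reference variant,
        # the other a 3-change variant with the same reference
        h, _ = simulate_paralog_haplotypes(
            ancestral_cds, 3, 1, 1.0, 1.0, seed=3,
            haplotype_ids=("65I2", "243E20"),
        )
        counts = partition_variation(h)
        assert counts.divergence_nonsyn == pytest.approx(3.5)
        assert counts.diversity_nonsyn == pytest.approx(1.0)

    def test_incomplete_haplotype_excluded_with_warning(self, ancestral_cds):
        h, _ = simulate_paralog_haplotypes(ancestral_cds, 2, 2, seed=0)
        h.sequences[("hap3", PROXIMAL)] = h.sequences[("hap1", PROXIMAL)]
        with pytest.warns(UserWarning):
            counts = partition_variation(h)
        assert counts is not None

    def test_corrected_at_least_raw(self, ancestral_cds):
        h, _ = simulate_paralog_haplotypes(ancestral_cds, 12, 6, seed=9)
        c = partition_variation(h)
        assert (c.corrected_table() >= c.raw_table() - 1e-12).all()


# ---------------------------------------------------------------------------
# mk_test
# ---------------------------------------------------------------------------


class TestMkTest:
    def test_matches_enumeration_oracle_on_given_table(self):
        table = np.array([[10, 2], [2, 8]])
        result = mk_test(table, use_corrected=False)
        assert result.p_value == pytest.approx(
            oracle_fisher_two_sided(table), abs=1e-12
        )

    def test_random_tables_match_oracle(self, rng):
        for _ in range(300):
            table = rng.integers(0, 16, size=(2, 2))
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            result = mk_test(table, use_corrected=False)
            assert result.p_value == pytest.approx(
                oracle_fisher_two_sided(table), abs=1e-12
            ), f"table {table.tolist()}"

    def test_symmetric_table_is_null(self):
        result = mk_test(np.array([[5, 5], [5, 5]]), use_corrected=False)
        assert result.p_value == pytest.approx(1.0)
        assert result.neutrality_index == pytest.approx(1.0)
        assert result.direction == "neutral"

    def test_row_swap_leaves_p_unchanged(self):
        a = mk_test(np.array([[10, 2], [2, 8]]), use_corrected=False)
        b = mk_test(np.array([[2, 8], [10, 2]]), use_corrected=False)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_zero_margin_uninformative(self):
        result = mk_test(np.array([[0, 0], [3, 4]]), use_corrected=False)
        assert result.p_value == 1.0
        assert not result.informative
        assert result.direction == "neutral"

    def test_positive_selection_direction(self):
        result = mk_test(np.array([[15, 3], [2, 9]]), use_corrected=False)
        assert result.direction == "positive"
        assert result.neutrality_index < 1


# ---------------------------------------------------------------------------
# diff_aa and pairwise identity
# ---------------------------------------------------------------------------


class TestDiffAa:
    def test_identical_is_empty(self, ancestral_cds):
        assert diff_aa(ancestral_cds, ancestral_cds) == []

    def test_single_gly_to_arg_at_45(self):
        ref = "ATG" + "GCT" * 43 + "GGA" + "GCT" * 15  # Gly at residue 45
        var = ref[: 44 * 3] + "AGA" + ref[45 * 3 :]
        assert diff_aa(var, ref) == ["G45R"]

    def test_premature_stop_labelled_x(self):
        ref = "ATGGCTGCAGCT"
        var = "ATGTAAGCAGCT"
        with pytest.warns(UserWarning):
            labels = diff_aa(var, ref)
        assert labels == ["A2X"]

    def test_label_format(self, ancestral_cds):
        import re

        h, _ = simulate_paralog_haplotypes(
            ancestral_cds, 4, 0, nonsyn_fraction_paralog=1.0, seed=2
        )
        labels = diff_aa(
            h.sequences[("hap1", DISTAL)], h.sequences[("hap1", PROXIMAL)]
        )
        assert len(labels) == 4
        assert all(re.fullmatch(r"[A-Z]\d+[A-Z]", lab) for lab in labels)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        seq = random_cds(34, np.random.default_rng(0))[:100]
        assert pairwise_identity(seq, seq) == 100.0

    def test_single_substitution_in_100mer(self):
        a = random_cds(34, np.random.default_rng(1))[:100]
        b = a[:50] + ("A" if a[50] != "A" else "C") + a[51:]
        assert pairwise_identity(a, b) == 99.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(DataError):
            pairwise_identity("", "ACGT")

    def test_substitutions_plus_indel_match_dp_oracle(self):
        rng = np.random.default_rng(42)
        a = random_cds(67, rng)[:200]
        b = list(a)
        # 9 substitutions at well-separated positions
        for pos in (10, 30, 55, 80, 105, 130, 150, 170, 190):
            b[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[b[pos]]
        # one 3-bp deletion
        del b[60:63]
        b = "".join(b)
        _, expected = oracle_affine_alignment_identity(a, b)
        assert pairwise_identity(a, b) == expected
        # the analytic value for this construction: 200 columns, 188 matches
        assert expected == 94.0
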