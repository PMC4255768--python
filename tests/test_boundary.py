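"""Correlation-track boundary mapping, HMM segmentation (checked against an
exhaustive path-enumeration oracle) and the internal-dropout scan."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvblock.boundary import (
    HMMModel,
    call_block,
    dropout_scan,
    hmm_segment,
    probe_cn_r2,
)
from cnvblock.errors import ConfigurationError, DataError
from cnvblock.genome import IntensityMatrix, Interval, ProbeSet
from cnvblock.synthetic import make_probe_set, simulate_cohort

from conftest import small_config


def matrix_from(values, samples=None):
    values = np.asarray(values, dtype=float)
    probes = [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return IntensityMatrix(np.array(probes), np.array(samples), values)


def cn_series(values, samples=None):
    import pandas as pd

    samples = samples or [f"s{j}" for j in range(len(values))]
    return pd.Series(values, index=samples, dtype=float)


class TestProbeCnR2:
    def test_linear_probe_is_one(self):
        cn = cn_series([2, 3, 4, 5])
        m = matrix_from([[0.1 + 0.5 * v for v in cn]])
        track = probe_cn_r2(m, cn)
        assert track.r2[0] == pytest.approx(1.0)

    def test_constant_probe_is_zero_by_convention(self):
        cn = cn_series([2, 3, 4, 5])
        m = matrix_from([[0.7, 0.7, 0.7, 0.7]])
        assert probe_cn_r2(m, cn).r2[0] == 0.0

    def test_hand_computed_value(self):
        # x = (0.9, 1.1, 0.5, 1.6), y = (4, 4, 3, 5):
        # cov = 1.1, Sxx = 0.6275, Syy = 2 -> r2 = 1.21 / 1.255
        cn = cn_series([4, 4, 3, 5])
        m = matrix_from([[0.9, 1.1, 0.5, 1.6]])
        assert probe_cn_r2(m, cn).r2[0] == pytest.approx(1.21 / 1.255, rel=1e-12)

    def test_insufficient_overlap_masks_probe(self):
        cn = cn_series([2, 3, 4, 5])
        values = np.array([[0.5, np.nan, np.nan, 0.9], [0.1, 0.2, 0.3, 0.4]])
        track = probe_cn_r2(matrix_from(values), cn)
        assert np.isnan(track.r2[0]) and np.isfinite(track.r2[1])

    def test_too_few_samples_rejected(self):
        cn = cn_series([2, 3])
        with pytest.raises(DataError):
            probe_cn_r2(matrix_from([[0.1, 0.2]]), cn)

    @given(
        a=st.floats(0.1, 5), b=st.floats(-3, 3),
        c=st.floats(0.1, 5), d=st.floats(-3, 3),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b, c, d):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(5, 12))
        y = rng.normal(size=12)
        base = probe_cn_r2(matrix_from(x), cn_series(y)).r2
        scaled = probe_cn_r2(matrix_from(a * x + b), cn_series(c * y + d)).r2
        assert np.allclose(base, scaled, atol=1e-9)


class TestCallBlock:
    def _track_and_probes(self, r2):
        n = len(r2)
        probes = ProbeSet(
            np.array(["chrT"] * n),
            np.arange(n) * 100,
            np.arange(n) * 100 + 60,
            np.array([f"p{i}" for i in range(n)]),
        )
        from cnvblock.boundary import CorrelationTrack

        track = CorrelationTrack(
            probes.probe_ids, np.asarray(r2, dtype=float), np.full(n, 10)
        )
        return track, probes

    def test_noise_free_cohort_recovers_truth_block_exactly(self, mini_cohort):
        config, probes, matrix, truth = mini_cohort
        track = probe_cn_r2(matrix, truth.cn.astype(float))
        calls = call_block(track, probes, min_probes=5)
        assert len(calls) == 1
        in_block = np.nonzero(probes.in_interval(config.block))[0]
        assert calls[0].start == probes.starts[in_block[0]]
        assert calls[0].end == probes.ends[in_block[-1]]

    def test_gap_tolerance_bridges_internal_dip(self):
        r2 = [0.9] * 15 + [0.1] * 5 + [0.9] * 15
        track, probes = self._track_and_probes(r2)
        calls = call_block(track, probes, min_probes=10, max_gap_probes=20)
        assert len(calls) == 1
        assert calls[0].n_support == 30

    def test_gap_longer_than_tolerance_splits_runs(self):
        r2 = [0.9] * 12 + [0.1] * 6 + [0.9] * 12
        track, probes = self._track_and_probes(r2)
        calls = call_block(track, probes, min_probes=10, max_gap_probes=5)
        assert len(calls) == 2

    def test_min_probes_discards_small_runs(self):
        r2 = [0.9] * 3 + [0.0] * 30 + [0.9] * 12
        track, probes = self._track_and_probes(r2)
        calls = call_block(track, probes, min_probes=10, max_gap_probes=5)
        assert len(calls) == 1 and calls[0].n_support == 12

    def test_all_sub_threshold_returns_empty(self):
        track, probes = self._track_and_probes([0.2] * 30)
        assert call_block(track, probes) == []

    def test_decoy_with_independent_cn_not_merged(self):
        # a decoy CNV's probes correlate with its own copy numbers, not the
        # block's; with a wide separation the decoy is never merged
        import dataclasses

        from cnvblock.synthetic import DecoySpec

        config = dataclasses.replace(
            small_config(noise_sd=0.05, n_samples=20),
            decoys=(DecoySpec(Interval("chrT", 5_000, 20_000), (1, 4)),),
        )
        probes = make_probe_set(config.region, config.mean_spacing, seed=3)
        matrix, truth = simulate_cohort(probes, config, rng=11)
        track = probe_cn_r2(matrix, truth.cn.astype(float))
        calls = call_block(track, probes, min_probes=5)
        block = calls[0]
        assert block.start >= config.block.start - config.mean_spacing
        assert block.end <= config.block.end + config.mean_spacing


class TestHmmSegment:
    def test_flat_track_is_one_neutral_segment(self):
        seg = hmm_segment(np.zeros(50) + 0.01)
        assert seg.breakpoints == []
        assert set(seg.state_path) == {"neutral"}

    def test_step_track_places_single_loss_breakpoint(self, rng):
        values = np.concatenate(
            [rng.normal(0.0, 0.1, 40), rng.normal(-0.8, 0.1, 40)]
        )
        model = HMMModel(sds=np.array([0.1, 0.1, 0.1]))
        seg = hmm_segment(values, model)
        assert len(seg.breakpoints) == 1
        bp = seg.breakpoints[0]
        assert (bp.left_index, bp.right_index) == (39, 40)
        assert (bp.left_state, bp.right_state) == ("neutral", "loss")

    def test_breakpoint_reported_as_probe_interval(self):
        probes = ProbeSet(
            np.array(["chrT"] * 6),
            np.arange(6) * 1000,
            np.arange(6) * 1000 + 60,
            np.array([f"p{i}" for i in range(6)]),
        )
        values = [0.0, 0.0, 0.0, -1.0, -1.0, -1.0]
        seg = hmm_segment(values, probes=probes)
        assert seg.breakpoints[0].interval == (2000, 3060)

    def test_conservative_transitions_suppress_outlier_segments(self):
        values = np.zeros(31)
        values[15] = -1.3
        loose = HMMModel(transition_p=0.01)
        strict = HMMModel(transition_p=1e-6)
        assert len(hmm_segment(values, loose).breakpoints) == 2
        assert hmm_segment(values, strict).breakpoints == []

    def test_degenerate_equal_means_rejected(self):
        with pytest.raises(ConfigurationError):
            HMMModel(means=np.array([0.0, 0.0, 0.5]))

    def test_short_track_rejected(self):
        with pytest.raises(DataError):
            hmm_segment([0.1])

    @pytest.mark.parametrize("n_probes", [2, 5, 9, 12])
    def test_viterbi_matches_exhaustive_enumeration(self, n_probes, rng):
        """Viterbi path log-likelihood equals the brute-force maximum over
        all 3^n state paths."""
        model = HMMModel(transition_p=0.05)
        values = rng.normal(0, 0.8, size=n_probes)
        seg = hmm_segment(values, model)

        log_e = model.log_emission(values)
        log_t = model.log_transition()
        log_init = -np.log(len(model.states))

        def path_score(path):
            score = log_init + log_e[0, path[0]]
            for i in range(1, len(path)):
                score += log_t[path[i - 1], path[i]] + log_e[i, path[i]]
            return score

        best = max(
            itertools.product(range(3), repeat=n_probes), key=path_score
        )
        assert path_score(tuple(seg.path)) == pytest.approx(
            path_score(best), rel=1e-12
        )


class TestDropoutScan:
    def test_homogeneous_block_is_empty(self):
        values = np.zeros((30, 10)) + 0.5
        assert dropout_scan(matrix_from(values)) == []

    def test_generator_dropout_recovered_with_carriers(self, human_cfg):
        probes = make_probe_set(human_cfg.region, human_cfg.mean_spacing, seed=4)
        matrix, truth = simulate_cohort(probes, human_cfg, rng=9)
        block_mask = probes.in_interval(human_cfg.block)
        calls = dropout_scan(
            matrix.subset_probes(block_mask), probes.subset(block_mask)
        )
        assert len(calls) == 1
        assert sorted(calls[0].carriers) == sorted(truth.dropout_carriers)
        lo, hi = calls[0].interval
        assert abs(lo - human_cfg.dropout.interval.start) <= 2 * human_cfg.mean_spacing
        assert abs(hi - human_cfg.dropout.interval.end) <= 2 * human_cfg.mean_spacing

    def test_sub_threshold_delta_is_ignored(self):
        values = np.zeros((30, 10))
        values[10:15, :3] -= 0.3  # below the default 0.5 threshold
        assert dropout_scan(matrix_from(values)) == []
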