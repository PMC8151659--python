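"""Spatiotemporal stride feature computations."""

import math

import numpy as np
import pytest

from vrgait.event_detection import GaitCycle, GaitEvent
from vrgait.features import (
    compute_stride_features,
    phase_percentages,
    stride_length,
    stride_time,
    stride_velocity,
    stride_width,
)


def _cycle(t_hs_prev, t_to, t_hs_cur, foot="left", idxs=(0, 1, 2)):
    return GaitCycle(
        foot,
        GaitEvent("HS", foot, t_hs_prev, idxs[0]),
        GaitEvent("TO", foot, t_to, idxs[1]),
        GaitEvent("HS", foot, t_hs_cur, idxs[2]),
    )


class TestElementaryFeatures:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0, 0), (1.20, 0.10), math.hypot(1.20, 0.10)),
            ((0.3, -0.2), (0.3, -0.2), 0.0),
            ((0, 0), (0, 0.5), 0.5),
        ],
    )
    def test_stride_length(self, a, b, expected):
        assert stride_length(a, b) == pytest.approx(expected, abs=1e-12)

    def test_stride_time(self):
        assert stride_time(10.0, 11.1) == pytest.approx(1.1)
        assert stride_time(0.0, 1 / 90) == pytest.approx(1 / 90)
        with pytest.raises(ValueError):
            stride_time(2.0, 2.0)

    def test_stride_width_midline_case(self):
        # same-foot strikes at (0,0)->(1,0), contralateral at the midline:
        # d^2 = 0.25 + 0.0144, SW = sqrt(d^2 - 0.25) = 0.12
        sw, valid = stride_width((1.0, 0.0), (0.5, 0.12), 1.0)
        assert valid and sw == pytest.approx(0.12, abs=1e-12)

    def test_stride_width_collinear_is_zero(self):
        sw, valid = stride_width((1.0, 0.0), (0.5, 0.0), 1.0)
        assert valid and sw == pytest.approx(0.0, abs=1e-9)

    def test_stride_width_negative_radicand_flagged(self):
        sw, valid = stride_width((1.0, 0.0), (0.9, 0.0), 1.0)
        assert not valid and math.isnan(sw)

    def test_stride_width_requires_positive_sl(self):
        with pytest.raises(ValueError):
            stride_width((1.0, 0.0), (0.5, 0.1), 0.0)

    def test_stride_velocity(self):
        assert stride_velocity(1.20416, 1.1) == pytest.approx(1.09469, abs=1e-5)
        assert stride_velocity(0.0, 1.0) == 0.0
        with pytest.raises(ValueError):
            stride_velocity(1.0, 0.0)

    @pytest.mark.parametrize(
        "t_to, expected", [(0.66, (60.0, 40.0)), (0.55, (50.0, 50.0))]
    )
    def test_phase_percentages(self, t_to, expected):
        stc, swc = phase_percentages(_cycle(0.0, t_to, 1.10))
        assert (stc, swc) == pytest.approx(expected, abs=1e-9)

    def test_phase_percentages_sum_to_100(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            hs0 = rng.uniform(0, 100)
            to = hs0 + rng.uniform(0.3, 0.9)
            hs1 = to + rng.uniform(0.3, 0.9)
            stc, swc = phase_percentages(_cycle(hs0, to, hs1))
            assert stc + swc == pytest.approx(100.0, abs=1e-9)


class TestStrideWidthOracle:
    def test_matches_point_to_line_distance_on_midpoint_geometries(self):
        # when the contralateral heel projects onto the midpoint of the
        # same-foot HS segment, the printed formula equals the perpendicular
        # point-to-line distance
        rng = np.random.default_rng(11)
        for _ in range(200):
            a = rng.uniform(-5, 5, 2)
            direction = rng.normal(size=2)
            direction /= np.linalg.norm(direction)
            sl = rng.uniform(0.5, 2.0)
            b = a + sl * direction
            mid = (a + b) / 2.0
            perp = np.array([-direction[1], direction[0]])
            w = rng.uniform(0.0, 0.4)
            contra = mid + w * perp * rng.choice([-1.0, 1.0])

            sw, valid = stride_width(b, contra, sl)
            # independent oracle: 2D cross-product point-to-line distance
            ab, ac = b - a, contra - a
            d_oracle = abs(ab[0] * ac[1] - ab[1] * ac[0]) / np.linalg.norm(ab)
            assert valid
            assert sw == pytest.approx(d_oracle, abs=1e-9)


class TestComputeStrideFeatures:
    def test_noiseless_trial_recovers_truth(self, noiseless_trial, noiseless_result):
        spec, trial = noiseless_trial
        feats = noiseless_result.features
        assert len(feats) == 2 * (spec.n_strides - 1)
        for f in feats:
            assert f.SL == pytest.approx(spec.SL_true, abs=1e-9)
            assert f.ST == pytest.approx(spec.ST_true, abs=1e-9)
            assert f.SV == pytest.approx(spec.SL_true / spec.ST_true, abs=1e-9)
            assert f.valid_SW
            # SW inherits millimeter-scale heel quantization through the
            # d/SW ~ 6 amplification of the width formula
            assert f.SW == pytest.approx(spec.SW_true, abs=0.015)
            assert f.STC_pct + f.SWC_pct == pytest.approx(100.0, abs=1e-9)
            assert f.SV * f.ST == pytest.approx(f.SL, abs=1e-9)

    def test_single_foot_trial_has_invalid_sw_only(self):
        cycles = [_cycle(1.0, 1.7, 2.1), _cycle(2.1, 2.8, 3.2, idxs=(2, 3, 4))]
        events = [c.hs_prev for c in cycles] + [c.to for c in cycles] + [c.hs_cur for c in cycles]
        events.sort(key=lambda e: e.t)
        heel = np.arange(10, dtype=float).reshape(5, 2)
        feats = compute_stride_features(cycles, [], events, [], heel, np.zeros((0, 2)))
        assert len(feats) == 2
        assert all(not f.valid_SW and math.isnan(f.SW) for f in feats)
        assert all(f.SL > 0 and f.ST > 0 for f in feats)

    def test_empty_input_gives_empty_output(self):
        out = compute_stride_features([], [], [], [], np.zeros((0, 2)), np.zeros((0, 2)))
        assert out == []

    def test_invariance_under_translation_and_time_shift(self):
        def build(shift_xy, shift_t):
            cyc_l = _cycle(1.0 + shift_t, 1.7 + shift_t, 2.1 + shift_t, "left", (0, 1, 2))
            cyc_r = _cycle(1.55 + shift_t, 2.25 + shift_t, 2.65 + shift_t, "right", (0, 1, 2))
            ev_l = [cyc_l.hs_prev, cyc_l.to, cyc_l.hs_cur]
            ev_r = [cyc_r.hs_prev, cyc_r.to, cyc_r.hs_cur]
            heel_l = np.array([[0.0, 0.05], [0.6, 0.05], [1.25, 0.05]]) + shift_xy
            heel_r = np.array([[0.62, -0.05], [1.2, -0.05], [1.9, -0.05]]) + shift_xy
            return compute_stride_features([cyc_l], [cyc_r], ev_l, ev_r, heel_l, heel_r)

        base = build(np.zeros(2), 0.0)
        moved = build(np.array([3.7, -1.2]), 11.0)
        for f0, f1 in zip(base, moved):
            for name in ("SL", "ST", "SW", "SV", "STC_pct", "SWC_pct"):
                assert getattr(f1, name) == pytest.approx(getattr(f0, name), abs=1e-9)
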