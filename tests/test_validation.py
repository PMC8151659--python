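"""Event matching, robust statistics and agreement reports."""

import numpy as np
import pytest
from conftest import optimal_match, random_event_streams

import vrgait as vg
from vrgait.validation import (
    feature_agreement,
    limits_of_agreement,
    mad_outlier_mask,
    match_events,
    matching_window_s,
    offset_statistics,
    pair_strides,
    sensitivity,
)


class TestMatchEvents:
    def test_worked_example(self):
        res = match_events([1.000, 2.105], [1.010, 2.090, 3.000], tol_s=0.0333)
        assert (res.TP, res.FN, res.FP) == (2, 1, 0)
        np.testing.assert_allclose(res.offsets_s, [-0.010, 0.015], atol=1e-12)
        assert sensitivity(res) == pytest.approx(66.667, abs=1e-2)

    def test_identical_streams_match_exactly(self):
        t = [1.0, 2.1, 3.2]
        res = match_events(t, t, tol_s=0.0333)
        assert res.TP == 3 and res.FN == 0 and res.FP == 0
        np.testing.assert_allclose(res.offsets_s, 0.0, atol=1e-12)

    def test_empty_detected_all_fn(self):
        res = match_events([], [1.0, 2.0], tol_s=0.0333)
        assert (res.TP, res.FN, res.FP) == (0, 2, 0)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_events([1.0], [1.0], tol_s=0.0)

    def test_greedy_equals_exhaustive_optimum_on_random_streams(self):
        rng = np.random.default_rng(123)
        tol = matching_window_s()
        for _ in range(200):
            det, ref = random_event_streams(rng, tol)
            res = match_events(list(det), list(ref), tol)
            n_opt, total_opt = optimal_match(det, ref, tol)
            assert res.TP == n_opt
            assert sum(abs(m.offset_s) for m in res.matches) == pytest.approx(
                total_opt, abs=1e-9
            )

    def test_sensitivity_monotone_in_tolerance(self):
        rng = np.random.default_rng(9)
        det, ref = random_event_streams(rng)
        prev = -1.0
        for tol in (0.005, 0.01, 0.02, 0.0333, 0.1, 0.5):
            res = match_events(list(det), list(ref), tol)
            s = sensitivity(res)
            assert s >= prev
            prev = s

    def test_sensitivity_undefined_without_reference(self):
        res = match_events([1.0], [], tol_s=0.0333)
        with pytest.raises(ValueError):
            sensitivity(res)


class TestMatchingWindow:
    def test_three_samples_at_90hz_is_33_3_ms(self):
        assert 1e3 * matching_window_s(3, 90.0) == pytest.approx(33.3, abs=0.05)


class TestMadOutliers:
    def test_hand_computed_example(self):
        # median 3, MAD 1, scaled 1.4826; only 100 exceeds 3.5 scaled MADs
        mask = mad_outlier_mask([1, 2, 3, 4, 100])
        assert list(mask) == [False, False, False, False, True]

    def test_constant_values_none_flagged(self):
        assert not mad_outlier_mask([5.0] * 6).any()

    def test_zero_mad_branch(self):
        mask = mad_outlier_mask([0, 0, 0, 0, 1])
        assert list(mask) == [False, False, False, False, True]

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            mad_outlier_mask([1.0, 2.0])

    def test_scale_and_shift_equivariant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        x[5] += 30.0
        base = mad_outlier_mask(x)
        for a, b in [(2.5, 0.0), (-1.0, 0.0), (0.3, 7.7), (-4.0, -2.0)]:
            assert (mad_outlier_mask(a * x + b) == base).all()


class TestOffsetStatistics:
    def test_symmetric_pair(self):
        s = offset_statistics([0.010, -0.010])
        assert s.mean_ms == pytest.approx(0.0, abs=1e-9)
        assert s.abs_mean_ms == pytest.approx(10.0, abs=1e-9)
        assert s.rmse_ms == pytest.approx(10.0, abs=1e-9)

    def test_constant_offsets(self):
        s = offset_statistics([0.005, 0.005, 0.005])
        assert s.mean_ms == pytest.approx(5.0)
        assert s.sd_ms == pytest.approx(0.0, abs=1e-12)
        assert s.rmse_ms == pytest.approx(5.0)

    def test_rmse_arithmetic(self):
        s = offset_statistics([0.003, -0.004])
        assert s.rmse_ms == pytest.approx(np.sqrt((9 + 16) / 2), abs=1e-9)

    def test_rmse_decomposition_identity(self):
        # RMSE^2 == mean^2 + SD^2 * (n-1)/n  (population variance identity)
        rng = np.random.default_rng(21)
        for _ in range(50):
            x = rng.normal(0.005, 0.01, size=rng.integers(3, 50))
            s = offset_statistics(x)
            n = s.n
            assert s.rmse_ms**2 == pytest.approx(
                s.mean_ms**2 + s.sd_ms**2 * (n - 1) / n, rel=1e-9
            )

    def test_mask_applied_and_empty_rejected(self):
        s = offset_statistics([0.01, 5.0], mask=[False, True])
        assert s.n == 1 and s.mean_ms == pytest.approx(10.0)
        with pytest.raises(ValueError):
            offset_statistics([1.0], mask=[True])


class TestLimitsOfAgreement:
    def test_mean2_sd05(self):
        lo, hi = limits_of_agreement([1.5, 2.0, 2.5])
        assert (lo, hi) == pytest.approx((1.02, 2.98), abs=1e-9)

    def test_constant_errors(self):
        lo, hi = limits_of_agreement([0.7, 0.7, 0.7])
        assert lo == pytest.approx(0.7, abs=1e-12)
        assert hi == pytest.approx(0.7, abs=1e-12)

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            limits_of_agreement([1.0])


def _feat(foot, t_prev, t_cur, SL=1.25, ST=1.1, SW=0.10, STC=62.0):
    return vg.StrideFeatures(
        foot=foot, t_hs_prev=t_prev, t_to=t_prev + 0.62 * ST, t_hs_cur=t_cur,
        SL=SL, ST=ST, SW=SW, SV=SL / ST, STC_pct=STC, SWC_pct=100 - STC,
    )


class TestFeatureAgreement:
    def _paired(self, n=10, sl_bias=0.0, seed=0):
        rng = np.random.default_rng(seed)
        ref, wit = [], []
        t = 0.0
        for _ in range(n):
            t += 1.1
            sl = rng.uniform(1.1, 1.4)
            ref.append(_feat("left", t - 1.1, t, SL=sl))
            wit.append(_feat("left", t - 1.1, t, SL=sl + sl_bias))
        return wit, ref

    def test_identical_lists_zero_error_perfect_correlation(self):
        vr, ref = self._paired()
        out = feature_agreement(vr, ref)
        sl = out["SL"]
        assert sl.rmse == pytest.approx(0.0, abs=1e-12)
        assert sl.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_constant_feature_has_undefined_correlation(self):
        vr, ref = self._paired()
        out = feature_agreement(vr, ref)
        assert out["ST"].pearson_r is None  # ST constant across strides

    def test_constant_bias_recovered(self):
        vr, ref = self._paired(sl_bias=0.01)
        sl = feature_agreement(vr, ref)["SL"]
        assert sl.mean_offset == pytest.approx(1.0, abs=1e-9)   # cm
        assert sl.sd_offset == pytest.approx(0.0, abs=1e-9)
        assert sl.rmse == pytest.approx(1.0, abs=1e-9)

    def test_insufficient_pairs_rejected(self):
        vr, ref = self._paired(n=1)
        with pytest.raises(ValueError):
            feature_agreement(vr, ref)


class TestPairStrides:
    def test_pairs_by_matching_heel_strikes(self):
        vr = [_feat("left", 0.0, 1.1), _feat("left", 1.1, 2.2)]
        ref = [
            _feat("left", 0.005, 1.105),
            _feat("left", 1.105, 2.21),
            _feat("left", 2.21, 3.3),  # stride the detector missed
        ]
        a, b = pair_strides(vr, ref, tol_s=3 / 90)
        assert len(a) == len(b) == 2

    def test_mismatched_opening_strike_rejected(self):
        vr = [_feat("left", 0.0, 1.1)]
        ref = [_feat("left", 0.5, 1.1)]  # same closing HS, different opening HS
        a, b = pair_strides(vr, ref, tol_s=3 / 90)
        assert a == [] and b == []


class TestValidationReport:
    def test_roundtrip_through_json(self, tmp_path, noiseless_trial, noiseless_result):
        spec, trial = noiseless_trial
        report = vg.validate_trial(
            noiseless_result.all_events, trial.reference,
            noiseless_result.features, trial.ref_features, vg.RunConfig(),
        )
        path = tmp_path / "report.json"
        vg.write_report(report, path)
        report2 = vg.ValidationReport.from_dict(vg.io_formats.read_report(path))
        assert report2.to_dict() == report.to_dict()
        assert report2.events["HS"].sensitivity_pct == pytest.approx(100.0)

    def test_outlier_offsets_removed_before_statistics(self):
        import pandas as pd

        # one detected HS displaced by 30 ms within a tight cluster
        base = 1.1 * np.arange(1, 11)
        det = [vg.GaitEvent("HS", "left", float(b), i) for i, b in enumerate(base)]
        det[4] = vg.GaitEvent("HS", "left", float(base[4] + 0.030), 4)
        with pytest.warns(UserWarning, match="alternation"):  # HS-only table
            table = vg.ReferenceEventTable(
                events=pd.DataFrame({"kind": "HS", "foot": "left", "t": base})
            )
        out = vg.validate_events(det, table, vg.RunConfig())["HS"]
        assert out.tp == 10
        assert out.n_outliers == 1
        assert out.stats.n == 9
        assert out.stats.abs_mean_ms == pytest.approx(0.0, abs=1e-9)

    def test_sync_offset_applied_to_reference(self):
        import pandas as pd

        det = [vg.GaitEvent("HS", "left", 1.0, 0), vg.GaitEvent("HS", "left", 2.1, 1)]
        with pytest.warns(UserWarning, match="alternation"):  # HS-only table
            table = vg.ReferenceEventTable(
                events=pd.DataFrame({"kind": "HS", "foot": "left", "t": [1.012, 2.112]})
            )
        cfg = vg.RunConfig(sync_offset_s=0.012)
        out = vg.validate_events(det, table, cfg)["HS"]
        assert out.tp == 2
        assert out.stats.mean_ms == pytest.approx(0.0, abs=1e-6)
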