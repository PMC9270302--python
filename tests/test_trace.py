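import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qfrpullback import (
    InvalidParameterError,
    PullbackPreprocessor,
    PullbackTrace,
    delta_qfr_vessel,
    index_qfr,
    monotone_envelope,
    preprocess_trace,
    resample_trace,
)
from qfrpullback.errors import InvalidTraceError, OutOfRangeError

from ._oracles import interp as oracle_interp
from .conftest import make_trace


class TestValidation:
    def test_rejects_structural_violations(self):
        with pytest.raises(InvalidTraceError):
            PullbackTrace("v", [0.0], [1.0])  # too short
        with pytest.raises(InvalidTraceError):
            PullbackTrace("v", [1.0, 2.0], [1.0, 0.9])  # must start at 0
        with pytest.raises(InvalidTraceError):
            PullbackTrace("v", [0.0, 2.0, 1.0], [1.0, 0.9, 0.8])  # not increasing
        with pytest.raises(InvalidTraceError):
            PullbackTrace("v", [0.0, 1.0], [1.2, 0.9])  # qfr above tolerance
        with pytest.raises(InvalidTraceError):
            PullbackTrace("v", [0.0, 1.0], [1.0, 0.0])  # qfr must be positive
        with pytest.raises(InvalidTraceError):
            PullbackTrace("v", [0.0, 1.0], [1.0, 0.9], phase="during_pci")

    def test_landmark_properties(self):
        t = make_trace([(0, 0.98), (65, 0.74)])
        assert t.tvl_mm == 65
        assert t.ostial_qfr == 0.98
        assert t.distal_qfr == 0.74


class TestResample:
    def test_two_point_linear(self):
        t = make_trace([(0, 1.00), (80, 0.75)])
        r = resample_trace(t, 20)
        np.testing.assert_allclose(r.positions_mm, [0, 20, 40, 60, 80])
        np.testing.assert_allclose(r.qfr, [1.00, 0.9375, 0.875, 0.8125, 0.75])

    def test_identity_on_matching_grid(self):
        t = make_trace([(0, 1.0), (60, 0.8)], step=2.0)
        r = resample_trace(t, 2.0)
        np.testing.assert_array_equal(r.positions_mm, t.positions_mm)
        np.testing.assert_allclose(r.qfr, t.qfr)

    def test_matches_pointwise_interpolation_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(5, 40)
            pos = np.sort(rng.uniform(0, 70, size=n))
            pos[0] = 0.0
            pos = np.unique(pos)
            q = np.clip(np.sort(rng.uniform(0.6, 1.0, size=pos.size))[::-1], 0.01, 1.05)
            t = PullbackTrace("v", pos, q)
            r = resample_trace(t, 0.5)
            expected = [oracle_interp(pos, q, x) for x in r.positions_mm]
            np.testing.assert_allclose(r.qfr, expected, atol=1e-12)

    def test_idempotent_and_preserves_tvl(self):
        t = make_trace([(0, 1.0), (13.3, 0.9), (66.1, 0.7)])
        r1 = resample_trace(t, 0.5)
        r2 = resample_trace(r1, 0.5)
        assert r1.tvl_mm == t.tvl_mm
        np.testing.assert_array_equal(r1.positions_mm, r2.positions_mm)
        np.testing.assert_allclose(r1.qfr, r2.qfr)

    def test_invalid_step(self):
        t = make_trace([(0, 1.0), (60, 0.8)])
        with pytest.raises(InvalidParameterError):
            resample_trace(t, 0.0)
        with pytest.raises(InvalidParameterError):
            resample_trace(t, 61.0)


class TestMonotoneEnvelope:
    def test_identity_on_monotone_input(self):
        t = make_trace([(0, 1.0), (20, 0.9), (40, 0.9), (60, 0.7)], step=1.0)
        m = monotone_envelope(t)
        np.testing.assert_allclose(m.qfr, t.qfr, atol=1e-12)

    def test_noise_blip_pooled_to_mean(self):
        # pool-adjacent-violators averages the 0.80/0.82 violation to 0.81
        t = PullbackTrace("v", [0, 1, 2, 3, 4, 5], [1.0, 0.9, 0.80, 0.82, 0.78, 0.70])
        m = monotone_envelope(t)
        np.testing.assert_allclose(m.qfr[2:4], [0.81, 0.81])
        assert m.qfr[0] - m.qfr[-1] == pytest.approx(0.30)  # ΔQFR unchanged

    def test_recovers_monotone_truth_under_noise(self):
        # truth: gentle ramp; envelope should stay within 3 sigma of it
        sigma = 0.005
        t0 = make_trace([(0, 0.98), (10, 0.98), (55, 0.76), (65, 0.76)], step=0.5)
        truth = t0.qfr
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            noisy = PullbackTrace(
                "v", t0.positions_mm, np.clip(truth + rng.normal(0, sigma, truth.shape), 0.01, 1.05)
            )
            m = monotone_envelope(noisy)
            if np.max(np.abs(m.qfr - truth)) < 3 * sigma:
                hits += 1
        assert hits >= 0.95 * n_rep

    @given(
        st.lists(st.floats(min_value=0.05, max_value=1.04), min_size=2, max_size=40)
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_nonincreasing_and_idempotent(self, values):
        t = PullbackTrace("v", np.arange(len(values), dtype=float), values)
        m = monotone_envelope(t)
        assert np.all(np.diff(m.qfr) <= 1e-12)
        m2 = monotone_envelope(m)
        np.testing.assert_allclose(m2.qfr, m.qfr, atol=1e-12)


class TestIndexQfr:
    def test_point_lookup(self):
        t = make_trace([(0, 0.98), (40, 0.78), (80, 0.74)])
        assert index_qfr(t, 0) == pytest.approx(0.98)
        assert index_qfr(t, 20) == pytest.approx(0.88)  # midpoint of linear segment
        assert index_qfr(t, 40) == pytest.approx(0.78)  # grid point exact
        with pytest.raises(OutOfRangeError):
            index_qfr(t, -1.0)
        with pytest.raises(OutOfRangeError):
            index_qfr(t, 80.5)


class TestDeltaQfr:
    def test_values_and_warning(self):
        assert delta_qfr_vessel(make_trace([(0, 1.0), (60, 1.0)])) == 0
        assert delta_qfr_vessel(make_trace([(0, 0.98), (60, 0.74)])) == pytest.approx(0.24)
        with pytest.warns(UserWarning, match="negative"):
            delta_qfr_vessel(PullbackTrace("v", [0, 30, 60], [0.90, 0.85, 0.95]))

    def test_invariant_under_resampling(self):
        t = make_trace([(0, 0.99), (22.7, 0.9), (61.3, 0.71)])
        r = resample_trace(t, 0.5)
        assert delta_qfr_vessel(r) == pytest.approx(delta_qfr_vessel(t), abs=1e-12)


class TestPreprocessor:
    def test_sklearn_contract_and_pipeline(self):
        from sklearn.base import clone
        from sklearn.pipeline import Pipeline

        from qfrpullback import QvpIndexExtractor

        pre = PullbackPreprocessor(step_mm=0.5)
        assert clone(pre).get_params()["step_mm"] == 0.5
        pipe = Pipeline(
            [("pre", PullbackPreprocessor()), ("qvp", QvpIndexExtractor(preprocess=False))]
        )
        traces = [make_trace([(0, 0.99), (30, 0.80), (65, 0.78)])]
        df = pipe.fit_transform(traces)
        assert df.shape[0] == 1
        assert 0 <= df.loc[0, "qvp_index"] <= 1

    def test_preprocess_outputs_monotone_uniform(self):
        t = make_trace([(0, 0.97), (17.2, 0.9), (63.9, 0.72)])
        p = preprocess_trace(t)
        assert np.all(np.diff(p.qfr) <= 1e-12)
        assert p.tvl_mm == t.tvl_mm
        assert np.allclose(np.diff(p.positions_mm)[:-1], 0.5)
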