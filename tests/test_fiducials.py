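import numpy as np
import pandas as pd
import pytest
import pywt
from hypothesis import given, settings, strategies as st

from glyecg import DelineationError
from glyecg.fiducials import (
    FEATURE_NAMES,
    FiducialSet,
    _denoise,
    _padded_length,
    _swt_operators,
    delineate,
    delineate_matrix,
    extract_features,
    features_from_beats,
)
from glyecg.synthetic_data import (
    DYSGLYCEMIA,
    EUGLYCEMIA,
    gaussian_beat,
    solve_wave_params,
    state_targets,
)


def _beat(state=EUGLYCEMIA, cfg=None):
    p = solve_wave_params(state_targets(state))
    t = (np.arange(125) - 50) / 125.0
    return p, gaussian_beat(p, t)


class TestSwtOperators:
    def test_forward_matrices_match_pywt(self):
        x = np.random.default_rng(0).normal(size=128)
        fwd, _ = _swt_operators("db4", 3, 128)
        coeffs = pywt.swt(x, "db4", level=3, trim_approx=True)
        for c, M in zip(coeffs, fwd):
            np.testing.assert_allclose(c, M @ x, atol=1e-10)

    def test_inverse_reconstructs_identity(self):
        x = np.random.default_rng(1).normal(size=128)
        fwd, inv = _swt_operators("db4", 3, 128)
        recon = sum(inv[b] @ (fwd[b] @ x) for b in range(4))
        np.testing.assert_allclose(recon, x, atol=1e-10)

    def test_noise_free_denoising_is_identity(self, cfg):
        _, beat = _beat()
        den, _ = _denoise(beat[None, :], cfg)
        # residual far below the 1 uV amplitude quantization of the data
        np.testing.assert_allclose(den[0], beat, atol=5e-4)

    def test_padding_rounds_up_to_block(self):
        assert _padded_length(125, 3) == 128
        assert _padded_length(128, 3) == 128


class TestDelineation:
    @pytest.mark.parametrize("state", [EUGLYCEMIA, DYSGLYCEMIA])
    def test_round_trip_on_noise_free_beat(self, cfg, state):
        """Designed fiducials are recovered within one sample and 1 uV on
        an isolated noise-free beat."""
        p, beat = _beat(state)
        designed = p.designed_fiducials(cfg)
        fid = delineate(beat, cfg)
        for w in "PQRST":
            assert abs(fid.indices[w] - designed["index"][w]) <= 1
            assert abs(fid.amplitudes[w]
                       - designed["amplitude_mv"][w]) <= 1e-3

    def test_negated_t_wave_still_found(self, cfg):
        p, _ = _beat()
        amps = dict(p.amplitudes_mv, T=-p.amplitudes_mv["T"])
        q = type(p)(centers_s=p.centers_s, amplitudes_mv=amps,
                    widths_s=p.widths_s, heart_period_s=p.heart_period_s)
        t = (np.arange(125) - 50) / 125.0
        fid = delineate(gaussian_beat(q, t), cfg)
        assert abs(fid.indices["T"] - 86) <= 1
        assert fid.amplitudes["T"] < 0  # sign preserved

    def test_monotone_ramp_fails(self, cfg):
        with pytest.raises(DelineationError):
            delineate(np.linspace(0.0, 1.0, 125), cfg)

    def test_t_search_capped_before_next_qrs(self, cfg):
        """With a short next-beat interval, the next QRS enters the
        window; the capped search must not latch onto it."""
        p, beat = _beat(DYSGLYCEMIA)
        t = (np.arange(125) - 50) / 125.0
        rr = 0.52
        two = beat + gaussian_beat(p, t - rr)
        res = delineate_matrix(two[None, :], cfg, rr_next_s=np.array([rr]))
        assert res["valid"][0]
        designed_t = p.designed_fiducials(cfg)["index"]["T"]
        assert abs(res["idx"]["T"][0] - designed_t) <= 1

    def test_amplitude_shift_invariance(self, cfg):
        _, beat = _beat()
        base = extract_features(delineate(beat, cfg), 0.8, cfg)
        shifted = extract_features(delineate(beat + 0.5, cfg), 0.8, cfg)
        pd.testing.assert_series_equal(base, shifted, atol=1e-9, rtol=0)

    @pytest.mark.parametrize("gain", [0.5, 2.0])
    def test_gain_equivariance(self, cfg, gain):
        _, beat = _beat()
        f1 = extract_features(delineate(beat, cfg), 0.8, cfg)
        f2 = extract_features(delineate(beat * gain, cfg), 0.8, cfg)
        for name in FEATURE_NAMES:
            if name.endswith("interval"):
                assert f2[name] == pytest.approx(f1[name], abs=1e-12)
            else:  # amplitudes and slopes scale with the gain
                assert f2[name] == pytest.approx(gain * f1[name], rel=1e-9)


class TestFeatures:
    def test_feature_vector_has_26_canonical_names(self):
        assert len(FEATURE_NAMES) == 26
        assert sum(n.endswith("interval") for n in FEATURE_NAMES) == 11
        assert sum(n.endswith("amplitude") for n in FEATURE_NAMES) == 10
        assert sum(n.endswith("slope") for n in FEATURE_NAMES) == 5

    def test_designed_geometry_gives_reference_qt(self, cfg):
        p, beat = _beat(EUGLYCEMIA)
        f = extract_features(delineate(beat, cfg), 0.74, cfg)
        assert f["QT_interval"] == pytest.approx(0.37, abs=0.008)
        assert f["RR_interval"] == 0.74

    def test_interval_amplitude_slope_arithmetic(self, cfg):
        fid = FiducialSet(idx_p=24, idx_q=40, idx_r=50, idx_s=55, idx_t=86,
                          amp_p=0.1, amp_q=0.1, amp_r=0.65, amp_s=-0.10,
                          amp_t=0.5)
        f = extract_features(fid, 0.8, cfg)
        assert f["RS_interval"] == pytest.approx(5 / 125)
        assert f["RS_amplitude"] == pytest.approx(0.75)
        assert f["PQ_amplitude"] == 0.0  # equal P and Q amplitudes
        assert f["PQ_slope"] == 0.0
        # signed slope: (amp_T - amp_S) / interval
        assert f["ST_slope"] == pytest.approx((0.5 + 0.10) / (31 / 125))

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_additivity_and_slope_identities(self, cfg, data):
        idx = sorted(data.draw(st.lists(
            st.integers(0, 124), min_size=5, max_size=5, unique=True)))
        amps = data.draw(st.lists(
            st.floats(-2, 2, allow_nan=False), min_size=5, max_size=5))
        fid = FiducialSet(*idx, *amps)
        f = extract_features(fid, 0.7, cfg)
        assert f["PT_interval"] == pytest.approx(
            f["PQ_interval"] + f["QR_interval"] + f["RS_interval"]
            + f["ST_interval"], abs=1e-12)
        assert all(f[n] > 0 for n in FEATURE_NAMES if n.endswith("interval"))
        for pair in ("PR", "PQ", "QS", "ST", "RT"):
            signed = (fid.amplitudes[pair[1]] - fid.amplitudes[pair[0]])
            assert f[f"{pair}_slope"] * f[f"{pair}_interval"] == pytest.approx(
                signed, abs=1e-9)

    def test_last_beat_without_rr_excluded(self, cfg, eu_run):
        from glyecg.beats import detect_r_peaks, quality_filter, segment_beats

        rec, _ = eu_run
        peaks = detect_r_peaks(rec.samples[:30000], cfg)
        beats, _ = segment_beats(rec.samples[:30000], peaks, cfg)
        accepted, _ = quality_filter(beats, cfg)
        feats, dropped = features_from_beats(accepted, cfg)
        n_with_rr = sum(b.rr_next_s is not None for b in accepted)
        assert dropped["no-next-rr"] == len(accepted) - n_with_rr
        assert len(feats) <= n_with_rr
        assert not feats.isna().any().any()
        assert (feats["RR_interval"] > 0).all()

    def test_ordering_violation_rejected(self):
        with pytest.raises(DelineationError):
            FiducialSet(idx_p=45, idx_q=40, idx_r=50, idx_s=55, idx_t=86,
                        amp_p=0, amp_q=0, amp_r=1, amp_s=0, amp_t=0)
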