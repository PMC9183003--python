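"""Modified Beer-Lambert conversion: hand-checked values, algebraic
round trips, and structural invariants of the produced series."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nirsfatigue as nf
from nirsfatigue.recording import RecordingValidationError


class TestDeltaConcentrations:
    def test_equal_intensities_give_zero_change(self):
        assert nf.delta_concentrations(1.0, 1.0, 2.5, 2.5) == (0.0, 0.0)

    def test_hand_substitution_values(self):
        # 10% attenuation at both wavelengths, default extinction table,
        # worked through the two-equation inversion by hand with log10
        d_hbo2, d_hb = nf.delta_concentrations(1.0, 0.9, 1.0, 0.9)
        assert d_hbo2 == pytest.approx(0.01556, abs=5e-6)
        assert d_hb == pytest.approx(0.00514, abs=5e-6)

    def test_red_only_attenuation_is_attributed_to_hb(self):
        # at 660 nm Hb absorbs ~10x more than HbO2, so attenuation seen only
        # there must be explained by a rise in Hb (and a compensating HbO2 drop)
        d_hbo2, d_hb = nf.delta_concentrations(1.0, 0.9, 1.0, 1.0)
        assert d_hb > 0
        assert d_hbo2 < 0

    def test_rejects_nonpositive_intensity(self):
        with pytest.raises(ValueError, match="positive"):
            nf.delta_concentrations(1.0, 0.0, 1.0, 1.0)

    def test_degenerate_constants_rejected(self):
        bad = nf.OpticalConstants(
            epsilon_hb_l1=1.0, epsilon_hbo2_l1=1.0,
            epsilon_hb_l2=1.0, epsilon_hbo2_l2=1.0,
        )
        with pytest.raises(ValueError, match="determinant|degenerate"):
            nf.delta_concentrations(1.0, 0.9, 1.0, 0.9, bad)

    def test_linearity_in_log_ratio(self):
        # doubling both optical densities doubles both concentration changes
        d1 = nf.delta_concentrations(1.0, 0.9, 1.0, 0.95)
        d2 = nf.delta_concentrations(1.0, 0.81, 1.0, 0.9025)
        assert d2[0] == pytest.approx(2 * d1[0], abs=1e-12)
        assert d2[1] == pytest.approx(2 * d1[1], abs=1e-12)


class TestForwardInverse:
    def test_zero_change_returns_reference(self):
        i1, i2 = nf.forward_intensities(0.0, 0.0, 1.3, 0.7)
        assert (i1, i2) == (1.3, 0.7)

    def test_forward_of_hand_values_attenuates_ten_percent(self):
        i1, i2 = nf.forward_intensities(0.015559278103663475, 0.005136192404920882)
        assert i1 == pytest.approx(0.9, abs=1e-9)
        assert i2 == pytest.approx(0.9, abs=1e-9)

    @settings(max_examples=200, derandomize=True)
    @given(
        d_hbo2=st.floats(-0.05, 0.05),
        d_hb=st.floats(-0.05, 0.05),
        i_b1=st.floats(0.1, 10.0),
        i_b2=st.floats(0.1, 10.0),
    )
    def test_round_trip_identity(self, d_hbo2, d_hb, i_b1, i_b2):
        i_t1, i_t2 = nf.forward_intensities(d_hbo2, d_hb, i_b1, i_b2)
        r_hbo2, r_hb = nf.delta_concentrations(i_b1, i_t1, i_b2, i_t2)
        assert abs(r_hbo2 - d_hbo2) < 1e-10
        assert abs(r_hb - d_hb) < 1e-10

    def test_round_trip_on_series(self, rng):
        d_hbo2 = rng.normal(0, 0.01, 1000)
        d_hb = rng.normal(0, 0.005, 1000)
        i1, i2 = nf.forward_intensities(d_hbo2, d_hb)
        r1, r2 = nf.delta_concentrations(1.0, i1, 1.0, i2)
        assert np.max(np.abs(r1 - d_hbo2)) < 1e-10
        assert np.max(np.abs(r2 - d_hb)) < 1e-10


class TestIntensityToChromophores:
    def test_constant_recording_gives_zero_series(self):
        n = 20_000
        rec = nf.IntensityRecording(
            sampling_rate_hz=100.0,
            channels=(
                nf.ChannelIntensities("F7", np.full(n, 1.2), np.full(n, 0.8)),
                nf.ChannelIntensities("F8", np.full(n, 0.5), np.full(n, 2.0)),
            ),
            periods=(nf.Period(0, 100, "baseline_pre"), nf.Period(100, 200, "baseline_post")),
        )
        series = nf.intensity_to_chromophores(rec)
        for site in ("F7", "F8"):
            for c in ("HbO2", "Hb", "Hbt"):
                # identically zero up to round-off of the reference mean
                np.testing.assert_allclose(series.data[site][c], 0.0, atol=1e-15)

    def test_identical_channels_give_identical_series(self, rng):
        x1 = rng.uniform(0.9, 1.1, 15_000)
        x2 = rng.uniform(0.9, 1.1, 15_000)
        rec = nf.IntensityRecording(
            sampling_rate_hz=100.0,
            channels=(
                nf.ChannelIntensities("F7", x1, x2),
                nf.ChannelIntensities("F8", x1.copy(), x2.copy()),
            ),
            periods=(nf.Period(0, 150, "baseline_pre"),),
        )
        series = nf.intensity_to_chromophores(rec)
        for c in ("HbO2", "Hb", "Hbt"):
            np.testing.assert_array_equal(series.data["F7"][c], series.data["F8"][c])

    def test_recovers_known_deltas_when_reference_is_quiet(self):
        # concentration changes that are exactly zero over the reference
        # interval are recovered to numerical precision
        rate, n = 100.0, 30_000
        t = np.arange(n) / rate
        d_hbo2 = np.where(t >= 20, 0.01 * np.sin(2 * np.pi * 0.1 * (t - 20)), 0.0)
        d_hb = np.where(t >= 20, -0.004 * np.sin(2 * np.pi * 0.3 * (t - 20)), 0.0)
        i1, i2 = nf.forward_intensities(d_hbo2, d_hb)
        rec = nf.IntensityRecording(
            sampling_rate_hz=rate,
            channels=(nf.ChannelIntensities("F7", i1, i2),
                      nf.ChannelIntensities("F8", i1.copy(), i2.copy())),
            periods=(nf.Period(0, 120, "baseline_pre"),
                     nf.Period(120, 300, "baseline_post")),
        )
        series = nf.intensity_to_chromophores(rec)
        assert np.max(np.abs(series.data["F7"]["HbO2"] - d_hbo2)) < 1e-10
        assert np.max(np.abs(series.data["F7"]["Hb"] - d_hb)) < 1e-10

    def test_hbt_is_sum_invariant(self, default_recording):
        series = nf.intensity_to_chromophores(default_recording)
        for site in series.sites:
            np.testing.assert_allclose(
                series.data[site]["Hbt"],
                series.data[site]["HbO2"] + series.data[site]["Hb"],
                rtol=0, atol=1e-12,
            )

    def test_reference_policy_interval_outside_recording(self):
        rec = nf.IntensityRecording(
            sampling_rate_hz=100.0,
            channels=(nf.ChannelIntensities("F7", np.ones(500), np.ones(500)),),
            periods=(),
        )
        policy = nf.ReferenceIntervalPolicy(mode="first_k_seconds", k_s=10.0)
        # falls back to start of the recording (5 s available)
        series = nf.intensity_to_chromophores(rec, policy)
        assert series.n_samples == 500

    def test_whole_pre_baseline_policy(self, default_recording):
        series = nf.intensity_to_chromophores(
            default_recording, nf.ReferenceIntervalPolicy(mode="whole_pre_baseline")
        )
        assert series.n_samples == default_recording.n_samples


def test_chromophore_series_rejects_broken_hbt():
    with pytest.raises(RecordingValidationError, match="Hbt"):
        nf.ChromophoreSeries(
            sampling_rate_hz=100.0,
            data={"F7": {"HbO2": np.ones(10), "Hb": np.ones(10), "Hbt": np.ones(10)}},
        )
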