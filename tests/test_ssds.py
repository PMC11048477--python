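import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nirsox import (
    ChromophoreState,
    DPFSet,
    MissingChannelError,
    Recording,
    SsdsCalibration,
    ValidationError,
    WavelengthTriple,
    calibrate_k,
    mua_spectrum,
    pairwise_attenuation_differences,
    simulate_recording,
    ssds_sto2,
    ssds_timeseries,
)
from nirsox.io import channel_name
from nirsox.simulate import NoiseModel

WL = WavelengthTriple()


def exact_forward_intensities(state, table, i0=(1.0, 0.9, 1.1), dpf=6.0, d=3.0, G=0.0):
    """Homogeneous Beer–Lambert forward model with coupling loss G (OD)."""
    mua = mua_spectrum(state, table)
    return tuple(i0[j] * 10.0 ** (-dpf * d * mua[j] - G) for j in range(3))


def cal_from_sources(i0=(1.0, 0.9, 1.1)):
    return SsdsCalibration(k1=i0[0] / i0[1], k2=i0[2] / i0[1])


class TestPairwiseTerms:
    def test_unity_ratios_give_zero(self):
        a12, a32, a31 = pairwise_attenuation_differences(
            1.0, 1.0, 1.0, SsdsCalibration(1.0, 1.0)
        )
        assert a12 == a32 == a31 == 0.0

    @given(
        i=st.tuples(*[st.floats(1e-3, 1e3) for _ in range(3)]),
        k=st.tuples(st.floats(0.1, 10), st.floats(0.1, 10)),
    )
    @settings(max_examples=50, deadline=None)
    def test_third_terms_are_antisymmetric(self, i, k):
        """log(k2 i1/(k1 i3)) and its reciprocal (denominator term) cancel."""
        cal = SsdsCalibration(*k)
        _, _, a31 = pairwise_attenuation_differences(*i, cal)
        denominator_third = np.log10(cal.k1 * i[2] / (cal.k2 * i[0]))
        assert a31 + denominator_third == pytest.approx(0.0, abs=1e-12)

    def test_terms_equal_forward_model_attenuation_differences(self, table):
        state = ChromophoreState.from_sto2(65.0, 55.0)
        dpf, d = 6.0, 3.0
        I = exact_forward_intensities(state, table, dpf=dpf, d=d, G=0.7)
        mua = mua_spectrum(state, table)
        a12, a32, a31 = pairwise_attenuation_differences(*I, cal_from_sources())
        assert a12 == pytest.approx(dpf * d * (mua[0] - mua[1]), abs=1e-12)
        assert a32 == pytest.approx(dpf * d * (mua[2] - mua[1]), abs=1e-12)
        assert a31 == pytest.approx(dpf * d * (mua[2] - mua[0]), abs=1e-12)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_attenuation_differences(0.0, 1.0, 1.0, SsdsCalibration(1, 1))


class TestSsdsExactness:
    @pytest.mark.parametrize("g_od", [0.0, 1.0, 3.0])
    @pytest.mark.parametrize("d", [3.0, 4.0])
    def test_exact_on_homogeneous_model(self, table, g_od, d):
        """The estimator's central property: algebraic exactness.

        Under the equal-DPF homogeneous model with wavelength-independent
        coupling loss, the estimate equals true StO₂ for every saturation and
        total hemoglobin — DPF, separation and coupling all cancel."""
        for sto2 in range(0, 101, 10):
            for thb in (30.0, 60.0, 120.0):
                state = ChromophoreState.from_sto2(float(sto2), thb)
                I = exact_forward_intensities(state, table, d=d, G=g_od)
                res = ssds_sto2(*I, cal_from_sources(), DPFSet(), table)
                assert res.sto2 == pytest.approx(float(sto2), abs=1e-6)

    def test_pure_hbo_returns_100(self, table):
        I = exact_forward_intensities(ChromophoreState(60.0, 0.0), table)
        res = ssds_sto2(*I, cal_from_sources(), DPFSet(), table)
        assert res.sto2 == pytest.approx(100.0, abs=1e-6)

    @given(gain=st.floats(1e-3, 1e3))
    @settings(max_examples=30, deadline=None)
    def test_common_intensity_factor_cancels(self, table, gain):
        state = ChromophoreState.from_sto2(70.0, 60.0)
        I = exact_forward_intensities(state, table)
        ref = ssds_sto2(*I, cal_from_sources(), DPFSet(), table).sto2
        scaled = ssds_sto2(
            *(x * gain for x in I), cal_from_sources(), DPFSet(), table
        ).sto2
        assert scaled == pytest.approx(ref, abs=1e-9)

    def test_calibration_covariance(self, table):
        """Scaling I(λ1) by g together with k1 by g leaves the output fixed."""
        state = ChromophoreState.from_sto2(62.0, 70.0)
        i1, i2, i3 = exact_forward_intensities(state, table)
        cal = cal_from_sources()
        ref = ssds_sto2(i1, i2, i3, cal, DPFSet(), table).sto2
        g = 2.71
        cov = ssds_sto2(
            i1 * g, i2, i3, SsdsCalibration(cal.k1 * g, cal.k2), DPFSet(), table
        ).sto2
        assert cov == pytest.approx(ref, abs=1e-9)

    def test_monotone_in_true_sto2(self, table):
        estimates = []
        for sto2 in range(5, 100, 5):
            I = exact_forward_intensities(
                ChromophoreState.from_sto2(float(sto2), 60.0), table
            )
            estimates.append(ssds_sto2(*I, cal_from_sources(), DPFSet(), table).sto2)
        assert np.all(np.diff(estimates) > 0)

    def test_log_base_invariance(self, table):
        state = ChromophoreState.from_sto2(48.0, 90.0)
        I = exact_forward_intensities(state, table)
        b10 = ssds_sto2(*I, cal_from_sources(), DPFSet(), table, base10=True).sto2
        ln = ssds_sto2(*I, cal_from_sources(), DPFSet(), table, base10=False).sto2
        assert ln == pytest.approx(b10, abs=1e-9)


class TestSsdsQc:
    def test_degenerate_denominator_flagged_not_fabricated(self, table):
        res = ssds_sto2(1.0, 1.0, 1.0, SsdsCalibration(1.0, 1.0), DPFSet(), table)
        assert res.flags["denominator_near_zero"].all()
        assert not np.isfinite(res.sto2)

    def test_out_of_range_flag_tracks_value(self, table):
        state = ChromophoreState.from_sto2(70.0, 60.0)
        I = exact_forward_intensities(state, table)
        res = ssds_sto2(*I, cal_from_sources(), DPFSet(), table)
        assert not res.flags["out_of_physio_range"].any()
        # mis-calibrated k pushes the raw estimate outside [0, 100]
        res_bad = ssds_sto2(*I, SsdsCalibration(50.0, 0.02), DPFSet(), table)
        outside = not (0 <= res_bad.sto2 <= 100)
        assert res_bad.flags["out_of_physio_range"].any() == outside


class TestSsdsTimeseries:
    def test_constant_tissue_gives_constant_trace(self, table):
        state = ChromophoreState.from_sto2(70.0, 60.0)
        I = exact_forward_intensities(state, table)
        n = 50
        data = {"time_s": np.arange(n) / 10.0}
        for j, wl in enumerate(WL):
            data[channel_name(wl, 3.0)] = np.full(n, I[j])
        rec = Recording(pd.DataFrame(data), 10.0, WL, (3.0,), {})
        trace = ssds_timeseries(rec, cal_from_sources(), 3.0, table=table)
        assert np.allclose(trace.sto2, 70.0, atol=1e-6)

    def test_zero_sample_flagged_locally(self, table):
        state = ChromophoreState.from_sto2(70.0, 60.0)
        I = exact_forward_intensities(state, table)
        n = 50
        data = {"time_s": np.arange(n) / 10.0}
        for j, wl in enumerate(WL):
            col = np.full(n, I[j])
            data[channel_name(wl, 3.0)] = col
        data[channel_name(730.0, 3.0)][25] = 0.0
        rec = Recording(pd.DataFrame(data), 10.0, WL, (3.0,), {})
        trace = ssds_timeseries(rec, cal_from_sources(), 3.0, table=table)
        assert trace.flags["nonpositive_intensity"][25]
        assert np.isnan(trace.sto2[25])
        assert trace.sto2[24] == pytest.approx(70.0, abs=1e-6)
        assert trace.sto2[26] == pytest.approx(70.0, abs=1e-6)

    def test_missing_channel_named(self, silent_exact_sim):
        with pytest.raises(MissingChannelError) as err:
            ssds_timeseries(
                silent_exact_sim.recording,
                SsdsCalibration(1.0, 1.0),
                separation_cm=9.9,
            )
        assert "9.9" in str(err.value)

    def test_breath_hold_extrema_match_truth(self, silent_exact_sim):
        """On a noiseless scenario the trace dips and peaks where the true
        saturation does, within one sample."""
        sim = silent_exact_sim
        cal = calibrate_k(sim.recording, "source_spec")
        trace = ssds_timeseries(sim.recording, cal, 3.0)
        true = sim.truth["sto2"].to_numpy()
        assert abs(int(np.nanargmin(trace.sto2)) - int(np.argmin(true))) <= 1
        assert abs(int(np.nanargmax(trace.sto2)) - int(np.argmax(true))) <= 1


class TestCalibration:
    def test_source_spec_equal_sources(self, silent_exact_sim):
        cal = calibrate_k(
            silent_exact_sim.recording, "source_spec",
            source_intensities=(2.0, 2.0, 2.0),
        )
        assert cal.k1 == cal.k2 == 1.0

    def test_baseline_method_recovers_generating_ratios(self, silent_exact_sim):
        sim = silent_exact_sim
        i0 = sim.params["instrument"]["source_intensities"]
        true_state = ChromophoreState.from_sto2(
            sim.params["tissue"]["baseline_sto2_pct"],
            sim.params["tissue"]["baseline_thb_um"],
        )
        onset = sim.params["scenario"]["t_onset_s"]
        cal = calibrate_k(
            sim.recording,
            "baseline_assumed_sto2",
            separation_cm=3.0,
            baseline_epoch=(onset - 5.0, onset),
            assumed_state=true_state,
        )
        assert cal.k1 == pytest.approx(i0[0] / i0[1], rel=1e-6)
        assert cal.k2 == pytest.approx(i0[2] / i0[1], rel=1e-6)

    def test_wrong_assumed_sto2_biases_monotonically(self, silent_exact_sim):
        """Assuming the wrong baseline saturation shifts the whole estimate
        monotonically with the assumption."""
        sim = silent_exact_sim
        onset = sim.params["scenario"]["t_onset_s"]
        baselines = []
        for assumed in (60.0, 65.0, 70.0, 75.0, 80.0):
            cal = calibrate_k(
                sim.recording,
                "baseline_assumed_sto2",
                separation_cm=3.0,
                baseline_epoch=(onset - 5.0, onset),
                assumed_state=ChromophoreState.from_sto2(assumed, 60.0),
            )
            trace = ssds_timeseries(sim.recording, cal, 3.0)
            mask = (trace.time >= onset - 5.0) & (trace.time < onset)
            baselines.append(np.nanmean(trace.sto2[mask]))
        assert np.all(np.diff(baselines) > 0)

    def test_short_baseline_rejected(self, silent_exact_sim):
        with pytest.raises(ValidationError):
            calibrate_k(
                silent_exact_sim.recording,
                "baseline_assumed_sto2",
                separation_cm=3.0,
                baseline_epoch=(10.0, 10.5),
                assumed_state=ChromophoreState.from_sto2(70.0, 60.0),
            )
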