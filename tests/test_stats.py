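import numpy as np
import pandas as pd
import pytest

from nirsox import (
    NoiseModel,
    Recording,
    ValidationError,
    WavelengthTriple,
    baseline_subtract,
    epoch_windows,
    group_analysis,
    one_sample_t,
    oneway_anova,
    pearson,
    simulate_recording,
    snr_screen,
)
from nirsox.io import channel_name


def anova_by_sums_of_squares(groups):
    """Independent oracle: explicit between/within sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = sum(g.size for g in groups) - len(groups)
    return (ssb / df1) / (ssw / df2)


class TestEpochWindows:
    def test_constant_trace(self):
        t = np.arange(-10, 60, 0.01)
        w = epoch_windows(t, np.full(t.size, 3.3), onset=0.0)
        assert w.shape == (10,)
        assert np.allclose(w, 3.3)

    def test_ramp_gives_window_midpoints(self):
        fs = 1000.0
        t = np.arange(-6, 50, 1 / fs)
        w = epoch_windows(t, t.copy(), onset=0.0)
        expected = np.arange(-2.5, 45.0, 5.0)
        assert np.allclose(w, expected, atol=1 / fs)

    def test_qc_flagged_samples_excluded(self):
        t = np.arange(-5, 45, 0.1)
        x = np.zeros(t.size)
        qc = np.zeros(t.size, dtype=bool)
        x[(t >= 0) & (t < 5)] = 100.0
        qc[(t >= 0) & (t < 5) & (np.arange(t.size) % 2 == 0)] = True
        w = epoch_windows(t, x, onset=0.0, qc_mask=qc)
        assert w[1] == pytest.approx(100.0)  # survivors still average correctly

    def test_missing_window_named(self):
        t = np.arange(-5, 30, 0.1)  # coverage stops before 45 s
        with pytest.raises(ValidationError, match=r"\[30, 35\)"):
            epoch_windows(t, np.zeros(t.size), onset=0.0)


class TestBaselineSubtract:
    def test_baseline_becomes_zero(self, rng):
        w = rng.normal(size=10)
        out = baseline_subtract(w)
        assert out[0] == 0.0

    def test_shift_invariance_and_idempotence(self, rng):
        w = rng.normal(size=10)
        assert np.allclose(baseline_subtract(w + 17.0), baseline_subtract(w))
        once = baseline_subtract(w)
        assert np.allclose(baseline_subtract(once), once)


class TestAnova:
    def test_hand_example(self):
        res = oneway_anova([[1, 2], [3, 4]])
        assert res.F == pytest.approx(8.0, abs=1e-12)
        assert (res.df1, res.df2) == (1, 2)
        assert res.p == pytest.approx(0.10557280900008, abs=1e-12)

    def test_identical_means_give_zero_f(self):
        res = oneway_anova([[1.0, 2.0], [1.0, 2.0]])
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_zero_within_variance_is_error(self):
        with pytest.raises(ValidationError):
            oneway_anova([[1.0, 1.0], [2.0, 2.0]])

    def test_agreement_with_sums_of_squares_oracle(self, rng):
        for _ in range(100):
            k = rng.integers(2, 6)
            groups = [rng.normal(rng.normal(), 1.0, rng.integers(3, 12))
                      for _ in range(k)]
            res = oneway_anova(groups)
            assert res.F == pytest.approx(anova_by_sums_of_squares(groups), abs=1e-10)


class TestOneSampleT:
    def test_symmetric_values(self):
        res = one_sample_t([-1.0, 1.0])
        assert res.t == pytest.approx(0.0, abs=1e-15)
        assert res.p == pytest.approx(1.0)

    def test_closed_form_example(self):
        res = one_sample_t([1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2.0 * np.sqrt(3.0), rel=1e-12)
        assert res.df == 2
        # closed form for df=2: p = 1 − t/sqrt(2 + t²)
        assert res.p == pytest.approx(0.07417990022745, abs=1e-12)

    def test_scale_invariance_about_zero(self, rng):
        x = rng.normal(1.0, 1.0, 20)
        assert one_sample_t(x).t == pytest.approx(one_sample_t(2 * x).t, rel=1e-12)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValidationError):
            one_sample_t([2.0, 2.0, 2.0])


class TestPearson:
    def test_perfect_linear(self):
        assert pearson([1, 2, 3, 4], [3, 5, 7, 9]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert pearson([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_example(self):
        assert pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5, abs=1e-12)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValidationError):
            pearson([1, 1, 1], [1, 2, 3])


def _noise_recording(sd, seed=0, n=2000, fs=100.0, mean=0.0):
    rng = np.random.default_rng(seed)
    data = {"time_s": np.arange(n) / fs}
    for wl in (730.0, 800.0, 850.0):
        data[channel_name(wl, 3.0)] = mean + sd * rng.standard_normal(n)
    return Recording(pd.DataFrame(data), fs, WavelengthTriple(), (3.0,), {})


class TestSnrScreen:
    def test_noiseless_simulation_passes(self, silent_exact_sim):
        res = snr_screen(silent_exact_sim.recording, threshold=1e4)
        assert res.passed

    def test_pure_noise_fails(self):
        rec = _noise_recording(sd=1.0, mean=0.05)
        res = snr_screen(rec, threshold=20.0)
        assert not res.passed

    def test_metric_monotone_in_noise(self):
        metrics = []
        for sd in (0.001, 0.01, 0.1, 1.0):
            sim = simulate_recording(
                noise=NoiseModel(white_sd_rel=sd, cardiac_amp_um=0, resp_amp_um=0,
                                 mayer_amp_um=0, drift_rel_per_min_sd=0,
                                 hold_fluct_sd_pct=0, seed=11),
            )
            res = snr_screen(sim.recording)
            metrics.append(min(res.metrics.values()))
        assert np.all(np.diff(metrics) < 0)


def _toy_window_table(n_trials=6, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    starts = np.arange(-5.0, 45.0, 5.0)
    shape = np.concatenate([[0.0], np.sin(np.linspace(0, np.pi, 9))])
    for trial in range(n_trials):
        for sig in ("hbo_3cm", "sto2_srs"):
            scale = 1.0 if sig == "hbo_3cm" else 10.0
            vals = scale * shape + rng.normal(0, 0.1, 10)
            vals[0] = 0.0
            for t0, v in zip(starts, vals):
                rows.append({"trial": f"t{trial}", "signal": sig,
                             "window_start": t0, "value": v})
    return pd.DataFrame(rows)


class TestGroupAnalysis:
    def test_report_invariants(self):
        report = group_analysis(_toy_window_table())
        for res in report.anova.values():
            assert res.F >= 0 and 0 < res.p <= 1
        for per in report.ttests.values():
            for r in per.values():
                assert 0 < r.p <= 1
        corr = report.correlations
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_duplicating_trials_halves_se(self):
        table = _toy_window_table()
        dup = table.copy()
        dup["trial"] = dup["trial"] + "_copy"
        doubled = pd.concat([table, dup], ignore_index=True)
        r1 = group_analysis(table)
        r2 = group_analysis(doubled)
        m1 = r1.group_means.sort_values(["signal", "window_start"])
        m2 = r2.group_means.sort_values(["signal", "window_start"])
        assert np.allclose(m1["mean"].to_numpy(), m2["mean"].to_numpy())
        # exact duplication: sd picks up a ddof factor sqrt(2(n-1)/(2n-1))
        n = table["trial"].nunique()
        factor = np.sqrt(2 * (n - 1) / (2 * n - 1)) / np.sqrt(2)
        nz = m1["se"].to_numpy() > 0
        assert np.allclose(
            m2["se"].to_numpy()[nz], m1["se"].to_numpy()[nz] * factor, rtol=1e-9
        )

    def test_single_trial_rejected(self):
        table = _toy_window_table(n_trials=1)
        with pytest.raises(ValidationError):
            group_analysis(table)

    def test_bonferroni_never_decreases_p(self):
        table = _toy_window_table()
        raw = group_analysis(table)
        adj = group_analysis(table, mt_correction="bonferroni")
        for sig in raw.ttests:
            for w in raw.ttests[sig]:
                assert adj.ttests[sig][w].p >= raw.ttests[sig][w].p - 1e-15
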