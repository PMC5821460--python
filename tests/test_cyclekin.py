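"""Cell-cycle quantitation: age structure, deconvolution, slopes, timer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from l1cycle import cyclekin, defaults
from l1cycle.cyclekin import (
    DNAContentModel,
    FTTrace,
    WesternSeries,
    deconvolve_dna,
    durations_from_fractions,
    estimate_conversion_time,
    ft_trace,
    fucci_contingency,
    gate_ft,
    normalize_westerns,
    onset_curve,
    onset_quantiles,
    phase_fractions_from_durations,
    phase_windows_from_model,
    relative_to_t0,
    slope_analysis,
)
from l1cycle.datatypes import (
    CellCycleModel,
    FTKinetics,
    InvalidParameterError,
    PhaseFractions,
)
from l1cycle import synthgen


# ---------------------------------------------------------------- age structure

class TestPhaseFractions:
    def test_all_g1_when_g1_spans_cycle(self):
        m = CellCycleModel(T=24, d_G1=24, d_S=0, d_G2M=0)
        f = phase_fractions_from_durations(m)
        assert f.f_G1 == pytest.approx(1.0)
        assert f.f_S == pytest.approx(0.0)

    def test_equal_durations_give_decreasing_fractions(self):
        m = CellCycleModel(T=24, d_G1=8, d_S=8, d_G2M=8)
        f = phase_fractions_from_durations(m)
        assert f.f_G1 > f.f_S > f.f_G2M

    def test_g1_fraction_matches_numerical_integration(self):
        # independent oracle: integrate the age density over [0, d_G1]
        T, d_G1 = 24.0, 9.84
        density = lambda a: (2 * math.log(2) / T) * 2 ** (-a / T)
        expected, _ = integrate.quad(density, 0, d_G1)
        m = CellCycleModel(T=T, d_G1=d_G1, d_S=10.0, d_G2M=T - d_G1 - 10.0)
        assert phase_fractions_from_durations(m).f_G1 == pytest.approx(
            expected, abs=1e-9
        )
        # the G1 occupancy measured for an asynchronous HeLa culture
        assert expected == pytest.approx(0.495, abs=1e-3)

    def test_inversion_trivial(self):
        m = durations_from_fractions(PhaseFractions(1.0, 0.0, 0.0), 24.0)
        assert m.d_G1 == pytest.approx(24.0)

    def test_inversion_of_measured_distribution_roundtrips(self):
        f = PhaseFractions.from_percent(49.5, 34.2, 15.2)
        m = durations_from_fractions(f, 24.0)
        back = phase_fractions_from_durations(m)
        assert back.f_G1 == pytest.approx(f.f_G1, abs=1e-9)
        assert back.f_S == pytest.approx(f.f_S, abs=1e-9)
        assert back.f_G2M == pytest.approx(f.f_G2M, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        g1=st.floats(0.01, 0.97),
        s_rel=st.floats(0.01, 0.98),
        T=st.floats(5.0, 60.0),
    )
    def test_roundtrip_identity_property(self, g1, s_rel, T):
        s = (1.0 - g1) * s_rel
        f = PhaseFractions(g1, s, 1.0 - g1 - s)
        back = phase_fractions_from_durations(durations_from_fractions(f, T))
        assert np.allclose(back.as_array(), f.as_array(), atol=1e-9)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(InvalidParameterError):
            PhaseFractions(0.7, 0.7, -0.4)
        with pytest.raises(InvalidParameterError):
            PhaseFractions(0.5, 0.3, 0.1)  # sums to 0.9


# ---------------------------------------------------------------- deconvolution

class TestDNAContentDeconvolution:
    def test_all_events_at_2n_is_pure_g1(self):
        fr, res = deconvolve_dna(np.full(2000, 100.0))
        assert fr.f_G1 == pytest.approx(1.0)
        assert res.mu == pytest.approx(100.0)

    def test_planted_mixture_recovered(self):
        facs = synthgen.gen_facs_snapshot(
            n=100_000, event_rule="fixed_phase_mixture",
            mixture=(0.5, 0.3, 0.2), seed=21,
        )
        fr, res = deconvolve_dna(facs)
        assert res.converged
        assert np.allclose(fr.as_array(), [0.5, 0.3, 0.2], atol=0.02)
        assert res.mu == pytest.approx(defaults.DNA_2N, rel=0.02)

    def test_too_few_events_rejected(self):
        with pytest.raises(InvalidParameterError):
            DNAContentModel(np.full(500, 100.0))

    def test_summary_mentions_fractions(self):
        fr, res = deconvolve_dna(np.full(2000, 100.0))
        assert "G1 fraction" in res.summary()


# ---------------------------------------------------------------- slope analysis

class TestSlopeAnalysis:
    def test_hand_computed_forward_differences(self):
        ss = slope_analysis([0, 3, 6, 9, 12], [0, 0, 2, 8, 9])
        assert np.allclose(ss.slopes, [0, 2 / 3, 2, 1 / 3])
        assert ss.peak_interval == (6, 9)
        assert not ss.no_peak

    def test_linear_rise_flags_no_peak(self):
        ss = slope_analysis([0, 3, 6, 9, 12], [0, 2, 4, 6, 8])
        assert ss.no_peak

    def test_phase_annotation_from_model_windows(self, model):
        windows = phase_windows_from_model(model, 24.0)
        ss = slope_analysis(
            np.arange(0, 25, 3), np.zeros(9), phase_windows=windows
        )
        # first interval [0,3] lies entirely inside G1 (d_G1 ~ 10 h)
        assert ss.phase_annotation[0] == "G1"
        # interval [12,15] lies entirely inside S
        assert ss.phase_annotation[4] == "S"

    def test_windows_cover_whole_range(self, model):
        windows = phase_windows_from_model(model, 50.0)
        covered = sum(hi - lo for lo, hi, _ in windows)
        assert covered == pytest.approx(50.0)

    def test_errors(self):
        with pytest.raises(InvalidParameterError):
            slope_analysis([0, 3], [0, 1])
        with pytest.raises(InvalidParameterError):
            slope_analysis([0, 3, 2], [0, 1, 2])

    def test_relative_to_t0(self):
        assert np.allclose(relative_to_t0([2.0, 4.0, 1.0]), [1, 2, 0.5])
        with pytest.raises(InvalidParameterError):
            relative_to_t0([0.0, 1.0])


# ---------------------------------------------------------------- FT kinetics

class TestFTTrace:
    def test_red_zero_at_time_zero(self, kinetics):
        tr = ft_trace(kinetics, [0.0, 1.0, 2.0])
        assert tr.red[0] == 0.0

    def test_constant_burst_matches_closed_form(self, kinetics):
        t = np.linspace(0, 20, 200)
        tr = ft_trace(kinetics, t, amplitude=3.0)
        expected = 3.0 * (1 - np.exp(-kinetics.k_mat * t))
        assert np.allclose(tr.red, expected, atol=1e-9)
        assert np.allclose(tr.blue + tr.red, 3.0, atol=1e-9)

    def test_conversion_time_is_half_life(self, kinetics):
        tr = ft_trace(kinetics, [0.0, 1.0])
        assert tr.conversion_time == pytest.approx(
            math.log(2) / kinetics.k_mat
        )

    def test_ongoing_transcription_keeps_blue_pool(self, kinetics):
        t = np.linspace(0, 40, 100)
        tr = ft_trace(kinetics, t, "ongoing_transcription", amplitude=5.0)
        # steady-state blue pool of young proteins alongside growing red
        assert tr.blue[-1] == pytest.approx(5.0, rel=1e-3)
        assert tr.red[-1] > tr.blue[-1]


class TestConversionTimeEstimator:
    def test_noiseless_traces_give_exact_half_life(self):
        kin = FTKinetics(k_mat=math.log(2) / 2.35)
        t = np.arange(0, 24.01, 0.25)
        traces = [ft_trace(kin, t) for _ in range(12)]
        mean, sd, diag = estimate_conversion_time(traces)
        assert mean == pytest.approx(2.35, abs=0.01)
        assert diag["n_used"] == 12

    def test_single_noiseless_trace_sd_zero(self, kinetics):
        t = np.arange(0, 24.01, 0.25)
        mean, sd, _ = estimate_conversion_time([ft_trace(kinetics, t)])
        assert sd == 0.0

    @pytest.mark.parametrize("k_mat", [0.1, 0.3, 0.5, 1.0])
    def test_estimator_bias_under_noise(self, k_mat):
        # record long enough for the red plateau (~10 half-lives)
        kin = FTKinetics(k_mat=k_mat)
        times = np.arange(0, 10.0 / k_mat, 0.25)
        traces = synthgen.gen_ft_traces(
            200, kin, times=times, noise_sd_frac=0.05, seed=int(k_mat * 100)
        )
        mean, _, _ = estimate_conversion_time(traces)
        truth = math.log(2) / k_mat
        assert abs(mean - truth) / truth < 0.05

    def test_unplateaued_traces_excluded(self, kinetics):
        t = np.arange(0, 1.0, 0.1)  # far shorter than the 2.35 h half-rise
        short = ft_trace(kinetics, t)
        with pytest.raises(InvalidParameterError):
            estimate_conversion_time([short])


class TestOnsetQuantiles:
    def test_step_curve(self):
        # discontinuity encoded with a repeated time value
        t50, t90 = onset_quantiles([0.0, 3.0, 3.0], [0.0, 0.0, 1.0])
        assert t50 == 3.0 and t90 == 3.0

    def test_lognormal_delays_match_closed_form(self, kinetics):
        rng = np.random.default_rng(0)
        delays = kinetics.sample_onset_delays(200_000, rng)
        t, f = onset_curve(delays)
        t50, t90 = onset_quantiles(t, f)
        q50 = math.exp(kinetics.onset_mu)
        q90 = math.exp(kinetics.onset_mu + 1.2815515655 * kinetics.onset_sigma)
        assert t50 == pytest.approx(q50, rel=0.02)
        assert t90 == pytest.approx(q90, rel=0.03)

    def test_unreached_level_is_none(self):
        t50, t90 = onset_quantiles([0, 1, 2], [0, 0.3, 0.6])
        assert t50 is not None and t90 is None

    def test_decreasing_curve_rejected(self):
        with pytest.raises(InvalidParameterError):
            onset_quantiles([0, 1, 2], [0.0, 0.5, 0.4])


# ---------------------------------------------------------------- gating

class TestGateFT:
    def test_all_below_threshold(self):
        import pandas as pd
        from l1cycle.datatypes import FACSTable

        ev = pd.DataFrame({"blue": [1.0, 2.0], "red": [0.0, 1.0],
                           "dna": [100.0, 200.0]})
        g = gate_ft(FACSTable(ev), blue_threshold=5.0)
        assert (g.labels == "blue_neg").all()

    def test_monotone_rescaling_invariance(self):
        facs = synthgen.gen_facs_snapshot(n=5000, event_rule="uniform_in_S",
                                          seed=3)
        g1 = gate_ft(facs, blue_threshold=10.0)
        scaled = synthgen.gen_facs_snapshot(n=5000, event_rule="uniform_in_S",
                                            seed=3)
        scaled.events["blue"] *= 3.0
        scaled.events["red"] *= 7.0
        g2 = gate_ft(scaled, blue_threshold=30.0)
        assert (g1.labels == g2.labels).all()

    def test_auto_threshold_uses_eventless_cells(self):
        facs = synthgen.gen_facs_snapshot(n=20_000, event_rule="uniform_in_S",
                                          seed=4)
        g = gate_ft(facs)
        neg = facs.events["true_event_time"].isna()
        assert g.blue_threshold == facs.events.loc[neg, "blue"].max()
        assert (g.labels[neg.to_numpy()] == "blue_neg").all()


# ---------------------------------------------------------------- FUCCI, westerns

class TestFucci:
    def test_empty_input(self):
        import pandas as pd

        fc = fucci_contingency(
            pd.DataFrame(columns=["nuclear_orf1p", "nucleus_color"])
        )
        assert fc.total == 0

    def test_random_colors_binomial(self, model):
        import pandas as pd

        rng = np.random.default_rng(11)
        n, q = 20_000, 0.5
        df = pd.DataFrame({
            "nuclear_orf1p": rng.uniform(size=n) < 0.1,
            "nucleus_color": np.where(rng.uniform(size=n) < q, "red", "green"),
        })
        fc = fucci_contingency(df)
        n_nuc = int(df["nuclear_orf1p"].sum())
        se = math.sqrt(n_nuc * q * (1 - q))
        assert abs(fc[True, "red"] - q * n_nuc) < 3 * se

    def test_unknown_color_rejected(self):
        import pandas as pd

        with pytest.raises(InvalidParameterError):
            fucci_contingency(pd.DataFrame(
                {"nuclear_orf1p": [True], "nucleus_color": ["blue"]}
            ))


class TestWesterns:
    def test_target_equal_loading_gives_ones(self):
        s = WesternSeries(np.array([0, 3]), np.array([5.0, 7.0]),
                          np.array([5.0, 7.0]))
        assert np.allclose(normalize_westerns(s), 1.0)

    def test_hand_computed_ratios(self):
        s = WesternSeries(np.array([0, 3]), np.array([100.0, 300.0]),
                          np.array([100.0, 150.0]))
        assert np.allclose(normalize_westerns(s), [1.0, 2.0])

    def test_zero_loading_rejected(self):
        s = WesternSeries(np.array([0, 3]), np.array([1.0, 1.0]),
                          np.array([1.0, 0.0]))
        with pytest.raises(InvalidParameterError):
            normalize_westerns(s)
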