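"""Generators: seeded determinism, ground truth, and contract recovery."""

import numpy as np
import pandas as pd
import pytest

from l1cycle import synthgen
from l1cycle.datatypes import (
    CellCycleModel,
    FTKinetics,
    InvalidParameterError,
    PhaseFractions,
)
from l1cycle.cyclekin import phase_fractions_from_durations


class TestGenCellField:
    def test_empty_field(self):
        f = synthgen.gen_cell_field(0, 0.5, seed=1)
        assert len(f) == 0

    def test_no_nuclear_cells_at_zero_fraction(self):
        f = synthgen.gen_cell_field(500, 0.0, seed=2)
        assert not f.nuclear_mask.any()

    def test_pair_separation_sample_mean(self):
        # sample-mean oracle over the generated pairs
        f = synthgen.gen_cell_field(
            10_000, frac_nuclear=1.0, frac_paired=1.0, pair_sep_mean=10.0,
            pair_sep_sd=1.0, width=2000.0, height=2000.0, seed=3,
        )
        cells = f.cells.dropna(subset=["pair_id"])
        seps = []
        for _, grp in cells.groupby("pair_id"):
            a, b = grp[["x", "y"]].to_numpy()
            seps.append(np.hypot(*(a - b)))
        assert len(seps) == 5000
        assert np.mean(seps) == pytest.approx(10.0, abs=0.1)

    def test_pairs_are_nuclear_and_grouped_in_twos(self, paired_field):
        cells = paired_field.cells
        paired = cells.dropna(subset=["pair_id"])
        assert (paired.groupby("pair_id").size() == 2).all()
        assert paired["nuclear_positive"].all()

    def test_deterministic_given_seed(self):
        a = synthgen.gen_cell_field(200, 0.3, 0.5, seed=5)
        b = synthgen.gen_cell_field(200, 0.3, 0.5, seed=5)
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            synthgen.gen_cell_field(-1, 0.5)
        with pytest.raises(InvalidParameterError):
            synthgen.gen_cell_field(10, 1.5)
        with pytest.raises(InvalidParameterError):
            synthgen.gen_cell_field(10, 0.5, width=-5.0)


class TestGenImage:
    def test_empty_field_is_pure_background(self):
        f = synthgen.gen_cell_field(0, 0.0, width=50.0, height=50.0, seed=1)
        img = synthgen.gen_image(f, intensity_params=(400, 250, 50, 0), seed=1)
        assert np.all(img.nuclear_channel == 50)
        assert np.all(img.marker_channel == 50)

    def test_noiseless_nuclear_disk_identity(self):
        cells = pd.DataFrame(
            {"id": [0], "x": [30.0], "y": [30.0],
             "nuclear_positive": [True],
             "pair_id": pd.array([pd.NA], dtype="Int64")}
        )
        from l1cycle.datatypes import CellField

        f = CellField(cells, 60.0, 60.0)
        img = synthgen.gen_image(
            f, pixel_size=1.0, nucleus_radius=6,
            intensity_params=(400.0, 250.0, 50.0, 0.0), seed=0,
        )
        t = img.truth.iloc[0]
        Y, X = np.mgrid[0:img.marker_channel.shape[0], 0:img.marker_channel.shape[1]]
        disk = (X - t.cx_px) ** 2 + (Y - t.cy_px) ** 2 <= 6 ** 2
        assert img.marker_channel[disk].mean() == pytest.approx(450.0)

    def test_truth_table_complete(self, small_image):
        field, img = small_image
        assert len(img.truth) == len(field)
        assert set(img.truth["id"]) == set(field.cells["id"])

    def test_overcrowded_field_raises(self):
        f = synthgen.gen_cell_field(200, 0.0, width=40.0, height=40.0, seed=2)
        with pytest.raises(synthgen.PlacementError):
            synthgen.gen_image(f, nucleus_radius=6, seed=2)


class TestSamplePhases:
    def test_pure_g1_model(self):
        m = CellCycleModel(T=24, d_G1=24, d_S=0, d_G2M=0)
        df = synthgen.sample_phases(m, 500, seed=1)
        assert (df["phase"] == "G1").all()

    def test_mean_age_below_half_cycle(self, model):
        df = synthgen.sample_phases(model, 20_000, seed=2)
        assert df["age"].mean() < model.T / 2

    def test_fractions_match_closed_form(self, model):
        n = 100_000
        df = synthgen.sample_phases(model, n, seed=3)
        expected = phase_fractions_from_durations(model).as_array()
        observed = (
            df["phase"].value_counts(normalize=True)
            .reindex(["G1", "S", "G2M"]).to_numpy()
        )
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(observed - expected) < 3 * se)


class TestGenFacsSnapshot:
    def test_zero_cv_pure_g1_is_exactly_2n(self):
        facs = synthgen.gen_facs_snapshot(
            n=200, event_rule="fixed_phase_mixture", mixture=(1.0, 0.0, 0.0),
            dna_cv=0.0, seed=1,
        )
        assert np.all(facs.events["dna"] == 100.0)

    def test_mixture_fractions_multinomial(self):
        n = 100_000
        facs = synthgen.gen_facs_snapshot(
            n=n, event_rule="fixed_phase_mixture", mixture=(0.5, 0.3, 0.2),
            seed=2,
        )
        expected = np.array([0.5, 0.3, 0.2])
        observed = (
            facs.events["true_phase"].value_counts(normalize=True)
            .reindex(["G1", "S", "G2M"]).to_numpy()
        )
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(observed - expected) < 3 * se)

    def test_invalid_mixture_rejected(self):
        with pytest.raises(InvalidParameterError):
            synthgen.gen_facs_snapshot(
                n=100, event_rule="fixed_phase_mixture", mixture=(0.5, 0.3, 0.1)
            )

    def test_blue_positive_red_low_enriched_in_s(self):
        facs = synthgen.gen_facs_snapshot(n=50_000, event_rule="uniform_in_S",
                                          seed=5)
        ev = facs.events
        kin = FTKinetics()
        blue_pos = ev["blue"] > kin.blue_detect_threshold
        red_med = ev.loc[blue_pos, "red"].median()
        red_low = blue_pos & (ev["red"] <= red_med)
        frac_s = (ev.loc[red_low, "true_phase"] == "S").mean()
        overall_s = (ev["true_phase"] == "S").mean()
        assert frac_s > 0.5
        assert frac_s > overall_s

    def test_truth_always_present(self):
        facs = synthgen.gen_facs_snapshot(n=100, event_rule="uniform_in_cycle",
                                          seed=6)
        assert facs.events["true_phase"].notna().all()


class TestGenTimecourse:
    def test_zero_event_probability(self, model):
        tc = synthgen.gen_timecourse(model, n_cells=500, p_event=0.0, seed=1)
        assert np.all(tc.gfp_fraction == 0)

    def test_cumulative_and_bounded(self, model):
        tc = synthgen.gen_timecourse(model, n_cells=5000, seed=2)
        assert np.all(np.diff(tc.gfp_fraction) >= 0)
        assert tc.gfp_fraction[-1] <= 100.0

    def test_no_events_before_s_phase_when_synchronized(self, model):
        tc = synthgen.gen_timecourse(model, n_cells=5000, seed=3)
        detect = tc.truth["detect_time"].dropna()
        assert detect.min() >= model.d_G1

    def test_invalid_timepoints(self, model):
        with pytest.raises(InvalidParameterError):
            synthgen.gen_timecourse(model, timepoints=[0.0], n_cells=10)
        with pytest.raises(InvalidParameterError):
            synthgen.gen_timecourse(model, timepoints=[0.0, 3.0, 2.0],
                                    n_cells=10)


class TestGenPeptideTable:
    def test_empty(self):
        t = synthgen.gen_peptide_table({"red": 0, "orange": 0, "yellow": 0,
                                        "gray": 0})
        assert len(t) == 0

    def test_planted_truth_columns(self):
        t = synthgen.gen_peptide_table({"red": 5, "orange": 5, "yellow": 5,
                                        "gray": 5}, seed=1)
        assert len(t) == 20
        assert t.rows["planted_class"].notna().all()

    def test_deterministic(self):
        a = synthgen.gen_peptide_table({"red": 3, "gray": 3}, seed=9)
        b = synthgen.gen_peptide_table({"red": 3, "gray": 3}, seed=9)
        pd.testing.assert_frame_equal(a.rows, b.rows)


class TestGenFtTraces:
    def test_deterministic_and_noisy(self, kinetics):
        a = synthgen.gen_ft_traces(3, kinetics, seed=4)
        b = synthgen.gen_ft_traces(3, kinetics, seed=4)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.red, tb.red)
        assert not np.array_equal(a[0].red, a[1].red)

    def test_intensities_nonnegative(self, kinetics):
        for tr in synthgen.gen_ft_traces(5, kinetics, seed=5):
            assert (tr.blue >= 0).all() and (tr.red >= 0).all()


class TestGenFucciCells:
    def test_nuclear_cells_forced_g1(self):
        df = synthgen.gen_fucci_cells(1000, 50, seed=1)
        nuc = df[df["nuclear_orf1p"]]
        assert len(nuc) == 50
        assert (nuc["nucleus_color"] == "red").all()

    def test_invalid_counts(self):
        with pytest.raises(InvalidParameterError):
            synthgen.gen_fucci_cells(10, 20)
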