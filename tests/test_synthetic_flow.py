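"""Generator statistics, determinism and event-table I/O."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from utrtune.synthetic_flow import (
    DETECTORS, FLUOROPHORES, OBSERVED_COLUMNS, PRIMARY_DETECTOR,
    ConstructSpec, SimulationConfig, TransfectionMix, double_transfection,
    triple_transfection, simulate_cotransfection, simulate_mock,
    simulate_single_color_controls, simulate_triple_transfection,
    read_events_csv, read_events_fcs, write_events_csv,
    default_spillover_matrix, identity_spillover_matrix,
)

from conftest import make_construct, write_minimal_fcs


class TestConstructSpec:
    def test_rejects_unknown_motif_and_reporter(self):
        with pytest.raises(ValueError, match="motif"):
            make_construct(motif="XYZ")
        with pytest.raises(ValueError, match="reporter"):
            ConstructSpec("x", motif="Kt", copies=1, reporter="mCherry")

    def test_zero_copies_only_for_controls(self):
        ConstructSpec("ctrl", motif="none", copies=0)
        ConstructSpec("dctrl", motif="dKt", copies=0)
        with pytest.raises(ValueError, match="copies"):
            ConstructSpec("bad", motif="Kl", copies=0)

    def test_defective_motif_efficiency_may_exceed_one(self):
        spec = make_construct(e=1.3, motif="dKt")
        assert spec.e_effective("L7Ae") == 1.3
        assert spec.e_effective("MS2CP") == 1.0

    @pytest.mark.parametrize("motif,cognate", [
        ("Kt", "L7Ae"), ("Kl", "L7Ae"), ("Kl2", "L7Ae"),
        ("MS2SL", "MS2CP"), ("Fr15", "S15"),
    ])
    def test_cognate_pairing(self, motif, cognate):
        spec = make_construct(e=0.1, motif=motif)
        assert spec.e_effective(cognate) == 0.1
        others = {"L7Ae", "MS2CP", "S15"} - {cognate}
        assert all(spec.e_effective(t) == 1.0 for t in others)

    def test_unknown_pairing_names_the_pair(self):
        spec = make_construct(motif="Kt")
        with pytest.raises(ValueError, match="Kt.*Cas9"):
            spec.e_effective("Cas9")


class TestTransfectionMix:
    def test_default_double_masses_give_copy_ratio_point_two(self):
        mix = double_transfection(make_construct(), "L7Ae")
        assert mix.copy_ratios() == {"Kt-EGFP-test": pytest.approx(0.2)}

    def test_copy_ratio_recorded_in_provenance(self, noiseless_config):
        mix = double_transfection(make_construct(), "L7Ae")
        table = simulate_cotransfection(noiseless_config, mix)
        assert table.attrs["copy_ratio"]["Kt-EGFP-test"] == pytest.approx(0.2)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError, match="negative mass"):
            TransfectionMix(((make_construct(), -0.1),), 0.5, "L7Ae")


class TestCotransfection:
    def test_row_count_equals_requested_events(self, default_config):
        mix = double_transfection(make_construct(), "L7Ae")
        for n in (0, 1, 1000):
            table = simulate_cotransfection(replace(default_config,
                                                    n_events=n), mix)
            assert len(table) == n

    def test_empty_table_has_all_columns(self, default_config):
        mix = double_transfection(make_construct(), "L7Ae")
        table = simulate_cotransfection(replace(default_config, n_events=0),
                                        mix)
        assert set(OBSERVED_COLUMNS) <= set(table.columns)
        assert "viable" in table.columns

    def test_noise_off_ratio_identity(self, noiseless_config):
        """Cognate/non-cognate mean ratio equals e exactly with matched
        seeds and noise off."""
        spec = make_construct(e=0.5)
        cog = simulate_cotransfection(noiseless_config,
                                      double_transfection(spec, "L7Ae"))
        non = simulate_cotransfection(noiseless_config,
                                      double_transfection(spec, "MS2CP"))
        ratio = cog["det530"].mean() / non["det530"].mean()
        assert ratio == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("e", [0.017, 0.24, 1.0, 1.3])
    def test_ratio_identity_across_efficiencies(self, noiseless_config, e):
        spec = make_construct(e=e, motif="Kt", reporter="ECFP")
        cog = simulate_cotransfection(noiseless_config,
                                      double_transfection(spec, "L7Ae"))
        non = simulate_cotransfection(noiseless_config,
                                      double_transfection(spec, "MS2CP"))
        assert cog["det450"].mean() / non["det450"].mean() == \
            pytest.approx(e, rel=1e-9)

    def test_determinism_bit_identical(self, default_config):
        mix = double_transfection(make_construct(), "L7Ae")
        t1 = simulate_cotransfection(default_config, mix)
        t2 = simulate_cotransfection(default_config, mix)
        pd.testing.assert_frame_equal(t1, t2)

    def test_seed_changes_data(self, default_config):
        mix = double_transfection(make_construct(), "L7Ae")
        t1 = simulate_cotransfection(default_config, mix)
        t2 = simulate_cotransfection(replace(default_config, seed=12), mix)
        assert not t1["det530"].equals(t2["det530"])

    def test_raw_signals_nonnegative(self, default_config):
        mix = double_transfection(make_construct(e=0.02), "L7Ae")
        table = simulate_cotransfection(default_config, mix)
        assert (table[list(DETECTORS)].to_numpy() >= 0).all()

    def test_window_dose_constancy(self, default_config):
        """Conditional on DsRed in [900, 1100], the trigger-copy CV is
        bounded by the window's relative half-width plus the ratio
        dispersion."""
        mix = double_transfection(make_construct(e=1.0), "L7Ae")
        table = simulate_cotransfection(replace(default_config,
                                                n_events=200_000), mix)
        sub = table[(table["truth_trigger_copies"] >= 900)
                    & (table["truth_trigger_copies"] <= 1100)]
        cv = sub["truth_trigger_copies"].std() / sub["truth_trigger_copies"].mean()
        assert cv <= 0.1 + mix.copy_ratio_dispersion

    def test_hill_mode_represses_more_at_high_dose(self):
        cfg = SimulationConfig(n_events=100_000, seed=3,
                               repression_mode="hill").noiseless()
        cfg = replace(cfg, repression_mode="hill")
        spec = make_construct(e=0.1)
        cog = simulate_cotransfection(cfg, double_transfection(spec, "L7Ae"))
        non = simulate_cotransfection(cfg, double_transfection(spec, "MS2CP"))
        dose = cog["truth_trigger_copies"]
        lo = (dose > 10) & (dose < 30)      # below the Hill midpoint
        hi = dose > 500                      # deep on the plateau
        r_lo = cog.loc[lo, "det530"].mean() / non.loc[lo, "det530"].mean()
        r_hi = cog.loc[hi, "det530"].mean() / non.loc[hi, "det530"].mean()
        assert r_hi < r_lo <= 1.0
        assert r_hi == pytest.approx(0.1, rel=0.05)


class TestSingleColorControls:
    def test_identity_spillover_leaves_other_detectors_dark(self,
                                                            noiseless_config):
        table = simulate_single_color_controls(noiseless_config, "EGFP")
        assert (table["det450"] == 0).all()
        assert (table["det695"] == 0).all()
        assert (table["det530"] > 0).all()

    def test_detector_vector_follows_spillover_row(self, noiseless_config):
        """With a known mixing matrix and noise off, every event's detector
        vector is abundance times the fluorophore's matrix row."""
        m = default_spillover_matrix()
        cfg = replace(noiseless_config, spillover_truth=m)
        for i, f in enumerate(FLUOROPHORES):
            table = simulate_single_color_controls(cfg, f)
            det = table[list(DETECTORS)].to_numpy()
            primary = det[:, DETECTORS.index(PRIMARY_DETECTOR[f])]
            expected = primary[:, None] * m[i] / m[i, DETECTORS.index(
                PRIMARY_DETECTOR[f])]
            np.testing.assert_allclose(det, expected, rtol=1e-9)

    def test_event_count_conserved(self, default_config):
        table = simulate_single_color_controls(
            replace(default_config, n_events=1000), "DsRed")
        assert len(table) == 1000

    def test_unknown_fluorophore_rejected(self, default_config):
        with pytest.raises(ValueError, match="fluorophore"):
            simulate_single_color_controls(default_config, "mOrange")


class TestTripleTransfection:
    def test_same_fluorophore_pair_rejected(self, default_config):
        a = make_construct(motif="Kt", reporter="EGFP")
        b = make_construct(motif="dKt", reporter="EGFP", name="other")
        with pytest.raises(ValueError, match="EGFP twice"):
            triple_transfection(a, b, "L7Ae")

    def test_trigger_none_leaves_both_reporters_unrepressed(
            self, noiseless_config):
        a = make_construct(e=1.3, motif="dKt", reporter="EGFP", name="dKt-E")
        b = make_construct(e=0.67, motif="Kl", reporter="ECFP", name="Kl-C")
        mix = triple_transfection(a, b, "none")
        ref = triple_transfection(a, b, "MS2CP")
        t = simulate_triple_transfection(noiseless_config, mix)
        r = simulate_triple_transfection(noiseless_config, ref)
        # no cognate trigger anywhere: identical reporter output
        np.testing.assert_allclose(t["det530"], r["det530"], rtol=1e-12)
        np.testing.assert_allclose(t["det450"], r["det450"], rtol=1e-12)

    def test_cognate_trigger_scales_each_channel_by_its_own_efficiency(
            self, noiseless_config):
        a = make_construct(e=0.017, motif="Kt", reporter="EGFP", name="Kt-E")
        b = make_construct(e=0.67, motif="Kl", reporter="ECFP", name="Kl-C")
        cog = simulate_triple_transfection(
            noiseless_config, triple_transfection(a, b, "L7Ae"))
        non = simulate_triple_transfection(
            noiseless_config, triple_transfection(a, b, "MS2CP"))
        assert cog["det530"].mean() / non["det530"].mean() == \
            pytest.approx(0.017, rel=1e-9)
        assert cog["det450"].mean() / non["det450"].mean() == \
            pytest.approx(0.67, rel=1e-9)

    def test_untransfected_fraction_zero_means_no_dark_cells(
            self, noiseless_config):
        a = make_construct(motif="Kt", reporter="EGFP")
        b = make_construct(motif="Kl", reporter="ECFP", name="b")
        table = simulate_triple_transfection(
            noiseless_config, triple_transfection(a, b, "L7Ae"))
        assert not table["truth_untransfected"].any()

    def test_untransfected_subpopulation_has_zero_dsred(self):
        cfg = SimulationConfig(n_events=20_000, seed=4,
                               untransfected_fraction=0.3).noiseless()
        cfg = replace(cfg, untransfected_fraction=0.3)
        a = make_construct(motif="Kt", reporter="EGFP")
        b = make_construct(motif="Kl", reporter="ECFP", name="b")
        table = simulate_triple_transfection(
            cfg, triple_transfection(a, b, "L7Ae"))
        frac = table["truth_untransfected"].mean()
        assert frac == pytest.approx(0.3, abs=0.02)
        assert (table.loc[table["truth_untransfected"], "det695"] == 0).all()


class TestEventsIO:
    def test_csv_round_trip(self, default_config, tmp_path):
        mix = double_transfection(make_construct(), "L7Ae")
        table = simulate_cotransfection(replace(default_config, n_events=100),
                                        mix)
        path = tmp_path / "events.csv"
        write_events_csv(table, path)
        back = read_events_csv(path)
        for col in DETECTORS:
            np.testing.assert_allclose(back[col], table[col], rtol=1e-6)

    def test_observed_export_strips_truth_columns(self, default_config,
                                                  tmp_path):
        mix = double_transfection(make_construct(), "L7Ae")
        table = simulate_cotransfection(replace(default_config, n_events=50),
                                        mix)
        path = tmp_path / "observed.csv"
        write_events_csv(table, path, observed_only=True)
        back = pd.read_csv(path)
        assert list(back.columns) == list(OBSERVED_COLUMNS)

    def test_missing_column_error_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"fsc": [1.0], "ssc": [1.0], "det450": [0.0],
                      "det530": [0.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="det695"):
            read_events_csv(path)

    def test_fcs_ingestion_with_channel_map(self, tmp_path):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 1000, size=(200, 5)).astype(np.float32)
        path = tmp_path / "sample.fcs"
        write_minimal_fcs(path, data, ["FSC-A", "SSC-A", "FL1", "FL2", "FL3"])
        table = read_events_fcs(path, channel_map={
            "FSC-A": "fsc", "SSC-A": "ssc", "FL1": "det450",
            "FL2": "det530", "FL3": "det695"})
        assert len(table) == 200
        np.testing.assert_allclose(table["det530"], data[:, 3], rtol=1e-6)

    def test_fcs_unmappable_channels_error(self, tmp_path):
        data = np.zeros((5, 3), dtype=np.float32)
        path = tmp_path / "bad.fcs"
        write_minimal_fcs(path, data, ["A", "B", "C"])
        with pytest.raises(ValueError, match="channel_map"):
            read_events_fcs(path)


class TestDefaults:
    def test_both_printed_windows_are_populated(self, default_config):
        """The uptake calibration must leave >= 1% of events in each of the
        500 +/- 50 and 1000 +/- 100 a.u. DsRed windows."""
        mix = double_transfection(make_construct(e=1.0), "L7Ae")
        table = simulate_cotransfection(replace(default_config,
                                                n_events=100_000), mix)
        ds = table["truth_trigger_copies"]
        for lo, hi in ((900, 1100), (450, 550)):
            assert ((ds >= lo) & (ds <= hi)).mean() >= 0.01

    def test_identity_matrix_shape(self):
        m = identity_spillover_matrix()
        assert m.sum() == 3 and ((m == 0) | (m == 1)).all()
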