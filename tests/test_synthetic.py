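"""The synthetic-recording generator: determinism, Poisson statistics,
tonotopy by construction, baseline behavior and cohort structure."""

import numpy as np
import pytest
from scipy import stats

from ocipipe import synthetic as syn
from ocipipe.signal import ResponseWindow
from ocipipe.stc import build_response_matrix, build_stc, cumulative_dprime


class TestGeometryTypes:
    def test_place_frequency_map_inverts(self, model):
        x = np.linspace(0, model.length_mm, 23)
        assert np.allclose(model.place_at(model.freq_at(x)), x)
        f = model.freq_at(x)
        assert np.all(np.diff(f) < 0)  # frequency falls from base to apex

    def test_layout_span_and_validation(self):
        layout = syn.EmitterLayout(n_emitters=16, pitch_mm=0.25)
        assert layout.span_mm == pytest.approx(3.75)
        with pytest.raises(ValueError):
            syn.EmitterLayout(n_emitters=0)

    def test_ladder_requires_zero_baseline_and_monotonicity(self):
        with pytest.raises(ValueError, match="0"):
            syn.StimulusLadder("single_led", (1.0, 2.0))
        with pytest.raises(ValueError):
            syn.StimulusLadder("single_led", (0.0, 2.0, 1.0))

    def test_flux_curve_anchors(self):
        ladder = syn.default_ladder("single_led")
        assert ladder.flux_per_current(10.0) == pytest.approx(0.76, abs=0.02)
        assert 4 * ladder.flux_per_current(2.5) == pytest.approx(0.99, abs=0.03)


class TestFraGenerator:
    def test_same_seed_identical(self, model, probe, act_uniform):
        ladder = syn.default_acoustic_ladder(5)
        a = syn.simulate_fra_dataset(model, probe, act_uniform, ladder, seed=5)
        b = syn.simulate_fra_dataset(model, probe, act_uniform, ladder, seed=5)
        assert a.equals(b)

    def test_generative_tonotopy_exact_by_construction(self, probe):
        act = syn.ActivationModel()
        depths = probe.depths_mm()
        bf = act.best_frequency(depths)
        slope = np.polyfit(depths, np.log2(bf), 1)[0]
        assert slope == pytest.approx(act.tonotopic_slope_oct_per_mm, abs=1e-12)
        # two electrodes a known distance apart differ by exactly slope*dx octaves
        assert np.log2(bf[10] / bf[4]) == pytest.approx(
            act.tonotopic_slope_oct_per_mm * 6 * probe.pitch_mm, abs=1e-12
        )

    def test_poisson_mean_at_tip_matches_tally(self, model, probe):
        """25 trials of a 100 ms tone at a strongly driven cell: mean count
        in the tone window ~ evoked 8 + baseline 2, within 3 SE."""
        act = syn.ActivationModel()
        ladder = syn.default_acoustic_ladder(25)
        table = syn.simulate_fra_dataset(
            model, probe, act, ladder, seed=6,
            threshold_range_db=(30.0, 30.0),
        )
        el, f_lab = 1, "0.5"  # electrode 1's bf is exactly 0.5 kHz
        sub = table[(table.electrode == el) & (table.emitter_set == f_lab)
                    & (table.intensity == 80.0)]
        counts = [
            ((g.t_ms >= 5.0) & (g.t_ms < 105.0)).sum()
            for _, g in sub.groupby("trial")
        ]
        counts = np.array(counts + [0] * (25 - len(counts)), dtype=float)
        expect = 8.0 + act.baseline_rate_hz * 0.1
        se = np.sqrt(expect / 25)
        assert abs(counts.mean() - expect) <= 3 * se

    def test_deaf_animal_has_spontaneous_activity_only(self, model, probe):
        act = syn.ActivationModel()
        ladder = syn.default_acoustic_ladder(10)
        table = syn.simulate_fra_dataset(model, probe, act, ladder, seed=7,
                                         hearing=False)
        # rate in the tone window equals the baseline rate everywhere
        n_stim = len(ladder.intensities) * 25 * 10 * probe.n_electrodes
        in_win = ((table.t_ms >= 0) & (table.t_ms < 100)).sum()
        total_rate = in_win / (len(ladder.intensities) * 25 * 10 * probe.n_electrodes * 0.1)
        assert total_rate == pytest.approx(act.baseline_rate_hz, rel=0.05)

    def test_narrow_grid_rejected(self, model, probe, act_uniform):
        with pytest.raises(ValueError, match="octaves"):
            syn.simulate_fra_dataset(
                model, probe, act_uniform, syn.default_acoustic_ladder(5),
                seed=0, freqs_khz=(4.0, 5.0, 6.0),
            )


class TestOpticalGenerator:
    def test_same_seed_identical(self, model, probe, layout250, act_uniform):
        ladder = syn.default_ladder("block4", n_trials=5)
        a = syn.simulate_optical_trials(model, layout250, act_uniform, ladder,
                                        (4, 5, 6, 7), 8, probe=probe)
        b = syn.simulate_optical_trials(model, layout250, act_uniform, ladder,
                                        (4, 5, 6, 7), 8, probe=probe)
        assert a.equals(b)

    def test_zero_intensity_step_emits_baseline_rate(self, model, probe,
                                                     layout250, act_uniform):
        ladder = syn.default_ladder("single_led", n_trials=50)
        table = syn.simulate_optical_trials(model, layout250, act_uniform,
                                            ladder, (8,), 9, probe=probe)
        base = table[table.intensity == 0.0]
        rate = len(base) / (50 * probe.n_electrodes * 0.05)
        se = act_uniform.baseline_rate_hz / np.sqrt(len(base))
        assert rate == pytest.approx(act_uniform.baseline_rate_hz, abs=3 * se)

    def test_full_array_recruits_more_than_single(self, model, probe,
                                                  layout250, act_uniform):
        """All 16 emitters at maximum vs one at maximum: strictly more evoked
        spikes, tallied over 200 trials."""
        win = ResponseWindow()
        totals = {}
        for mode, active in (("single_led", (8,)), ("all_leds", tuple(range(16)))):
            ladder = syn.StimulusLadder(
                mode, (0.0, 10.0 if mode == "single_led" else 40.0),
                n_trials_per_step=200,
            )
            table = syn.simulate_optical_trials(model, layout250, act_uniform,
                                                ladder, active, 10, probe=probe)
            stim = table[table.intensity > 0]
            totals[mode] = ((stim.t_ms >= win.start_ms) & (stim.t_ms < win.end_ms)).sum()
        assert totals["all_leds"] > totals["single_led"]

    def test_fiber_drives_nearly_all_sites(self, model, probe, layout250,
                                           act_uniform):
        """Broad suprathreshold fiber illumination with full transduction
        reaches >= 30 of 32 recording sites."""
        ladder = syn.default_ladder("fiber")
        table = syn.simulate_optical_trials(model, layout250, act_uniform,
                                            ladder, (), 11, probe=probe)
        rm = build_response_matrix(table, ladder, ResponseWindow())
        stc = build_stc(cumulative_dprime(rm))
        assert stc.n_active >= 30

    def test_emitter_outside_cochlea_rejected(self, model, probe, act_uniform):
        layout = syn.EmitterLayout(pitch_mm=0.25, insertion_depth_mm=10.0)
        with pytest.raises(ValueError, match="outside the cochlea"):
            syn.simulate_optical_trials(model, layout, act_uniform,
                                        syn.default_ladder("single_led"),
                                        (15,), 0, probe=probe)

    def test_wildtype_without_hair_cells_is_silent(self, model, probe, layout250):
        act = syn.ActivationModel(transduction_profile=0.0, latency_ms=5.0,
                                  duration_ms=5.5)
        ladder = syn.default_ladder("all_leds", n_trials=30)
        table = syn.simulate_optical_trials(model, layout250, act, ladder,
                                            tuple(range(16)), 12, probe=probe)
        rm = build_response_matrix(table, ladder, ResponseWindow())
        stc = build_stc(cumulative_dprime(rm))
        assert stc.max_dprime < 1.0

    def test_wildtype_optoacoustic_response_is_dorsal_and_weak(
        self, model, probe, layout250
    ):
        act = syn.ActivationModel(transduction_profile=0.0, latency_ms=5.0,
                                  duration_ms=5.5, optoacoustic_gain_hz=250.0)
        ladder = syn.default_ladder("all_leds", n_trials=30)
        table = syn.simulate_optical_trials(model, layout250, act, ladder,
                                            tuple(range(16)), 13, probe=probe,
                                            hearing_hair_cells=True)
        rm = build_response_matrix(table, ladder, ResponseWindow())
        stc = build_stc(cumulative_dprime(rm))
        assert stc.best_electrode is not None and stc.best_electrode <= 8
        # weaker than the transduced condition at the same drive
        act_t = syn.ActivationModel(transduction_profile=1.0)
        table_t = syn.simulate_optical_trials(model, layout250, act_t, ladder,
                                              tuple(range(16)), 13, probe=probe)
        stc_t = build_stc(cumulative_dprime(
            build_response_matrix(table_t, ladder, ResponseWindow())
        ))
        assert stc.max_dprime < stc_t.max_dprime


class TestCohort:
    def test_statuses_respected(self, model):
        spec = syn.CohortSpec(
            4, ("hearing", "deaf", "wildtype_hearing", "wildtype_deaf"), seed=3
        )
        animals = syn.draw_cohort(spec, model)
        assert [a.hears for a in animals] == [True, False, True, False]
        assert [a.transduced for a in animals] == [True, True, False, False]
        assert animals[2].act.transduction_profile == 0.0
        assert animals[2].act.latency_ms == 5.0
        assert animals[3].act.optoacoustic_gain_hz == 0.0

    def test_cohort_reproducible_and_animals_differ(self, model):
        spec = syn.CohortSpec(3, ("hearing",) * 3, seed=4)
        a = syn.draw_cohort(spec, model)
        b = syn.draw_cohort(spec, model)
        assert all(x.act.rate_max_hz == y.act.rate_max_hz for x, y in zip(a, b))
        assert len({round(x.act.rate_max_hz, 6) for x in a}) == 3

    def test_optical_counts_indistinguishable_hearing_vs_deaf(self, model, probe,
                                                              layout250):
        """Equal-parameter hearing and deafened animals give statistically
        indistinguishable optical window counts (KS test, alpha = 0.01)."""
        act = syn.ActivationModel(transduction_profile=1.0)
        ladder = syn.default_ladder("all_leds", n_trials=30)
        win = ResponseWindow()
        samples = []
        for seed in (21, 22):  # same model, independent noise -> same law
            table = syn.simulate_optical_trials(model, layout250, act, ladder,
                                                tuple(range(16)), seed,
                                                probe=probe)
            rm = build_response_matrix(table, ladder, win)
            samples.append(rm.counts[:, -1, :].ravel())
        p = stats.ks_2samp(samples[0], samples[1]).pvalue
        assert p > 0.01


class TestRawTrace:
    def test_zero_spikes_zero_noise_gives_zero_trace(self):
        trace = syn.simulate_raw_trace(np.empty(0), noise_sd=0.0, fs=32000.0,
                                       seed=0, duration_ms=10.0)
        assert np.all(trace.samples == 0)

    def test_same_seed_identical(self):
        a = syn.simulate_raw_trace([5.0, 9.0], noise_sd=1.0, fs=32000.0, seed=1,
                                   duration_ms=20.0)
        b = syn.simulate_raw_trace([5.0, 9.0], noise_sd=1.0, fs=32000.0, seed=1,
                                   duration_ms=20.0)
        assert np.array_equal(a.samples, b.samples)

    def test_overlapping_spikes_warn(self):
        with pytest.warns(UserWarning, match="overlap"):
            syn.simulate_raw_trace([5.0, 5.2], noise_sd=0.5, fs=32000.0, seed=2,
                                   duration_ms=20.0)

    def test_detector_recall_on_ground_truth(self):
        from ocipipe.signal import detect_spikes

        true_t = np.arange(5.0, 55.0, 5.0)  # 10 spikes
        trace = syn.simulate_raw_trace(true_t, noise_sd=1.0, fs=32000.0, seed=3,
                                       amplitude=10.0, duration_ms=60.0,
                                       noise="uniform")
        found = detect_spikes(trace, prefiltered=True)
        assert all(np.any(np.abs(found - t) < 0.3) for t in true_t)
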