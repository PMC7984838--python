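"""Response extraction, selectivity indices, screens and plaid-strength metrics."""

import numpy as np
import pandas as pd
import pytest

import plaidpss as pp
from plaidpss.tuning import estimate_latency


def _table_from_rates(stim_set, rate_of, reps=None, rng=None):
    """Build a trial table with counts defined by ``rate_of(condition)`` (Hz)."""
    reps = reps or stim_set.reps
    rows = []
    for cond in stim_set.conditions:
        lam = rate_of(cond) * stim_set.window_s
        for t in range(reps):
            k = rng.poisson(lam) if rng is not None else int(round(lam))
            rows.append(
                ("a", 0, t, cond.kind, cond.pattern_direction, cond.dori, cond.contrast,
                 int(k), stim_set.window_s)
            )
    return pd.DataFrame(
        rows,
        columns=["animal_id", "neuron_id", "trial", "kind", "pattern_direction_deg",
                 "dori_deg", "contrast", "count", "window_s"],
    )


class TestMeanResponses:
    def test_uniform_counts_give_the_flat_rate(self, classic_set):
        trials = _table_from_rates(classic_set, lambda c: 3.0 if c.kind != "blank" else 0.0)
        prof = pp.mean_responses(trials, classic_set)
        assert np.allclose(prof.grating_rates, 3.0)
        assert np.allclose(prof.plaid_rates, 3.0)

    def test_classic_subtracts_the_blank_rate(self, classic_set):
        trials = _table_from_rates(classic_set, lambda c: 5.0 if c.kind != "blank" else 2.0)
        prof = pp.mean_responses(trials, classic_set)
        assert np.allclose(prof.grating_rates, 3.0)
        assert prof.blank_rate == 0.0

    def test_streaming_keeps_raw_rates(self, streaming_set):
        trials = _table_from_rates(streaming_set, lambda c: 6.0 if c.kind != "blank" else 3.0)
        prof = pp.mean_responses(trials, streaming_set)
        assert np.allclose(prof.grating_rates, 6.0)
        assert prof.blank_rate == pytest.approx(3.0)

    def test_missing_condition_is_named(self, classic_set):
        trials = _table_from_rates(classic_set, lambda c: 3.0)
        trials = trials[trials["kind"] != "blank"]
        with pytest.raises(ValueError, match="blank"):
            pp.mean_responses(trials, classic_set)


class TestLatency:
    def test_recovers_the_generating_latency(self, young_bank):
        stim_set = pp.build_streaming_set(reps=30)
        neuron = pp.simulate_population(1, seed=30)[0]
        extract = pp.streaming_extractor(
            neuron, stim_set, young_bank, seed=90, true_latency_s=0.05
        )
        grid = np.arange(0.0, 0.151, 0.01)
        assert estimate_latency(extract, grid) == pytest.approx(0.05)

    def test_flat_data_tie_breaks_to_smallest(self, classic_set):
        flat = _table_from_rates(classic_set, lambda c: 4.0)
        assert estimate_latency(lambda lat: flat, [0.02, 0.0, 0.05]) == 0.0

    def test_single_element_grid(self, classic_set):
        flat = _table_from_rates(classic_set, lambda c: 4.0)
        assert estimate_latency(lambda lat: flat, [0.03]) == 0.03

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            estimate_latency(lambda lat: None, [])


class TestSelectivity:
    def test_textbook_values(self):
        rates = np.zeros(16)
        rates[0] = 10.0
        assert pp.selectivity_indices(rates).dsi == pytest.approx(1.0)
        rates[8] = 10.0
        assert pp.selectivity_indices(rates).dsi == pytest.approx(0.0)
        rates = np.zeros(16)
        rates[0] = 8.0
        rates[4] = 2.0
        rates[12] = 4.0
        assert pp.selectivity_indices(rates).osi == pytest.approx(1 - 3.0 / 8.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        rates = rng.uniform(0.5, 10, 16)
        a = pp.selectivity_indices(rates)
        b = pp.selectivity_indices(rates * 7.3)
        assert a.dsi == pytest.approx(b.dsi) and a.osi == pytest.approx(b.osi)

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(ValueError):
            pp.selectivity_indices(np.zeros(16))


class TestScreens:
    def test_strong_model_neuron_passes_streaming_screen(self, streaming_set, young_bank):
        neuron = pp.GroundTruthNeuron(
            pp.PSSParams(3.0, 3.0, 1.0, 1.5, 25.0), 90.0, baseline_rate=0.2
        )
        trials = pp.generate_trials(neuron, streaming_set, young_bank, seed=21)
        prof = pp.mean_responses(trials, streaming_set)
        res = pp.screen_streaming(prof, trials)
        assert res.passed, res.reasons

    def test_unresponsive_neuron_fails_with_reasons(self, streaming_set, young_bank):
        neuron = pp.GroundTruthNeuron(
            pp.PSSParams(2.0, 2.0, 0.5, 1.0, 30.0), 0.0, baseline_rate=1.0
        )
        trials = pp.generate_trials(neuron, streaming_set, young_bank, seed=22)
        flat = trials.copy()
        rng = np.random.default_rng(0)
        flat["count"] = rng.poisson(0.05, size=len(flat))  # condition-independent
        prof = pp.mean_responses(flat, streaming_set)
        res = pp.screen_streaming(prof, flat)
        assert not res.passed
        assert any("anova" in r for r in res.reasons)
        assert any("best_grating" in r for r in res.reasons)

    def test_dsi_exactly_at_boundary_fails(self, streaming_set, young_bank):
        neuron = pp.GroundTruthNeuron(
            pp.PSSParams(3.0, 3.0, 1.0, 1.5, 25.0), 90.0, baseline_rate=0.2
        )
        trials = pp.generate_trials(neuron, streaming_set, young_bank, seed=21)
        prof = pp.mean_responses(trials, streaming_set)
        # force DSI = 0.7 exactly: strict inequality must reject it
        prof.grating_rates[:] = 0.0
        prof.grating_rates[prof.pref_index] = 10.0
        prof.grating_rates[(prof.pref_index + 8) % 16] = 3.0
        res = pp.screen_streaming(prof, trials)
        assert any(r.startswith("dsi") for r in res.reasons)

    def test_classic_screen_rate_threshold(self, classic_set, young_bank):
        # tuned but weak: best below 2 Hz fails
        weak = _table_from_rates(
            classic_set,
            lambda c: 1.0 if (c.kind == "grating" and c.pattern_direction == 0.0) else 0.0,
            rng=None,
        )
        prof = pp.mean_responses(weak, classic_set)
        res = pp.screen_classic(prof, weak, experiment="plaid")
        assert any("best_rate" in r for r in res.reasons)

    def test_classic_screen_passes_strongly_tuned_cell(self, classic_set):
        rng = np.random.default_rng(3)
        tuned = _table_from_rates(
            classic_set,
            lambda c: 0.5 + 12.0 * np.exp(3 * (np.cos(np.deg2rad(c.pattern_direction)) - 1))
            if c.kind != "blank"
            else 0.5,
            rng=rng,
        )
        prof = pp.mean_responses(tuned, classic_set)
        assert pp.screen_classic(prof, tuned, experiment="plaid").passed

    def test_classic_screen_fails_untuned_cell(self, classic_set):
        rng = np.random.default_rng(4)
        untuned = _table_from_rates(
            classic_set, lambda c: 5.0 if c.kind != "blank" else 5.0, rng=rng
        )
        prof = pp.mean_responses(untuned, classic_set)
        res = pp.screen_classic(prof, untuned, experiment="plaid")
        assert not res.passed

    def test_rate_screens_are_monotone_in_scale(self, streaming_set, young_bank):
        neuron = pp.GroundTruthNeuron(
            pp.PSSParams(3.0, 3.0, 1.0, 1.5, 25.0), 90.0, baseline_rate=0.2
        )
        trials = pp.generate_trials(neuron, streaming_set, young_bank, seed=21)
        prof = pp.mean_responses(trials, streaming_set)
        scaled = pp.TuningProfile2D(
            prof.plaid_rates * 3, prof.grating_rates * 3, prof.blank_rate * 3,
            prof.dori_values,
        )
        before = pp.screen_streaming(prof, trials)
        after = pp.screen_streaming(scaled, trials)
        rate_fail_before = {r.split("=")[0] for r in before.reasons if "Hz" in r}
        rate_fail_after = {r.split("=")[0] for r in after.reasons if "Hz" in r}
        assert rate_fail_after <= rate_fail_before


class TestRelativePlaidMetrics:
    def _profile(self, streaming_set, grid, grating):
        return pp.TuningProfile2D(grid, grating, 0.0, streaming_set.dori_values)

    def test_constant_grid_maps_to_ones(self, streaming_set):
        prof = self._profile(streaming_set, np.full((7, 16), 4.0), np.full(16, 4.0))
        grid, _ = pp.relative_plaid_profile(prof)
        assert np.allclose(grid, 1.0)
        assert np.allclose(pp.relative_plaid_by_dori(grid), 1.0)

    def test_alignment_moves_pref_to_zero(self, streaming_set):
        grating = np.zeros(16)
        grating[5] = 2.0
        grid = np.arange(112, dtype=float).reshape(7, 16)
        prof = self._profile(streaming_set, grid, grating + 1.0)
        aligned, rel = pp.relative_plaid_profile(prof)
        assert rel[0] == 0.0
        denom = np.mean(grating + 1.0)
        assert np.allclose(aligned[:, 0], grid[:, 5] / denom)

    def test_max_grating_normalizer_identity_on_unit_profile(self, streaming_set):
        prof = self._profile(streaming_set, np.full((7, 16), 0.5), np.linspace(0.1, 1.0, 16))
        grid, _ = pp.relative_plaid_profile(prof, normalizer="max_grating")
        assert np.allclose(grid, 0.5)

    def test_zero_denominator_rejected(self, streaming_set):
        prof = self._profile(streaming_set, np.ones((7, 16)), np.zeros(16))
        with pytest.raises(ValueError):
            pp.relative_plaid_profile(prof)

    def test_max_plaid_grating_ratio(self, streaming_set):
        grid = np.zeros((7, 16))
        grid[3, 4] = 3.0  # dOri = 90 row
        prof = self._profile(streaming_set, grid, np.array([6.0] + [0.1] * 15))
        assert pp.max_plaid_grating_ratio(prof, dori=90.0) == pytest.approx(0.5)
        scaled = self._profile(streaming_set, grid * 2.5, np.array([15.0] + [0.25] * 15))
        assert pp.max_plaid_grating_ratio(scaled, dori=90.0) == pytest.approx(0.5)


class TestWilsonHilferty:
    def test_cube_root_values(self):
        assert pp.wilson_hilferty(8.0) == pytest.approx(2.0)
        assert pp.wilson_hilferty(0.0) == 0.0
        assert np.allclose(pp.wilson_hilferty(np.array([1.0, 27.0])), [1.0, 3.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pp.wilson_hilferty(-1.0)

    def test_reduces_chi_square_skewness(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        x = rng.chisquare(10, size=10000)
        assert abs(stats.skew(pp.wilson_hilferty(x))) < abs(stats.skew(x))
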