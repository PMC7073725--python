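"""Chance correction, psychometric fitting and Feller-model classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aromix as am
from aromix import NonIdentifiableError, ValidationError
from aromix.psychophysics import DetectionDataset
from aromix.synthetic import (
    MixtureSimConfig,
    PanelSimConfig,
    expected_panel,
    simulate_mixture_panel,
    simulate_panel,
)

LEVELS = [1.4, 1.7, 2.0, 2.3, 2.6, 2.9]


class TestChanceCorrection:
    @pytest.mark.parametrize("p_c,m,expected", [(1 / 3, 3, 0.0), (1.0, 3, 1.0),
                                                (2 / 3, 3, 0.5), (0.5, 2, 0.0)])
    def test_known_points(self, p_c, m, expected):
        assert am.correct_for_chance(p_c, m) == pytest.approx(expected)

    def test_subchance_returned_with_flag(self):
        res = am.correct_for_chance(0.2, 3, with_flag=True)
        assert res.P < 0 and res.subchance

    def test_m_below_two_rejected(self):
        with pytest.raises(ValidationError):
            am.correct_for_chance(0.5, 1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(P=st.floats(0, 1), m=st.integers(2, 6))
    def test_guessing_model_inversion_identity(self, P, m):
        # folding P into the guessing model and correcting for chance is exact
        p_c = 1 / m + (1 - 1 / m) * P
        assert am.correct_for_chance(p_c, m) == pytest.approx(P, abs=1e-12)


class TestLogistic:
    def test_threshold_definition(self):
        assert am.psychometric_probability(2.0, c=2.0, D=0.15) == pytest.approx(0.5)

    def test_asymptotes(self):
        assert am.psychometric_probability(-1e3, 2.0, 0.15) == pytest.approx(0.0)
        assert am.psychometric_probability(1e3, 2.0, 0.15) == pytest.approx(1.0)

    def test_quartile_point(self):
        # P = 0.75 exactly D*ln(3) above threshold
        x = 2.0 + 0.15 * math.log(3)
        assert am.psychometric_probability(x, 2.0, 0.15) == pytest.approx(0.75)

    def test_strictly_increasing(self):
        xs = np.linspace(0, 4, 100)
        ps = am.psychometric_probability(xs, 2.0, 0.3)
        assert np.all(np.diff(ps) > 0)

    def test_nonpositive_gradient_rejected(self):
        with pytest.raises(ValidationError):
            am.psychometric_probability(1.0, 2.0, 0.0)


class TestFit:
    def test_noiseless_inversion_recovers_parameters(self):
        cfg = PanelSimConfig(true_c=2.0, true_D=0.15, concentration_levels=LEVELS,
                             n_panelists=200, reps=1)
        fit = am.fit_psychometric(expected_panel(cfg))
        assert fit.c == pytest.approx(2.0, abs=1e-3)
        assert fit.D == pytest.approx(0.15, abs=1e-3)
        assert fit.converged

    def test_seeded_panel_recovery_within_tolerance(self):
        # 20 panellists x 3 reps, 6 levels: |c_hat - c| <= 0.15 log units
        for seed in range(10):
            cfg = PanelSimConfig(true_c=2.0, true_D=0.15,
                                 concentration_levels=LEVELS, seed=seed)
            fit = am.fit_psychometric(simulate_panel(cfg))
            assert abs(fit.c - 2.0) <= 0.15

    def test_mean_bias_over_100_panels(self):
        errs = []
        for seed in range(100):
            cfg = PanelSimConfig(true_c=2.0, true_D=0.15,
                                 concentration_levels=LEVELS, seed=10_000 + seed)
            errs.append(am.fit_psychometric(simulate_panel(cfg)).c - 2.0)
        assert abs(np.mean(errs)) <= 0.05

    def test_two_levels_rejected(self):
        data = DetectionDataset("d", [(1.0, 60, 25), (3.0, 60, 58)])
        with pytest.raises(NonIdentifiableError):
            am.fit_psychometric(data)

    @pytest.mark.parametrize("k_per_level", [60, 20])
    def test_flat_data_not_identifiable(self, k_per_level):
        # all-correct (ceiling) and all-chance data carry no threshold
        data = DetectionDataset("d", [(x, 60, k_per_level) for x in LEVELS])
        with pytest.raises(NonIdentifiableError):
            am.fit_psychometric(data)

    def test_threshold_linear_scale(self):
        fit = am.PsychometricFit("s", c=2.0, D=0.1)
        assert fit.threshold_linear == pytest.approx(100.0)


class TestFeller:
    @pytest.mark.parametrize("pa,pb,expected", [(0.5, 0.5, 0.75), (0.0, 0.37, 0.37),
                                                (1.0, 0.37, 1.0)])
    def test_known_combinations(self, pa, pb, expected):
        assert am.feller_probability(pa, pb) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            am.feller_probability(1.2, 0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(pa=st.floats(0, 1), pb=st.floats(0, 1))
    def test_complement_identity_and_bounds(self, pa, pb):
        p = am.feller_probability(pa, pb)
        assert p == pytest.approx(1 - (1 - pa) * (1 - pb), abs=1e-12)
        assert max(pa, pb) - 1e-12 <= p <= 1.0
        assert p == pytest.approx(am.feller_probability(pb, pa))


class TestFellerPrediction:
    FIT_A = am.PsychometricFit("A", c=2.0, D=0.15)
    FIT_B = am.PsychometricFit("B", c=2.6, D=0.20)

    def test_equal_components_threshold_below_either(self):
        fit = am.PsychometricFit("A", c=2.0, D=0.15)
        pred = am.feller_predicted_curve(fit, fit, (0.5, 0.5))
        # each component alone (at half the total) crosses 0.5 at total
        # 2*10^c; independence pulls the mixture threshold below that
        single = 2.0 * 10**fit.c
        assert pred.threshold_linear < single

    def test_negligible_component_collapses_to_other(self):
        ghost = am.PsychometricFit("ghost", c=50.0, D=0.15)
        pred = am.feller_predicted_curve(self.FIT_A, ghost, (0.5, 0.5))
        # prediction reduces to component A shifted by its proportion
        assert pred.threshold == pytest.approx(self.FIT_A.c - math.log10(0.5), abs=1e-6)

    def test_threshold_matches_grid_oracle(self):
        pred = am.feller_predicted_curve(self.FIT_A, self.FIT_B, (0.5, 0.5))
        grid = np.linspace(0.0, 5.0, 500_001)
        p = am.feller_probability(
            self.FIT_A.detection_probability(grid + math.log10(0.5)),
            self.FIT_B.detection_probability(grid + math.log10(0.5)),
        )
        oracle = grid[np.searchsorted(p, 0.5)]
        assert pred.threshold == pytest.approx(oracle, abs=2e-5)

    def test_threshold_bounded_by_scaled_components(self):
        pred = am.feller_predicted_curve(self.FIT_A, self.FIT_B, (0.3, 0.7))
        bound = min(10**self.FIT_A.c / 0.3, 10**self.FIT_B.c / 0.7)
        assert pred.threshold_linear <= bound + 1e-9

    def test_prediction_at_threshold_is_half(self):
        pred = am.feller_predicted_curve(self.FIT_A, self.FIT_B, (0.4, 0.6))
        assert pred.detection_probability(pred.threshold) == pytest.approx(0.5, abs=1e-9)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValidationError):
            am.feller_predicted_curve(self.FIT_A, self.FIT_B, (0.5, 0.6))


class TestClassify:
    FIT_A = am.PsychometricFit("A", c=2.0, D=0.15)
    FIT_B = am.PsychometricFit("B", c=2.6, D=0.20)

    def _simulate_and_classify(self, mode, factor, seed, n_boot=400):
        cfg = MixtureSimConfig(self.FIT_A, self.FIT_B, 0.5, 0.5,
                               interaction_mode=mode, factor=factor, seed=seed)
        levels = list(np.linspace(cfg.true_threshold - 0.75,
                                  cfg.true_threshold + 0.75, 6))
        data = simulate_mixture_panel(cfg, levels)
        obs = am.fit_psychometric(data)
        return am.classify_feller(obs, cfg.feller_prediction, data,
                                  n_boot=n_boot, seed=seed + 1)

    def test_observed_equal_predicted_is_additive(self):
        # feed the prediction's own expected counts back as "observed"
        pred = am.feller_predicted_curve(self.FIT_A, self.FIT_B, (0.5, 0.5))
        levels = np.linspace(pred.threshold - 0.75, pred.threshold + 0.75, 6)
        n = 60
        pts = [(x, n, n * (1 / 3 + 2 / 3 * pred.detection_probability(x)))
               for x in levels]
        data = DetectionDataset("mix", pts)
        obs = am.fit_psychometric(data)
        cmp_ = am.classify_feller(obs, pred, data, n_boot=400, seed=0)
        assert cmp_.classification == "independent-additive"
        # the Feller-combined curve is not exactly logistic, so projecting it
        # onto the logistic family shifts the crossing slightly (<1%)
        assert cmp_.threshold_ratio == pytest.approx(1.0, abs=0.01)

    def test_synthetic_synergy_detected_with_ratio(self):
        cmp_ = self._simulate_and_classify("factor", 0.5, seed=11)
        assert cmp_.classification == "synergy"
        assert cmp_.threshold_ratio == pytest.approx(0.5, abs=0.15)

    def test_synthetic_suppression_detected(self):
        cmp_ = self._simulate_and_classify("factor", 2.0, seed=12)
        assert cmp_.classification == "suppression"
        assert cmp_.threshold_ratio == pytest.approx(2.0, rel=0.3)

    def test_deterministic_under_seed(self):
        a = self._simulate_and_classify("independent", 1.0, seed=5)
        b = self._simulate_and_classify("independent", 1.0, seed=5)
        assert (a.p_value, a.classification, a.threshold_ratio) == (
            b.p_value, b.classification, b.threshold_ratio)

    def test_classification_consistent_with_threshold_sign(self):
        for seed in range(6):
            cmp_ = self._simulate_and_classify("factor", 0.5, seed=100 + seed)
            if cmp_.classification == "synergy":
                assert cmp_.observed_threshold < cmp_.predicted_threshold
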