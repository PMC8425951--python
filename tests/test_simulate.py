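"""Generative-model behaviour of the synthetic screen."""

import math

import numpy as np
import pytest

import qhtskit as q
from qhtskit.simulate import (
    CompoundTruth,
    ProtectionParams,
    SimulationConfig,
    TruthTable,
    _draw_signals,
    hill_protection,
    simulate_combination,
    simulate_screen,
    simulate_well,
)


def expected_baseline_mean(cfg: SimulationConfig) -> float:
    # lognormal mean = median * exp(sigma^2 / 2)
    return cfg.baseline.median * math.exp(cfg.baseline.sigma**2 / 2)


class TestSignalModel:
    def test_hill_midpoint_is_half_emax(self):
        for h in (0.5, 1.0, 2.0, 4.0):
            assert hill_protection(0.25, 0.8, 0.25, h) == pytest.approx(0.4)

    def test_hill_monotone_and_bounded(self):
        concs = np.array([0.01, 0.1, 0.5, 1.0, 4.0, 100.0])
        p = hill_protection(concs, 0.7, 0.5, 2.0)
        assert np.all(np.diff(p) > 0)
        assert np.all((p >= 0) & (p <= 0.7))
        assert hill_protection(0.0, 0.7, 0.5, 2.0) == 0.0

    def test_inactive_ablated_mean_matches_closed_form(self, rng):
        cfg = SimulationConfig(dispensing_error_rate=0.0)
        sig, _, _ = _draw_signals(cfg, CompoundTruth("x", "inactive"), 1.0, True, rng, 40_000)
        expected = cfg.background.mean + cfg.residual_fraction * expected_baseline_mean(cfg)
        assert sig.mean() == pytest.approx(expected, rel=0.02)

    def test_protective_at_ec50_mean_matches_closed_form(self, rng):
        cfg = SimulationConfig(dispensing_error_rate=0.0)
        truth = CompoundTruth("x", "protective", emax=1.0, ec50_uM=0.5, hill=2.0)
        sig, _, _ = _draw_signals(cfg, truth, 0.5, True, rng, 40_000)
        r = cfg.residual_fraction
        expected = cfg.background.mean + expected_baseline_mean(cfg) * (r + (1 - r) * 0.5)
        assert sig.mean() == pytest.approx(expected, rel=0.02)

    def test_saturating_full_rescue_normalizes_to_100pct(self, rng):
        """A planted Emax=1 protectant at saturating dose reads as a 100% effect."""
        cfg = SimulationConfig(dispensing_error_rate=0.0)
        truth = CompoundTruth("x", "protective", emax=1.0, ec50_uM=1e-4, hill=2.0)
        n = 10_000
        treated, _, _ = _draw_signals(cfg, truth, 4.0, True, rng, n)
        neg, _, _ = _draw_signals(cfg, CompoundTruth("", "inactive"), 0.0, True, rng, n)
        pos, _, _ = _draw_signals(cfg, CompoundTruth("", "inactive"), 0.0, False, rng, n)
        effect = q.normalize(treated, neg.mean(), pos.mean()).mean()
        assert effect == pytest.approx(100.0, abs=2.0)

    def test_inactive_normalizes_to_0pct(self, rng):
        cfg = SimulationConfig(dispensing_error_rate=0.0)
        n = 10_000
        treated, _, _ = _draw_signals(cfg, CompoundTruth("x", "inactive"), 4.0, True, rng, n)
        neg, _, _ = _draw_signals(cfg, CompoundTruth("", "inactive"), 0.0, True, rng, n)
        pos, _, _ = _draw_signals(cfg, CompoundTruth("", "inactive"), 0.0, False, rng, n)
        effect = q.normalize(treated, neg.mean(), pos.mean()).mean()
        assert effect == pytest.approx(0.0, abs=2.0)

    def test_signal_monotone_in_protection(self, rng):
        cfg = SimulationConfig(dispensing_error_rate=0.0)
        means = []
        for emax in (0.2, 0.5, 0.9):
            truth = CompoundTruth("x", "protective", emax=emax, ec50_uM=1e-4, hill=2.0)
            sig, _, _ = _draw_signals(cfg, truth, 4.0, True, rng, 20_000)
            means.append(sig.mean())
        assert means[0] < means[1] < means[2]

    def test_toxic_wells_die_and_emit_background(self, rng):
        cfg = SimulationConfig(dispensing_error_rate=0.0)
        truth = CompoundTruth("x", "toxic", lc50_uM=0.1, slope=6.0)
        sig, alive, _ = _draw_signals(cfg, truth, 4.0, True, rng, 5_000)
        assert alive.mean() < 0.01
        dead = sig[~alive]
        assert dead.mean() == pytest.approx(cfg.background.mean, rel=0.05)

    def test_autofluorescent_gain_is_linear_in_concentration(self, rng):
        cfg = SimulationConfig(dispensing_error_rate=0.0, autofluor_gain=500.0)
        truth = CompoundTruth("x", "autofluorescent", autofluor_gain=500.0)
        lo, _, _ = _draw_signals(cfg, truth, 1.0, True, rng, 20_000)
        hi, _, _ = _draw_signals(cfg, truth, 4.0, True, rng, 20_000)
        assert hi.mean() - lo.mean() == pytest.approx(500.0 * 3.0, rel=0.05)

    def test_dispensing_error_rate_and_flagging(self, rng):
        cfg = SimulationConfig(dispensing_error_rate=0.2)
        _, _, disp = _draw_signals(cfg, CompoundTruth("x", "inactive"), 1.0, True, rng, 10_000)
        assert disp.mean() == pytest.approx(0.2, abs=0.02)
        well = simulate_well(cfg, "inactive", 1.0, True, np.random.default_rng(3))
        assert well.group == "drug"


class TestScreenGeneration:
    def test_determinism_under_fixed_seed(self):
        cfg = SimulationConfig(seed=42, n_compounds=3)
        a, ta = simulate_screen(cfg)
        b, tb = simulate_screen(cfg)
        assert a == b
        assert list(ta) == list(tb)

    def test_different_run_ids_give_independent_draws(self):
        cfg = SimulationConfig(seed=42, n_compounds=1)
        a, _ = simulate_screen(cfg, run_id="rep1")
        b, _ = simulate_screen(cfg, run_id="rep2")
        assert a != b

    def test_no_compounds_gives_controls_only(self):
        cfg = SimulationConfig(seed=1, n_compounds=0)
        records, truth = simulate_screen(cfg)
        assert len(truth) == 0
        assert {r.group for r in records} == {"neg_ctrl", "pos_ctrl", "nontransgenic"}

    def test_class_fractions_respected(self):
        cfg = SimulationConfig(
            seed=1, n_compounds=20, frac_protective=0.25,
            frac_toxic=0.1, frac_autofluorescent=0.05,
        )
        _, truth = simulate_screen(cfg)
        assert len(truth.ids_of_class("protective")) == 5
        assert len(truth.ids_of_class("toxic")) == 2
        assert len(truth.ids_of_class("autofluorescent")) == 1
        assert len(truth) == 20

    def test_every_compound_has_a_full_titration(self, small_screen):
        _, records, truth = small_screen
        for entry in truth:
            concs = {r.concentration_uM for r in records if r.compound_id == entry.compound_id}
            assert len(concs) == 6

    def test_truth_table_round_trip(self, tmp_path, small_screen):
        _, _, truth = small_screen
        path = tmp_path / "truth.csv"
        truth.to_csv(path)
        back = TruthTable.from_csv(path)
        assert len(back) == len(truth)
        for e in truth:
            assert back[e.compound_id].compound_class == e.compound_class


class TestCombinationGeneration:
    def _truths(self, pa, pb):
        return (
            CompoundTruth("A", "protective", emax=pa, ec50_uM=1e-3, hill=1.0),
            CompoundTruth("B", "protective", emax=pb, ec50_uM=1e-3, hill=1.0),
        )

    def test_none_interaction_with_inert_partner_equals_single(self, rng):
        """With P_B = 0 the pair behaves exactly like compound A alone."""
        cfg = SimulationConfig(seed=9, dispensing_error_rate=0.0)
        ta, tb = self._truths(0.4, 1e-9)
        records = simulate_combination(cfg, (ta, tb), "none", n_per_group=2000)
        a = np.mean([r.raw_signal for r in records if r.compound_id == "A"])
        ab = np.mean([r.raw_signal for r in records if r.compound_id == "A+B"])
        assert ab == pytest.approx(a, rel=0.03)

    def test_bliss_effect_size(self, rng):
        """Bliss independence: P_AB = 0.4 + 0.4 - 0.16 = 0.64."""
        cfg = SimulationConfig(seed=9, dispensing_error_rate=0.0)
        ta, tb = self._truths(0.4, 0.4)
        records = simulate_combination(cfg, (ta, tb), "bliss", n_per_group=4000)
        neg = np.mean([r.raw_signal for r in records if r.group == "neg_ctrl"])
        pos = np.mean([r.raw_signal for r in records if r.group == "pos_ctrl"])
        ab = [r.raw_signal for r in records if r.compound_id == "A+B"]
        effect = q.normalize(ab, neg, pos).mean()
        assert effect == pytest.approx(64.0, abs=4.0)

    def test_nonprotective_pair_member_rejected(self):
        cfg = SimulationConfig(seed=9)
        ta = CompoundTruth("A", "protective", 0.4, 1e-3, 1.0)
        tb = CompoundTruth("B", "inactive")
        with pytest.raises(ValueError, match="not protective"):
            simulate_combination(cfg, (ta, tb), "bliss")

    def test_unknown_interaction_rejected(self):
        cfg = SimulationConfig(seed=9)
        with pytest.raises(ValueError, match="interaction"):
            simulate_combination(cfg, self._truths(0.3, 0.3), "loewe")


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(frac_protective=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(residual_fraction=-0.1)
    with pytest.raises(ValueError):
        SimulationConfig(protection=ProtectionParams(emax=0.0))
    with pytest.raises(ValueError):
        SimulationConfig(frac_protective=0.6, frac_toxic=0.6)
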