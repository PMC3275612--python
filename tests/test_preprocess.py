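"""Preprocessing chain: singlet gate, mitotic gate, background subtraction,
outlier gates, and the combined gating strategy."""

import numpy as np
import pandas as pd
import pytest

from flowworm.events import EventTable, GateMask
from flowworm.preprocess import (ContourGateSpec, background_subtract,
                                 contour_gate, mitotic_gate, outlier_gates,
                                 s1_preprocess, singlet_gate)
from flowworm.synth import PiecewiseCurve, default_phase_model, sample_population


def flat_width_model():
    model = default_phase_model()
    model.marker_curves["dna_width"] = PiecewiseCurve(
        [dict(u0=0.0, u1=1.0, kind="const", params=(1.0,))])
    return model


@pytest.fixture(scope="module")
def doublet_pop():
    return sample_population(flat_width_model(), 20_000, seed=9,
                             doublet_fraction=0.10)


@pytest.fixture(scope="module")
def bimodal_phh3():
    """96% interphase at baseline PHH3, 4% mitotic at 20x baseline."""
    rng = np.random.default_rng(4)
    n, frac = 50_000, 0.04
    n_mit = int(n * frac)
    phh3 = np.concatenate([
        5.0 * rng.lognormal(0, 0.15, n - n_mit),
        100.0 * rng.lognormal(0, 0.15, n_mit),
    ])
    truth = np.concatenate([np.zeros(n - n_mit, bool), np.ones(n_mit, bool)])
    return EventTable(pd.DataFrame({"phh3": phh3})), truth


class TestSingletGate:
    def test_retains_singlets_excludes_doublets(self, doublet_pop):
        gate = singlet_gate(doublet_pop.events)
        doublet = (doublet_pop.truth["phase"] == "doublet").to_numpy()
        assert gate.mask[~doublet].mean() >= 0.98
        assert gate.mask[doublet].mean() < 0.01

    def test_level_100_rejected(self, doublet_pop):
        with pytest.raises(ValueError):
            singlet_gate(doublet_pop.events, level=100)

    def test_too_few_events_rejected(self):
        table = EventTable(pd.DataFrame({"dna_width": np.ones(100),
                                         "dna": np.full(100, 100.0)}))
        with pytest.raises(ValueError):
            singlet_gate(table)


class TestMitoticGate:
    def test_recovers_mitotic_fraction(self, bimodal_phh3):
        events, truth = bimodal_phh3
        gate = mitotic_gate(events)
        assert abs(gate.count / events.n_events - 0.04) < 0.005
        # truth-label oracle: the gated set is the spiked subpopulation
        assert gate.mask[truth].mean() > 0.99
        assert gate.mask[~truth].mean() < 0.005

    def test_unimodal_gives_empty_mask_and_warning(self):
        rng = np.random.default_rng(1)
        events = EventTable(pd.DataFrame(
            {"phh3": 5.0 * rng.lognormal(0, 0.15, 20_000)}))
        with pytest.warns(UserWarning, match="unimodal"):
            gate = mitotic_gate(events)
        assert gate.count == 0

    def test_zero_threshold_override_flags_everything(self, bimodal_phh3):
        events, _ = bimodal_phh3
        gate = mitotic_gate(events, threshold=0.0)
        assert gate.count == events.n_events


class TestBackgroundSubtract:
    def test_exact_line_corrected_to_zero(self):
        rng = np.random.default_rng(0)
        ssc = rng.uniform(100, 300, 2_000)
        table = EventTable(pd.DataFrame({"cyclin_a2": 0.05 * ssc, "ssc": ssc}))
        ref = GateMask("g1", np.ones(2_000, bool))
        out = background_subtract(table, "cyclin_a2", "ssc", ref)
        np.testing.assert_allclose(out["cyclin_a2"], 0.0, atol=1e-12)
        assert out.metadata["background_beta"]["cyclin_a2"] == pytest.approx(0.05)

    def test_no_size_dependence_is_identity(self):
        rng = np.random.default_rng(0)
        table = EventTable(pd.DataFrame({
            "cyclin_a2": np.full(2_000, 5.0),
            "ssc": rng.uniform(100, 300, 2_000)}))
        ref = GateMask("g1", np.ones(2_000, bool))
        out = background_subtract(table, "cyclin_a2", "ssc", ref)
        np.testing.assert_array_equal(out["cyclin_a2"], table["cyclin_a2"])

    def test_noisy_background_median_within_eps(self):
        rng = np.random.default_rng(3)
        n = 20_000
        ssc = rng.uniform(100, 300, n)
        cyclin = 0.05 * ssc * rng.lognormal(0, 0.2, n)
        table = EventTable(pd.DataFrame({"cyclin_a2": cyclin, "ssc": ssc}))
        ref = GateMask("g1", np.ones(n, bool))
        out = background_subtract(table, "cyclin_a2", "ssc", ref)
        eps = 0.01 * np.quantile(cyclin, 0.9)
        assert abs(np.median(out["cyclin_a2"])) < eps
        # fixed point: re-estimating the slope on corrected data gives ~0
        refit = background_subtract(out, "cyclin_a2", "ssc", ref)
        beta2 = refit.metadata["background_beta"]["cyclin_a2"]
        assert abs(beta2) < 0.002

    def test_negative_slope_clamped_with_warning(self):
        rng = np.random.default_rng(5)
        ssc = rng.uniform(100, 300, 2_000)
        table = EventTable(pd.DataFrame({"cyclin_a2": -0.05 * ssc + 20,
                                         "ssc": ssc}))
        ref = GateMask("g1", np.ones(2_000, bool))
        with pytest.warns(UserWarning, match="clamped"):
            out = background_subtract(table, "cyclin_a2", "ssc", ref)
        np.testing.assert_array_equal(out["cyclin_a2"], table["cyclin_a2"])


class TestOutlierGates:
    def test_clean_data_mostly_retained(self, pop50):
        gate = outlier_gates(pop50.events, "cyclin_a2", "dna", level=99)
        assert gate.count / pop50.events.n_events >= 0.98

    def test_uniform_contaminant_rejected(self, model):
        pop = sample_population(model, 20_000, seed=12)
        rng = np.random.default_rng(13)
        n_c = 1_000
        data = pop.events.data.copy()
        cloud = data.sample(n_c, random_state=1).copy()
        cloud["cyclin_a2"] = rng.uniform(0, 600, n_c)
        cloud["dna"] = rng.uniform(50, 400, n_c)
        table = EventTable(pd.concat([data, cloud], ignore_index=True))
        contaminant = np.zeros(len(table.data), bool)
        contaminant[-n_c:] = True
        gate = outlier_gates(table, "cyclin_a2", "dna",
                             interphase_mask=~contaminant, level=99)
        assert gate.mask[contaminant].mean() < 0.20

    def test_nonpositive_level_rejected(self, pop50):
        with pytest.raises(ValueError):
            contour_gate(pop50.events, ContourGateSpec("cyclin_a2", "dna", 0))


class TestFullChain:
    def test_s1_chain_sensitivity_and_rejoin(self):
        pop = sample_population(flat_width_model(), 50_000, seed=5,
                                doublet_fraction=0.05)
        events = pop.events.with_channel(
            "cyclin_a2", pop.events["cyclin_a2"] + 0.05 * pop.events["ssc"])
        result = s1_preprocess(events, cyclin_channels=("cyclin_a2",))
        truth = pop.truth
        doublet = (truth["phase"] == "doublet").to_numpy()
        final = result.final.mask
        assert final[~doublet].mean() >= 0.98       # sensitivity
        assert final[doublet].mean() <= 0.20        # contaminant retention
        # every PHH3-high mitotic event is restored by the OR R3 clause
        mitotic = (truth["phase"] == "M").to_numpy() & (events["phh3"] > 40)
        assert final[mitotic].all()
        # size-dependent background removed: G1 median specific fluorescence ~0
        g1 = (truth["phase"] == "G1").to_numpy()
        eps = 0.01 * np.quantile(events["cyclin_a2"], 0.9)
        assert abs(np.median(result.events["cyclin_a2"][g1])) < eps
        assert result.events.metadata["background_beta"]["cyclin_a2"] == \
            pytest.approx(0.05, rel=0.05)
        assert [entry for entry in result.log if entry.get("gate") == "final"]
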