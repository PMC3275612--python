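"""Frequency-domain profile assembly, boundary points, replicates, merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize

from flowworm.events import EventTable
from flowworm.extraction import (ExpressionProfile, combine_replicates,
                                 extract_profile, frequency_to_time,
                                 insert_boundary_points, join_profiles,
                                 merge_panels)
from flowworm.gating import segment_histogram_1d
from flowworm.pipeline import dna_segment_boundaries
from flowworm.synth import sample_histogram


def profile_from(values, labels, order=None, channel="c"):
    table = EventTable(pd.DataFrame({channel: values}))
    return extract_profile(table, labels, [channel], label_order=order)


class TestExtractProfile:
    def test_single_segment_centered(self):
        prof = profile_from(np.arange(10.0), np.zeros(10, int))
        assert prof.x[0] == 0.5 and prof.values["c"][0] == 4.5

    def test_two_equal_segments(self):
        values = np.array([1.0] * 5 + [2.0] * 5)
        labels = np.array([0] * 5 + [1] * 5)
        prof = profile_from(values, labels)
        np.testing.assert_allclose(prof.x, [0.25, 0.75])
        np.testing.assert_allclose(prof.values["c"], [1.0, 2.0])

    def test_first_fraction_060_centers_at_030(self):
        labels = np.array([0] * 60 + [1] * 40)
        prof = profile_from(np.arange(100.0), labels)
        assert prof.x[0] == pytest.approx(0.30)

    def test_unassigned_events_excluded_from_fractions(self):
        labels = np.array([0] * 50 + [1] * 25 + [-1] * 25)
        prof = profile_from(np.arange(100.0), labels)
        np.testing.assert_allclose(prof.fractions, [2 / 3, 1 / 3])

    def test_empty_segment_skipped_with_warning(self):
        labels = np.array([0] * 5 + [2] * 5)
        with pytest.warns(UserWarning, match="empty"):
            prof = profile_from(np.arange(10.0), labels, order=[0, 1, 2])
        assert prof.n_points == 2

    def test_frequency_conservation(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 7, 1_000)
        prof = profile_from(rng.random(1_000), labels)
        assert abs(prof.fractions.sum() - 1.0) < 1e-9

    def test_indirect_channel_extracted_from_same_regions(self):
        table = EventTable(pd.DataFrame({
            "a": np.concatenate([np.zeros(50), np.ones(50)]),
            "b": np.concatenate([np.full(50, 7.0), np.full(50, 9.0)])}))
        labels = np.array([0] * 50 + [1] * 50)
        prof = extract_profile(table, labels, ["a", "b"])
        np.testing.assert_allclose(prof.values["b"], [7.0, 9.0])


class TestEarlyRegionSensitivity:
    """Frequency bookkeeping under boundary perturbation, in closed form."""

    def test_interior_boundary_shift_is_local(self):
        # moving the 1|2 boundary by delta shifts x1 and x2 by delta/2
        # and leaves every later point unchanged
        values = np.arange(1000.0)
        base = segment_histogram_1d(values, [99.5, 299.5, 599.5])
        moved = segment_histogram_1d(values, [149.5, 299.5, 599.5])
        p0 = profile_from(values, base.labels, order=range(4))
        p1 = profile_from(values, moved.labels, order=range(4))
        delta = 0.05  # 50 of 1000 events moved from segment 2 to segment 1
        np.testing.assert_allclose(p1.x[:2] - p0.x[:2], delta / 2)
        np.testing.assert_allclose(p1.x[2:], p0.x[2:])

    def test_front_mass_admission_shifts_downstream(self):
        # admitting extra front mass delta rescales downstream centers by
        # x' = (delta + C) / (1 + delta): the shift decays with 1 - x
        values = np.arange(1000.0)
        labels = np.where(values < 400, 0, np.where(values < 700, 1, 2))
        full = profile_from(values, labels)
        trimmed = np.where(values < 100, -1, labels)  # 100 events unassigned
        cut = profile_from(values, trimmed)
        delta = 100 / 900
        expected = (delta + cut.x) / (1 + delta)
        np.testing.assert_allclose(full.x[1:], expected[1:])


class TestBoundaryPoints:
    def test_flat_profile_extends_at_plateau_value(self):
        prof = ExpressionProfile(x=np.array([0.25, 0.75]),
                                 values={"c": np.array([5.0, 5.0])},
                                 fractions=np.array([0.5, 0.5]),
                                 counts=np.array([10, 10]))
        out = insert_boundary_points(prof)
        assert out.x[0] == 0.0 and out.x[-1] == 1.0
        np.testing.assert_allclose(out.values["c"][out.synthetic], 5.0)

    def test_linear_stretch_extrapolates_on_line(self):
        x = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        prof = ExpressionProfile(x=x, values={"c": 2 * x + 1},
                                 fractions=np.full(5, 0.2),
                                 counts=np.full(5, 10))
        out = insert_boundary_points(prof)
        assert out.values["c"][0] == pytest.approx(1.0)
        assert out.values["c"][-1] == pytest.approx(3.0)

    def test_fig2_g1s_boundary_recovers_2c(self, fig2_mixture):
        h = sample_histogram(fig2_mixture, 50_000, seed=1)
        seg = segment_histogram_1d(h.values, dna_segment_boundaries(100, 3,
                                                                    200, 6, 7))
        prof = profile_from(h.values, seg.labels, order=range(9),
                            channel="dna")
        out = insert_boundary_points(prof, [1, 8])
        synth = out.synthetic
        # the plateau-side boundary point at the G1/S transition sits on 2C
        g1s = out.values["dna"][synth][1]
        assert abs(g1s - 100.0) < 1.0  # within 1% of the 2C value
        # and the 4C-side end point sits on 4C
        assert abs(out.values["dna"][synth][-1] - 200.0) < 2.0

    def test_single_point_stretch_extends_constant(self):
        prof = ExpressionProfile(x=np.array([0.15, 0.5, 0.85]),
                                 values={"c": np.array([1.0, 4.0, 6.0])},
                                 fractions=np.array([0.3, 0.4, 0.3]),
                                 counts=np.array([3, 4, 3]))
        with pytest.warns(UserWarning, match="constant extension"):
            out = insert_boundary_points(prof, [1])
        # left stretch has one real point: its boundary value is that point
        assert out.values["c"][out.synthetic][1] == 1.0


class TestFrequencyToTime:
    def test_endpoints_fixed(self):
        assert frequency_to_time(0.0, "age_corrected") == 0.0
        assert frequency_to_time(1.0, "age_corrected") == pytest.approx(1.0)

    def test_midpoint_matches_numeric_inversion(self):
        cdf = lambda t: integrate.quad(
            lambda a: 2 * np.log(2) * 2 ** (-a), 0, t)[0]
        oracle = optimize.brentq(lambda t: cdf(t) - 0.5, 0, 1, xtol=1e-12)
        assert abs(frequency_to_time(0.5, "age_corrected") - oracle) < 1e-6
        assert frequency_to_time(0.5, "age_corrected") == pytest.approx(
            0.41504, abs=5e-6)

    def test_identity_mode(self):
        x = np.linspace(0, 1, 11)
        np.testing.assert_array_equal(frequency_to_time(x), x)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            frequency_to_time(1.2, "age_corrected")


class TestCombineReplicates:
    def make(self, values):
        return ExpressionProfile(x=np.array([0.25, 0.75]),
                                 values={"c": np.asarray(values, float)},
                                 counts=np.array([10, 10]))

    def test_identical_replicates_zero_sem(self):
        comb = combine_replicates([self.make([1, 2])] * 3)
        np.testing.assert_allclose(comb.dispersion["c"], 0.0)

    def test_symmetric_spread_closed_form(self):
        v, d = 5.0, 0.6
        comb = combine_replicates([self.make([v, v]), self.make([v + d, v + d]),
                                   self.make([v - d, v - d])])
        np.testing.assert_allclose(comb.values["c"], v)
        np.testing.assert_allclose(comb.dispersion["c"], d / np.sqrt(3))

    def test_ci_covers_true_2c_plateau(self, fig2_mixture):
        profs = []
        bounds = dna_segment_boundaries(100, 3, 200, 6, 7)
        for seed in (1, 2, 3):
            h = sample_histogram(fig2_mixture, 50_000, seed=seed)
            seg = segment_histogram_1d(h.values, bounds)
            profs.append(profile_from(h.values, seg.labels, order=range(9),
                                      channel="dna"))
        comb = combine_replicates(profs)
        assert abs(comb.values["dna"][0] - 100.0) <= comb.ci["dna"][0]

    def test_mismatched_point_counts_rejected(self):
        other = ExpressionProfile(x=np.array([0.5]),
                                  values={"c": np.array([1.0])},
                                  counts=np.array([10]))
        with pytest.raises(ValueError):
            combine_replicates([self.make([1, 2]), other])


class TestMergeAndJoin:
    def make(self, x, y, channel="phh3"):
        return ExpressionProfile(x=np.asarray(x, float),
                                 values={channel: np.asarray(y, float)})

    def test_profile_merged_with_itself_zero_deviation(self):
        p = self.make([0.2, 0.5, 0.8], [1.0, 5.0, 2.0])
        _, report = merge_panels(p, p, "phh3")
        assert report.max_abs_deviation == 0.0

    def test_constant_shift_reports_that_constant(self):
        p = self.make([0.2, 0.5, 0.8], [1.0, 5.0, 2.0])
        q = self.make([0.2, 0.5, 0.8], [2.5, 6.5, 3.5])
        _, report = merge_panels(p, q, "phh3", threshold=1.0)
        assert report.max_abs_deviation == pytest.approx(1.5)
        assert report.agrees is False

    def test_axis_mode_mismatch_rejected(self):
        p = self.make([0.2, 0.8], [1.0, 2.0])
        q = self.make([0.2, 0.8], [1.0, 2.0])
        q.axis_mode = "age-corrected-time"
        with pytest.raises(ValueError):
            merge_panels(p, q, "phh3")

    def test_join_with_single_profile_is_identity(self):
        p = self.make([0.2, 0.8], [1.0, 2.0])
        assert join_profiles([p]) is p

    def test_join_interleaves_and_sorts(self):
        p = self.make([0.1, 0.5, 0.9], [1, 2, 3])
        q = self.make([0.3, 0.7], [1.5, 2.5])
        joined = join_profiles([p, q])
        assert joined.n_points == 5
        assert np.all(np.diff(joined.x) > 0)

    def test_join_densifies_mitotic_decay(self, panels):
        # the joined shared channel has more points in the decay window
        # than either input panel alone
        a, b = panels["a2"]["profile"], panels["b1"]["profile"]
        joined = join_profiles([a, b])
        window = lambda p: int(np.sum((p.x > 0.985) & (p.x <= 1.0)
                                      & ~p.synthetic))
        assert window(joined) > max(window(a), window(b))


class TestProfileContainer:
    def test_centering_invariant_enforced(self):
        with pytest.raises(ValueError, match="cumulative fraction"):
            ExpressionProfile(x=np.array([0.2, 0.6]),
                              values={"c": np.array([1.0, 2.0])},
                              fractions=np.array([0.5, 0.5]))

    def test_csv_roundtrip(self, tmp_path):
        prof = ExpressionProfile(x=np.array([0.25, 0.75]),
                                 values={"c": np.array([1.0, 2.0])},
                                 fractions=np.array([0.5, 0.5]),
                                 counts=np.array([5, 5]))
        path = tmp_path / "p.csv"
        prof.to_csv(path)
        back = ExpressionProfile.from_csv(path)
        np.testing.assert_allclose(back.x, prof.x)
        np.testing.assert_allclose(back.values["c"], prof.values["c"])
        np.testing.assert_array_equal(back.synthetic, prof.synthetic)


@settings(deadline=None, max_examples=40)
@given(st.lists(st.integers(1, 500), min_size=1, max_size=12))
def test_centering_rule_holds_for_any_segmentation(sizes):
    labels = np.repeat(np.arange(len(sizes)), sizes)
    prof = profile_from(np.arange(labels.size, dtype=float), labels)
    fractions = np.asarray(sizes) / sum(sizes)
    expected = np.cumsum(fractions) - fractions / 2
    np.testing.assert_allclose(prof.x, expected, atol=1e-12)
    assert np.all(np.diff(prof.x) > 0)
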