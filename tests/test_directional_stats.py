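"""Tests for axis summaries, plane projections, rose histograms and
regional anisotropy contrasts."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibrefab.directional_stats import (
    dominant_axis_fractions,
    project_to_plane,
    region_contrast,
    rose_histogram,
    summarize_anisotropy,
)

from conftest import make_field


class TestDominantAxisFractions:
    def test_even_split(self):
        field = make_field([(1, 0, 0), (0, 1, 0), (0, 0, 1)])
        s = dominant_axis_fractions(field)
        assert s.fractions == (pytest.approx(1 / 3),) * 3
        assert sum(s.exact_fractions()) == Fraction(1)

    def test_dominance_by_largest_component(self):
        field = make_field([(0.9, 0.1, 0.0), (0.8, 0.0, 0.2)])
        s = dominant_axis_fractions(field)
        assert s.counts == (2, 0, 0)

    def test_tie_breaks_toward_x(self):
        field = make_field([(0.7071, 0.7071, 0.0)])
        assert dominant_axis_fractions(field).counts == (1, 0, 0)

    def test_empty_field_rejected(self):
        with pytest.raises(ValueError):
            dominant_axis_fractions(make_field([]))


class TestProjectToPlane:
    def test_sagittal_angle(self):
        angle, weight = project_to_plane(np.array([0, 0.6, 0.8]), "sagittal_YZ")
        assert angle == pytest.approx(53.13010235)
        assert weight == pytest.approx(1.0)

    def test_out_of_plane_excluded(self):
        assert project_to_plane(np.array([1.0, 0, 0]), "sagittal_YZ") is None

    def test_transverse_diagonal(self):
        angle, weight = project_to_plane(np.array([0.7071, 0.7071, 0]),
                                         "transverse_XY")
        assert angle == pytest.approx(45.0)
        assert weight == pytest.approx(1.0, rel=1e-4)

    def test_axial_folding(self):
        a1, _ = project_to_plane(np.array([0, 0.6, 0.8]), "sagittal_YZ")
        a2, _ = project_to_plane(np.array([0, -0.6, -0.8]), "sagittal_YZ")
        assert a1 == pytest.approx(a2)

    def test_unknown_plane(self):
        with pytest.raises(ValueError):
            project_to_plane(np.array([0, 1, 0]), "coronal")


class TestRoseHistogram:
    def test_binning_rule(self):
        # angles 10 and 170 degrees in the transverse plane
        v1 = (np.cos(np.radians(10)), np.sin(np.radians(10)), 0)
        v2 = (np.cos(np.radians(170)), np.sin(np.radians(170)), 0)
        field = make_field([v1, v2])
        hist = rose_histogram(field, "transverse_XY", 18)
        assert hist.counts[1] == 1      # [10, 20)
        assert hist.counts[17] == 1     # [170, 180)
        assert sum(hist.counts) == 2

    def test_sum_magnitude_accumulates(self):
        v = (np.cos(np.radians(45)), np.sin(np.radians(45)), 0)
        field = make_field([v, v], magnitudes=[0.5, 0.7])
        hist = rose_histogram(field, "transverse_XY", 18)
        assert hist.sum_magnitude_um[4] == pytest.approx(1.2)

    def test_conservation_with_exclusions(self):
        field = make_field([(1, 0, 0), (0, 1, 0), (0, 0, 1)])
        hist = rose_histogram(field, "sagittal_YZ", 18)
        assert sum(hist.counts) + hist.excluded == 3
        assert hist.excluded == 1  # the pure-X sample has no YZ component

    def test_identical_support_of_weightings(self):
        rng = np.random.default_rng(0)
        vecs = rng.standard_normal((40, 3))
        field = make_field(vecs, magnitudes=np.full(40, 2.0))
        hist = rose_histogram(field, "frontal_XZ", 12)
        support_freq = [c > 0 for c in hist.counts]
        support_mag = [m > 0 for m in hist.sum_magnitude_um]
        assert support_freq == support_mag

    def test_empty_field_rejected(self):
        with pytest.raises(ValueError):
            rose_histogram(make_field([]), "sagittal_YZ", 18)


class TestSummaries:
    def test_basic_statistics(self):
        field = make_field([(1, 0, 0)] * 3, anisotropies=[0.2, 0.4, 0.6])
        s = summarize_anisotropy(field)
        assert (s.mean, s.median) == (pytest.approx(0.4), pytest.approx(0.4))
        assert s.sd == pytest.approx(0.2)

    def test_single_sample_sd_zero(self):
        s = summarize_anisotropy(make_field([(1, 0, 0)]))
        assert s.sd == 0.0 and s.n == 1

    def test_by_axis_grouping(self):
        field = make_field([(1, 0, 0), (0, 1, 0)], anisotropies=[0.3, 0.7])
        groups = summarize_anisotropy(field, by_axis=True)
        assert groups["X"].mean == pytest.approx(0.3)
        assert groups["Y"].mean == pytest.approx(0.7)
        assert "Z" not in groups

    def test_empty_field_rejected(self):
        with pytest.raises(ValueError):
            summarize_anisotropy(make_field([]))


class TestRegionContrast:
    def test_identical_regions_zero_difference(self):
        field = make_field([(1, 0, 0)] * 4, anisotropies=[0.5] * 4)
        rc = region_contrast(field, ["a", "a", "b", "b"], "a", "b")
        assert rc.mean_difference == pytest.approx(0.0)

    def test_difference_sign(self):
        field = make_field([(1, 0, 0)] * 4, anisotropies=[0.8, 0.8, 0.2, 0.2])
        rc = region_contrast(field, ["rim", "rim", "center", "center"],
                             "rim", "center")
        assert rc.mean_difference == pytest.approx(0.6)

    def test_empty_region_rejected(self):
        field = make_field([(1, 0, 0)] * 2)
        with pytest.raises(ValueError, match="center"):
            region_contrast(field, ["rim", "rim"], "rim", "center")


class TestAxialSymmetry:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 16))
    def test_sign_flips_change_no_statistic(self, seed):
        rng = np.random.default_rng(seed)
        vecs = rng.standard_normal((12, 3))
        vecs /= np.linalg.norm(vecs, axis=1)[:, None]
        flips = rng.choice([-1.0, 1.0], size=12)
        f1 = make_field(vecs)
        f2 = make_field(vecs * flips[:, None])
        assert (dominant_axis_fractions(f1).counts
                == dominant_axis_fractions(f2).counts)
        for plane in ("sagittal_YZ", "frontal_XZ", "transverse_XY"):
            h1, h2 = (rose_histogram(f, plane, 18) for f in (f1, f2))
            assert h1.counts == h2.counts
            assert h1.excluded == h2.excluded
            np.testing.assert_allclose(h1.sum_magnitude_um, h2.sum_magnitude_um)

    def test_quarter_turn_about_z_swaps_x_and_y_dominance(self):
        rng = np.random.default_rng(3)
        vecs = rng.standard_normal((30, 3))
        vecs /= np.linalg.norm(vecs, axis=1)[:, None]
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        s1 = dominant_axis_fractions(make_field(vecs))
        s2 = dominant_axis_fractions(make_field(vecs @ rot.T))
        assert s1.counts[0] == s2.counts[1]
        assert s1.counts[1] == s2.counts[0]
        assert s1.counts[2] == s2.counts[2]
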