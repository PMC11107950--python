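"""Calibre summaries, tortuosity and fractal dimension."""
import collections
import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fundusmorph as fm
from fundusmorph.scene import _disk_mask, render_vessel


# --- independent oracle for the revised pairwise-combination formulas -------

def _knudtson_oracle(widths, k):
    """Step-by-step pairing procedure coded independently (deque-based)."""
    vals = collections.deque(sorted(widths, reverse=True)[:6])
    while len(vals) > 1:
        vals = collections.deque(sorted(vals))
        nxt = []
        if len(vals) % 2:
            nxt.append(statistics.median(vals))
            vals.remove(statistics.median(vals))
        while vals:
            lo = vals.popleft()
            hi = vals.pop()
            nxt.append(k * (lo**2 + hi**2) ** 0.5)
        vals = collections.deque(nxt)
    return vals[0]


class TestKnudtson:
    def test_single_width_passes_through(self):
        assert fm.knudtson_summary([9.3], "artery") == pytest.approx(9.3)
        assert fm.knudtson_summary([9.3], "vein") == pytest.approx(9.3)

    def test_six_equal_arterial_widths_match_oracle(self):
        got = fm.knudtson_summary([10.0] * 6, "artery")
        assert got == pytest.approx(_knudtson_oracle([10.0] * 6, 0.88), abs=1e-12)
        assert got == pytest.approx(17.5, abs=0.05)

    @pytest.mark.parametrize("kind,k", [("artery", 0.88), ("vein", 0.95)])
    def test_matches_oracle_on_random_multisets(self, kind, k, rng):
        for _ in range(500):
            n = rng.integers(1, 7)
            widths = rng.uniform(4.0, 25.0, size=n).tolist()
            assert fm.knudtson_summary(widths, kind) == pytest.approx(
                _knudtson_oracle(widths, k), abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.permutations(list(range(6))))
    def test_order_invariance(self, perm):
        base = [14.0, 8.5, 11.2, 9.9, 17.3, 12.6]
        shuffled = [base[i] for i in perm]
        assert fm.knudtson_summary(shuffled, "vein") == pytest.approx(
            fm.knudtson_summary(base, "vein"), abs=1e-12)

    def test_more_than_six_keeps_the_widest(self):
        widths = [20, 18, 16, 14, 12, 10, 3, 2]
        assert fm.knudtson_summary(widths, "artery") == pytest.approx(
            fm.knudtson_summary(widths[:6], "artery"), abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fm.knudtson_summary([], "artery")
        with pytest.raises(ValueError, match="kind"):
            fm.knudtson_summary([10], "capillary")


class TestMeasureWidths:
    @staticmethod
    def _od_fit():
        # disc of diameter 120 at the canvas center: annulus 120-180 px out
        return fm.fit_ellipse(_disk_mask((912, 912), (456, 456), 60))

    def test_straight_vessel_recovers_width(self):
        fit = self._od_fit()
        mask = render_vessel((912, 912), np.array([[100, 606], [812, 606]]), 10)
        samples = fm.measure_widths(mask, fit)
        assert len(samples) == 1
        assert samples[0].median_width == pytest.approx(10, abs=1.0)

    def test_two_parallel_vessels(self):
        fit = self._od_fit()
        m1 = render_vessel((912, 912), np.array([[100, 600], [812, 600]]), 8)
        m2 = render_vessel((912, 912), np.array([[100, 625], [812, 625]]), 14)
        samples = fm.measure_widths(m1 | m2, fit)
        medians = sorted(s.median_width for s in samples)
        assert len(samples) == 2
        assert medians[0] == pytest.approx(8, abs=1.0)
        assert medians[1] == pytest.approx(14, abs=1.0)

    def test_vessels_inside_half_disc_diameter_excluded(self):
        fit = self._od_fit()
        # short segment < 0.5 disc diameters from the margin (dist < 120 px)
        mask = render_vessel((912, 912), np.array([[410, 550], [500, 550]]), 10)
        with pytest.warns(UserWarning, match="annulus"):
            samples = fm.measure_widths(mask, fit)
        assert samples == []


class TestTortuosity:
    def test_straight_segment_is_unity(self):
        mask = render_vessel((400, 400), np.array([[50, 30], [350, 370]]), 8)
        assert fm.tortuosity(mask) == pytest.approx(1.0, abs=0.02)

    def test_semicircle_is_pi_over_two(self):
        th = np.linspace(0, np.pi, 400)
        pts = np.column_stack([200 + 150 * np.sin(th), 200 + 150 * np.cos(th)])
        mask = render_vessel((400, 400), pts, 6)
        assert fm.tortuosity(mask) == pytest.approx(np.pi / 2, abs=0.05)

    def test_monotone_in_sinusoid_amplitude(self):
        values = []
        for amp in (0.0, 6.0, 12.0):
            rows = np.arange(60, 860, dtype=float)
            cols = 450 + amp * np.sin(2 * np.pi * rows / 200)
            mask = render_vessel((912, 912), np.column_stack([rows, cols]), 8)
            values.append(fm.tortuosity(mask))
        assert values[0] < values[1] < values[2]
        assert all(v >= 1.0 for v in values)

    def test_rotation_invariance(self):
        rows = np.arange(100, 700, dtype=float)
        cols = 400 + 10 * np.sin(2 * np.pi * rows / 150)
        pts = np.column_stack([rows, cols])
        t0 = fm.tortuosity(render_vessel((912, 912), pts, 7))
        ang = np.deg2rad(35)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        pts_r = (pts - pts.mean(0)) @ rot.T + np.array([456, 456])
        t1 = fm.tortuosity(render_vessel((912, 912), pts_r, 7))
        assert t1 == pytest.approx(t0, rel=0.02)

    def test_no_eligible_segment_raises(self):
        mask = np.zeros((50, 50), bool)
        mask[25, 25] = True
        with pytest.raises(ValueError):
            fm.tortuosity(mask)


class TestFractalDimension:
    def test_straight_line_is_one(self):
        mask = np.zeros((912, 912), bool)
        mask[456, :] = True
        assert fm.fractal_dimension(mask) == pytest.approx(1.0, abs=0.1)

    def test_filled_plane_is_two(self):
        assert fm.fractal_dimension(np.ones((912, 912), bool)) == pytest.approx(2.0, abs=0.05)

    def test_bounded_and_translation_invariant(self):
        rows = np.arange(100, 800, dtype=float)
        pts = np.column_stack([rows, 300 + 0.3 * (rows - 450)])
        base = render_vessel((912, 912), pts, 9)
        fd0 = fm.fractal_dimension(base)
        shifted = np.roll(base, (40, 60), axis=(0, 1))
        fd1 = fm.fractal_dimension(shifted)
        assert 0.0 < fd0 <= 2.0
        assert fd1 == pytest.approx(fd0, abs=0.05)

    def test_monotone_in_branching(self):
        # nested family: tree with k branches is a subset of the tree with k' > k
        rng = np.random.default_rng(99)
        branches = []
        for _ in range(80):
            r0 = rng.uniform(80, 830)
            ang = rng.uniform(0, 2 * np.pi)
            end = np.clip(np.array([r0, 456.0]) + 200 * np.array([np.sin(ang), np.cos(ang)]),
                          5, 906)
            branches.append((r0, end))
        trunk = render_vessel((912, 912), np.array([[50.0, 456.0], [860.0, 456.0]]), 6)
        values = []
        for k in (0, 8, 30, 80):
            mask = trunk.copy()
            for r0, end in branches[:k]:
                mask |= render_vessel((912, 912), np.array([[r0, 456.0], end]), 5)
            values.append(fm.fractal_dimension(mask))
        assert values == sorted(values)
        assert values[0] < values[-1]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fm.fractal_dimension(np.zeros((64, 64), bool))


def test_vessel_summary_combines_metrics(default_scene, od_fit):
    m = default_scene.masks
    s = fm.vessel_summary(m.artery, m.vein, od_fit)
    assert s.avr == pytest.approx(s.crae / s.crve)
    assert s.crae < s.crve  # rendered artery (11 px) narrower than vein (14 px)
    assert s.tortuosity >= 1.0
    assert 0.0 < s.fd <= 2.0
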