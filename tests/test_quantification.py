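"""Thresholding, per-ROI metrics against a brute-force oracle, densities."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from imcfiber.panel import ChannelStack, load_panel
from imcfiber.quantify import (
    ThresholdSet,
    apply_threshold,
    auto_threshold,
    metrics_frame,
    object_density,
    roi_metrics,
)


def _stack(panel, pix, sid="s"):
    return ChannelStack(pixels=pix.astype(np.uint16), panel=panel, sample_id=sid)


def brute_force_metrics(plane, roi, t):
    """Per-pixel loop oracle for positive fraction and mean intensities."""
    n = n_pos = 0
    s = s_pos = 0.0
    h, w = plane.shape
    for r in range(h):
        for c in range(w):
            if not roi[r, c]:
                continue
            v = float(plane[r, c])
            n += 1
            s += v
            if v >= t:
                n_pos += 1
                s_pos += v
    return (
        100.0 * n_pos / n,
        s / n,
        (s_pos / n_pos) if n_pos else None,
    )


class TestApplyThreshold:
    def test_all_zero_plane(self):
        assert not apply_threshold(np.zeros((3, 3)), 1).any()

    def test_zero_threshold_marks_everything(self, rng):
        plane = rng.integers(0, 50, (5, 5))
        assert apply_threshold(plane, 0).all()

    def test_elementwise_example(self):
        plane = np.array([[1, 5], [3, 9]])
        np.testing.assert_array_equal(
            apply_threshold(plane, 4), [[False, True], [False, True]]
        )

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            apply_threshold(np.zeros((2, 2)), -1)


class TestAutoThreshold:
    def test_quantile_matches_sorted_pixel_oracle(self, rng):
        plane = np.zeros((20, 20))
        idx = rng.choice(400, size=40, replace=False)
        plane.ravel()[idx] = 100.0
        roi = np.ones((20, 20), bool)
        t = auto_threshold(plane, roi, method="quantile", quantile=0.95)
        srt = np.sort(plane.ravel())
        assert t == float(np.quantile(srt, 0.95))
        assert t > 0
        # positive calls consistent with the planted 10% mixture
        assert apply_threshold(plane, t).sum() == 40

    def test_otsu_matches_exhaustive_two_class_search(self, rng):
        vals = np.concatenate([rng.integers(0, 5, 180), rng.integers(990, 1010, 60)])
        plane = vals.reshape(12, 20).astype(float)
        roi = np.ones((12, 20), bool)
        t = auto_threshold(plane, roi, method="otsu")
        # exhaustive search over candidate thresholds (between-class variance)
        best_t, best_v = None, -1.0
        flat = plane.ravel()
        for cand in np.unique(flat):
            lo, hi = flat[flat < cand], flat[flat >= cand]
            if lo.size == 0 or hi.size == 0:
                continue
            wv = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
            if wv > best_v:
                best_v, best_t = wv, cand
        # both split the same bimodal data: all high positive, no low positive
        assert (flat >= t).sum() == (flat >= best_t).sum() == 60

    def test_constant_plane_falls_back(self):
        plane = np.full((4, 4), 7.0)
        with pytest.warns(UserWarning, match="constant"):
            t = auto_threshold(plane, np.ones((4, 4), bool), method="otsu")
        assert t == 8.0
        assert not apply_threshold(plane, t).any()

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            auto_threshold(np.zeros((4, 4)), np.zeros((4, 4), bool))


class TestRoiMetrics:
    def test_known_fraction(self, small_panel_csv, rng):
        panel = load_panel(small_panel_csv)
        pix = np.zeros((5, 5, 3), dtype=np.uint16)
        pix[:2, :3, 0] = 10  # 6 of 25 pixels at/above threshold on channel 0
        stack = _stack(panel, pix)
        ts = ThresholdSet.uniform(panel.marker_names, 5.0)
        out = roi_metrics(stack, np.ones((5, 5), bool), ts)
        lam = next(m for m in out if m.marker_name == "Laminin")
        assert lam.positive_fraction == 24.0
        assert lam.roi_area_um2 == 25.0

    def test_all_and_none_positive(self, small_panel_csv, rng):
        panel = load_panel(small_panel_csv)
        pix = rng.integers(1, 10, (4, 4, 3))
        stack = _stack(panel, pix)
        roi = np.ones((4, 4), bool)
        all_pos = roi_metrics(stack, roi, ThresholdSet.uniform(panel.marker_names, 0.0))
        for m in all_pos:
            assert m.positive_fraction == 100.0
            assert m.positive_mean_intensity == m.mean_intensity
        none = roi_metrics(stack, roi, ThresholdSet.uniform(panel.marker_names, 1000.0))
        for m in none:
            assert m.positive_fraction == 0.0
            assert m.positive_mean_intensity is None

    def test_matches_brute_force_oracle(self, small_panel_csv, rng):
        panel = load_panel(small_panel_csv)
        for _ in range(5):
            pix = rng.integers(0, 30, (16, 16, 3))
            roi = rng.random((16, 16)) < 0.6
            if not roi.any():
                continue
            stack = _stack(panel, pix)
            ts = ThresholdSet.uniform(panel.marker_names, 12.0)
            for m in roi_metrics(stack, roi, ts):
                frac, mean, pos_mean = brute_force_metrics(
                    stack.plane(m.marker_name), roi, 12.0
                )
                assert m.positive_fraction == frac
                assert m.mean_intensity == pytest.approx(mean, abs=1e-12)
                if pos_mean is None:
                    assert m.positive_mean_intensity is None
                else:
                    assert m.positive_mean_intensity == pytest.approx(pos_mean, abs=1e-12)

    def test_union_of_disjoint_rois_is_area_weighted_average(self, small_panel_csv, rng):
        panel = load_panel(small_panel_csv)
        pix = rng.integers(0, 20, (10, 10, 3))
        stack = _stack(panel, pix)
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[:5] = True
        b[7:] = True
        ts = ThresholdSet.uniform(panel.marker_names, 10.0)
        ma = roi_metrics(stack, a, ts)
        mb = roi_metrics(stack, b, ts)
        mu = roi_metrics(stack, a | b, ts)
        for xa, xb, xu in zip(ma, mb, mu):
            wa, wb = xa.roi_area_um2, xb.roi_area_um2
            assert xu.positive_fraction == pytest.approx(
                (wa * xa.positive_fraction + wb * xb.positive_fraction) / (wa + wb),
                abs=1e-12,
            )
            assert xu.mean_intensity == pytest.approx(
                (wa * xa.mean_intensity + wb * xb.mean_intensity) / (wa + wb), abs=1e-12
            )

    @given(st.integers(0, 10**6), st.integers(0, 25))
    def test_positive_fraction_monotone_in_threshold(self, seed, tmax):
        rg = np.random.default_rng(seed)
        plane = rg.integers(0, 25, (8, 8))
        fracs = [
            100.0 * (plane >= t).sum() / plane.size for t in range(tmax + 1)
        ]
        assert all(x >= y for x, y in zip(fracs, fracs[1:]))

    def test_empty_roi_rejected(self, small_panel_csv):
        panel = load_panel(small_panel_csv)
        stack = _stack(panel, np.zeros((4, 4, 3)))
        with pytest.raises(ValueError, match="empty"):
            roi_metrics(stack, np.zeros((4, 4), bool), ThresholdSet.uniform(panel.marker_names, 1))

    def test_metrics_frame_shape(self, small_panel_csv):
        panel = load_panel(small_panel_csv)
        stack = _stack(panel, np.zeros((4, 4, 3)))
        df = metrics_frame(
            roi_metrics(stack, np.ones((4, 4), bool), ThresholdSet.uniform(panel.marker_names, 1))
        )
        assert len(df) == 3
        assert set(["marker_name", "positive_fraction", "mean_intensity"]) <= set(df.columns)


class TestThresholdSet:
    def test_wildcard_fallback_and_specific(self):
        ts = ThresholdSet()
        ts.set("*", "CD68", 5.0)
        ts.set("s2", "CD68", 9.0, provenance="auto")
        assert ts.get("s1", "CD68").value == 5.0
        assert ts.get("s2", "CD68").value == 9.0
        assert ts.get("s2", "CD68").provenance == "auto"

    def test_missing_names_sample_and_marker(self):
        ts = ThresholdSet()
        with pytest.raises(KeyError, match="s1.*CD68"):
            ts.get("s1", "CD68")

    def test_csv_roundtrip(self, tmp_path):
        ts = ThresholdSet()
        ts.set("s1", "CD68", 5.5)
        ts.set("*", "Laminin", 3.0, provenance="auto")
        f = tmp_path / "t.csv"
        ts.to_csv(f)
        back = ThresholdSet.from_csv(f)
        assert back.get("s1", "CD68").value == 5.5
        assert back.get("anything", "Laminin").provenance == "auto"

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSet().set("s", "m", -2)


class TestObjectDensity:
    def test_arithmetic(self):
        roi = np.zeros((1000, 1000), bool)
        roi[:500, :] = True  # 5·10⁵ µm²
        assert object_density(50, roi) == 100.0
        assert object_density(0, roi) == 0.0

    def test_doubling_area_halves_density(self):
        a = np.ones((100, 100), bool)
        b = np.ones((200, 100), bool)
        assert object_density(30, a) == 2 * object_density(30, b)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            object_density(1, np.zeros((5, 5), bool))
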