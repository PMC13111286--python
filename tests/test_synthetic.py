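"""Generator behaviour: templates, tremor model, rendering, derived features."""

import numpy as np
import pandas as pd
import pytest

from qhandpd import synthetic as syn
from qhandpd.preprocessing import suppress_grayscale


def test_spiral_radius_monotone_and_angular_extent():
    t = syn.generate_template("spiral", n_turns=3, canvas_size=512, seed=0)
    c = 512 / 2.0
    rel = t.points - c
    r = np.linalg.norm(rel, axis=1)
    assert np.all(np.diff(r) > -1e-9)
    # unwrapped polar angle spans n_turns revolutions
    theta = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    extent = theta[-1] - theta[0]
    assert abs(extent - 6 * np.pi) < 0.1


def test_meander_stays_in_canvas_and_is_deterministic():
    a = syn.generate_template("meander", 2, 512, seed=0)
    b = syn.generate_template("meander", 2, 512, seed=0)
    assert np.array_equal(a.points, b.points)
    assert a.points.min() >= 0 and a.points.max() <= 511


def test_invalid_template_kind_rejected():
    with pytest.raises(ValueError):
        syn.generate_template("circle", 2, 512)


def test_zero_tremor_reproduces_template_exactly():
    t = syn.generate_template("spiral", 2, 256)
    s = syn.simulate_subject_trace(t, syn.TremorParams(0, 0, 0))
    assert np.array_equal(s.points, t.points)
    assert syn.compute_structured_features(t, s) == (0.0, 0.0, 0.0)


def test_tremor_displacement_amplitude_bound():
    t = syn.generate_template("spiral", 3, 512)
    s = syn.simulate_subject_trace(t, syn.TremorParams(5.0, 4.0, 0.0))
    d = np.linalg.norm(s.points - t.points, axis=1)
    assert abs(d.max() - 5.0) < 0.05
    assert d.max() <= 5.0 + 1e-9


def test_tremor_seed_determinism():
    t = syn.generate_template("meander", 2, 256)
    p = syn.TremorParams(2.0, 6.0, 1.0, seed=5)
    a = syn.simulate_subject_trace(t, p)
    b = syn.simulate_subject_trace(t, p)
    assert np.array_equal(a.points, b.points)


def test_negative_tremor_rejected():
    with pytest.raises(ValueError):
        syn.TremorParams(amplitude=-1.0)


class TestRasterization:
    def setup_method(self):
        self.template = syn.generate_template("spiral", 2, 256)
        self.subject = syn.simulate_subject_trace(
            self.template, syn.TremorParams(4.0, 10.0, 0.5, seed=3))

    def test_template_pixels_satisfy_grayscale_predicate(self):
        img = syn.rasterize_exam(self.template, self.subject, 256,
                                 template_color=(80, 80, 80))
        tm = syn.trace_mask(self.template, 256)
        sm = syn.trace_mask(self.subject, 256)
        only_template = tm & ~sm
        px = img[only_template].astype(int)
        diffs = np.abs(px[:, [0, 0, 1]] - px[:, [1, 2, 2]])
        assert np.all(diffs < 45)

    def test_pen_pixels_fail_grayscale_predicate(self):
        img = syn.rasterize_exam(self.template, self.subject, 256,
                                 pen_color=(0, 0, 255))
        sm = syn.trace_mask(self.subject, 256)
        px = img[sm].astype(int)
        diffs = np.abs(px[:, [0, 0, 1]] - px[:, [1, 2, 2]])
        assert np.all(diffs.max(axis=1) >= 45)

    def test_background_is_pure_white(self):
        img = syn.rasterize_exam(self.template, self.subject, 256)
        untouched = ~(syn.trace_mask(self.template, 256)
                      | syn.trace_mask(self.subject, 256))
        assert np.all(img[untouched] == 255)

    def test_gray_pen_rejected(self):
        with pytest.raises(ValueError):
            syn.rasterize_exam(self.template, self.subject, 256,
                               pen_color=(100, 110, 120))

    def test_saturated_template_rejected(self):
        with pytest.raises(ValueError):
            syn.rasterize_exam(self.template, self.subject, 256,
                               template_color=(200, 40, 40))


class TestStructuredFeatures:
    def test_known_deviations(self):
        t = syn.PolylineTrace(np.array([[0.0, 0.0], [10.0, 0.0]]), "spiral")
        s = syn.PolylineTrace(np.array([[0.0, 3.0], [10.0, 4.0]]), "spiral")
        rms, mrt, std = syn.compute_structured_features(t, s)
        assert rms == pytest.approx(np.sqrt(12.5))
        assert mrt == pytest.approx(1.0)          # |4 - 3|
        assert std == pytest.approx(0.5)

    def test_constant_deviation(self):
        t = syn.PolylineTrace(np.array([[0.0, 0], [1, 0], [2, 0]]), "spiral")
        s = syn.PolylineTrace(t.points + [0.0, 2.0], "spiral")
        rms, mrt, std = syn.compute_structured_features(t, s)
        assert rms == pytest.approx(2.0)
        assert mrt == 0.0
        assert std == 0.0

    def test_mismatched_lengths_rejected(self):
        t = syn.PolylineTrace(np.zeros((4, 2)) + [[1, 1]], "spiral")
        s = syn.PolylineTrace(np.zeros((3, 2)) + [[1, 1]], "spiral")
        with pytest.raises(ValueError):
            syn.compute_structured_features(t, s)


class TestDatasetGeneration:
    def test_counts_columns_and_determinism(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        m1 = syn.generate_dataset(10, 10, 4, seed=1, out_dir=d1,
                                  canvas_size=256)
        syn.generate_dataset(10, 10, 4, seed=1, out_dir=d2, canvas_size=256)
        assert len(m1) == 80
        csv1 = (d1 / "meta.csv").read_bytes()
        csv2 = (d2 / "meta.csv").read_bytes()
        assert csv1 == csv2
        meta = pd.read_csv(d1 / "meta.csv")
        assert list(meta.columns) == [
            "exam_id", "image_name", "patient_id", "class_label", "gender",
            "handedness", "age", "rms", "mrt", "std_diff"]

    def test_group_rms_separation(self, tiny_manifest):
        g = tiny_manifest.records.groupby("class_label")["rms"].mean()
        assert g["P"] > g["H"]

    def test_age_ranges(self, tiny_manifest):
        ages = tiny_manifest.records["age"]
        assert ages.between(18, 90).all()

    def test_pd_mean_rms_monotone_in_amplitude(self):
        means = []
        for amp in (0.5, 2.0, 4.0, 8.0):
            cfg = syn.TremorConfig(pd_amplitude=amp)
            recs = syn.simulate_feature_records(2, 6, 2, tremor_config=cfg,
                                                seed=3, canvas_size=256)
            means.append(recs.loc[recs.class_label == "P", "rms"].mean())
        assert np.all(np.diff(means) >= 0)

    def test_pen_trace_survives_suppression(self, tiny_manifest):
        from qhandpd.io import load_image
        for p in tiny_manifest.records["image_path"][:4]:
            sup = suppress_grayscale(load_image(p))
            assert (sup != 255).any()
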