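import numpy as np
import pytest

from grasemap.datasets import healthy_example_segments
from grasemap.phantoms import PhantomSpec, generate_cardiac
from grasemap.protocols import preset
from grasemap.segments import (
    SEGMENT_NAMES,
    SegmentModel,
    assign_segments,
    regional_contrasts,
    segment_ids,
    segment_report,
)


def circle(cx, cy, r, n=64):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])


@pytest.fixture
def concentric_model():
    return SegmentModel(
        endo_contour=circle(32, 32, 8),
        epi_contour=circle(32, 32, 16),
        rv_insertion=np.array([32 - 18 * np.cos(np.radians(30)), 32 - 18 * np.sin(np.radians(30))]),
        slice_level="mid",
    )


def report_from_segment_values(values_by_id):
    """Constant-valued segments laid out as pixel blocks, then reported."""
    ids = sorted(values_by_id)
    labels = np.zeros((4, 4 * len(ids)), dtype=int)
    t2 = np.zeros_like(labels, dtype=float)
    for i, sid in enumerate(ids):
        labels[:, 4 * i : 4 * (i + 1)] = sid
        t2[:, 4 * i : 4 * (i + 1)] = values_by_id[sid]
    return segment_report(t2, labels)


class TestGeometry:
    def test_labels_partition_myocardium(self, concentric_model):
        labels = assign_segments(concentric_model, (64, 64))
        myo = labels > 0
        assert set(np.unique(labels[myo])) == set(segment_ids("mid"))
        # ring area between the polygons, roughly pi*(16^2 - 8^2)
        assert 500 < myo.sum() < 640

    def test_six_sectors_of_equal_span(self, concentric_model):
        labels = assign_segments(concentric_model, (64, 64))
        counts = np.bincount(labels[labels > 0])[7:13]
        assert counts.min() > 0.8 * counts.max()

    def test_apical_model_four_segments(self):
        model = SegmentModel(
            endo_contour=circle(32, 32, 6),
            epi_contour=circle(32, 32, 13),
            rv_insertion=np.array([16.0, 24.0]),
            slice_level="apical",
        )
        labels = assign_segments(model, (64, 64))
        assert set(np.unique(labels[labels > 0])) == set(segment_ids("apical"))

    def test_rv_insertion_inside_endo_rejected(self):
        with pytest.raises(ValueError, match="rv_insertion"):
            SegmentModel(
                endo_contour=circle(32, 32, 8),
                epi_contour=circle(32, 32, 16),
                rv_insertion=np.array([32.0, 32.0]),
                slice_level="mid",
            )

    def test_roundtrip_against_generator_truth(self, protocol_6ec):
        # default acquisition-matrix geometry: boundary pixels are the
        # only expected disagreements
        spec = PhantomSpec(kind="cardiac", seed=5)
        stack, model, truth = generate_cardiac(
            spec, protocol_6ec, (55.5, 57.1, 50.2, 50.2, 54.6, 49.2), "mid"
        )
        labels = assign_segments(model, stack.shape)
        myo = truth["label_map"] > 0
        agree = (labels[myo] == truth["label_map"][myo]).mean()
        assert agree > 0.99


class TestReport:
    def test_worked_example_global_mean_and_sd(self):
        seg = healthy_example_segments()
        rep = report_from_segment_values(dict(zip(seg["aha_id"], seg["t2_ms"])))
        assert round(rep.global_mean, 1) == 51.6
        assert round(rep.global_sd, 1) == 3.3  # population SD of segment means

    def test_constant_segments(self):
        rep = report_from_segment_values({i: 47.0 for i in range(1, 7)})
        assert rep.global_mean == pytest.approx(47.0)
        assert rep.global_sd == pytest.approx(0.0)

    def test_invariant_to_pixel_ordering(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 7, size=(20, 20))
        t2 = rng.uniform(40, 60, size=(20, 20))
        rep1 = segment_report(t2, labels)
        perm = rng.permutation(400)
        rep2 = segment_report(t2.ravel()[perm].reshape(20, 20), labels.ravel()[perm].reshape(20, 20))
        assert rep1.global_mean == pytest.approx(rep2.global_mean)
        assert sorted(rep1.table["mean_ms"]) == pytest.approx(sorted(rep2.table["mean_ms"]))

    def test_empty_segment_flagged_and_excluded(self):
        labels = np.array([[1, 1, 2, 2]])
        t2 = np.array([[50.0, 50.0, 60.0, 60.0]])
        valid = np.array([[True, True, False, False]])
        rep = segment_report(t2, labels, converged=valid)
        assert rep.meta["empty_segments"] == [2]
        assert rep.global_mean == pytest.approx(50.0)

    def test_pixelweighted_alternative_differs_when_sizes_differ(self):
        labels = np.array([[1, 1, 1, 2]])
        t2 = np.array([[40.0, 40.0, 40.0, 80.0]])
        rep = segment_report(t2, labels)
        assert rep.global_mean == pytest.approx(60.0)  # mean of segment means
        assert rep.global_mean_pixelweighted == pytest.approx(50.0)


class TestRegionalContrasts:
    def _slice_report(self, level, values):
        ids = segment_ids(level)
        return report_from_segment_values(dict(zip(ids, values)))

    def test_identical_slices_zero_contrasts(self):
        reports = {
            "basal": self._slice_report("basal", [52.0] * 6),
            "mid": self._slice_report("mid", [52.0] * 6),
            "apical": self._slice_report("apical", [52.0] * 4),
        }
        out = regional_contrasts(reports)
        assert out["apical_minus_mid"] == pytest.approx(0.0)
        assert out["septal_minus_lateral"] == pytest.approx(0.0)
        assert out["missing_slices"] == []

    def test_constructed_apical_elevation_recovered(self):
        mid = [52.0, 53.0, 51.0, 52.5, 51.5, 52.0]
        apical = [np.mean(mid) + 1.2] * 4
        reports = {
            "mid": self._slice_report("mid", mid),
            "apical": self._slice_report("apical", apical),
        }
        out = regional_contrasts(reports)
        assert out["apical_minus_mid"] == pytest.approx(1.2)
        assert out["missing_slices"] == ["basal"]
        assert out["apical_minus_basal"] is None

    def test_worked_example_apical_minus_mid(self):
        seg = healthy_example_segments()
        reports = {
            lv: self._slice_report(lv, seg.loc[seg["level"] == lv, "t2_ms"].tolist())
            for lv in ("basal", "mid", "apical")
        }
        out = regional_contrasts(reports)
        # apical segment mean 53.45, mid segment mean 52.80
        assert out["apical_minus_mid"] == pytest.approx(53.45 - 52.80, abs=1e-10)


def test_segment_naming_table():
    assert SEGMENT_NAMES[1] == ("basal", "anterior")
    assert SEGMENT_NAMES[14] == ("apical", "septal")
    assert len(SEGMENT_NAMES) == 16
    with pytest.raises(ValueError):
        segment_ids("cap")
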