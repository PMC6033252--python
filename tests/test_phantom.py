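"""Phantom generator: determinism, geometry, text rendering, DICOM wrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roipack import phantom
from roipack.dicom_io import read_dicom
from roipack.errors import (
    CompletenessError,
    SizingError,
    UnsupportedCharacterError,
)
from roipack.font import DEFAULT_ATLAS
from roipack.ocr import TextRun

META = {
    "PatientName": "ERDAL",
    "PatientSurname": "TEST",
    "CitizenshipID": "12345678901",
    "StudyDate": "2016-01-01",
    "HIMSID": "52721",
}


def glyph_pixels(truth) -> np.ndarray:
    """Boolean map of every rendered glyph pixel, from the ground truth runs."""
    shape = truth.roi_mask.shape
    out = np.zeros(shape, dtype=bool)
    probe = np.zeros(shape, dtype=np.uint16)
    for run in truth.text_runs:
        stamped = phantom.render_text(probe, run)
        out |= stamped > 0
    return out


class TestGeneratePhantom:
    def test_same_spec_gives_bit_identical_phantoms(self):
        spec = phantom.PhantomSpec(seed=42)
        a, _ = phantom.generate_phantom(spec)
        b, _ = phantom.generate_phantom(spec)
        assert a.pixels.tobytes() == b.pixels.tobytes()

    def test_realized_roi_fraction_tracks_request_at_512(self):
        spec = phantom.PhantomSpec(rows=512, cols=512, roi_fraction=0.3284, seed=3)
        _, truth = phantom.generate_phantom(spec)
        assert truth.roi_area_fraction == pytest.approx(0.3284, abs=0.03)

    @pytest.mark.parametrize("size", [64, 128, 512, 1024])
    def test_realized_fraction_within_band_across_frame_sizes(self, size):
        spec = phantom.PhantomSpec(
            rows=size, cols=size, roi_fraction=0.25, seed=size,
            text_lines=("A 1",),
        )
        _, truth = phantom.generate_phantom(spec)
        assert truth.roi_area_fraction == pytest.approx(0.25, abs=0.03)

    def test_noiseless_background_is_exactly_background_level(self):
        spec = phantom.PhantomSpec(seed=1, noise_sigma=0.0, background_level=17)
        rec, truth = phantom.generate_phantom(spec)
        untouched = ~truth.roi_mask & ~glyph_pixels(truth)
        assert (rec.pixels[untouched] == 17).all()

    def test_noise_stays_inside_roi_by_default(self):
        spec = phantom.PhantomSpec(seed=1, noise_sigma=500.0)
        rec, truth = phantom.generate_phantom(spec)
        untouched = ~truth.roi_mask & ~glyph_pixels(truth)
        assert (rec.pixels[untouched] == 0).all()

    def test_oversized_roi_is_a_sizing_error(self):
        with pytest.raises(SizingError):
            phantom.generate_phantom(phantom.PhantomSpec(roi_fraction=0.95))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        size=st.integers(72, 200),
        frac=st.floats(0.05, 0.45),
        sigma=st.floats(0.0, 2000.0),
    )
    def test_mask_and_glyphs_are_disjoint_for_all_specs(self, seed, size, frac, sigma):
        spec = phantom.PhantomSpec(
            rows=size, cols=size, roi_fraction=frac, noise_sigma=sigma,
            seed=seed, text_lines=("AB 12", "XY-9"),
        )
        rec, truth = phantom.generate_phantom(spec)
        glyphs = glyph_pixels(truth)
        assert truth.roi_mask.any()
        assert not (truth.roi_mask & glyphs).any()
        for run in truth.text_runs:
            assert not truth.roi_mask[run.anchor]
        assert truth.roi_area_fraction == pytest.approx(frac, abs=0.03)


class TestRenderText:
    def test_glyph_stamp_changes_exactly_the_atlas_pixel_set(self):
        img = np.zeros((32, 32), dtype=np.uint16)
        run = TextRun(text="A", anchor=(10, 10), intensity=999)
        out = phantom.render_text(img, run)
        diff = np.argwhere(out != img)
        expected = np.argwhere(DEFAULT_ATLAS.glyph("A")) + [10, 10]
        assert sorted(map(tuple, diff)) == sorted(map(tuple, expected))
        assert (out[out != img] == 999).all()

    def test_two_disjoint_runs_diff_is_union_of_single_run_diffs(self):
        img = np.zeros((40, 60), dtype=np.uint16)
        r1 = TextRun(text="7A", anchor=(2, 3), intensity=100)
        r2 = TextRun(text="Z", anchor=(20, 30), intensity=200)
        both = phantom.render_text(phantom.render_text(img, r1), r2)
        d1 = {tuple(p) for p in np.argwhere(phantom.render_text(img, r1) != img)}
        d2 = {tuple(p) for p in np.argwhere(phantom.render_text(img, r2) != img)}
        dboth = {tuple(p) for p in np.argwhere(both != img)}
        assert dboth == d1 | d2

    def test_unsupported_character_is_rejected(self):
        img = np.zeros((20, 20), dtype=np.uint16)
        with pytest.raises(UnsupportedCharacterError):
            phantom.render_text(img, TextRun(text="a", anchor=(1, 1), intensity=5))

    def test_run_must_fit_in_frame(self):
        img = np.zeros((10, 10), dtype=np.uint16)
        with pytest.raises(ValueError):
            phantom.render_text(img, TextRun(text="ABC", anchor=(1, 1), intensity=5))


class TestWrapDicom:
    def test_wrap_then_read_reproduces_pixels_bit_exactly(self, default_phantom):
        rec, _ = default_phantom
        back = read_dicom(phantom.wrap_dicom(rec, META))
        assert (back.pixels == rec.pixels).all()
        assert back.bits_stored == rec.bits_stored

    def test_patient_metadata_survives_the_header(self, default_phantom):
        rec, _ = default_phantom
        back = read_dicom(phantom.wrap_dicom(rec, META))
        assert back.metadata["PatientName"] == "ERDAL"
        assert back.metadata["PatientSurname"] == "TEST"
        assert back.metadata["HIMSID"] == "52721"
        assert back.metadata["StudyDate"] == "2016-01-01"

    def test_sixteen_bit_phantom_writes_two_bytes_per_pixel(self, default_phantom):
        import pydicom
        from io import BytesIO

        rec, _ = default_phantom
        ds = pydicom.dcmread(BytesIO(phantom.wrap_dicom(rec, META)))
        assert ds.file_meta.TransferSyntaxUID.is_little_endian
        assert ds.BitsAllocated == 16
        assert len(ds.PixelData) == rec.rows * rec.cols * 2

    def test_missing_required_field_is_rejected(self, default_phantom):
        rec, _ = default_phantom
        with pytest.raises(CompletenessError):
            phantom.wrap_dicom(rec, {"PatientName": "X"})


class TestGroundTruthSidecar:
    def test_ground_truth_json_round_trips(self, default_phantom):
        _, truth = default_phantom
        again = phantom.ground_truth_from_json(phantom.ground_truth_to_json(truth))
        assert (again.roi_mask == truth.roi_mask).all()
        assert again.roi_area_fraction == truth.roi_area_fraction
        assert [(r.text, r.anchor, r.intensity) for r in again.text_runs] == [
            (r.text, r.anchor, r.intensity) for r in truth.text_runs
        ]
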