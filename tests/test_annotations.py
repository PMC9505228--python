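"""Annotation I/O: coordinate conventions, round-trips, preprocessing."""

import numpy as np
import pytest

from acnedet.annotations import (
    AnnotatedImage,
    AnnotationError,
    LesionBox,
    load_manifest_dataset,
    normalize_image,
    read_voc_xml,
    read_yolo_txt,
    resize_with_boxes,
    write_voc_xml,
    write_yolo_txt,
)


def _random_image(rng, n_boxes, size=100):
    boxes = []
    for _ in range(n_boxes):
        x0, y0 = rng.integers(0, size - 10, size=2)
        w, h = rng.integers(2, 10, size=2)
        boxes.append(LesionBox(float(x0), float(y0), float(x0 + w), float(y0 + h)))
    return AnnotatedImage(image_id="t", width=size, height=size, boxes=boxes)


class TestVocXml:
    def test_voc_coordinates_are_one_based_inclusive(self, tmp_path):
        xml = tmp_path / "a.xml"
        xml.write_text(
            "<annotation><filename>a.png</filename>"
            "<size><width>100</width><height>100</height><depth>3</depth></size>"
            "<object><name>lesion</name><bndbox>"
            "<xmin>10</xmin><ymin>20</ymin><xmax>30</xmax><ymax>40</ymax>"
            "</bndbox></object></annotation>"
        )
        img = read_voc_xml(xml)
        b = img.boxes[0]
        assert (b.xmin, b.ymin, b.xmax, b.ymax) == (9, 19, 30, 40)

    def test_count_equals_number_of_objects(self, tmp_path):
        img = _random_image(np.random.default_rng(0), 3)
        path = tmp_path / "b.xml"
        write_voc_xml(img, path)
        assert read_voc_xml(path).count == 3

    def test_round_trip_on_random_annotations(self, tmp_path, rng):
        for k in range(50):
            img = _random_image(rng, int(rng.integers(1, 8)))
            path = tmp_path / f"{k}.xml"
            write_voc_xml(img, path)
            back = read_voc_xml(path)
            assert back.count == img.count
            for a, b in zip(img.boxes, back.boxes):
                assert (a.xmin, a.ymin, a.xmax, a.ymax) == (b.xmin, b.ymin, b.xmax, b.ymax)

    def test_malformed_xml_names_file(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<annotation><size>")
        with pytest.raises(AnnotationError, match="bad.xml"):
            read_voc_xml(bad)

    def test_out_of_bounds_box_rejected_not_clamped(self, tmp_path):
        xml = tmp_path / "oob.xml"
        xml.write_text(
            "<annotation><size><width>50</width><height>50</height></size>"
            "<object><bndbox><xmin>40</xmin><ymin>40</ymin>"
            "<xmax>60</xmax><ymax>60</ymax></bndbox></object></annotation>"
        )
        with pytest.raises(AnnotationError, match="outside image bounds"):
            read_voc_xml(xml)


class TestYoloTxt:
    def test_full_image_box(self, tmp_path):
        p = tmp_path / "a.txt"
        write_yolo_txt([LesionBox(0, 0, 100, 100)], 100, 100, p)
        assert p.read_text().split() == ["0", "0.500000000", "0.500000000",
                                         "1.000000000", "1.000000000"]

    def test_normalized_center_arithmetic(self, tmp_path):
        p = tmp_path / "b.txt"
        write_yolo_txt([LesionBox(9, 19, 30, 40)], 100, 100, p)
        _, cx, cy, w, h = p.read_text().split()
        assert np.allclose([float(cx), float(cy), float(w), float(h)],
                           [0.195, 0.295, 0.21, 0.21])

    def test_round_trip_error_below_tolerance(self, tmp_path, rng):
        size = 640
        boxes = []
        for _ in range(50):
            x0, y0 = rng.uniform(0, size - 20, size=2)
            w, h = rng.uniform(1, 20, size=2)
            boxes.append(LesionBox(x0, y0, x0 + w, y0 + h))
        p = tmp_path / "c.txt"
        write_yolo_txt(boxes, size, size, p)
        back = read_yolo_txt(p, size, size)
        err = max(
            abs(getattr(a, f) - getattr(b, f))
            for a, b in zip(boxes, back)
            for f in ("xmin", "ymin", "xmax", "ymax")
        )
        assert err < 1e-6 * size

    def test_value_outside_unit_interval_rejected(self, tmp_path):
        p = tmp_path / "d.txt"
        p.write_text("0 0.5 0.5 1.5 0.1\n")
        with pytest.raises(AnnotationError, match="outside"):
            read_yolo_txt(p, 100, 100)


class TestResize:
    def test_uniform_halving(self):
        img = AnnotatedImage(
            "t", 448, 448, [LesionBox(0, 0, 448, 448)],
            pixels=np.zeros((448, 448, 3), np.uint8),
        )
        out = resize_with_boxes(img, (224, 224))
        b = out.boxes[0]
        assert out.pixels.shape == (224, 224, 3)
        assert (b.xmin, b.ymin, b.xmax, b.ymax) == (0, 0, 224, 224)

    def test_anisotropic_scaling_applies_per_axis(self):
        img = AnnotatedImage("t", 100, 200, [LesionBox(10, 20, 30, 60)])
        out = resize_with_boxes(img, (224, 224))
        b = out.boxes[0]
        assert np.allclose([b.xmin, b.xmax], [10 * 2.24, 30 * 2.24])
        assert np.allclose([b.ymin, b.ymax], [20 * 1.12, 60 * 1.12])

    def test_resize_to_own_size_is_identity(self, easy_images):
        img = easy_images[0]
        out = resize_with_boxes(img, (img.width, img.height))
        assert np.array_equal(out.pixels, img.pixels)
        assert all(
            (a.xmin, a.ymin, a.xmax, a.ymax) == (b.xmin, b.ymin, b.xmax, b.ymax)
            for a, b in zip(img.boxes, out.boxes)
        )

    def test_degenerate_box_flagged_and_kept_at_one_pixel(self):
        img = AnnotatedImage("t", 100, 100, [LesionBox(50, 50, 52, 52)])
        with pytest.warns(UserWarning, match="degenerate"):
            out = resize_with_boxes(img, (32, 32))
        b = out.boxes[0]
        assert b.width >= 1.0 and b.height >= 1.0

    def test_area_ordering_preserved_under_uniform_scaling(self, rng):
        boxes = []
        for _ in range(10):
            x0, y0 = rng.uniform(0, 80, 2)
            boxes.append(LesionBox(x0, y0, x0 + rng.uniform(1, 20), y0 + rng.uniform(1, 20)))
        img = AnnotatedImage("t", 100, 100, boxes)
        out = resize_with_boxes(img, (250, 250))
        before = np.argsort([b.area for b in img.boxes])
        after = np.argsort([b.area for b in out.boxes])
        assert np.array_equal(before, after)


class TestNormalize:
    def test_midpoint_maps_to_zero(self):
        px = np.full((2, 2, 3), 127.5)
        assert np.allclose(normalize_image(px, (0.5,) * 3, (0.5,) * 3), 0.0)

    def test_identity_scale(self):
        px = np.full((1, 1, 3), 255)
        assert np.allclose(normalize_image(px, (0,) * 3, (1,) * 3), 1.0)

    def test_per_channel_fixture(self):
        px = np.array([[[255, 0, 51], [102, 153, 204]]], dtype=float)
        out = normalize_image(px, (0.1, 0.2, 0.3), (0.5, 0.4, 0.2))
        expect = np.array([[[(1.0 - 0.1) / 0.5, (0.0 - 0.2) / 0.4, (0.2 - 0.3) / 0.2],
                            [(0.4 - 0.1) / 0.5, (0.6 - 0.2) / 0.4, (0.8 - 0.3) / 0.2]]])
        assert np.allclose(out, expect, atol=1e-6)

    def test_zero_std_rejected(self):
        with pytest.raises(ValueError):
            normalize_image(np.zeros((1, 1, 3)), (0.5,) * 3, (0.5, 0.0, 0.5))


def test_reader_invariants_on_synthetic_dataset(tmp_path, easy_images):
    from acnedet.synthetic import generate_dataset

    root = generate_dataset(10, seed=3, out_dir=tmp_path / "ds")
    loaded = load_manifest_dataset(root)
    assert len(loaded) == 10
    for img in loaded:
        assert img.count == len(img.boxes)
        for b in img.boxes:
            b.validate_within(img.width, img.height)
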