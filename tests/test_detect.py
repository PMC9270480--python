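import numpy as np
import pytest

from mammotile.detect import (
    DetectorConfig,
    DoGDetector,
    ScriptedDetector,
    detect,
    run_scale,
)
from mammotile.errors import ConfigError
from mammotile.evaluate import is_hit
from mammotile.geometry import Box, Detection, Frame, box_center
from mammotile.phantom import PhantomSpec, generate_phantom

from conftest import SMALL_KW


def gaussian_blob(shape, cy, cx, sigma, amplitude=0.5):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    return amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))


class TestDetectorConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"sigma_min": 0.0},
            {"sigma_min": 10.0, "sigma_max": 5.0},
            {"n_sigma": 1},
            {"response_threshold": -1.0},
        ],
    )
    def test_invalid(self, kw):
        with pytest.raises(ConfigError):
            DetectorConfig(**kw)

    def test_sigma_ladder(self):
        cfg = DetectorConfig(sigma_min=2.0, sigma_max=8.0, n_sigma=2)
        np.testing.assert_allclose(cfg.sigmas(), [2.0, 4.0, 8.0])


class TestDetect:
    def test_zeros_empty(self):
        assert detect(np.zeros((128, 128)), DetectorConfig()) == []

    def test_single_blob_in_band(self):
        """Brute-force check: one blob of sigma 8 within band [4, 16] yields
        exactly one detection centered on it (within 2 px)."""
        img = gaussian_blob((200, 200), 100, 100, 8.0)
        cfg = DetectorConfig(sigma_min=4.0, sigma_max=16.0, n_sigma=6,
                             response_threshold=0.05)
        dets = detect(img, cfg)
        assert len(dets) == 1
        cx, cy = box_center(dets[0].box)
        assert abs(cx - 100) <= 2 and abs(cy - 100) <= 2
        # brute-force peak: the blob maximum is at (100, 100)
        peak = np.unravel_index(np.argmax(img), img.shape)
        assert peak == (100, 100)

    def test_blob_outside_band_missed(self):
        """The receptive-field analog: a blob far larger than the sigma
        band produces no detection at the default threshold, while a
        band matched to the blob does detect it."""
        img = gaussian_blob((200, 200), 100, 100, 8.0, amplitude=0.15)
        narrow = DetectorConfig(sigma_min=1.0, sigma_max=3.0, n_sigma=4)
        matched = DetectorConfig(sigma_min=4.0, sigma_max=16.0, n_sigma=6)
        assert detect(img, narrow) == []
        assert len(detect(img, matched)) >= 1

    def test_deterministic(self, small_phantom):
        tile = small_phantom.image[:256, :256]
        a = detect(tile, DetectorConfig())
        b = detect(tile, DetectorConfig())
        assert a == b

    def test_scores_in_unit_interval(self, small_phantom):
        for det in detect(small_phantom.image[:256, :256], DetectorConfig()):
            assert 0.0 <= det.score <= 1.0

    def test_run_scale_clips_to_image(self):
        img = gaussian_blob((64, 64), 3, 3, 4.0)
        cfg = DetectorConfig(sigma_min=2.0, sigma_max=8.0, response_threshold=0.02)
        for d in run_scale(img, 1.0, 64, DoGDetector(cfg)):
            assert d.box.x_min >= 0 and d.box.y_min >= 0
            assert d.box.x_max <= 64 and d.box.y_max <= 64


class TestRunScale:
    def test_blank_image_empty(self):
        for scale in (1.0, 0.5, 0.25):
            out = run_scale(np.zeros((512, 416), dtype=np.uint16), scale, 256,
                            DoGDetector())
            assert out == []

    def test_phantom_lesion_detected_full_scale(self):
        spec = PhantomSpec(lesion_diameters=(12.0,), seed=5, **SMALL_KW)
        phantom = generate_phantom(spec)
        dets = run_scale(phantom.image, 1.0, 256, DoGDetector(
            DetectorConfig(sigma_min=6.0, sigma_max=24.0, n_sigma=6)
        ))
        assert any(is_hit(d.box, phantom.gt_boxes[0]) for d in dets)

    def test_offsets_remapped(self):
        """A detection scripted in the tile at long-axis offset 1024 has
        full-res y >= 1024/scale."""
        scale = 0.5
        scripted = ScriptedDetector({
            (scale, 0.0, 1024.0): [
                Detection(box=Box(10, 10, 20, 20), score=0.9)
            ],
        })
        img = np.zeros((4096, 1500), dtype=np.uint16)
        dets = run_scale(img, scale, 1024, scripted)
        assert len(dets) == 1
        assert dets[0].box.y_min >= 1024 / scale
        assert dets[0].box == Box(20, 2068, 40, 2088)
        assert dets[0].frame == Frame(scale=0.5, tile_offset=(0.0, 1024.0))

    def test_mock_detector_contract(self):
        """Any callable image -> detections is accepted."""
        calls = []

        def mock(image):
            calls.append(image.shape)
            return [Detection(box=Box(1, 1, 5, 5), score=0.5)]

        img = np.zeros((1000, 300), dtype=np.uint16)
        dets = run_scale(img, 1.0, 256, mock, seam_nms_iou=None)
        assert len(calls) == 4  # ceil(1000/256)
        assert len(dets) == 4

    def test_seam_lesion_single_detection(self):
        """Regression: a lesion centered exactly on a tile boundary must
        survive seam NMS as one box, not two."""
        img = np.zeros((512, 200))
        img += gaussian_blob((512, 200), 256, 100, 6.0)  # boundary at y=256
        cfg = DetectorConfig(sigma_min=3.0, sigma_max=12.0, response_threshold=0.05)
        dets = run_scale(img, 1.0, 256, DoGDetector(cfg))
        near = [d for d in dets if abs(box_center(d.box)[1] - 256) < 15]
        assert len(near) == 1

    def test_seam_nms_disabled_keeps_duplicates(self):
        img = np.zeros((512, 200))
        img += gaussian_blob((512, 200), 256, 100, 6.0)
        cfg = DetectorConfig(sigma_min=3.0, sigma_max=12.0, response_threshold=0.05)
        with_nms = run_scale(img, 1.0, 256, DoGDetector(cfg))
        without = run_scale(img, 1.0, 256, DoGDetector(cfg), seam_nms_iou=None)
        assert len(without) >= len(with_nms)

    def test_csv_tile_prediction_adapter(self, tmp_path):
        """External per-tile predictions flow through run_scale's
        remapping exactly like a live detector's output."""
        import pandas as pd

        from mammotile.detect import load_tile_predictions_csv

        path = tmp_path / "tiles.csv"
        pd.DataFrame(
            [
                {"scale": 0.5, "tile_x": 0.0, "tile_y": 1024.0,
                 "x_min": 10, "y_min": 10, "x_max": 20, "y_max": 20, "score": 0.9},
            ]
        ).to_csv(path, index=False)
        detector = load_tile_predictions_csv(path)
        dets = run_scale(np.zeros((4096, 1500), dtype=np.uint16), 0.5, 1024, detector)
        assert len(dets) == 1
        assert dets[0].box == Box(20, 2068, 40, 2088)

    def test_csv_tile_adapter_rejects_missing_columns(self, tmp_path):
        from mammotile.detect import load_tile_predictions_csv
        from mammotile.errors import InputError

        path = tmp_path / "bad.csv"
        path.write_text("scale,x_min\n1.0,2\n")
        with pytest.raises(InputError, match="missing columns"):
            load_tile_predictions_csv(path)

    def test_scale_selectivity(self):
        """Fixed sigma band: small lesions only at full resolution, large
        lesions only at reduced scale."""
        spec = PhantomSpec(lesion_diameters=(5.0, 28.0), seed=3, **SMALL_KW)
        phantom = generate_phantom(spec)
        small_gt, large_gt = phantom.gt_boxes
        detector = DoGDetector()

        def top_hit(scale, gt):
            dets = run_scale(phantom.image, scale, 256, detector)
            return max((d.score for d in dets if is_hit(d.box, gt)), default=0.0)

        assert top_hit(1.0, small_gt) > top_hit(0.25, small_gt)
        assert top_hit(0.25, large_gt) > top_hit(1.0, large_gt)
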