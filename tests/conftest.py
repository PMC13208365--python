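import numpy as np
import pytest

from mercquant import Calibration, LabelMask


@pytest.fixture
def unit_cal() -> Calibration:
    return Calibration(1.0)


@pytest.fixture
def rect_mask(unit_cal) -> LabelMask:
    """12x12 scene: one 4x10 mitochondrion above one 3x10 ER sheet.

    The vertical gap between the facing contours (mito row 4, ER row 8)
    is 4 px = 4 nm.
    """
    labels = np.zeros((12, 12), dtype=np.uint8)
    labels[1:5, 1:11] = 1
    labels[8:11, 1:11] = 2
    return LabelMask(labels, unit_cal, image_id="rect")


def random_label_mask(seed: int, shape=(48, 48), p=(0.8, 0.1, 0.1)) -> LabelMask:
    """Random speckle mask — worst-case geometry for oracle comparisons."""
    rng = np.random.default_rng(seed)
    labels = rng.choice([0, 1, 2], size=shape, p=p).astype(np.uint8)
    return LabelMask(labels, Calibration(1.0), image_id=f"rand_{seed}")


def blob_label_mask(seed: int, shape=(64, 64)) -> LabelMask:
    """Random blobby mask: a few rectangles and bars of each class."""
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.uint8)
    h, w = shape
    for class_id in (1, 2, 1, 2, 1):
        rh = int(rng.integers(2, max(3, h // 4)))
        rw = int(rng.integers(2, max(3, w // 4)))
        r0 = int(rng.integers(0, h - rh))
        c0 = int(rng.integers(0, w - rw))
        labels[r0 : r0 + rh, c0 : c0 + rw] = class_id
    return LabelMask(labels, Calibration(1.0), image_id=f"blob_{seed}")
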