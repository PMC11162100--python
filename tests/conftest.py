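import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from uromorph.segmentation import CalibratedImage, segment
from uromorph.synthetic import PRESETS, calibrate_preset, render_field

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def group5_field():
    """A rendered high-grade field (60 nuclei) with its ground truth."""
    cfg = calibrate_preset(PRESETS["group5"], n_nuclei=60)
    rgb, gt = render_field(cfg, seed=11)
    return cfg, rgb, gt


@pytest.fixture(scope="session")
def group1_field():
    """A rendered low-grade field (60 nuclei) with its ground truth."""
    cfg = calibrate_preset(PRESETS["group1"], n_nuclei=60)
    rgb, gt = render_field(cfg, seed=11)
    return cfg, rgb, gt


@pytest.fixture(scope="session")
def group5_segmented(group5_field):
    cfg, rgb, gt = group5_field
    mask = segment(CalibratedImage(rgb, cfg.microns_per_pixel))
    return cfg, rgb, gt, mask


def match_labels(mask: np.ndarray, truth_mask: np.ndarray, iou_threshold: float = 0.5):
    """Greedy IoU matching between segmented and ground-truth labels.

    Returns a DataFrame with columns (truth_label, seg_label, iou) for
    matches above the threshold; unmatched truth labels are absent.
    """
    seg_ids = np.unique(mask)
    seg_ids = seg_ids[seg_ids > 0]
    truth_ids = np.unique(truth_mask)
    truth_ids = truth_ids[truth_ids > 0]
    if len(seg_ids) == 0 or len(truth_ids) == 0:
        return pd.DataFrame(columns=["truth_label", "seg_label", "iou"])
    # joint histogram of (truth, seg) label pairs
    pair = truth_mask.astype(np.int64) * (mask.max() + 1) + mask
    counts = np.bincount(pair.ravel())
    truth_sizes = np.bincount(truth_mask.ravel())
    seg_sizes = np.bincount(mask.ravel())
    rows = []
    stride = mask.max() + 1
    for t in truth_ids:
        base = t * stride
        inter_counts = counts[base : base + stride] if base + stride <= len(counts) else np.pad(
            counts[base:], (0, base + stride - len(counts))
        )
        if inter_counts[1:].sum() == 0:
            continue
        s = int(np.argmax(inter_counts[1:])) + 1
        inter = inter_counts[s]
        union = truth_sizes[t] + seg_sizes[s] - inter
        iou = inter / union
        if iou >= iou_threshold:
            rows.append({"truth_label": int(t), "seg_label": int(s), "iou": float(iou)})
    return pd.DataFrame(rows, columns=["truth_label", "seg_label", "iou"])
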