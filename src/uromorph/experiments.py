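"""Canned study-scale experiments: preset recovery and end-to-end grading.

These drive the full measurement chain — calibrate a grade-group preset,
render fields, segment, extract the 40 features, aggregate per image — at
the package's study scale (by default 300 nuclei per field at 0.5 µm/px)
and report the statistics the grading analysis is built on: the pooled
(grand) mean nuclear area, and the across-image means of the per-image
10th and 90th area percentiles.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aggregate import summarize_images
from .features import extract_features
from .grading import (
    agreement_rate,
    assign_groups,
    fit_linear_grader,
    select_features,
)
from .segmentation import CalibratedImage, SegmentationParams, segment
from .synthetic import (
    PRESETS,
    RaterNoiseModel,
    calibrate_preset,
    render_field,
    simulate_score_panel,
)

__all__ = [
    "grading_experiment",
    "measure_preset_fields",
    "recovery_statistics",
]


def measure_preset_fields(
    preset_name: str,
    seeds: Iterable[int],
    n_nuclei: int = 300,
    microns_per_pixel: float = 0.5,
    params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Render, segment and feature-extract one field per seed.

    Returns the concatenated per-nucleus feature table with one
    ``image_id`` per seed (``{preset}_{seed}``).
    """
    cfg = calibrate_preset(
        PRESETS[preset_name], n_nuclei=n_nuclei, microns_per_pixel=microns_per_pixel
    )
    tables = []
    for seed in seeds:
        rgb, _ = render_field(cfg, seed=seed)
        img = CalibratedImage(rgb, cfg.microns_per_pixel)
        mask = segment(img, params)
        tables.append(extract_features(img, mask, image_id=f"{preset_name}_{seed:05d}"))
    return pd.concat(tables, ignore_index=True)


def recovery_statistics(records: pd.DataFrame) -> dict[str, float]:
    """Grand mean area plus across-image means of per-image area p10/p90."""
    summaries = summarize_images(records, features=("area_um2",))
    return {
        "grand_mean_area_um2": float(records["area_um2"].mean()),
        "mean_p10_area_um2": float(summaries["area_um2_p10"].mean()),
        "mean_p90_area_um2": float(summaries["area_um2_p90"].mean()),
        "n_nuclei": int(len(records)),
        "n_images": int(summaries.shape[0]),
    }


def grading_experiment(
    group1_summaries: pd.DataFrame,
    group5_summaries: pd.DataFrame,
    seed: int = 0,
    alpha: float = 0.01,
    parameter: str = "area_um2_p10",
) -> dict:
    """Fit and evaluate the two-point grader on synthetic group-1/group-5
    fields with simulated concordant score panels.

    Latent grades are 1 for every group-1 image and 5 for every group-5
    image; the concordant five-rater panel reproduces them, so the grade
    groups are recovered exactly.  Returns the selection row for
    ``parameter``, the fitted anchors, and the grader-vs-latent agreement
    rate (agreement = |delta| < 2).
    """
    summaries = pd.concat([group1_summaries, group5_summaries])
    latent = [1] * len(group1_summaries) + [5] * len(group5_summaries)
    scores = simulate_score_panel(
        latent, RaterNoiseModel.concordant(), seed=seed,
        image_ids=list(summaries.index),
    )
    groups = assign_groups(scores)
    selection = select_features(summaries, groups, alpha=alpha)
    row = selection.loc[parameter]
    grader = fit_linear_grader(row["m1"], row["m5"], feature=parameter)
    predicted = pd.Series(
        grader.predict(summaries[parameter].to_numpy()), index=summaries.index
    )
    latent_series = pd.Series(latent, index=summaries.index, dtype=float)
    report = agreement_rate(predicted, latent_series)
    return {
        "selection": selection,
        "parameter": parameter,
        "p_value": float(row["p_value"]),
        "selected": bool(row["selected"]),
        "m1": float(row["m1"]),
        "m5": float(row["m5"]),
        "agreement_percent": report.rate_percent,
        "n_images": report.n,
    }
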