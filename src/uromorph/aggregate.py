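"""Per-image aggregation of nucleus records.

Grading operates on image-level summaries, not on single nuclei: for each
of the 40 features the summary holds the mean, sample SD, and the 10th and
90th percentiles over the nuclei of one image.  The percentile convention
is linear interpolation between order statistics at position ``(n - 1) * q``
(the numpy default); this is fixed and documented because the headline
grade predictor of this pipeline *is* a percentile.  NaN feature values
(the undefined sentinel) are excluded from that feature's aggregation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

__all__ = ["STATS", "summarize", "summarize_images", "summary_column"]

STATS = ("mean", "sd", "p10", "p90")


def summary_column(feature: str, stat: str) -> str:
    """Column name of one feature × statistic cell, e.g. ``area_um2_p10``."""
    if stat not in STATS:
        raise ValueError(f"unknown statistic {stat!r}")
    return f"{feature}_{stat}"


def _aggregate(values: np.ndarray) -> dict[str, float]:
    v = values[~np.isnan(values)]
    if v.size == 0:
        return {s: np.nan for s in STATS}
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
        "p10": float(np.percentile(v, 10)),
        "p90": float(np.percentile(v, 90)),
    }


def summarize(records: pd.DataFrame, features: tuple[str, ...] = FEATURE_NAMES) -> pd.Series:
    """Collapse one image's nucleus records into a feature × statistic row.

    ``records`` must carry a single ``image_id`` (or none).  An empty record
    list yields ``n_nuclei = 0`` with every aggregate NaN.
    """
    if "image_id" in records.columns and records["image_id"].nunique() > 1:
        raise ValueError("summarize expects records from a single image")
    out: dict[str, float] = {"n_nuclei": len(records)}
    for feat in features:
        vals = (
            records[feat].to_numpy(dtype=float)
            if feat in records.columns and len(records)
            else np.array([])
        )
        for stat, value in _aggregate(vals).items():
            out[summary_column(feat, stat)] = value
    name = records["image_id"].iloc[0] if ("image_id" in records.columns and len(records)) else None
    return pd.Series(out, name=name)


def summarize_images(
    records: pd.DataFrame, features: tuple[str, ...] = FEATURE_NAMES
) -> pd.DataFrame:
    """Per-image summary table (one row per ``image_id``)."""
    if "image_id" not in records.columns:
        raise ValueError("records need an image_id column")
    rows = {
        image_id: summarize(group, features)
        for image_id, group in records.groupby("image_id", sort=True)
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "image_id"
    df["n_nuclei"] = df["n_nuclei"].astype(int)
    return df
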