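"""Aggregation of vertex-level annotations to regions.

Fine units (surface vertices or voxels) carry a continuous hierarchy scalar
and a coarse class label; each maps to exactly one parent region.  Regions
inherit the mean of their member scalars and the mode of their member
labels (ties broken by the smallest label id, for determinism).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["aggregate_scalar", "aggregate_label"]

_REQUIRED = ("vertex_id", "region_id")


def _check(vertices: pd.DataFrame, column: str) -> None:
    for col in (*_REQUIRED, column):
        if col not in vertices.columns:
            raise ValueError(f"vertex table lacks required column '{column}'")
    if vertices["vertex_id"].duplicated().any():
        raise ValueError("each vertex must map to exactly one region")


def aggregate_scalar(vertices: pd.DataFrame, regions=None) -> pd.Series:
    """Per-region arithmetic mean of member vertex scalars.

    ``vertices`` needs columns ``vertex_id``, ``region_id``, ``scalar``;
    missing scalars are excluded from the mean.  If ``regions`` is given,
    the result is reindexed to it and empty regions are NaN.
    """
    _check(vertices, "scalar")
    out = vertices.groupby("region_id")["scalar"].mean()
    if regions is not None:
        out = out.reindex(regions)
    return out.rename("scalar")


def aggregate_label(vertices: pd.DataFrame, regions=None) -> pd.Series:
    """Per-region modal label; ties resolved to the smallest label id."""
    _check(vertices, "label")
    labelled = vertices.dropna(subset=["label"])

    def _mode(s: pd.Series):
        counts = s.value_counts()
        top = counts[counts == counts.max()]
        return np.min(top.index.values)

    out = labelled.groupby("region_id")["label"].agg(_mode)
    if regions is not None:
        out = out.reindex(regions)
    return out.rename("label")
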