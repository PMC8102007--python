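"""Spatial statistics of segmented pigment cells.

Nearest-neighbor distances, densities relative to the imaged flank area, and
pigment-area summaries (the 2-D area of contracted melanin granules serves as
a per-cell melanin-content proxy). Median nearest-neighbor distance is only
reported for individuals with ten or more cells of the class; when aggregating
across individuals, the convention is the median of per-individual medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .synthetic import MELANOPHORE, XANTHOPHORE

#: minimum cell count for a median NN distance to be defined
MIN_CELLS_FOR_NN = 10


def nn_distances(cells: pd.DataFrame, class_filter: str | None = None) -> np.ndarray:
    """Per-cell Euclidean distance to the nearest same-class neighbor.

    Returned in ascending cell-id order. With fewer than two cells of the
    class there is no neighbor and an empty array is returned.
    """
    sub = cells
    if class_filter is not None and "class" in cells:
        sub = cells[cells["class"] == class_filter]
    sub = sub.sort_values("id") if "id" in sub else sub
    pts = sub[["x", "y"]].to_numpy(dtype=float)
    if len(pts) < 2:
        return np.empty(0)
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1]


@dataclass
class CellSummary:
    melanophore_count: int
    melanophore_median_nn: float | None
    melanophore_density: float
    melanophore_median_area: float | None
    xanthophore_count: int
    xanthophore_median_nn: float | None
    xanthophore_density: float
    xanthophore_median_area: float | None


def _class_summary(cells: pd.DataFrame, cls: str, roi_area: float):
    sub = cells[cells["class"] == cls] if "class" in cells else cells
    count = len(sub)
    nn = nn_distances(sub)
    med_nn = float(np.median(nn)) if count >= MIN_CELLS_FOR_NN else None
    med_area = float(sub["area"].median()) if count else None
    return count, med_nn, count / roi_area, med_area


def summarize_cells(cells: pd.DataFrame, roi_area: float) -> CellSummary:
    """Counts, median NN distances, densities, and median pigment areas per class."""
    if roi_area <= 0:
        raise ValueError("roi_area must be positive")
    m = _class_summary(cells, MELANOPHORE, roi_area)
    x = _class_summary(cells, XANTHOPHORE, roi_area)
    return CellSummary(*m, *x)
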