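"""Pattern-element masks and morphospace statistics.

The pattern morphospace places each individual by the variation of its
binarized melanized pattern along the two body axes: DV variation is the
standard deviation of the row-wise mean grey profile (each row is one
anteroposterior transect), AP variation the reciprocal column-wise quantity,
and the morphospace diagonal coordinate is log2(DV:AP variation). Stripes sit
high on the ratio, vertical bars low, spots and uniform fields near zero.
Element-level metrics (count, total perimeter, total area, coverage) describe
entire spots or stripes rather than single cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import disk

from .synthetic import MELANOPHORE

_EIGHT = np.ones((3, 3), dtype=int)


def build_element_mask(cells: pd.DataFrame, shape: tuple, radius: int = 20,
                       mode: str = "dilate", blur_sigma: float = 5.0,
                       blur_threshold: float = 128.0) -> np.ndarray:
    """Melanized-element mask: all pixels within ``radius`` px of a melanophore.

    The default 20 px radius approximates the average nearest-neighbor
    distance between melanophores, so overlapping disks fuse the cells of one
    stripe or spot into one element. ``expand_blur`` additionally blurs the
    dilated mask (Gaussian, ``blur_sigma``) and rethresholds at 50% intensity
    to fill residual gaps, approximating natural (uncontracted) cell edges.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if mode not in ("dilate", "expand_blur"):
        raise ValueError(f"unknown mode {mode!r}")
    H, W = shape
    seeds = np.zeros((H, W), dtype=bool)
    mel = cells[cells["class"] == MELANOPHORE] if "class" in cells else cells
    for x, y in zip(mel["x"], mel["y"]):
        r, c = int(round(y)), int(round(x))
        if 0 <= r < H and 0 <= c < W:
            seeds[r, c] = True
    out = ndi.binary_dilation(seeds, structure=disk(radius))
    if mode == "expand_blur":
        blurred = ndi.gaussian_filter(out.astype(np.float64) * 255.0, blur_sigma)
        out = blurred >= blur_threshold
    return out.astype(np.uint8) * 255


def binarize_by_fraction(img: np.ndarray, target_fraction: float) -> np.ndarray:
    """Global dark-object threshold chosen to hit a target foreground fraction.

    Scans all 256 thresholds and picks the one whose foreground (pixels <=
    threshold) fraction is nearest the target, ties going to the lower
    threshold. Used for images that cannot be segmented cell-wise and must be
    matched to the coverage of properly segmented individuals. A constant image
    yields an all-background mask with a warning.
    """
    if not (0.0 < target_fraction < 1.0):
        raise ValueError("target_fraction must be in (0, 1)")
    img = np.asarray(img)
    if img.min() == img.max():
        warnings.warn("constant image: returning all-background mask")
        return np.zeros(img.shape, dtype=np.uint8)
    counts = np.bincount(img.ravel().astype(np.int64), minlength=256)
    frac = np.cumsum(counts) / img.size  # frac[t] = fraction of pixels <= t
    best = int(np.argmin(np.abs(frac - target_fraction)))  # argmin takes lowest tie
    return (img <= best).astype(np.uint8) * 255


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 255))):
        raise ValueError("mask must be two-valued on the 0/255 scale")
    return mask


def axis_variation(mask: np.ndarray, ddof: int = 1) -> tuple[float, float]:
    """(DV, AP) variation of a binary pattern mask.

    DV variation: standard deviation over rows of the row-mean grey profile;
    AP variation: the same over columns. Sample (n-1) standard deviation by
    default; pass ``ddof=0`` for the population convention.
    """
    mask = _check_mask(mask)
    if mask.shape[0] < 2 or mask.shape[1] < 2:
        raise ValueError("mask must have at least 2 rows and 2 columns")
    row_profile = mask.mean(axis=1, dtype=np.float64)
    col_profile = mask.mean(axis=0, dtype=np.float64)
    return float(row_profile.std(ddof=ddof)), float(col_profile.std(ddof=ddof))


def log2_ratio(dv: float, ap: float, floor: float = 0.5) -> float:
    """log2(DV:AP variation) with both terms floored to avoid degenerate ratios."""
    return float(np.log2(max(dv, floor) / max(ap, floor)))


@dataclass
class ElementStats:
    count: int
    total_perimeter: int
    total_area: int
    coverage: float


def element_stats(mask: np.ndarray) -> ElementStats:
    """Count, total perimeter, total area and coverage of melanized elements.

    Components are 8-connected; perimeter counts 4-adjacent foreground/
    background pixel edges (image borders count as background), so a solid
    n x m rectangle has perimeter 2(n+m).
    """
    mask = _check_mask(mask)
    fg = mask > 0
    _, count = ndi.label(fg, structure=_EIGHT)
    area = int(fg.sum())
    padded = np.pad(fg, 1)
    perim = 0
    for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        perim += int(np.sum(padded & ~np.roll(padded, shift, axis=ax)))
    return ElementStats(count, perim, area, area / fg.size)


def phenotype_pca(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of a phenotype table on the correlation matrix.

    Columns are standardized to zero mean and unit variance (constant columns
    are dropped with a warning); the eigendecomposition of the correlation
    matrix gives loadings and the per-component share of total variance, which
    sums to 1. Signs are fixed so each component's largest-magnitude loading
    is positive.
    """
    num = table.select_dtypes(include=[np.number])
    keep = []
    for c in num.columns:
        if np.nanstd(num[c].to_numpy(dtype=float)) == 0:
            warnings.warn(f"dropping constant column {c!r}")
        else:
            keep.append(c)
    if len(keep) < 2:
        raise ValueError("need at least 2 non-constant numeric columns")
    X = num[keep].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    corr = (X.T @ X) / (len(X) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    loadings = pd.DataFrame(
        eigvec, index=keep,
        columns=[f"PC{j + 1}" for j in range(eigvec.shape[1])],
    )
    return loadings, eigval / eigval.sum()


def pattern_stats(mask: np.ndarray, ddof: int = 1, floor: float = 0.5) -> dict:
    """All morphospace and element metrics of one binarized pattern, as a dict."""
    dv, ap = axis_variation(mask, ddof=ddof)
    es = element_stats(mask)
    return {
        "dv_variation": dv,
        "ap_variation": ap,
        "log2_dv_ap": log2_ratio(dv, ap, floor=floor),
        "element_count": es.count,
        "element_total_perimeter": es.total_perimeter,
        "element_total_area": es.total_area,
        "coverage": es.coverage,
    }
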