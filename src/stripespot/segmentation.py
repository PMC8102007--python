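"""Pigment cell segmentation from RGB flank images.

The operator chain follows the published protocol for epinephrine-treated
fish: remove bright glare outliers within a 25 px radius, isolate the red
channel, threshold locally with the Sauvola method (radius 25, k = 0.34),
label connected components, and retain components in a class-specific size
band (100–1500 px for melanophores; 10–200 px for xanthophores after
red-minus-blue channel arithmetic). Manual corrections are consumed as
add/remove lists, added cells being circles of diameter 15 px.

Sauvola thresholding is computed here with integral images over a square
window of side 2*radius+1 and replicate padding, so the result is exactly the
windowed mean/standard-deviation formula — a convention a brute-force oracle
can reproduce pixel for pixel.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import rank
from skimage.morphology import disk

from .synthetic import CELL_COLUMNS, MELANOPHORE, XANTHOPHORE

#: default local-window radius (px) for outlier removal and Sauvola
DEFAULT_RADIUS = 25
#: default Sauvola sensitivity
DEFAULT_K = 0.34
#: dynamic range of the standard deviation for 8-bit images
DEFAULT_R = 128.0
#: retained component area bands, px
MELANOPHORE_BAND = (100, 1500)
XANTHOPHORE_BAND = (10, 200)

_EIGHT = np.ones((3, 3), dtype=int)


def remove_bright_outliers(img: np.ndarray, radius: int = DEFAULT_RADIUS,
                           t: float = 50.0) -> np.ndarray:
    """Replace pixels brighter than their local median by more than ``t``.

    The local median is taken over a circular window of the given radius
    (the bright-outlier-removal operator of ImageJ). Pixels at most ``t`` grey
    units above their local median are left untouched, so the operator is
    idempotent on outlier-free images.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    med = rank.median(img.astype(np.uint8), footprint=disk(radius))
    out = img.copy()
    hot = img.astype(np.int32) > med.astype(np.int32) + t
    out[hot] = med[hot]
    return out


def _window_mean_std(img: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Local mean and standard deviation over a (2r+1)^2 window, replicate-padded."""
    f = np.pad(np.asarray(img, dtype=np.float64), radius, mode="edge")
    one = np.ones_like(f)

    def winsum(a):
        s = np.cumsum(np.cumsum(a, axis=0), axis=1)
        s = np.pad(s, ((1, 0), (1, 0)))
        w = 2 * radius + 1
        return (s[w:, w:] - s[:-w, w:] - s[w:, :-w] + s[:-w, :-w])

    n = winsum(one)
    m = winsum(f) / n
    var = winsum(f * f) / n - m * m
    s = np.sqrt(np.clip(var, 0.0, None))
    return m, s


def sauvola_threshold(img: np.ndarray, radius: int = DEFAULT_RADIUS,
                      k: float = DEFAULT_K, r_dynamic: float = DEFAULT_R) -> np.ndarray:
    """Sauvola local threshold, dark-object convention.

    Foreground (255) where pixel value < T(x,y) = m*(1 + k*(s/R - 1)) with m, s
    the local window mean and standard deviation. On a constant image s = 0 so
    T = m*(1-k) < m everywhere and the mask is empty.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if not (0.0 < k < 1.0):
        raise ValueError("k must be in (0, 1)")
    m, s = _window_mean_std(img, radius)
    thresh = m * (1.0 + k * (s / r_dynamic - 1.0))
    return (np.asarray(img, dtype=np.float64) < thresh).astype(np.uint8) * 255


def _components_to_cells(mask: np.ndarray, band: tuple, cls: str,
                         frame: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """8-connected components of a mask, filtered to an area band."""
    labels, n = ndi.label(mask > 0, structure=_EIGHT)
    recs = []
    keep = np.zeros(mask.shape, dtype=bool)
    if n:
        areas = ndi.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        coms = ndi.center_of_mass(mask > 0, labels, np.arange(1, n + 1))
        cid = 0
        for lab, (area, com) in enumerate(zip(areas, coms), start=1):
            if band[0] <= area <= band[1]:
                keep |= labels == lab
                recs.append((cid, frame, com[1], com[0], float(area), cls))
                cid += 1
    cells = pd.DataFrame(recs, columns=CELL_COLUMNS)
    return cells, keep.astype(np.uint8) * 255


def segment_melanophores(img: np.ndarray, radius: int = DEFAULT_RADIUS,
                         k: float = DEFAULT_K, r_dynamic: float = DEFAULT_R,
                         outlier_radius: int = DEFAULT_RADIUS,
                         outlier_t: float = 50.0,
                         band: tuple = MELANOPHORE_BAND,
                         frame: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Detect melanophores: red channel -> outlier removal -> Sauvola -> size band.

    Returns a cell table (id, frame, x, y, area, class) with centroids as
    unweighted means of component pixel coordinates (x = column, y = row,
    0-based pixel centers), and the binary mask of retained components.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    red = remove_bright_outliers(img[:, :, 0], radius=outlier_radius, t=outlier_t)
    mask = sauvola_threshold(red, radius=radius, k=k, r_dynamic=r_dynamic)
    return _components_to_cells(mask, band, MELANOPHORE, frame)


def segment_xanthophores(img: np.ndarray, radius: int = DEFAULT_RADIUS,
                         k: float = DEFAULT_K, r_dynamic: float = DEFAULT_R,
                         band: tuple = XANTHOPHORE_BAND,
                         frame: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Detect xanthophores via red/blue channel arithmetic.

    Yellow/orange cells have high red and low blue, so the clipped difference
    red - blue is bright on xanthophores; inverting it makes them dark objects
    for the same Sauvola detector used for melanophores. Components of 10–200
    px are retained.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    diff = np.clip(img[:, :, 0].astype(np.int32) - img[:, :, 2].astype(np.int32),
                   0, 255).astype(np.uint8)
    inverted = (255 - diff).astype(np.uint8)
    mask = sauvola_threshold(inverted, radius=radius, k=k, r_dynamic=r_dynamic)
    return _components_to_cells(mask, band, XANTHOPHORE, frame)


def apply_corrections(cells: pd.DataFrame, additions=(), removals=(),
                      circle_diameter: float = 15.0) -> pd.DataFrame:
    """Apply manual corrections: drop removed ids, add circles of fixed diameter.

    Each added (x, y) becomes a cell of area round(pi*(d/2)^2) px — 177 px for
    the default 15 px diameter — mirroring the circle-replacement convention
    used to correct improperly segmented cells.
    """
    out = cells.copy()
    removals = list(removals)
    if removals:
        known = set(out["id"])
        unknown = [r for r in removals if r not in known]
        if unknown:
            raise KeyError(f"cannot remove unknown cell ids: {unknown}")
        out = out[~out["id"].isin(removals)]
    if len(additions):
        next_id = int(out["id"].max()) + 1 if len(out) else 0
        area = float(round(math.pi * (circle_diameter / 2.0) ** 2))
        frame = int(out["frame"].iloc[0]) if len(out) else 0
        cls = out["class"].iloc[0] if len(out) else MELANOPHORE
        add = pd.DataFrame(
            [(next_id + i, frame, x, y, area, cls)
             for i, (x, y) in enumerate(additions)],
            columns=CELL_COLUMNS,
        )
        out = pd.concat([out, add], ignore_index=True)
    return out.reset_index(drop=True)
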