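"""Ground-truthed synthetic data: pattern images, developmental series, backcross families.

Every downstream stage of the pipeline (segmentation, pattern metrics, tracking,
QTL/F_ST mapping) is exercised against output of this module, which records the
truth it plants: cell centroids and areas, melanized-element masks, per-day
displacement vectors, and the genetic model behind each simulated backcross.

Images emulate epinephrine-treated flank regions of interest: dark melanophore
disks tiling the dark pattern elements (stripes, bars, spots, or a uniform
field), orange xanthophore disks tiling the light regions, a pinkish skin
background, and near-white glare disks mimicking iridophore reflections.
Backcross families are simulated with independent meioses per transmitting
parent under the Haldane (no-interference) mapping function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

MELANOPHORE = "melanophore"
XANTHOPHORE = "xanthophore"

CELL_COLUMNS = ["id", "frame", "x", "y", "area", "class"]

_LAYOUTS = ("horizontal_stripes", "vertical_bars", "spots", "uniform", "blank")


@dataclass
class PatternSpec:
    """Parameters of one synthetic flank ROI.

    Distances are in pixels. ``element_width`` is the stripe/bar width or spot
    diameter; ``cell_spacing`` is the lattice spacing of planted cells, chosen
    by default near the ~20 px nearest-neighbor distance typical of contracted
    melanophores; ``cell_radius`` defaults so cell areas sit near the
    15-px-diameter circle convention used when correcting segmentations.
    """

    layout: str = "horizontal_stripes"
    image_height: int = 512
    image_width: int = 512
    n_elements: int = 3
    element_width: int = 64
    cell_radius: float = 7.0
    cell_spacing: float = 24.0
    xanthophore_radius: float = 4.0
    melanophore_color: tuple = (35, 30, 30)
    xanthophore_color: tuple = (240, 160, 60)
    background_color: tuple = (190, 160, 155)
    glare_density: float = 0.0
    jitter_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.layout not in _LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}; expected one of {_LAYOUTS}")
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if not (0.0 <= self.glare_density < 0.1):
            raise ValueError("glare_density must be in [0, 0.1)")
        for name in ("melanophore_color", "xanthophore_color", "background_color"):
            c = getattr(self, name)
            if len(c) != 3 or any(not (0 <= v <= 255) for v in c):
                raise ValueError(f"{name} must be an RGB triple in 0..255")
        if self.cell_radius <= 0 or self.cell_spacing <= 0:
            raise ValueError("cell_radius and cell_spacing must be positive")


@dataclass
class GroundTruth:
    """Truth planted into a synthetic image or series frame."""

    cells: pd.DataFrame
    element_mask: np.ndarray  # uint8 {0, 255}, the true melanized elements
    glare_mask: np.ndarray  # bool, pixels painted as glare
    element_labels: np.ndarray | None = None  # int label image of elements
    displacements: pd.DataFrame | None = None  # (id, day, dx, dy) into this frame


# ---------------------------------------------------------------------------
# pattern images
# ---------------------------------------------------------------------------


def _layout_mask(spec: PatternSpec) -> tuple[np.ndarray, np.ndarray]:
    """Boolean mask of true dark elements plus an integer element-label image."""
    H, W = spec.image_height, spec.image_width
    mask = np.zeros((H, W), dtype=bool)
    labels = np.zeros((H, W), dtype=np.int32)
    n, w = spec.n_elements, spec.element_width
    if spec.layout == "blank":
        return mask, labels
    if spec.layout == "uniform":
        mask[:] = True
        labels[:] = 1
        return mask, labels
    if spec.layout in ("horizontal_stripes", "vertical_bars"):
        extent = H if spec.layout == "horizontal_stripes" else W
        if n * w > extent:
            raise ValueError(
                f"{n} elements of width {w} px do not fit in {extent} px"
            )
        centers = (np.arange(n) + 0.5) * extent / n
        for i, c in enumerate(centers, start=1):
            lo = int(round(c - w / 2))
            hi = int(round(c + w / 2))
            if spec.layout == "horizontal_stripes":
                mask[lo:hi, :] = True
                labels[lo:hi, :] = i
            else:
                mask[:, lo:hi] = True
                labels[:, lo:hi] = i
        return mask, labels
    # spots: a grid of disks of diameter `element_width`
    n_cols = max(1, int(math.ceil(math.sqrt(n * W / H))))
    n_rows = int(math.ceil(n / n_cols))
    dx, dy = W / n_cols, H / n_rows
    if w > min(dx, dy):
        raise ValueError(
            f"spot diameter {w} exceeds grid pitch {min(dx, dy):.1f}; spots would merge"
        )
    yy, xx = np.mgrid[0:H, 0:W]
    k = 0
    for r in range(n_rows):
        for c in range(n_cols):
            if k >= n:
                break
            cx, cy = (c + 0.5) * dx, (r + 0.5) * dy
            d2 = (xx - cx) ** 2 + (yy - cy) ** 2
            inside = d2 <= (w / 2) ** 2
            mask |= inside
            labels[inside] = k + 1
            k += 1
    return mask, labels


def _place_in_mask(mask, spacing, jitter_sd, rng, margin=0.0):
    """Lattice positions inside a boolean mask with Gaussian jitter.

    Jitter is resampled (up to 10 draws) if it would move a point outside the
    mask, so every returned centroid is guaranteed to lie on a True pixel.
    """
    H, W = mask.shape
    pts = []
    ys = np.arange(spacing / 2, H, spacing)
    xs = np.arange(spacing / 2, W, spacing)
    for y0 in ys:
        for x0 in xs:
            if not mask[int(y0), int(x0)]:
                continue
            x, y = x0, y0
            if jitter_sd > 0:
                for _ in range(10):
                    jx, jy = rng.normal(0.0, jitter_sd, size=2)
                    xi = min(max(x0 + jx, margin), W - 1 - margin)
                    yi = min(max(y0 + jy, margin), H - 1 - margin)
                    if mask[int(yi), int(xi)]:
                        x, y = xi, yi
                        break
            pts.append((x, y))
    return pts


def _draw_disk(img, cx, cy, r, color):
    """Paint a filled disk; returns the number of pixels painted."""
    H, W = img.shape[:2]
    x0, x1 = max(0, int(math.floor(cx - r))), min(W - 1, int(math.ceil(cx + r)))
    y0, y1 = max(0, int(math.floor(cy - r))), min(H - 1, int(math.ceil(cy + r)))
    if x1 < x0 or y1 < y0:
        return 0
    yy, xx = np.ogrid[y0 : y1 + 1, x0 : x1 + 1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    img[y0 : y1 + 1, x0 : x1 + 1][inside] = color
    return int(inside.sum())


def _sprinkle_glare(img, glare_mask, density, rng):
    H, W = img.shape[:2]
    target = int(round(density * H * W))
    guard = 0
    while glare_mask.sum() < target and guard < 100000:
        guard += 1
        cx, cy = rng.uniform(0, W), rng.uniform(0, H)
        r = rng.integers(1, 4)  # disks of radius 1..3 px
        val = int(rng.integers(245, 256))
        tmp = np.zeros((H, W), dtype=bool)
        _draw_disk(tmp[..., None], cx, cy, r, True)
        img[tmp] = (val, val, val)
        glare_mask |= tmp


def _render_cells(img, cells, radii, color):
    areas = np.empty(len(cells), dtype=float)
    for i, ((x, y), r) in enumerate(zip(cells, radii)):
        areas[i] = _draw_disk(img, x, y, r, color)
    return areas


def gen_pattern_image(spec: PatternSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one ROI image and the ground truth planted into it.

    Melanophores tile the layout's dark elements on a jittered lattice of pitch
    ``cell_spacing``; xanthophores tile the light regions; glare disks (near
    white) are sprinkled at ``glare_density``. Identical specs (same seed)
    produce bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_height, spec.image_width
    mask, labels = _layout_mask(spec)
    img = np.empty((H, W, 3), dtype=np.uint8)
    img[:] = spec.background_color

    records = []
    # xanthophores first so melanophores overdraw at element borders
    light = ~ndi.binary_dilation(
        mask, iterations=max(1, int(spec.cell_radius + spec.xanthophore_radius))
    )
    if spec.layout != "blank":
        xpts = _place_in_mask(light, spec.cell_spacing, spec.jitter_sd, rng,
                              margin=spec.xanthophore_radius)
        xradii = np.maximum(1.5, rng.normal(spec.xanthophore_radius,
                                            0.1 * spec.xanthophore_radius, len(xpts)))
        xareas = _render_cells(img, xpts, xradii, spec.xanthophore_color)
        for (x, y), a in zip(xpts, xareas):
            records.append((len(records), 0, x, y, a, XANTHOPHORE))

    if spec.layout == "uniform":
        # a patternless fish carries the cell complement its elements would
        # hold, spread evenly over the whole flank: widen the lattice so the
        # total number of cells matches the striped equivalent
        scale = math.sqrt(H / max(1, spec.n_elements * spec.element_width))
        spacing = spec.cell_spacing * max(1.0, scale)
    else:
        spacing = spec.cell_spacing
    mpts = _place_in_mask(mask, spacing, spec.jitter_sd, rng,
                          margin=spec.cell_radius)
    mradii = np.maximum(2.0, rng.normal(spec.cell_radius, 0.1 * spec.cell_radius,
                                        len(mpts)))
    mareas = _render_cells(img, mpts, mradii, spec.melanophore_color)
    for (x, y), a in zip(mpts, mareas):
        records.append((len(records), 0, x, y, a, MELANOPHORE))

    glare = np.zeros((H, W), dtype=bool)
    if spec.glare_density > 0:
        _sprinkle_glare(img, glare, spec.glare_density, rng)

    cells = pd.DataFrame(records, columns=CELL_COLUMNS)
    truth = GroundTruth(
        cells=cells,
        element_mask=(mask.astype(np.uint8) * 255),
        glare_mask=glare,
        element_labels=labels,
    )
    return img, truth


# ---------------------------------------------------------------------------
# developmental image series
# ---------------------------------------------------------------------------


def gen_development_series(
    spec: PatternSpec,
    n_days: int,
    appearance_rate: float = 0.0,
    drift: float = 0.0,
    motion_mode: str = "stripe_hold",
    loss_rate: float = 0.0,
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Daily image series with persistent cell identities and known motion.

    New melanophores appear unpaired (de novo differentiation) inside the dark
    elements at ``appearance_rate`` cells/day; ``loss_rate`` cells/day are lost.
    In ``spot_consolidate`` mode each cell drifts toward a target point near its
    element's centroid at up to ``drift`` px/day; in ``stripe_hold`` mode cells
    jiggle with step length ``0.1 * drift`` so the pattern holds. True per-day
    displacement vectors are recorded on each frame's ground truth.
    """
    if n_days < 2:
        raise ValueError("n_days must be >= 2")
    if drift < 0:
        raise ValueError("drift must be non-negative")
    if motion_mode not in ("stripe_hold", "spot_consolidate"):
        raise ValueError(f"unknown motion_mode {motion_mode!r}")

    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_height, spec.image_width
    mask, labels = _layout_mask(spec)
    n_lab = int(labels.max())
    centers = np.zeros((n_lab + 1, 2))
    if n_lab:
        coms = ndi.center_of_mass(mask, labels, index=np.arange(1, n_lab + 1))
        centers[1:] = [(c[1], c[0]) for c in coms]  # (x, y)

    margin = spec.cell_radius

    def new_target(lab, x, y):
        if motion_mode != "spot_consolidate" or lab == 0:
            return (x, y)
        # spread of consolidation targets within an element: wide enough that
        # settled cells pack densely (NN distances ~10 px, as in spotted adults)
        # while remaining individually resolvable
        off = rng.normal(0.0, spec.element_width * 0.2, size=2)
        return (centers[lab][0] + off[0], centers[lab][1] + off[1])

    pts = _place_in_mask(mask, spec.cell_spacing, spec.jitter_sd, rng, margin=margin)
    state = {}  # id -> dict(x, y, r, target)
    next_id = 0
    for x, y in pts:
        lab = labels[int(y), int(x)]
        state[next_id] = {
            "x": x, "y": y,
            "r": max(2.0, rng.normal(spec.cell_radius, 0.1 * spec.cell_radius)),
            "target": new_target(lab, x, y),
        }
        next_id += 1

    frames = []

    def emit(day, disp_rows):
        img = np.empty((H, W, 3), dtype=np.uint8)
        img[:] = spec.background_color
        recs = []
        for cid in sorted(state):
            c = state[cid]
            a = _draw_disk(img, c["x"], c["y"], c["r"], spec.melanophore_color)
            recs.append((cid, day, c["x"], c["y"], float(a), MELANOPHORE))
        glare = np.zeros((H, W), dtype=bool)
        if spec.glare_density > 0:
            _sprinkle_glare(img, glare, spec.glare_density, rng)
        cells = pd.DataFrame(recs, columns=CELL_COLUMNS)
        disp = pd.DataFrame(disp_rows, columns=["id", "day", "dx", "dy"])
        frames.append((img, GroundTruth(cells, (mask.astype(np.uint8) * 255),
                                        glare, labels, disp)))

    # cells are physical disks: they cannot overlap, so consolidating cells
    # jam around their targets at about one cell diameter spacing, as densely
    # packed melanophores do within spots
    min_sep = 2.0 * spec.cell_radius

    emit(0, [])
    for day in range(1, n_days):
        disp_rows = []
        # motion
        for cid in sorted(state):
            c = state[cid]
            if motion_mode == "spot_consolidate":
                tx, ty = c["target"]
                vx, vy = tx - c["x"], ty - c["y"]
                dist = math.hypot(vx, vy)
                step = min(drift, dist)
                if dist > 0.1 * drift and step > 0:
                    dx, dy = vx / dist * step, vy / dist * step
                else:
                    # arrived: residual jiggle, as settled cells still wobble
                    theta = rng.uniform(0, 2 * math.pi)
                    dx = 0.1 * drift * math.cos(theta)
                    dy = 0.1 * drift * math.sin(theta)
            else:
                step = 0.1 * drift
                theta = rng.uniform(0, 2 * math.pi)
                dx, dy = step * math.cos(theta), step * math.sin(theta)
            others = np.array(
                [[o["x"], o["y"]] for k, o in state.items() if k != cid]
            ) if len(state) > 1 else np.empty((0, 2))
            # try the full step, then shorter steps, then a small jiggle
            # (jammed cells wobble in place rather than freeze), else stay
            candidates = [(dx, dy), (dx / 2, dy / 2), (dx / 4, dy / 4)]
            for _ in range(3):
                theta = rng.uniform(0, 2 * math.pi)
                candidates.append((0.1 * drift * math.cos(theta),
                                   0.1 * drift * math.sin(theta)))
            candidates.append((0.0, 0.0))
            nx, ny = c["x"], c["y"]
            for cdx, cdy in candidates:
                px = min(max(c["x"] + cdx, margin), W - 1 - margin)
                py = min(max(c["y"] + cdy, margin), H - 1 - margin)
                if (cdx, cdy) == (0.0, 0.0) or len(others) == 0 or np.min(
                    np.hypot(others[:, 0] - px, others[:, 1] - py)
                ) >= min_sep:
                    nx, ny = px, py
                    break
            disp_rows.append((cid, day, nx - c["x"], ny - c["y"]))
            c["x"], c["y"] = nx, ny
        # loss
        n_lost = rng.poisson(loss_rate)
        for _ in range(min(n_lost, len(state))):
            gone = sorted(state)[rng.integers(len(state))]
            del state[gone]
        # de novo appearance, unpaired with existing cells
        n_new = rng.poisson(appearance_rate)
        occupied = np.array([[c["x"], c["y"]] for c in state.values()]) \
            if state else np.empty((0, 2))
        for _ in range(n_new):
            for _try in range(50):
                x = rng.uniform(margin, W - 1 - margin)
                y = rng.uniform(margin, H - 1 - margin)
                if not mask[int(y), int(x)]:
                    continue
                if len(occupied) and np.min(
                    np.hypot(occupied[:, 0] - x, occupied[:, 1] - y)
                ) < 2.5 * spec.cell_radius:
                    continue
                lab = labels[int(y), int(x)]
                state[next_id] = {
                    "x": x, "y": y,
                    "r": max(2.0, rng.normal(spec.cell_radius,
                                             0.1 * spec.cell_radius)),
                    "target": new_target(lab, x, y),
                }
                occupied = np.vstack([occupied, [x, y]])
                next_id += 1
                break
        emit(day, disp_rows)
    return frames


# ---------------------------------------------------------------------------
# stripe -> spot-chain mask pairs (the ontogenetic signature)
# ---------------------------------------------------------------------------


def gen_stripe_and_spot_chain_masks(
    height: int = 256,
    width: int = 256,
    n_stripes: int = 3,
    stripe_height: int = 24,
    n_spots_per_stripe: int = 8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A stripe mask and its exact equal-area split into chains of aligned spots.

    Each full-width stripe of height h is replaced by ``n_spots_per_stripe``
    rectangles of height 2h at 50% duty cycle along the stripe — the same total
    melanized area redistributed into more, shorter elements, mimicking the
    ontogenetic break-up of stripes into spots. ``width`` must be divisible by
    2 * ``n_spots_per_stripe`` so areas match exactly. Seed jitters stripe
    placement and chain phase so repeated draws differ. Returns uint8 {0,255}
    masks.
    """
    if width % (2 * n_spots_per_stripe) != 0:
        raise ValueError("width must be divisible by 2 * n_spots_per_stripe")
    rng = np.random.default_rng(seed)
    stripes = np.zeros((height, width), dtype=bool)
    chains = np.zeros((height, width), dtype=bool)
    pitch = height / n_stripes
    seg = width // n_spots_per_stripe
    on = seg // 2
    for i in range(n_stripes):
        c = (i + 0.5) * pitch + rng.uniform(-0.1, 0.1) * pitch
        lo = int(round(c - stripe_height / 2))
        hi = lo + stripe_height
        if lo < 0 or hi > height or stripe_height * 2 > pitch - 4:
            raise ValueError("stripes too tall for the image; reduce stripe_height")
        stripes[lo:hi, :] = True
        h2 = 2 * stripe_height
        lo2 = max(0, min(height - h2, (lo + hi) // 2 - stripe_height))
        phase = int(rng.integers(0, on))
        for j in range(n_spots_per_stripe):
            cols = (np.arange(on) + j * seg + phase) % width
            chains[lo2 : lo2 + h2, cols] = True
    return stripes.astype(np.uint8) * 255, chains.astype(np.uint8) * 255


# ---------------------------------------------------------------------------
# backcross families
# ---------------------------------------------------------------------------

HYBRID = "hybrid"  # transmission from the F1 hybrid parent (interspecific)
PURE = "pure"  # transmission from the pure D. kyathit parent (intraspecific)


def make_marker_map(
    n_chromosomes: int = 25,
    markers_per_chromosome: int = 10,
    spacing_cm: float = 10.0,
) -> pd.DataFrame:
    """Evenly spaced marker map: columns (marker, chrom, pos) with pos in cM."""
    rows = []
    for c in range(1, n_chromosomes + 1):
        for j in range(markers_per_chromosome):
            rows.append((f"chr{c}_m{j}", c, j * spacing_cm))
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos"])


def haldane_r(d_cm) -> float:
    """Recombination fraction for a map distance in cM (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


@dataclass
class QTLLocus:
    marker: str
    origin: str = HYBRID  # which transmission carries the variant
    effect: float = 1.0  # added to the phenotype when the coded allele (1) is present


@dataclass
class EpistaticInteraction:
    """Extra effect applied only to one two-locus genotype combination."""

    marker_a: str
    marker_b: str
    genotypes: tuple = (1, 1)
    effect: float = 0.0
    origin_a: str = HYBRID
    origin_b: str = PURE


@dataclass
class QTLModel:
    mean: float = 0.0
    residual_sd: float = 1.0
    loci: list = field(default_factory=list)
    epistatic_pairs: list = field(default_factory=list)

    def __post_init__(self):
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


@dataclass
class BackcrossFamily:
    """Marker map, phased genotypes per transmitting parent, phenotypes.

    Genotypes are coded 0/1 (hybrid parent: 0 = kyathit allele, 1 = quagga
    allele; pure parent: 0/1 = which of the parent's two kyathit haplotypes),
    with -1 for missing. Phenotype rows align with genotype rows.
    """

    markers: pd.DataFrame
    genotypes: dict  # origin -> int8 array (n_individuals, n_markers)
    phenotypes: pd.DataFrame
    pedigree: str = "BC"

    @property
    def n_individuals(self) -> int:
        return len(self.phenotypes)

    def marker_index(self, marker: str) -> int:
        idx = self.markers.index[self.markers["marker"] == marker]
        if len(idx) == 0:
            raise KeyError(f"marker {marker!r} not on the map")
        return int(idx[0])

    def genotype_at(self, marker: str, origin: str = HYBRID) -> np.ndarray:
        return self.genotypes[origin][:, self.marker_index(marker)]


def _simulate_gametes(markers: pd.DataFrame, n: int, rng) -> np.ndarray:
    """n gametes over the map, one Markov chain per chromosome (Haldane)."""
    m = len(markers)
    out = np.empty((n, m), dtype=np.int8)
    for _, idx in markers.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        pos = markers.loc[idx, "pos"].to_numpy(dtype=float)
        if np.any(np.diff(pos) < 0):
            raise ValueError("marker map must be ordered within chromosomes")
        col = rng.integers(0, 2, size=n, dtype=np.int8)
        out[:, idx[0]] = col
        r = haldane_r(np.diff(pos))
        for j in range(1, len(idx)):
            switch = rng.random(n) < r[j - 1]
            col = np.where(switch, 1 - col, col).astype(np.int8)
            out[:, idx[j]] = col
    return out


def gen_backcross(
    n_individuals: int,
    marker_map: pd.DataFrame,
    qtl: QTLModel,
    seed: int = 0,
    phenotype_name: str = "trait",
    missing_rate: float = 0.0,
    pedigree: str = "BC",
) -> BackcrossFamily:
    """Simulate a backcross family segregating the given QTL model.

    Both transmissions (the F1 hybrid parent's recombinant gamete and the pure
    kyathit parent's gamete over its two haplotypes) are simulated
    independently; phenotype = mean + sum of additive effects + epistatic terms
    + Gaussian noise with sd ``residual_sd``.
    """
    rng = np.random.default_rng(seed)
    geno = {
        HYBRID: _simulate_gametes(marker_map, n_individuals, rng),
        PURE: _simulate_gametes(marker_map, n_individuals, rng),
    }
    marker_ids = set(marker_map["marker"])
    y = np.full(n_individuals, float(qtl.mean))
    col = {m: j for j, m in enumerate(marker_map["marker"])}
    for locus in qtl.loci:
        if locus.marker not in marker_ids:
            raise KeyError(f"QTL locus {locus.marker!r} not on the map")
        y = y + locus.effect * geno[locus.origin][:, col[locus.marker]]
    for ep in qtl.epistatic_pairs:
        for mk in (ep.marker_a, ep.marker_b):
            if mk not in marker_ids:
                raise KeyError(f"epistatic locus {mk!r} not on the map")
        ga = geno[ep.origin_a][:, col[ep.marker_a]]
        gb = geno[ep.origin_b][:, col[ep.marker_b]]
        hit = (ga == ep.genotypes[0]) & (gb == ep.genotypes[1])
        y = y + ep.effect * hit
    if qtl.residual_sd > 0:
        y = y + rng.normal(0.0, qtl.residual_sd, n_individuals)
    if missing_rate > 0:
        for origin in geno:
            miss = rng.random(geno[origin].shape) < missing_rate
            geno[origin] = np.where(miss, np.int8(-1), geno[origin])
    phen = pd.DataFrame({"id": np.arange(n_individuals), phenotype_name: y})
    return BackcrossFamily(marker_map.reset_index(drop=True), geno, phen, pedigree)
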