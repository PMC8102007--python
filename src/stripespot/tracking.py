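"""Registration and linking of daily melanophore point sets into tracks.

Daily detections are first registered rigidly (rotation + translation) to a
common reference frame by robust sampling of distance-compatible point-pair
correspondences followed by a least-squares (Kabsch) refit on inliers,
requiring an inlier fraction of at least 0.20. Registered detections are then
linked frame to frame under a displacement cap of 100 px per 24 h, with gap
links across at most one missing day (cap scaled by the gap length). Tracks
spanning seven or more days with no more than one missing day enter motion
statistics: net total displacement and median per-day speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


@dataclass
class RegistrationResult:
    ok: bool
    rotation: float  # radians
    translation: np.ndarray  # (2,)
    inliers: list  # list of (index_a, index_b) correspondences
    residual_rms: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        R = _rot(self.rotation)
        return points @ R.T + self.translation


def _rot(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def _kabsch_2d(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares rigid transform mapping a onto b (2-D Kabsch)."""
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    H = (a - ca).T @ (b - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    theta = math.atan2(R[1, 0], R[0, 0])
    t = cb - _rot(theta) @ ca
    return theta, t


def rigid_register(points_a, points_b, inlier_ratio: float = 0.20,
                   tol: float = 3.0, n_samples: int = 200,
                   seed: int = 0) -> RegistrationResult:
    """Estimate the rigid transform taking ``points_a`` onto ``points_b``.

    Hypotheses are generated by sampling point pairs from A and matching them
    to pairs in B with compatible inter-point distance (rigidity preserves
    distances), scoring each candidate transform by its inlier count (residual
    to the nearest B point below ``tol``), then refitting by Kabsch on the
    inlier correspondences. Registration fails (``ok=False``) if no model
    reaches an inlier fraction of ``inlier_ratio``.
    """
    a = np.asarray(points_a, dtype=float).reshape(-1, 2)
    b = np.asarray(points_b, dtype=float).reshape(-1, 2)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 points in each set")
    rng = np.random.default_rng(seed)
    from scipy.spatial import cKDTree

    tree_b = cKDTree(b)
    # precompute pairwise distances in B for compatibility search
    db = np.linalg.norm(b[:, None, :] - b[None, :, :], axis=2)

    def score(theta, t):
        moved = a @ _rot(theta).T + t
        d, j = tree_b.query(moved, k=1)
        inl = np.nonzero(d < tol)[0]
        return inl, j, float(np.sqrt(np.mean(d[inl] ** 2))) if len(inl) else np.inf

    best = (-1, 0.0, np.zeros(2))
    for _ in range(n_samples):
        i1, i2 = rng.choice(len(a), size=2, replace=False)
        d12 = np.linalg.norm(a[i1] - a[i2])
        if d12 < 2 * tol:  # nearly coincident sample: degenerate, skip
            continue
        cand = np.argwhere(np.abs(db - d12) < 2 * tol)
        cand = cand[cand[:, 0] != cand[:, 1]]
        if len(cand) == 0:
            continue
        if len(cand) > 10:
            cand = cand[rng.choice(len(cand), size=10, replace=False)]
        for j1, j2 in cand:
            va, vb = a[i2] - a[i1], b[j2] - b[j1]
            theta = math.atan2(vb[1], vb[0]) - math.atan2(va[1], va[0])
            t = b[j1] - _rot(theta) @ a[i1]
            inl, _, _ = score(theta, t)
            if len(inl) > best[0]:
                best = (len(inl), theta, t)

    if best[0] < max(3, inlier_ratio * len(a)):
        return RegistrationResult(False, 0.0, np.zeros(2), [], math.inf)

    theta, t = best[1], best[2]
    # iterative least-squares refit on inlier correspondences
    for _ in range(3):
        inl, j, _ = score(theta, t)
        if len(inl) < 2:
            break
        theta, t = _kabsch_2d(a[inl], b[j[inl]])
    inl, j, rms = score(theta, t)
    if len(inl) < max(3, inlier_ratio * len(a)):
        return RegistrationResult(False, 0.0, np.zeros(2), [], math.inf)
    return RegistrationResult(True, theta, np.asarray(t, dtype=float),
                              [(int(i), int(j[i])) for i in inl], rms)


def register_series(frames: list, **kwargs) -> list:
    """Register each frame's points to the first frame by composing pairwise fits.

    ``frames`` is a list of (n_i, 2) arrays. Returns the transformed copies,
    all expressed in frame 0 coordinates.
    """
    out = [np.asarray(frames[0], dtype=float)]
    theta_acc, t_acc = 0.0, np.zeros(2)
    for prev, cur in zip(frames, frames[1:]):
        res = rigid_register(cur, prev, **kwargs)
        if not res.ok:
            raise RuntimeError("pairwise registration failed")
        # compose: frame0 <- prev <- cur
        theta_acc, t_acc = (theta_acc + res.rotation,
                            _rot(theta_acc) @ res.translation + t_acc)
        out.append(np.asarray(cur, dtype=float) @ _rot(theta_acc).T + t_acc)
    return out


@dataclass
class Track:
    track_id: int
    days: list = field(default_factory=list)
    xs: list = field(default_factory=list)
    ys: list = field(default_factory=list)

    def append(self, day, x, y):
        self.days.append(int(day))
        self.xs.append(float(x))
        self.ys.append(float(y))

    @property
    def span_days(self) -> int:
        return self.days[-1] - self.days[0] + 1

    @property
    def n_missing(self) -> int:
        return self.span_days - len(self.days)

    @property
    def total_displacement(self) -> float:
        return math.hypot(self.xs[-1] - self.xs[0], self.ys[-1] - self.ys[0])

    @property
    def median_speed(self) -> float:
        if len(self.days) < 2:
            return 0.0
        speeds = [
            math.hypot(x1 - x0, y1 - y0) / (d1 - d0)
            for (d0, x0, y0), (d1, x1, y1) in zip(
                zip(self.days, self.xs, self.ys),
                zip(self.days[1:], self.xs[1:], self.ys[1:]),
            )
        ]
        return float(np.median(speeds))


def link_tracks(frames: list, days: list | None = None,
                max_disp: float = 100.0, max_gap_days: int = 1,
                method: str = "greedy") -> list[Track]:
    """Link registered per-day detections into tracks.

    ``frames`` is a list of cell tables (or (n, 2) arrays) ordered by day.
    Frame-to-frame assignment minimizes linking distance subject to the per-day
    displacement cap; a track skipping g missing days may reconnect within
    (g+1) * ``max_disp``. Unmatched detections start new tracks. The default
    greedy nearest-pair linker is deterministic and order-independent (ties
    broken by coordinates); ``method="optimal"`` solves the assignment problem
    exactly per frame pair.
    """
    if days is None:
        days = list(range(len(frames)))
    pts = []
    for f in frames:
        if isinstance(f, pd.DataFrame):
            pts.append(f[["x", "y"]].to_numpy(dtype=float))
        else:
            pts.append(np.asarray(f, dtype=float).reshape(-1, 2))

    tracks: list[Track] = []
    open_tracks: list[Track] = []
    for day, p in zip(days, pts):
        active = [
            tr for tr in open_tracks
            if 1 <= day - tr.days[-1] <= max_gap_days + 1
        ]
        assigned_t: set[int] = set()
        assigned_d: set[int] = set()
        if active and len(p):
            ends = np.array([[tr.xs[-1], tr.ys[-1]] for tr in active])
            gaps = np.array([day - tr.days[-1] for tr in active])
            dist = np.linalg.norm(ends[:, None, :] - p[None, :, :], axis=2)
            caps = gaps[:, None] * max_disp
            allowed = dist <= caps
            if method == "optimal":
                BIG = 1e12
                cost = np.where(allowed, dist, BIG)
                ri, ci = linear_sum_assignment(cost)
                for i, jj in zip(ri, ci):
                    if allowed[i, jj]:
                        active[i].append(day, p[jj, 0], p[jj, 1])
                        assigned_t.add(i)
                        assigned_d.add(jj)
            else:
                pairs = np.argwhere(allowed)
                order = sorted(
                    range(len(pairs)),
                    key=lambda k: (
                        dist[pairs[k][0], pairs[k][1]],
                        ends[pairs[k][0]][0], ends[pairs[k][0]][1],
                        p[pairs[k][1]][0], p[pairs[k][1]][1],
                    ),
                )
                for k in order:
                    i, jj = pairs[k]
                    if i in assigned_t or jj in assigned_d:
                        continue
                    active[i].append(day, p[jj, 0], p[jj, 1])
                    assigned_t.add(i)
                    assigned_d.add(jj)
        for jj in range(len(p)):
            if jj not in assigned_d:
                tr = Track(track_id=len(tracks))
                tr.append(day, p[jj, 0], p[jj, 1])
                tracks.append(tr)
                open_tracks.append(tr)
    return tracks


def motion_stats(tracks: list[Track], min_span_days: int = 7,
                 max_missing: int = 1) -> pd.DataFrame:
    """Per-track displacement and speed, filtered by span and missing-day rules.

    Only tracks observed across at least ``min_span_days`` days (first to last,
    inclusive) with at most ``max_missing`` missing days qualify. Returns a
    table with total (net) displacement and median per-day speed per track;
    empty if no track qualifies.
    """
    rows = [
        (tr.track_id, tr.days[0], tr.days[-1], tr.span_days, tr.n_missing,
         tr.total_displacement, tr.median_speed)
        for tr in tracks
        if tr.span_days >= min_span_days and tr.n_missing <= max_missing
    ]
    return pd.DataFrame(
        rows,
        columns=["track_id", "first_day", "last_day", "span_days",
                 "n_missing", "total_displacement", "median_speed"],
    )
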