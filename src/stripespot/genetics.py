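"""Backcross QTL mapping, epistasis analysis, and extreme-phenotype F_ST scans.

Single-QTL genome scans use Haley–Knott regression: at each marker the
phenotype is regressed on the expected genotype of the selected transmitting
parent (observed 0/1 codes where genotyped, conditional expectations from
flanking markers under the Haldane map function where missing), and
LOD = (n/2) * log10(RSS0 / RSS1) against the intercept-only null. Genome-wide
significance thresholds come from permutation of phenotype labels; support
intervals from a 1.5-LOD drop around each peak. Two-locus epistasis is
assessed by one-way ANOVA over the four genotype combinations with an
interaction contrast and Tukey–Kramer letter groupings. Extreme-phenotype
scans compute per-marker Weir–Cockerham F_ST between the phenotypic tails,
with permutation P values and Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.libqsturng import psturng
from statsmodels.stats.multitest import multipletests

from .synthetic import HYBRID, PURE, BackcrossFamily, haldane_r

#: LOD values above this are capped and flagged as degenerate fits
LOD_CAP = 300.0


# ---------------------------------------------------------------------------
# genotype expectation (Haley–Knott imputation)
# ---------------------------------------------------------------------------


def expected_genotypes(family: BackcrossFamily, origin: str = HYBRID) -> np.ndarray:
    """Genotype probabilities P(code = 1) with missing values imputed.

    Missing entries are replaced by the conditional expectation given the
    nearest flanking genotyped markers on the same chromosome under the
    Haldane mapping function; 0.5 when a chromosome is wholly ungenotyped.
    This is what makes the marker regression Haley–Knott.
    """
    g = family.genotypes[origin]
    out = g.astype(np.float64)
    if not np.any(g < 0):
        return out
    markers = family.markers
    for _, idx in markers.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        pos = markers.loc[idx, "pos"].to_numpy(dtype=float)
        sub = g[:, idx]
        rows = np.nonzero(np.any(sub < 0, axis=1))[0]
        for i in rows:
            obs = np.nonzero(sub[i] >= 0)[0]
            for jj in np.nonzero(sub[i] < 0)[0]:
                left = obs[obs < jj]
                right = obs[obs > jj]
                li = left[-1] if len(left) else None
                ri = right[0] if len(right) else None
                if li is None and ri is None:
                    p = 0.5
                elif ri is None:
                    a, r1 = sub[i, li], haldane_r(pos[jj] - pos[li])
                    p = a * (1 - r1) + (1 - a) * r1
                elif li is None:
                    b, r2 = sub[i, ri], haldane_r(pos[ri] - pos[jj])
                    p = b * (1 - r2) + (1 - b) * r2
                else:
                    a, b = sub[i, li], sub[i, ri]
                    r1 = haldane_r(pos[jj] - pos[li])
                    r2 = haldane_r(pos[ri] - pos[jj])
                    r12 = r1 + r2 - 2 * r1 * r2
                    if a == b:
                        p_diff = r1 * r2 / (1 - r12)
                        p = p_diff if a == 0 else 1 - p_diff
                    else:
                        # P(g=1 | flanks differ): one switch on one side
                        p1 = (r1 * (1 - r2)) if a == 0 else ((1 - r1) * r2)
                        p = p1 / r12
                out[i, idx[jj]] = p
    return out


# ---------------------------------------------------------------------------
# LOD scan
# ---------------------------------------------------------------------------


@dataclass
class QTLScanResult:
    table: pd.DataFrame  # marker, chrom, pos, lod, degenerate
    phenotype: str
    origin: str
    threshold: float | None = None
    constant_phenotype: bool = False
    peaks: list = field(default_factory=list)

    def lod(self, marker: str) -> float:
        row = self.table[self.table["marker"] == marker]
        if row.empty:
            raise KeyError(f"marker {marker!r} not in scan")
        return float(row["lod"].iloc[0])

    @property
    def max_lod(self) -> float:
        return float(self.table["lod"].max())


def _lod_columns(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """LOD for every marker (columns of X) against every phenotype column of Y."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx2 = np.einsum("ij,ij->j", Xc, Xc)
    sy2 = np.einsum("ij,ij->j", Yc, Yc)
    num = Xc.T @ Yc  # (m, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = num**2 / (sx2[:, None] * sy2[None, :])
    r2 = np.where((sx2[:, None] > 0) & (sy2[None, :] > 0), r2, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        lod = -(n / 2.0) * np.log10(1.0 - r2)
    return np.minimum(lod, LOD_CAP)


def lod_scan(family: BackcrossFamily, phenotype: str,
             origin: str = HYBRID, drop_missing: bool = False) -> QTLScanResult:
    """Haley–Knott single-QTL scan of one phenotype over one transmission.

    With ``drop_missing`` markers carrying any missing genotype are excluded
    (the stricter published convention) instead of being imputed.
    """
    y = family.phenotypes[phenotype].to_numpy(dtype=float)
    if len(y) < 20:
        raise ValueError("need at least 20 individuals for a scan")
    X = expected_genotypes(family, origin)
    markers = family.markers.copy()
    if drop_missing:
        keep = ~np.any(family.genotypes[origin] < 0, axis=0)
        X = X[:, keep]
        markers = markers.loc[keep].reset_index(drop=True)
    if np.std(y) == 0:
        table = markers.assign(lod=0.0, degenerate=False)
        return QTLScanResult(table, phenotype, origin, constant_phenotype=True)
    lod = _lod_columns(X, y[:, None])[:, 0]
    table = markers.assign(lod=lod, degenerate=lod >= LOD_CAP)
    return QTLScanResult(table, phenotype, origin)


def permutation_threshold(family: BackcrossFamily, phenotype: str,
                          origin: str = HYBRID, n_perm: int = 1000,
                          alpha: float = 0.05, seed: int = 0) -> float:
    """Genome-wide LOD threshold from phenotype-label permutations.

    The empirical (1 - alpha) quantile (type-7 interpolation) of the
    genome-wide maximum LOD over ``n_perm`` permutations.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    y = family.phenotypes[phenotype].to_numpy(dtype=float)
    X = expected_genotypes(family, origin)
    perms = np.empty((len(y), n_perm))
    for p in range(n_perm):
        perms[:, p] = y[rng.permutation(len(y))]
    maxima = _lod_columns(X, perms).max(axis=0)
    return float(np.quantile(maxima, 1.0 - alpha))


def lod_interval(scan: QTLScanResult, peak_marker: str,
                 drop: float = 1.5) -> tuple[str, str]:
    """1.5-LOD support interval around a peak marker.

    The widest contiguous run of markers on the peak's chromosome with
    LOD >= peak - drop, extended one marker beyond on each side when available
    (a conservative convention). One-sided at chromosome ends.
    """
    t = scan.table
    row = t[t["marker"] == peak_marker]
    if row.empty:
        raise KeyError(f"marker {peak_marker!r} not in scan")
    chrom = row["chrom"].iloc[0]
    sub = t[t["chrom"] == chrom].reset_index(drop=True)
    j = int(sub.index[sub["marker"] == peak_marker][0])
    cut = float(row["lod"].iloc[0]) - drop
    lo = j
    while lo > 0 and sub["lod"].iloc[lo - 1] >= cut:
        lo -= 1
    hi = j
    while hi < len(sub) - 1 and sub["lod"].iloc[hi + 1] >= cut:
        hi += 1
    lo = max(0, lo - 1)
    hi = min(len(sub) - 1, hi + 1)
    return str(sub["marker"].iloc[lo]), str(sub["marker"].iloc[hi])


def variance_explained(family: BackcrossFamily, phenotype: str,
                       marker: str, origin: str = HYBRID) -> float:
    """Percent of phenotypic variance explained by the single-marker model."""
    y = family.phenotypes[phenotype].to_numpy(dtype=float)
    x = expected_genotypes(family, origin)[:, family.marker_index(marker)]
    yc, xc = y - y.mean(), x - x.mean()
    sx2 = float(xc @ xc)
    sy2 = float(yc @ yc)
    if sx2 == 0 or sy2 == 0:
        return 0.0
    r2 = (float(xc @ yc)) ** 2 / (sx2 * sy2)
    return 100.0 * r2


def find_peaks(scan: QTLScanResult, threshold: float,
               family: BackcrossFamily | None = None,
               drop: float = 1.5) -> list[dict]:
    """Per-chromosome LOD peaks above a threshold, with support intervals.

    When the family is supplied, each peak also reports the percent variance
    explained by its marker.
    """
    peaks = []
    for chrom, sub in scan.table.groupby("chrom", sort=False):
        j = sub["lod"].idxmax()
        if sub.loc[j, "lod"] < threshold:
            continue
        marker = str(sub.loc[j, "marker"])
        lo, hi = lod_interval(scan, marker, drop=drop)
        peak = {
            "marker": marker,
            "chrom": chrom,
            "pos": float(sub.loc[j, "pos"]),
            "lod": float(sub.loc[j, "lod"]),
            "interval": (lo, hi),
        }
        if family is not None:
            peak["pct_var"] = variance_explained(
                family, scan.phenotype, marker, scan.origin
            )
        peaks.append(peak)
    scan.peaks = peaks
    return peaks


# ---------------------------------------------------------------------------
# two-locus epistasis analysis
# ---------------------------------------------------------------------------


@dataclass
class TwoLocusResult:
    class_table: pd.DataFrame  # genotype combo, n, mean, sd, letters
    f_stat: float
    p_value: float
    interaction_contrast: float
    contrast_se: float
    letters: dict  # combo -> letter string


def _tukey_letters(combos, means, reject) -> dict:
    """Compact letter display from an all-pairs significance matrix.

    Insert-and-absorb: classes in mean order share a letter iff no pair within
    the letter's group differs significantly.
    """
    order = np.argsort(means)
    groups: list[set] = []
    for c in order:
        placed = False
        for grp in groups:
            if all(not reject[c, o] for o in grp):
                grp.add(c)
                placed = True
        if not placed:
            groups.append({c})
    # drop groups fully contained in another
    groups = [g for g in groups
              if not any(g < h for h in groups)]
    letters = {i: "" for i in range(len(combos))}
    for li, grp in enumerate(groups):
        ch = chr(ord("a") + li)
        for c in grp:
            letters[c] += ch
    return {combos[i]: "".join(sorted(letters[i])) for i in range(len(combos))}


def two_locus_analysis(family: BackcrossFamily, phenotype: str,
                       marker_i: str, marker_j: str,
                       origin_i: str = HYBRID, origin_j: str = PURE,
                       transform=None, alpha: float = 0.05) -> TwoLocusResult:
    """Epistasis test over the four two-locus genotype combinations.

    One-way ANOVA across the classes, the 2x2 interaction contrast
    mean(1,1) - mean(1,0) - mean(0,1) + mean(0,0) with its standard error, and
    Tukey–Kramer all-pairs comparisons summarized as letter groupings (classes
    sharing a letter are not significantly different). An optional variance-
    stabilizing ``transform`` (e.g. ``np.log``) is applied to the phenotype
    first. Individuals missing either genotype are excluded.
    """
    gi = family.genotype_at(marker_i, origin_i)
    gj = family.genotype_at(marker_j, origin_j)
    y = family.phenotypes[phenotype].to_numpy(dtype=float)
    ok = (gi >= 0) & (gj >= 0)
    gi, gj, y = gi[ok], gj[ok], y[ok]
    if transform is not None:
        y = transform(y)
    combos = [(0, 0), (0, 1), (1, 0), (1, 1)]
    samples = {c: y[(gi == c[0]) & (gj == c[1])] for c in combos}
    present = [c for c in combos if len(samples[c]) > 0]
    if len(present) < len(combos):
        warnings.warn("empty genotype class; analysis restricted to remaining classes")
    groups = [samples[c] for c in present]
    if any(len(s) < 4 for s in groups):
        warnings.warn("fewer than 4 individuals in some genotype class")
    f_stat, p_value = stats.f_oneway(*groups)
    ns = np.array([len(s) for s in groups])
    means = np.array([s.mean() for s in groups])
    sds = np.array([s.std(ddof=1) if len(s) > 1 else np.nan for s in groups])
    df_resid = int(sum(ns) - len(groups))
    s2 = float(sum((n - 1) * sd**2 for n, sd in zip(ns, sds) if n > 1) / df_resid)

    if all(c in present for c in combos):
        m = {c: samples[c].mean() for c in combos}
        contrast = m[(1, 1)] - m[(1, 0)] - m[(0, 1)] + m[(0, 0)]
        se = math.sqrt(s2 * sum(1.0 / len(samples[c]) for c in combos))
    else:
        contrast, se = np.nan, np.nan

    # Tukey–Kramer all-pairs on the studentized range
    kk = len(groups)
    reject = np.zeros((kk, kk), dtype=bool)
    for aix in range(kk):
        for bix in range(aix + 1, kk):
            se_ab = math.sqrt(s2 / 2.0 * (1.0 / ns[aix] + 1.0 / ns[bix]))
            q = abs(means[aix] - means[bix]) / se_ab if se_ab > 0 else np.inf
            p = float(np.atleast_1d(psturng(q, kk, df_resid))[0])
            reject[aix, bix] = reject[bix, aix] = p < alpha
    letters = _tukey_letters(present, means, reject)

    table = pd.DataFrame({
        "genotype": present,
        "n": ns,
        "mean": means,
        "sd": sds,
        "letters": [letters[c] for c in present],
    })
    return TwoLocusResult(table, float(f_stat), float(p_value),
                          float(contrast), float(se), letters)


# ---------------------------------------------------------------------------
# extreme-phenotype selection and F_ST scan
# ---------------------------------------------------------------------------


def select_extremes(phenotypes: pd.Series | np.ndarray,
                    fraction: float = 0.035) -> tuple[np.ndarray, np.ndarray]:
    """Index sets of the lowest and highest ceil(fraction * n) individuals.

    Boundary ties are broken by positional index. With the default 3.5%
    fraction and n = 457 this selects 16 per tail (ceil of 15.995).
    """
    if not (0.0 < fraction < 0.5):
        raise ValueError("fraction must be in (0, 0.5)")
    v = np.asarray(phenotypes, dtype=float)
    n = len(v)
    k = int(math.ceil(fraction * n))
    order = np.lexsort((np.arange(n), v))
    return np.sort(order[:k]), np.sort(order[-k:])


def weir_cockerham_fst(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Per-marker two-population Weir–Cockerham F_ST on 0/1 allele codes.

    Each backcross individual contributes one transmitted allele per marker, so
    the data are haploid and the Weir–Cockerham (1984) variance-components
    estimator reduces to its mean-squares form:

        MSP = sum_i n_i (p_i - p_bar)^2 / (r - 1)
        MSG = sum_i n_i p_i (1 - p_i) / sum_i (n_i - 1)
        theta = (MSP - MSG) / (MSP + (n_c - 1) MSG)

    with n_c = (sum n_i - sum n_i^2 / sum n_i) / (r - 1). Missing codes (-1)
    are excluded per marker; markers monomorphic across both groups return NaN.
    The estimator may be slightly negative under no differentiation and is not
    clamped.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    v1, v2 = g1 >= 0, g2 >= 0
    n1, n2 = v1.sum(axis=0), v2.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(v1, g1, 0.0).sum(axis=0) / n1
        p2 = np.where(v2, g2, 0.0).sum(axis=0) / n2
        ntot = n1 + n2
        pbar = (n1 * p1 + n2 * p2) / ntot
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # / (r-1) = 1
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
        nc = ntot - (n1**2 + n2**2) / ntot  # / (r-1) = 1
        denom = msp + (nc - 1.0) * msg
        out = (msp - msg) / denom
    bad = (n1 < 2) | (n2 < 2) | (pbar == 0.0) | (pbar == 1.0) | (denom == 0)
    return np.where(bad, np.nan, out)


@dataclass
class FstScanResult:
    table: pd.DataFrame  # marker, chrom, pos, fst, p_value, p_adj, significant
    group_sizes: tuple

    @property
    def max_marker(self) -> str:
        j = self.table["fst"].idxmax()
        return str(self.table.loc[j, "marker"])


def fst_scan(family: BackcrossFamily, groups: tuple,
             origin: str = HYBRID, n_perm: int = 0,
             alpha: float = 0.01, seed: int = 0) -> FstScanResult:
    """Genome-wide F_ST between two phenotype-defined groups of individuals.

    ``groups`` are disjoint index sets (e.g. from :func:`select_extremes`).
    With ``n_perm`` > 0, per-marker permutation P values (group labels
    shuffled) are Benjamini–Hochberg adjusted and markers flagged significant
    at ``alpha``.
    """
    lo, hi = (np.asarray(g, dtype=int) for g in groups)
    if len(np.intersect1d(lo, hi)):
        raise ValueError("groups must be disjoint")
    if len(lo) < 2 or len(hi) < 2:
        raise ValueError("each group needs at least 2 individuals")
    g = family.genotypes[origin]
    obs = weir_cockerham_fst(g[lo], g[hi])
    table = family.markers.assign(fst=obs)
    p = p_adj = np.full(len(obs), np.nan)
    sig = np.zeros(len(obs), dtype=bool)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        pool = np.concatenate([lo, hi])
        exceed = np.zeros(len(obs))
        for _ in range(n_perm):
            perm = rng.permutation(pool)
            f = weir_cockerham_fst(g[perm[: len(lo)]], g[perm[len(lo):]])
            exceed += (np.nan_to_num(f, nan=-np.inf)
                       >= np.nan_to_num(obs, nan=np.inf))
        p = (1.0 + exceed) / (n_perm + 1.0)
        valid = ~np.isnan(obs)
        p_adj = np.full(len(obs), np.nan)
        if valid.any():
            _, adj, _, _ = multipletests(p[valid], method="fdr_bh")
            p_adj[valid] = adj
            sig[valid] = adj < alpha
    table = table.assign(p_value=p, p_adj=p_adj, significant=sig)
    return FstScanResult(table, (len(lo), len(hi)))
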