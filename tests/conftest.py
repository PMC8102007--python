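import numpy as np
import pytest
from scipy.spatial import cKDTree

from stripespot.synthetic import MELANOPHORE


def match_detections(detected, truth_cells, tol=5.0, cls=MELANOPHORE):
    """Greedy one-to-one matching of detections to planted cells.

    Returns (precision, recall, f1, median centroid error of matches).
    """
    t = truth_cells
    if "class" in t:
        t = t[t["class"] == cls]
    tpts = t[["x", "y"]].to_numpy(dtype=float)
    dpts = detected[["x", "y"]].to_numpy(dtype=float)
    if len(dpts) == 0 or len(tpts) == 0:
        return 0.0, 0.0, 0.0, np.nan
    tree = cKDTree(tpts)
    dist, j = tree.query(dpts)
    used, tp, errs = set(), 0, []
    for k in np.argsort(dist):
        if dist[k] <= tol and j[k] not in used:
            used.add(j[k])
            tp += 1
            errs.append(dist[k])
    prec, rec = tp / len(dpts), tp / len(tpts)
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1, float(np.median(errs)) if errs else np.nan


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
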