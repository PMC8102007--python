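"""Plain-text interchange: cell tables, masks, images, maps, genotypes, tracks.

Cells travel as CSV (id, frame, x, y, area_px, class); masks and images as
8-bit PNG/TIFF; marker maps and genotype matrices as TSV with 0/1/NA codes;
phenotypes as CSV. These match the formats the synthetic generator emits so
real data can be substituted file-for-file.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from PIL import Image

from .synthetic import CELL_COLUMNS, BackcrossFamily

_CSV_COLUMNS = ["id", "frame", "x", "y", "area_px", "class"]


def write_cells(cells: pd.DataFrame, path) -> None:
    out = cells[CELL_COLUMNS].rename(columns={"area": "area_px"})
    out.to_csv(path, index=False)


def read_cells(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df[_CSV_COLUMNS].rename(columns={"area_px": "area"})


def write_image(img: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(img, dtype=np.uint8)).save(path)


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path))


def write_mask(mask: np.ndarray, path) -> None:
    write_image(mask, path)


def read_mask(path) -> np.ndarray:
    m = read_image(path)
    if m.ndim == 3:
        m = m[..., 0]
    return (m > 127).astype(np.uint8) * 255


def write_family(family: BackcrossFamily, prefix) -> None:
    """Write markers TSV, one genotype TSV per origin, and the phenotype CSV."""
    family.markers.to_csv(f"{prefix}.markers.tsv", sep="\t", index=False)
    for origin, g in family.genotypes.items():
        df = pd.DataFrame(g, columns=family.markers["marker"])
        df = df.replace(-1, pd.NA)
        df.insert(0, "id", family.phenotypes["id"].to_numpy())
        df.to_csv(f"{prefix}.geno_{origin}.tsv", sep="\t", index=False, na_rep="NA")
    family.phenotypes.to_csv(f"{prefix}.pheno.csv", index=False)


def read_family(prefix, origins=("hybrid", "pure"), pedigree="BC") -> BackcrossFamily:
    markers = pd.read_csv(f"{prefix}.markers.tsv", sep="\t")
    genotypes = {}
    for origin in origins:
        df = pd.read_csv(f"{prefix}.geno_{origin}.tsv", sep="\t")
        g = df.drop(columns=["id"]).to_numpy(dtype=float)
        genotypes[origin] = np.where(np.isnan(g), -1, g).astype(np.int8)
    phen = pd.read_csv(f"{prefix}.pheno.csv")
    return BackcrossFamily(markers, genotypes, phen, pedigree)


def write_tracks(tracks, path) -> None:
    rows = [
        (tr.track_id, d, x, y)
        for tr in tracks
        for d, x, y in zip(tr.days, tr.xs, tr.ys)
    ]
    pd.DataFrame(rows, columns=["track_id", "day", "x", "y"]).to_csv(path, index=False)
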