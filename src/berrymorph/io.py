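"""File formats: the fourway-csv genotype dialect, trait tables, configs.

The genotype file ("fourway-csv") is a plain CSV laid out as:

* row 1 — marker names (first cell = ``id``),
* row 2 — linkage-group labels,
* row 3 — cM positions,
* rows 4+ — one individual per row: individual ID, then genotype codes
  1=ac, 2=ad, 3=bc, 4=bd, 0=missing.

Every reader and writer in the package uses exactly this dialect.  Images
are written as 8-bit grayscale PNG.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .synthetic import SimCross


def write_fourway_csv(cross: SimCross, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id"] + cross.gmap["marker"].tolist())
        w.writerow([""] + cross.gmap["lg"].astype(str).tolist())
        w.writerow([""] + [f"{c:g}" for c in cross.gmap["cm"]])
        for i, gid in enumerate(cross.ids):
            w.writerow([gid] + [str(int(g)) for g in cross.geno[i]])


def read_fourway_csv(path: str | Path) -> SimCross:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise ValueError("fourway-csv needs 3 header rows and >= 1 individual")
    markers = rows[0][1:]
    lgs = rows[1][1:]
    cms = [float(c) for c in rows[2][1:]]
    gmap = pd.DataFrame({"marker": markers,
                         "lg": [int(l) if l.isdigit() else l for l in lgs],
                         "cm": cms})
    ids = [r[0] for r in rows[3:]]
    geno = np.array([[int(v) for v in r[1:]] for r in rows[3:]], dtype=int)
    if geno.shape[1] != len(markers):
        raise ValueError("genotype row length does not match marker count")
    if geno.min() < 0 or geno.max() > 4:
        raise ValueError("genotype codes must lie in {0,1,2,3,4}")
    return SimCross(gmap, geno, ids)


def write_scene_png(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(Path(path))


def read_scene_png(path: str | Path) -> np.ndarray:
    return np.array(Image.open(Path(path)).convert("L"))


def write_mask_png(grid: np.ndarray, path: str | Path) -> None:
    write_scene_png(np.where(np.asarray(grid, bool), 255, 0).astype(np.uint8), path)


def read_mask_png(path: str | Path) -> np.ndarray:
    return read_scene_png(path) > 127


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
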