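"""Reading and writing the toolkit's on-disk formats.

Tabular data travels as TSV/CSV (pandas); reports as JSON; tissue masks as
8-bit label PNGs (1 px = 1 um by default) with a JSON sidecar carrying the
pixel size and the label legend.  Event tables embed their generator seed
as a ``# seed=<int>`` comment line so a table is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import InputError
from .spatial import TissueMap

__all__ = [
    "write_table",
    "read_table",
    "write_counts",
    "read_counts",
    "write_points",
    "read_points",
    "write_tissue_map",
    "read_tissue_map",
    "write_report",
    "read_report",
]

#: Combined medulla x compartment encoding for the single-channel label mask.
MASK_LEGEND = {
    0: "background",
    1: "cortex/K8",
    2: "cortex/K5K8",
    3: "medulla/K5K8",
    4: "medulla/K5",
}


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV, with the generator seed as a comment header if known."""
    path = Path(path)
    with open(path, "w") as fh:
        if "seed" in df.attrs:
            fh.write(f"# seed={df.attrs['seed']}\n")
        df.to_csv(fh, sep="\t", index=not isinstance(df.index, pd.RangeIndex))


def read_table(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# seed="):
        df.attrs["seed"] = int(first.split("=", 1)[1])
    return df


def write_counts(counts: np.ndarray, path: str | Path) -> None:
    """Single-column TSV of per-section counts."""
    pd.DataFrame({"count": np.asarray(counts, dtype=int)}).to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "count" not in df.columns:
        raise InputError(f"{path}: expected a 'count' column")
    return df["count"].to_numpy(dtype=int)


def write_points(points: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(points, dtype=float), columns=["x_um", "y_um"]).to_csv(
        path, index=False
    )


def read_points(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, comment="#")
    if not {"x_um", "y_um"} <= set(df.columns):
        raise InputError(f"{path}: expected columns x_um, y_um")
    return df[["x_um", "y_um"]].to_numpy(dtype=float)


def _encode_mask(tmap: TissueMap) -> np.ndarray:
    label = np.zeros(tmap.shape, dtype=np.uint8)
    med, comp, tis = tmap.medulla, tmap.compartments, tmap.tissue
    label[tis & ~med & (comp == 2)] = 1
    label[tis & ~med & (comp == 3)] = 2
    label[tis & med & (comp == 3)] = 3
    label[tis & med & (comp == 1)] = 4
    return label


def write_tissue_map(tmap: TissueMap, mask_path: str | Path, points_path: str | Path) -> None:
    """Write a tissue map as label PNG + JSON sidecar plus a points CSV."""
    mask_path = Path(mask_path)
    iio.imwrite(mask_path, _encode_mask(tmap))
    sidecar = {
        "pixel_size_um": tmap.pixel_size_um,
        "legend": {str(k): v for k, v in MASK_LEGEND.items()},
        "shape": list(tmap.shape),
    }
    mask_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    write_points(tmap.points, points_path)


def read_tissue_map(mask_path: str | Path, points_path: str | Path | None = None) -> TissueMap:
    mask_path = Path(mask_path)
    label = np.asarray(iio.imread(mask_path))
    if label.ndim != 2:
        raise InputError(f"{mask_path}: expected a single-channel label image")
    sidecar = json.loads(mask_path.with_suffix(".json").read_text())
    medulla = (label == 3) | (label == 4)
    tissue = label > 0
    compartments = np.zeros_like(label, dtype=np.uint8)
    compartments[label == 4] = 1
    compartments[label == 1] = 2
    compartments[(label == 2) | (label == 3)] = 3
    points = read_points(points_path) if points_path else np.empty((0, 2))
    return TissueMap(
        points=points,
        medulla=medulla,
        compartments=compartments,
        tissue=tissue,
        pixel_size_um=float(sidecar["pixel_size_um"]),
    )


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
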