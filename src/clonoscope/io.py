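"""File formats: object matrices and feature tables as CSV, label stacks as
16-bit TIFF, lineage forests and reports as JSON.

CSV dialect: comma-separated, UTF-8, header row, '.' decimal; missing or
masked values are written as empty fields.  All write/read pairs round-trip
losslessly for the fields they carry.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

from .lineage import CellRecord, LineageForest, ObjectMatrix
from .measure import FeatureTable


def write_object_matrix(
    m: ObjectMatrix, path: str | Path, centroid_path: str | Path | None = None
) -> None:
    """CSV with the frame index in the first column and cell ids as header."""
    df = pd.DataFrame(m.values, columns=m.cells)
    df.insert(0, "frame", np.arange(m.n_frames))
    df.to_csv(path, index=False)
    if centroid_path is not None and m.centroids is not None:
        rows = [
            {"frame": f, "label": lab, "x_um": x, "y_um": y}
            for (f, lab), (x, y) in sorted(m.centroids.items())
        ]
        pd.DataFrame(rows).to_csv(centroid_path, index=False)


def read_object_matrix(
    path: str | Path,
    frame_interval_min: float = 15.0,
    centroid_path: str | Path | None = None,
) -> ObjectMatrix:
    _check_rectangular(path)
    df = pd.read_csv(path)
    if "frame" not in df.columns:
        raise ValueError(f"{path}: missing 'frame' column")
    df = df.sort_values("frame")
    centroids = None
    if centroid_path is not None:
        cdf = pd.read_csv(centroid_path)
        centroids = {
            (int(r.frame), int(r.label)): (float(r.x_um), float(r.y_um))
            for r in cdf.itertuples()
        }
    return ObjectMatrix(
        values=df.drop(columns="frame").to_numpy(dtype=np.int64),
        cells=[str(c) for c in df.columns if c != "frame"],
        frame_interval_min=frame_interval_min,
        centroids=centroids,
    )


def _check_rectangular(path: str | Path) -> None:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            width = len(next(reader))
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        for i, row in enumerate(reader, start=2):
            if row and len(row) != width:
                raise ValueError(
                    f"{path}: row {i} has {len(row)} fields, expected {width}"
                )


def write_forest(f: LineageForest, path: str | Path) -> None:
    payload = {
        "frame_interval_min": f.frame_interval_min,
        "roots": f.roots,
        "records": [asdict(f.records[cid]) for cid in sorted(f.records)],
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_forest(path: str | Path) -> LineageForest:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    records = {r["cell_id"]: CellRecord(**r) for r in payload["records"]}
    return LineageForest(
        records=records,
        roots=list(payload["roots"]),
        frame_interval_min=payload["frame_interval_min"],
    )


def write_label_stack(frames: Iterable[np.ndarray], path: str | Path) -> None:
    """Multi-page 16-bit TIFF, one page per frame."""
    stack = np.stack([np.asarray(f, dtype=np.uint16) for f in frames])
    tifffile.imwrite(path, stack, photometric="minisblack")


def read_label_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    return arr[None] if arr.ndim == 2 else arr


def write_label_frames(
    frames: Mapping[int, np.ndarray], directory: str | Path, prefix: str = "frame"
) -> None:
    """Per-frame TIFF files, zero-padded by frame index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pad = max(4, len(str(max(frames))))
    for idx, img in sorted(frames.items()):
        tifffile.imwrite(
            directory / f"{prefix}_{idx:0{pad}d}.tif",
            np.asarray(img, dtype=np.uint16),
        )


def write_feature_table(
    t: FeatureTable, path: str | Path, mask_path: str | Path | None = None
) -> None:
    """Data CSV with masked entries blanked; optional mask sidecar CSV."""
    blanked = t.data.mask(~t.mask)
    blanked.to_csv(path)
    if mask_path is not None:
        t.mask.to_csv(mask_path)


def read_feature_table(
    path: str | Path, mask_path: str | Path | None = None
) -> FeatureTable:
    data = pd.read_csv(path, index_col=0)
    data.index = data.index.astype(str)
    if mask_path is not None:
        mask = pd.read_csv(mask_path, index_col=0).astype(bool)
        mask.index = mask.index.astype(str)
    else:
        mask = data.notna()
    return FeatureTable(data=data, mask=mask)


def write_report(obj, path: str | Path) -> None:
    """DataFrames to CSV, everything JSON-serialisable to JSON."""
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    else:
        path.write_text(
            json.dumps(obj, indent=1, default=_jsonify), encoding="utf-8"
        )


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "__dataclass_fields__"):
        return asdict(o)
    raise TypeError(f"cannot serialise {type(o)}")
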