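"""Per-frame geometry, neighbour statistics, colony hull metrics, and the
derived per-cell feature table.

Coordinate convention: 0-based pixel indices, origin at the top-left corner,
``x`` increasing along columns and ``y`` along rows.  Object geometry is
computed with :func:`skimage.measure.regionprops` and reported in both pixel
and micron units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree
from skimage.measure import regionprops_table

from .lineage import MINUTES_PER_DAY, LineageForest, descendant_counts

#: length of the early-lifetime averaging window, in days (the mean
#: dividing-cell lifetime); at 15-min frames this is 80 frames.
EARLY_WINDOW_D = 0.83

#: frames before division over which the pre-division area is averaged
#: (1-2 h at 15-min frames, i.e. division frame minus 8 .. minus 4)
PREDIV_WINDOW = (8, 4)


def measure_frame(img: np.ndarray, pixel_size_um: float = 1.0) -> pd.DataFrame:
    """Geometry of every labelled object in a label image.

    Returns a DataFrame indexed by object label with centroid, area,
    perimeter, axis lengths, eccentricity, orientation, solidity, extent,
    form factor (4*pi*A/P^2) and compactness (P^2/(4*pi*A)), carrying both
    pixel and micron units.  An empty image yields an empty frame.
    """
    img = np.asarray(img)
    if img.max() == 0:
        return pd.DataFrame(
            columns=[
                "centroid_x_px", "centroid_y_px", "centroid_x_um", "centroid_y_um",
                "area_px2", "area_um2", "perimeter_px", "perimeter_um",
                "major_axis_px", "major_axis_um", "minor_axis_px", "minor_axis_um",
                "eccentricity", "orientation", "solidity", "extent",
                "form_factor", "compactness",
            ]
        )
    props = regionprops_table(
        img,
        properties=(
            "label", "centroid", "area", "perimeter",
            "axis_major_length", "axis_minor_length",
            "eccentricity", "orientation", "solidity", "extent",
        ),
    )
    df = pd.DataFrame(props).set_index("label")
    out = pd.DataFrame(index=df.index)
    out["centroid_x_px"] = df["centroid-1"]
    out["centroid_y_px"] = df["centroid-0"]
    out["centroid_x_um"] = df["centroid-1"] * pixel_size_um
    out["centroid_y_um"] = df["centroid-0"] * pixel_size_um
    out["area_px2"] = df["area"]
    out["area_um2"] = df["area"] * pixel_size_um**2
    out["perimeter_px"] = df["perimeter"]
    out["perimeter_um"] = df["perimeter"] * pixel_size_um
    out["major_axis_px"] = df["axis_major_length"]
    out["major_axis_um"] = df["axis_major_length"] * pixel_size_um
    out["minor_axis_px"] = df["axis_minor_length"]
    out["minor_axis_um"] = df["axis_minor_length"] * pixel_size_um
    out["eccentricity"] = df["eccentricity"]
    out["orientation"] = df["orientation"]
    out["solidity"] = df["solidity"]
    out["extent"] = df["extent"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ff = 4.0 * math.pi * df["area"] / df["perimeter"] ** 2
    out["form_factor"] = ff.replace([np.inf, -np.inf], np.nan)
    out["compactness"] = 1.0 / out["form_factor"]
    return out


def _boundary_pixels(img: np.ndarray) -> dict[int, np.ndarray]:
    """Per-label (row, col) coordinates of boundary pixels."""
    padded = np.pad(img, 1)
    interior = np.ones_like(padded, dtype=bool)
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        interior &= np.roll(padded, shift, axis=(0, 1)) == padded
    boundary = (padded != 0) & ~interior
    rows, cols = np.nonzero(boundary)
    labels = padded[rows, cols]
    out: dict[int, np.ndarray] = {}
    order = np.argsort(labels, kind="stable")
    coords = np.column_stack([rows - 1, cols - 1])[order]
    labels = labels[order]
    for lab in np.unique(labels):
        out[int(lab)] = coords[labels == lab]
    return out


def neighbor_stats(img: np.ndarray, threshold_px: float = 15.0) -> pd.DataFrame:
    """Neighbour counts and nearest-object distances for every label.

    Two objects are neighbours when their minimum edge-to-edge distance is at
    most ``threshold_px`` (default 15 px, i.e. 9.7 um at the calibrated pixel
    size).  Edge-to-edge distance is the smallest centre-to-centre distance
    between boundary pixels minus one pixel (so squares separated by a
     10-pixel empty gap are 10 px apart), floored at zero for touching
    objects.  The two nearest distances are reported regardless of the
    threshold; they are NaN when fewer than one/two other objects exist.
    """
    bpix = _boundary_pixels(np.asarray(img))
    labels = sorted(bpix)
    n = len(labels)
    dmat = np.full((n, n), np.inf)
    trees = {lab: cKDTree(bpix[lab]) for lab in labels}
    for i, li in enumerate(labels):
        for j in range(i + 1, n):
            lj = labels[j]
            d, _ = trees[lj].query(bpix[li], k=1)
            dmat[i, j] = dmat[j, i] = max(float(d.min()) - 1.0, 0.0)
    rows = []
    for i, lab in enumerate(labels):
        others = np.sort(dmat[i][np.isfinite(dmat[i])])
        rows.append(
            {
                "n_neighbors": int((others <= threshold_px).sum()),
                "first_closest_distance": others[0] if others.size >= 1 else np.nan,
                "second_closest_distance": others[1] if others.size >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows, index=pd.Index(labels, name="label"))


@dataclass
class ColonyMetrics:
    """Convex-hull summary of one colony at one frame.

    ``approx_diameter_mm`` is the diameter of the circle whose area equals
    the hull area: ``2 * sqrt(hull_area / pi)``.
    """

    hull_area_um2: float
    occupied_area_um2: float
    confluency: float
    approx_diameter_mm: float
    centroid_x_um: float
    centroid_y_um: float
    from_positions: bool = False

    @property
    def hull_area_mm2(self) -> float:
        return self.hull_area_um2 / 1e6


def _hull_area(points: np.ndarray) -> float:
    if len(points) < 3:
        return 0.0
    try:
        return float(ConvexHull(points).volume)
    except QhullError:  # collinear members
        return 0.0


def colony_hull_metrics(
    label_image: np.ndarray | None = None,
    members: Iterable[int] | None = None,
    *,
    positions: np.ndarray | None = None,
    areas: np.ndarray | None = None,
    pixel_size_um: float = 1.0,
) -> ColonyMetrics:
    """Convex-hull area, occupancy, confluency and circle-equivalent diameter.

    Image mode: the hull is taken over the outer pixel corners of all member
    objects (so it always contains the occupied pixels), the occupied area is
    their pixel count, and the colony centroid is the unweighted mean of the
    member object centroids.

    Position mode (``positions`` given as an (n, 2) array of x/y in um, with
    optional per-cell ``areas`` in um^2): the hull is taken over the
    centroids only and the result is flagged ``from_positions``; this
    understates the hull by about one cell radius along the rim.
    """
    if (label_image is None) == (positions is None):
        raise ValueError("pass exactly one of label_image or positions")
    if label_image is not None:
        img = np.asarray(label_image)
        if members is None:
            mask = img > 0
        else:
            mask = np.isin(img, list(members))
        occupied_px = int(mask.sum())
        if occupied_px == 0:
            raise ValueError("no member pixels in the image")
        rows, cols = np.nonzero(mask)
        # hull over the outer corners of the member pixels, so that the hull
        # always contains the occupied area (confluency <= 1); vertices lie
        # on per-row extremes, which keeps the Qhull input small
        order = np.argsort(rows, kind="stable")
        rs, cs = rows[order], cols[order]
        row_starts = np.searchsorted(rs, np.unique(rs), side="left")
        row_ends = np.append(row_starts[1:], rs.size)
        pts = []
        for s, e in zip(row_starts, row_ends):
            r = rs[s]
            lo, hi = cs[s:e].min(), cs[s:e].max()
            pts.extend(
                [
                    (lo - 0.5, r - 0.5), (lo - 0.5, r + 0.5),
                    (hi + 0.5, r - 0.5), (hi + 0.5, r + 0.5),
                ]
            )
        hull_px2 = _hull_area(np.asarray(pts, dtype=float))
        hull_um2 = hull_px2 * pixel_size_um**2
        occupied_um2 = occupied_px * pixel_size_um**2
        # unweighted mean of per-object centroids
        labs = img[mask]
        counts = np.bincount(labs)
        sum_c = np.bincount(labs, weights=cols)
        sum_r = np.bincount(labs, weights=rows)
        present = counts > 0
        cx = float(np.mean(sum_c[present] / counts[present])) * pixel_size_um
        cy = float(np.mean(sum_r[present] / counts[present])) * pixel_size_um
        from_positions = False
    else:
        pts = np.asarray(positions, dtype=float)
        hull_um2 = _hull_area(pts)
        occupied_um2 = float(np.sum(areas)) if areas is not None else np.nan
        cx, cy = pts.mean(axis=0)
        from_positions = True
    confluency = occupied_um2 / hull_um2 if hull_um2 > 0 else np.nan
    diameter_mm = 2.0 * math.sqrt(hull_um2 / math.pi) / 1e3
    return ColonyMetrics(
        hull_area_um2=hull_um2,
        occupied_area_um2=occupied_um2,
        confluency=confluency,
        approx_diameter_mm=diameter_mm,
        centroid_x_um=float(cx),
        centroid_y_um=float(cy),
        from_positions=from_positions,
    )


@dataclass
class MitoticEvent:
    cell_id: str
    frame: int
    x_um: float
    y_um: float
    distance_from_centroid_um: float
    confluency: float


def mitotic_event_map(
    f: LineageForest,
    positions: Mapping[tuple[str, int], tuple[float, float]],
    metrics_by_frame: Mapping[int, ColonyMetrics],
) -> list[MitoticEvent]:
    """One event per division, at the parent's final-frame centroid.

    ``positions`` maps (cell_id, frame) to the cell centroid in um;
    ``metrics_by_frame`` supplies the colony centroid and confluency at each
    division frame.
    """
    events = []
    for rec in sorted(f.records.values(), key=lambda r: (r.last_frame, r.cell_id)):
        if not rec.divided:
            continue
        x, y = positions[(rec.cell_id, rec.last_frame)]
        met = metrics_by_frame[rec.last_frame]
        d = math.hypot(x - met.centroid_x_um, y - met.centroid_y_um)
        events.append(
            MitoticEvent(
                cell_id=rec.cell_id,
                frame=rec.last_frame,
                x_um=x,
                y_um=y,
                distance_from_centroid_um=d,
                confluency=met.confluency,
            )
        )
    return events


@dataclass
class FeatureTable:
    """Per-cell derived properties with per-column validity masks.

    ``data`` holds one row per cell; ``mask`` is a same-shaped boolean frame
    where True marks a valid entry.  Masked entries must be excluded from all
    downstream statistics: lifetime-dependent columns are masked for cells
    without a documented lifetime (founders, whose birth precedes
    observation, and never-dividing cells), and parent-derived columns are
    masked for first- and second-generation cells, whose parents have
    unknown properties.
    """

    data: pd.DataFrame
    mask: pd.DataFrame

    def valid(self, column: str) -> pd.Series:
        """Values of one column restricted to its valid rows."""
        return self.data.loc[self.mask[column], column]


#: columns only defined for cells with a documented lifetime
LIFETIME_COLUMNS = ("lifetime_d",)
#: columns only defined when the parent's properties are observable (gen >= 3)
PARENT_COLUMNS = (
    "parent_max_area_um2",
    "parent_lifetime_d",
    "parent_area_before_division_um2",
)
#: columns only defined for cells that divide
DIVISION_COLUMNS = ("area_before_division_um2", "n_senescent_daughters")


def build_feature_table(
    f: LineageForest,
    tracks: pd.DataFrame,
    *,
    fates: Mapping[str, str] | None = None,
    progeny_classes: Mapping[str, str] | None = None,
    colony_ids: Mapping[str, str] | None = None,
    passthrough: pd.DataFrame | None = None,
) -> FeatureTable:
    """Assemble the per-cell feature table from per-frame tracks.

    ``tracks`` is a tidy frame with columns ``cell_id``, ``frame``, ``x_um``,
    ``y_um``, ``area_um2`` and optionally ``n_neighbors``, one row per cell
    per frame of its existence.  ``fates`` maps cell ids to
    'proliferative'/'senescent'/'censored' labels (used for the
    senescent-daughter counts), ``progeny_classes`` maps founder ids to
    'slow'/'moderate'/'fast', and ``colony_ids`` maps founder ids to colony
    identifiers (defaults to the founder id itself).  Extra per-cell columns
    in ``passthrough`` (indexed by cell id) are carried through unmasked.

    The early-area column averages over the first 0.83 days of each cell's
    record (80 frames at 15-min sampling) or its whole record if shorter;
    the pre-division area averages the frames 1-2 h before division.
    """
    dt_d = f.frame_interval_min / MINUTES_PER_DAY
    window = max(1, round(EARLY_WINDOW_D / dt_d))
    fates = fates or {}
    progeny_classes = progeny_classes or {}
    n_desc = descendant_counts(f)

    grouped = {str(cid): g.sort_values("frame") for cid, g in tracks.groupby("cell_id")}
    rows = {}
    for cid in sorted(f.records):
        rec = f.records[cid]
        g = grouped.get(cid)
        if g is None:
            raise ValueError(f"no track rows for cell {cid}")
        area = g["area_um2"].to_numpy()
        frames = g["frame"].to_numpy()
        dx = np.diff(g["x_um"].to_numpy())
        dy = np.diff(g["y_um"].to_numpy())
        lifetime = f.lifetime_d(cid)
        if rec.divided:
            div_frame = rec.last_frame + 1
            lo, hi = div_frame - PREDIV_WINDOW[0], div_frame - PREDIV_WINDOW[1]
            in_win = (frames >= lo) & (frames <= hi)
            prediv = float(area[in_win].mean()) if in_win.any() else float(area[-1])
            kids = rec.children
            n_sen = sum(1 for k in kids if fates.get(k) == "senescent")
        else:
            prediv = np.nan
            n_sen = np.nan
        nn = g["n_neighbors"].to_numpy() if "n_neighbors" in g else None
        root = f.root_of(cid)
        rows[cid] = {
            "avg_area_um2": float(area.mean()),
            "max_area_um2": float(area.max()),
            "area_at_birth_um2": float(area[0]),
            "area_before_division_um2": prediv,
            "avg_area_first_0.83d_um2": float(area[:window].mean()),
            "total_distance_traveled_um": float(np.hypot(dx, dy).sum()),
            "avg_n_neighbors": float(nn.mean()) if nn is not None else np.nan,
            "max_n_neighbors": float(nn.max()) if nn is not None else np.nan,
            "cumulative_n_neighbors": float(nn.sum()) if nn is not None else np.nan,
            "n_neighbors_at_birth": float(nn[0]) if nn is not None else np.nan,
            "birth_time_d": rec.birth_frame * dt_d,
            "lifetime_d": lifetime if lifetime is not None else np.nan,
            "generation": rec.generation,
            "n_progeny": n_desc[cid],
            "n_senescent_daughters": n_sen,
            "progeny_class": progeny_classes.get(root, ""),
            "colony_id": colony_ids[root] if colony_ids else root,
        }
    for cid, row in rows.items():
        rec = f.records[cid]
        if rec.parent_id is not None:
            p = rows[rec.parent_id]
            row["parent_max_area_um2"] = p["max_area_um2"]
            row["parent_lifetime_d"] = p["lifetime_d"]
            row["parent_area_before_division_um2"] = p["area_before_division_um2"]
        else:
            row["parent_max_area_um2"] = np.nan
            row["parent_lifetime_d"] = np.nan
            row["parent_area_before_division_um2"] = np.nan

    data = pd.DataFrame.from_dict(rows, orient="index")
    data.index.name = "cell_id"
    if passthrough is not None:
        data = data.join(passthrough.reindex(data.index))

    mask = pd.DataFrame(True, index=data.index, columns=data.columns)
    gen = data["generation"]
    has_lifetime = data["lifetime_d"].notna()
    for col in LIFETIME_COLUMNS:
        mask[col] = has_lifetime
    mask["birth_time_d"] = gen >= 2
    divided = pd.Series(
        [f.records[cid].divided for cid in data.index], index=data.index
    )
    mask["area_before_division_um2"] = divided
    mask["n_senescent_daughters"] = divided & bool(fates)
    for col in PARENT_COLUMNS:
        mask[col] = (gen >= 3) & data[col].notna()
    if "n_neighbors" not in tracks.columns:
        for col in (
            "avg_n_neighbors", "max_n_neighbors",
            "cumulative_n_neighbors", "n_neighbors_at_birth",
        ):
            mask[col] = False
    return FeatureTable(data=data, mask=mask)


def tracks_from_experiment(exp) -> pd.DataFrame:
    """Tidy per-frame track table from a simulated experiment."""
    recs = []
    for cid in sorted(exp.agents):
        a = exp.agents[cid]
        frames = np.arange(a.birth_frame, a.end_frame + 1)
        recs.append(
            pd.DataFrame(
                {
                    "cell_id": str(cid),
                    "frame": frames,
                    "x_um": a.x_um,
                    "y_um": a.y_um,
                    "area_um2": a.area_um2,
                }
            )
        )
    return pd.concat(recs, ignore_index=True)
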