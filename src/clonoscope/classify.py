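"""Categorical calls on cells, progenies and colonies.

Operational definitions (all relative to 15-min frames, with frame 374
labelled Day 4 and frame 672 Day 7):

* fate — a cell present at the Day-4 reference frame is *senescent* if it
  does not divide by the Day-7 horizon, *proliferative* if it does, and
  *censored* when its track ends before the horizon without a division.
* proliferative class of a progeny — fewer than 8 cells at Day 4 (under
  three population doublings) is *slow*, more than 16 (over four doublings)
  is *fast*, 8-16 inclusive is *moderate*.
* twin asynchrony — sibling lifetimes differing by strictly more than one
  dataset-wide standard deviation of dividing-cell lifetime.
* colony origin — single-cell-derived (SCD) when exactly one founder's
  progeny makes up the colony, multi-cell-derived (MCD) otherwise.
* colony — a group of at least 50 cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .lineage import LineageForest, progeny_counts, twin_pairs

DAY4_FRAME = 374
DAY7_FRAME = 672
COLONY_MIN_CELLS = 50

#: monitored field-of-view grids (width_mm, height_mm) and the day each
#: expansion happened: 2x2 from the start, 3x3 at Day 2, 4x4 at Day 6
FOV_SIZES_MM = ((1.7, 1.3), (2.6, 2.1), (3.5, 2.6))
FOV_EXPANSION_DAYS = (0.0, 2.0, 6.0)


@dataclass
class FateLabel:
    cell_id: str
    fate: str  # 'proliferative' | 'senescent' | 'censored'
    assessed_at_frame: int
    horizon_frame: int


def classify_fate(
    f: LineageForest,
    reference_frame: int = DAY4_FRAME,
    horizon_frame: int = DAY7_FRAME,
) -> list[FateLabel]:
    """Label every cell alive at the reference frame by its future fate.

    Senescent iff the cell does not divide by the horizon; a cell whose
    track ends before the horizon without division (data end) is censored
    rather than called senescent.
    """
    if reference_frame > f.end_frame:
        raise ValueError(
            f"reference frame {reference_frame} beyond tracked data "
            f"(last frame {f.end_frame})"
        )
    labels = []
    for cid in sorted(f.alive_at(reference_frame)):
        rec = f.records[cid]
        if rec.divided and rec.last_frame + 1 <= horizon_frame:
            fate = "proliferative"
        elif not rec.divided and rec.last_frame < min(horizon_frame, f.end_frame):
            fate = "censored"
        elif rec.last_frame >= horizon_frame and not rec.divided:
            fate = "senescent"
        elif not rec.divided:  # track runs to data end, short of horizon
            fate = "censored"
        else:  # divided, but only after the horizon
            fate = "senescent"
        labels.append(
            FateLabel(
                cell_id=cid,
                fate=fate,
                assessed_at_frame=reference_frame,
                horizon_frame=horizon_frame,
            )
        )
    return labels


@dataclass
class ProgenyClass:
    founder_id: str
    n_cells_at_day4: int
    proliferative_class: str  # 'slow' | 'moderate' | 'fast'


def classify_progeny(counts: Mapping[str, int]) -> list[ProgenyClass]:
    """Slow (< 8 cells), moderate (8-16) or fast (> 16) proliferators."""
    out = []
    for founder, n in sorted(counts.items()):
        if n < 8:
            cls = "slow"
        elif n <= 16:
            cls = "moderate"
        else:
            cls = "fast"
        out.append(
            ProgenyClass(founder_id=founder, n_cells_at_day4=int(n),
                         proliferative_class=cls)
        )
    return out


def classify_progeny_at(
    f: LineageForest, frame: int = DAY4_FRAME
) -> dict[str, ProgenyClass]:
    """Proliferative class of every founder, counted at ``frame``."""
    return {
        pc.founder_id: pc
        for pc in classify_progeny(progeny_counts(f, frame))
    }


@dataclass
class TwinAsynchrony:
    pair: tuple[str, str]
    lifetime_difference_d: float
    asynchronous: bool


def classify_asynchrony(
    f: LineageForest, sd_d: float | None = None
) -> list[TwinAsynchrony]:
    """Flag twin pairs whose lifetimes differ by more than one SD.

    ``sd_d`` defaults to the sample standard deviation of all documented
    dividing-cell lifetimes in the forest (0.27 d in the calibrated model).
    Pairs in which either lifetime is undefined are excluded.  The
    comparison is strict: a difference exactly equal to the SD is
    synchronous.
    """
    lts = {cid: f.lifetime_d(cid) for cid in f.records}
    if sd_d is None:
        defined = [v for v in lts.values() if v is not None]
        if len(defined) < 2:
            raise ValueError("cannot estimate the lifetime SD from < 2 lifetimes")
        sd_d = float(np.std(defined, ddof=1))
    out = []
    for a, b in twin_pairs(f):
        la, lb = lts[a], lts[b]
        if la is None or lb is None:
            continue
        diff = abs(la - lb)
        out.append(
            TwinAsynchrony(pair=(a, b), lifetime_difference_d=diff,
                           asynchronous=diff > sd_d)
        )
    return out


@dataclass
class ColonyOrigin:
    colony_id: str
    n_founders: int
    origin: str  # 'SCD' | 'MCD'
    infiltrated: bool


def classify_origin(
    f: LineageForest,
    members: Iterable[str],
    *,
    colony_id: str = "colony",
    assessment_frame: int | None = None,
) -> ColonyOrigin:
    """Single- vs multi-cell origin of a colony.

    ``n_founders`` counts roots with living descendants among the members at
    the assessment frame (default: all members).  The colony is flagged
    infiltrated when any member descends from a root whose track began after
    frame 0 (a cell that migrated into the field).
    """
    members = list(members)
    if assessment_frame is not None:
        alive = set(f.alive_at(assessment_frame))
        members = [m for m in members if m in alive]
    roots = {f.root_of(m) for m in members}
    started_at_zero = {r for r in roots if f.records[r].birth_frame == 0}
    n_founders = len(started_at_zero) or len(roots)
    return ColonyOrigin(
        colony_id=colony_id,
        n_founders=n_founders,
        origin="SCD" if n_founders == 1 else "MCD",
        infiltrated=len(roots) > len(started_at_zero),
    )


def is_colony(n_cells: int) -> bool:
    """Full colony formation: a group of at least 50 cells."""
    return n_cells >= COLONY_MIN_CELLS


@dataclass
class IsolationScore:
    colony_id: str
    score: int  # 1 (least isolated) .. 5 (most isolated)


def isolation_score(
    first_seen_day_by_fov: Sequence[float | None],
    *,
    colony_id: str = "colony",
) -> IsolationScore:
    """Score how isolated a colony developed, 1-5.

    ``first_seen_day_by_fov`` gives, for each of the three monitored
    field-of-view sizes (2x2 = 1.7x1.3 mm, 3x3 = 2.6x2.1 mm,
    4x4 = 3.5x2.6 mm), the earliest day a non-colony cell appears inside
    that field, or None if never.  Scores: 1 — foreign cells in the initial
    field from the start; 2 — foreign cells entered the initial field within
    the first two days; 3 — foreign cells revealed by the Day-2 expansion;
    4 — foreign cells migrated into the expanded field between Days 2 and 6;
    5 — none revealed until the Day-6 expansion.
    """
    if len(first_seen_day_by_fov) != 3:
        raise ValueError("expected first-seen days for the three FOV sizes")
    t_small, t_mid, _ = first_seen_day_by_fov
    if t_small is not None and t_small <= 0.0:
        score = 1
    elif t_small is not None and t_small <= FOV_EXPANSION_DAYS[1]:
        score = 2
    elif t_mid is not None and t_mid <= FOV_EXPANSION_DAYS[1]:
        score = 3
    elif t_mid is not None and t_mid <= FOV_EXPANSION_DAYS[2]:
        score = 4
    else:
        score = 5
    return IsolationScore(colony_id=colony_id, score=score)


def first_seen_days(
    foreign_tracks,
    center_xy_um: tuple[float, float],
    frame_interval_min: float = 15.0,
) -> list[float | None]:
    """Earliest day a foreign cell enters each monitored field of view.

    ``foreign_tracks`` is an iterable of (frame, x_um, y_um) triples for
    cells not belonging to the colony; fields of view are centred on
    ``center_xy_um``.
    """
    from .lineage import MINUTES_PER_DAY

    first: list[float | None] = [None, None, None]
    cx, cy = center_xy_um
    for frame, x, y in foreign_tracks:
        day = frame * frame_interval_min / MINUTES_PER_DAY
        for i, (w_mm, h_mm) in enumerate(FOV_SIZES_MM):
            if abs(x - cx) <= w_mm * 1e3 / 2 and abs(y - cy) <= h_mm * 1e3 / 2:
                if first[i] is None or day < first[i]:
                    first[i] = day
    return first
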