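"""Lineage forests from object-number matrices.

The tracking exchange format is a frames x cells integer matrix of per-frame
segmentation labels ("object numbers"), with 0 marking frames at which a cell
does not exist.  A cell's column holds non-zero labels over a contiguous
interval of frames; when a cell divides, its column ends and exactly two new
columns begin at the next frame.  This module validates that structure,
reconstructs the lineage forest (parent / twin / generation / fate per cell),
and derives per-cell genealogy quantities such as lifetimes and progeny
counts.

Conventions
-----------
* Generation is 1 for founders (cells present at the first frame, or cells
  whose column begins without a coincident division) and increments by one at
  every division.
* A cell's lifetime spans both its birth and its final frame:
  ``lifetime = (last_frame - birth_frame + 1) * frame_interval``.  It is
  undefined for founders (unknown birth) and for cells that never divide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

MINUTES_PER_DAY = 24.0 * 60.0


@dataclass
class ObjectMatrix:
    """Frames x cells matrix of per-frame object labels (0 = absent).

    Parameters
    ----------
    values : ndarray of int, shape (n_frames, n_cells)
        Per-frame object labels; 0 where the cell does not exist.
    cells : sequence of str
        Unique cell identifiers, one per column.
    frame_interval_min : float
        Minutes between consecutive frames (default 15).
    centroids : dict, optional
        Mapping ``(frame_index, label) -> (x_um, y_um)``.  Required only to
        disambiguate simultaneous divisions during forest construction.
    """

    values: np.ndarray
    cells: Sequence[str]
    frame_interval_min: float = 15.0
    centroids: dict[tuple[int, int], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (frames x cells) array")
        if self.values.shape[1] != len(self.cells):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.cells)} cell ids"
            )
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("cell ids must be unique")
        if (self.values < 0).any():
            raise ValueError("object labels must be >= 0")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        self.cells = list(self.cells)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def support(self, column: int) -> tuple[int, int] | None:
        """(first, last) frame indices with non-zero labels, or None."""
        nz = np.nonzero(self.values[:, column])[0]
        if nz.size == 0:
            return None
        return int(nz[0]), int(nz[-1])


@dataclass
class TrackingError:
    """A single finding from matrix validation.

    kind is one of 'gap' (zeros inside a column's support), 'merge' (a column
    ends without two successor columns), 'orphan' (a column starts without an
    attributable division), or 'late_sibling' (a sibling column starting one
    frame late, reported only when the slack option is enabled).
    """

    kind: str
    frame: int
    cells: tuple[str, ...]
    message: str


@dataclass
class CellRecord:
    cell_id: str
    parent_id: str | None
    twin_id: str | None
    generation: int
    birth_frame: int
    last_frame: int
    divided: bool
    children: list[str] = field(default_factory=list)


@dataclass
class LineageForest:
    """Collection of cell records forming trees rooted at founders."""

    records: dict[str, CellRecord]
    roots: list[str]
    frame_interval_min: float = 15.0

    def __post_init__(self) -> None:
        for rec in self.records.values():
            if rec.last_frame < rec.birth_frame:
                raise ValueError(f"cell {rec.cell_id}: last_frame < birth_frame")

    @property
    def n_divisions(self) -> int:
        return sum(1 for r in self.records.values() if r.divided)

    @property
    def end_frame(self) -> int:
        return max(r.last_frame for r in self.records.values())

    def alive_at(self, frame: int) -> list[str]:
        return [
            r.cell_id
            for r in self.records.values()
            if r.birth_frame <= frame <= r.last_frame
        ]

    def root_of(self, cell_id: str) -> str:
        rec = self.records[cell_id]
        while rec.parent_id is not None:
            rec = self.records[rec.parent_id]
        return rec.cell_id

    def lifetime_d(self, cell_id: str) -> float | None:
        """Lifetime in days; None for founders and never-dividing cells."""
        rec = self.records[cell_id]
        if rec.generation == 1 or not rec.divided:
            return None
        n = rec.last_frame - rec.birth_frame + 1
        return n * self.frame_interval_min / MINUTES_PER_DAY


class AmbiguousDivisionError(ValueError):
    """Simultaneous divisions that cannot be paired without centroids."""


def _column_bounds(m: ObjectMatrix) -> list[tuple[int, int] | None]:
    return [m.support(j) for j in range(m.n_cells)]


def validate_matrix(
    m: ObjectMatrix, *, late_sibling_slack: bool = False
) -> list[TrackingError]:
    """Check the division bookkeeping of an object matrix.

    Returns the complete list of findings (never stops at the first).  An
    empty list means every column's support is contiguous and every column
    ending before the final frame is matched by exactly two columns starting
    at the next frame.  Columns that begin mid-experiment at a frame where no
    column ended are treated as migrating-in founders, not errors.

    With ``late_sibling_slack`` a missing sibling that appears exactly one
    frame late is reported as a 'late_sibling' finding instead of a 'merge';
    forest construction can then absorb it.
    """
    findings: list[TrackingError] = []
    bounds = _column_bounds(m)

    for j, b in enumerate(bounds):
        if b is None:
            continue
        first, last = b
        col = m.values[first : last + 1, j]
        zero_frames = np.nonzero(col == 0)[0]
        if zero_frames.size:
            # one finding per run of internal zeros
            runs = np.split(zero_frames, np.nonzero(np.diff(zero_frames) > 1)[0] + 1)
            for run in runs:
                f = int(run[0]) + first
                findings.append(
                    TrackingError(
                        "gap",
                        f,
                        (m.cells[j],),
                        f"column {m.cells[j]} has zeros inside its support "
                        f"starting at frame {f}",
                    )
                )

    enders: dict[int, list[int]] = {}
    starters: dict[int, list[int]] = {}
    for j, b in enumerate(bounds):
        if b is None:
            continue
        first, last = b
        if last < m.n_frames - 1:
            enders.setdefault(last, []).append(j)
        if first > 0:
            starters.setdefault(first, []).append(j)

    claimed_late: set[int] = set()
    for t, ends in sorted(enders.items()):
        starts = starters.get(t + 1, [])
        deficit = 2 * len(ends) - len(starts)
        if deficit > 0 and late_sibling_slack:
            late = [
                j
                for j in starters.get(t + 2, [])
                if not enders.get(t + 1) and j not in claimed_late
            ]
            for j in late[:deficit]:
                claimed_late.add(j)
                findings.append(
                    TrackingError(
                        "late_sibling",
                        t + 2,
                        (m.cells[j],),
                        f"column {m.cells[j]} starts one frame after the "
                        f"division at frame {t}",
                    )
                )
            deficit -= min(deficit, len(late))
        if deficit > 0:
            names = tuple(m.cells[j] for j in ends)
            for _ in range(deficit):
                findings.append(
                    TrackingError(
                        "merge",
                        t,
                        names,
                        f"division ending at frame {t} has "
                        f"{len(starts)} successor column(s), expected "
                        f"{2 * len(ends)}",
                    )
                )
        elif deficit < 0:
            names = tuple(m.cells[j] for j in starts)
            for _ in range(-deficit):
                findings.append(
                    TrackingError(
                        "orphan",
                        t + 1,
                        names,
                        f"{len(starts)} column(s) start at frame {t + 1} but "
                        f"only {2 * len(ends)} can be attributed to divisions",
                    )
                )
    return findings


def build_forest(
    m: ObjectMatrix, *, late_sibling_slack: bool = False
) -> LineageForest:
    """Reconstruct the lineage forest from a validated object matrix.

    Founders are columns live at the first frame plus columns that begin at a
    frame where no division ended (migrating-in cells); both get generation 1.
    When two or more divisions end at the same frame the daughter columns are
    attributed to parents by minimising the summed parent-end-centroid to
    daughter-start-centroid distance, which requires the matrix to carry
    centroids; an :class:`AmbiguousDivisionError` is raised otherwise.
    """
    problems = [
        e
        for e in validate_matrix(m, late_sibling_slack=late_sibling_slack)
        if e.kind != "late_sibling"
    ]
    if problems:
        raise ValueError(
            f"matrix has {len(problems)} tracking error(s); first: "
            f"{problems[0].message}"
        )

    bounds = _column_bounds(m)
    live = [(j, b) for j, b in enumerate(bounds) if b is not None]

    enders: dict[int, list[int]] = {}
    for j, (first, last) in live:
        if last < m.n_frames - 1:
            enders.setdefault(last, []).append(j)

    records: dict[str, CellRecord] = {}
    for j, (first, last) in live:
        records[m.cells[j]] = CellRecord(
            cell_id=m.cells[j],
            parent_id=None,
            twin_id=None,
            generation=1,
            birth_frame=first,
            last_frame=last,
            divided=False,
        )

    # attribute daughters to parents at every division boundary
    slack = 2 if late_sibling_slack else 1
    consumed: set[int] = set()
    for t, ends in sorted(enders.items()):
        starts = sorted(
            (
                j
                for j, (first, _) in live
                if t + 1 <= first <= t + slack and j not in consumed
            ),
            key=lambda j: (bounds[j][0], j),
        )[: 2 * len(ends)]
        if len(starts) != 2 * len(ends):
            raise ValueError(
                f"division boundary at frame {t}: {len(starts)} daughters "
                f"for {len(ends)} parents"
            )
        consumed.update(starts)
        if len(ends) == 1:
            pairing = {ends[0]: starts}
        else:
            if m.centroids is None:
                raise AmbiguousDivisionError(
                    f"{len(ends)} simultaneous divisions end at frame {t} "
                    "and the matrix carries no centroids"
                )
            cost = np.empty((2 * len(ends), len(starts)))
            for i, pj in enumerate(ends):
                p_xy = m.centroids[(t, int(m.values[t, pj]))]
                for k, dj in enumerate(starts):
                    dfirst = bounds[dj][0]
                    d_xy = m.centroids[(dfirst, int(m.values[dfirst, dj]))]
                    cost[2 * i, k] = cost[2 * i + 1, k] = np.hypot(
                        p_xy[0] - d_xy[0], p_xy[1] - d_xy[1]
                    )
            rows, cols = linear_sum_assignment(cost)
            pairing = {pj: [] for pj in ends}
            for r, c in zip(rows, cols):
                pairing[ends[r // 2]].append(starts[c])
        for pj, daughters in pairing.items():
            parent = records[m.cells[pj]]
            parent.divided = True
            a, b = (records[m.cells[dj]] for dj in daughters)
            parent.children = [a.cell_id, b.cell_id]
            a.parent_id = b.parent_id = parent.cell_id
            a.twin_id, b.twin_id = b.cell_id, a.cell_id

    roots = [r.cell_id for r in records.values() if r.parent_id is None]
    # generations by breadth-first descent from the roots
    stack = list(roots)
    while stack:
        cid = stack.pop()
        rec = records[cid]
        for ch in rec.children:
            records[ch].generation = rec.generation + 1
            stack.append(ch)

    roots.sort(key=lambda c: (records[c].birth_frame, c))
    return LineageForest(
        records=records, roots=roots, frame_interval_min=m.frame_interval_min
    )


def lifetimes(f: LineageForest) -> dict[str, float | None]:
    """Per-cell lifetime in days; None where undefined.

    Undefined for generation-1 cells (their birth precedes observation) and
    for cells that never divide within the tracked window.
    """
    return {cid: f.lifetime_d(cid) for cid in f.records}


def twin_pairs(f: LineageForest) -> list[tuple[str, str]]:
    """One unordered (cell, twin) pair per division, sorted for determinism."""
    pairs = []
    for rec in f.records.values():
        if rec.divided:
            pairs.append(tuple(sorted(rec.children)))
    return sorted(pairs)


def progeny_counts(f: LineageForest, frame: int) -> dict[str, int]:
    """Living-cell count at ``frame``, grouped by founder (root ancestor)."""
    counts = {root: 0 for root in f.roots}
    for cid in f.alive_at(frame):
        counts[f.root_of(cid)] += 1
    return counts


def descendant_counts(f: LineageForest) -> dict[str, int]:
    """Total number of descendants (progeny) of every cell."""
    order: list[str] = []
    stack = list(f.roots)
    while stack:
        cid = stack.pop()
        order.append(cid)
        stack.extend(f.records[cid].children)
    counts = {cid: 0 for cid in f.records}
    for cid in reversed(order):
        for ch in f.records[cid].children:
            counts[cid] += 1 + counts[ch]
    return counts
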