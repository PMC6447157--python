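"""Agent-based simulator of sparse colony-formation experiments.

Emulates the statistical structure of a colony-forming-unit assay followed by
15-minute time-lapse imaging: founders attach sparsely (~30 cells/cm^2), wait
roughly a day before their first division, then proliferate with stochastic
cell-cycle times (dividing-cell lifetimes ~0.83 +/- 0.27 days), while each
daughter independently becomes senescent with a small probability.  Senescent
cells never divide and keep growing in spread area; proliferating cells shrink
from generation to generation.  Cells migrate as persistent random walks
reflected at the field borders, and media exchanges (first one near Day 4,
then twice weekly) inflate the variability of subsequent lifetime and
birth-area draws.

The simulator produces ground-truth lineages, per-frame label images, and the
frames x cells object-number matrix that the analysis pipeline ingests, so
every downstream stage can be exercised without raw image data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from skimage.draw import ellipse as draw_ellipse

from .lineage import MINUTES_PER_DAY, ObjectMatrix

#: default media-exchange schedule: Day 4, then twice weekly (every 3.5 days)
DEFAULT_MEDIA_EXCHANGES = (374, 710, 1046)

_MIN_AREA_UM2 = 100.0


@dataclass
class SimulationConfig:
    """All generative parameters of the synthetic colony model.

    Defaults are calibrated to the summary statistics of a 14-day sparse
    BMSC colony-formation experiment: 15-min frames, dividing-cell lifetime
    0.83 +/- 0.27 d, ~1 d first-generation lag, per-daughter senescence
    probability tuned so ~16% of Day-4 cells are senescent, and spread-area /
    migration parameters tuned so Day-7 colonies average ~12.7% confluency
    and ~1.9 mm approximate diameter.
    """

    frame_interval_min: float = 15.0
    n_frames: int = 1344
    field_width_um: float = 4300.0
    field_height_um: float = 3300.0
    pixel_size_um: float = 0.6467
    seed_density_cells_per_cm2: float = 30.0
    n_founders: int | None = None
    lifetime_mean_d: float = 0.83
    lifetime_sd_d: float = 0.27
    founder_lag_mean_d: float = 1.0
    p_senescent_daughter: float = 0.08
    area_birth_um2: float = 3500.0
    area_growth_rate_um2_per_d: float = 4600.0
    generation_shrink_factor: float = 0.9
    senescent_growth_rate_um2_per_d: float = 1200.0
    migration_step_sd_um: float = 13.5
    migration_persistence: float = 0.6
    render_aspect_ratio: float = 2.5
    media_exchange_frames: tuple[int, ...] = DEFAULT_MEDIA_EXCHANGES
    media_perturbation_sd: float = 0.15
    rng_seed: int = 0

    def __post_init__(self) -> None:
        finite_nonneg = {
            "frame_interval_min": self.frame_interval_min,
            "field_width_um": self.field_width_um,
            "field_height_um": self.field_height_um,
            "pixel_size_um": self.pixel_size_um,
            "seed_density_cells_per_cm2": self.seed_density_cells_per_cm2,
            "lifetime_mean_d": self.lifetime_mean_d,
            "lifetime_sd_d": self.lifetime_sd_d,
            "founder_lag_mean_d": self.founder_lag_mean_d,
            "area_birth_um2": self.area_birth_um2,
            "area_growth_rate_um2_per_d": self.area_growth_rate_um2_per_d,
            "generation_shrink_factor": self.generation_shrink_factor,
            "senescent_growth_rate_um2_per_d": self.senescent_growth_rate_um2_per_d,
            "migration_step_sd_um": self.migration_step_sd_um,
            "media_perturbation_sd": self.media_perturbation_sd,
        }
        for name, v in finite_nonneg.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.generation_shrink_factor <= 0:
            raise ValueError("generation_shrink_factor must be > 0")
        if not 0.0 <= self.p_senescent_daughter <= 1.0:
            raise ValueError("p_senescent_daughter must be in [0, 1]")
        if not 0.0 <= self.migration_persistence < 1.0:
            raise ValueError("migration_persistence must be in [0, 1)")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def frames_per_day(self) -> float:
        return MINUTES_PER_DAY / self.frame_interval_min

    def resolved_founders(self) -> int:
        if self.n_founders is not None:
            if self.n_founders < 1:
                raise ValueError("n_founders must be >= 1")
            return self.n_founders
        area_cm2 = (self.field_width_um / 1e4) * (self.field_height_um / 1e4)
        n = round(self.seed_density_cells_per_cm2 * area_cm2)
        if n < 1:
            raise ValueError(
                f"field of {area_cm2:.4f} cm^2 at "
                f"{self.seed_density_cells_per_cm2} cells/cm^2 seeds no cells; "
                "enlarge the field or set n_founders"
            )
        return n


@dataclass
class CellAgent:
    """Ground truth for one simulated cell."""

    cell_id: int
    parent_id: int | None
    generation: int
    birth_frame: int
    end_frame: int
    fate: str  # 'divided' | 'senescent' | 'alive_at_end'
    x_um: np.ndarray  # per-frame positions, frames birth_frame..end_frame
    y_um: np.ndarray
    area_um2: np.ndarray
    orientation: float = 0.0

    def alive_at(self, frame: int) -> bool:
        return self.birth_frame <= frame <= self.end_frame

    def position(self, frame: int) -> tuple[float, float]:
        i = frame - self.birth_frame
        return float(self.x_um[i]), float(self.y_um[i])

    def area(self, frame: int) -> float:
        return float(self.area_um2[frame - self.birth_frame])


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    agents: dict[int, CellAgent]
    founders: list[int]

    def alive_at(self, frame: int) -> list[int]:
        return sorted(
            cid for cid, a in self.agents.items() if a.alive_at(frame)
        )

    def labels_at(self, frame: int) -> dict[int, int]:
        """Per-frame object numbers: living cells in id order get 1..k."""
        return {cid: i + 1 for i, cid in enumerate(self.alive_at(frame))}


def _reflect(p: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (handles multiple bounces)."""
    span = hi - lo
    q = np.mod(p - lo, 2 * span)
    return lo + np.where(q > span, 2 * span - q, q)


def _draw_lifetime_d(
    rng: np.random.Generator, cfg: SimulationConfig, noise_scale: float
) -> float:
    """Dividing-cell lifetime in days, truncated at one frame."""
    lower = cfg.frame_interval_min / MINUTES_PER_DAY
    if cfg.lifetime_sd_d == 0:
        lt = cfg.lifetime_mean_d
    else:
        a = (lower - cfg.lifetime_mean_d) / cfg.lifetime_sd_d
        lt = float(
            sps.truncnorm.rvs(
                a, np.inf, loc=cfg.lifetime_mean_d, scale=cfg.lifetime_sd_d,
                random_state=rng,
            )
        )
    if noise_scale > 0:
        lt *= math.exp(rng.normal(0.0, noise_scale))
    return max(lt, lower)


def _walk(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    x0: float,
    y0: float,
    n_steps: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Persistent (AR(1)-velocity) random walk reflected at field borders."""
    if n_steps == 0:
        return np.array([x0]), np.array([y0])
    phi = cfg.migration_persistence
    sd = cfg.migration_step_sd_um
    eta = rng.normal(0.0, sd, size=(n_steps, 2))
    v = np.empty((n_steps, 2))
    v[0] = rng.normal(0.0, sd, size=2) if phi > 0 else eta[0]
    innov = math.sqrt(1.0 - phi * phi)
    for i in range(1, n_steps):
        v[i] = phi * v[i - 1] + innov * eta[i]
    xy = np.concatenate([[[x0, y0]], [[x0, y0]] + np.cumsum(v, axis=0)])
    x = _reflect(xy[:, 0], 0.0, cfg.field_width_um)
    y = _reflect(xy[:, 1], 0.0, cfg.field_height_um)
    return x, y


def simulate(config: SimulationConfig) -> SimulatedExperiment:
    """Run the agent-based colony model.

    Reproducible for a fixed ``rng_seed``: agents are processed in a
    deterministic first-in-first-out order and all randomness flows from one
    :class:`numpy.random.Generator`.
    """
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    fpd = cfg.frames_per_day
    dt_d = 1.0 / fpd
    exchanges = sorted(cfg.media_exchange_frames)

    def noise_scale_at(frame: int) -> float:
        k = sum(1 for e in exchanges if frame > e)
        return cfg.media_perturbation_sd * math.sqrt(k) if k else 0.0

    n_found = cfg.resolved_founders()
    agents: dict[int, CellAgent] = {}
    next_id = 1
    # (birth_frame, id, parent_id, generation, birth_area, birth_x, birth_y)
    queue: list[tuple[int, int, int | None, int, float, float, float]] = []
    for _ in range(n_found):
        x0 = rng.uniform(0.0, cfg.field_width_um)
        y0 = rng.uniform(0.0, cfg.field_height_um)
        queue.append((0, next_id, None, 1, cfg.area_birth_um2, x0, y0))
        next_id += 1
    founders = [q[1] for q in queue]

    qi = 0
    while qi < len(queue):
        birth, cid, parent, gen, area0, x0, y0 = queue[qi]
        qi += 1
        scale = noise_scale_at(birth)
        if gen == 1:
            senescent = False
        else:
            senescent = rng.random() < cfg.p_senescent_daughter
        if senescent:
            end = cfg.n_frames - 1
            fate = "senescent"
        else:
            lt_d = _draw_lifetime_d(rng, cfg, scale)
            if gen == 1:
                lt_d += cfg.founder_lag_mean_d
            lt_frames = max(1, round(lt_d * fpd))
            end = birth + lt_frames - 1
            if end >= cfg.n_frames - 1:
                end = cfg.n_frames - 1
                fate = "alive_at_end"
            else:
                fate = "divided"
        orientation = rng.uniform(0.0, math.pi)
        x, y = _walk(rng, cfg, x0, y0, end - birth)
        rate = (
            cfg.senescent_growth_rate_um2_per_d
            if senescent
            else cfg.area_growth_rate_um2_per_d
        )
        t_rel = np.arange(end - birth + 1) * dt_d
        area = np.maximum(area0 + rate * t_rel, _MIN_AREA_UM2)
        agents[cid] = CellAgent(
            cell_id=cid,
            parent_id=parent,
            generation=gen,
            birth_frame=birth,
            end_frame=end,
            fate=fate,
            x_um=x,
            y_um=y,
            area_um2=area,
            orientation=orientation,
        )
        if fate == "divided":
            a_end = float(area[-1])
            px, py = float(x[-1]), float(y[-1])
            r = math.sqrt(a_end / math.pi)
            theta = rng.uniform(0.0, 2.0 * math.pi)
            child_scale = noise_scale_at(end + 1)
            for sign in (+1.0, -1.0):
                a_child = cfg.generation_shrink_factor * a_end / 2.0
                if child_scale > 0:
                    a_child *= math.exp(rng.normal(0.0, child_scale))
                a_child = max(a_child, _MIN_AREA_UM2)
                cx = float(
                    _reflect(
                        np.array([px + sign * r * math.cos(theta)]),
                        0.0,
                        cfg.field_width_um,
                    )[0]
                )
                cy = float(
                    _reflect(
                        np.array([py + sign * r * math.sin(theta)]),
                        0.0,
                        cfg.field_height_um,
                    )[0]
                )
                queue.append((end + 1, next_id, cid, gen + 1, a_child, cx, cy))
                next_id += 1

    return SimulatedExperiment(config=cfg, agents=agents, founders=founders)


def render_labels(
    exp: SimulatedExperiment, frame: int, aspect_ratio: float | None = None
) -> np.ndarray:
    """Draw every living cell as a filled, labelled ellipse.

    Labels are the per-frame object numbers (living cells in id order get
    1..k).  Where ellipses overlap, contested pixels go to the nearer
    centroid, and every living cell is guaranteed at least one pixel.
    Returns a uint16 label image of shape (height_px, width_px).
    """
    cfg = exp.config
    if not 0 <= frame < cfg.n_frames:
        raise ValueError(f"frame {frame} outside experiment (0..{cfg.n_frames - 1})")
    ar = cfg.render_aspect_ratio if aspect_ratio is None else aspect_ratio
    h = int(round(cfg.field_height_um / cfg.pixel_size_um))
    w = int(round(cfg.field_width_um / cfg.pixel_size_um))
    owner = np.zeros((h, w), dtype=np.uint16)
    dist = np.full((h, w), np.inf, dtype=np.float32)
    labels = exp.labels_at(frame)
    centers: dict[int, tuple[int, int]] = {}
    for cid, label in labels.items():
        agent = exp.agents[cid]
        x, y = agent.position(frame)
        a = agent.area(frame)
        r_px = y / cfg.pixel_size_um
        c_px = x / cfg.pixel_size_um
        # semi-axes preserving the target area at the configured aspect ratio
        semi_maj = math.sqrt(a * ar / math.pi) / cfg.pixel_size_um
        semi_min = math.sqrt(a / (ar * math.pi)) / cfg.pixel_size_um
        rr, cc = draw_ellipse(
            r_px, c_px, max(semi_min, 0.8), max(semi_maj, 0.8),
            shape=(h, w), rotation=agent.orientation,
        )
        if rr.size == 0 and not (0 <= r_px < h and 0 <= c_px < w):
            raise ValueError(
                f"cell {cid} lies fully outside the field at frame {frame}"
            )
        d = (rr - r_px) ** 2 + (cc - c_px) ** 2
        take = d < dist[rr, cc]
        owner[rr[take], cc[take]] = label
        dist[rr[take], cc[take]] = d[take]
        centers[label] = (
            min(max(int(round(r_px)), 0), h - 1),
            min(max(int(round(c_px)), 0), w - 1),
        )
    # overlap resolution can strip a small cell entirely; restore one pixel
    present = np.bincount(owner.ravel(), minlength=len(labels) + 1)
    for label, (ri, ci) in centers.items():
        if present[label] == 0:
            owner[ri, ci] = label
    return owner


def export_tracking_matrix(exp: SimulatedExperiment) -> ObjectMatrix:
    """Ground-truth object-number matrix (frames x cells, 0 = absent)."""
    cfg = exp.config
    ids = sorted(exp.agents)
    values = np.zeros((cfg.n_frames, len(ids)), dtype=np.int64)
    centroids: dict[tuple[int, int], tuple[float, float]] = {}
    col = {cid: j for j, cid in enumerate(ids)}
    for frame in range(cfg.n_frames):
        for cid, label in exp.labels_at(frame).items():
            values[frame, col[cid]] = label
            centroids[(frame, label)] = exp.agents[cid].position(frame)
    return ObjectMatrix(
        values=values,
        cells=[str(cid) for cid in ids],
        frame_interval_min=cfg.frame_interval_min,
        centroids=centroids,
    )


@dataclass
class CorruptionResult:
    """Corrupted matrix plus bookkeeping of every injected error."""

    matrix: ObjectMatrix
    injected: list[dict] = field(default_factory=list)


def corrupt_matrix(
    m: ObjectMatrix,
    *,
    n_gaps: int = 0,
    n_merges: int = 0,
    n_orphans: int = 0,
    rng_seed: int = 0,
) -> CorruptionResult:
    """Inject the tracking-error classes that manual curation must catch.

    gap: a zero inside a column's support (a cell missed for one frame).
    merge: one daughter column of a division deleted (two touching cells
    segmented as one, so a division appears to have a single successor).
    orphan: a duplicate daughter column added at an existing division
    boundary (an extra column with no attributable parent).

    An identity specification returns an unchanged copy of the matrix.
    """
    rng = np.random.default_rng(rng_seed)
    values = m.values.copy()
    cells = list(m.cells)
    injected: list[dict] = []

    def supports() -> list[tuple[int, int, int] | None]:
        out = []
        for j in range(values.shape[1]):
            nz = np.nonzero(values[:, j])[0]
            out.append((j, int(nz[0]), int(nz[-1])) if nz.size else None)
        return out

    sup = [s for s in supports() if s is not None]
    gap_candidates = [s for s in sup if s[2] - s[1] >= 2]
    if n_gaps > len(gap_candidates):
        raise ValueError("not enough long columns to host the requested gaps")
    for idx in rng.choice(len(gap_candidates), size=n_gaps, replace=False):
        j, first, last = gap_candidates[int(idx)]
        f = int(rng.integers(first + 1, last))
        values[f, j] = 0
        injected.append({"kind": "gap", "frame": f, "cell": cells[j]})

    n_frames = values.shape[0]
    for _ in range(n_merges):
        sup_now = supports()
        # divisions whose boundary has exactly one ender and a leaf daughter
        options = []
        for s in sup_now:
            if s is None:
                continue
            j, first, last = s
            if last >= n_frames - 1:
                continue
            daughters = [
                t
                for t in sup_now
                if t is not None and t[1] == last + 1 and t[2] == n_frames - 1
            ]
            if daughters:
                options.append((j, last, daughters))
        if not options:
            raise ValueError("no division with a leaf daughter left to merge")
        j, last, daughters = options[int(rng.integers(len(options)))]
        dj = daughters[int(rng.integers(len(daughters)))][0]
        values[:, dj] = 0
        injected.append(
            {"kind": "merge", "frame": last, "cell": cells[j], "deleted": cells[dj]}
        )

    for _ in range(n_orphans):
        sup_now = [s for s in supports() if s is not None]
        boundaries = sorted(
            {s[1] for s in sup_now if s[1] > 0}
            & {s[2] + 1 for s in sup_now if s[2] < n_frames - 1}
        )
        if not boundaries:
            raise ValueError("no division boundary available for an orphan")
        start = boundaries[int(rng.integers(len(boundaries)))]
        template = [s for s in sup_now if s[1] == start][0]
        end = template[2]
        new_col = np.zeros(n_frames, dtype=values.dtype)
        for f in range(start, end + 1):
            new_col[f] = values[f].max() + 1
        values = np.column_stack([values, new_col])
        new_id = f"orphan_{len(cells)}"
        cells.append(new_id)
        injected.append({"kind": "orphan", "frame": start, "cell": new_id})

    out = ObjectMatrix(
        values=values,
        cells=cells,
        frame_interval_min=m.frame_interval_min,
        centroids=m.centroids,
    )
    return CorruptionResult(matrix=out, injected=injected)
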