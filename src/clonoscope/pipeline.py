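"""End-to-end orchestration: simulate/ingest -> lineage -> measure ->
classify -> stats -> viz, with per-stage logging and deterministic outputs
for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .classify import (
    classify_asynchrony,
    classify_fate,
    classify_origin,
    classify_progeny_at,
    is_colony,
)
from .lineage import build_forest, progeny_counts, validate_matrix
from .measure import build_feature_table, colony_hull_metrics, tracks_from_experiment
from .sim_colony import SimulationConfig, export_tracking_matrix, render_labels, simulate
from .stats import correlation_matrix, generation_area_trend, generation_dispersion, pca_embed
from .viz import glyph_to_svg, render_glyph, render_tree, tree_to_svg

log = logging.getLogger("clonoscope")


@dataclass
class PipelineConfig:
    """Run configuration; day-frame indices follow the 374/672/960 labelling."""

    simulation: SimulationConfig | None = None
    matrix_path: str | None = None
    centroid_path: str | None = None
    frame_interval_min: float = 15.0
    pixel_size_um: float = 0.6467
    day4_frame: int = 374
    day7_frame: int = 672
    day10_frame: int = 960
    neighbor_threshold_px: float = 15.0
    alpha: float = 0.05
    rng_seed: int = 0
    write_images: bool = False
    run_stats: bool = True
    run_viz: bool = True

    def __post_init__(self) -> None:
        if not self.day4_frame < self.day7_frame < self.day10_frame:
            raise ValueError("day frames must be strictly increasing")
        if self.neighbor_threshold_px <= 0:
            raise ValueError("neighbor_threshold_px must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        if self.simulation is not None:
            raw["simulation"] = dataclasses.asdict(self.simulation)
            raw["simulation"]["media_exchange_frames"] = list(
                self.simulation.media_exchange_frames
            )
        Path(path).write_text(yaml.safe_dump(raw), encoding="utf-8")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run all enabled stages and write the report bundle to ``out_dir``.

    Returns a dict of in-memory artifacts (matrix, forest, feature table,
    reports).  Reruns with the same config and seed produce byte-identical
    CSV/JSON outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Any] = {}

    # --- simulate / ingest -------------------------------------------------
    tracks = None
    exp = None
    if config.simulation is not None:
        sim_cfg = dataclasses.replace(config.simulation, rng_seed=config.rng_seed)
        exp = simulate(sim_cfg)
        log.info("simulated %d cells from %d founders",
                 len(exp.agents), len(exp.founders))
        matrix = export_tracking_matrix(exp)
        tracks = tracks_from_experiment(exp)
        cio.write_object_matrix(matrix, out / "object_matrix.csv",
                                out / "centroids.csv")
        if config.write_images:
            frames = {
                f: render_labels(exp, f)
                for f in range(sim_cfg.n_frames)
            }
            cio.write_label_stack(
                [frames[f] for f in sorted(frames)], out / "labels.tif"
            )
    elif config.matrix_path is not None:
        matrix = cio.read_object_matrix(
            config.matrix_path,
            frame_interval_min=config.frame_interval_min,
            centroid_path=config.centroid_path,
        )
        log.info("ingested matrix with %d frames x %d cells",
                 matrix.n_frames, matrix.n_cells)
        if matrix.centroids:
            rows = []
            for j, cell in enumerate(matrix.cells):
                for f in range(matrix.n_frames):
                    lab = int(matrix.values[f, j])
                    if lab and (f, lab) in matrix.centroids:
                        x, y = matrix.centroids[(f, lab)]
                        rows.append(
                            {"cell_id": cell, "frame": f, "x_um": x,
                             "y_um": y, "area_um2": np.nan}
                        )
            tracks = pd.DataFrame(rows)
    else:
        raise ValueError("config needs either a simulation or a matrix_path")

    # --- lineage -----------------------------------------------------------
    errors = validate_matrix(matrix)
    cio.write_report(
        [dataclasses.asdict(e) for e in errors], out / "tracking_errors.json"
    )
    if errors:
        log.warning("matrix failed validation with %d finding(s)", len(errors))
        raise ValueError(
            f"{len(errors)} tracking error(s); fix the matrix before analysis"
        )
    forest = build_forest(matrix)
    log.info("forest: %d cells, %d founders, %d divisions",
             len(forest.records), len(forest.roots), forest.n_divisions)
    cio.write_forest(forest, out / "lineage.json")
    artifacts.update(matrix=matrix, forest=forest, experiment=exp)

    end = forest.end_frame
    day4 = min(config.day4_frame, end)
    day7 = min(config.day7_frame, end)

    # --- classify ----------------------------------------------------------
    fates = {
        fl.cell_id: fl.fate for fl in classify_fate(forest, day4, day7)
    }
    prog = classify_progeny_at(forest, day4)
    origins = [
        classify_origin(forest, [c for c in forest.records
                                 if forest.root_of(c) == root],
                        colony_id=root)
        for root in forest.roots
    ]
    asyn = classify_asynchrony(forest) if forest.n_divisions >= 3 else []
    day7_counts = progeny_counts(forest, day7)
    classification = {
        "fates": fates,
        "progeny_classes": {
            k: dataclasses.asdict(v) for k, v in sorted(prog.items())
        },
        "origins": [dataclasses.asdict(o) for o in origins],
        "asynchrony": [dataclasses.asdict(a) for a in asyn],
        "is_colony_at_day7": {
            root: is_colony(n) for root, n in sorted(day7_counts.items())
        },
    }
    cio.write_report(classification, out / "classification.json")
    artifacts["classification"] = classification

    # --- measure -----------------------------------------------------------
    table = None
    if tracks is not None and tracks["area_um2"].notna().all():
        table = build_feature_table(
            forest, tracks, fates=fates,
            progeny_classes={k: v.proliferative_class for k, v in prog.items()},
        )
        cio.write_feature_table(table, out / "features.csv",
                                out / "features_mask.csv")
        artifacts["features"] = table
        metrics = {}
        for root in forest.roots:
            ids = [c for c in forest.alive_at(day7)
                   if forest.root_of(c) == root]
            if len(ids) < 3:
                continue
            sub = tracks[(tracks.cell_id.isin(ids)) & (tracks.frame == day7)]
            metrics[root] = dataclasses.asdict(
                colony_hull_metrics(
                    positions=sub[["x_um", "y_um"]].to_numpy(),
                    areas=sub["area_um2"].to_numpy(),
                )
            )
        cio.write_report(metrics, out / "colony_metrics_day7.json")
        artifacts["colony_metrics_day7"] = metrics

    # --- stats -------------------------------------------------------------
    if config.run_stats and table is not None:
        corr = correlation_matrix(table, alpha=config.alpha)
        cio.write_report(corr.pairs, out / "correlations.csv")
        trends = generation_area_trend(table)
        cio.write_report(
            pd.DataFrame([dataclasses.asdict(t) for t in trends]),
            out / "generation_area_trend.csv",
        )
        disp = generation_dispersion(forest, day4)
        cio.write_report(disp, out / "generation_dispersion_day4.json")
        artifacts["correlations"] = corr
        artifacts["trends"] = trends
        n_complete = (table.mask.all(axis=1) & table.data.notna().all(axis=1)).sum()
        if n_complete >= 6:
            emb = pca_embed(table, random_state=config.rng_seed)
            cio.write_report(
                emb.scores.join(emb.cluster_labels).reset_index(),
                out / "pca_scores.csv",
            )
            artifacts["embedding"] = emb
        log.info("stats: %d property pairs, %d trends", corr.m, len(trends))

    # --- viz ---------------------------------------------------------------
    if config.run_viz and tracks is not None:
        areas = {
            str(cid): grp.sort_values("frame")["area_um2"].tolist()
            for cid, grp in tracks.groupby("cell_id")
        }
        tree = render_tree(forest, areas)
        tree_to_svg(tree, out / "lineage_tree.svg")
        alive = forest.alive_at(day4)
        snap = tracks[(tracks.cell_id.isin(alive)) & (tracks.frame == day4)]
        if len(snap):
            glyph = render_glyph(
                positions={r.cell_id: (r.x_um, r.y_um)
                           for r in snap.itertuples()},
                areas={r.cell_id: r.area_um2 for r in snap.itertuples()},
                generations={c: forest.records[c].generation for c in alive},
                senescent={c: fates.get(c) == "senescent" for c in alive},
                progeny_classes={k: v.proliferative_class
                                 for k, v in prog.items()},
            )
            glyph_to_svg(glyph, out / "colony_glyph_day4.svg")

    cfg_out = out / "effective_config.yaml"
    config.to_yaml(cfg_out)
    return artifacts
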