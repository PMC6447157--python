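"""Parameter-recovery experiments on the synthetic colony model.

These routines run the full analysis pipeline on freshly simulated
single-founder experiments and recover the calibrated population summaries:
dividing-cell lifetime moments, the Day-4 senescent fraction, and Day-7
whole-colony geometry (confluency and circle-equivalent diameter).  They are
the package's self-consistency checks: the estimates travel through the
exported object matrix, the rebuilt lineage forest, the rendered label
images and the hull metrics, never through the generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import DAY4_FRAME, DAY7_FRAME, classify_fate
from .lineage import LineageForest, build_forest
from .measure import colony_hull_metrics
from .sim_colony import (
    SimulationConfig,
    SimulatedExperiment,
    export_tracking_matrix,
    render_labels,
    simulate,
)


def colony_config(rng_seed: int, n_frames: int = DAY7_FRAME + 1) -> SimulationConfig:
    """Default-calibrated single-founder experiment tracked through Day 7."""
    return SimulationConfig(n_founders=1, n_frames=n_frames, rng_seed=rng_seed)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def simulate_colonies(
    n_colonies: int, seed: int, n_frames: int = DAY7_FRAME + 1
) -> list[tuple[SimulatedExperiment, LineageForest]]:
    """Simulate independent single-founder colonies and rebuild each lineage
    forest from its exported object matrix (the round-trip the real pipeline
    performs)."""
    out = []
    for s in _spawn_seeds(seed, n_colonies):
        exp = simulate(colony_config(s, n_frames))
        forest = build_forest(export_tracking_matrix(exp))
        out.append((exp, forest))
    return out


@dataclass
class RecoveryResult:
    lifetime_mean_d: float
    lifetime_sd_d: float
    n_dividing_cells: int
    senescent_fraction_pct: float
    n_colonies: int


def lifetime_and_senescence(
    colonies: list[tuple[SimulatedExperiment, LineageForest]],
    reference_frame: int = DAY4_FRAME,
    horizon_frame: int = DAY7_FRAME,
) -> RecoveryResult:
    """Pipeline estimates of dividing-cell lifetime moments and the mean
    per-colony Day-4 senescent fraction.

    Lifetimes pool every cell born by the reference frame whose division is
    documented in the forest (founders excluded: their birth precedes
    observation).  Restricting to cells present during the single-cell
    window while tracking divisions through the Day-7 horizon avoids the
    right-censoring bias that a hard Day-4 cut-off would impose.  Senescence
    follows the operational call: alive at the reference frame with no
    division by the horizon.
    """
    lifetimes_d: list[float] = []
    fractions: list[float] = []
    for _, forest in colonies:
        for cid in forest.records:
            rec = forest.records[cid]
            if rec.birth_frame <= reference_frame:
                lt = forest.lifetime_d(cid)
                if lt is not None:
                    lifetimes_d.append(lt)
        fates = [
            fl.fate
            for fl in classify_fate(forest, reference_frame, horizon_frame)
            if fl.fate != "censored"
        ]
        if fates:
            fractions.append(fates.count("senescent") / len(fates))
    arr = np.asarray(lifetimes_d)
    return RecoveryResult(
        lifetime_mean_d=float(arr.mean()),
        lifetime_sd_d=float(arr.std(ddof=1)),
        n_dividing_cells=len(arr),
        senescent_fraction_pct=100.0 * float(np.mean(fractions)),
        n_colonies=len(fractions),
    )


@dataclass
class GeometryResult:
    confluency_pct: float
    diameter_mm: float
    n_colonies: int


def day7_geometry(
    colonies: list[tuple[SimulatedExperiment, LineageForest]],
    frame: int = DAY7_FRAME,
) -> GeometryResult:
    """Mean Day-7 colony confluency and approximate diameter.

    Each colony is rendered as a label image at the Day-7 frame and measured
    with the convex-hull metrics (occupied pixels over hull area; diameter
    of the equal-area circle).
    """
    confluencies = []
    diameters = []
    for exp, _ in colonies:
        img = render_labels(exp, frame)
        met = colony_hull_metrics(img, pixel_size_um=exp.config.pixel_size_um)
        confluencies.append(met.confluency)
        diameters.append(met.approx_diameter_mm)
    return GeometryResult(
        confluency_pct=100.0 * float(np.mean(confluencies)),
        diameter_mm=float(np.mean(diameters)),
        n_colonies=len(confluencies),
    )
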