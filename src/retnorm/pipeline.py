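"""End-to-end chains from segmented volumes to summaries.

Thin composition layer: interfaces -> thickness map -> orientation
standardization -> validity screening -> whole-area mean and/or block grid.
The CLI and the reproduction script both run through these functions, so a
pipeline result is always obtainable programmatically as well.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from . import geometry as geom
from .normative import NormativeDatabase, build_normative
from .synthetic import InterfaceSet
from .thickness import (BlockGrid, ThicknessMap, apply_validity_criteria,
                        compute_thickness_map, crop_and_block,
                        standardize_orientation, whole_area_mean)

log = logging.getLogger(__name__)


def eye_layer_map(interfaces: InterfaceSet, layer: str,
                  screen: bool = True,
                  bounds: tuple[float, float] | None = None) -> ThicknessMap:
    """Standardized, quality-screened thickness map of one layer of one eye."""
    tmap = compute_thickness_map(interfaces, layer)
    tmap = standardize_orientation(tmap)
    if screen:
        tmap = apply_validity_criteria(tmap, bounds=bounds)
    return tmap


def eye_whole_area_mean(interfaces: InterfaceSet, layer: str,
                        screen: bool = True) -> float:
    """Whole-area mean thickness (um) of one layer of one eye."""
    return whole_area_mean(eye_layer_map(interfaces, layer, screen=screen))


def cohort_whole_area_means(cohort: Iterable[InterfaceSet], layer: str,
                            screen: bool = True) -> np.ndarray:
    """Per-eye whole-area means of one layer over a cohort."""
    return np.array([eye_whole_area_mean(ifs, layer, screen=screen)
                     for ifs in cohort])


def cohort_block_grids(cohort: Iterable[InterfaceSet],
                       layers: Sequence[str] = geom.ALL_LAYERS,
                       screen: bool = True) -> list[BlockGrid]:
    """Block grids for every (eye, layer) combination of a cohort."""
    grids = []
    for ifs in cohort:
        for layer in layers:
            grids.append(crop_and_block(eye_layer_map(ifs, layer, screen=screen)))
    return grids


def cohort_whole_means_frame(cohort: Iterable[InterfaceSet],
                             layers: Sequence[str] = geom.ALL_LAYERS,
                             screen: bool = True) -> pd.DataFrame:
    """Tidy whole-area means (one row per eye and layer) for database building."""
    rows = []
    for ifs in cohort:
        for layer in layers:
            rows.append({"subject": ifs.subject, "group": ifs.group,
                         "eye": ifs.eye, "age_months": ifs.age_months,
                         "layer": layer,
                         "mean_um": eye_whole_area_mean(ifs, layer, screen=screen)})
    return pd.DataFrame(rows)


def build_database(cohort: Sequence[InterfaceSet],
                   layers: Sequence[str] = geom.ALL_LAYERS,
                   screen: bool = True) -> tuple[NormativeDatabase, pd.DataFrame]:
    """Full normative-database build plus a per-block QC report.

    Returns the database (block and whole-area cells, per eye and combined)
    and a QC frame with the percentage of block grids in which each block
    1..9 was removed by the 90% rule — the same per-block removal summary
    reported for real cohorts.
    """
    grids = cohort_block_grids(cohort, layers=layers, screen=screen)
    whole = cohort_whole_means_frame(cohort, layers=layers, screen=screen)
    db = build_normative(grids, whole)
    removal = []
    for b in range(1, 10):
        r, c = divmod(b - 1, 3)
        dropped = sum(1 for g in grids if not g.block_valid[r, c])
        removal.append({"block": b,
                        "removed_percent": 100.0 * dropped / max(len(grids), 1)})
    return db, pd.DataFrame(removal)
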