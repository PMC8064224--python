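"""Per-layer thickness maps and their 3x3 block aggregation.

A thickness map is the axial distance between two adjacent boundary
surfaces, expressed in micrometres, on the 512 x 512 en-face grid.  Left
eyes are mirrored into the right-eye convention so that the left half of a
standardized map is always temporal retina and the right half nasal.  For
block statistics the map is cropped by one pixel per edge to 510 x 510 and
partitioned into nine 170 x 170 blocks; a block is retained only if at
least 90% of its values survive the per-pixel validity criteria.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import geometry as geom
from .errors import (DataError, DimensionError, NoDataError, ParameterError)
from .synthetic import InterfaceSet

log = logging.getLogger(__name__)

#: Interface index pairs delimiting each layer (TRT spans the full stack).
LAYER_INTERFACES: dict[str, tuple[int, int]] = {
    **{layer: (i, i + 1) for i, layer in enumerate(geom.LAYERS)},
    geom.TRT: (0, geom.N_INTERFACES - 1),
}


@dataclass
class ThicknessMap:
    """One layer's en-face thickness map with a per-pixel validity mask."""

    layer: str
    values: np.ndarray
    validity: np.ndarray
    eye: str = "OD"
    orientation: str = "native"
    group: str = geom.GROUP_WT
    age_months: int = 1
    subject: str = "unknown"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.layer not in LAYER_INTERFACES:
            raise ParameterError(f"unknown layer {self.layer!r}")
        if self.values.ndim != 2:
            raise DimensionError("values must be a 2-D grid")
        if self.validity.shape != self.values.shape:
            raise DimensionError("validity mask must match the value grid")
        if self.orientation not in ("native", "standardized"):
            raise ParameterError(f"unknown orientation {self.orientation!r}")

    @property
    def valid_fraction(self) -> float:
        return float(self.validity.mean())

    def replace(self, **changes) -> "ThicknessMap":
        return dataclasses.replace(self, **changes)

    # ---- I/O -------------------------------------------------------------

    def to_tiff(self, path: str | Path) -> None:
        """Two-page TIFF (float32 values, 8-bit mask) plus a JSON sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.values.astype(np.float32))
        tifffile.imwrite(path.with_suffix(".mask.tif"),
                         self.validity.astype(np.uint8))
        meta = {"layer": self.layer, "eye": self.eye,
                "orientation": self.orientation, "group": self.group,
                "age_months": int(self.age_months), "subject": self.subject}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "ThicknessMap":
        path = Path(path)
        values = tifffile.imread(path)
        validity = tifffile.imread(path.with_suffix(".mask.tif")).astype(bool)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(values=values, validity=validity, **meta)


@dataclass
class BlockGrid:
    """3x3 block means of one standardized thickness map.

    ``block_means`` holds NaN wherever ``block_valid`` is False; blocks are
    numbered 1..9 in row-major order, top-left first.
    """

    block_means: np.ndarray
    valid_counts: np.ndarray
    block_valid: np.ndarray
    layer: str = geom.TRT
    eye: str = "OD"
    group: str = geom.GROUP_WT
    age_months: int = 1
    subject: str = "unknown"

    def __post_init__(self):
        self.block_means = np.asarray(self.block_means, dtype=float)
        self.valid_counts = np.asarray(self.valid_counts, dtype=int)
        self.block_valid = np.asarray(self.block_valid, dtype=bool)
        for name in ("block_means", "valid_counts", "block_valid"):
            if getattr(self, name).shape != (3, 3):
                raise DimensionError(f"{name} must be 3x3")

    def block(self, index: int) -> tuple[float, bool]:
        """(mean, retained) of block ``index`` (1..9 row-major)."""
        if not 1 <= index <= 9:
            raise ParameterError(f"block index must be in 1..9, got {index}")
        r, c = divmod(index - 1, 3)
        return float(self.block_means[r, c]), bool(self.block_valid[r, c])

    def column_mean(self, blocks: Sequence[int]) -> float:
        """Mean of the retained blocks among ``blocks``; NaN if none retained."""
        vals = [self.block(b)[0] for b in blocks if self.block(b)[1]]
        return float(np.mean(vals)) if vals else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in range(1, 10):
            r, c = divmod(b - 1, 3)
            rows.append({"subject": self.subject, "group": self.group,
                         "eye": self.eye, "age_months": self.age_months,
                         "layer": self.layer, "block": b,
                         "mean_um": self.block_means[r, c],
                         "valid_count": int(self.valid_counts[r, c]),
                         "retained": bool(self.block_valid[r, c])})
        return pd.DataFrame(rows)


# ---- operations ----------------------------------------------------------


def compute_thickness_map(interfaces: InterfaceSet, layer: str) -> ThicknessMap:
    """Thickness of one layer as the axial distance between its boundaries.

    Values are ``(lower_depth - upper_depth) * pixel_pitch_axial`` in
    micrometres; the validity mask starts all-true and is refined later by
    :func:`apply_validity_criteria`.
    """
    try:
        upper, lower = LAYER_INTERFACES[layer]
    except KeyError:
        raise ParameterError(
            f"unknown layer {layer!r}; expected one of {sorted(LAYER_INTERFACES)}")
    values = (interfaces.surfaces[lower] - interfaces.surfaces[upper]) \
        * interfaces.pixel_pitch_axial
    return ThicknessMap(layer=layer, values=values,
                        validity=np.ones(values.shape, dtype=bool),
                        eye=interfaces.eye, orientation="native",
                        group=interfaces.group,
                        age_months=interfaces.age_months,
                        subject=interfaces.subject)


def standardize_orientation(tmap: ThicknessMap, force: bool = False) -> ThicknessMap:
    """Mirror left-eye maps into the right-eye convention.

    After standardization the left half of the map is temporal retina and
    the right half nasal for either eye.  Standardizing an
    already-standardized map is a logged no-op unless ``force`` is set, in
    which case the flip is applied unconditionally (useful for testing the
    involution).
    """
    flip = force or (tmap.orientation == "native" and tmap.eye == "OS")
    if tmap.orientation == "standardized" and not force:
        log.warning("map for %s already standardized; skipping flip", tmap.subject)
        return tmap.replace()
    values = tmap.values[:, ::-1].copy() if flip else tmap.values.copy()
    validity = tmap.validity[:, ::-1].copy() if flip else tmap.validity.copy()
    return tmap.replace(values=values, validity=validity,
                        orientation="standardized")


def default_bounds(layer: str, age_months: int, group: str = geom.GROUP_WT
                   ) -> tuple[float, float]:
    """Generous physiological bounds: [0, 3x the packaged age-matched mean]."""
    from .normative import load_packaged

    db = load_packaged("wt" if group == geom.GROUP_WT else "ad")
    cell = db.cell(group, "combined", age_months, layer, "whole")
    return (0.0, 3.0 * cell.mean)


def robust_z(values: np.ndarray, validity: np.ndarray) -> np.ndarray:
    """Median/MAD standard scores over the currently valid positions.

    The MAD is scaled by 1.4826 to be consistent with a Gaussian sd; a zero
    MAD yields zero scores (a constant map deviates nowhere).
    """
    ref = values[validity]
    med = np.median(ref)
    mad = np.median(np.abs(ref - med)) * 1.4826
    if mad == 0:
        return np.zeros_like(values)
    return (values - med) / mad


def apply_validity_criteria(tmap: ThicknessMap,
                            rules: Sequence[Callable[[ThicknessMap], np.ndarray]]
                            | None = None,
                            *,
                            bounds: tuple[float, float] | None = None,
                            robust_z_threshold: float = 6.0) -> ThicknessMap:
    """Refine the validity mask by a conjunction of per-pixel quality rules.

    With ``rules=None`` the default battery runs: non-negative thickness,
    per-layer physiological bounds (``bounds`` or the packaged defaults),
    and a robust (median/MAD) standard-score cut at ``robust_z_threshold``,
    emulating the image-quality / boundary-consistency / value-distribution
    screening applied to real segmentations.  An explicitly empty rule list
    leaves the mask unchanged and logs a warning.
    """
    if rules is not None and len(rules) == 0:
        log.warning("empty validity rule list; mask left unchanged")
        return tmap.replace()
    if rules is None:
        lo, hi = bounds if bounds is not None else \
            default_bounds(tmap.layer, tmap.age_months, tmap.group)

        def nonnegative(m):
            return m.values >= 0.0

        def physiological(m):
            return (m.values >= lo) & (m.values <= hi)

        def distributional(m):
            return np.abs(robust_z(m.values, m.validity)) <= robust_z_threshold

        rules = [nonnegative, physiological, distributional]
    mask = tmap.validity.copy()
    for rule in rules:
        outcome = np.asarray(rule(tmap), dtype=bool)
        if outcome.shape != mask.shape:
            raise DimensionError("validity rule returned a wrong-shaped mask")
        mask &= outcome
    return tmap.replace(validity=mask)


def crop_and_block(tmap: ThicknessMap) -> BlockGrid:
    """Aggregate a standardized 512x512 map into the 3x3 block grid.

    The map is centre-cropped to 510x510 (one pixel per edge) so all blocks
    are 170x170; block means are taken over valid positions only, and a
    block is retained iff at least 90% of its 28,900 positions are valid
    (inclusive threshold).  Means of dropped blocks are NaN.
    """
    if tmap.orientation != "standardized":
        raise ParameterError("crop_and_block requires a standardized map")
    if tmap.values.shape != (geom.GRID_SIZE, geom.GRID_SIZE):
        raise DimensionError(
            f"expected a {geom.GRID_SIZE}x{geom.GRID_SIZE} grid, got "
            f"{tmap.values.shape}")
    m = geom.CROP_MARGIN
    vals = tmap.values[m:-m, m:-m]
    mask = tmap.validity[m:-m, m:-m]
    s = geom.BLOCK_SIZE
    v4 = vals.reshape(3, s, 3, s)
    m4 = mask.reshape(3, s, 3, s)
    counts = m4.sum(axis=(1, 3))
    sums = np.where(m4, v4, 0.0).sum(axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    valid = counts / geom.BLOCK_PIXELS >= geom.BLOCK_RETENTION_FRACTION
    means = np.where(valid, means, np.nan)
    return BlockGrid(block_means=means, valid_counts=counts, block_valid=valid,
                     layer=tmap.layer, eye=tmap.eye, group=tmap.group,
                     age_months=tmap.age_months, subject=tmap.subject)


def whole_area_mean(tmap: ThicknessMap, min_valid_fraction: float = 0.5) -> float:
    """Mean thickness over the valid positions of the full 512x512 grid.

    Raises :class:`NoDataError` when fewer than ``min_valid_fraction`` of
    the positions are valid — too little support for a whole-area summary.
    """
    if tmap.orientation != "standardized":
        raise ParameterError("whole_area_mean requires a standardized map")
    n_valid = int(tmap.validity.sum())
    if n_valid == 0:
        raise NoDataError(f"map for {tmap.subject}/{tmap.layer} has no valid values")
    if n_valid / tmap.validity.size < min_valid_fraction:
        raise NoDataError(
            f"only {n_valid / tmap.validity.size:.1%} of positions valid "
            f"(minimum {min_valid_fraction:.0%})")
    return float(tmap.values[tmap.validity].mean())


def radial_profile(tmap: ThicknessMap,
                   disc_centre: tuple[float, float] | None = None,
                   n_bins: int = 10) -> pd.DataFrame:
    """Mean thickness as a function of distance to the optic-disc centre.

    Valid positions are binned by normalised Euclidean distance into
    ``n_bins`` equal-width bins; the result has one row per bin with the
    bin centre, mean thickness and count.
    """
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    d = geom.disc_distance(tmap.values.shape, disc_centre)
    dv = d[tmap.validity]
    tv = tmap.values[tmap.validity]
    if dv.size == 0:
        raise NoDataError("no valid positions to profile")
    edges = np.linspace(0.0, dv.max() * (1 + 1e-12), n_bins + 1)
    which = np.clip(np.digitize(dv, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        rows.append({
            "distance_bin_centre": 0.5 * (edges[b] + edges[b + 1]),
            "mean_um": float(tv[sel].mean()) if sel.any() else float("nan"),
            "n": int(sel.sum()),
        })
    return pd.DataFrame(rows)


def block_grids_to_frame(grids: Sequence[BlockGrid]) -> pd.DataFrame:
    """Concatenate block grids into one tidy table (the CSV exchange format)."""
    if not grids:
        return pd.DataFrame(columns=["subject", "group", "eye", "age_months",
                                     "layer", "block", "mean_um",
                                     "valid_count", "retained"])
    return pd.concat([g.to_frame() for g in grids], ignore_index=True)
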