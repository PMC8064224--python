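"""Synthetic segmented OCT volumes with the statistical structure of mouse retinas.

No public repository of segmented Micron IV volumes exists, so downstream
stages are exercised on simulated boundary surfaces.  The generator emulates
the features the analysis depends on: per-layer mean thickness at the level
of the published cohort tables, a nasal-temporal gradient (nasal thicker),
thickness declining with distance to the optic disc, per-pixel measurement
noise, and injectable invalid regions that exercise the block-retention
quality filter.  It also ships the two B-scan augmentation transforms used
when training segmentation networks on small OCT datasets: horizontal
mirroring and sinusoidal circular shifting of A-scans.

The generative model for the thickness of one layer at en-face position
(r, c) is

    t(r, c) = base + g_nt * x(c) + g_d * d(r, c) + eps(r, c),   eps ~ N(0, sigma^2)

clamped at zero, where ``x`` is the centred nasal-temporal coordinate
(+0.5 at the nasal edge) and ``d`` the normalised distance to the optic-disc
centre.  Boundary surfaces are the running depth sums of the layer
thicknesses below a flat inner limiting membrane, which makes the monotone
depth ordering hold by construction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import geometry as geom
from .errors import DimensionError, ParameterError

log = logging.getLogger(__name__)

#: Nominal per-layer base thicknesses (um): the published wild-type
#: one-month whole-area means.  Cohort samplers override these per draw.
DEFAULT_BASE_UM: dict[str, float] = {
    "RNFL-GCL": 12.90,
    "IPL": 51.55,
    "INL": 25.57,
    "OPL": 15.22,
    "ONL": 62.13,
    "IS": 10.79,
    "OS": 11.61,
    "RPE": 20.93,
}

#: Depth (pixels) of the innermost interface; keeps every surface well inside
#: the 1024-pixel A-scan for murine total thicknesses (~150 px).
DEFAULT_TOP_DEPTH_PX = 200.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic segmented volume.

    Parameters
    ----------
    base_thickness_um
        Mean thickness per layer, in micrometres, for the eight segmented
        layers (inner to outer).
    nasal_temporal_slope_um
        Thickness difference (um) between the nasal and temporal edge
        columns; positive means nasal thicker.  Applied per layer.
    disc_distance_slope_um
        Thickness change (um) per unit normalised disc distance; negative
        reproduces the decline of thickness away from the optic disc.
    noise_sd_um
        Standard deviation of the i.i.d. Gaussian per-pixel thickness noise.
    invalid_fraction
        Fraction of positions to mark invalid when a degraded map is
        requested downstream (informational here; degradation itself is
        applied by :func:`inject_invalid`).
    eye, group, age_months, subject
        Metadata carried through to every derived product.
    seed
        Seed of the generator's private random stream.
    grid_shape
        En-face grid shape; (512, 512) matches the acquisition, smaller
        grids are accepted for quick experiments.
    disc_centre
        (row, col) of the optic-disc centre; defaults to the midpoint of the
        bottom edge, matching a scan placed directly above the disc.
    """

    base_thickness_um: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_UM))
    nasal_temporal_slope_um: float = 1.0
    disc_distance_slope_um: float = -2.0
    noise_sd_um: float = 2.0
    invalid_fraction: float = 0.0
    eye: str = "OD"
    group: str = geom.GROUP_WT
    age_months: int = 1
    subject: str = "sim-000"
    seed: int = 0
    grid_shape: tuple[int, int] = (geom.GRID_SIZE, geom.GRID_SIZE)
    disc_centre: tuple[float, float] | None = None
    top_depth_px: float = DEFAULT_TOP_DEPTH_PX

    def __post_init__(self):
        missing = [k for k in geom.LAYERS if k not in self.base_thickness_um]
        if missing:
            raise ParameterError(f"base_thickness_um missing layers: {missing}")
        for layer, value in self.base_thickness_um.items():
            if layer not in geom.LAYERS:
                raise ParameterError(f"unknown layer {layer!r} in base_thickness_um")
            if not np.isfinite(value) or value <= 0:
                raise ParameterError(
                    f"base thickness for {layer!r} must be positive, got {value!r}")
        for name in ("nasal_temporal_slope_um", "disc_distance_slope_um"):
            if not np.isfinite(getattr(self, name)):
                raise ParameterError(f"{name} must be finite")
        if not np.isfinite(self.noise_sd_um) or self.noise_sd_um < 0:
            raise ParameterError("noise_sd_um must be >= 0")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ParameterError("invalid_fraction must be in [0, 1]")
        if self.eye not in ("OD", "OS"):
            raise ParameterError(f"eye must be 'OD' or 'OS', got {self.eye!r}")
        if self.age_months not in geom.AGES_MONTHS:
            raise ParameterError(
                f"age_months must be one of {geom.AGES_MONTHS}, got {self.age_months!r}")

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Load a config from a YAML or JSON file."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ParameterError(f"config file {path} does not hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config fields: {sorted(unknown)}")
        if "grid_shape" in data:
            data["grid_shape"] = tuple(data["grid_shape"])
        if data.get("disc_centre") is not None:
            data["disc_centre"] = tuple(data["disc_centre"])
        return cls(**data)


def default_config(group: str = geom.GROUP_WT, age_months: int = 1,
                   **overrides) -> SimConfig:
    """A :class:`SimConfig` whose layer bases are the packaged whole-area
    means of the requested group and age."""
    from .normative import load_packaged

    db = load_packaged("wt" if group == geom.GROUP_WT else "ad")
    base = {layer: db.cell(group, "combined", age_months, layer, "whole").mean
            for layer in geom.LAYERS}
    return SimConfig(base_thickness_um=base, group=group,
                     age_months=age_months, **overrides)


@dataclass
class InterfaceSet:
    """Nine ordered boundary surfaces of one segmented volume.

    ``surfaces`` has shape (9, rows, cols) and holds sub-pixel depths along
    the A-scan axis; surface k is everywhere at or above surface k+1 in the
    image (monotone non-decreasing depth), and all depths lie in [0, 1024).
    """

    surfaces: np.ndarray
    pixel_pitch_axial: float = geom.AXIAL_PITCH_UM
    eye: str = "OD"
    group: str = geom.GROUP_WT
    age_months: int = 1
    subject: str = "sim-000"

    def __post_init__(self):
        self.surfaces = np.asarray(self.surfaces, dtype=float)
        if self.surfaces.ndim != 3 or self.surfaces.shape[0] != geom.N_INTERFACES:
            raise DimensionError(
                f"surfaces must have shape (9, rows, cols), got {self.surfaces.shape}")
        if np.any(np.diff(self.surfaces, axis=0) < 0):
            raise ParameterError("interface depths must be monotone non-decreasing")
        if self.surfaces.min() < 0 or self.surfaces.max() >= geom.DEPTH_PIXELS:
            raise ParameterError("interface depths must lie in [0, 1024)")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.surfaces.shape[1:]

    # ---- I/O -------------------------------------------------------------

    def to_tiff(self, path: str | Path) -> None:
        """Write the nine depth maps as a multi-page float32 TIFF with the
        metadata in the ImageDescription tag."""
        meta = {"eye": self.eye, "group": self.group,
                "age_months": int(self.age_months), "subject": self.subject,
                "pixel_pitch_axial": self.pixel_pitch_axial}
        tifffile.imwrite(path, self.surfaces.astype(np.float32),
                         description=json.dumps(meta))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "InterfaceSet":
        with tifffile.TiffFile(path) as tif:
            surfaces = tif.asarray()
            desc = tif.pages[0].description
        meta = json.loads(desc) if desc else {}
        return cls(surfaces=surfaces,
                   pixel_pitch_axial=meta.get("pixel_pitch_axial", geom.AXIAL_PITCH_UM),
                   eye=meta.get("eye", "OD"), group=meta.get("group", geom.GROUP_WT),
                   age_months=meta.get("age_months", 1),
                   subject=meta.get("subject", "unknown"))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: row, col, interface_index, depth_px."""
        k, rows, cols = self.surfaces.shape
        idx, rr, cc = np.meshgrid(np.arange(k), np.arange(rows),
                                  np.arange(cols), indexing="ij")
        return pd.DataFrame({"row": rr.ravel(), "col": cc.ravel(),
                             "interface_index": idx.ravel(),
                             "depth_px": self.surfaces.ravel()})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **metadata) -> "InterfaceSet":
        k = int(frame["interface_index"].max()) + 1
        rows = int(frame["row"].max()) + 1
        cols = int(frame["col"].max()) + 1
        surfaces = np.full((k, rows, cols), np.nan)
        surfaces[frame["interface_index"], frame["row"], frame["col"]] = \
            frame["depth_px"].to_numpy(dtype=float)
        if np.isnan(surfaces).any():
            raise ParameterError("boundary table does not cover the full grid")
        return cls(surfaces=surfaces, **metadata)


def layer_thickness_fields(config: SimConfig) -> dict[str, np.ndarray]:
    """Per-layer thickness fields (um) of the generative model, clamped >= 0."""
    rows, cols = config.grid_shape
    x = geom.nasal_temporal_coordinate(cols, config.eye)
    d = geom.disc_distance((rows, cols), config.disc_centre)
    rng = np.random.default_rng(config.seed)
    fields = {}
    for layer in geom.LAYERS:
        t = (config.base_thickness_um[layer]
             + config.nasal_temporal_slope_um * x[np.newaxis, :]
             + config.disc_distance_slope_um * d)
        if config.noise_sd_um > 0:
            t = t + rng.normal(0.0, config.noise_sd_um, size=(rows, cols))
        else:
            t = np.broadcast_to(t, (rows, cols)).copy()
        fields[layer] = np.clip(t, 0.0, None)
    return fields


def generate_interfaces(config: SimConfig) -> InterfaceSet:
    """Build a segmented volume's nine boundary surfaces from a :class:`SimConfig`.

    Deterministic given ``config.seed``: two calls with the same config are
    bit-identical.
    """
    fields = layer_thickness_fields(config)
    rows, cols = config.grid_shape
    surfaces = np.empty((geom.N_INTERFACES, rows, cols))
    surfaces[0] = config.top_depth_px
    for i, layer in enumerate(geom.LAYERS):
        surfaces[i + 1] = surfaces[i] + fields[layer] / geom.AXIAL_PITCH_UM
    if surfaces.max() >= geom.DEPTH_PIXELS:
        raise ParameterError(
            "generated depths exceed the 1024-pixel A-scan; reduce "
            "base thicknesses or top_depth_px")
    return InterfaceSet(surfaces=surfaces, eye=config.eye, group=config.group,
                        age_months=config.age_months, subject=config.subject)


def sample_cohort(db, group: str, eye: str, age_months: int, n_eyes: int,
                  between_eye_sd_scale: float = 1.0, seed: int = 0,
                  anchor: str = "layers",
                  config_template: SimConfig | None = None) -> list[InterfaceSet]:
    """Draw a cohort of synthetic eyes from a normative database's whole-area cells.

    Per eye and per layer, a mean thickness is drawn from
    ``Normal(cell.mean, between_eye_sd_scale * cell.sd)`` and a volume is
    generated around those means with :func:`generate_interfaces`.  The layer
    base is compensated for the disc-distance term so that the expected
    whole-area mean of each layer equals its draw exactly.

    ``anchor`` selects which cells the cohort reproduces:

    - ``"layers"`` (default): each of the eight layers is drawn from its own
      cell; the total retinal thickness is their sum, which need not match
      the database's TRT cell.
    - ``"TRT"``: a total retinal thickness is additionally drawn from the TRT
      cell and the eight layer draws are rescaled proportionally to sum to
      it, so the cohort reproduces the TRT cell statistics (at the cost of a
      small relative bias, the TRT/layer-sum ratio, on individual layers).

    Cell lookup uses the combined-eyes reference when present, falling back
    to the requested eye.
    """
    from .errors import MissingCellError

    if n_eyes < 0:
        raise ParameterError("n_eyes must be >= 0")
    if anchor not in ("layers", "TRT"):
        raise ParameterError(f"anchor must be 'layers' or 'TRT', got {anchor!r}")
    template = config_template or SimConfig()

    def _cell(layer):
        try:
            return db.cell(group, "combined", age_months, layer, "whole")
        except MissingCellError:
            return db.cell(group, eye, age_months, layer, "whole")

    cells = {layer: _cell(layer) for layer in geom.LAYERS}
    trt_cell = _cell(geom.TRT) if anchor == "TRT" else None

    rows, cols = template.grid_shape
    mean_d = float(geom.disc_distance((rows, cols), template.disc_centre).mean())
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_eyes):
        draws = {layer: rng.normal(c.mean, between_eye_sd_scale * c.sd)
                 for layer, c in cells.items()}
        if trt_cell is not None:
            trt_draw = rng.normal(trt_cell.mean, between_eye_sd_scale * trt_cell.sd)
            total = sum(draws.values())
            draws = {layer: v * trt_draw / total for layer, v in draws.items()}
        # shift the base so E[whole-area mean] equals the draw despite the
        # disc-distance gradient (the nasal-temporal coordinate is centred
        # already)
        base = {layer: max(v - template.disc_distance_slope_um * mean_d, 1e-3)
                for layer, v in draws.items()}
        config = template.replace(
            base_thickness_um=base, eye=eye, group=group, age_months=age_months,
            subject=f"{group}-m{age_months}-{eye}-{i:03d}",
            seed=int(rng.integers(2 ** 31)))
        cohort.append(generate_interfaces(config))
    return cohort


def inject_invalid(tmap, fraction: float, pattern: str = "random",
                   block_index: int | None = None, seed: int = 0):
    """Mark an exact fraction of a thickness map's valid positions invalid.

    ``pattern="random"`` draws positions uniformly over the whole map;
    ``pattern="block_targeted"`` restricts the draw to the named 170x170
    block (1..9, row-major on the standardized map), which is the natural
    way to push a single block below the retention threshold.  Exactly
    ``round(fraction * n_valid)`` positions are marked, where ``n_valid``
    counts the currently valid positions of the affected region.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError("fraction must be in [0, 1]")
    if pattern not in ("random", "block_targeted"):
        raise ParameterError(f"unknown pattern {pattern!r}")
    validity = tmap.validity.copy()
    if pattern == "block_targeted":
        if block_index is None:
            raise ParameterError("block_targeted requires block_index")
        region = np.zeros_like(validity)
        rs, cs = geom.block_slices(block_index)
        region[rs, cs] = True
    else:
        region = np.ones_like(validity)
    candidates = np.flatnonzero(validity & region)
    k = int(round(fraction * candidates.size))
    if k:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(candidates, size=k, replace=False)
        validity.flat[chosen] = False
    return dataclasses.replace(tmap, validity=validity)


# ---- B-scan augmentation transforms --------------------------------------


def sinusoid_augment(bscan_image: np.ndarray, amplitude: float,
                     frequency: float, phase: float) -> np.ndarray:
    """Circularly shift each A-scan by a sinusoid of the column index.

    Column ``j`` of the B-scan (depth along axis 0) is rolled by
    ``round(amplitude * sin(2*pi*frequency*j/width + phase))`` pixels, which
    modulates the apparent retina position without altering any column's
    pixel multiset.  Negating the amplitude inverts the transform.
    """
    img = np.asarray(bscan_image)
    if img.size == 0:
        return img.copy()
    depth, width = img.shape
    j = np.arange(width)
    shifts = np.rint(amplitude * np.sin(2 * np.pi * frequency * j / width + phase))
    shifts = shifts.astype(int)
    row_idx = (np.arange(depth)[:, None] - shifts[None, :]) % depth
    return img[row_idx, j[None, :]]


def sinusoid_restore(bscan_image: np.ndarray, amplitude: float,
                     frequency: float, phase: float) -> np.ndarray:
    """Invert :func:`sinusoid_augment` applied with the same parameters."""
    return sinusoid_augment(bscan_image, -amplitude, frequency, phase)


def mirror_augment(bscan_image: np.ndarray) -> np.ndarray:
    """Mirror a B-scan horizontally (reverse the A-scan order); involutive."""
    return np.asarray(bscan_image)[:, ::-1].copy()
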