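"""Scan geometry constants and coordinate helpers.

The acquisition geometry is a volume of 512 B-scans x 512 A-scans with a
1024-pixel depth axis spanning 1.4 mm of tissue, scanned directly above the
optic disc and horizontally centred on it.  All en-face maps in this package
live on the 512 x 512 grid spanned by (B-scan index, A-scan index).
"""

from __future__ import annotations

import numpy as np

#: En-face grid side length (B-scans = rows, A-scans per B-scan = columns).
GRID_SIZE = 512

#: Depth-axis length of one A-scan, in pixels.
DEPTH_PIXELS = 1024

#: Axial extent imaged by one A-scan, in micrometres.
IMAGING_DEPTH_UM = 1400.0

#: Micrometres of tissue per depth pixel (1400 um over 1024 px).
AXIAL_PITCH_UM = IMAGING_DEPTH_UM / DEPTH_PIXELS

#: Crop applied before block averaging: 512 -> 510, one pixel per edge.
CROP_MARGIN = 1
CROPPED_SIZE = GRID_SIZE - 2 * CROP_MARGIN  # 510

#: Side length of one of the 3x3 aggregation blocks, in pixels.
BLOCK_SIZE = CROPPED_SIZE // 3  # 170
BLOCK_PIXELS = BLOCK_SIZE * BLOCK_SIZE  # 28,900

#: Fraction of a block's pixels that must be valid for the block to be kept
#: (inclusive threshold).
BLOCK_RETENTION_FRACTION = 0.90

#: The eight segmented layers, inner to outer, plus the total retina.
LAYERS = ("RNFL-GCL", "IPL", "INL", "OPL", "ONL", "IS", "OS", "RPE")
TRT = "TRT"
ALL_LAYERS = LAYERS + (TRT,)

#: Number of boundary surfaces delimiting the eight layers.
N_INTERFACES = len(LAYERS) + 1

#: Ages covered by the longitudinal design, in months.
AGES_MONTHS = (1, 2, 3, 4)

GROUP_WT = "WT"
GROUP_AD = "3xTg-AD"


def default_disc_centre(shape: tuple[int, int] | None = None) -> tuple[float, float]:
    """Optic-disc centre in (row, col) en-face coordinates.

    The scan is placed vertically above the optic disc and horizontally
    centred on it, so the disc sits at the midpoint of the bottom edge of
    the en-face grid.
    """
    rows, cols = shape if shape is not None else (GRID_SIZE, GRID_SIZE)
    return (float(rows - 1), (cols - 1) / 2.0)


def disc_distance(shape: tuple[int, int],
                  disc_centre: tuple[float, float] | None = None) -> np.ndarray:
    """Normalised Euclidean distance of every en-face position to the disc centre.

    Distances are in units of the grid width minus one (so one full map width
    equals a distance of 1.0), which keeps slope parameters expressed
    per-map-width regardless of grid size.
    """
    rows, cols = shape
    if disc_centre is None:
        disc_centre = default_disc_centre(shape)
    r0, c0 = disc_centre
    if not (np.isfinite(r0) and np.isfinite(c0)):
        from .errors import ParameterError

        raise ParameterError(f"disc centre must be finite, got {disc_centre!r}")
    rr, cc = np.meshgrid(np.arange(rows, dtype=float),
                         np.arange(cols, dtype=float), indexing="ij")
    return np.hypot(rr - r0, cc - c0) / max(cols - 1, 1)


def nasal_temporal_coordinate(cols: int, eye: str) -> np.ndarray:
    """Signed en-face column coordinate, +0.5 at the nasal edge.

    On a right eye (OD) the nasal retina maps to the right-hand side of the
    en-face grid; on a left eye (OS) it maps to the left-hand side, so the
    coordinate is mirrored.  The coordinate is centred (mean exactly zero),
    so a pure nasal-temporal gradient does not shift the map mean.
    """
    x = (np.arange(cols, dtype=float) - (cols - 1) / 2.0) / max(cols - 1, 1)
    if eye == "OS":
        x = -x
    elif eye != "OD":
        from .errors import ParameterError

        raise ParameterError(f"eye must be 'OD' or 'OS', got {eye!r}")
    return x


def block_slices(block_index: int) -> tuple[slice, slice]:
    """Full-grid (row, col) slices of one 170x170 block.

    Blocks are numbered 1..9 in row-major order with block 1 at the top-left
    of the standardized (right-eye convention) map; slices account for the
    one-pixel crop margin.
    """
    from .errors import ParameterError

    if not 1 <= int(block_index) <= 9:
        raise ParameterError(f"block_index must be in 1..9, got {block_index!r}")
    b = int(block_index) - 1
    br, bc = divmod(b, 3)
    rows = slice(CROP_MARGIN + br * BLOCK_SIZE, CROP_MARGIN + (br + 1) * BLOCK_SIZE)
    cols = slice(CROP_MARGIN + bc * BLOCK_SIZE, CROP_MARGIN + (bc + 1) * BLOCK_SIZE)
    return rows, cols


#: Blocks making up the temporal and nasal columns of the standardized map.
TEMPORAL_BLOCKS = (1, 4, 7)
NASAL_BLOCKS = (3, 6, 9)
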