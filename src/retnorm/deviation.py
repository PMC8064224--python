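"""Scoring an individual eye against the normative database.

Each retained block of a 3x3 block grid is converted to a signed standard
score against the matching normative cell and to a two-sided normative
p-value: the probability that the reference Normal generates a value at
least as far from its mean, p = 2 * (1 - Phi(|z|)).  The p-value is 1.00
exactly at the normative mean and shrinks towards the tails, so it reads
as "how normal is this thickness" rather than as a hypothesis test.  The
rendering paints blocks blue when thinner than the reference and red when
thicker, with colour intensity 1 - p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDistributionError, ParameterError
from .normative import NormativeCell, NormativeDatabase
from .thickness import BlockGrid


@dataclass(frozen=True)
class DeviationScore:
    z: float
    p: float
    direction: str  # "below" | "at" | "above"


def deviation_score(thickness_um: float, cell: NormativeCell) -> DeviationScore:
    """Signed standard score and two-sided normative p-value of one thickness.

    ``z = (thickness - mean) / sd`` and ``p = 2 * (1 - Phi(|z|))``; the
    direction is the sign of z.  Requires a non-degenerate reference
    (sd > 0).
    """
    if cell.sd <= 0:
        raise DegenerateDistributionError(
            "normative cell has sd = 0; deviation undefined")
    z = (float(thickness_um) - cell.mean) / cell.sd
    p = float(2.0 * stats.norm.sf(abs(z)))
    direction = "at" if z == 0 else ("below" if z < 0 else "above")
    return DeviationScore(float(z), p, direction)


@dataclass
class DeviationMap:
    """3x3 deviation of one eye's layer against a normative reference."""

    z: np.ndarray
    p: np.ndarray
    direction: np.ndarray
    valid: np.ndarray
    thickness_um: np.ndarray
    layer: str
    subject: str
    reference_group: str
    reference_eye: str
    reference_age_months: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in range(1, 10):
            r, c = divmod(b - 1, 3)
            rows.append({"block": b,
                         "thickness_um": self.thickness_um[r, c],
                         "z": self.z[r, c], "p": self.p[r, c],
                         "direction": self.direction[r, c],
                         "valid": bool(self.valid[r, c])})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def deviation_map(grid: BlockGrid, db: NormativeDatabase,
                  reference_group: str, reference_age_months: int,
                  reference_eye: str = "combined") -> DeviationMap:
    """Score every retained block of a grid against the database.

    The reference defaults to the eyes-combined cells of the given group
    and age, for the grid's layer.  Blocks dropped by the 90% quality rule
    are marked invalid and receive no score; a missing reference cell for
    a retained block is an error.
    """
    z = np.full((3, 3), np.nan)
    p = np.full((3, 3), np.nan)
    direction = np.full((3, 3), "", dtype=object)
    for b in range(1, 10):
        r, c = divmod(b - 1, 3)
        mean, retained = grid.block(b)
        if not retained:
            continue
        cell = db.cell(reference_group, reference_eye, reference_age_months,
                       grid.layer, f"block{b}")
        score = deviation_score(mean, cell)
        z[r, c], p[r, c], direction[r, c] = score.z, score.p, score.direction
    return DeviationMap(z=z, p=p, direction=direction,
                        valid=grid.block_valid.copy(),
                        thickness_um=grid.block_means.copy(),
                        layer=grid.layer, subject=grid.subject,
                        reference_group=reference_group,
                        reference_eye=reference_eye,
                        reference_age_months=reference_age_months)


#: Neutral colour of blocks that were excluded by the quality filter.
INVALID_GRAY = (0.5, 0.5, 0.5)


def render_deviation(dmap: DeviationMap) -> dict:
    """Colour specification of a deviation map.

    Blocks below the reference mean are blue, above it red, with intensity
    ``1 - p`` interpolated linearly from white (p = 1) to the full hue
    (p = 0); invalid blocks are neutral gray.  Returns a dict with the
    3x3x3 RGB array (floats in [0, 1]) and per-block annotations of
    thickness and p (p to two decimals, as rendered).
    """
    rgb = np.ones((3, 3, 3))
    annotations = []
    for b in range(1, 10):
        r, c = divmod(b - 1, 3)
        if not dmap.valid[r, c]:
            rgb[r, c] = INVALID_GRAY
            annotations.append({"block": b, "label": "excluded"})
            continue
        intensity = 1.0 - dmap.p[r, c]
        hue = np.array([1.0, 0.0, 0.0]) if dmap.direction[r, c] == "above" \
            else np.array([0.0, 0.0, 1.0])
        if dmap.direction[r, c] == "at":
            hue = np.array([1.0, 1.0, 1.0])
        rgb[r, c] = (1.0 - intensity) * np.ones(3) + intensity * hue
        annotations.append({
            "block": b,
            "label": f"{dmap.thickness_um[r, c]:.2f}\np={dmap.p[r, c]:.2f}"})
    return {"rgb": rgb, "annotations": annotations}


def render_deviation_figure(dmap: DeviationMap, path: str | Path | None = None):
    """Matplotlib rendering of :func:`render_deviation`; optionally saved."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    spec = render_deviation(dmap)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(spec["rgb"], interpolation="nearest")
    for ann in spec["annotations"]:
        r, c = divmod(ann["block"] - 1, 3)
        ax.text(c, r, ann["label"], ha="center", va="center", fontsize=8)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"{dmap.layer} — {dmap.subject} vs "
                 f"{dmap.reference_group} m{dmap.reference_age_months}")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
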