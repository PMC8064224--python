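"""Normative thickness databases: construction, packaged tables, queries.

Because block and whole-area thickness summaries are close to normally
distributed in healthy cohorts, a reference distribution is fully described
by a (mean, sd, n) triple per cell, keyed by group, eye, age, layer and
region (the whole imaged area or one of the nine blocks).  The package
ships the published whole-area tables for wild-type C57BL6/129S and
3xTg-AD mice at one to four months, plus the cohort weight table; databases
built from (synthetic or real) cohorts use the same container.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import geometry as geom
from .errors import (DegenerateDistributionError, IntegrityError,
                     MissingCellError, ParameterError)

log = logging.getLogger(__name__)

COLUMNS = ["group", "eye", "age_months", "layer", "region", "mean_um",
           "sd_um", "n"]

#: SHA-256 digests of the packaged data files, checked at load time.
_PACKAGED = {
    "wt": "wt_whole_area.csv",
    "ad": "ad_whole_area.csv",
    "weights": "weights.csv",
}
_CHECKSUMS = {
    "wt_whole_area.csv":
        "a9f6df9c3d1f85bb5b70b1d1072bdeb3ef92062bd2228c04f97d6d618d10ca3a",
    "ad_whole_area.csv":
        "75fb39e319c89f432656f60f7fb48a493af02db7211a392b7024a3228eecbc62",
    "weights.csv":
        "d155ba14a7d72342439c4d547c0a4322ad7ccdff47e16a54eed4bf5853846382",
}


@dataclass(frozen=True)
class NormativeCell:
    """Reference distribution of one cell: mean and sd in um, sample size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ParameterError("cell sd must be >= 0")
        if self.n < 1:
            raise ParameterError("cell n must be >= 1")


class NormativeDatabase:
    """Collection of :class:`NormativeCell` keyed by
    (group, eye, age_months, layer, region).

    ``eye`` is ``"OD"``, ``"OS"`` or ``"combined"``; ``region`` is
    ``"whole"`` or ``"block1"``..``"block9"``.  Backed by a tidy DataFrame
    in the package's CSV dialect (UTF-8, comma separator, ``.`` decimal).
    """

    def __init__(self, frame: pd.DataFrame | None = None,
                 provenance: str = "built"):
        if frame is None:
            frame = pd.DataFrame(columns=COLUMNS)
        missing = set(COLUMNS) - set(frame.columns)
        if missing:
            raise ParameterError(f"database frame missing columns {sorted(missing)}")
        frame = frame[COLUMNS].copy()
        frame["age_months"] = frame["age_months"].astype(int)
        frame["n"] = frame["n"].astype(int)
        key = ["group", "eye", "age_months", "layer", "region"]
        if frame.duplicated(subset=key).any():
            raise ParameterError("duplicate cell keys in database frame")
        self.frame = frame.reset_index(drop=True)
        self.provenance = provenance
        self._index = {
            (r.group, r.eye, int(r.age_months), r.layer, r.region):
                NormativeCell(float(r.mean_um), float(r.sd_um), int(r.n))
            for r in frame.itertuples()}

    def __len__(self) -> int:
        return len(self._index)

    def cell(self, group: str, eye: str, age_months: int, layer: str,
             region: str = "whole") -> NormativeCell:
        try:
            return self._index[(group, eye, int(age_months), layer, region)]
        except KeyError:
            raise MissingCellError(group, eye, age_months, layer, region) from None

    def has_cell(self, group, eye, age_months, layer, region="whole") -> bool:
        return (group, eye, int(age_months), layer, region) in self._index

    # ---- I/O -------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "built"
                 ) -> "NormativeDatabase":
        return cls(pd.read_csv(path), provenance=provenance)

    def to_json(self, path: str | Path) -> None:
        self.frame.to_json(path, orient="records", indent=1)


# ---- construction --------------------------------------------------------


def build_normative(block_grids=(), whole_means: pd.DataFrame | None = None
                    ) -> NormativeDatabase:
    """Aggregate per-eye summaries into a normative database.

    ``block_grids`` is a collection of :class:`~retnorm.thickness.BlockGrid`;
    only retained blocks contribute.  ``whole_means`` is a tidy frame with
    columns subject, group, eye, age_months, layer, mean_um holding
    whole-area means.  Cells are produced per eye *and* pooled across eyes
    (``eye="combined"``, treating eyes as independent samples); any cell
    with fewer than two contributing eyes is omitted and logged.  Means use
    the plain average and sds the n-1 sample estimator.
    """
    records = []
    from .thickness import block_grids_to_frame

    blocks = block_grids_to_frame(list(block_grids))
    if len(blocks):
        blocks = blocks[blocks["retained"]].copy()
        blocks["region"] = "block" + blocks["block"].astype(str)
        records.append(blocks[["group", "eye", "age_months", "layer",
                               "region", "mean_um"]])
    if whole_means is not None and len(whole_means):
        w = whole_means.copy()
        w["region"] = "whole"
        records.append(w[["group", "eye", "age_months", "layer", "region",
                          "mean_um"]])
    if not records:
        log.warning("build_normative received no input; empty database")
        return NormativeDatabase()
    tidy = pd.concat(records, ignore_index=True)
    pooled = tidy.copy()
    pooled["eye"] = "combined"
    tidy = pd.concat([tidy, pooled], ignore_index=True)

    grouped = tidy.groupby(["group", "eye", "age_months", "layer", "region"],
                           as_index=False)["mean_um"]
    out = grouped.agg(mean_um="mean", sd_um=lambda v: v.std(ddof=1), n="count")
    thin = out["n"] < 2
    if thin.any():
        for r in out[thin].itertuples():
            log.warning("dropping cell %s/%s/%s/%s/%s with n=%d < 2",
                        r.group, r.eye, r.age_months, r.layer, r.region, r.n)
        out = out[~thin]
    return NormativeDatabase(out.reset_index(drop=True), provenance="built")


def ks_normality(values, method: str = "ks",
                 mean: float | None = None,
                 sd: float | None = None) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov normality check.

    Tests the sample against a Normal with the sample's own mean and
    (n-1) sd and returns ``(statistic, p)``, two-sided.  Estimating the
    parameters from the same sample makes the plain KS p-value conservative
    (the Lilliefors effect); ``method="lilliefors"`` applies the corrected
    null distribution instead, and passing ``mean``/``sd`` explicitly tests
    against a fully specified Normal (exact KS null).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ParameterError(f"need at least 5 values, got {x.size}")
    sample_sd = x.std(ddof=1)
    if sample_sd == 0 and sd is None:
        raise DegenerateDistributionError("sample is constant; sd = 0")
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        stat, p = lilliefors(x, dist="norm")
        return float(stat), float(p)
    if method != "ks":
        raise ParameterError(f"method must be 'ks' or 'lilliefors', got {method!r}")
    loc = x.mean() if mean is None else float(mean)
    scale = sample_sd if sd is None else float(sd)
    if scale <= 0:
        raise DegenerateDistributionError("reference sd must be > 0")
    if mean is None or sd is None:
        log.debug("plain KS with estimated parameters is conservative "
                  "(Lilliefors effect)")
    res = stats.kstest(x, "norm", args=(loc, scale))
    return float(res.statistic), float(res.pvalue)


# ---- packaged tables -----------------------------------------------------


def _read_packaged(filename: str) -> pd.DataFrame:
    ref = resources.files("retnorm.data").joinpath(filename)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[filename]:
        raise IntegrityError(
            f"packaged file {filename} checksum mismatch: {digest}")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_packaged(table: str):
    """Load a packaged reference table.

    ``table`` is one of:

    - ``"wt"`` — wild-type whole-area mean(sd) thickness per layer and age
      (both eyes combined), as a :class:`NormativeDatabase`;
    - ``"ad"`` — the same for the 3xTg-AD group;
    - ``"weights"`` — cohort body weights per group and age, as a DataFrame
      (columns group, age_months, mean_g, sd_g, printed_p).
    """
    if table in ("wt", "ad"):
        return NormativeDatabase(_read_packaged(_PACKAGED[table]),
                                 provenance="packaged")
    if table == "weights":
        return _read_packaged(_PACKAGED["weights"])
    if table == "blocks":
        raise ParameterError(
            "no per-block reference table is packaged; load one with "
            "load_block_table(path)")
    raise ParameterError(
        f"unknown packaged table {table!r}; expected 'wt', 'ad' or 'weights'")


def load_block_table(path: str | Path) -> NormativeDatabase:
    """Load a user-supplied per-block normative table.

    Expected schema: the database CSV dialect with ``region`` values
    ``block1``..``block9`` (and optionally ``whole``).  This is the slot
    for supplementary per-block reference data not shipped with the
    package.
    """
    db = NormativeDatabase.from_csv(path, provenance="external")
    regions = set(db.frame["region"])
    expected = {f"block{i}" for i in range(1, 10)} | {"whole"}
    unknown = regions - expected
    if unknown:
        raise ParameterError(f"unexpected region labels: {sorted(unknown)}")
    return db


def aggregate_cells(db: NormativeDatabase, layers, group: str,
                    age_months: int, region: str = "whole",
                    eye: str = "combined") -> float:
    """Sum of cell means over ``layers`` for one (group, age, region).

    Only the means are summed; sds are not combined because between-layer
    covariances are unknown.  Note that the sum of the eight layer cells
    need not equal the TRT cell: block retention and per-pixel screening
    run independently per layer.
    """
    total = 0.0
    for layer in layers:
        total += db.cell(group, eye, age_months, layer, region).mean
    return total
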