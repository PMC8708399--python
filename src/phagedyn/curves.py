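"""Plate-reader growth-curve data model and I/O.

A coculture experiment lives on a 96-well plate read every 30 min for 22 h
at OD600.  This module holds the validated in-memory representation
(:class:`PlateExperiment` of :class:`GrowthCurve` objects on a shared
:class:`TimeGrid`), the CSV/TSV readers and writers, and baseline
adjustment.  Downstream analysis (scoring, ordination, clustering) consumes
only baseline-adjusted curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeGrid",
    "CombinationKey",
    "GrowthCurve",
    "PlateExperiment",
    "PlateValidationError",
    "NONE_TOKEN",
    "VALID_MOIS",
    "VALID_ROLES",
    "read_plate_table",
    "write_plate_table",
    "baseline_adjust",
    "write_scores_table",
    "read_scores_table",
]

NONE_TOKEN = "NONE"
VALID_MOIS = (10.0, 1.0, 0.1, 0.0)
VALID_ROLES = ("treatment", "bacteria_control", "phage_control", "blank")

_GRID_UNIFORM_TOL = 1e-9


class PlateValidationError(ValueError):
    """Raised when a plate table or its metadata violates the data contract."""


@dataclass(frozen=True)
class TimeGrid:
    """Shared sampling grid in hours: ascending, uniform, starting at 0."""

    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or t.size < 2:
            raise PlateValidationError("time grid needs >= 2 points")
        if abs(t[0]) > _GRID_UNIFORM_TOL:
            raise PlateValidationError(f"time grid must start at 0 h, got {t[0]}")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise PlateValidationError("time grid must be strictly increasing")
        if np.ptp(steps) > _GRID_UNIFORM_TOL:
            raise PlateValidationError("time grid must be uniformly spaced")

    @classmethod
    def default(cls, t_end: float = 22.0, step: float = 0.5) -> "TimeGrid":
        n = int(round(t_end / step)) + 1
        return cls(np.linspace(0.0, t_end, n))

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size

    def __eq__(self, other) -> bool:
        return isinstance(other, TimeGrid) and np.array_equal(self.times, other.times)

    def __hash__(self):
        return hash((self.times.size, float(self.times[-1])))


@dataclass(frozen=True, order=True)
class CombinationKey:
    """Identity of one well: (phage, bacterium, MOI, replicate, role).

    MOI 0 with ``phage_id == NONE`` encodes the phage-free bacteria control;
    ``bacterium_id == NONE`` the bacteria-free phage control; both NONE the
    media blank.
    """

    phage_id: str
    bacterium_id: str
    moi: float
    replicate: int
    role: str = "treatment"

    def __post_init__(self):
        if self.role not in VALID_ROLES:
            raise PlateValidationError(f"invalid role {self.role!r}")
        if self.moi not in VALID_MOIS:
            raise PlateValidationError(f"invalid MOI {self.moi!r} (allowed: 10, 1, 0.1, 0)")
        if self.replicate < 1:
            raise PlateValidationError("replicate must be a positive integer")
        if self.role == "bacteria_control" and not (
            self.phage_id == NONE_TOKEN and self.moi == 0.0
        ):
            raise PlateValidationError(
                "bacteria_control requires phage_id=NONE and moi=0"
            )
        if self.role == "phage_control" and self.bacterium_id != NONE_TOKEN:
            raise PlateValidationError("phage_control requires bacterium_id=NONE")
        if self.role == "blank" and not (
            self.phage_id == NONE_TOKEN and self.bacterium_id == NONE_TOKEN
        ):
            raise PlateValidationError("blank requires phage_id=NONE and bacterium_id=NONE")
        if self.role == "treatment" and (
            self.phage_id == NONE_TOKEN or self.bacterium_id == NONE_TOKEN
        ):
            raise PlateValidationError("treatment wells need both a phage and a bacterium")

    @property
    def combination(self) -> tuple:
        """(phage, bacterium, MOI) triple ignoring the replicate."""
        return (self.phage_id, self.bacterium_id, self.moi)


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD600 time series on a shared grid."""

    key: CombinationKey
    grid: TimeGrid
    od: np.ndarray
    adjusted: bool = False

    def __post_init__(self):
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "od", od)
        if od.shape != (len(self.grid),):
            raise PlateValidationError(
                f"curve length {od.size} != grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(od)):
            bad = int(np.flatnonzero(~np.isfinite(od))[0])
            raise PlateValidationError(
                f"non-finite OD for well ({self.key.phage_id},{self.key.bacterium_id},"
                f"moi={self.key.moi},rep={self.key.replicate}) at row {bad}"
            )
        if self.adjusted and np.any(od < 0):
            raise PlateValidationError("adjusted curves must be non-negative")

    @property
    def endpoint_od(self) -> float:
        return float(self.od[-1])


def require_adjusted(curve: GrowthCurve, what: str = "this operation") -> None:
    """Guard: downstream analyses consume only baseline-adjusted curves."""
    if not curve.adjusted:
        raise ValueError(f"{what} requires baseline-adjusted curves; got a raw curve")


@dataclass
class PlateExperiment:
    """A validated set of growth curves sharing one time grid."""

    curves: list[GrowthCurve]
    grid: TimeGrid
    provenance: str = ""
    adjusted: bool = False

    def validate(self) -> "PlateExperiment":
        roles = [c.key.role for c in self.curves]
        if "blank" not in roles:
            raise PlateValidationError(
                f"plate {self.provenance or '<unnamed>'} has no blank well"
            )
        if "bacteria_control" not in roles:
            raise PlateValidationError(
                f"plate {self.provenance or '<unnamed>'} has no bacteria_control well"
            )
        for c in self.curves:
            if c.grid != self.grid:
                raise PlateValidationError("all curves must share the plate grid")
        return self

    def wells(self, role: str | None = None) -> list[GrowthCurve]:
        if role is None:
            return list(self.curves)
        return [c for c in self.curves if c.key.role == role]

    @property
    def blank(self) -> GrowthCurve:
        return self.wells("blank")[0]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_moi(raw) -> float:
    try:
        moi = float(raw)
    except (TypeError, ValueError):
        raise PlateValidationError(f"invalid MOI {raw!r}") from None
    if moi not in VALID_MOIS:
        raise PlateValidationError(f"invalid MOI {moi!r} (allowed: 10, 1, 0.1, 0)")
    return moi


def read_plate_table(path, metadata_path) -> PlateExperiment:
    """Read a plate CSV (time_h + one column per well) and its metadata TSV.

    The metadata TSV maps each well ID to phage_id, bacterium_id, moi,
    replicate and role.  Wells present in one file but not the other are an
    error; so are NaN ODs, a non-uniform time grid, and missing
    blank/control wells.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    tab = pd.read_csv(path)
    if tab.columns[0] != "time_h":
        raise PlateValidationError(f"{path}: first column must be 'time_h'")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    expected = ["well", "phage_id", "bacterium_id", "moi", "replicate", "role"]
    if list(meta.columns) != expected:
        raise PlateValidationError(
            f"{metadata_path}: expected columns {expected}, got {list(meta.columns)}"
        )

    plate_wells = set(tab.columns[1:])
    meta_wells = set(meta["well"])
    if plate_wells != meta_wells:
        unknown = sorted(plate_wells ^ meta_wells)
        raise PlateValidationError(
            f"well mismatch between {path.name} and {metadata_path.name}: {unknown}"
        )

    grid = TimeGrid(tab["time_h"].to_numpy(dtype=float))
    curves = []
    for row in meta.sort_values("well").itertuples(index=False):
        key = CombinationKey(
            phage_id=row.phage_id,
            bacterium_id=row.bacterium_id,
            moi=_parse_moi(row.moi),
            replicate=int(row.replicate),
            role=row.role,
        )
        od = tab[row.well].to_numpy(dtype=float)
        if np.any(~np.isfinite(od)):
            bad = int(np.flatnonzero(~np.isfinite(od))[0])
            raise PlateValidationError(
                f"{path.name}: NaN OD in well {row.well} at row {bad + 1}"
            )
        curves.append(GrowthCurve(key=key, grid=grid, od=od))
    return PlateExperiment(curves=curves, grid=grid, provenance=str(path)).validate()


def write_plate_table(plate: PlateExperiment, path, metadata_path) -> None:
    """Write a PlateExperiment back to the plate CSV + metadata TSV pair."""
    cols = {"time_h": plate.grid.times}
    meta_rows = []
    for i, c in enumerate(plate.curves):
        well = f"W{i + 1:03d}"
        cols[well] = c.od
        meta_rows.append(
            {
                "well": well,
                "phage_id": c.key.phage_id,
                "bacterium_id": c.key.bacterium_id,
                "moi": _format_moi(c.key.moi),
                "replicate": c.key.replicate,
                "role": c.key.role,
            }
        )
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")
    pd.DataFrame(meta_rows).to_csv(metadata_path, sep="\t", index=False)


def _format_moi(moi: float) -> str:
    return str(int(moi)) if moi in (10.0, 1.0, 0.0) else str(moi)


# ---------------------------------------------------------------------------
# Baseline adjustment
# ---------------------------------------------------------------------------

def baseline_adjust(plate: PlateExperiment, mode: str = "blank_timewise") -> PlateExperiment:
    """Baseline-adjust every non-blank well; negatives are clipped to 0.

    ``blank_timewise`` (default) subtracts the plate's blank-well trace at
    each timepoint — the media background is read off the same plate at the
    same time, so drift and condensation cancel.  ``t0_per_well`` subtracts
    each well's own t=0 reading instead.
    """
    if plate.adjusted:
        raise ValueError("plate is already baseline-adjusted")
    if mode not in ("blank_timewise", "t0_per_well"):
        raise ValueError(f"unknown baseline mode {mode!r}")
    plate.validate()
    blank_od = plate.blank.od
    out = []
    for c in plate.curves:
        if c.key.role == "blank":
            od = np.zeros_like(c.od)
        elif mode == "blank_timewise":
            od = c.od - blank_od
        else:
            od = c.od - c.od[0]
        out.append(replace(c, od=np.clip(od, 0.0, None), adjusted=True))
    return PlateExperiment(
        curves=out, grid=plate.grid, provenance=plate.provenance, adjusted=True
    )


# ---------------------------------------------------------------------------
# Scores table
# ---------------------------------------------------------------------------

_SCORE_COLS = [
    "phage_id",
    "bacterium_id",
    "moi",
    "replicate",
    "auc_full",
    "auc_local",
    "phage_score",
    "virulence_score",
    "endpoint_od",
    "endpoint_category",
]


def write_scores_table(results: Iterable, path) -> None:
    """Write ScoreResults as TSV in deterministic (phage, bacterium, moi,
    replicate) order; an empty collection yields a header-only file."""
    rows = [
        {
            "phage_id": r.key.phage_id,
            "bacterium_id": r.key.bacterium_id,
            "moi": r.key.moi,
            "replicate": r.key.replicate,
            "auc_full": r.auc_full,
            "auc_local": r.auc_local,
            "phage_score": r.phage_score,
            "virulence_score": r.virulence_score,
            "endpoint_od": r.endpoint_od,
            "endpoint_category": r.endpoint_category,
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=_SCORE_COLS)
    if len(df):
        df = df.sort_values(["phage_id", "bacterium_id", "moi", "replicate"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scores_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _SCORE_COLS:
        raise PlateValidationError(f"{path}: not a scores table")
    return df
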