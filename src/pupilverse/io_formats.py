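"""Reading and writing the long-format sample tables and result tables.

The on-disk dialect is fixed: comma-separated, UTF-8, decimal point, one
header row, missing values written as empty fields.  One row of a sample
table is one eye-tracker sample; ``(participant_id, block, trial, t_trial)``
is a unique key.  Pupil diameters are in millimetres, gaze coordinates in
pixels with the origin at the top-left of the screen (x rightward, y
downward), and ``t_trial`` is milliseconds from the onset of the trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError, SchemaError, StateError

#: Required columns of a sample table, in storage order.
SAMPLE_COLUMNS = (
    "participant_id",
    "block",
    "trial",
    "t_trial",
    "pupil_left",
    "pupil_right",
    "gaze_x",
    "gaze_y",
)

#: Optional ground-truth columns a synthetic session may carry.
GROUND_TRUTH_COLUMNS = ("latent", "is_blink", "is_trackloss", "is_extreme")

#: The two familiarization block labels.
BLOCKS = ("audiovisual", "visual")

_KEY = ["participant_id", "block", "trial", "t_trial"]
_FLOAT_COLUMNS = ("t_trial", "pupil_left", "pupil_right", "gaze_x", "gaze_y", "latent")


@dataclass(frozen=True)
class ScreenGeometry:
    """Screen and area-of-interest rectangle, both in pixels.

    The AoI covers the central visual stimulus plus a safety margin; gaze
    membership uses the *closed* rectangle (points exactly on an edge count
    as inside).
    """

    width: float = 2560.0
    height: float = 1440.0
    aoi_left: float = 1012.0
    aoi_top: float = 452.0
    aoi_right: float = 1548.0
    aoi_bottom: float = 988.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ConfigError("screen dimensions must be positive")
        if not (self.aoi_left < self.aoi_right and self.aoi_top < self.aoi_bottom):
            raise ConfigError("AoI rectangle must satisfy left < right and top < bottom")
        if (
            self.aoi_left <= 0
            or self.aoi_top <= 0
            or self.aoi_right >= self.width
            or self.aoi_bottom >= self.height
        ):
            raise ConfigError("AoI rectangle must lie strictly inside the screen")

    def contains(self, x, y):
        """Vectorized closed-rectangle membership test for gaze points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.aoi_left)
            & (x <= self.aoi_right)
            & (y >= self.aoi_top)
            & (y <= self.aoi_bottom)
        )


# Default geometry: 27-inch 16:9 screen at 109 ppi viewed from 60 cm.  A
# 10 deg x 10 deg stimulus subtends ~105 mm ~ 450 px; a 1 cm margin adds
# ~43 px per side, centred on the screen.
DEFAULT_GEOMETRY = ScreenGeometry()


def validate_samples(table: pd.DataFrame) -> None:
    """Check a sample table against the schema; raise on violation.

    Raises
    ------
    SchemaError
        If a required column is absent (the message names it).
    IntegrityError
        If the (participant, block, trial, t_trial) key is duplicated, a
        block label is unknown, t_trial is negative, trial is < 1, or a
        present pupil value is non-positive.
    """
    for col in SAMPLE_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"required column {col!r} is missing")
    if len(table) == 0:
        return
    bad_blocks = set(table["block"].unique()) - set(BLOCKS)
    if bad_blocks:
        raise IntegrityError(f"unknown block labels: {sorted(bad_blocks)!r}")
    if table.duplicated(subset=_KEY).any():
        raise IntegrityError(
            "duplicate (participant_id, block, trial, t_trial) key in sample table"
        )
    if (table["t_trial"] < 0).any():
        raise IntegrityError("t_trial must be non-negative")
    if (table["trial"] < 1).any():
        raise IntegrityError("trial indices start at 1")
    for col in ("pupil_left", "pupil_right"):
        vals = table[col]
        if (vals.dropna() <= 0).any():
            raise IntegrityError(f"{col} must be positive where present")


def _ordered_columns(table: pd.DataFrame) -> list[str]:
    cols = list(SAMPLE_COLUMNS)
    cols += [c for c in GROUND_TRUTH_COLUMNS if c in table.columns]
    return cols


def read_samples(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a sample table from delimited text.

    Parameters
    ----------
    path
        CSV file written by :func:`write_samples` (or matching its schema).
    column_map
        Optional mapping from the file's column names to the schema names,
        the hook for ingesting third-party exports
        (e.g. ``{"id": "participant_id"}``).
    """
    table = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        table = table.rename(columns=dict(column_map))
    validate_samples(table)
    table = table[_ordered_columns(table)].copy()
    table["participant_id"] = table["participant_id"].astype(int)
    table["trial"] = table["trial"].astype(int)
    table["block"] = table["block"].astype(str)
    for col in _FLOAT_COLUMNS:
        if col in table.columns:
            table[col] = table[col].astype(float)
    for col in ("is_blink", "is_trackloss", "is_extreme"):
        if col in table.columns:
            table[col] = table[col].astype(int)
    return table.reset_index(drop=True)


def write_samples(table: pd.DataFrame, path) -> Path:
    """Write a sample table as CSV with the fixed dialect; returns the path."""
    validate_samples(table)
    path = Path(path)
    out = table[_ordered_columns(table)].copy()
    for col in ("is_blink", "is_trackloss", "is_extreme"):
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False, na_rep="")
    return path


def write_results(curve, comparisons, path_prefix) -> tuple[Path, Path]:
    """Write the two tidy multiverse result tables.

    ``{prefix}_estimates.csv`` holds one row per (dataset x model) effect
    estimate (96 on a complete run); ``{prefix}_comparisons.csv`` holds one
    row per dataset (48) with the BIC and R-squared comparison.

    Raises
    ------
    StateError
        If the run is incomplete (no points or no comparisons); nothing is
        written in that case.
    """
    est = curve.to_frame() if hasattr(curve, "to_frame") else curve
    comp = (
        pd.DataFrame([c.to_record() for c in comparisons])
        if comparisons and hasattr(comparisons[0], "to_record")
        else pd.DataFrame(comparisons)
    )
    if est is None or len(est) == 0 or len(comp) == 0:
        raise StateError("multiverse run incomplete: no estimates or no comparisons")
    prefix = Path(path_prefix)
    est_path = prefix.with_name(prefix.name + "_estimates.csv")
    comp_path = prefix.with_name(prefix.name + "_comparisons.csv")
    est.to_csv(est_path, index=False, na_rep="")
    comp.to_csv(comp_path, index=False, na_rep="")
    return est_path, comp_path
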