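"""The five forking preprocessing operators and the 48-dataset lattice.

Each recording admits several arbitrary-but-plausible preprocessing
choices ("researcher degrees of freedom"):

1. extreme values  -- keep everything, or keep only 2 mm < pupil < 8 mm
                      (strict inequalities);
2. area of interest -- keep the whole screen, or only samples whose gaze
                      falls inside the closed AoI rectangle;
3. gaps            -- drop missing samples, or linearly interpolate
                      interior gaps (blinks) within a participant x block;
4. baseline        -- subtract the per-trial median of the first 16, 100
                      or 200 ms;
5. participants    -- keep everyone, or exclude participants with more
                      than 30% missing samples (strictly greater).

The cross of all levels (2 x 2 x 2 x 3 x 2) yields 48 processed datasets
from one recording; operators are applied in the fixed order listed, with
participant exclusion last and missingness measured after the filters but
before gap handling.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import ScreenGeometry

__all__ = [
    "ForkSpec",
    "ProcessedDataset",
    "BlinkSegment",
    "all_forks",
    "average_eyes",
    "filter_extreme",
    "filter_aoi",
    "find_missing_runs",
    "detect_blinks",
    "handle_gaps",
    "baseline_correct",
    "participant_missingness",
    "build_multiverse",
]

EXTREME_LEVELS = ("all_values", "trimmed")
AOI_LEVELS = ("whole_screen", "aoi_only")
GAP_LEVELS = ("exclude", "interpolate")
BASELINE_LEVELS = (16, 100, 200)
PARTICIPANT_LEVELS = ("include_all", "exclude_high_missing")

_TOKENS = {
    "all_values": "all",
    "trimmed": "trimmed",
    "whole_screen": "screen",
    "aoi_only": "aoi",
    "exclude": "drop",
    "interpolate": "interp",
    "include_all": "incl",
    "exclude_high_missing": "excl",
}
_FROM_TOKEN = {v: k for k, v in _TOKENS.items()}

MISSING_THRESHOLD = 0.30  # strict: flag participants with fraction > 0.30


@dataclass(frozen=True)
class ForkSpec:
    """One point of the 2x2x2x3x2 preprocessing lattice."""

    extreme_filter: str = "all_values"
    aoi_filter: str = "whole_screen"
    gap_handling: str = "exclude"
    baseline_ms: int = 100
    participant_rule: str = "include_all"

    def __post_init__(self) -> None:
        checks = (
            (self.extreme_filter, EXTREME_LEVELS, "extreme_filter"),
            (self.aoi_filter, AOI_LEVELS, "aoi_filter"),
            (self.gap_handling, GAP_LEVELS, "gap_handling"),
            (self.baseline_ms, BASELINE_LEVELS, "baseline_ms"),
            (self.participant_rule, PARTICIPANT_LEVELS, "participant_rule"),
        )
        for value, levels, name in checks:
            if value not in levels:
                raise ConfigError(f"{name} must be one of {levels}, got {value!r}")

    @property
    def token(self) -> str:
        """Short serialization, e.g. ``trimmed|aoi|interp|100|excl``."""
        return "|".join(
            [
                _TOKENS[self.extreme_filter],
                _TOKENS[self.aoi_filter],
                _TOKENS[self.gap_handling],
                str(self.baseline_ms),
                _TOKENS[self.participant_rule],
            ]
        )

    @classmethod
    def from_token(cls, token: str) -> "ForkSpec":
        parts = token.split("|")
        if len(parts) != 5:
            raise ConfigError(f"fork token must have 5 fields: {token!r}")
        try:
            return cls(
                extreme_filter=_FROM_TOKEN[parts[0]],
                aoi_filter=_FROM_TOKEN[parts[1]],
                gap_handling=_FROM_TOKEN[parts[2]],
                baseline_ms=int(parts[3]),
                participant_rule=_FROM_TOKEN[parts[4]],
            )
        except KeyError as exc:
            raise ConfigError(f"unknown fork level in token {token!r}") from exc


def all_forks() -> list[ForkSpec]:
    """The 48 fork specifications in deterministic lattice order."""
    return [
        ForkSpec(ef, af, gap, bl, pr)
        for ef, af, gap, bl, pr in itertools.product(
            EXTREME_LEVELS, AOI_LEVELS, GAP_LEVELS, BASELINE_LEVELS, PARTICIPANT_LEVELS
        )
    ]


@dataclass(frozen=True)
class BlinkSegment:
    """A maximal run of missing samples, in block time (ms)."""

    participant_id: int
    block: str
    start: float
    end: float
    n_samples: int
    kind: str = "blink"  # or "trackloss"


@dataclass
class ProcessedDataset:
    """Model-ready dataset for one fork: rows (id, block, trial, t_trial, y)."""

    fork: ForkSpec
    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    degenerate: bool = False

    @property
    def token(self) -> str:
        return self.fork.token


# ---------------------------------------------------------------------------
# individual operators
# ---------------------------------------------------------------------------

_MONO_COLUMNS = ["participant_id", "block", "trial", "t_trial", "pupil", "gaze_x", "gaze_y"]


def average_eyes(table: pd.DataFrame) -> pd.DataFrame:
    """Average the two eyes into one monocular series.

    The per-sample pupil is the mean of the two eyes when both are
    observed and missing otherwise; one-eye samples stay missing here and
    are resolved by gap handling (dropped or interpolated).
    """
    out = table.copy()
    left = out["pupil_left"].to_numpy(dtype=float)
    right = out["pupil_right"].to_numpy(dtype=float)
    pupil = 0.5 * (left + right)  # NaN if either eye is NaN
    out["pupil"] = pupil
    keep = [c for c in _MONO_COLUMNS if c in out.columns]
    extra = [c for c in ("latent",) if c in out.columns]
    return out[keep + extra]


def filter_extreme(series: pd.DataFrame, low: float = 2.0, high: float = 8.0) -> pd.DataFrame:
    """Set pupil values outside the open interval (low, high) to missing.

    Strict inequalities: a value of exactly 2.0 or 8.0 mm is removed.
    """
    if low >= high:
        raise ConfigError(f"low must be < high, got ({low}, {high})")
    out = series.copy()
    p = out["pupil"].to_numpy(dtype=float)
    bad = np.isfinite(p) & ~((p > low) & (p < high))
    out.loc[bad, "pupil"] = np.nan
    return out


def filter_aoi(series: pd.DataFrame, geom: ScreenGeometry) -> pd.DataFrame:
    """Set pupil to missing where gaze is absent or outside the closed AoI."""
    if not isinstance(geom, ScreenGeometry):
        raise ConfigError("geom must be a ScreenGeometry")
    out = series.copy()
    x = out["gaze_x"].to_numpy(dtype=float)
    y = out["gaze_y"].to_numpy(dtype=float)
    inside = np.zeros(len(out), dtype=bool)
    finite = np.isfinite(x) & np.isfinite(y)
    inside[finite] = geom.contains(x[finite], y[finite])
    out.loc[~inside, "pupil"] = np.nan
    return out


def _block_time(df: pd.DataFrame, trial_duration: float) -> np.ndarray:
    return (df["trial"].to_numpy() - 1) * trial_duration + df["t_trial"].to_numpy()


def _infer_dt(series: pd.DataFrame) -> float:
    t = np.sort(series["t_trial"].unique())
    if len(t) < 2:
        return 1000.0 / 60.0
    return float(np.median(np.diff(t)))


def _infer_trial_duration(series: pd.DataFrame) -> float:
    if len(series) == 0:
        return 1000.0
    t = series["t_trial"].to_numpy()
    dt = _infer_dt(series)
    return float(t.max() + dt)


def find_missing_runs(series: pd.DataFrame, max_blink_ms: float = 500.0) -> list[BlinkSegment]:
    """All maximal missing runs per (participant, block), classified.

    Runs of duration <= ``max_blink_ms`` are blinks; longer runs are
    trackloss.  Times are in block time (ms from block onset).
    """
    dt = _infer_dt(series)
    trial_duration = _infer_trial_duration(series)
    segments: list[BlinkSegment] = []
    for (pid, block), grp in series.groupby(["participant_id", "block"], sort=True):
        grp = grp.sort_values(["trial", "t_trial"])
        missing = grp["pupil"].isna().to_numpy()
        t = _block_time(grp, trial_duration)
        if not missing.any():
            continue
        # boundaries of runs of consecutive True
        padded = np.concatenate([[False], missing, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for s, e in zip(starts, ends):
            n = int(e - s)
            duration = n * dt
            segments.append(
                BlinkSegment(
                    participant_id=int(pid),
                    block=str(block),
                    start=float(t[s]),
                    end=float(t[e - 1] + dt),
                    n_samples=n,
                    kind="blink" if duration <= max_blink_ms else "trackloss",
                )
            )
    return segments


def detect_blinks(series: pd.DataFrame, max_blink_ms: float = 500.0) -> list[BlinkSegment]:
    """Maximal missing runs short enough to be blinks (<= max_blink_ms)."""
    return [s for s in find_missing_runs(series, max_blink_ms) if s.kind == "blink"]


def handle_gaps(series: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Resolve missing samples: drop them, or linearly interpolate interior gaps.

    In ``interpolate`` mode interior missing runs are filled by linear
    interpolation over block time between the nearest observed neighbours
    within the same (participant, block); leading/trailing runs have no
    neighbour on one side and are dropped.  Observed values are never
    altered.  A (participant, block) with zero observed samples is dropped
    with a warning.  The returned table has no missing pupil values.
    """
    if mode not in GAP_LEVELS:
        raise ConfigError(f"gap mode must be one of {GAP_LEVELS}, got {mode!r}")
    if mode == "exclude" or len(series) == 0:
        return series[series["pupil"].notna()].copy()

    trial_duration = _infer_trial_duration(series)
    pieces = []
    for (pid, block), grp in series.groupby(["participant_id", "block"], sort=False):
        grp = grp.sort_values(["trial", "t_trial"]).copy()
        p = grp["pupil"].to_numpy(dtype=float)
        obs = np.isfinite(p)
        if not obs.any():
            warnings.warn(
                f"participant {pid} block {block!r}: no observed samples, unit dropped",
                stacklevel=2,
            )
            continue
        t = _block_time(grp, trial_duration)
        filled = p.copy()
        interior = ~obs
        interior[: np.argmax(obs)] = False  # leading run
        last = len(obs) - 1 - np.argmax(obs[::-1])
        interior[last + 1 :] = False  # trailing run
        if interior.any():
            filled[interior] = np.interp(t[interior], t[obs], p[obs])
        grp["pupil"] = filled
        pieces.append(grp[np.isfinite(filled)])
    if not pieces:
        return series.iloc[0:0].copy()
    return pd.concat(pieces).sort_index().reset_index(drop=True)


def baseline_correct(
    series: pd.DataFrame, window_ms: int, method: str = "subtractive"
) -> pd.DataFrame:
    """Per-trial baseline correction of a gap-handled series.

    For each (participant, block, trial) the baseline is the median of the
    observed samples with ``t_trial < window_ms``; the corrected value is
    ``y = pupil - baseline`` (subtractive) or ``y = pupil / baseline``
    (divisive).  Trials with no observed sample inside the window are
    dropped, as are divisive trials with a non-positive baseline (with a
    warning).
    """
    if method not in ("subtractive", "divisive"):
        raise ConfigError(f"unknown baseline method {method!r}")
    if window_ms <= 0:
        raise ConfigError("window_ms must be positive")
    out = series[series["pupil"].notna()].copy()
    if len(out) == 0:
        out["y"] = pd.Series(dtype=float)
        return out

    keys = ["participant_id", "block", "trial"]
    in_window = out["t_trial"].to_numpy() < float(window_ms)
    base = (
        out.loc[in_window]
        .groupby(keys, sort=False)["pupil"]
        .median()
        .rename("baseline")
    )
    out = out.join(base, on=keys)
    n_no_window = out["baseline"].isna()
    out = out[~n_no_window].copy()
    if method == "subtractive":
        out["y"] = out["pupil"] - out["baseline"]
    else:
        bad = out["baseline"] <= 0
        if bad.any():
            n_bad = out.loc[bad, keys].drop_duplicates().shape[0]
            warnings.warn(
                f"divisive baseline: {n_bad} trial(s) with non-positive baseline dropped",
                stacklevel=2,
            )
            out = out[~bad].copy()
        out["y"] = out["pupil"] / out["baseline"]
    return out.drop(columns=["baseline"])


def participant_missingness(series: pd.DataFrame) -> pd.DataFrame:
    """Per-participant missing fraction, measured post-filter / pre-gap-handling.

    Expects one row per expected sample (filters mark pupil missing rather
    than dropping rows).  Returns a frame indexed by participant with
    columns ``fraction`` and ``flagged`` (strictly greater than 30%).
    """
    g = series.groupby("participant_id")["pupil"]
    frac = g.apply(lambda s: float(s.isna().mean()))
    return pd.DataFrame(
        {"fraction": frac, "flagged": frac > MISSING_THRESHOLD}
    )


# ---------------------------------------------------------------------------
# lattice construction
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = ["participant_id", "block", "trial", "t_trial", "y"]


def build_multiverse(
    table: pd.DataFrame,
    geom: ScreenGeometry,
    *,
    low: float = 2.0,
    high: float = 8.0,
    max_blink_ms: float = 500.0,
    forks: Iterable[ForkSpec] | None = None,
    counts: dict | None = None,
) -> list[ProcessedDataset]:
    """Apply every fork of the preprocessing lattice to one recording.

    Operators run in the fixed order: eye averaging, extreme-value filter,
    AoI filter, gap handling, subtractive baseline correction, participant
    exclusion.  Returns one :class:`ProcessedDataset` per fork (48 for the
    full lattice), each carrying provenance counts; forks that end with no
    rows are flagged degenerate but kept in the lattice.

    If ``counts`` is a dict it receives the number of distinct intermediate
    datasets constructed after steps 1-2, 1-3 and 1-4 (the growth of the
    lattice: 4, 8, 24 for the full fork set).
    """
    wanted = list(forks) if forks is not None else all_forks()
    mono = average_eyes(table)
    n_input = int(mono["pupil"].notna().sum())

    results: dict[str, ProcessedDataset] = {}
    n_filter_variants = 0
    n_gap_variants = 0
    n_baseline_variants = 0

    for ef in EXTREME_LEVELS:
        if not any(f.extreme_filter == ef for f in wanted):
            continue
        df1 = filter_extreme(mono, low, high) if ef == "trimmed" else mono
        n_after_extreme = int(df1["pupil"].notna().sum())
        for af in AOI_LEVELS:
            sub_af = [f for f in wanted if f.extreme_filter == ef and f.aoi_filter == af]
            if not sub_af:
                continue
            df2 = filter_aoi(df1, geom) if af == "aoi_only" else df1
            n_after_aoi = int(df2["pupil"].notna().sum())
            n_filter_variants += 1
            missing = participant_missingness(df2)
            flagged = set(missing.index[missing["flagged"]])
            for gap in GAP_LEVELS:
                sub_gap = [f for f in sub_af if f.gap_handling == gap]
                if not sub_gap:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    df3 = handle_gaps(df2, gap)
                n_gap_variants += 1
                n_interpolated = (
                    int(len(df3) - n_after_aoi) if gap == "interpolate" else 0
                )
                for bl in BASELINE_LEVELS:
                    sub_bl = [f for f in sub_gap if f.baseline_ms == bl]
                    if not sub_bl:
                        continue
                    df4 = baseline_correct(df3, bl, method="subtractive")
                    n_baseline_variants += 1
                    trials_before = df3.groupby(
                        ["participant_id", "block", "trial"]
                    ).ngroups
                    trials_after = df4.groupby(
                        ["participant_id", "block", "trial"]
                    ).ngroups
                    for fork in sub_bl:
                        if fork.participant_rule == "exclude_high_missing":
                            df5 = df4[~df4["participant_id"].isin(flagged)]
                            excluded = sorted(flagged)
                        else:
                            df5 = df4
                            excluded = []
                        data = df5[_RESULT_COLUMNS].reset_index(drop=True)
                        provenance = {
                            "n_input_observed": n_input,
                            "n_extreme_removed": n_input - n_after_extreme,
                            "n_aoi_removed": n_after_extreme - n_after_aoi,
                            "n_interpolated": n_interpolated,
                            "n_trials_dropped_baseline": trials_before - trials_after,
                            "participants_excluded": excluded,
                            "missing_fraction": {
                                int(k): float(v)
                                for k, v in missing["fraction"].items()
                            },
                            "n_rows": int(len(data)),
                        }
                        results[fork.token] = ProcessedDataset(
                            fork=fork,
                            data=data,
                            provenance=provenance,
                            degenerate=len(data) == 0,
                        )
    if counts is not None:
        counts["after_step_2"] = n_filter_variants
        counts["after_step_3"] = n_gap_variants
        counts["after_step_4"] = n_baseline_variants
        counts["full_lattice"] = len(results)
    return [results[f.token] for f in wanted]
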