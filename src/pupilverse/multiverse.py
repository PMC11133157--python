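"""Orchestrate the full lattice run, specification curve and diagnostics.

For each of the 48 preprocessed datasets both candidate models are
fitted; the per-dataset comparison records delta BIC (candidate minus the
within-dataset best) and both adjusted R^2 values, and the specification
curve collects all (dataset x model) estimates of the Visual -
Audiovisual block effect, sorted by magnitude and annotated with each
specification's forks and significance.  Forks whose dataset is
degenerate or whose fit fails stay visible as flagged gaps rather than
disappearing — the multiverse reports every path taken.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .gamm import (
    NO_TIME_MODEL,
    TIME_MODEL,
    ModelSpec,
    delta_bic_label,
    fit_model,
)
from .io_formats import ScreenGeometry
from .preprocess import (
    EXTREME_LEVELS,
    AOI_LEVELS,
    ForkSpec,
    average_eyes,
    build_multiverse,
    detect_blinks,
    filter_aoi,
    filter_extreme,
    participant_missingness,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SpecCurvePoint",
    "SpecCurve",
    "ModelComparison",
    "MultiverseResult",
    "run_multiverse",
    "build_spec_curve",
    "diagnostics",
]


@dataclass(frozen=True)
class SpecCurvePoint:
    """One estimate of the block effect under one full specification."""

    fork: ForkSpec
    model_kind: str
    estimate: float | None
    ci: tuple | None
    significant: bool | None
    direction: str | None  # positive / negative / none
    absent: bool = False
    reason: str | None = None


@dataclass
class SpecCurve:
    """All specification-curve points, sorted ascending by estimate."""

    points: list
    n_positive: int
    n_negative: int
    n_nonsig: int
    n_absent: int

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pt in self.points:
            rows.append(
                {
                    "fork": pt.fork.token,
                    "extreme_filter": pt.fork.extreme_filter,
                    "aoi_filter": pt.fork.aoi_filter,
                    "gap_handling": pt.fork.gap_handling,
                    "baseline_ms": pt.fork.baseline_ms,
                    "participant_rule": pt.fork.participant_rule,
                    "model_kind": pt.model_kind,
                    "estimate": pt.estimate,
                    "ci_low": pt.ci[0] if pt.ci else None,
                    "ci_high": pt.ci[1] if pt.ci else None,
                    "significant": pt.significant,
                    "direction": pt.direction,
                    "absent": pt.absent,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class ModelComparison:
    """Within-dataset BIC/R^2 comparison of the two candidate models."""

    fork: ForkSpec
    status: str  # "ok", "degenerate", "fit_error"
    winner: str | None = None
    delta_bic: float | None = None  # loser's BIC minus winner's (>= 0)
    evidence_label: str | None = None
    bic_time: float | None = None
    bic_no_time: float | None = None
    r2_time: float | None = None
    r2_no_time: float | None = None
    reason: str | None = None

    def to_record(self) -> dict:
        return {
            "fork": self.fork.token,
            "extreme_filter": self.fork.extreme_filter,
            "aoi_filter": self.fork.aoi_filter,
            "gap_handling": self.fork.gap_handling,
            "baseline_ms": self.fork.baseline_ms,
            "participant_rule": self.fork.participant_rule,
            "status": self.status,
            "winner": self.winner,
            "delta_bic": self.delta_bic,
            "evidence_label": self.evidence_label,
            "bic_time": self.bic_time,
            "bic_no_time": self.bic_no_time,
            "r2_time": self.r2_time,
            "r2_no_time": self.r2_no_time,
        }


@dataclass
class MultiverseResult:
    """Everything a full lattice run produced."""

    datasets: list
    fits: dict  # token -> {kind: FitResult | None}
    fit_errors: dict  # (token, kind) -> reason
    comparisons: list
    timings: dict = field(default_factory=dict)

    @property
    def n_fits(self) -> int:
        return sum(1 for d in self.fits.values() for f in d.values() if f is not None)


def run_multiverse(
    table: pd.DataFrame,
    geom: ScreenGeometry,
    time_spec: ModelSpec | None = None,
    no_time_spec: ModelSpec | None = None,
    *,
    forks=None,
    max_blink_ms: float = 500.0,
) -> MultiverseResult:
    """Build the preprocessing lattice and fit both models to every dataset.

    Fit errors are recorded per fork, never fatal to the run.
    """
    time_spec = time_spec or ModelSpec(kind=TIME_MODEL)
    no_time_spec = no_time_spec or ModelSpec(kind=NO_TIME_MODEL)
    datasets = build_multiverse(table, geom, max_blink_ms=max_blink_ms, forks=forks)

    fits: dict = {}
    fit_errors: dict = {}
    comparisons: list[ModelComparison] = []
    timings: dict = {}

    for ds in datasets:
        token = ds.token
        fits[token] = {TIME_MODEL: None, NO_TIME_MODEL: None}
        if ds.degenerate:
            comparisons.append(
                ModelComparison(fork=ds.fork, status="degenerate", reason="no rows")
            )
            logger.info("fork=%s status=degenerate", token)
            continue
        t0 = time.perf_counter()
        for kind, spec in ((TIME_MODEL, time_spec), (NO_TIME_MODEL, no_time_spec)):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fits[token][kind] = fit_model(ds, spec)
            except Exception as exc:  # recorded, not raised
                fit_errors[(token, kind)] = str(exc)
        timings[token] = time.perf_counter() - t0

        ft = fits[token][TIME_MODEL]
        fn = fits[token][NO_TIME_MODEL]
        if ft is None or fn is None:
            comparisons.append(
                ModelComparison(
                    fork=ds.fork,
                    status="fit_error",
                    reason="; ".join(
                        fit_errors.get((token, k), "")
                        for k in (TIME_MODEL, NO_TIME_MODEL)
                    ),
                    bic_time=None if ft is None else ft.bic,
                    bic_no_time=None if fn is None else fn.bic,
                    r2_time=None if ft is None else ft.r2,
                    r2_no_time=None if fn is None else fn.r2,
                )
            )
            logger.info("fork=%s status=fit_error", token)
            continue
        winner = TIME_MODEL if ft.bic <= fn.bic else NO_TIME_MODEL
        delta = abs(ft.bic - fn.bic)
        comparisons.append(
            ModelComparison(
                fork=ds.fork,
                status="ok",
                winner=winner,
                delta_bic=delta,
                evidence_label=delta_bic_label(delta),
                bic_time=ft.bic,
                bic_no_time=fn.bic,
                r2_time=ft.r2,
                r2_no_time=fn.r2,
            )
        )
        logger.info(
            "fork=%s rows=%d bic_time=%.1f bic_no_time=%.1f beta=%.4f t=%.2fs",
            token, len(ds.data), ft.bic, fn.bic, ft.beta_hat, timings[token],
        )
    return MultiverseResult(
        datasets=datasets,
        fits=fits,
        fit_errors=fit_errors,
        comparisons=comparisons,
        timings=timings,
    )


def _point_from_fit(fork: ForkSpec, kind: str, fit, reason=None) -> SpecCurvePoint:
    if fit is None:
        return SpecCurvePoint(
            fork=fork, model_kind=kind, estimate=None, ci=None,
            significant=None, direction=None, absent=True, reason=reason,
        )
    lo, hi = fit.beta_ci
    significant = bool(lo > 0 or hi < 0)
    if significant:
        direction = "positive" if fit.beta_hat > 0 else "negative"
    else:
        direction = "none"
    return SpecCurvePoint(
        fork=fork, model_kind=kind, estimate=float(fit.beta_hat),
        ci=(float(lo), float(hi)), significant=significant, direction=direction,
    )


def build_spec_curve(result: MultiverseResult) -> SpecCurve:
    """Assemble the specification curve from a completed run.

    Points are sorted ascending by estimate (ties broken by fork token and
    model kind); absent points (degenerate datasets, failed fits) come
    last and are excluded from the direction counts.  Assembly is a pure
    function of the fit list.
    """
    points = []
    for ds in result.datasets:
        for kind in (TIME_MODEL, NO_TIME_MODEL):
            fit = result.fits.get(ds.token, {}).get(kind)
            reason = result.fit_errors.get((ds.token, kind))
            if ds.degenerate:
                reason = reason or "degenerate dataset"
            points.append(_point_from_fit(ds.fork, kind, fit, reason))
    present = [p for p in points if not p.absent]
    absent = [p for p in points if p.absent]
    present.sort(key=lambda p: (p.estimate, p.fork.token, p.model_kind))
    absent.sort(key=lambda p: (p.fork.token, p.model_kind))
    return SpecCurve(
        points=present + absent,
        n_positive=sum(1 for p in present if p.direction == "positive"),
        n_negative=sum(1 for p in present if p.direction == "negative"),
        n_nonsig=sum(1 for p in present if p.direction == "none"),
        n_absent=len(absent),
    )


def diagnostics(
    table: pd.DataFrame,
    geom: ScreenGeometry,
    *,
    max_blink_ms: float = 500.0,
) -> dict:
    """Missingness and blink diagnostics of one raw recording.

    Returns a dict of tidy tables:

    ``eye_patterns``
        counts of samples by eye-missingness pattern (both observed, left
        only missing, right only missing, both missing);
    ``trackloss_by_trial``
        per participant x block x trial missing fraction of the averaged
        series (trackloss over experiment time);
    ``blink_counts``
        per-participant blink counts under each of the four pre-gap
        filter variants (extreme x AoI);
    ``missingness``
        per-participant missing percentage with the 30% cut-off flag
        (computed on the unfiltered averaged series).
    """
    left_na = table["pupil_left"].isna()
    right_na = table["pupil_right"].isna()
    eye_patterns = pd.DataFrame(
        {
            "pattern": ["both_observed", "left_missing", "right_missing", "both_missing"],
            "n_samples": [
                int((~left_na & ~right_na).sum()),
                int((left_na & ~right_na).sum()),
                int((~left_na & right_na).sum()),
                int((left_na & right_na).sum()),
            ],
        }
    )

    mono = average_eyes(table)
    trackloss = (
        mono.assign(missing=mono["pupil"].isna())
        .groupby(["participant_id", "block", "trial"], as_index=False)["missing"]
        .mean()
        .rename(columns={"missing": "missing_fraction"})
    )

    blink_rows = []
    for ef in EXTREME_LEVELS:
        df1 = filter_extreme(mono) if ef == "trimmed" else mono
        for af in AOI_LEVELS:
            df2 = filter_aoi(df1, geom) if af == "aoi_only" else df1
            segs = detect_blinks(df2, max_blink_ms)
            counts = pd.Series([s.participant_id for s in segs]).value_counts().to_dict()
            for pid in sorted(mono["participant_id"].unique()):
                blink_rows.append(
                    {
                        "extreme_filter": ef,
                        "aoi_filter": af,
                        "participant_id": int(pid),
                        "n_blinks": int(counts.get(pid, 0)),
                    }
                )
    blink_counts = pd.DataFrame(blink_rows)

    miss = participant_missingness(mono).reset_index()
    miss["percent_missing"] = 100.0 * miss["fraction"]

    return {
        "eye_patterns": eye_patterns,
        "trackloss_by_trial": trackloss,
        "blink_counts": blink_counts,
        "missingness": miss[["participant_id", "fraction", "percent_missing", "flagged"]],
    }
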