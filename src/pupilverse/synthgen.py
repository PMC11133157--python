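"""Synthetic two-eye familiarization sessions with known ground truth.

The generator emulates the structure of a 60-Hz binocular infant
pupillometry recording: each participant completes two familiarization
blocks (audiovisual and visual), each made of nine consecutive 1-s trials.
The latent pupil signal is

    latent(p, block, t) = tonic_p
                          + r(t)
                          + 1[block == visual] * (beta_true + diff_curve(t))
                          + f_p(t)

where ``tonic_p`` is a participant-level tonic pupil diameter, ``r(t)`` is
the common event-locked response within each trial (a decline of pupil
size over the second after stimulus onset, the familiarization signature
both blocks share), the condition difference carries a constant offset
``beta_true`` plus a zero-mean time course ``diff_curve`` over the trial
window, and ``f_p`` is a smooth zero-mean per-participant random curve.  Both observed eyes are
the latent signal plus correlated white measurement noise.  Artifacts are
injected afterwards: blinks (short binocular missing runs), trackloss
(longer runs, possibly monocular), and occasional extreme-yet-plausible
pupil values outside the 2-8 mm physiological band.  Gaze points are a
mixture of uniform draws inside the central area of interest and uniform
spill-over across the rest of the screen.

Everything is driven by a single integer seed, so a session is exactly
reproducible, and the ground truth (latent signal and artifact flags) is
retained in dedicated columns for parameter-recovery tests downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import BLOCKS, DEFAULT_GEOMETRY, SAMPLE_COLUMNS, ScreenGeometry

__all__ = [
    "SessionConfig",
    "TrueEffect",
    "sinusoidal_diff_curve",
    "linear_decline",
    "generate_session",
    "inject_artifacts",
    "true_difference",
]


@dataclass
class SessionConfig:
    """Configuration of one synthetic recording session.

    Rates and probabilities are fractions in [0, 1] except ``blink_rate``
    (blinks per second of recording).  ``trackloss_sd_between`` spreads the
    trackloss rate across participants (lognormal multiplier), mirroring
    the large between-infant differences in data quality seen in real
    sessions.  Participants listed in ``high_missing_ids`` receive extra
    trackloss until more than 30% of their samples are missing.
    """

    n_participants: int = 16
    sampling_rate: float = 60.0  # Hz
    n_blocks: int = 2  # fixed: audiovisual, visual
    n_trials: int = 9
    trial_duration: float = 1000.0  # ms
    tonic_mean: float = 4.0  # mm
    tonic_sd_between: float = 0.3  # mm
    noise_sd: float = 0.15  # mm, white sample noise
    eye_corr: float = 0.9  # correlation of left/right measurement noise
    blink_rate: float = 0.1  # blinks per second
    blink_duration: tuple[float, float] = (100.0, 400.0)  # ms
    trackloss_rate: float = 0.12  # mean fraction of samples lost in long runs
    trackloss_sd_between: float = 0.25  # lognormal sigma of per-participant multiplier
    extreme_rate: float = 0.01  # fraction of samples replaced by out-of-band values
    aoi_inside_prob: float = 0.9  # probability a gaze sample falls inside the AoI
    high_missing_ids: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        if self.n_blocks != 2:
            raise ConfigError("n_blocks is fixed at 2 (audiovisual, visual)")
        if self.n_trials <= 0:
            raise ConfigError("n_trials must be positive")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if self.samples_per_trial < 1:
            raise ConfigError("trial_duration must contain at least one sample")
        for name in ("trackloss_rate", "extreme_rate", "aoi_inside_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.eye_corr <= 1.0:
            raise ConfigError("eye_corr must be in [0, 1]")
        if self.blink_rate < 0:
            raise ConfigError("blink_rate must be >= 0")
        lo, hi = self.blink_duration
        if not 0 < lo <= hi:
            raise ConfigError("blink_duration must be an increasing positive range")
        if self.noise_sd < 0 or self.tonic_sd_between < 0 or self.trackloss_sd_between < 0:
            raise ConfigError("standard deviations must be >= 0")

    @property
    def samples_per_trial(self) -> int:
        return int(math.floor(self.trial_duration * self.sampling_rate / 1000.0))

    @property
    def dt(self) -> float:
        """Sample spacing in ms."""
        return 1000.0 / self.sampling_rate

    @property
    def n_samples_per_participant(self) -> int:
        return self.n_blocks * self.n_trials * self.samples_per_trial


def sinusoidal_diff_curve(amplitude: float = 0.25, period: float = 1000.0) -> Callable:
    """Zero-mean early-positive / late-negative condition time course (mm).

    One full sine period over the trial window: the visual block runs above
    the audiovisual block early in the trial and below it late, the shape
    the difference-smooth analysis is expected to recover.
    """

    def curve(t):
        return amplitude * np.sin(2.0 * np.pi * np.asarray(t, dtype=float) / period)

    return curve


def _zero_curve(t):
    return np.zeros_like(np.asarray(t, dtype=float))


def linear_decline(amplitude: float = 0.4, period: float = 1000.0) -> Callable:
    """Common event-locked trial response: pupil declines over the trial.

    Repeated stimulation reduces the phasic dilation response within each
    trial; both familiarization blocks share this decline, which is the
    dominant time structure of a familiarization recording.
    """

    def curve(t):
        return -amplitude * np.asarray(t, dtype=float) / period

    return curve


@dataclass
class TrueEffect:
    """Ground-truth Visual - Audiovisual effect.

    ``beta_true`` is the constant mean offset (mm); ``diff_curve`` the
    zero-mean time course over the trial window; ``participant_curve_sd``
    the amplitude (mm) of the smooth random per-participant time curves;
    ``trial_response`` the common event-locked time course both blocks
    share (it cancels in the Visual - Audiovisual difference).
    """

    beta_true: float = 0.05
    diff_curve: Callable = field(default_factory=sinusoidal_diff_curve)
    participant_curve_sd: float = 0.2
    trial_response: Callable = field(default_factory=linear_decline)

    def validate(self, trial_duration: float, samples_per_trial: int) -> None:
        """Check that diff_curve is (numerically) zero-mean over the trial."""
        t = np.arange(samples_per_trial) * trial_duration / samples_per_trial
        vals = np.asarray(self.diff_curve(t), dtype=float)
        scale = max(1e-9, float(np.max(np.abs(vals))))
        if abs(float(np.mean(vals))) > 1e-6 + 1e-3 * scale:
            raise ConfigError(
                "diff_curve must be zero-mean over the trial window; "
                "the constant part of the effect belongs in beta_true"
            )


def true_difference(effect: TrueEffect, t, trial_duration: float = 1000.0):
    """Ground-truth Visual - Audiovisual pupil difference (mm) at trial time t.

    The oracle for parameter-recovery tests: ``beta_true + diff_curve(t)``.

    Raises
    ------
    ValueError
        If any t lies outside [0, trial_duration].
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > trial_duration):
        raise ValueError(f"t must lie within [0, {trial_duration}] ms")
    out = effect.beta_true + np.asarray(effect.diff_curve(t_arr), dtype=float)
    return float(out) if np.isscalar(t) else out


def _participant_curves(rng, n: int, sd: float) -> np.ndarray:
    """Random coefficients of smooth zero-mean curves, one row per participant.

    Curves are linear combinations of the shifted Legendre polynomials of
    degree 1-3 on [0, 1] (orthonormal, each with zero mean), scaled so the
    expected variance over the window equals sd**2.
    """
    return rng.standard_normal((n, 3)) * (sd / math.sqrt(3.0))


def _eval_participant_curve(coefs: np.ndarray, s: np.ndarray) -> np.ndarray:
    p1 = math.sqrt(3.0) * (2.0 * s - 1.0)
    p2 = math.sqrt(5.0) * (6.0 * s**2 - 6.0 * s + 1.0)
    p3 = math.sqrt(7.0) * (20.0 * s**3 - 30.0 * s**2 + 12.0 * s - 1.0)
    return coefs[0] * p1 + coefs[1] * p2 + coefs[2] * p3


def _empty_table() -> pd.DataFrame:
    cols = list(SAMPLE_COLUMNS) + ["latent", "is_blink", "is_trackloss", "is_extreme"]
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
    for c in ("participant_id", "trial", "is_blink", "is_trackloss", "is_extreme"):
        df[c] = df[c].astype(int)
    df["block"] = df["block"].astype(str)
    return df


def generate_session(
    config: SessionConfig,
    effect: TrueEffect | None = None,
    geom: ScreenGeometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Generate the artifact-free session table (one row per sample).

    Returns a sample table with the schema of :mod:`pupilverse.io_formats`
    plus ground-truth columns (``latent``, ``is_blink``, ``is_trackloss``,
    ``is_extreme``, all flags zero here).  Use :func:`inject_artifacts` to
    add blinks, trackloss and extreme values.
    """
    config.validate()
    effect = effect if effect is not None else TrueEffect()
    effect.validate(config.trial_duration, config.samples_per_trial)
    if config.n_participants == 0:
        return _empty_table()

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    S = config.samples_per_trial
    n_per_block = config.n_trials * S
    ids = np.arange(1, config.n_participants + 1)

    tonic = config.tonic_mean + config.tonic_sd_between * rng.standard_normal(len(ids))
    curves = _participant_curves(rng, len(ids), effect.participant_curve_sd)

    t_in_trial = np.arange(S) * config.dt
    trial_idx = np.repeat(np.arange(1, config.n_trials + 1), S)
    t_block = np.tile(t_in_trial, config.n_trials)
    s_frac = t_block / config.trial_duration  # position within trial in [0, 1)

    frames = []
    for i, pid in enumerate(ids):
        f_p = _eval_participant_curve(curves[i], s_frac)
        common = np.asarray(effect.trial_response(t_block), dtype=float)
        for block in BLOCKS:
            latent = tonic[i] + common + f_p
            if block == "visual":
                latent = latent + effect.beta_true + np.asarray(
                    effect.diff_curve(t_block), dtype=float
                )
            z0 = rng.standard_normal(n_per_block)
            zl = rng.standard_normal(n_per_block)
            zr = rng.standard_normal(n_per_block)
            shared = math.sqrt(config.eye_corr) * z0
            resid = math.sqrt(1.0 - config.eye_corr)
            left = latent + config.noise_sd * (shared + resid * zl)
            right = latent + config.noise_sd * (shared + resid * zr)

            inside = rng.random(n_per_block) < config.aoi_inside_prob
            gx = np.empty(n_per_block)
            gy = np.empty(n_per_block)
            gx[inside] = rng.uniform(geom.aoi_left, geom.aoi_right, inside.sum())
            gy[inside] = rng.uniform(geom.aoi_top, geom.aoi_bottom, inside.sum())
            n_out = int((~inside).sum())
            ox, oy = _sample_outside_aoi(rng, geom, n_out)
            gx[~inside] = ox
            gy[~inside] = oy

            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "block": block,
                        "trial": trial_idx,
                        "t_trial": t_block,
                        "pupil_left": left,
                        "pupil_right": right,
                        "gaze_x": gx,
                        "gaze_y": gy,
                        "latent": latent,
                        "is_blink": 0,
                        "is_trackloss": 0,
                        "is_extreme": 0,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _sample_outside_aoi(rng, geom: ScreenGeometry, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform draws over the screen minus the AoI rectangle (rejection)."""
    xs = np.empty(n)
    ys = np.empty(n)
    filled = 0
    while filled < n:
        m = max(16, 2 * (n - filled))
        cx = rng.uniform(0.0, geom.width, m)
        cy = rng.uniform(0.0, geom.height, m)
        keep = ~geom.contains(cx, cy)
        take = min(int(keep.sum()), n - filled)
        xs[filled : filled + take] = cx[keep][:take]
        ys[filled : filled + take] = cy[keep][:take]
        filled += take
    return xs, ys


def inject_artifacts(table: pd.DataFrame, config: SessionConfig) -> pd.DataFrame:
    """Inject blinks, trackloss and extreme values into a generated session.

    Blinks hit both eyes simultaneously (short runs); trackloss runs are
    longer and monocular half of the time.  Samples whose pupil is set
    missing also lose their gaze point when both eyes are gone (the tracker
    has no eye to locate).  Participants in ``config.high_missing_ids``
    receive additional binocular trackloss until their missing fraction
    (either eye absent) exceeds 30%.
    """
    config.validate()
    if len(table) == 0:
        return table.copy()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    out = table.copy().reset_index(drop=True)
    S = config.samples_per_trial
    dt = config.dt
    block_ms = config.n_trials * config.trial_duration

    left = out["pupil_left"].to_numpy(dtype=float, copy=True)
    right = out["pupil_right"].to_numpy(dtype=float, copy=True)
    is_blink = out["is_blink"].to_numpy(copy=True)
    is_track = out["is_trackloss"].to_numpy(copy=True)
    is_extreme = out["is_extreme"].to_numpy(copy=True)

    ids = out["participant_id"].to_numpy()
    unique_ids = pd.unique(ids)
    tl_mult = np.exp(
        config.trackloss_sd_between * rng.standard_normal(len(unique_ids))
        - 0.5 * config.trackloss_sd_between**2
    )
    mult_of = dict(zip(unique_ids, tl_mult))

    # Positional index of each (participant, block) group, in time order.
    grouped = out.groupby(["participant_id", "block"], sort=False).indices

    for (pid, _block), idx in grouped.items():
        idx = np.asarray(idx)
        n = len(idx)
        sample_time = (out["trial"].to_numpy()[idx] - 1) * config.trial_duration + out[
            "t_trial"
        ].to_numpy()[idx]

        # --- blinks: Poisson number of short binocular runs
        n_blinks = rng.poisson(config.blink_rate * block_ms / 1000.0)
        for _ in range(n_blinks):
            dur = rng.uniform(*config.blink_duration)
            start = rng.uniform(0.0, max(dt, block_ms - dur))
            hit = (sample_time >= start) & (sample_time < start + dur)
            sel = idx[hit]
            left[sel] = np.nan
            right[sel] = np.nan
            is_blink[sel] = 1

        # --- trackloss: longer runs until the configured fraction is lost
        # blink-lost samples do not count toward the trackloss budget
        target = config.trackloss_rate * mult_of[pid] * n
        lost = 0
        guard = 0
        while lost < target and guard < 10 * config.n_trials:
            guard += 1
            dur = rng.uniform(600.0, 2000.0)
            # clip the final run so the realized fraction tracks the target
            dur = min(dur, max(2.0 * dt, (target - lost) * dt))
            start = rng.uniform(0.0, max(dt, block_ms - dur))
            hit = (sample_time >= start) & (sample_time < start + dur)
            sel = idx[hit]
            both = rng.random() < 0.5
            if both:
                fresh = ~(np.isnan(left[sel]) & np.isnan(right[sel]))
                left[sel] = np.nan
                right[sel] = np.nan
            else:
                if rng.random() < 0.5:
                    fresh = ~np.isnan(left[sel])
                    left[sel] = np.nan
                else:
                    fresh = ~np.isnan(right[sel])
                    right[sel] = np.nan
            is_track[sel] = 1
            lost += int(np.count_nonzero(fresh))

    # --- extreme yet plausible values: sustained excursions just outside
    # the 2-8 mm band.  Pupil size is a slow signal (isolated one-sample
    # jumps of several mm are physiologically impossible), so extremes are
    # injected as runs of 200-1000 ms during which the tracked value sits
    # a little beyond the physiological bound, hitting observed samples of
    # both eyes.
    if config.extreme_rate > 0:
        for (pid, _block), idx in grouped.items():
            idx = np.asarray(idx)
            n = len(idx)
            sample_time = (out["trial"].to_numpy()[idx] - 1) * config.trial_duration + out[
                "t_trial"
            ].to_numpy()[idx]
            target = config.extreme_rate * n
            hit_count = 0
            guard = 0
            while hit_count < target and guard < 5 * config.n_trials:
                guard += 1
                dur = rng.uniform(200.0, 1000.0)
                dur = min(dur, max(2.0 * dt, (target - hit_count) * dt))
                start = rng.uniform(0.0, max(dt, block_ms - dur))
                run = (sample_time >= start) & (sample_time < start + dur)
                sel = idx[run]
                sel = sel[~(np.isnan(left[sel]) | np.isnan(right[sel]))]
                if len(sel) == 0:
                    continue
                high = rng.random() < 0.5
                value = rng.uniform(8.1, 8.8) if high else rng.uniform(1.3, 1.9)
                jitter = 0.03 * rng.standard_normal((2, len(sel)))
                if high:  # wobble must not re-enter the physiological band
                    left[sel] = np.maximum(value + jitter[0], 8.01)
                    right[sel] = np.maximum(value + jitter[1], 8.01)
                else:
                    left[sel] = np.minimum(value + jitter[0], 1.99)
                    right[sel] = np.minimum(value + jitter[1], 1.99)
                is_extreme[sel] = 1
                hit_count += len(sel)

    # --- force designated participants above 30% missingness
    for pid in config.high_missing_ids:
        sel = np.flatnonzero(ids == pid)
        if len(sel) == 0:
            continue
        expected = len(sel)
        guard = 0
        while (
            np.mean(np.isnan(left[sel]) | np.isnan(right[sel])) <= 0.32
            and guard < 200
        ):
            guard += 1
            dur = rng.uniform(600.0, 2000.0)
            start = rng.uniform(0.0, max(dt, 2 * block_ms - dur))
            # treat the participant's samples as one concatenated timeline
            rel = np.arange(expected) * dt
            hit = (rel >= start) & (rel < start + dur)
            left[sel[hit]] = np.nan
            right[sel[hit]] = np.nan
            is_track[sel[hit]] = 1

    out["pupil_left"] = left
    out["pupil_right"] = right
    both_gone = np.isnan(left) & np.isnan(right)
    out.loc[both_gone, ["gaze_x", "gaze_y"]] = np.nan
    out["is_blink"] = is_blink
    out["is_trackloss"] = is_track
    out["is_extreme"] = is_extreme
    return out


def generate_full_session(
    config: SessionConfig,
    effect: TrueEffect | None = None,
    geom: ScreenGeometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Convenience wrapper: :func:`generate_session` + :func:`inject_artifacts`."""
    return inject_artifacts(generate_session(config, effect, geom), config)
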