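"""Penalized-spline additive models for the pupil time course.

Two competing models are fitted to every processed dataset:

* the *time model*  Y = a + b*X + f_X(t) + f_id(t) + e, with a cubic
  B-spline smooth of trial time per familiarization block (k basis
  functions, second-order difference penalty, sum-to-zero constrained)
  and one penalized smooth of time per participant sharing a single
  smoothing parameter (the random-smooth analogue);
* the *no-time model*  Y = a + b*X + u_(X,id) + e, which replaces the
  smooths with one ridge-penalized coefficient per participant x block
  cell.

Coefficients minimize ||y - X theta||^2 + sum_j lambda_j theta' S_j theta.
Smoothing parameters are chosen by minimizing the generalized
cross-validation score GCV = n * RSS / (n - edf)^2 over a log-spaced grid
by coordinate descent.  Because the smooths are sum-to-zero constrained,
the block coefficient b is directly interpretable as the mean
Visual - Audiovisual pupil difference, the quantity the specification
curve displays.

Model comparison uses BIC = -2 l(theta_hat) + k log(n) with the Gaussian
log-likelihood at the ML residual variance and k = edf + 1 (effective
degrees of freedom plus the residual scale), and the adjusted R^2
1 - (RSS/(n - edf)) / (TSS/(n - 1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, null_space, LinAlgError

from .errors import BasisError, FitError, SpecificationError
from .preprocess import ProcessedDataset

__all__ = [
    "ModelSpec",
    "FitResult",
    "DifferenceSmooth",
    "bspline_basis",
    "build_design",
    "fit_model",
    "bic",
    "delta_bic_label",
    "r_squared",
    "difference_smooth",
]

TIME_MODEL = "time_model"
NO_TIME_MODEL = "no_time_model"
MIN_ROWS_PER_PARTICIPANT = 10


@dataclass
class ModelSpec:
    """Specification of one candidate model."""

    kind: str = TIME_MODEL
    k_basis: int = 20
    penalty_order: int = 2
    lambda_grid: Sequence[float] = field(
        default_factory=lambda: tuple(np.logspace(-4.0, 8.0, 13))
    )
    ci_level: float = 0.95
    time_scale: str = "trial"  # "trial": t_trial; "block": time from block onset
    participant_smooths: bool = True  # False: population-level time model only

    def __post_init__(self) -> None:
        if self.kind not in (TIME_MODEL, NO_TIME_MODEL):
            raise SpecificationError(f"unknown model kind {self.kind!r}")
        if self.k_basis < 4:
            raise SpecificationError("k_basis must be >= 4")
        if not 0 < self.penalty_order < self.k_basis:
            raise SpecificationError("penalty_order must be in (0, k_basis)")
        if not 0 < self.ci_level < 1:
            raise SpecificationError("ci_level must be in (0, 1)")
        if self.time_scale not in ("trial", "block"):
            raise SpecificationError("time_scale must be 'trial' or 'block'")


def bspline_basis(t, k: int, degree: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline basis with equally spaced interior knots.

    Returns the n x k design matrix and the full (clamped) knot vector
    spanning [min(t), max(t)].  Rows sum to one at every t (partition of
    unity).
    """
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        raise BasisError("t must be non-empty")
    if k < degree + 1:
        raise BasisError(f"k must be >= degree + 1 = {degree + 1}")
    lo, hi = float(t.min()), float(t.max())
    if not hi > lo:
        raise BasisError("degenerate time range: all t identical")
    n_interior = k - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    B = BSpline.design_matrix(t, knots, degree, extrapolate=False).toarray()
    return B, knots


def _eval_basis(t, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    t = np.clip(np.asarray(t, dtype=float), knots[0], knots[-1])
    return BSpline.design_matrix(t, knots, degree, extrapolate=False).toarray()


def _difference_penalty(k: int, order: int) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def _constrain(B: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Absorb the sum-to-zero constraint 1'B theta = 0.

    Reparametrizes the smooth so its fitted contribution sums to zero over
    the data rows; returns (constrained columns, transformed penalty, Z).
    """
    s = B.sum(axis=0)[None, :]
    Z = null_space(s)  # k x (k-1)
    return B @ Z, Z.T @ S @ Z, Z


@dataclass
class PenaltyGroup:
    """Columns sharing one smoothing parameter: list of (offset, S_block)."""

    name: str
    blocks: list


@dataclass
class Design:
    """Assembled design for one model on one dataset."""

    X: np.ndarray
    y: np.ndarray
    penalty_groups: list
    col_map: dict
    kind: str
    meta: dict

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def penalty_matrix(self, name: str) -> np.ndarray:
        """Full p x p penalty matrix of one group (unit smoothing parameter)."""
        S = np.zeros((self.p, self.p))
        group = next(g for g in self.penalty_groups if g.name == name)
        for offset, Sb in group.blocks:
            m = Sb.shape[0]
            S[offset : offset + m, offset : offset + m] += Sb
        return S


def _model_time(data: pd.DataFrame, spec: ModelSpec):
    if spec.time_scale == "trial":
        return data["t_trial"].to_numpy(dtype=float)
    t_trial = data["t_trial"].to_numpy(dtype=float)
    # infer trial duration from the sampling grid
    tt = np.sort(np.unique(t_trial))
    dt = float(np.median(np.diff(tt))) if len(tt) > 1 else 1000.0 / 60.0
    duration = float(tt.max() + dt)
    return (data["trial"].to_numpy(dtype=float) - 1.0) * duration + t_trial


def build_design(dataset: ProcessedDataset, spec: ModelSpec) -> Design:
    """Build the design matrix, penalty blocks and column map for one model.

    Participants contributing fewer than MIN_ROWS_PER_PARTICIPANT rows are
    dropped from the fit with a warning.
    """
    if dataset.degenerate or len(dataset.data) == 0:
        raise FitError(f"dataset {dataset.token!r} is degenerate (no rows)")
    data = dataset.data
    counts = data["participant_id"].value_counts()
    thin = counts.index[counts < MIN_ROWS_PER_PARTICIPANT]
    if len(thin) > 0:
        warnings.warn(
            f"{dataset.token}: dropping participants with <"
            f"{MIN_ROWS_PER_PARTICIPANT} rows: {sorted(map(int, thin))}",
            stacklevel=2,
        )
        data = data[~data["participant_id"].isin(thin)]
    blocks = sorted(data["block"].unique())
    if set(blocks) != {"audiovisual", "visual"}:
        raise SpecificationError(
            f"dataset {dataset.token!r}: both familiarization blocks required, "
            f"found {blocks}"
        )
    participants = np.sort(data["participant_id"].unique())
    if len(participants) < 2:
        raise SpecificationError(
            f"dataset {dataset.token!r}: at least 2 participants required"
        )

    y = data["y"].to_numpy(dtype=float)
    n = len(y)
    visual = (data["block"].to_numpy() == "visual").astype(float)
    pid = data["participant_id"].to_numpy()

    cols = [np.ones(n), visual]
    col_map = {"intercept": slice(0, 1), "block_visual": slice(1, 2)}
    penalty_groups: list[PenaltyGroup] = []
    meta: dict = {"participants": participants.tolist(), "kind": spec.kind}

    if spec.kind == TIME_MODEL:
        t = _model_time(data, spec)
        B, knots = bspline_basis(t, spec.k_basis)
        S0 = _difference_penalty(spec.k_basis, spec.penalty_order)
        meta.update({"knots": knots, "t_range": (float(t.min()), float(t.max()))})
        offset = 2
        for level, mask in (("audiovisual", visual == 0.0), ("visual", visual == 1.0)):
            Bl = B * mask[:, None]
            C, Sc, Z = _constrain(Bl, S0)
            m = C.shape[1]
            cols.append(C)
            col_map[f"smooth_{level}"] = slice(offset, offset + m)
            penalty_groups.append(PenaltyGroup(f"smooth_{level}", [(offset, Sc)]))
            meta[f"Z_{level}"] = Z
            offset += m
        if not spec.participant_smooths:
            X = np.column_stack(cols)
            return Design(X=X, y=y, penalty_groups=penalty_groups,
                          col_map=col_map, kind=spec.kind, meta=meta)
        # Per-participant factor smooths: unconstrained, fully penalized.
        # The difference penalty controls wiggliness; a shared ridge on the
        # penalty null space (constant + linear) shrinks participant-level
        # offsets and trends like random effects, so the term can absorb
        # tonic differences between infants without stealing the block
        # coefficient.
        N = null_space(np.diff(np.eye(spec.k_basis), n=spec.penalty_order, axis=0))
        S_null = N @ N.T
        wiggle_blocks = []
        null_blocks = []
        for p in participants:
            Bp = B * (pid == p).astype(float)[:, None]
            m = Bp.shape[1]
            cols.append(Bp)
            col_map[f"smooth_id_{int(p)}"] = slice(offset, offset + m)
            wiggle_blocks.append((offset, S0))
            null_blocks.append((offset, S_null))
            offset += m
        penalty_groups.append(PenaltyGroup("smooth_participants", wiggle_blocks))
        penalty_groups.append(PenaltyGroup("participants_null", null_blocks))
    else:
        offset = 2
        cell_cols = []
        cell_labels = []
        for p in participants:
            for level in ("audiovisual", "visual"):
                cell_cols.append(((pid == p) & (visual == (level == "visual"))).astype(float))
                cell_labels.append((int(p), level))
        m = len(cell_cols)
        cols.append(np.column_stack(cell_cols))
        col_map["cells"] = slice(offset, offset + m)
        penalty_groups.append(PenaltyGroup("cells", [(offset, np.eye(m))]))
        meta["cell_labels"] = cell_labels

    X = np.column_stack([np.atleast_2d(c.T).T if c.ndim == 1 else c for c in cols])
    return Design(X=X, y=y, penalty_groups=penalty_groups, col_map=col_map,
                  kind=spec.kind, meta=meta)


@dataclass
class FitResult:
    """A fitted penalized model with everything model comparison needs."""

    kind: str
    alpha_hat: float
    beta_hat: float
    beta_se: float
    beta_ci: tuple
    smooth_coefs: dict
    lambdas: dict
    edf: float
    loglik: float
    n: int
    k_params: float
    bic: float
    r2: float
    coef_cov: np.ndarray
    residual_sd: float
    rss: float
    tss: float
    theta: np.ndarray
    col_map: dict
    meta: dict
    ci_level: float
    gcv: float


def _assemble(design: Design):
    XtX = design.X.T @ design.X
    Xty = design.X.T @ design.y
    yty = float(design.y @ design.y)
    S_full = [design.penalty_matrix(g.name) for g in design.penalty_groups]
    return XtX, Xty, yty, S_full


def _penalized_solve(XtX, Xty, yty, S_full, lams, n):
    A = XtX.copy()
    for lam, S in zip(lams, S_full):
        if lam != 0.0:
            A += lam * S
    try:
        c = cho_factor(A, lower=True)
    except LinAlgError as exc:
        raise FitError(f"singular penalized system (lambdas={lams})") from exc
    theta = cho_solve(c, Xty)
    rss = max(yty - 2.0 * float(theta @ Xty) + float(theta @ (XtX @ theta)), 0.0)
    edf = float(np.trace(cho_solve(c, XtX)))
    denom = n - edf
    gcv = np.inf if denom <= 0 else n * rss / denom**2
    return theta, rss, edf, gcv, c


def _select_lambdas(XtX, Xty, yty, S_full, grid, n, max_sweeps=25, tol=1e-6):
    """Coordinate descent over the lambda grid minimizing GCV."""
    G = len(S_full)
    grid = list(grid)
    lams = [grid[len(grid) // 2]] * G
    best = _penalized_solve(XtX, Xty, yty, S_full, lams, n)[3]
    for _ in range(max_sweeps):
        prev = best
        for g in range(G):
            scores = []
            for val in grid:
                trial = list(lams)
                trial[g] = val
                try:
                    scores.append(
                        _penalized_solve(XtX, Xty, yty, S_full, trial, n)[3]
                    )
                except FitError:
                    scores.append(np.inf)
            j = int(np.argmin(scores))
            lams[g] = grid[j]
            best = scores[j]
        if abs(prev - best) < tol * (1.0 + abs(best)):
            break
    return lams, best


def fit_model(
    dataset: ProcessedDataset, spec: ModelSpec, lambdas=None
) -> FitResult:
    """Fit one model to one processed dataset.

    ``lambdas`` overrides smoothing-parameter selection: a scalar applies
    to every penalty group, a dict maps group names to values (0 gives the
    unpenalized least-squares fit when the design is full rank).
    """
    design = build_design(dataset, spec)
    XtX, Xty, yty, S_full = _assemble(design)
    n = design.n
    if n <= design.p and lambdas == 0.0:
        raise FitError("unpenalized fit requires n > p")

    group_names = [g.name for g in design.penalty_groups]
    if lambdas is None:
        lams, gcv_score = _select_lambdas(
            XtX, Xty, yty, S_full, spec.lambda_grid, n
        )
    else:
        if np.isscalar(lambdas):
            lams = [float(lambdas)] * len(group_names)
        else:
            lams = [float(lambdas[name]) for name in group_names]
        gcv_score = np.nan

    theta, rss, edf, gcv_val, c = _penalized_solve(XtX, Xty, yty, S_full, lams, n)
    if not np.isnan(gcv_score):
        gcv_val = gcv_score
    if n - edf <= 0:
        raise FitError("effective degrees of freedom exhausted the sample")

    sigma2 = rss / (n - edf)
    cov = sigma2 * cho_solve(c, np.eye(design.p))
    ybar = float(design.y.mean())
    tss = float(((design.y - ybar) ** 2).sum())

    loglik = -0.5 * n * (np.log(2.0 * np.pi * max(rss, 1e-300) / n) + 1.0)
    k_params = edf + 1.0
    bic_val = -2.0 * loglik + k_params * np.log(n)
    if tss <= 0:
        raise FitError("zero total variance: R^2 undefined")
    r2 = 1.0 - (rss / (n - edf)) / (tss / (n - 1))
    r2 = float(min(1.0, max(0.0, r2)))

    z = stats.norm.ppf(0.5 + spec.ci_level / 2.0)
    beta = float(theta[1])
    beta_se = float(np.sqrt(max(cov[1, 1], 0.0)))
    smooth_coefs = {
        name: theta[sl].copy()
        for name, sl in design.col_map.items()
        if name not in ("intercept", "block_visual")
    }
    return FitResult(
        kind=spec.kind,
        alpha_hat=float(theta[0]),
        beta_hat=beta,
        beta_se=beta_se,
        beta_ci=(beta - z * beta_se, beta + z * beta_se),
        smooth_coefs=smooth_coefs,
        lambdas=dict(zip(group_names, map(float, lams))),
        edf=float(edf),
        loglik=float(loglik),
        n=int(n),
        k_params=float(k_params),
        bic=float(bic_val),
        r2=r2,
        coef_cov=cov,
        residual_sd=float(np.sqrt(sigma2)),
        rss=float(rss),
        tss=tss,
        theta=theta,
        col_map=design.col_map,
        meta=design.meta,
        ci_level=spec.ci_level,
        gcv=float(gcv_val),
    )


def bic(fit: FitResult) -> float:
    """BIC = -2 l(theta_hat) + k log(n), recomputed from the fit."""
    if fit.n <= 1:
        raise ValueError("BIC requires n > 1")
    return -2.0 * fit.loglik + fit.k_params * np.log(fit.n)


def delta_bic_label(delta: float) -> str:
    """Evidence band for a BIC difference against the best model."""
    if delta < 0:
        raise ValueError("delta BIC must be >= 0")
    if delta < 2:
        return "weak"
    if delta < 6:
        return "positive"
    if delta < 10:
        return "strong"
    return "very strong"


def r_squared(fit: FitResult) -> float:
    """Adjusted R^2 = 1 - (RSS/(n-edf)) / (TSS/(n-1)), clipped to [0, 1]."""
    if fit.tss <= 0:
        raise ValueError("zero total variance: R^2 undefined")
    r2 = 1.0 - (fit.rss / (fit.n - fit.edf)) / (fit.tss / (fit.n - 1))
    return float(min(1.0, max(0.0, r2)))


@dataclass
class DifferenceSmooth:
    """The estimated Visual - Audiovisual difference as a function of time."""

    t_grid: np.ndarray
    diff_hat: np.ndarray
    diff_se: np.ndarray
    ci: tuple
    significant_windows: list


def difference_smooth(fit: FitResult, t_grid=None, n_grid: int = 101) -> DifferenceSmooth:
    """Pointwise condition-difference curve with CI and significant windows.

    diff(t) = beta_hat + f_visual(t) - f_audiovisual(t); the standard error
    comes from the joint posterior covariance of the block coefficient and
    the two constrained smooths.  Significant windows are maximal runs of
    grid points whose CI excludes zero.
    """
    if fit.kind != TIME_MODEL:
        raise SpecificationError("difference_smooth requires a time-model fit")
    lo, hi = fit.meta["t_range"]
    if t_grid is None:
        t_grid = np.linspace(lo, hi, n_grid)
    t_grid = np.asarray(t_grid, dtype=float)
    B = _eval_basis(t_grid, fit.meta["knots"])
    p = len(fit.theta)
    Xg = np.zeros((len(t_grid), p))
    Xg[:, fit.col_map["block_visual"]] = 1.0
    Xg[:, fit.col_map["smooth_visual"]] = B @ fit.meta["Z_visual"]
    Xg[:, fit.col_map["smooth_audiovisual"]] = -(B @ fit.meta["Z_audiovisual"])
    diff = Xg @ fit.theta
    var = np.einsum("ij,jk,ik->i", Xg, fit.coef_cov, Xg)
    se = np.sqrt(np.maximum(var, 0.0))
    z = stats.norm.ppf(0.5 + fit.ci_level / 2.0)
    lo_ci = diff - z * se
    hi_ci = diff + z * se
    sig = (lo_ci > 0) | (hi_ci < 0)
    windows = []
    start = None
    for i, flag in enumerate(sig):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            windows.append((float(t_grid[start]), float(t_grid[i - 1])))
            start = None
    if start is not None:
        windows.append((float(t_grid[start]), float(t_grid[-1])))
    return DifferenceSmooth(
        t_grid=t_grid,
        diff_hat=diff,
        diff_se=se,
        ci=(lo_ci, hi_ci),
        significant_windows=windows,
    )
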