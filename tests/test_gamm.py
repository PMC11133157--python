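import numpy as np
import pandas as pd
import pytest

from pupilverse.errors import SpecificationError
from pupilverse.gamm import (
    NO_TIME_MODEL,
    TIME_MODEL,
    FitResult,
    ModelSpec,
    bic,
    bspline_basis,
    build_design,
    delta_bic_label,
    difference_smooth,
    fit_model,
    r_squared,
)
from pupilverse.gamm import _penalized_solve
from pupilverse.preprocess import ForkSpec, ProcessedDataset

from conftest import recovery_dataset


def cox_de_boor(t, i, d, knots):
    """Independent recursive B-spline evaluation (the textbook recursion)."""
    if d == 0:
        # right-closed top interval so the basis sums to 1 at the last knot
        if knots[i] <= t < knots[i + 1]:
            return 1.0
        if t == knots[-1] and knots[i] < knots[i + 1] <= knots[-1]:
            # t at the right boundary belongs to the last non-empty interval
            last = max(j for j in range(len(knots) - 1) if knots[j] < knots[j + 1])
            return 1.0 if i == last else 0.0
        return 0.0
    left = 0.0
    if knots[i + d] > knots[i]:
        left = (t - knots[i]) / (knots[i + d] - knots[i]) * cox_de_boor(t, i, d - 1, knots)
    right = 0.0
    if knots[i + d + 1] > knots[i + 1]:
        right = (
            (knots[i + d + 1] - t)
            / (knots[i + d + 1] - knots[i + 1])
            * cox_de_boor(t, i + 1, d - 1, knots)
        )
    return left + right


def small_dataset(seed=0, n_participants=2, n_trials=3, samples=16):
    """Tiny balanced dataset for design/fit bookkeeping tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(1, n_participants + 1):
        for block in ("audiovisual", "visual"):
            for trial in range(1, n_trials + 1):
                t = np.arange(samples) * 1000.0 / samples
                y = 0.05 * (block == "visual") + 0.1 * np.sin(t / 300.0)
                y = y + 0.02 * rng.standard_normal(samples)
                rows.append(
                    pd.DataFrame(
                        {
                            "participant_id": pid,
                            "block": block,
                            "trial": trial,
                            "t_trial": t,
                            "y": y,
                        }
                    )
                )
    return ProcessedDataset(fork=ForkSpec(), data=pd.concat(rows, ignore_index=True))


class TestBsplineBasis:
    @pytest.mark.parametrize("k", [4, 7, 10, 20])
    def test_partition_of_unity(self, k):
        t = np.linspace(0.0, 1000.0, 57)
        B, _ = bspline_basis(t, k)
        assert B.shape == (57, k)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_k4_is_bernstein_cubic(self):
        t = np.array([0.0, 0.5, 1.0])
        B, _ = bspline_basis(t, 4)
        np.testing.assert_allclose(B[0], [1.0, 0.0, 0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(B[2], [0.0, 0.0, 0.0, 1.0], atol=1e-12)
        # interior point matches the Bernstein closed form
        s = 0.5
        bern = [(1 - s) ** 3, 3 * s * (1 - s) ** 2, 3 * s**2 * (1 - s), s**3]
        np.testing.assert_allclose(B[1], bern, atol=1e-12)

    @pytest.mark.parametrize("k", [4, 6, 9])
    def test_matches_cox_de_boor_recursion_oracle(self, k):
        rng = np.random.default_rng(1)
        t = np.sort(np.concatenate([[0.0, 1000.0], rng.uniform(0, 1000, 15)]))
        B, knots = bspline_basis(t, k)
        oracle = np.array(
            [[cox_de_boor(tv, i, 3, knots) for i in range(k)] for tv in t]
        )
        np.testing.assert_allclose(B, oracle, atol=1e-10)

    def test_degenerate_range_rejected(self):
        from pupilverse.errors import BasisError

        with pytest.raises(BasisError):
            bspline_basis(np.full(5, 3.0), 6)
        with pytest.raises(BasisError):
            bspline_basis(np.linspace(0, 1, 5), 3)


class TestBuildDesign:
    def test_time_model_column_bookkeeping(self):
        ds = small_dataset(n_participants=2)
        spec = ModelSpec(kind=TIME_MODEL, k_basis=8)
        design = build_design(ds, spec)
        # 2 unpenalized + 2 constrained condition smooths (k-1 each)
        # + 2 unconstrained participant smooths (k each)
        assert design.p == 2 + 2 * 7 + 2 * 8
        names = [g.name for g in design.penalty_groups]
        assert names == [
            "smooth_audiovisual",
            "smooth_visual",
            "smooth_participants",
            "participants_null",
        ]
        # participant wiggliness and null-space groups each cover 2 blocks
        assert len(design.penalty_groups[2].blocks) == 2
        assert len(design.penalty_groups[3].blocks) == 2

    def test_no_time_model_column_bookkeeping(self):
        ds = small_dataset(n_participants=8, n_trials=1, samples=8)
        design = build_design(ds, ModelSpec(kind=NO_TIME_MODEL))
        assert design.p == 2 + 16  # intercept, block, 8x2 ridge cells
        assert [g.name for g in design.penalty_groups] == ["cells"]
        assert design.penalty_groups[0].blocks[0][1].shape == (16, 16)

    def test_condition_smooth_contribution_sums_to_zero(self):
        ds = small_dataset()
        spec = ModelSpec(kind=TIME_MODEL, k_basis=8)
        design = build_design(ds, spec)
        fit = fit_model(ds, spec)
        for name in ("smooth_audiovisual", "smooth_visual"):
            sl = design.col_map[name]
            contribution = design.X[:, sl] @ fit.theta[sl]
            assert contribution.sum() == pytest.approx(0.0, abs=1e-8)

    def test_single_block_rejected(self):
        ds = small_dataset()
        ds.data = ds.data[ds.data["block"] == "visual"].reset_index(drop=True)
        with pytest.raises(SpecificationError, match="block"):
            build_design(ds, ModelSpec(kind=TIME_MODEL, k_basis=6))


class TestFitModel:
    def test_zero_penalty_equals_ols_oracle(self):
        # population-level variant: full rank without the factor smooths
        ds = small_dataset(n_participants=2, n_trials=2, samples=12)
        spec = ModelSpec(kind=TIME_MODEL, k_basis=5, participant_smooths=False)
        design = build_design(ds, spec)
        assert design.n <= 200
        fit = fit_model(ds, spec, lambdas=0.0)
        oracle, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
        np.testing.assert_allclose(fit.theta, oracle, rtol=1e-8, atol=1e-10)

    def test_solver_matches_normal_equations_on_random_instance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 7))
        y = rng.standard_normal(60)
        theta, rss, edf, _gcv, _ = _penalized_solve(
            X.T @ X, X.T @ y, float(y @ y), [np.zeros((7, 7))], [0.0], 60
        )
        np.testing.assert_allclose(
            theta, np.linalg.solve(X.T @ X, X.T @ y), rtol=1e-10
        )
        assert edf == pytest.approx(7.0, abs=1e-8)

    def test_rss_nondecreasing_in_lambda(self):
        ds = small_dataset()
        spec = ModelSpec(kind=TIME_MODEL, k_basis=8)
        rss_vals = []
        for lam in (1e-4, 1e-1, 1e2, 1e5, 1e8):
            fit = fit_model(ds, spec, lambdas=lam)
            rss_vals.append(fit.rss)
        assert all(a <= b + 1e-10 for a, b in zip(rss_vals, rss_vals[1:]))

    def test_infinite_smoothing_leaves_penalty_null_space(self):
        # with a huge order-2 wiggliness penalty each condition smooth
        # collapses into the penalty null space: the underlying basis
        # coefficients become linear in index (zero second differences),
        # projected through the sum-to-zero constraint
        ds = small_dataset(seed=4)
        spec = ModelSpec(kind=TIME_MODEL, k_basis=8, participant_smooths=False)
        design = build_design(ds, spec)
        fit = fit_model(ds, spec, lambdas=1e12)
        for name in ("smooth_audiovisual", "smooth_visual"):
            sl = design.col_map[name]
            Z = fit.meta[f"Z_{name.removeprefix('smooth_')}"]
            coefs = Z @ fit.theta[sl]
            scale = 1 + np.max(np.abs(coefs))
            assert np.max(np.abs(np.diff(coefs, n=2))) < 1e-6 * scale

    def test_duplicating_rows_keeps_beta_changes_bic(self):
        ds = small_dataset()
        spec = ModelSpec(kind=TIME_MODEL, k_basis=6)
        fit1 = fit_model(ds, spec, lambdas=1.0)
        doubled = ProcessedDataset(
            fork=ds.fork,
            data=pd.concat([ds.data, ds.data], ignore_index=True),
        )
        fit2 = fit_model(doubled, spec, lambdas=1.0)
        assert fit2.beta_hat == pytest.approx(fit1.beta_hat, abs=1e-8)
        assert fit2.n == 2 * fit1.n
        assert fit2.bic != pytest.approx(fit1.bic)

    def test_fit_result_internal_consistency(self):
        ds = small_dataset(seed=2)
        for kind in (TIME_MODEL, NO_TIME_MODEL):
            fit = fit_model(ds, ModelSpec(kind=kind, k_basis=6))
            assert 0.0 <= fit.r2 <= 1.0
            assert fit.beta_ci[0] <= fit.beta_hat <= fit.beta_ci[1]
            assert fit.bic == pytest.approx(
                -2 * fit.loglik + fit.k_params * np.log(fit.n), rel=1e-12
            )
            assert fit.k_params == pytest.approx(fit.edf + 1.0)
            assert fit.edf <= fit.theta.size
            assert bic(fit) == pytest.approx(fit.bic)
            assert r_squared(fit) == pytest.approx(fit.r2)


class TestBicHelpers:
    def test_formula_at_natural_base(self):
        fit = FitResult(
            kind=NO_TIME_MODEL, alpha_hat=0.0, beta_hat=0.0, beta_se=1.0,
            beta_ci=(-1, 1), smooth_coefs={}, lambdas={}, edf=4.0,
            loglik=-100.0, n=int(np.e) + 1, k_params=5.0, bic=np.nan, r2=0.5,
            coef_cov=np.eye(2), residual_sd=1.0, rss=1.0, tss=2.0,
            theta=np.zeros(2), col_map={}, meta={}, ci_level=0.95, gcv=np.nan,
        )
        # n = 3 here; check the formula directly at n = e via the helper math
        assert -2 * (-100.0) + 5.0 * np.log(np.e) == pytest.approx(205.0)
        assert bic(fit) == pytest.approx(200.0 + 5.0 * np.log(fit.n))

    @pytest.mark.parametrize(
        "delta,label",
        [(0.0, "weak"), (1.9, "weak"), (4.0, "positive"), (8.0, "strong"),
         (12.0, "very strong")],
    )
    def test_delta_bic_evidence_bands(self, delta, label):
        assert delta_bic_label(delta) == label

    def test_adjusted_r2_matches_hand_computation(self):
        # 10-point toy regression, fit with one ridge cell block at lambda~0
        ds = small_dataset(n_participants=2, n_trials=1, samples=5)
        spec = ModelSpec(kind=NO_TIME_MODEL)
        fit = fit_model(ds, spec, lambdas=1e-6)
        design = build_design(ds, spec)
        resid = design.y - design.X @ fit.theta
        rss = float(resid @ resid)
        tss = float(((design.y - design.y.mean()) ** 2).sum())
        expected = 1 - (rss / (fit.n - fit.edf)) / (tss / (fit.n - 1))
        assert fit.r2 == pytest.approx(max(0.0, min(1.0, expected)), rel=1e-8)


class TestDifferenceSmooth:
    def test_requires_time_model(self):
        ds = small_dataset()
        fit = fit_model(ds, ModelSpec(kind=NO_TIME_MODEL))
        with pytest.raises(SpecificationError):
            difference_smooth(fit)

    def test_grid_and_windows_structure(self):
        ds = small_dataset()
        fit = fit_model(ds, ModelSpec(kind=TIME_MODEL, k_basis=8))
        smooth = difference_smooth(fit)
        assert len(smooth.t_grid) == 101
        assert smooth.diff_se.min() >= 0
        lo, hi = smooth.ci
        sig = (lo > 0) | (hi < 0)
        # windows are exactly the maximal runs of significant grid points
        flagged = np.zeros(len(smooth.t_grid), dtype=bool)
        for start, end in smooth.significant_windows:
            flagged |= (smooth.t_grid >= start) & (smooth.t_grid <= end)
        np.testing.assert_array_equal(flagged, sig)

    def test_flat_difference_recovered(self):
        # beta_true = 0.1 with a flat (zero) time course: the mean of the
        # difference smooth recovers the constant offset
        from pupilverse.synthgen import _zero_curve
        from pupilverse import TrueEffect

        diffs = []
        for seed in range(5):
            ds, _ = recovery_dataset(
                400 + seed,
                effect=TrueEffect(beta_true=0.1, diff_curve=_zero_curve),
            )
            fit = fit_model(ds, ModelSpec(kind=TIME_MODEL))
            diffs.append(difference_smooth(fit).diff_hat.mean())
        assert np.mean(diffs) == pytest.approx(0.1, abs=0.02)

    def test_shaped_difference_tracks_truth(self):
        from pupilverse.synthgen import true_difference

        ds, effect = recovery_dataset(77)
        fit = fit_model(ds, ModelSpec(kind=TIME_MODEL))
        smooth = difference_smooth(fit)
        truth = true_difference(effect, smooth.t_grid)
        assert np.corrcoef(smooth.diff_hat, truth)[0, 1] > 0.8
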