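"""OLS fitting, residual-variance summaries, information criteria."""

import numpy as np
import pytest

from orthoglm import (
    CollinearityError,
    DegenerateInputError,
    DesignMatrix,
    Regressor,
    build_designs,
    fit_glm,
    information_criteria,
    zscore,
)
from orthoglm.glm import GLMFit

from conftest import random_regressor_pair


def test_exact_span_gives_zero_rss_and_unit_r_squared(rng):
    a, b = random_regressor_pair(rng)
    y = 1.5 * a.samples - 0.7 * b.samples + 2.0
    fit = fit_glm(y, DesignMatrix([a, b]))
    assert fit.rss <= 1e-16 * fit.n
    assert fit.r_squared == pytest.approx(1.0)
    assert np.allclose(fit.betas, [1.5, -0.7, 2.0], atol=1e-8)


def test_zero_noise_mixture_recovers_weights_exactly(rng):
    """y = 0.8 A + 0.2 B with z-scored regressors -> betas (0.8, 0.2, 0)."""
    a, b = random_regressor_pair(rng)
    y = 0.8 * a.samples + 0.2 * b.samples
    fit = fit_glm(y, DesignMatrix([a, b]))
    # independent oracle: normal equations solved directly
    m = np.column_stack([a.samples, b.samples, np.ones(fit.n)])
    oracle = np.linalg.solve(m.T @ m, m.T @ y)
    assert np.allclose(fit.betas, [0.8, 0.2, 0.0], atol=1e-8)
    assert np.allclose(fit.betas, oracle, atol=1e-8)


def test_betas_match_pseudoinverse_on_random_problems(rng):
    for _ in range(20):
        n = int(rng.integers(30, 120))
        k = int(rng.integers(1, 5))
        regs = [
            Regressor(f"x{j}", rng.standard_normal(n), dt=1.0)
            for j in range(k)
        ]
        y = rng.standard_normal(n)
        X = DesignMatrix(regs)
        fit = fit_glm(y, X)
        oracle = np.linalg.pinv(X.matrix()) @ y
        assert np.allclose(fit.betas, oracle, atol=1e-8)
        assert np.all(np.abs(X.matrix().T @ fit.residuals) < 1e-6)


def test_rank_deficient_design_names_collinear_columns(rng):
    x = rng.standard_normal(50)
    a = Regressor("first", x, dt=1.0)
    b = Regressor("double", 2 * x, dt=1.0)
    with pytest.raises(CollinearityError, match="double|first"):
        fit_glm(rng.standard_normal(50), DesignMatrix([a, b]))


def test_length_mismatch_rejected(rng):
    a = Regressor("a", rng.standard_normal(50), dt=1.0)
    with pytest.raises(ValueError, match="samples"):
        fit_glm(rng.standard_normal(49), DesignMatrix([a]))


class TestInformationCriteria:
    def _fit(self, rng, n=100, k_extra=1, noise=1.0):
        regs = [
            Regressor(f"x{j}", rng.standard_normal(n), dt=1.0)
            for j in range(k_extra)
        ]
        y = regs[0].samples + noise * rng.standard_normal(n)
        return fit_glm(y, DesignMatrix(regs))

    def test_hand_computed_aic(self):
        fit = GLMFit(
            betas=np.zeros(2),
            column_names=("x", "intercept"),
            residuals=np.ones(100),
            rss=100.0,
            n=100,
            k=2,
            r_squared=0.0,
        )
        aic, bic = information_criteria(fit)
        assert aic == pytest.approx(4.0)
        assert bic - aic == pytest.approx(2 * (np.log(100) - 2))

    def test_equal_k_aic_ordering_follows_log_res_var(self, rng):
        fits = [self._fit(rng, noise=s) for s in (0.5, 1.0, 2.0, 0.2, 3.0)]
        for f1 in fits:
            for f2 in fits:
                assert np.sign(f1.aic - f2.aic) == np.sign(
                    f1.log_res_var - f2.log_res_var
                )
                assert np.sign(f1.bic - f2.bic) == np.sign(
                    f1.log_res_var - f2.log_res_var
                )

    def test_zero_rss_rejected(self):
        fit = GLMFit(
            betas=np.zeros(1),
            column_names=("intercept",),
            residuals=np.zeros(10),
            rss=0.0,
            n=10,
            k=1,
            r_squared=1.0,
        )
        with pytest.raises(DegenerateInputError):
            information_criteria(fit)


def test_full_model_rss_never_exceeds_reduced(rng, ref_regs):
    ro, rpe = ref_regs
    designs = build_designs(ro, rpe)
    for _ in range(10):
        y = rng.standard_normal(ro.n_samples)
        full = fit_glm(y, designs["full_1"]).rss
        assert full <= fit_glm(y, designs["reduced_A"]).rss + 1e-10
        assert full <= fit_glm(y, designs["reduced_B"]).rss + 1e-10


def test_orthogonalized_beta_equals_joint_model_beta(rng, ref_regs):
    """The beta of the serially orthogonalized regressor equals its beta in
    the non-orthogonalized joint model (no rescaling after residualizing)."""
    ro, rpe = ref_regs
    designs = build_designs(ro, rpe)
    y = 0.6 * ro.samples + 0.4 * rpe.samples + rng.standard_normal(ro.n_samples)
    beta_perp = fit_glm(y, designs["full_1"]).betas[1]
    beta_joint = fit_glm(y, DesignMatrix([ro, rpe])).betas[1]
    assert beta_perp == pytest.approx(beta_joint, abs=1e-8)
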