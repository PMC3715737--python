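"""HRF, regressor construction, standardization, orthogonalization."""

import numpy as np
import pytest

from orthoglm import (
    DegenerateInputError,
    EventSpec,
    Regressor,
    build_designs,
    build_regressor,
    canonical_hrf,
    orthogonalize,
    rw_trace,
    zscore,
)
from orthoglm.design import center_modulations

from conftest import random_regressor_pair


class TestCanonicalHRF:
    def test_zero_at_origin_unit_peak_near_five_seconds(self):
        dt = 0.1
        h = canonical_hrf(dt)
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)
        peak_t = np.argmax(h) * dt
        assert 4.5 <= peak_t <= 5.5
        # undershoot exists and is small relative to the peak
        assert -0.25 < h.min() < 0

    @pytest.mark.parametrize("dt", [0, -0.5, 2.5])
    def test_bad_dt_rejected(self, dt):
        with pytest.raises(ValueError):
            canonical_hrf(dt)


class TestBuildRegressor:
    def test_single_impulse_reproduces_shifted_hrf(self):
        ev = EventSpec([10.0], [0.0], [1.0], label="stick")
        reg = build_regressor(ev, total_duration=60.0, dt=1.0)
        h = canonical_hrf(1.0)
        expected = np.zeros(60)
        expected[10 : 10 + h.size] = h
        assert np.allclose(reg.samples, expected, atol=1e-12)

    def test_zero_modulations_give_zero_samples(self):
        ev = EventSpec([5.0, 20.0], [0.0, 0.0], [0.0, 0.0])
        reg = build_regressor(ev, 60.0, 1.0)
        assert np.all(reg.samples == 0)

    def test_boxcar_integrates_more_than_stick(self):
        stick = build_regressor(EventSpec([5.0], [0.0], [1.0]), 60.0, 1.0)
        boxcar = build_regressor(EventSpec([5.0], [4.0], [1.0]), 60.0, 1.0)
        assert boxcar.samples.sum() > 2 * stick.samples.sum()

    def test_onset_beyond_series_rejected(self):
        ev = EventSpec([70.0], [0.0], [1.0])
        with pytest.raises(ValueError, match="beyond"):
            build_regressor(ev, 60.0, 1.0)

    def test_negative_duration_rejected_at_event_spec(self):
        with pytest.raises(ValueError, match="non-negative"):
            EventSpec([5.0], [-1.0], [1.0])

    def test_well_separated_events_preserve_modulation_correlation(self):
        """With gaps >= 25 s, the convolved-regressor correlation equals the
        Pearson correlation of the (centered) modulation vectors."""
        ro_mod = np.array([1, 0, 0, 1, 1, 1, 0], float)
        rpe_mod = rw_trace(ro_mod, 0.5).deltas
        onsets = 10.0 + 27.0 * np.arange(7)
        zeros = np.zeros(7)
        ro = build_regressor(
            center_modulations(EventSpec(onsets, zeros, ro_mod, "RO")),
            200.0,
            1.0,
        )
        rpe = build_regressor(
            center_modulations(EventSpec(onsets, zeros, rpe_mod, "RPE")),
            200.0,
            1.0,
        )
        r_conv = np.corrcoef(ro.samples, rpe.samples)[0, 1]
        r_mod = np.corrcoef(ro_mod, rpe_mod)[0, 1]
        assert r_conv == pytest.approx(r_mod, abs=0.01)
        assert round(r_conv, 2) == 0.89

    def test_center_modulations_leaves_constant_vector_alone(self):
        ev = EventSpec([1.0, 2.0], [0.0, 0.0], [1.0, 1.0])
        assert np.array_equal(center_modulations(ev).modulations, [1.0, 1.0])


class TestZscore:
    def test_hand_computed_example(self):
        reg = Regressor("x", np.array([1.0, 2.0, 3.0]), dt=1.0)
        z = zscore(reg)
        assert np.allclose(z.samples, [-1.224744871, 0, 1.224744871])
        assert z.standardized

    def test_idempotent_and_affine_invariant(self, rng):
        x = rng.standard_normal(100)
        z1 = zscore(Regressor("x", x, dt=1.0))
        assert np.allclose(zscore(z1).samples, z1.samples, atol=1e-12)
        z2 = zscore(Regressor("x", 3.7 * x + 11.0, dt=1.0))
        assert np.allclose(z2.samples, z1.samples, atol=1e-10)

    def test_constant_regressor_rejected(self):
        with pytest.raises(DegenerateInputError):
            zscore(Regressor("c", np.ones(10), dt=1.0))


class TestOrthogonalize:
    def test_already_orthogonal_target_unchanged(self, rng):
        a, _ = random_regressor_pair(rng, rho=0.0)
        b_raw = rng.standard_normal(a.n_samples)
        b_raw -= b_raw.mean()
        b_raw -= (b_raw @ a.samples) / (a.samples @ a.samples) * a.samples
        b = Regressor("B", b_raw, dt=1.0)
        out = orthogonalize(b, [a])
        assert np.allclose(out.samples, b.samples, atol=1e-10)

    def test_residual_is_uncorrelated_with_bases(self, ref_regs):
        ro, rpe = ref_regs
        for target, base in ((rpe, ro), (ro, rpe)):
            perp = orthogonalize(target, [base])
            assert abs(np.corrcoef(perp.samples, base.samples)[0, 1]) < 1e-8
            assert perp.orthogonalized_against == (base.name,)
            assert not perp.standardized

    def test_target_equal_to_base_is_degenerate(self, ref_regs):
        ro, _ = ref_regs
        with pytest.raises(DegenerateInputError, match="span"):
            orthogonalize(ro, [ro])


class TestBuildDesigns:
    def test_requires_standardized_regressors(self, rng):
        a, b = random_regressor_pair(rng)
        raw = Regressor("A", a.samples, dt=1.0)  # standardized flag unset
        with pytest.raises(ValueError, match="standardized"):
            build_designs(raw, b)

    def test_grid_mismatch_rejected(self, rng):
        a, _ = random_regressor_pair(rng, n=200)
        _, b = random_regressor_pair(rng, n=100)
        with pytest.raises(ValueError, match="grid"):
            build_designs(a, b)

    def test_four_designs_with_intercept(self, ref_regs):
        designs = build_designs(*ref_regs)
        assert set(designs) == {"full_1", "full_2", "reduced_A", "reduced_B"}
        for d in designs.values():
            assert d.include_intercept
            assert d.column_names[-1] == "intercept"
        assert designs["full_1"].n_columns == 3
        assert designs["reduced_A"].n_columns == 2

    def test_uncorrelated_pair_gives_same_columns_up_to_order(self, rng):
        a, _ = random_regressor_pair(rng, rho=0.0)
        b_raw = rng.standard_normal(a.n_samples)
        b_raw -= b_raw.mean()
        b_raw -= (b_raw @ a.samples) / (a.samples @ a.samples) * a.samples
        b = zscore(Regressor("B", b_raw, dt=1.0))
        designs = build_designs(a, b)
        m1, m2 = designs["full_1"].matrix(), designs["full_2"].matrix()
        assert np.allclose(m1[:, 0], m2[:, 1], atol=1e-8)
        assert np.allclose(m1[:, 1], m2[:, 0], atol=1e-8)

    def test_full_designs_span_the_same_space(self, ref_regs):
        """Hat matrices of the two full designs agree: orthogonalization
        reorders the basis without changing the fitted-value space."""
        designs = build_designs(*ref_regs)
        hats = []
        for key in ("full_1", "full_2"):
            m = designs[key].matrix()
            hats.append(m @ np.linalg.pinv(m))
        assert np.linalg.norm(hats[0] - hats[1], ord="fro") < 1e-8
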