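"""Scatter corrections, gap-segment derivatives and the treatment pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cocoanir import (
    MathTreatment, apply_treatment_matrix, detrend, gap_derivative, msc,
    snv, snv_detrend,
)
from cocoanir.exceptions import ConfigError, DataValidationError, DegenerateDataError


class TestSNV:
    def test_simple_example(self):
        np.testing.assert_allclose(snv([1, 2, 3]), [-1, 0, 1], atol=1e-12)

    def test_output_moments(self, rng):
        out = snv(rng.normal(2.0, 0.3, size=200))
        assert abs(out.mean()) < 1e-12
        assert abs(out.std(ddof=1) - 1) < 1e-12

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        x = np.sin(np.linspace(0, 3, 50)) + np.linspace(0, 1, 50)
        np.testing.assert_allclose(snv(a * x + b), snv(x), atol=1e-8)

    def test_constant_spectrum_errors(self):
        with pytest.raises(DegenerateDataError):
            snv(np.full(10, 3.0))


class TestDetrend:
    wl = np.linspace(900, 1680, 120)

    def test_quadratic_baseline_annihilated(self):
        base = 2.0 + 0.01 * self.wl + 1e-5 * self.wl ** 2
        np.testing.assert_allclose(detrend(base, self.wl), 0, atol=1e-8)

    def test_idempotent(self, rng):
        x = rng.normal(size=self.wl.size)
        once = detrend(x, self.wl)
        np.testing.assert_allclose(detrend(once, self.wl), once, atol=1e-10)

    def test_residual_orthogonal_to_quadratic_design(self, rng):
        x = rng.normal(size=self.wl.size)
        resid = detrend(x, self.wl)
        w = (self.wl - self.wl.mean()) / (np.ptp(self.wl) / 2)
        for basis in (np.ones_like(w), w, w ** 2):
            assert abs(resid @ basis) < 1e-8 * np.linalg.norm(x) * np.linalg.norm(basis)


class TestMSC:
    def test_inverts_affine_scatter_exactly(self, rng):
        ref = rng.normal(0.5, 0.1, size=80)
        np.testing.assert_allclose(msc(2 * ref + 1, ref), ref, atol=1e-10)
        np.testing.assert_allclose(msc(ref, ref), ref, atol=1e-12)

    def test_refit_gives_unit_transform(self, rng):
        ref = rng.normal(0.5, 0.1, size=60)
        x = rng.normal(0.5, 0.1, size=60)
        out = msc(x, ref)
        rc = ref - ref.mean()
        b = (out @ rc) / (rc @ rc)
        a = out.mean() - b * ref.mean()
        assert abs(a) < 1e-10 and abs(b - 1) < 1e-10

    def test_zero_variance_reference_errors(self):
        with pytest.raises(DegenerateDataError):
            msc(np.arange(5.0), np.ones(5))


class TestGapDerivative:
    def test_identity_code(self, rng):
        x = rng.normal(size=40)
        y, offset = gap_derivative(x, 0, 0, 1, 1)
        assert offset == 0
        np.testing.assert_array_equal(y, x)

    def test_ramp_first_derivative(self):
        # gap-4 central difference of a slope-m ramp is 2*4*m everywhere
        m = 0.7
        x = m * np.arange(60.0)
        y, offset = gap_derivative(x, 1, 4, 4, 1)
        np.testing.assert_allclose(y, 8 * m, atol=1e-12)
        assert offset == 4 + 2  # gap + half of the width-4 smooth

    def test_brute_force_stencil_oracle(self, rng):
        x = rng.normal(size=50)
        d, g, s1, s2 = 2, 5, 5, 1
        # independent loop: two gap-difference passes then one running mean
        step1 = [x[i + g] - x[i - g] for i in range(g, x.size - g)]
        step2 = [step1[i + g] - step1[i - g] for i in range(g, len(step1) - g)]
        sm = [np.mean(step2[i:i + s1]) for i in range(len(step2) - s1 + 1)]
        y, offset = gap_derivative(x, d, g, s1, s2)
        np.testing.assert_allclose(y, sm, atol=1e-12)
        assert offset == 2 * g + s1 // 2

    def test_quadratic_second_derivative_constant(self):
        x = np.arange(80.0) ** 2
        y, _ = gap_derivative(x, 2, 5, 1, 1)
        # f''(x) * (2g)^2 = 2 * 100 for f(i) = i^2, gap 5
        np.testing.assert_allclose(y, 2 * (2 * 5) ** 2, atol=1e-9)

    def test_linearity(self, rng):
        x, z = rng.normal(size=50), rng.normal(size=50)
        a, b = 2.5, -1.5
        lhs, _ = gap_derivative(a * x + b * z, 1, 4, 4, 1)
        dx, _ = gap_derivative(x, 1, 4, 4, 1)
        dz, _ = gap_derivative(z, 1, 4, 4, 1)
        np.testing.assert_allclose(lhs, a * dx + b * dz, atol=1e-10)

    def test_too_short_errors(self):
        with pytest.raises(DataValidationError):
            gap_derivative(np.arange(8.0), 2, 5, 5, 1)


class TestMathTreatment:
    def test_code_round_trip(self):
        t = MathTreatment.from_code("SNV_DT", "1,4,4,1")
        assert (t.d, t.g, t.s1, t.s2) == (1, 4, 4, 1)
        assert t.code == "1,4,4,1"
        assert MathTreatment.from_code("NONE", "2551").code == "2,5,5,1"

    @pytest.mark.parametrize("scatter,code", [
        ("BAD", "0,0,1,1"), ("NONE", "3,1,1,1"), ("NONE", "1,0,1,1"),
        ("NONE", "0,0,0,1"), ("NONE", "abc"),
    ])
    def test_invalid_treatments(self, scatter, code):
        with pytest.raises(ConfigError):
            MathTreatment.from_code(scatter, code)


class TestApplyTreatment:
    wl = np.linspace(900, 1680, 391)

    def _spectra(self, rng, n=6):
        base = 0.4 + 1e-4 * (self.wl - 900)
        bands = 0.2 * np.exp(-0.5 * ((self.wl - 1200) / 40) ** 2)
        X = base + np.outer(rng.uniform(0.5, 1.5, n), bands)
        return X + rng.normal(scale=0.005, size=X.shape)

    def test_identity_pipeline(self, rng):
        X = self._spectra(rng)
        t = MathTreatment.from_code("NONE", "0,0,1,1")
        Xp, wl, ref = apply_treatment_matrix(X, self.wl, t)
        np.testing.assert_array_equal(Xp, X)
        np.testing.assert_array_equal(wl, self.wl)
        assert ref is None

    def test_snv_dt_idempotent(self, rng):
        X = self._spectra(rng)
        t = MathTreatment.from_code("SNV_DT", "0,0,1,1")
        once, _, _ = apply_treatment_matrix(X, self.wl, t)
        twice, _, _ = apply_treatment_matrix(once, self.wl, t)
        np.testing.assert_allclose(twice, once, atol=1e-8)

    def test_scatter_corrections_undo_planted_affine(self, rng):
        X = self._spectra(rng)
        a = rng.uniform(0.7, 1.3, size=X.shape[0])[:, None]
        b = rng.normal(scale=0.1, size=(X.shape[0], 1))
        for scatter in ("SNV_DT", "MSC"):
            t = MathTreatment.from_code(scatter, "1,4,4,1")
            ref = X.mean(axis=0)
            clean, _, _ = apply_treatment_matrix(X, self.wl, t, msc_reference=ref)
            dirty, _, _ = apply_treatment_matrix(a * X + b, self.wl, t, msc_reference=ref)
            np.testing.assert_allclose(dirty, clean, atol=1e-8)

    def test_msc_reference_frozen_for_prediction(self, rng):
        X = self._spectra(rng)
        t = MathTreatment.from_code("MSC", "0,0,1,1")
        Xp, _, ref = apply_treatment_matrix(X, self.wl, t)
        # a rescaled copy of a training spectrum maps to the same output
        scaled, _, _ = apply_treatment_matrix(
            (3.0 * X[0] + 0.2)[None, :], self.wl, t, msc_reference=ref
        )
        np.testing.assert_allclose(scaled[0], Xp[0], atol=1e-8)

    def test_rowwise_commutes_with_sample_permutation(self, rng):
        X = self._spectra(rng)
        perm = rng.permutation(X.shape[0])
        t = MathTreatment.from_code("SNV_DT", "1,4,4,1")
        Xp, _, _ = apply_treatment_matrix(X, self.wl, t)
        Xp_perm, _, _ = apply_treatment_matrix(X[perm], self.wl, t)
        np.testing.assert_allclose(Xp_perm, Xp[perm], atol=1e-12)

    def test_derivative_retained_grid(self, rng):
        X = self._spectra(rng)
        t = MathTreatment.from_code("NONE", "2,5,5,1")
        Xp, wl, _ = apply_treatment_matrix(X, self.wl, t)
        assert wl.size == Xp.shape[1] == 391 - 4 * 5 - (5 - 1)
        assert wl[0] == self.wl[2 * 5 + 5 // 2]
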