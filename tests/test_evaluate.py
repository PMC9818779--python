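"""Cross-validation, metrics, outlier rule, interpretation bands, factor
selection, iPLS and the treatment grid search."""

import numpy as np
import pytest

from cocoanir import (
    MathTreatment, SpectralDataset, compute_metrics, evaluate_constituent,
    grid_search, interpret, kfold_cv, remove_outliers, select_n_factors,
)
from cocoanir.evaluate import (
    interval_slices, ipls_forward, kfold_indices, rmsecv, rpd,
)
from cocoanir.exceptions import DataValidationError, DegenerateDataError
from cocoanir.regress import coefficient_path


class TestKFold:
    def test_fold_sizes(self):
        folds = kfold_indices(10, 5, seed=1)
        assert sorted(len(f) for f in folds) == [2] * 5
        assert sorted(np.concatenate(folds).tolist()) == list(range(10))

    def test_uneven_sizes_differ_by_at_most_one(self):
        sizes = [len(f) for f in kfold_indices(53, 5, seed=1)]
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        a = kfold_cv(X, y, "PLS", 3, seed=7)
        b = kfold_cv(X, y, "PLS", 3, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_loo_matches_explicit_loop(self, rng):
        X = rng.normal(size=(8, 4))
        y = rng.normal(size=8)
        got = kfold_cv(X, y, "PLS", 2, k_folds=8, seed=3)
        expected = np.empty(8)
        order = [int(f[0]) for f in kfold_indices(8, 8, seed=3)]
        for i in order:
            train = [j for j in range(8) if j != i]
            path = coefficient_path(X[train], y[train], 2, "PLS")
            expected[i] = path.predict(X[i][None, :], 2)[0]
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_too_few_samples(self):
        with pytest.raises(DataValidationError):
            kfold_indices(3, 5)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = compute_metrics(y, y, y, n_factors=1)
        assert m["sec"] == 0 and m["secv"] == 0
        assert m["r2cal"] == m["r2cv"] == 1
        assert m["rpd_is_guarded"]

    def test_mean_predictor_closed_form(self):
        y = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        y_cv = np.full(5, y.mean())
        m = compute_metrics(y, y_cv, y_cv, n_factors=0)
        assert m["r2cv"] == 0.0
        # SECV = sqrt(SST/(n-1)) = SD, so RPD is exactly 1
        np.testing.assert_allclose(m["rpd"], 1.0, atol=1e-12)

    def test_rpd_printed_precision_example(self):
        # a cross-validated TA model with SD 3.86 and SECV 1.43
        assert round(rpd(3.86, 1.43), 2) == 2.70

    def test_constant_reference_errors(self):
        y = np.ones(5)
        with pytest.raises(DegenerateDataError):
            compute_metrics(y, y, y)


class TestInterpret:
    @pytest.mark.parametrize("r2,rpd_v,labels", [
        (0.91, 3.40, ("excellent", "adequate")),
        (0.95, 2.51, ("excellent", "adequate")),
        (0.905, 2.0, ("good", "intermediate")),
        (0.82, 1.6, ("good", "intermediate")),
        (0.815, 1.49, ("approximate", "unsatisfactory")),
        (0.66, 1.0, ("approximate", "unsatisfactory")),
        (0.65, 0.9, ("poor", "unsatisfactory")),
        (0.0, 2.6, ("poor", "adequate")),
    ])
    def test_bands(self, r2, rpd_v, labels):
        assert interpret(r2, rpd_v) == labels


class TestOutlierRule:
    def test_clean_set_untouched(self, rng):
        y = rng.normal(size=20)
        pred = y + rng.normal(scale=0.1, size=20)
        retained, removed = remove_outliers(y, pred)
        assert removed.size == 0 and retained.size == 20

    def test_planted_gross_outlier_removed(self, rng):
        y = rng.normal(size=20)
        pred = y + rng.normal(scale=0.1, size=20)
        pred[7] += 0.1 * 25  # far beyond 2.5 residual SDs
        retained, removed = remove_outliers(y, pred)
        assert removed.tolist() == [7]
        assert 7 not in retained

    def test_two_pass_bookkeeping_matches_loop(self, rng):
        n = 30
        band = np.exp(-0.5 * ((np.arange(40) - 20) / 5) ** 2)
        conc = rng.uniform(0, 1, size=n)
        X = np.outer(conc, band) + rng.normal(scale=0.01, size=(n, 40))
        y = conc.copy()
        y[3] += 1.5  # corrupted reference value
        report = evaluate_constituent(X, y, method="PLS", max_k=3)
        # independent loop reproducing cull-then-final-CV
        retained = np.arange(n)
        removed = []
        for _ in range(2):
            k = select_n_factors(X[retained], y[retained], "PLS", 3)
            y_cv = kfold_cv(X[retained], y[retained], "PLS", k)
            keep, drop = remove_outliers(y[retained], y_cv)
            if drop.size == 0:
                break
            removed.extend(retained[drop].tolist())
            retained = retained[keep]
        assert report.n == retained.size
        assert report.n + len(report.removed_ids) == n
        assert sorted(report.removed_ids) == sorted(str(i) for i in removed)
        assert "3" in report.removed_ids

    def test_all_flagged_is_degenerate(self):
        # two samples, symmetric residuals: both exceed 2.5 SDs is impossible,
        # so force it via a tiny threshold
        y = np.array([0.0, 1.0, 2.0])
        pred = np.array([10.0, -10.0, 30.0])
        with pytest.raises(DegenerateDataError):
            remove_outliers(y, pred, threshold=0.01)


class TestSelectFactors:
    def test_noiseless_single_component(self, rng):
        band = np.exp(-0.5 * ((np.arange(30) - 10) / 3) ** 2)
        conc = rng.uniform(1, 2, size=15)
        X = np.outer(conc, band)
        assert select_n_factors(X, conc, "PLS", 5) == 1

    def test_pure_noise_picks_tiny_model(self, rng):
        X = rng.normal(size=(25, 15))
        y = rng.normal(size=25)
        k = select_n_factors(X, y, "PLS", 8)
        assert k <= 1

    def test_never_exceeds_argmin(self, rng):
        X = rng.normal(size=(20, 10))
        y = X[:, 0] + rng.normal(scale=0.2, size=20)
        from cocoanir.evaluate import cv_path
        preds = cv_path(X, y, "PLS", 6)
        secv = np.sqrt(np.sum((preds - y[:, None]) ** 2, 0) / 19)
        assert select_n_factors(X, y, "PLS", 6) <= int(np.argmin(secv))


class TestIPLS:
    def test_interval_partition_391(self):
        slices = interval_slices(391, 30)
        sizes = [s.stop - s.start for s in slices]
        assert sizes[:-1] == [13] * 29 and sizes[-1] == 14

    def test_single_band_signal_selects_its_interval(self, rng):
        n, p = 40, 120
        X = rng.normal(scale=0.01, size=(n, p))
        conc = rng.normal(size=n)
        band = np.exp(-0.5 * ((np.arange(p) - 50) / 4.0) ** 2)
        X += 0.5 * np.outer(conc, band)
        y = conc + rng.normal(scale=0.05, size=n)
        res = ipls_forward(X, y, n_intervals=30, steps=1)
        assert res.selected_intervals[0] == 50 // 4
        assert res.final_rmsecv <= res.per_interval_rmsecv[res.selected_intervals[0]]

    def test_step1_winner_matches_exhaustive_loop(self, rng):
        n, p = 30, 60
        X = rng.normal(size=(n, p))
        y = X[:, 25] + rng.normal(scale=0.3, size=n)
        res = ipls_forward(X, y, n_intervals=10, steps=1, max_k=3)
        # independent exhaustive loop over the same 10 single-interval models
        losses = []
        for s in interval_slices(p, 10):
            Xs = X[:, s]
            k = select_n_factors(Xs, y, "PLS", 3)
            losses.append(rmsecv(y, kfold_cv(Xs, y, "PLS", k)))
        assert res.selected_intervals[0] == int(np.argmin(losses))
        np.testing.assert_allclose(res.per_interval_rmsecv, losses, atol=1e-10)

    def test_too_many_intervals(self, rng):
        with pytest.raises(DataValidationError):
            interval_slices(20, 30)


class TestGridSearch:
    def test_grid_shape_and_winner(self, ground_portable):
        res = grid_search(ground_portable, "fat")
        assert len(res.reports) == 9
        assert all(res.best.secv <= r.secv for r in res.reports)
        treatments = {(r.treatment.scatter, r.treatment.code) for r in res.reports}
        assert len(treatments) == 9

    def test_rpd_consistency_every_report(self, ground_portable):
        res = grid_search(ground_portable, "protein")
        for r in res.reports:
            assert abs(r.rpd - r.sd / r.secv) < 5e-3

    def test_retained_sample_bookkeeping(self, ground_portable):
        for r in grid_search(ground_portable, "ta").reports:
            assert r.n + len(r.removed_ids) == int(
                np.isfinite(ground_portable.references["ta"]).sum()
            )

    def test_scatter_cell_beats_none_on_planted_scatter(self):
        # scatter-sensitive regime: few calibration samples, pure
        # multiplicative/affine scatter planted by the whole-bean mode
        from dataclasses import replace

        from cocoanir import PORTABLE, SyntheticSpec, generate_compositions, generate_spectra

        spec = replace(SyntheticSpec(), n_samples=20, shell_interference=0.0,
                       whole_noise_sd=0.002)
        comps = generate_compositions(spec)
        ds = generate_spectra(comps, spec, "whole", PORTABLE)
        res = grid_search(ds, "protein")
        cells = {(r.treatment.scatter, r.treatment.code): r.r2cv for r in res.reports}
        corrected = max(cells[("MSC", "0,0,1,1")], cells[("SNV_DT", "0,0,1,1")])
        assert corrected - cells[("NONE", "0,0,1,1")] >= 0.1
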