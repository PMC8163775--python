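"""Elastic-net tuning, stability selection and the final fit."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mixsig import (ElasticNetParams, EmptyModelError, MixsigError, TuningConfig,
                    fit_enet, fit_final, split_cohort, stability_select,
                    tune_parameters)
from mixsig.enet import lambda_path


def _signal_data(rng, n=120, p=20, n_info=4, beta=1.5):
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{j:02d}" for j in range(p)])
    eta = X.iloc[:, :n_info].to_numpy() @ np.full(n_info, beta)
    y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int), index=X.index)
    return X, y


class TestSplit:
    def test_stratification_arithmetic(self):
        X = pd.DataFrame(np.arange(80).reshape(40, 2), index=[f"s{i}" for i in range(40)])
        y = pd.Series([0] * 20 + [1] * 20, index=X.index)
        tr, te = split_cohort(X, y, TuningConfig(seed=0))
        assert len(tr) == 32 and len(te) == 8
        assert y.loc[tr].sum() == 16 and y.loc[te].sum() == 4

    def test_same_seed_identical_split(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 3)))
        y = pd.Series([0] * 15 + [1] * 15)
        t1 = split_cohort(X, y, TuningConfig(seed=5))
        t2 = split_cohort(X, y, TuningConfig(seed=5))
        assert list(t1[0]) == list(t2[0]) and list(t1[1]) == list(t2[1])

    def test_per_class_counts_within_one_of_fraction(self, rng):
        y = pd.Series([0] * 23 + [1] * 14)
        X = pd.DataFrame(rng.normal(size=(37, 2)))
        tr, _ = split_cohort(X, y, TuningConfig(seed=1))
        for cls, size in [(0, 23), (1, 14)]:
            got = (y.loc[tr] == cls).sum()
            assert abs(got - round(0.8 * size)) <= 1

    def test_class_too_small_raises(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)))
        y = pd.Series([0] * 8 + [1] * 2)
        with pytest.raises(MixsigError, match="stratify"):
            split_cohort(X, y, TuningConfig(n_folds=4))


class TestSparsityPath:
    def test_sparsity_monotone_in_lambda_at_fixed_alpha(self, rng):
        X, y = _signal_data(rng)
        from mixsig.enet import _standardize
        Xs, _, _ = _standardize(X.to_numpy())
        path = lambda_path(Xs, y.to_numpy(), alpha=1.0, n_lambda=12, decades=3)
        sizes = [len(fit_enet(X, y, ElasticNetParams(1.0, lam)).nonzero_features)
                 for lam in path]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))  # path descends
        assert sizes[0] == 0  # at lambda_max everything is zero

    def test_ridge_is_dense(self, rng):
        X, y = _signal_data(rng)
        model = fit_enet(X, y, ElasticNetParams(0.0, 0.05))
        assert len(model.nonzero_features) == X.shape[1]


class TestTuning:
    def test_default_alpha_grid_has_21_values(self):
        assert len(TuningConfig().alpha_grid) == 21
        assert TuningConfig().alpha_grid[0] == 0.0
        assert TuningConfig().alpha_grid[-1] == 1.0

    def test_surface_shape_and_argmax(self, rng):
        X, y = _signal_data(rng, n=60, p=8, n_info=2)
        cfg = TuningConfig(alpha_grid=(0.2, 1.0), n_replicates=2,
                           lambda_path_length=8, seed=0)
        params, surface = tune_parameters(X, y, cfg)
        assert len(surface) == 2 * 8
        best = surface.loc[surface["mean_auc"].idxmax()]
        assert surface[(surface.alpha == params.alpha)
                       & (surface["lambda"] == params.lam)]["mean_auc"].iloc[0] == \
            pytest.approx(best["mean_auc"])

    def test_null_model_cv_auc_near_half(self, rng):
        """On signal-free data at the top of the lambda path (essentially
        all-zero fits) the out-of-fold AUC sits at chance level."""
        X = pd.DataFrame(rng.normal(size=(60, 8)), columns=[f"f{j}" for j in range(8)])
        y = pd.Series(([0, 1] * 30)[:60])
        cfg = TuningConfig(alpha_grid=(1.0,), n_replicates=1,
                           lambda_path_length=6, lambda_decades=2, seed=0)
        _, surface = tune_parameters(X, y, cfg)
        top_lambda_auc = surface.iloc[0]["mean_auc"]
        assert top_lambda_auc == pytest.approx(0.5, abs=0.12)

    def test_separable_signal_reaches_high_cv_auc(self, rng):
        X, y = _signal_data(rng, n=200, p=20, n_info=4, beta=1.5)
        cfg = TuningConfig(alpha_grid=(0.15, 0.7), n_replicates=2,
                           lambda_path_length=15, seed=0)
        _, surface = tune_parameters(X, y, cfg)
        assert surface["mean_auc"].max() > 0.9


class TestStability:
    def test_median_rounding_half_up(self, rng):
        X, y = _signal_data(rng, n=60, p=10, n_info=2)
        res = stability_select(X, y, ElasticNetParams(0.8, 0.05), n_boot=25, seed=0)
        expected = int(np.floor(np.median(res.model_sizes) + 0.5))
        assert res.median_size == expected
        assert len(res.top_features) == res.median_size

    def test_fixed_seed_identical_frequencies(self, rng):
        X, y = _signal_data(rng, n=60, p=10, n_info=2)
        r1 = stability_select(X, y, ElasticNetParams(0.8, 0.05), n_boot=20, seed=3)
        r2 = stability_select(X, y, ElasticNetParams(0.8, 0.05), n_boot=20, seed=3)
        pd.testing.assert_series_equal(r1.selection_frequency, r2.selection_frequency)

    def test_signal_features_selected_more_often(self, rng):
        X, y = _signal_data(rng, n=150, p=20, n_info=4, beta=1.5)
        res = stability_select(X, y, ElasticNetParams(0.9, 0.03), n_boot=60, seed=1)
        info = res.selection_frequency[[f"f{j:02d}" for j in range(4)]].mean()
        noise = res.selection_frequency[[f"f{j:02d}" for j in range(4, 20)]].mean()
        assert info > noise

    def test_null_data_no_preferred_features(self):
        """Signal-free data: planted-position frequencies sit inside the
        background spread."""
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(80, 15)), columns=[f"f{j}" for j in range(15)])
        y = pd.Series((rng.random(80) < 0.5).astype(int))
        res = stability_select(X, y, ElasticNetParams(0.9, 0.08), n_boot=60, seed=2)
        freqs = res.selection_frequency.to_numpy()
        assert freqs.max() - freqs.min() <= 60  # no runaway feature
        assert freqs.std() < 20


class TestFinalFit:
    def test_huge_lambda_empty_model_error(self, rng):
        X, y = _signal_data(rng, n=50, p=6, n_info=2)
        with pytest.raises(EmptyModelError):
            fit_final(X, y, ElasticNetParams(1.0, 50.0))

    def test_recovered_signs_match_truth(self, rng):
        n, p = 300, 10
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{j}" for j in range(p)])
        beta_true = np.r_[2.0, -2.0, 1.5, -1.5, np.zeros(p - 4)]
        eta = X.to_numpy() @ beta_true
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int))
        model = fit_final(X, y, ElasticNetParams(0.5, 0.02))
        for j in range(4):
            f = f"f{j}"
            if f in model.nonzero_features:
                assert np.sign(model.coefficients[f]) == np.sign(beta_true[j])

    def test_refit_identical(self, rng):
        X, y = _signal_data(rng, n=60, p=8, n_info=2)
        m1 = fit_final(X, y, ElasticNetParams(0.5, 0.05))
        m2 = fit_final(X, y, ElasticNetParams(0.5, 0.05))
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, atol=1e-10)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-10)

    def test_json_roundtrip(self, tmp_path, rng):
        from mixsig import FittedModel
        X, y = _signal_data(rng, n=60, p=8, n_info=2)
        m = fit_final(X, y, ElasticNetParams(0.5, 0.05))
        m.to_json(tmp_path / "m.json")
        back = FittedModel.from_json(tmp_path / "m.json")
        pd.testing.assert_series_equal(m.coefficients, back.coefficients,
                                       check_names=False)


class TestLabelPermutationCalibration:
    def test_out_of_fold_auc_near_half_on_permuted_labels(self):
        """Shuffling labels kills the signal: pooled out-of-fold AUC stays
        near 0.5 across replicates."""
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            X, y = _signal_data(rng, n=100, p=15, n_info=3)
            y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            cfg = TuningConfig(alpha_grid=(0.5,), n_replicates=1,
                               lambda_path_length=6, lambda_decades=2,
                               seed=int(rng.integers(2 ** 31)))
            _, surface = tune_parameters(X, y_perm, cfg)
            # AUC at the most permissive lambda (most overfit) still OOF
            auc = surface.iloc[-1]["mean_auc"]
            hits += 0.35 <= auc <= 0.65
        assert hits >= int(0.85 * n_rep)
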