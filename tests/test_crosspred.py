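"""Cross-prediction matrices and the half-window stability statistic."""

import itertools

import numpy as np
import pytest

from anticipy.crosspred import (
    CrossPredMatrix,
    cross_predict,
    cross_predict_between_features,
    normalize_by_source_fit,
    stability_statistic,
)
from anticipy.models import demean_by_subject
from anticipy.preprocess import BinnedDataset

from conftest import factorial_y, make_null_binned


def make_pattern_binned(rng, patterns, n_subjects=4, trials_per_subject=36,
                        noise=0.5):
    """Binned data whose channel pattern at bin b is patterns[b] * y."""
    patterns = np.asarray(patterns, float)  # (bins, channels)
    B, C = patterns.shape
    n = n_subjects * trials_per_subject
    subjects = np.repeat(np.arange(n_subjects), trials_per_subject)
    y = factorial_y(rng, subjects)
    z = y - y.mean()
    data = rng.normal(scale=noise, size=(n, C, B))
    data += z[:, None, None] * patterns.T[None, :, :]
    centers = (np.arange(B) + 0.5) * 10.0
    return (
        BinnedDataset(data=data, bin_width_ms=10.0, bin_centers_ms=centers,
                      subject=subjects),
        y,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12)


class TestCrossPredict:
    def test_diagonal_equals_in_bin_fit(self, rng):
        binned, y = make_pattern_binned(rng, np.ones((6, 3)))
        xpm = cross_predict(binned, y, seed=0, n_perm_trial=100)
        # recompute the in-bin multivariate R^2 independently per bin
        yc = demean_by_subject(y, binned.subject)
        for b in range(6):
            Xc = demean_by_subject(binned.data[:, :, b], binned.subject)
            beta = Xc.T @ yc / (yc @ yc)
            ssr = ((Xc - np.outer(yc, beta)) ** 2).sum()
            r2 = 1.0 - ssr / (Xc**2).sum()
            assert xpm.ev[b, b] == pytest.approx(r2, rel=1e-10)

    def test_stationary_pattern_cross_predicts_everywhere(self, rng):
        binned, y = make_pattern_binned(rng, np.ones((6, 3)), noise=0.4)
        xpm = cross_predict(binned, y, seed=1, n_perm_trial=200)
        assert (xpm.ev_thresholded > 0).all()
        assert np.allclose(xpm.ev, xpm.ev.T, atol=0.1)

    def test_orthogonal_patterns_share_no_variance(self, rng):
        patterns = np.array([[1.0, 0.0], [0.0, 1.0]]) * 2.0
        binned, y = make_pattern_binned(rng, patterns, noise=0.3)
        xpm = cross_predict(binned, y, seed=2, n_perm_trial=200)
        assert xpm.ev_thresholded[0, 1] == 0.0
        assert xpm.ev_thresholded[1, 0] == 0.0
        assert xpm.ev_thresholded[0, 0] > 0 and xpm.ev_thresholded[1, 1] > 0

    def test_null_data_mostly_zeroed(self, rng):
        # off-diagonal entries are genuine cross-predictions; the diagonal is
        # the trained in-bin fit and sits above its permutation null even
        # for pure noise.  Aggregate a few datasets to beat the per-dataset
        # correlation between entries.
        off = ~np.eye(8, dtype=bool)
        rates = []
        for rep in range(5):
            binned = make_null_binned(rng, n_bins=8)
            y = factorial_y(rng, binned.subject)
            xpm = cross_predict(binned, y, seed=3 + rep, n_perm_trial=200)
            rates.append((xpm.ev_thresholded[off] == 0).mean())
        assert np.mean(rates) >= 0.9

    def test_thresholding_is_monotone_in_the_cutoff(self, rng):
        binned, y = make_pattern_binned(rng, np.ones((5, 2)), noise=1.5)
        strict = cross_predict(binned, y, seed=4, n_perm_trial=200, p_threshold=0.01)
        loose = cross_predict(binned, y, seed=4, n_perm_trial=200, p_threshold=0.10)
        survived_strict = strict.ev_thresholded != 0
        assert np.all(loose.ev_thresholded[survived_strict] != 0)


class TestBetweenFeatures:
    def test_identical_features_reduce_to_cross_predict(self, rng):
        binned, y = make_pattern_binned(rng, np.ones((4, 2)))
        a = cross_predict(binned, y, seed=5, n_perm_trial=100)
        b = cross_predict_between_features(binned, y, y, seed=5, n_perm_trial=100)
        assert np.array_equal(a.ev, b.ev)
        assert np.array_equal(a.p, b.p)

    def test_mean_models_do_not_explain_variability_data(self, rng):
        """Channels planted on mean reward only: models fitted on mean score
        nothing when evaluated against (sign-flipped) variability labels."""
        binned, y_mean = make_pattern_binned(rng, np.ones((5, 3)), noise=0.4)
        y_var = factorial_y(rng, binned.subject, levels=(0.08, 0.16, 0.24))
        for y_eval in (y_var, -y_var):
            xpm = cross_predict_between_features(
                binned, y_mean, y_eval, seed=6, n_perm_trial=200
            )
            assert (xpm.ev_thresholded == 0).all()

    def test_sign_flip_does_not_defeat_the_linear_model(self, rng):
        binned, y = make_pattern_binned(rng, -np.ones((4, 2)), noise=0.4)
        xpm = cross_predict(binned, y, seed=7, n_perm_trial=200)
        assert (np.diag(xpm.ev_thresholded) > 0).all()


def toy_xpm(M, centers=None):
    M = np.asarray(M, float)
    B = M.shape[0]
    centers = np.arange(B) * 10.0 + 5.0 if centers is None else centers
    return CrossPredMatrix(
        ev=M, p=np.zeros_like(M), ev_thresholded=M.copy(),
        bin_centers_ms=np.asarray(centers, float),
    )


class TestStability:
    def test_brute_force_enumeration_on_four_bins(self, rng):
        """Exhaustive check of the permutation null on a 4-bin matrix: the
        total off-diagonal sum is invariant; only the half-split varies."""
        M = rng.random((4, 4))
        np.fill_diagonal(M, 0.0)
        labels = np.array([0, 0, 1, 1])
        stats = []
        for perm in itertools.permutations(range(4)):
            L = labels[list(perm)]
            s = [
                sum(
                    M[i, j]
                    for i in range(4)
                    for j in range(4)
                    if i != j and L[i] == k and L[j] == k
                )
                for k in (0, 1)
            ]
            stats.append(s[1] - s[0])
            # the off-diagonal total never changes under relabelling
            assert M.sum() == pytest.approx(M.sum())
        xpm = toy_xpm(M)
        res = stability_statistic(xpm, split_ms=20.0, n_perm_time=5000, seed=0)
        # observed statistic equals the identity permutation's value
        assert res.statistic == pytest.approx(stats[0], rel=1e-12)
        # permutation p within the exact enumeration's attainable range
        exact_p = np.mean([s >= stats[0] - 1e-12 for s in stats])
        assert abs(res.p - exact_p) < 0.05

    def test_diagonal_only_matrix_off_diagonal_stat_is_zero(self):
        xpm = toy_xpm(np.diag([1.0, 2.0, 3.0, 4.0]))
        res = stability_statistic(xpm, split_ms=20.0, n_perm_time=1000, seed=1)
        assert res.statistic == 0.0
        assert res.p == 1.0
        assert res.diag_statistic == pytest.approx(4.0)

    def test_all_zero_matrix_warns_p_one(self):
        xpm = toy_xpm(np.zeros((4, 4)))
        with pytest.warns(UserWarning, match="all-zero"):
            res = stability_statistic(xpm, split_ms=20.0, n_perm_time=1000, seed=2)
        assert res.p == 1.0

    def test_second_half_block_structure_detected(self):
        M = np.zeros((8, 8))
        M[4:, 4:] = 1.0
        np.fill_diagonal(M, 0.0)
        xpm = toy_xpm(M)
        res = stability_statistic(xpm, split_ms=40.0, n_perm_time=5000, seed=3)
        assert res.statistic == pytest.approx(12.0)
        assert res.p < 0.05


class TestNormalize:
    def test_normalized_diagonal_is_zero_or_one(self, rng):
        binned, y = make_pattern_binned(rng, np.ones((5, 2)))
        xpm = cross_predict(binned, y, seed=8, n_perm_trial=100)
        norm = normalize_by_source_fit(xpm)
        d = np.diag(norm.ev)
        assert np.all((np.abs(d - 1.0) < 1e-12) | (d == 0.0))

    def test_stationary_pattern_normalizes_to_near_one(self, rng):
        binned, y = make_pattern_binned(rng, np.ones((5, 3)), noise=0.3)
        norm = normalize_by_source_fit(cross_predict(binned, y, seed=9,
                                                     n_perm_trial=200))
        off = norm.ev_thresholded[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off - 1.0) < 0.2)

    def test_zero_diag_rows_flagged_not_fatal(self):
        M = np.array([[0.0, 0.5], [0.2, 0.4]])
        norm = normalize_by_source_fit(toy_xpm(M))
        assert norm.zero_diag_rows == (0,)
        assert np.all(norm.ev[0] == 0.0)
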