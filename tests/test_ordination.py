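import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pubertome.ordination import (
    PCoAResult,
    bray_curtis,
    euclidean_log,
    pc_sum_score,
    pcoa,
    stage_score_test,
)


def brute_force_pcoa(D):
    """Independent oracle: element-wise Gower centering + dense eigensolve."""
    n = D.shape[0]
    D2 = D**2
    row = D2.mean(axis=1)
    grand = D2.mean()
    B = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            B[i, j] = -0.5 * (D2[i, j] - row[i] - row[j] + grand)
    vals, vecs = np.linalg.eig(B)
    vals, vecs = np.real(vals), np.real(vecs)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def random_euclidean_distance(rng, n, d=3):
    pts = rng.normal(size=(n, d))
    return np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        X = np.array([[0.3, 0.7], [0.3, 0.7]])
        assert bray_curtis(X)[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_one(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert bray_curtis(X)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_value(self):
        X = np.array([[0.6, 0.4], [0.2, 0.8]])
        assert bray_curtis(X)[0, 1] == pytest.approx(0.4, abs=1e-12)

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="summing to 1"):
            bray_curtis(np.array([[0.5, 0.2], [0.5, 0.5]]))

    @given(
        counts=arrays(
            np.int64, (5, 7), elements=st.integers(min_value=0, max_value=500)
        ).filter(lambda m: (m.sum(axis=1) > 0).all())
    )
    @settings(max_examples=30, deadline=None)
    def test_metric_properties(self, counts):
        X = counts / counts.sum(axis=1, keepdims=True)
        D = bray_curtis(X)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert np.all(D >= -1e-12) and np.all(D <= 1.0 + 1e-12)

    def test_matches_direct_formula_oracle(self, rng):
        counts = rng.integers(0, 300, size=(6, 10))
        counts[:, 0] += 1
        X = counts / counts.sum(axis=1, keepdims=True)
        D = bray_curtis(X)
        for i in range(6):
            for j in range(6):
                expected = 1.0 - np.minimum(X[i], X[j]).sum()
                assert D[i, j] == pytest.approx(expected, abs=1e-12)


class TestEuclideanLog:
    def test_matches_direct_computation(self, rng):
        counts = rng.integers(1, 200, size=(4, 5))
        X = counts / counts.sum(axis=1, keepdims=True)
        D = euclidean_log(X)
        logX = np.log10(X + 1e-6)
        for i in range(4):
            for j in range(4):
                assert D[i, j] == pytest.approx(
                    np.linalg.norm(logX[i] - logX[j]), abs=1e-12
                )
        assert np.allclose(np.diag(D), 0.0)

    def test_is_valid_pcoa_input(self, rng):
        counts = rng.integers(1, 200, size=(5, 6))
        X = counts / counts.sum(axis=1, keepdims=True)
        res = pcoa(euclidean_log(X))
        # Euclidean distances embed exactly: no negative eigenvalue mass
        assert res.negative_eigenvalue_mass < 1e-8


class TestPcoa:
    def test_equilateral_simplex(self):
        # three mutually equidistant points: two equal positive eigenvalues
        D = np.ones((3, 3)) - np.eye(3)
        res = pcoa(D)
        assert len(res.eigenvalues) == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], rel=1e-10)
        vals, _ = brute_force_pcoa(D)
        np.testing.assert_allclose(res.eigenvalues, vals[:2], atol=1e-10)

    def test_reproduces_euclidean_distances(self, rng):
        D = random_euclidean_distance(rng, 5)
        res = pcoa(D)
        coords = res.coordinates
        recon = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(recon, D, atol=1e-8)

    def test_matches_bruteforce_oracle_random(self, rng):
        for n in (3, 5, 8, 10):
            D = random_euclidean_distance(rng, n)
            res = pcoa(D)
            vals, vecs = brute_force_pcoa(D)
            pos = vals > 1e-10
            np.testing.assert_allclose(res.eigenvalues, vals[pos], atol=1e-8)
            oracle_coords = vecs[:, pos] * np.sqrt(vals[pos])
            for k in range(res.coordinates.shape[1]):
                a, b = res.coordinates[:, k], oracle_coords[:, k]
                assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_duplicate_sample_collapses(self, rng):
        counts = rng.integers(1, 100, size=(4, 6))
        X = counts / counts.sum(axis=1, keepdims=True)
        X = np.vstack([X, X[0]])
        res = pcoa(bray_curtis(X))
        gap = np.abs(res.coordinates[0] - res.coordinates[4]).max()
        assert gap < 1e-8

    def test_asymmetric_rejected(self):
        D = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(D)

    def test_eigenvalues_non_increasing_and_proportions(self, rng):
        D = random_euclidean_distance(rng, 8)
        res = pcoa(D)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert res.proportion_explained.sum() == pytest.approx(1.0)


class TestPcSumScore:
    def _result(self, coords, ids):
        return PCoAResult(
            sample_ids=ids,
            coordinates=np.asarray(coords, dtype=float),
            eigenvalues=np.array([2.0, 1.0]),
            proportion_explained=np.array([2 / 3, 1 / 3]),
            negative_eigenvalue_mass=0.0,
        )

    def test_orientation_rule_arithmetic(self):
        res = self._result([[1.0, 1.0], [-3.0, 2.0]], ["kid", "adult"])
        scores = pc_sum_score(res, ["adult"])
        # axis 1 flipped (adult centroid -3 < 0): kid scores -1 + 1 = 0
        assert scores["kid"] == pytest.approx(0.0)

    def test_sign_flip_invariance(self, rng):
        coords = rng.normal(size=(6, 2))
        ids = [f"s{i}" for i in range(6)]
        base = pc_sum_score(self._result(coords, ids), ids[4:])
        flipped = pc_sum_score(self._result(coords * np.array([-1.0, 1.0]), ids), ids[4:])
        pd.testing.assert_series_equal(base, flipped)

    def test_requires_two_axes(self):
        res = PCoAResult(["a", "b"], np.ones((2, 1)), np.array([1.0]), np.array([1.0]), 0.0)
        with pytest.raises(ValueError, match="2 positive axes"):
            pc_sum_score(res, ["a"])

    def test_requires_adults_present(self):
        res = self._result([[1.0, 1.0], [2.0, 2.0]], ["a", "b"])
        with pytest.raises(ValueError, match="no adult"):
            pc_sum_score(res, ["zz"])


class TestStageScoreTest:
    def test_null_calibration(self, rng):
        reps, rejections = 200, 0
        for _ in range(reps):
            scores = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
            groups = pd.Series(["pre_peak"] * 15 + ["peak"] * 15, index=scores.index)
            out = stage_score_test(scores, groups, "pre_peak")
            if out.loc["peak", "pvalue"] < 0.05:
                rejections += 1
        assert 0.01 <= rejections / reps <= 0.12

    def test_power_with_offset_two(self, rng):
        hits = 0
        reps = 100
        for _ in range(reps):
            a = rng.normal(0.0, 1.0, 15)
            b = rng.normal(2.0, 1.0, 15)
            scores = pd.Series(np.concatenate([a, b]), index=[f"s{i}" for i in range(30)])
            groups = pd.Series(["pre_peak"] * 15 + ["peak"] * 15, index=scores.index)
            out = stage_score_test(scores, groups, "pre_peak")
            if out.loc["peak", "pvalue"] < 0.01 and abs(out.loc["peak", "difference"] - 2) < 1.5:
                hits += 1
        assert hits >= 95

    def test_constant_scores_do_not_crash(self):
        scores = pd.Series(np.ones(10), index=[f"s{i}" for i in range(10)])
        groups = pd.Series(["pre_peak"] * 5 + ["peak"] * 5, index=scores.index)
        out = stage_score_test(scores, groups, "pre_peak")
        assert out.loc["peak", "difference"] == pytest.approx(0.0)
        assert np.isnan(out.loc["peak", "pvalue"]) or out.loc["peak", "pvalue"] >= 0.99

    def test_missing_reference_rejected(self):
        scores = pd.Series(np.arange(6, dtype=float), index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["peak"] * 3 + ["post_peak_lt2y"] * 3, index=scores.index)
        with pytest.raises(ValueError, match="reference group"):
            stage_score_test(scores, groups, "pre_peak")
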