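"""K*-means geometry, clustering, and pseudo-inverse unmixing."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.optimize import linear_sum_assignment

from pars_stain import kstar, signals, synth
from pars_stain.kstar import (
    FeatureSet,
    ZeroVectorError,
    angular_distance,
    kstar_cluster,
    learn_features,
    unmix,
    update_centroid,
)
from pars_stain.signals import TimeWindow


class TestAngularDistance:
    def test_scaled_and_inverted_signals_have_zero_distance(self):
        local = np.random.default_rng(42)
        for _ in range(20):
            x = local.standard_normal(16)
            # sqrt(1 - cos^2) amplifies float error to ~sqrt(eps) near zero
            assert angular_distance(x, x) == pytest.approx(0.0, abs=1e-6)
            assert angular_distance(x, -x) == pytest.approx(0.0, abs=1e-6)
            assert angular_distance(x, 2 * x) == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_signals_have_maximum_distance(self):
        assert angular_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_45_degrees(self):
        assert angular_distance([1, 0], [1, 1]) == pytest.approx(
            np.sqrt(2) / 2, abs=1e-12
        )

    def test_zero_vector_raises_distinct_error(self):
        with pytest.raises(ZeroVectorError):
            angular_distance([0, 0], [1, 0])

    def test_scale_and_sign_invariance_pseudometric(self, rng):
        for _ in range(50):
            x = rng.standard_normal(8)
            y = rng.standard_normal(8)
            a, b = rng.uniform(-3, 3, 2)
            if abs(a) < 1e-3 or abs(b) < 1e-3:
                continue
            assert angular_distance(a * x, b * y) == pytest.approx(
                angular_distance(x, y), abs=1e-9
            )
            assert angular_distance(x, y) == pytest.approx(
                angular_distance(y, x), abs=1e-12
            )

    def test_matches_arccos_construction(self, rng):
        # independent construction: sine of the arccos of cosine similarity
        for _ in range(200):
            x = rng.standard_normal(12)
            y = rng.standard_normal(12)
            cos = np.dot(x, y) / (np.linalg.norm(x) * np.linalg.norm(y))
            theta = np.arccos(np.clip(abs(cos), 0.0, 1.0))
            assert angular_distance(x, y) == pytest.approx(np.sin(theta), abs=1e-9)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    x=hnp.arrays(float, 8, elements=st.floats(-10, 10, allow_nan=False)),
    y=hnp.arrays(float, 8, elements=st.floats(-10, 10, allow_nan=False)),
    a=st.floats(0.01, 50),
    b=st.floats(0.01, 50),
    sx=st.sampled_from([-1.0, 1.0]),
    sy=st.sampled_from([-1.0, 1.0]),
)
def test_angular_distance_is_a_pseudometric_on_rays(x, y, a, b, sx, sy):
    """d(ax, by) == d(x, y) for any nonzero scalings/sign flips, symmetric,
    and bounded in [0, 1]."""
    assume(np.linalg.norm(x) > 1e-3 and np.linalg.norm(y) > 1e-3)
    d = angular_distance(x, y)
    assert 0.0 <= d <= 1.0
    assert angular_distance(y, x) == pytest.approx(d, abs=1e-12)
    assert angular_distance(sx * a * x, sy * b * y) == pytest.approx(d, abs=1e-7)


class TestUpdateCentroid:
    def test_rank_one_cluster_returns_the_direction(self, rng):
        v = rng.standard_normal(10)
        c = update_centroid(np.tile(v, (5, 1)))
        assert angular_distance(c, v) == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.norm(c) == pytest.approx(1.0)
        assert c[np.argmax(np.abs(c))] > 0  # sign convention

    def test_invariant_to_negating_members(self, rng):
        M = rng.standard_normal((7, 6))
        flip = M.copy()
        flip[::2] *= -1
        assert update_centroid(M) == pytest.approx(update_centroid(flip))

    def test_matches_scatter_eigendecomposition(self):
        M = np.array([[2.0, 0.0], [1.0, 1.0]])
        scatter = M.T @ M
        assert scatter == pytest.approx(np.array([[5.0, 1.0], [1.0, 1.0]]))
        w, V = np.linalg.eigh(scatter)
        lead = V[:, np.argmax(w)]
        c = update_centroid(M)
        assert angular_distance(c, lead) == pytest.approx(0.0, abs=1e-9)

    def test_eigen_oracle_on_random_clusters(self, rng):
        for _ in range(100):
            M = rng.standard_normal((rng.integers(2, 9), 5))
            scatter = M.T @ M
            w, V = np.linalg.eigh(scatter)
            lead = V[:, np.argmax(w)]
            # angular distance amplifies float error by sqrt near zero
            assert angular_distance(update_centroid(M), lead) < 1e-6

    def test_all_zero_members_raise(self):
        with pytest.raises(ZeroVectorError):
            update_centroid(np.zeros((3, 4)))


def _two_family_signals(rng, n=200):
    shapes = np.eye(2, 8)[:, :]  # two orthogonal shapes in R^8
    labels = rng.integers(0, 2, n)
    scales = rng.uniform(0.5, 2.0, n) * rng.choice([-1, 1], n)
    return shapes[labels] * scales[:, None], shapes, labels


class TestKStarCluster:
    def test_recovers_orthogonal_families(self, rng):
        X, shapes, _ = _two_family_signals(rng)
        fs, asn = kstar_cluster(X, 2, seed=0)
        D = kstar.pairwise_angular_distance(fs.centroids, shapes)
        r, c = linear_sum_assignment(D)
        assert np.all(D[r, c] < 1e-6)
        assert np.all(asn.distances < 1e-6)

    def test_deterministic_for_fixed_seed(self, rng):
        X, _, _ = _two_family_signals(rng)
        fs1, a1 = kstar_cluster(X, 2, seed=9)
        fs2, a2 = kstar_cluster(X, 2, seed=9)
        assert np.array_equal(fs1.centroids, fs2.centroids)
        assert np.array_equal(a1.labels, a2.labels)
        assert fs1.inertia == fs2.inertia

    def test_inertia_decreases_with_k_on_three_families(self, rng):
        shapes = np.eye(3, 9)
        labels = rng.integers(0, 3, 300)
        X = shapes[labels] * rng.uniform(0.5, 2, 300)[:, None]
        X += 0.01 * rng.standard_normal(X.shape)
        fs2, _ = kstar_cluster(X, 2, seed=0)
        fs3, _ = kstar_cluster(X, 3, seed=0)
        assert fs3.inertia < fs2.inertia

    def test_inertia_trajectory_decreases(self, skin_phantom):
        """Inertia falls overall; the amplitude-weighted centroid update may
        produce tiny one-step upticks but never a real regression."""
        ph = skin_phantom
        w = signals.post_excitation_window(ph.nr)
        fs = kstar.learn_features(ph.nr, w, 3, subset_fraction=0.2, seed=0)
        hist = fs.inertia_history
        assert len(hist) >= 2
        assert hist[-1] <= hist[0]
        for a, b in zip(hist, hist[1:]):
            assert b <= a * 1.01  # no more than 1% single-step increase

    def test_k_larger_than_signal_count_raises(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            kstar_cluster(rng.standard_normal((2, 5)), 3)

    def test_k_bounds_enforced(self, rng):
        X = rng.standard_normal((50, 5))
        with pytest.raises(ValueError, match="bounds"):
            kstar_cluster(X, 7)
        with pytest.raises(ValueError, match="bounds"):
            kstar_cluster(X, 1)

    def test_zero_signals_rejected(self):
        X = np.zeros((10, 4))
        X[0, 0] = 1.0
        with pytest.raises(ZeroVectorError):
            kstar_cluster(X, 2)


class TestUnmix:
    def _featureset(self, F):
        C = np.asarray(F, dtype=float).T
        C = C / np.linalg.norm(C, axis=1, keepdims=True)
        return FeatureSet(K=C.shape[0], centroids=C)

    def _raster_from_signals(self, X, hw):
        sig = X.reshape(hw[0], hw[1], -1)
        return signals.TDSignalRaster(sig, 1.0, ((signals.EX266, 0.0),))

    def test_exact_synthesis_recovered_to_machine_precision(self, rng):
        C = rng.standard_normal((3, 16))
        fs = FeatureSet(K=3, centroids=C / np.linalg.norm(C, axis=1, keepdims=True))
        W = rng.standard_normal((4, 5, 3))
        X = np.einsum("hwk,kn->hwn", W, fs.centroids)
        r = self._raster_from_signals(X, (4, 5))
        out = unmix(r, fs, TimeWindow(0, 16), dead_pixel_rel=0.0)
        got = np.stack([im.values for im in out.images], axis=2)
        assert got == pytest.approx(W, abs=1e-12)

    def test_zero_signal_gives_zero_amplitudes(self):
        fs = self._featureset(np.eye(8)[:, :2])
        r = self._raster_from_signals(np.zeros((2, 2, 8)), (2, 2))
        out = unmix(r, fs, TimeWindow(0, 8))
        for im in out.images:
            assert np.all(im.values == 0.0)

    def test_noisy_signals_match_normal_equations_oracle(self, rng):
        for _ in range(100):
            C = rng.standard_normal((3, 10))
            fs = FeatureSet(
                K=3, centroids=C / np.linalg.norm(C, axis=1, keepdims=True)
            )
            F = fs.feature_matrix
            s = rng.standard_normal(10)
            r = self._raster_from_signals(s.reshape(1, 1, 10), (1, 1))
            out = unmix(r, fs, TimeWindow(0, 10), dead_pixel_rel=0.0)
            a = np.array([im.values[0, 0] for im in out.images])
            oracle = np.linalg.solve(F.T @ F, F.T @ s)
            assert a == pytest.approx(oracle, abs=1e-8)

    def test_rank_deficient_matrix_names_offending_pair(self):
        C = np.zeros((3, 8))
        C[0, 0] = 1.0
        C[1, 1] = 1.0
        C[2, 0] = 1.0  # duplicate of the first centroid
        fs = FeatureSet(K=3, centroids=C)
        r = self._raster_from_signals(np.zeros((1, 1, 8)), (1, 1))
        with pytest.raises(ValueError, match="m_f1 and m_f3"):
            unmix(r, fs, TimeWindow(0, 8))


class TestLearnFeatures:
    def test_full_subset_reproduces_direct_clustering(self, rng):
        X, _, _ = _two_family_signals(rng, n=120)
        r = signals.TDSignalRaster(
            X.reshape(10, 12, 8), 1.0, ((signals.EX266, 0.0),)
        )
        fs = learn_features(r, TimeWindow(0, 8), 2, subset_fraction=1.0, seed=4)
        direct, _ = kstar_cluster(X, 2, seed=4)
        assert np.array_equal(fs.centroids, direct.centroids)

    def test_recovers_generating_shapes_on_phantom(self, skin_phantom):
        ph = skin_phantom
        w = signals.post_excitation_window(ph.nr)
        fs = learn_features(ph.nr, w, 3, subset_fraction=0.2, seed=0)
        B = ph.truth.basis[:, w.start_index :]
        B = B / np.linalg.norm(B, axis=1, keepdims=True)
        D = kstar.pairwise_angular_distance(fs.centroids, B)
        r, c = linear_sum_assignment(D)
        assert np.all(D[r, c] < 0.05)

    def test_seed_stability_up_to_permutation(self, skin_phantom):
        ph = skin_phantom
        w = signals.post_excitation_window(ph.nr)
        fs1 = learn_features(ph.nr, w, 3, subset_fraction=0.2, seed=1)
        fs2 = learn_features(ph.nr, w, 3, subset_fraction=0.2, seed=2)
        D = kstar.pairwise_angular_distance(fs1.centroids, fs2.centroids)
        r, c = linear_sum_assignment(D)
        # two independent-subset fits, each within ~0.05 of the basis, can
        # differ by up to twice that after matching
        assert np.all(D[r, c] < 0.08)

    def test_too_few_usable_signals_raise(self):
        sig = np.zeros((2, 2, 8))
        sig[0, 0] = 1.0  # single live pixel
        r = signals.TDSignalRaster(sig, 1.0, ((signals.EX266, 0.0),))
        with pytest.raises(ValueError, match="usable"):
            learn_features(r, TimeWindow(0, 8), 2, subset_fraction=1.0)


class TestEndToEndRecovery:
    def test_noiseless_phantom_weight_maps(self, noiseless_skin_phantom):
        """learn_features + unmix reproduce the generating weights up to
        per-feature scale and permutation."""
        ph = noiseless_skin_phantom
        w = signals.post_excitation_window(ph.nr)
        fs = learn_features(ph.nr, w, 3, subset_fraction=0.3, seed=0)
        feats = unmix(ph.nr, fs, w)
        got = np.stack([im.values for im in feats.images], axis=2)
        B = ph.truth.basis[:, w.start_index :]
        B = B / np.linalg.norm(B, axis=1, keepdims=True)
        D = kstar.pairwise_angular_distance(fs.centroids, B)
        r, c = linear_sum_assignment(D)
        for k_learned, k_true in zip(r, c):
            a = got[:, :, k_learned].ravel()
            b = ph.truth.weights[:, :, k_true].ravel()
            corr = abs(np.corrcoef(a, b)[0, 1])
            assert corr > 0.999


class TestSerialization:
    def test_round_trip_exact(self, tmp_path, rng):
        C = rng.standard_normal((3, 12))
        C = C / np.linalg.norm(C, axis=1, keepdims=True)
        fs = FeatureSet(
            K=3, centroids=C, subset_size=99, seed=5, n_iter=7,
            converged=True, inertia=1.25,
        )
        p = tmp_path / "fs.h5"
        kstar.save_featureset(p, fs)
        back = kstar.load_featureset(p)
        assert np.array_equal(back.centroids, fs.centroids)
        assert (back.K, back.subset_size, back.seed) == (3, 99, 5)
        assert back.converged and back.inertia == 1.25
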