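"""Covariance pooling, the GEVD, congruency scoring, forward models."""

import numpy as np
import pytest
from sklearn.base import clone

from fixcca import (
    CorrelatedComponents,
    CovarianceTable,
    congruency_features,
    forward_model,
    pairwise_cross_covariance,
    pooled_covariances,
    subject_congruency_scores,
    temporal_profiles,
)
from fixcca.congruency import PooledCovariances
from fixcca.containers import FRPSet

from conftest import random_pencil


class TestPairwiseCovariance:
    def test_matches_entrywise_sum_oracle(self):
        rng = np.random.default_rng(0)
        xi, xj = rng.standard_normal((3, 100)), rng.standard_normal((3, 100))
        r = pairwise_cross_covariance(xi, xj)
        oracle = np.zeros((3, 3))
        for a in range(3):
            for b in range(3):
                oracle[a, b] = sum(xi[a, t] * xj[b, t] for t in range(100)) / 100
        np.testing.assert_allclose(r, oracle, atol=1e-12)

    def test_auto_covariance_is_psd_and_symmetric(self):
        x = np.random.default_rng(1).standard_normal((4, 50))
        r = pairwise_cross_covariance(x, x)
        np.testing.assert_allclose(r, r.T, atol=1e-14)
        assert np.linalg.eigvalsh(r).min() > -1e-12

    def test_orthogonal_rows_give_zero(self):
        xi = np.array([[1.0, 0.0, 1.0, 0.0]])
        xj = np.array([[0.0, 1.0, 0.0, -1.0]])
        np.testing.assert_allclose(pairwise_cross_covariance(xi, xj), 0.0)

    def test_column_mismatch_rejected(self):
        with pytest.raises(ValueError, match="column mismatch"):
            pairwise_cross_covariance(np.zeros((2, 5)), np.zeros((2, 6)))


class TestPooled:
    def test_hand_enumerated_three_subject_average(self):
        rng = np.random.default_rng(2)
        xs = [rng.standard_normal((2, 8)) for _ in range(3)]
        pc = pooled_covariances(xs, shrinkage=0.0)
        pairs = [(i, j) for i in range(3) for j in range(3) if i != j]
        rb_hand = sum(xs[i] @ xs[j].T / 8 for i, j in pairs) / 6
        rw_hand = sum(x @ x.T / 8 for x in xs) / 3
        np.testing.assert_allclose(pc.rb, (rb_hand + rb_hand.T) / 2, atol=1e-12)
        np.testing.assert_allclose(pc.rw, rw_hand, atol=1e-12)

    def test_identical_subjects_make_between_equal_within(self):
        x = np.random.default_rng(3).standard_normal((3, 40))
        pc = pooled_covariances([x, x, x], shrinkage=0.0)
        np.testing.assert_allclose(pc.rb, pc.rw, atol=1e-12)

    def test_independent_noise_shrinks_between(self):
        rng = np.random.default_rng(4)
        xs = [rng.standard_normal((4, 4000)) for _ in range(6)]
        pc = pooled_covariances(xs, shrinkage=0.0)
        assert np.linalg.norm(pc.rb) < 0.2 * np.linalg.norm(pc.rw)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pooled_covariances([np.zeros((2, 4))])

    def test_table_subset_matches_direct_pooling(self):
        rng = np.random.default_rng(5)
        xs = [rng.standard_normal((3, 30)) for _ in range(5)]
        table = CovarianceTable(xs)
        sub = pooled_covariances(table, shrinkage=0.0, subject_ids=[0, 2, 4])
        direct = pooled_covariances([xs[0], xs[2], xs[4]], shrinkage=0.0)
        np.testing.assert_allclose(sub.rb, direct.rb, atol=1e-12)
        np.testing.assert_allclose(sub.rw, direct.rw, atol=1e-12)


class TestGEVD:
    def fit_pc(self, rb, rw, k, shrinkage=0.0):
        pc = PooledCovariances(rb=rb, rw=rw, shrinkage=shrinkage)
        return CorrelatedComponents(n_components=k, shrinkage=shrinkage).fit(pc)

    def test_diagonal_pencil(self):
        est = self.fit_pc(np.diag([3.0, 2.0, 1.0]), np.eye(3), 3)
        np.testing.assert_allclose(est.eigenvalues_, [3.0, 2.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(np.abs(est.filters_[:, 0]), [1, 0, 0], atol=1e-12)

    def test_identity_pencil_gives_unit_eigenvalues(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((4, 4))
        r = a @ a.T + 4 * np.eye(4)
        est = self.fit_pc(r, r, 4)
        np.testing.assert_allclose(est.eigenvalues_, 1.0, atol=1e-10)

    def test_top_eigenvalue_beats_random_search(self):
        rng = np.random.default_rng(7)
        rb, rw = random_pencil(rng)
        est = self.fit_pc(rb, rw, 4)
        w = rng.standard_normal((20000, 4))
        rho = np.einsum("nd,de,ne->n", w, rb, w) / np.einsum(
            "nd,de,ne->n", w, rw, w
        )
        assert est.eigenvalues_[0] >= rho.max() - 1e-6

    def test_rayleigh_quotient_equals_eigenvalue(self):
        rng = np.random.default_rng(8)
        rb, rw = random_pencil(rng)
        est = self.fit_pc(rb, rw, 4)
        np.testing.assert_allclose(est.rhos_, est.eigenvalues_, atol=1e-9)

    def test_filters_unit_norm_and_sign_convention(self):
        rng = np.random.default_rng(9)
        rb, rw = random_pencil(rng)
        est = self.fit_pc(rb, rw, 4)
        np.testing.assert_allclose(np.linalg.norm(est.filters_, axis=0), 1.0)
        for k in range(4):
            a = est.forward_models_[:, k]
            assert a[np.argmax(np.abs(a))] > 0

    def test_singular_within_covariance_suggests_shrinkage(self):
        rb = np.eye(3)
        rw = np.diag([1.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="shrinkage"):
            self.fit_pc(rb, rw, 2)

    def test_shrinkage_restores_solvability(self):
        # average-referenced data: rank D-1 within-covariance
        rng = np.random.default_rng(10)
        xs = [rng.standard_normal((4, 200)) for _ in range(3)]
        xs = [x - x.mean(axis=0) for x in xs]
        est = CorrelatedComponents(n_components=3, shrinkage=0.05).fit(xs)
        assert np.isfinite(est.eigenvalues_).all()

    def test_estimator_clones(self):
        est = CorrelatedComponents(n_components=5, shrinkage=0.1)
        assert clone(est).get_params() == est.get_params()

    def test_transform_projects_channels(self):
        rng = np.random.default_rng(11)
        xs = [rng.standard_normal((4, 100)) for _ in range(3)]
        est = CorrelatedComponents(n_components=2, shrinkage=0.01).fit(xs)
        y = est.transform(xs[0])
        np.testing.assert_allclose(y, est.filters_.T @ xs[0])
        with pytest.raises(ValueError, match="channel"):
            est.transform(np.zeros((5, 10)))


class TestScaleInvariance:
    def test_common_scaling_cancels_everywhere(self):
        rng = np.random.default_rng(12)
        xs = [rng.standard_normal((4, 300)) for _ in range(4)]
        shared = rng.standard_normal((1, 300))
        xs = [x + np.outer(np.ones(4), shared[0]) for x in xs]
        for scale in (1.0, 7.5):
            t = CovarianceTable([scale * x for x in xs])
            pc = pooled_covariances(t, shrinkage=0.0, subject_ids=[1, 2, 3])
            est = CorrelatedComponents(n_components=3, shrinkage=0.0).fit(pc)
            scores = subject_congruency_scores(t, 0, [1, 2, 3], est.filters_)
            if scale == 1.0:
                lam_ref, scores_ref = est.eigenvalues_, scores
        np.testing.assert_allclose(est.eigenvalues_, lam_ref, rtol=1e-9)
        np.testing.assert_allclose(scores, scores_ref, rtol=1e-9)


class TestForwardModel:
    def test_identity_covariance_returns_filter(self):
        w = np.array([0.6, 0.8])
        np.testing.assert_allclose(forward_model(np.eye(2), w), w)

    def test_homogeneity_in_filter_scale(self):
        rng = np.random.default_rng(13)
        rw = random_pencil(rng)[1]
        w = rng.standard_normal(4)
        a1 = forward_model(rw, w)
        a2 = forward_model(rw, 3.0 * w)
        np.testing.assert_allclose(a2, a1 / 3.0)

    def test_zero_filter_rejected(self):
        with pytest.raises(ValueError):
            forward_model(np.eye(3), np.zeros(3))


class TestCongruencyScores:
    def make_table(self, xs):
        return CovarianceTable(xs)

    def test_identical_subject_scores_exactly_one(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal((3, 60))
        t = self.make_table([x, x, x, x])
        w = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        scores = subject_congruency_scores(t, 0, [1, 2, 3], w)
        # between and within reductions agree to rounding error only
        np.testing.assert_allclose(scores, 1.0, rtol=0, atol=1e-12)

    def test_independent_subject_scores_near_zero(self):
        rng = np.random.default_rng(15)
        shared = rng.standard_normal((1, 12000))
        group = [
            np.vstack([shared[0] + 0.1 * rng.standard_normal(12000),
                       rng.standard_normal((2, 12000))])
            for _ in range(4)
        ]
        loner = rng.standard_normal((3, 12000))
        t = self.make_table(group + [loner])
        pc = pooled_covariances(t, shrinkage=0.0, subject_ids=[0, 1, 2, 3])
        est = CorrelatedComponents(n_components=3, shrinkage=0.0).fit(pc)
        scores = subject_congruency_scores(t, 4, [0, 1, 2, 3], est.filters_)
        assert np.abs(scores).max() < 0.1

    def test_sign_flipped_subject_scores_negative(self):
        rng = np.random.default_rng(16)
        shared = rng.standard_normal(5000)
        def member(flip):
            sig = -shared if flip else shared
            return np.vstack([sig + 0.05 * rng.standard_normal(5000),
                              rng.standard_normal((2, 5000))])
        group = [member(False) for _ in range(4)]
        t = self.make_table(group + [member(True)])
        pc = pooled_covariances(t, shrinkage=0.0, subject_ids=[0, 1, 2, 3])
        est = CorrelatedComponents(n_components=1, shrinkage=0.0).fit(pc)
        scores = subject_congruency_scores(t, 4, [0, 1, 2, 3], est.filters_)
        assert scores[0] < -0.5

    def test_reference_group_must_exclude_subject(self):
        t = self.make_table([np.eye(2), np.eye(2), np.eye(2)])
        with pytest.raises(ValueError, match="must not contain"):
            subject_congruency_scores(t, 0, [0, 1], np.eye(2))


class TestLeaveOneOutFeatures:
    def build(self, rng, n_cac=4, n_dys=2):
        shared = rng.standard_normal(800)
        xs, labels = [], []
        for i in range(n_cac + n_dys):
            gain = 1.0 if i < n_cac else 0.3
            xs.append(np.vstack([
                gain * shared + 0.3 * rng.standard_normal(800),
                rng.standard_normal((3, 800)),
            ]))
            labels.append("CAC" if i < n_cac else "DYS")
        return CovarianceTable(xs), labels

    def test_reference_member_excluded_from_own_basis(self):
        rng = np.random.default_rng(17)
        t, labels = self.build(rng)
        _, bases = congruency_features(
            t, labels, n_components=2, shrinkage=0.01, return_bases=True
        )
        # perturbing a CAC member must not change the basis that scores them:
        # the basis is a function of the *other* reference members only
        t2, _ = self.build(np.random.default_rng(17))
        t2.R[0] += 10.0  # corrupt all cross-covariances involving subject 0
        t2.R[:, 0] += 10.0
        _, bases2 = congruency_features(
            t2, labels, n_components=2, shrinkage=0.01, return_bases=True
        )
        np.testing.assert_array_equal(bases[0].filters_, bases2[0].filters_)

    def test_non_reference_member_gets_size_matched_reference(self):
        # every scored participant sees S-1 references: a non-member's
        # reference drops one member in deterministic rotation, so the first
        # DYS participant's basis equals the basis without the first CAC
        rng = np.random.default_rng(18)
        t, labels = self.build(rng)
        feats, bases = congruency_features(
            t, labels, n_components=2, shrinkage=0.01, return_bases=True
        )
        pc = pooled_covariances(t, shrinkage=0.01, subject_ids=[1, 2, 3])
        est = CorrelatedComponents(n_components=2, shrinkage=0.01).fit(pc)
        np.testing.assert_array_equal(bases[4].filters_, est.filters_)
        # and the second DYS drops the second CAC
        pc2 = pooled_covariances(t, shrinkage=0.01, subject_ids=[0, 2, 3])
        est2 = CorrelatedComponents(n_components=2, shrinkage=0.01).fit(pc2)
        np.testing.assert_array_equal(bases[5].filters_, est2.filters_)

    def test_too_small_reference_rejected(self):
        rng = np.random.default_rng(19)
        xs = [rng.standard_normal((3, 50)) for _ in range(3)]
        with pytest.raises(ValueError, match="too small"):
            congruency_features(CovarianceTable(xs), ["CAC", "CAC", "DYS"],
                                n_components=2)


class TestTemporalProfiles:
    def test_rank_one_epoch_recovers_time_course(self):
        w = np.array([0.6, -0.8, 0.0])
        g = np.sin(np.linspace(0, 3, 50))
        ep = np.outer(w, g)[:, :, None]  # single epoch w (x) g
        frp = FRPSet(epochs=ep, fs=256.0)
        prof = temporal_profiles(w[:, None], {"CAC": [frp]})
        np.testing.assert_allclose(prof["CAC"][0], g * (w @ w), atol=1e-12)

    def test_opposite_epochs_cancel(self):
        w = np.array([1.0, 0.0])
        g = np.cos(np.linspace(0, 2, 30))
        ep = np.stack([np.outer(w, g), np.outer(w, -g)], axis=2)
        frp = FRPSet(epochs=ep, fs=256.0)
        prof = temporal_profiles(w[:, None], {"g": [frp]})
        np.testing.assert_allclose(prof["g"][0], 0.0, atol=1e-12)

    def test_group_without_epochs_rejected(self):
        empty = FRPSet(epochs=np.zeros((2, 10, 0)), fs=256.0)
        with pytest.raises(ValueError, match="no epochs"):
            temporal_profiles(np.eye(2), {"CAC": [empty]})
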