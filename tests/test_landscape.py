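"""Featurization, PCA projection, free-energy surface and state assignment."""

import logging

import numpy as np
import pytest

from enzloop.landscape import (
    BOLTZMANN_KCAL,
    FeatureMatrix,
    LoopLandscapeModel,
    Projection,
    assign_states,
    estimate_fel,
    featurize_loop_contacts,
    pca_project,
)
from enzloop.structure import Selection, select_atoms
from enzloop.synthetic import LoopSimConfig, gen_loop_trajectory

from conftest import build_trajectory


def _toy_traj(n_frames=1, seed=0):
    rng = np.random.default_rng(seed)
    entries = [("CA", "GLY", "A", i + 1) for i in range(5)]
    return build_trajectory(entries, rng.uniform(-5, 5, (n_frames, 5, 3)))


def _proj_from_points(points):
    pts = np.asarray(points, dtype=float)
    return Projection(
        coordinates=pts,
        explained_variance_fraction=np.array([0.7, 0.3]),
        component_loadings=np.zeros((2, 4)),
    )


class TestFeaturize:
    def test_column_combinatorics(self):
        traj = _toy_traj()
        fm = featurize_loop_contacts(
            traj,
            Selection("a", (0, 1)),
            Selection("b", (2, 3, 4)),
        )
        assert fm.values.shape == (1, 6)
        assert len(fm.pair_labels) == 6

    def test_exact_distances_on_hand_built_frame(self):
        entries = [("CA", "GLY", "A", i + 1) for i in range(3)]
        traj = build_trajectory(entries, [[[0, 0, 0], [3, 4, 0], [0, 0, 2]]])
        fm = featurize_loop_contacts(
            traj, Selection("l", (0,)), Selection("r", (1, 2))
        )
        np.testing.assert_allclose(fm.values, [[5.0, 2.0]])

    def test_rotation_invariance(self):
        traj = _toy_traj(n_frames=4, seed=1)
        rng = np.random.default_rng(2)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        moved = traj.with_coordinates(traj.coordinates @ rot.T + 7.5)
        sel_l, sel_r = Selection("l", (0, 1)), Selection("r", (2, 3, 4))
        a = featurize_loop_contacts(traj, sel_l, sel_r)
        b = featurize_loop_contacts(moved, sel_l, sel_r)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9)

    def test_overlapping_selections_rejected(self):
        traj = _toy_traj()
        with pytest.raises(ValueError, match="disjoint"):
            featurize_loop_contacts(
                traj, Selection("l", (0, 1)), Selection("r", (1, 2))
            )


class TestPCA:
    def _features(self, X):
        return FeatureMatrix(
            values=np.asarray(X, float),
            pair_labels=tuple((0, j) for j in range(np.asarray(X).shape[1])),
            frame_provenance=tuple((0, i) for i in range(np.asarray(X).shape[0])),
        )

    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(0)
        n = 300
        labels = rng.random(n) < 0.5
        X = rng.normal(0, 1, (n, 8))
        # displace one cluster by 6 sd along a direction spanning 4 features
        # (correlated columns, as a concerted loop motion produces)
        X[labels, :4] += 6.0
        proj = pca_project(self._features(X))
        pc1 = proj.coordinates[:, 0]
        thr = pc1.mean()
        side = pc1 > thr
        acc = max(np.mean(side == labels), np.mean(side == ~labels))
        assert acc == 1.0

    def test_centered_projection_has_zero_mean(self):
        rng = np.random.default_rng(1)
        proj = pca_project(self._features(rng.normal(0, 1, (100, 5))))
        np.testing.assert_allclose(proj.coordinates.mean(axis=0), 0, atol=1e-10)

    def test_isotropic_cloud_no_dominant_component(self):
        rng = np.random.default_rng(2)
        proj = pca_project(self._features(rng.normal(0, 1, (4000, 10))))
        evf = proj.explained_variance_fraction
        assert evf[0] / evf[1] < 1.3
        assert abs(evf[0] - 0.1) < 0.03

    def test_matches_brute_force_eigendecomposition(self):
        """Cross-check against a direct covariance eigendecomposition."""
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (150, 6)) @ rng.normal(0, 1, (6, 6))
        proj = pca_project(self._features(X), center=True, scale=False)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (len(X) - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for c in range(2):
            vec = v[:, c]
            if vec[np.argmax(np.abs(vec))] < 0:
                vec = -vec
            np.testing.assert_allclose(
                proj.component_loadings[c], vec, atol=1e-8
            )
        np.testing.assert_allclose(
            proj.explained_variance_fraction, (w / w.sum())[:2], atol=1e-8
        )

    def test_zero_variance_columns_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (50, 4))
        X[:, 2] = 3.14
        with caplog.at_level(logging.WARNING, logger="enzloop.landscape"):
            proj = pca_project(self._features(X))
        assert "zero-variance" in caplog.text
        assert np.all(proj.component_loadings[:, 2] == 0)

    def test_components_orthogonal(self):
        rng = np.random.default_rng(5)
        proj = pca_project(self._features(rng.normal(0, 1, (80, 7))))
        dot = float(np.dot(proj.component_loadings[0], proj.component_loadings[1]))
        assert abs(dot) < 1e-8


class TestFreeEnergySurface:
    def test_equal_populations_both_zero(self):
        pts = np.concatenate([np.tile([[-3.0, -3.0]], (50, 1)),
                              np.tile([[3.0, 3.0]], (50, 1))])
        fel = estimate_fel(_proj_from_points(pts), n_bins=10)
        occ = fel.counts > 0
        assert occ.sum() == 2
        np.testing.assert_allclose(fel.grid[occ], 0.0)

    def test_80_20_split_closed_form(self):
        pts = np.concatenate([np.tile([[-3.0, -3.0]], (80, 1)),
                              np.tile([[3.0, 3.0]], (20, 1))])
        fel = estimate_fel(_proj_from_points(pts), n_bins=10, temperature=300.0)
        occ = fel.grid[fel.counts > 0]
        expected = -BOLTZMANN_KCAL * 300.0 * np.log(0.25)
        assert sorted(occ) == pytest.approx([0.0, expected])
        assert expected == pytest.approx(0.826, abs=5e-4)

    def test_single_occupied_bin(self):
        pts = np.tile([[1.0, 2.0]], (200, 1))
        fel = estimate_fel(_proj_from_points(pts), n_bins=10)
        assert (fel.counts > 0).sum() == 1
        assert len(fel.minima) == 1
        assert fel.minima[0].dG == 0.0
        assert np.isnan(fel.grid[fel.counts == 0]).all()

    def test_histogram_reconstructed_from_dG(self):
        """count ∝ exp(-dG/kT) reproduces the empirical histogram exactly."""
        rng = np.random.default_rng(6)
        pts = rng.normal(0, 1, (5000, 2))
        fel = estimate_fel(_proj_from_points(pts), n_bins=20)
        occ = fel.counts > 0
        recon = np.exp(-fel.grid[occ] / fel.kT) * fel.counts.max()
        np.testing.assert_allclose(recon, fel.counts[occ], rtol=1e-9)

    def test_min_bins_precondition(self):
        with pytest.raises(ValueError):
            estimate_fel(_proj_from_points(np.zeros((200, 2))), n_bins=5)


class TestAssignStates:
    def test_single_state_full_population(self):
        traj, _ = gen_loop_trajectory(LoopSimConfig(n_frames=500, p_open=1.0, seed=2))
        res = LoopLandscapeModel(traj).fit(seed=0)
        assert len(res.surface.minima) == 1
        assert res.populations == {"S0": 1.0}

    def test_populations_sum_to_one(self):
        traj, _ = gen_loop_trajectory(LoopSimConfig(n_frames=2000, p_open=0.5, seed=4))
        res = LoopLandscapeModel(traj).fit(seed=0)
        assert sum(res.populations.values()) == pytest.approx(1.0, abs=1e-12)

    def test_labels_invariant_to_frame_order(self):
        rng = np.random.default_rng(7)
        pts = np.concatenate([rng.normal(-4, 0.5, (200, 2)),
                              rng.normal(4, 0.5, (200, 2))])
        proj = _proj_from_points(pts)
        fel = estimate_fel(proj, n_bins=20)
        a = assign_states(proj, fel, seed=0)
        perm = rng.permutation(len(pts))
        b = assign_states(_proj_from_points(pts[perm]), fel, seed=0)
        np.testing.assert_array_equal(a.labels[perm], b.labels)

    def test_two_means_matches_generator(self):
        traj, labels = gen_loop_trajectory(
            LoopSimConfig(n_frames=3000, p_open=0.3, seed=5)
        )
        res = LoopLandscapeModel(traj).fit(method="two_means", seed=0)
        # S0 is the larger (closed) cluster here
        assert res.populations["S1"] == pytest.approx(
            np.mean(labels == "open"), abs=0.02
        )

    def test_bootstrap_reproducible(self):
        traj, _ = gen_loop_trajectory(LoopSimConfig(n_frames=1000, p_open=0.5, seed=6))
        r1 = LoopLandscapeModel(traj).fit(seed=42)
        r2 = LoopLandscapeModel(traj).fit(seed=42)
        assert r1.states.bootstrap_se == r2.states.bootstrap_se


class TestPopulationRecovery:
    def test_mean_absolute_error_over_seeds(self):
        """Two-state recovery: MAE of p_open <= 0.02 over seeds 1..10 at
        50,000 frames and separation/sd = 6."""
        errors = []
        for seed in range(1, 11):
            traj, labels = gen_loop_trajectory(
                LoopSimConfig(n_frames=50_000, p_open=0.7, basin_sd=1.0,
                              displacement=6.0, seed=seed)
            )
            res = LoopLandscapeModel(traj).fit(n_bootstrap=50, seed=seed)
            assert len(res.surface.minima) == 2
            # the open basin is the one the open-labelled frames fall into
            open_label = res.states.labels[labels == "open"][0]
            errors.append(abs(res.populations[open_label] - 0.7))
        assert np.mean(errors) <= 0.02
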