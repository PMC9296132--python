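"""Tests of the synthetic scene / embedding / AR-series generators."""

import numpy as np
import pytest

from selfee.synthetic import (
    EthogramScript,
    StateMotion,
    default_two_agent_script,
    generate_arhmm_series,
    generate_embedding_clusters,
    generate_scene_video,
    write_scene,
)
from selfee.timeseries import ARHMMParams


def _stationary_distribution(tm: np.ndarray) -> np.ndarray:
    # left eigenvector of the transition matrix for eigenvalue 1
    w, v = np.linalg.eig(tm.T)
    vec = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    return vec / vec.sum()


class TestSceneVideo:
    def test_absorbing_chain_stays_in_start_state(self):
        script = default_two_agent_script(duration=50, seed=0, arena_size=48)
        script.transition_matrix = np.eye(3)
        scene = generate_scene_video(script, arena=(48, 48), semi_axes=(4, 1.8),
                                     start_state=0)
        assert np.all(scene.labels == 0)

    def test_same_seed_bit_identical(self):
        for _ in range(2):
            script = default_two_agent_script(duration=40, seed=7, arena_size=48)
            scenes = [generate_scene_video(script, arena=(48, 48), semi_axes=(4, 1.8))
                      for _ in range(2)]
        assert np.array_equal(scenes[0].frames, scenes[1].frames)
        assert np.array_equal(scenes[0].labels, scenes[1].labels)
        assert np.array_equal(scenes[0].agent_tracks, scenes[1].agent_tracks)

    def test_state_frequencies_match_stationary_distribution(self):
        script = default_two_agent_script(duration=10_000, seed=3, arena_size=48)
        scene = generate_scene_video(script, arena=(48, 48), semi_axes=(4, 1.8))
        freq = np.bincount(scene.labels, minlength=3) / len(scene.labels)
        target = _stationary_distribution(script.transition_matrix)
        assert np.all(np.abs(freq - target) < 0.03)

    def test_transition_counts_chi2_consistent(self):
        from scipy.stats import chi2

        script = default_two_agent_script(duration=10_000, seed=5, arena_size=48)
        scene = generate_scene_video(script, arena=(48, 48), semi_axes=(4, 1.8))
        lab = scene.labels
        k = 3
        stat = 0.0
        dof = 0
        for s in range(k):
            idx = np.flatnonzero(lab[:-1] == s)
            obs = np.bincount(lab[idx + 1], minlength=k)
            exp = script.transition_matrix[s] * len(idx)
            keep = exp > 5
            stat += float(np.sum((obs[keep] - exp[keep]) ** 2 / exp[keep]))
            dof += int(keep.sum()) - 1
        assert stat < chi2.ppf(0.99, dof)

    def test_contact_states_overlap_blobs(self, small_scene):
        contact_idx = small_scene.state_names.index("contact")
        mask = small_scene.labels == contact_idx
        # skip the first frames after entering contact while agents converge
        settled = mask & np.concatenate([[False], mask[:-1]]) \
            & np.concatenate([[False, False], mask[:-2]])
        if not settled.any():
            pytest.skip("no settled contact frames in this short scene")
        d = np.linalg.norm(small_scene.agent_tracks[settled, 0]
                           - small_scene.agent_tracks[settled, 1], axis=1)
        assert np.median(d) < 10.0

    def test_labels_tracks_frames_aligned(self, small_scene):
        assert len(small_scene.frames) == len(small_scene.labels)
        assert len(small_scene.frames) == len(small_scene.agent_tracks)
        assert small_scene.frames.dtype == np.uint8

    def test_rejects_oversized_agent(self):
        script = default_two_agent_script(duration=10, seed=0, arena_size=20)
        with pytest.raises(ValueError, match="fit"):
            generate_scene_video(script, arena=(20, 20), semi_axes=(15, 6))

    def test_rejects_non_stochastic_matrix(self):
        with pytest.raises(ValueError, match="sum to 1"):
            EthogramScript(states=["a", "b"],
                           transition_matrix=np.array([[0.5, 0.4], [0.3, 0.7]]),
                           motion={"a": StateMotion(), "b": StateMotion()},
                           duration=10)

    def test_write_scene_layout(self, small_scene, tmp_path):
        out = write_scene(small_scene, tmp_path / "scene")
        assert (out / "000000.png").exists()
        assert (out / f"{len(small_scene.frames) - 1:06d}.png").exists()
        labels = (out / "labels.csv").read_text().strip().splitlines()
        assert labels[0] == "frame,label"
        assert len(labels) == len(small_scene.frames) + 1
        tracks = (out / "tracks.csv").read_text().strip().splitlines()
        assert tracks[0] == "frame,agent,x,y"


class TestEmbeddingClusters:
    def test_infinite_separation_collapses_to_centroids(self):
        x, y = generate_embedding_clusters(3, 5, 8, np.inf, seed=0)
        for c in range(3):
            rows = x[y == c]
            assert np.allclose(rows, rows[0])

    def test_single_class_single_label(self):
        _, y = generate_embedding_clusters(1, 10, 4, 5.0, seed=0)
        assert len(np.unique(y)) == 1

    def test_high_separation_perfect_1nn(self):
        x, y = generate_embedding_clusters(4, 20, 16, separation=20.0, seed=2)
        # brute-force leave-one-out nearest neighbor
        sims = x @ x.T
        np.fill_diagonal(sims, -np.inf)
        nearest = sims.argmax(axis=1)
        assert np.all(y[nearest] == y)

    def test_rows_unit_norm(self):
        x, _ = generate_embedding_clusters(2, 10, 6, 3.0, seed=1)
        assert np.allclose(np.linalg.norm(x, axis=1), 1.0)

    def test_rejects_dim_below_classes(self):
        with pytest.raises(ValueError, match="dim"):
            generate_embedding_clusters(5, 3, 3, 1.0)


def _two_state_params(p_stay=0.95, noise=0.01):
    A = np.stack([0.6 * np.eye(2), -0.6 * np.eye(2)])
    b = np.array([[1.0, 0.0], [0.0, 1.0]])
    sigma = np.stack([noise * np.eye(2)] * 2)
    tm = np.array([[p_stay, 1 - p_stay], [1 - p_stay, p_stay]])
    return ARHMMParams(A=A, b=b, sigma=sigma, transition=tm,
                       initial=np.array([0.5, 0.5]), lag=1)


class TestARSeries:
    def test_zero_noise_single_state_constant(self):
        params = ARHMMParams(A=np.zeros((1, 2, 2)), b=np.array([[2.0, -1.0]]),
                             sigma=np.stack([1e-12 * np.eye(2)]),
                             transition=np.array([[1.0]]), lag=1)
        x, s = generate_arhmm_series(params, 50, seed=0)
        assert np.allclose(x[5:], [2.0, -1.0], atol=1e-4)
        assert np.all(s == 0)

    def test_seed_determinism(self):
        params = _two_state_params()
        x1, s1 = generate_arhmm_series(params, 200, seed=9)
        x2, s2 = generate_arhmm_series(params, 200, seed=9)
        assert np.array_equal(x1, x2)
        assert np.array_equal(s1, s2)

    def test_dwell_time_matches_geometric(self):
        # self-transition 0.95 -> geometric dwell, mean 1/(1-p) = 20 frames
        params = _two_state_params(p_stay=0.95)
        _, states = generate_arhmm_series(params, 60_000, seed=4)
        change = np.flatnonzero(np.diff(states) != 0)
        dwells = np.diff(change)
        assert abs(dwells.mean() - 20.0) / 20.0 < 0.15

    def test_unstable_matrix_warns(self):
        A = np.stack([1.2 * np.eye(2)])
        params = ARHMMParams(A=A, b=np.zeros((1, 2)), sigma=np.stack([np.eye(2)]),
                             transition=np.array([[1.0]]), lag=1)
        with pytest.warns(UserWarning, match="unstable"):
            generate_arhmm_series(params, 10, seed=0)
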