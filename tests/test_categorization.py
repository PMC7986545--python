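"""Clustering of EI profiles, centroid naming, and bootstrap stability."""

import numpy as np
import pytest

import noisecat as nc
from noisecat.categorize import UNDEFINED, clustering_mse


def blob_profiles(centers, n, sd, seed=0):
    rng = np.random.default_rng(seed)
    X, labels = [], []
    for i, c in enumerate(centers):
        X.append(rng.normal(c, sd, size=(n, len(c))))
        labels += [i] * n
    return np.vstack(X), np.array(labels)


class TestKMeans:
    def test_k_equals_n_gives_zero_mse(self):
        X = np.array([[0.1, 0.2, 0.3], [0.5, 0.4, 0.3], [-0.2, -0.1, 0.0]])
        res = nc.kmeans_profiles(X, k=3, n_restarts=10, seed=0, label=False)
        assert res.mse == pytest.approx(0.0, abs=1e-12)

    def test_identical_profiles_single_cluster(self):
        X = np.tile([0.3, 0.2, 0.1], (8, 1))
        res = nc.kmeans_profiles(X, k=1, n_restarts=1, seed=0, label=False)
        assert res.mse == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.centroids[0], [0.3, 0.2, 0.1])

    def test_separated_blobs_recovered_exactly(self):
        X, planted = blob_profiles([[0.5, 0.5, 0.5], [-0.5, -0.5, -0.5]],
                                   n=30, sd=0.05, seed=1)
        res = nc.kmeans_profiles(X, k=2, n_restarts=10, seed=0, label=False)
        got = np.array([res.assignments[str(i)] for i in range(len(X))])
        # same partition up to relabeling
        assert (np.all(got[:30] == got[0]) and np.all(got[30:] == got[30])
                and got[0] != got[30])

    def test_fewer_profiles_than_k_rejected(self):
        with pytest.raises(ValueError):
            nc.kmeans_profiles(np.zeros((3, 3)), k=5)

    def test_undefined_profiles_rejected(self):
        X = np.array([[0.1, np.nan, 0.2]] * 6)
        with pytest.raises(ValueError):
            nc.kmeans_profiles(X, k=2)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_mse_matches_brute_force_formula(self, k):
        """Reported MSE must equal (1/N) sum ||centroid - profile||^2."""
        X, _ = blob_profiles([[0.6, 0.5, 0.3], [0.0, 0.0, 0.0],
                              [-0.4, -0.4, -0.3], [0.7, 0.2, -0.5],
                              [0.3, 0.3, 0.2]], n=12, sd=0.1, seed=k)
        res = nc.kmeans_profiles(X, k=k, n_restarts=10, seed=0, label=False)
        assignment = np.array([res.assignments[str(i)] for i in range(len(X))])
        assert res.mse == pytest.approx(
            clustering_mse(X, res.centroids, assignment), abs=1e-12)


class TestElbow:
    def test_planted_five_blobs_show_elbow_at_five(self):
        centers = [[0.8, 0.7, 0.6], [0.5, 0.4, 0.2], [0.6, 0.0, -0.6],
                   [0.0, 0.0, 0.0], [-0.4, -0.5, -0.5]]
        X, _ = blob_profiles(centers, n=40, sd=0.05, seed=2)
        mse = nc.elbow_curve(X, range(1, 8), n_restarts=10, seed=0)
        # drop ratio collapses once k reaches the planted cluster count
        assert mse[5] / mse[4] < mse[4] / mse[3]
        assert mse[6] / mse[5] > mse[5] / mse[4]

    def test_single_blob_shows_no_elbow(self):
        X, _ = blob_profiles([[0.2, 0.1, 0.0]], n=150, sd=0.1, seed=3)
        mse = nc.elbow_curve(X, range(1, 7), n_restarts=10, seed=0)
        ratios = [mse[k + 1] / mse[k] for k in range(2, 6)]
        assert max(ratios) - min(ratios) < 0.25

    def test_k1_mse_is_total_variance(self):
        X, _ = blob_profiles([[0.3, 0.2, 0.1], [-0.1, 0.0, 0.1]], 20, 0.2, 4)
        mse = nc.elbow_curve(X, [1], n_restarts=1, seed=0)
        assert mse[1] == pytest.approx(np.sum(np.var(X, axis=0)))


class TestLabelClusters:
    SPEC_CENTROIDS = np.array([
        [0.8, 0.7, 0.3],       # signal-like
        [0.4, 0.3, 0.1],       # signal-dominated
        [0.6, 0.1, -0.4],      # balanced
        [0.05, 0.0, -0.05],    # insensitive
        [-0.3, -0.3, -0.2],    # masker-like
    ])
    EXPECTED = ["signal-like", "signal-dominated", "balanced",
                "insensitive", "masker-like"]

    def test_reference_centroid_shapes_named_correctly(self):
        labels = nc.label_clusters(self.SPEC_CENTROIDS)
        assert [labels[i] for i in range(5)] == self.EXPECTED

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            perm = rng.permutation(5)
            labels = nc.label_clusters(self.SPEC_CENTROIDS[perm])
            assert [labels[i] for i in range(5)] == [self.EXPECTED[j]
                                                    for j in perm]

    def test_duplicate_centroids_tie_break_deterministic(self):
        dup = self.SPEC_CENTROIDS.copy()
        dup[1] = dup[0]
        l1 = nc.label_clusters(dup)
        l2 = nc.label_clusters(dup)
        assert l1 == l2 and sorted(l1.values()) == sorted(self.EXPECTED)

    def test_wrong_k_rejected(self):
        with pytest.raises(ValueError):
            nc.label_clusters(self.SPEC_CENTROIDS[:4])


CENTROIDS = np.array([[0.7, 0.65, 0.55], [0.45, 0.35, 0.15],
                      [0.6, 0.1, -0.5], [0.05, 0.0, 0.0],
                      [-0.3, -0.4, -0.5]])
LABEL_MAP = {0: "signal-like", 1: "signal-dominated", 2: "balanced",
             3: "insensitive", 4: "masker-like"}


@pytest.fixture(scope="module")
def centroids():
    return CENTROIDS, LABEL_MAP


class TestBootstrap:

    @staticmethod
    def _zero_variability_recording(protocol):
        """Every condition repeats one deterministic spike train."""
        rng = np.random.default_rng(17)
        blocks = {}
        for cid in protocol.condition_ids(include_tones=False):
            info = protocol.parse_condition(cid)
            if info["kind"] in ("clean", "noisy"):
                dur = protocol.voc_duration(info["voc_id"])
            else:
                dur = protocol.masker_analysis_period_s
            onset = protocol.spontaneous_window_s
            window = (0.0, onset + dur + 0.05)
            times = np.sort(rng.uniform(onset, onset + dur, 12))
            trains = [nc.SpikeTrain(times.copy(), window)
                      for _ in range(protocol.n_trials_voc)]
            blocks[cid] = nc.TrialBlock(cid, trains, onset, onset + dur)
        return nc.Recording("stable", "CNIC", blocks)

    def test_zero_variability_recording_is_perfectly_stable(self, protocol,
                                                            centroids):
        rec = self._zero_variability_recording(protocol)
        cents, label_map = centroids
        res = nc.bootstrap_stability(rec, "stationary", protocol, cents,
                                     label_map, n_boot=100, seed=0)
        assert res.bootstrap_mode_count == 100
        assert res.reliable

    def test_noisy_borderline_recording_not_reliable(self, protocol):
        """A profile equidistant from two close centroids, with trial noise,
        hops between them across bootstrap resamples."""
        from conftest import flat_recording
        rec = flat_recording(protocol, rate_hz=6.0, seed=3)
        # two centroids straddling the recording's near-zero EI profile
        cents = np.array([[0.12, 0.12, 0.12], [-0.12, -0.12, -0.12],
                          [0.7, 0.6, 0.5], [0.6, 0.0, -0.6],
                          [-0.5, -0.6, -0.7]])
        label_map = {0: "insensitive", 1: "masker-like", 2: "signal-like",
                     3: "balanced", 4: "signal-dominated"}
        res = nc.bootstrap_stability(rec, "stationary", protocol, cents,
                                     label_map, n_boot=100, seed=1)
        assert res.bootstrap_mode_count < 95
        assert not res.reliable

    def test_same_seed_reproduces_counts(self, protocol, centroids, voc_dataset):
        rec = voc_dataset.recordings[0]
        cents, label_map = centroids
        r1 = nc.bootstrap_stability(rec, "chorus", protocol, cents, label_map,
                                    50, seed=5)
        r2 = nc.bootstrap_stability(rec, "chorus", protocol, cents, label_map,
                                    50, seed=5)
        assert r1.bootstrap_mode_count == r2.bootstrap_mode_count
        assert r1.category == r2.category

    def test_silent_recording_counted_as_undefined(self, protocol, centroids):
        from noisecat import synth
        arch = nc.CategoryArchetype("insensitive", (0.5,) * 3, (0.5,) * 3,
                                    baseline_rate_hz=0.0, response_gain_hz=0.0)
        rec = synth.make_recording("r", "CN",
                                   {nt: arch for nt in protocol.noise_types},
                                   protocol, np.random.default_rng(2), False)
        cents, label_map = centroids
        res = nc.bootstrap_stability(rec, "stationary", protocol, cents,
                                     label_map, 20, seed=0)
        assert res.category == UNDEFINED
        assert not res.reliable
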