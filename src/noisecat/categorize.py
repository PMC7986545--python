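"""K-means categorization of EI profiles and bootstrap assignment stability.

Clustering is run separately per masker type on 3-value EI profiles (one
value per SNR, best SNR first).  Five clusters are canonical; a deterministic
rule maps the five centroids to the named categories (signal-like,
signal-dominated, balanced, insensitive, masker-like).  Assignment stability
is probed by resampling the 20 trials of every condition with replacement,
recomputing the EI profile, and reallocating it to the nearest original
centroid, 100 times per recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .dataset import CATEGORIES, Recording
from .extraction import _ei_matrix, _nanmean_cols, EIProfile
from .protocol import StimulusProtocol

__all__ = [
    "ClusteringResult", "CategoryAssignment",
    "kmeans_profiles", "elbow_curve", "label_clusters",
    "assign_to_centroids", "bootstrap_stability", "clustering_mse",
]

#: Bootstrap replicates whose EI profile is undefined fall in this bucket.
UNDEFINED = "undefined"


@dataclass
class ClusteringResult:
    k: int
    centroids: np.ndarray                    # k x 3
    assignments: dict[str, int]              # recording_id -> cluster index
    mse: float
    label_map: dict[int, str] = field(default_factory=dict)

    def category_of(self, recording_id: str) -> str:
        return self.label_map[self.assignments[recording_id]]


@dataclass
class CategoryAssignment:
    recording_id: str
    noise_type: str
    category: str
    centroid_distance: float
    bootstrap_mode_count: int = 0
    reliable: bool = False


def clustering_mse(profiles: np.ndarray, centroids: np.ndarray,
                   assignment: np.ndarray) -> float:
    """Mean squared error of a clustering: (1/N) sum ||centroid_i - EIP_i||^2."""
    diffs = profiles - centroids[assignment]
    return float(np.mean(np.sum(diffs ** 2, axis=1)))


def kmeans_profiles(profiles: np.ndarray | dict[str, np.ndarray], k: int,
                    n_restarts: int = 50, seed: int = 0,
                    label: bool = True) -> ClusteringResult:
    """Euclidean K-means on EI profiles, best of ``n_restarts`` by MSE.

    ``profiles`` is either an (N x 3) array or a mapping recording_id ->
    3-vector; all values must be defined (finite).
    """
    if isinstance(profiles, dict):
        ids = list(profiles)
        X = np.stack([np.asarray(profiles[i], dtype=float) for i in ids])
    else:
        X = np.asarray(profiles, dtype=float)
        ids = [str(i) for i in range(len(X))]
    if not np.all(np.isfinite(X)):
        raise ValueError("all EI values must be defined for clustering")
    if len(X) < k:
        raise ValueError(f"{len(X)} profiles < k={k}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    mse = clustering_mse(X, km.cluster_centers_, labels)
    label_map = (label_clusters(km.cluster_centers_) if (label and k == 5)
                 else {i: f"cluster_{i + 1}" for i in range(k)})
    return ClusteringResult(k, km.cluster_centers_,
                            dict(zip(ids, (int(l) for l in labels))),
                            mse, label_map)


def elbow_curve(profiles: np.ndarray | dict[str, np.ndarray],
                k_range=range(1, 11), n_restarts: int = 50,
                seed: int = 0) -> dict[int, float]:
    """MSE of clustering as a function of k (the elbow diagnostic)."""
    out: dict[int, float] = {}
    prev = np.inf
    for k in k_range:
        res = kmeans_profiles(profiles, k, n_restarts, seed, label=False)
        if res.mse > prev + 1e-12:
            warnings.warn(f"MSE increased at k={k}; consider more restarts")
        out[k] = res.mse
        prev = res.mse
    return out


def label_clusters(centroids: np.ndarray) -> dict[int, str]:
    """Deterministically name five centroids after the response categories.

    On centroid features m = mean(EI) and r = EI(best SNR) - EI(worst SNR):
    masker-like is the lowest-m centroid that is negative at every SNR (or
    the lowest m overall if none is); balanced the largest-r remainder with r
    above the remaining median; signal-like the highest m, insensitive the
    smallest |m|, and signal-dominated the rest.  Ties break by m descending
    then by cluster index.
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape[0] != 5:
        raise ValueError("named labels require exactly 5 centroids")
    m = centroids.mean(axis=1)
    r = centroids[:, 0] - centroids[:, -1]

    def pick(indices, key_desc):
        """Index maximizing key_desc; ties by m descending then index."""
        return max(indices, key=lambda i: (key_desc[i], m[i], -i))

    labels: dict[int, str] = {}
    remaining = set(range(5))

    all_neg = [i for i in remaining if np.all(centroids[i] < 0)]
    pool = all_neg if all_neg else list(remaining)
    masker = pick(pool, -m)
    labels[masker] = "masker-like"
    remaining.remove(masker)

    med_r = float(np.median([r[i] for i in remaining]))
    above = [i for i in remaining if r[i] > med_r]
    balanced = pick(above if above else list(remaining), r)
    labels[balanced] = "balanced"
    remaining.remove(balanced)

    sig = pick(list(remaining), m)
    labels[sig] = "signal-like"
    remaining.remove(sig)

    ins = pick(list(remaining), -np.abs(m))
    labels[ins] = "insensitive"
    remaining.remove(ins)

    labels[remaining.pop()] = "signal-dominated"
    return labels


def assign_to_centroids(profile: np.ndarray,
                        centroids: np.ndarray) -> tuple[int, float]:
    """Nearest original centroid (Euclidean) and the distance to it."""
    d = np.linalg.norm(centroids - np.asarray(profile, dtype=float), axis=1)
    i = int(np.argmin(d))
    return i, float(d[i])


def _condition_count_matrix(recording: Recording, cid: str, bin_s: float,
                            duration: float) -> np.ndarray:
    """(n_trials x n_bins) spike-count matrix over the evoked window."""
    block = recording.blocks[cid]
    start = block.onset_s
    n_bins = int(np.floor(duration / bin_s + 1e-9))
    edges = start + np.arange(n_bins + 1) * bin_s
    return np.stack([np.histogram(tr.spike_times, bins=edges)[0]
                     for tr in block.trains]).astype(float)


def bootstrap_stability(recording: Recording, noise_type: str,
                        protocol: StimulusProtocol,
                        original_centroids: np.ndarray,
                        label_map: dict[int, str],
                        n_boot: int = 100, seed: int = 0,
                        bin_s: float | None = None) -> CategoryAssignment:
    """Bootstrap category-assignment stability for one recording and masker.

    Per replicate, each condition's trials are independently resampled with
    replacement (same trial count), the PSTHs and the 3-value EI profile are
    recomputed, and the profile is reallocated to the nearest original
    centroid.  Replicates with any undefined EI value count against
    stability.  The assignment is reliable when the modal category occurs in
    at least 95 of 100 replicates.
    """
    bin_s = bin_s or protocol.psth_bin_s
    rng = np.random.default_rng(seed)
    snrs = protocol.snr_levels_db
    vocs = protocol.vocalization_ids
    n_trials = protocol.n_trials_voc

    def boot_psths(cid: str, duration: float) -> np.ndarray:
        """(n_boot x n_bins) bootstrap PSTH matrix for one condition."""
        C = _condition_count_matrix(recording, cid, bin_s, duration)
        W = rng.multinomial(n_trials, np.full(n_trials, 1.0 / n_trials),
                            size=n_boot)
        return (W @ C) / (n_trials * bin_s)

    clean = {v: boot_psths(protocol.clean_condition(v), protocol.voc_duration(v))
             for v in vocs}
    noise = {v: boot_psths(protocol.noise_condition(noise_type),
                           protocol.voc_duration(v))
             for v in vocs}
    profiles = np.full((n_boot, len(snrs)), np.nan)
    for si, snr in enumerate(snrs):
        per_voc = np.full((len(vocs), n_boot), np.nan)
        for vi, v in enumerate(vocs):
            p_snr = boot_psths(protocol.noisy_condition(v, noise_type, snr),
                               protocol.voc_duration(v))
            per_voc[vi] = _ei_matrix(p_snr, clean[v], noise[v])
        profiles[:, si] = _nanmean_cols(per_voc)

    counts: dict[str, int] = {}
    distances = []
    for b in range(n_boot):
        if np.any(np.isnan(profiles[b])):
            counts[UNDEFINED] = counts.get(UNDEFINED, 0) + 1
            continue
        ci, dist = assign_to_centroids(profiles[b], original_centroids)
        cat = label_map[ci]
        counts[cat] = counts.get(cat, 0) + 1
        distances.append(dist)
    mode_cat = max(counts, key=lambda c: (counts[c], c != UNDEFINED))
    mode_count = counts[mode_cat]
    return CategoryAssignment(
        recording_id=recording.recording_id,
        noise_type=noise_type,
        category=mode_cat,
        centroid_distance=float(np.mean(distances)) if distances else float("nan"),
        bootstrap_mode_count=mode_count,
        reliable=(mode_cat != UNDEFINED and mode_count >= 95 * n_boot // 100),
    )
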