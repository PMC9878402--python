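"""Clustering of TSPs into sub-clusters, transition-based pairing, occurrence
timecourses, and nearest-neighbour transfer of the cluster model to new runs.

Sub-clusters come from k-means with correlation distance (1 - Pearson r).
Because TSPs are unit vectors up to sign and an event of one sub-cluster is
frequently followed by an event of its anti-correlated partner, sub-clusters
are paired into clusters by maximum-weight matching on the symmetrized
transition-count matrix, gated on negative centroid correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


def center_unit(X: np.ndarray) -> np.ndarray:
    """Row-wise center and normalize, so dot products are Pearson correlations."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    X = X - X.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(X, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return X / nrm


@dataclass
class ClusterModel:
    """k sub-cluster centroids with event labels and pairing into clusters."""

    k: int
    centroids: np.ndarray        # (k, n_rois), centered unit vectors
    labels: np.ndarray           # per training event, in 0..k-1
    inertia: float               # sum over events of (1 - r to own centroid)
    tsps: np.ndarray             # training TSPs, centered-unit rows
    seed: int = 0
    pairing: dict = None         # sub-cluster -> cluster id

    @property
    def n_clusters(self) -> int:
        return self.k // 2 if self.pairing else self.k


def fit_kmeans_corr(tsps: np.ndarray, k: int = 12, n_init: int = 100,
                    seed: int = 0, max_iter: int = 100) -> ClusterModel:
    """Spherical k-means on TSPs with correlation distance.

    Each restart samples k events uniformly without replacement as initial
    centroids; centroids are updated as the renormalized mean of member
    vectors; an emptied cluster is re-seeded from the point farthest from its
    centroid. Over ``n_init`` restarts the solution minimizing the summed
    distance of TSPs to their assigned centroids is kept. Deterministic for a
    given ``seed``.
    """
    V = center_unit(tsps)
    n = V.shape[0]
    if k < 1:
        raise ValueError("k must be at least 1")
    if n < k:
        raise ValueError(f"need at least k={k} events, got {n}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        C = V[rng.choice(n, size=k, replace=False)].copy()
        labels = np.full(n, -1)
        for _ in range(max_iter):
            sims = V @ C.T
            new_labels = np.argmax(sims, axis=1)
            # re-seed empty clusters from the worst-fit point
            for c in range(k):
                if not np.any(new_labels == c):
                    far = int(np.argmin(sims[np.arange(n), new_labels]))
                    new_labels[far] = c
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                members = V[labels == c]
                m = members.mean(axis=0)
                m -= m.mean()
                nrm = np.linalg.norm(m)
                C[c] = m / nrm if nrm > 0 else members[0]
        inertia = float(np.sum(1.0 - (V @ C.T)[np.arange(n), labels]))
        if best is None or inertia < best[0]:
            best = (inertia, C.copy(), labels.copy())
    inertia, C, labels = best
    return ClusterModel(k=k, centroids=C, labels=labels, inertia=inertia,
                        tsps=V, seed=seed)


def transition_matrix(sequences, k: int) -> np.ndarray:
    """k x k counts of consecutive sub-cluster transitions.

    ``sequences`` is one time-ordered label sequence or a list of them (one
    per run); transitions are never counted across run boundaries.
    """
    if len(sequences) and np.isscalar(sequences[0]):
        sequences = [sequences]
    total = sum(len(s) for s in sequences)
    if total < 2:
        raise ValueError("need at least 2 events to count transitions")
    T = np.zeros((k, k), dtype=int)
    for seq in sequences:
        seq = np.asarray(seq, dtype=int)
        for a, b in zip(seq[:-1], seq[1:]):
            T[a, b] += 1
    return T


def pair_subclusters(model: ClusterModel, transitions: np.ndarray) -> dict:
    """Pair sub-clusters into clusters by mutual transitions.

    Greedy maximum-weight matching on the symmetrized transition counts,
    accepting a pair only if the centroid correlation is negative. Leftover
    sub-clusters are paired with their most anti-correlated unmatched partner
    under a warning. Sets and returns ``model.pairing``
    (sub-cluster -> cluster id).
    """
    k = model.k
    if k % 2 != 0:
        raise ValueError("pairing requires an even number of sub-clusters")
    W = np.asarray(transitions, dtype=float)
    W = W + W.T
    corr = model.centroids @ model.centroids.T
    unpaired = set(range(k))
    pairs = []
    order = np.dstack(np.unravel_index(np.argsort(W, axis=None)[::-1], W.shape))[0]
    for a, b in order:
        a, b = int(a), int(b)
        if a == b or a not in unpaired or b not in unpaired:
            continue
        if corr[a, b] >= 0:
            continue
        pairs.append((a, b))
        unpaired -= {a, b}
    if unpaired:
        warnings.warn(
            f"{len(unpaired)} sub-cluster(s) unmatched by transitions; "
            "falling back to most anti-correlated partners", stacklevel=2)
        while unpaired:
            a = min(unpaired)
            unpaired.discard(a)
            b = min(unpaired, key=lambda j: corr[a, j])
            unpaired.discard(b)
            pairs.append((a, b))
    pairing = {}
    for cid, (a, b) in enumerate(pairs):
        pairing[a] = cid
        pairing[b] = cid
    model.pairing = pairing
    return pairing


@dataclass
class OccurrenceTimecourse:
    """Per-frame cluster occurrence probabilities, boxcar-smoothed."""

    probs: np.ndarray          # (n_clusters, n_frames), smoothed
    raw: np.ndarray            # (n_clusters, n_frames), pre-smoothing
    any_ts: np.ndarray         # (n_frames,), smoothed any-event indicator
    smooth_w: int
    n_frames: int


def occurrence_timecourse(events, n_frames: int, pairing: dict,
                          smooth_w: int = 50) -> OccurrenceTimecourse:
    """Cluster occurrence probability timecourse from labeled events.

    Per cluster, the two sub-cluster occurrence indicators are averaged; at
    frames where any TS occurred the probabilities are normalized to sum to 1
    over clusters (conditional on a TS happening); the result is smoothed by
    a moving average of ``smooth_w`` frames, as is the any-TS indicator.
    """
    if smooth_w < 1:
        raise ValueError("smooth_w must be at least 1")
    n_clusters = len(set(pairing.values()))
    sub_ind = np.zeros((max(pairing) + 1, n_frames))
    for ev in events:
        frame = ev.center_frame if hasattr(ev, "center_frame") else ev[0]
        label = ev.sub_cluster if hasattr(ev, "center_frame") else ev[1]
        if label is None:
            raise ValueError("events must be labeled before computing occurrences")
        sub_ind[int(label), int(frame)] += 1.0
    raw = np.zeros((n_clusters, n_frames))
    for sub, cid in pairing.items():
        raw[cid] += sub_ind[sub] / 2.0
    any_raw = (sub_ind.sum(axis=0) > 0).astype(float)
    col = raw.sum(axis=0)
    nz = col > 0
    raw[:, nz] /= col[nz]
    if not any_raw.any():
        warnings.warn("no events: occurrence timecourse is all zero", stacklevel=2)
    kernel = np.ones(smooth_w) / smooth_w
    probs = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"),
                                1, raw)
    any_s = np.convolve(any_raw, kernel, mode="same")
    return OccurrenceTimecourse(probs=probs, raw=raw, any_ts=any_s,
                                smooth_w=smooth_w, n_frames=n_frames)


def knn_classify(query_tsps: np.ndarray, model: ClusterModel,
                 knn_k: int = 100, n_random: int = 10000, seed: int = 0):
    """k-nearest-neighbour transfer of sub-cluster labels to new TSPs.

    For each query the ``knn_k`` most correlated training TSPs vote; the
    score is the mean correlation to the voting neighbours of the winning
    label (ties broken toward the smaller label). Scores below the 5th
    percentile of scores for ``n_random`` random unit patterns are replaced
    by 0 with label ``None``.

    Returns (labels, scores, threshold); unclassified entries have label None.
    """
    train = model.tsps
    if knn_k > train.shape[0]:
        raise ValueError(f"knn_k={knn_k} exceeds training size {train.shape[0]}")

    def score_one(q):
        sims = train @ q
        nn = np.argsort(sims)[::-1][:knn_k]
        votes = np.bincount(model.labels[nn], minlength=model.k)
        label = int(np.argmax(votes))
        members = nn[model.labels[nn] == label]
        return label, float(sims[members].mean())

    rng = np.random.default_rng(seed)
    null = center_unit(rng.standard_normal((n_random, train.shape[1])))
    null_scores = np.array([score_one(q)[1] for q in null])
    threshold = float(np.percentile(null_scores, 5))

    Q = center_unit(query_tsps)
    labels, scores = [], []
    for q in Q:
        label, s = score_one(q)
        if s < threshold:
            labels.append(None)
            scores.append(0.0)
        else:
            labels.append(label)
            scores.append(s)
    return labels, np.array(scores), threshold
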