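"""Distance-dependent Chinese Restaurant Process clustering of trial samples.

Each of the n samples joins one *other* sample with probability proportional
to exp(-d^2 / gamma), where d is the positional distance and gamma (cm^2)
sets how quickly affinity decays; clusters are the connected components of
the resulting join graph. Because self-joins are excluded, every cluster has
at least two members. A Clusters-of-Samples (CoS) representation summarises
one clustering run by the cluster centroids c_k and relative weights
w_k = n_k / n.

The clustering is stochastic; observer models work with Monte-Carlo
ensembles of R independent runs per trial. An exact brute-force enumeration
over all (n-1)^n join vectors is provided as an oracle for small n.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .stimgen import TrialStimulus

__all__ = [
    "Partition",
    "CoSRepresentation",
    "ClusterEnsemble",
    "join_probabilities",
    "sample_partition",
    "enumerate_partitions",
    "build_ensemble",
    "cluster_size_histogram",
]


@dataclass(frozen=True)
class Partition:
    """Cluster labels and the join targets that induced them."""

    assignment: np.ndarray
    join_target: np.ndarray


@dataclass(frozen=True)
class CoSRepresentation:
    """Cluster centroids and relative weights {(c_k, w_k)} of one run."""

    centroids: np.ndarray
    weights: np.ndarray
    sizes: np.ndarray

    @property
    def K(self) -> int:
        return len(self.centroids)


@dataclass
class ClusterEnsemble:
    """R Monte-Carlo CoS representations of one trial at one gamma.

    Cluster-level quantities are stored flat across representations:
    representation ``j`` owns clusters ``rep_ptr[j]:rep_ptr[j+1]``.
    ``posterior_weights`` (summing to 1 over representations), when set,
    hold the probability that each representation was the one in use, as
    inferred from an observed Mode response.
    """

    positions: np.ndarray
    gamma: float
    rng_seed: int
    R: int
    rep_ptr: np.ndarray
    centroids: np.ndarray
    weights: np.ndarray
    sizes: np.ndarray
    posterior_weights: np.ndarray | None = None

    def rep(self, j: int) -> CoSRepresentation:
        sl = slice(self.rep_ptr[j], self.rep_ptr[j + 1])
        return CoSRepresentation(self.centroids[sl], self.weights[sl], self.sizes[sl])

    @property
    def reps(self) -> list[CoSRepresentation]:
        return [self.rep(j) for j in range(self.R)]


def join_log_probabilities(positions: np.ndarray, gamma: float) -> np.ndarray:
    """Log of the row-stochastic join matrix (diagonal is -inf)."""
    x = np.asarray(positions, dtype=float)
    if x.size < 2:
        raise ValueError("clustering impossible with fewer than two samples")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    logits = -((x[:, None] - x[None, :]) ** 2) / gamma
    np.fill_diagonal(logits, -np.inf)
    logits -= logits.max(axis=1, keepdims=True)
    logz = np.log(np.exp(logits).sum(axis=1, keepdims=True))
    return logits - logz


def join_probabilities(positions: np.ndarray, gamma: float) -> np.ndarray:
    """Row-stochastic matrix of P(sample j joins sample l)."""
    return np.exp(join_log_probabilities(positions, gamma))


def _labels_from_targets(targets: np.ndarray) -> np.ndarray:
    """Connected-component labels for batched join vectors (B, n) -> (B, n)."""
    b, n = targets.shape
    offs = np.arange(b)[:, None] * n
    rows = (offs + np.arange(n)).ravel()
    cols = (offs + targets).ravel()
    graph = sparse.coo_matrix(
        (np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(b * n, b * n)
    )
    _, labels = connected_components(graph, directed=False)
    return labels.reshape(b, n)


def _summarise(positions: np.ndarray, labels_flat: np.ndarray, n_rep: int):
    """Flat cluster sizes/centroids plus per-representation offsets."""
    n = positions.size
    ncl = labels_flat.max() + 1
    sizes = np.bincount(labels_flat, minlength=ncl)
    sums = np.bincount(labels_flat, weights=np.tile(positions, n_rep), minlength=ncl)
    centroids = sums / sizes
    rep_of = np.empty(ncl, dtype=np.int64)
    rep_of[labels_flat] = np.repeat(np.arange(n_rep), n)
    # component labels increase with first occurrence, hence rep_of is sorted
    rep_ptr = np.searchsorted(rep_of, np.arange(n_rep + 1))
    return rep_ptr, centroids, sizes / n, sizes


def sample_partition(
    positions: np.ndarray, gamma: float, rng: np.random.Generator
) -> tuple[Partition, CoSRepresentation]:
    """Draw one clustering: every sample joins a random other sample."""
    p = join_probabilities(positions, gamma)
    n = p.shape[0]
    u = rng.random((n, 1))
    targets = (p.cumsum(axis=1) < u).sum(axis=1)
    labels = _labels_from_targets(targets[None, :])[0]
    _, centroids, weights, sizes = _summarise(np.asarray(positions, float), labels, 1)
    return Partition(labels, targets), CoSRepresentation(centroids, weights, sizes)


def build_ensemble(
    stimulus: TrialStimulus | np.ndarray,
    gamma: float,
    R: int = 1000,
    seed: int = 0,
    batch: int = 250,
) -> ClusterEnsemble:
    """R independent clustering runs of one trial, deterministically seeded."""
    positions = stimulus.positions if isinstance(stimulus, TrialStimulus) else np.asarray(stimulus, float)
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    p = join_probabilities(positions, gamma)
    cum = p.cumsum(axis=1)
    n = positions.size
    label_chunks = []
    for start in range(0, R, batch):
        b = min(batch, R - start)
        u = rng.random((b, n, 1))
        targets = (cum[None, :, :] < u).sum(axis=2)
        label_chunks.append(_labels_from_targets(targets))
    # re-offset chunk-local labels into one increasing flat labelling
    flat = np.empty(R * n, dtype=np.int64)
    pos = 0
    offset = 0
    for chunk in label_chunks:
        flat[pos : pos + chunk.size] = chunk.ravel() + offset
        pos += chunk.size
        offset += chunk.max() + 1
    rep_ptr, centroids, weights, sizes = _summarise(positions, flat, R)
    return ClusterEnsemble(positions, float(gamma), seed, R, rep_ptr, centroids, weights, sizes)


def enumerate_partitions(positions: np.ndarray, gamma: float) -> dict[tuple, float]:
    """Exact distribution over set-partitions by brute-force enumeration.

    Iterates all (n-1)^n join vectors and accumulates their product
    probabilities per induced set-partition. Intended as a small-n oracle:
    the cost grows as (n-1)^n, so n is capped at 8 (n=8 takes minutes).
    """
    x = np.asarray(positions, dtype=float)
    n = x.size
    if n > 8:
        raise ValueError("enumeration oracle limited to n <= 8")
    logp = join_log_probabilities(x, gamma)
    candidates = [[l for l in range(n) if l != j] for j in range(n)]
    out: dict[tuple, float] = {}
    for joins in itertools.product(*candidates):
        parent = list(range(n))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for j, l in enumerate(joins):
            ra, rb = find(j), find(l)
            if ra != rb:
                parent[ra] = rb
        roots = [find(j) for j in range(n)]
        groups: dict[int, list[int]] = {}
        for j, r in enumerate(roots):
            groups.setdefault(r, []).append(j)
        key = tuple(sorted(tuple(g) for g in groups.values()))
        out[key] = out.get(key, 0.0) + float(np.exp(sum(logp[j, l] for j, l in enumerate(joins))))
    return out


def cluster_size_histogram(
    ensembles: list[ClusterEnsemble], use_posterior: bool = False, n_samples: int = 70
) -> np.ndarray:
    """Relative frequency of cluster sizes 1..n_samples.

    Within each representation, each cluster contributes 1/K; representations
    are averaged uniformly (or by their posterior weights) within a trial, and
    trials are averaged uniformly. Returned array index s-1 holds size s.
    """
    if not ensembles:
        raise ValueError("no ensembles given")
    acc = np.zeros(n_samples)
    for ens in ensembles:
        k_per_rep = np.diff(ens.rep_ptr).astype(float)
        if use_posterior:
            if ens.posterior_weights is None:
                raise ValueError("ensemble lacks posterior weights")
            rep_w = ens.posterior_weights
        else:
            rep_w = np.full(ens.R, 1.0 / ens.R)
        rep_of = np.repeat(np.arange(ens.R), np.diff(ens.rep_ptr))
        contrib = rep_w[rep_of] / k_per_rep[rep_of]
        acc += np.bincount(ens.sizes, weights=contrib, minlength=n_samples + 1)[1 : n_samples + 1]
    return acc / len(ensembles)
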