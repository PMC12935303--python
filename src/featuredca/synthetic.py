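"""Synthetic alignments and tiny enumerable models used as test beds.

The clustered-MSA generator emulates a protein family whose sequences fall
into a few well-separated subfamilies (distinct per-column symbol profiles),
optionally with correlated column pairs inside each cluster.  The tiny-model
helpers build fully enumerable autoregressive models (q^L <= 4096) and the
exact optimal-transport oracle used to validate the Sinkhorn divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, linprog
from scipy.spatial.distance import cdist

from .alignment import Alignment, Alphabet
from .errors import ParameterError
from .model import ModelParams, log_prob_batch

ENUMERATION_BOUND = 4096
OT_POINT_BOUND = 64


@dataclass(frozen=True)
class ClusterSpec:
    """Recipe for a clustered toy alignment.

    ``profile_divergence`` in [0, 1] interpolates each cluster's per-column
    profile between a shared base profile (0) and a cluster-specific random
    profile (1).  ``coupled_pair_fraction`` of the column pairs receive
    within-cluster dependence through a hidden per-sequence binary switch.
    """

    cluster_sizes: tuple[int, ...] = (1000, 1000)
    L: int = 30
    q: int = 8
    profile_divergence: float = 0.8
    coupled_pair_fraction: float = 0.0
    seed: int = 0
    concentration: float = 1.0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.cluster_sizes) or len(self.cluster_sizes) < 1:
            raise ParameterError("cluster sizes must be positive")
        if not (0.0 <= self.profile_divergence <= 1.0):
            raise ParameterError("profile_divergence must be in [0, 1]")
        if not (0.0 <= self.coupled_pair_fraction <= 1.0):
            raise ParameterError("coupled_pair_fraction must be in [0, 1]")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    @property
    def M(self) -> int:
        return sum(self.cluster_sizes)


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray, n: int) -> np.ndarray:
    """Vectorized categorical draws; probs is (n, q) or (q,)."""
    probs = np.atleast_2d(probs)
    if probs.shape[0] == 1:
        probs = np.broadcast_to(probs, (n, probs.shape[1]))
    u = rng.random(n)
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)


def make_cluster_msa(spec: ClusterSpec) -> tuple[Alignment, np.ndarray]:
    """Generate a clustered alignment; returns ``(alignment, cluster_labels)``.

    Deterministic given ``spec.seed`` (one named generator stream per call).
    Designated coupled pairs draw both columns from one of two product
    profiles selected by a per-sequence fair-coin switch, which induces a
    positive connected correlation within each cluster.
    """
    rng = np.random.default_rng(spec.seed)
    L, q = spec.L, spec.q
    alphabet = Alphabet("-ACDEFGHIKLMNPQRSTVWY"[:q])
    base = rng.dirichlet(np.full(q, spec.concentration), size=L)
    profiles = []
    for _ in range(spec.n_clusters):
        own = rng.dirichlet(np.full(q, spec.concentration), size=L)
        profiles.append((1 - spec.profile_divergence) * base + spec.profile_divergence * own)
    n_pairs_total = L // 2
    n_coupled = int(round(spec.coupled_pair_fraction * n_pairs_total))
    cols = rng.permutation(L)
    coupled_pairs = [(int(cols[2 * p]), int(cols[2 * p + 1])) for p in range(n_coupled)]
    # two alternative per-cluster product profiles per coupled pair
    switch_profiles = {
        (c, pair): (rng.dirichlet(np.full(q, 0.5), size=2),
                    rng.dirichlet(np.full(q, 0.5), size=2))
        for c in range(spec.n_clusters)
        for pair in coupled_pairs
    }
    data = np.empty((spec.M, L), dtype=np.int64)
    labels = np.empty(spec.M, dtype=np.int64)
    row = 0
    for c, size in enumerate(spec.cluster_sizes):
        block = np.empty((size, L), dtype=np.int64)
        for col in range(L):
            block[:, col] = _sample_categorical(rng, profiles[c][col], size)
        for pair in coupled_pairs:
            i, j = pair
            table0, table1 = switch_profiles[(c, pair)]
            switch = rng.random(size) < 0.5
            for s_val, table in ((False, table0), (True, table1)):
                idx = np.where(switch == s_val)[0]
                if len(idx):
                    block[idx, i] = _sample_categorical(rng, table[0], len(idx))
                    block[idx, j] = _sample_categorical(rng, table[1], len(idx))
        data[row : row + size] = block
        labels[row : row + size] = c
        row += size
    ids = [f"c{labels[m]}_s{m}" for m in range(spec.M)]
    return Alignment(ids=ids, data=data, alphabet=alphabet), labels


def coupled_pairs_of(spec: ClusterSpec) -> list[tuple[int, int]]:
    """The (i, j) column pairs that ``make_cluster_msa`` couples for this spec."""
    rng = np.random.default_rng(spec.seed)
    L, q = spec.L, spec.q
    rng.dirichlet(np.full(q, spec.concentration), size=L)
    for _ in range(spec.n_clusters):
        rng.dirichlet(np.full(q, spec.concentration), size=L)
    n_coupled = int(round(spec.coupled_pair_fraction * (L // 2)))
    cols = rng.permutation(L)
    return [tuple(sorted((int(cols[2 * p]), int(cols[2 * p + 1])))) for p in range(n_coupled)]


def make_tiny_model(
    L: int, q: int, d: int, scale: float = 0.5, seed: int = 0
) -> ModelParams:
    """Random enumerable model with i.i.d. normal(0, scale^2) parameters."""
    if L > 6 or q > 4 or d > 2 or q**L > ENUMERATION_BOUND:
        raise ParameterError("tiny model bounds exceeded (L <= 6, q <= 4, d <= 2)")
    rng = np.random.default_rng(seed)
    alphabet = Alphabet("-ACDEFGHIKLMNPQRSTVWY"[:q])
    J = [rng.normal(0.0, scale, size=(k, q, q)) for k in range(L)]
    h = rng.normal(0.0, scale, size=(L, q))
    G = rng.normal(0.0, scale, size=(L, q, d))
    return ModelParams(
        L=L, q=q, d=d, ordering=np.arange(L), J=J, h=h, G=G,
        reg={}, alphabet=alphabet,
    )


def enumerate_sequences(L: int, q: int) -> np.ndarray:
    """All q^L sequences as a (q^L, L) integer matrix, lexicographic order."""
    if q**L > ENUMERATION_BOUND:
        raise ParameterError(f"q^L = {q**L} exceeds enumeration bound {ENUMERATION_BOUND}")
    grids = np.meshgrid(*[np.arange(q)] * L, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def brute_force_distribution(params: ModelParams, y: np.ndarray) -> np.ndarray:
    """Exact P(a | y) over all q^L sequences via full enumeration."""
    seqs = enumerate_sequences(params.L, params.q)
    return np.exp(log_prob_batch(params, seqs, np.asarray(y, dtype=float)))


def exact_ot_distance(X: np.ndarray, Yp: np.ndarray) -> float:
    """Exact optimal-transport cost (squared-Euclidean, uniform weights).

    For equal-sized clouds this reduces to an assignment problem; otherwise
    the transport linear program is solved directly.  Bounded to <= 64
    points per cloud so it stays a fast oracle.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Yp = np.atleast_2d(np.asarray(Yp, dtype=float))
    n, m = X.shape[0], Yp.shape[0]
    if n > OT_POINT_BOUND or m > OT_POINT_BOUND:
        raise ParameterError(f"cloud sizes {n}, {m} exceed bound {OT_POINT_BOUND}")
    C = cdist(X, Yp, metric="sqeuclidean")
    if n == m:
        rows, cols = linear_sum_assignment(C)
        return float(C[rows, cols].mean())
    # transport LP: minimize <P, C> s.t. row sums 1/n, col sums 1/m, P >= 0
    A_eq = np.zeros((n + m, n * m))
    for i in range(n):
        A_eq[i, i * m : (i + 1) * m] = 1.0
    for j in range(m):
        A_eq[n + j, j::m] = 1.0
    b_eq = np.concatenate([np.full(n, 1.0 / n), np.full(m, 1.0 / m)])
    res = linprog(C.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)
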