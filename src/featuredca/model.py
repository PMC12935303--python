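"""Feature-conditioned autoregressive Potts model: likelihood, training, sampling.

The joint distribution over a sequence ``a`` (length L, q states) and a
conditioning feature vector ``y`` (dimension d) factorizes autoregressively,

    P(a, y) = P(y) * prod_k P(a_k | a_<k, y),

with each per-site conditional a Boltzmann distribution over the energy

    H(a_k | a_<k, y) = - sum_{i<k} J_ki(a_k, a_i) - h_k(a_k) - y . G_k(a_k).

``J`` are pairwise couplings to earlier sites in the autoregressive order,
``h`` local fields and ``G`` the per-symbol feature embeddings.  Setting
d = 0 removes the G block and recovers plain unconditioned autoregressive
DCA.  Every per-rank conditional is an independent convex multinomial
logistic problem, so maximum-likelihood training decomposes into L small
L2-regularized fits solved here by L-BFGS with analytic gradients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .alignment import Alignment, Alphabet, SequenceWeights, compute_weights, frequencies
from .errors import AlignmentShapeError, ModelFormatError, ParameterError
from .features import FeatureDensity, PCABasis, log_density

FORMAT_VERSION = 1


@dataclass
class ModelParams:
    """Trained parameter set of the feature-conditioned autoregressive model.

    ``ordering[k]`` is the alignment column processed at autoregressive rank
    ``k``.  ``J[k]`` has shape (k, q, q) with ``J[k][i][a, b]`` the coupling
    between symbol ``a`` at rank k and symbol ``b`` at earlier rank i;
    ``h`` is (L, q) and ``G`` is (L, q, d), both indexed by rank.
    """

    L: int
    q: int
    d: int
    ordering: np.ndarray
    J: list[np.ndarray]
    h: np.ndarray
    G: np.ndarray
    reg: dict = field(default_factory=dict)
    alphabet: Alphabet = field(default_factory=Alphabet)

    def __post_init__(self) -> None:
        self.ordering = np.asarray(self.ordering, dtype=np.int64)
        if sorted(self.ordering.tolist()) != list(range(self.L)):
            raise ParameterError("ordering must be a permutation of 0..L-1")
        if self.h.shape != (self.L, self.q):
            raise ParameterError(f"h has shape {self.h.shape}, expected {(self.L, self.q)}")
        if self.G.shape != (self.L, self.q, self.d):
            raise ParameterError(
                f"G has shape {self.G.shape}, expected {(self.L, self.q, self.d)}"
            )
        for k, Jk in enumerate(self.J):
            if Jk.shape != (k, self.q, self.q):
                raise ParameterError(f"J[{k}] has shape {Jk.shape}, expected {(k, self.q, self.q)}")

    @property
    def n_parameters(self) -> int:
        return parameter_count(self.L, self.q, self.d)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters for L2-regularized maximum-likelihood training."""

    lambda_J: float = 1e-2
    lambda_h: float = 1e-4
    lambda_G: float = 1e-4
    max_iterations: int = 500
    gradient_tolerance: float = 1e-5
    ordering_mode: str = "natural"  # "natural" | "entropic"
    seed: int = 0
    use_sequence_weights: bool = True
    similarity_threshold: float = 0.8
    standardize_features: bool = False

    def __post_init__(self) -> None:
        if self.gradient_tolerance <= 0:
            raise ParameterError("gradient_tolerance must be positive")
        if min(self.lambda_J, self.lambda_h, self.lambda_G) < 0:
            raise ParameterError("regularization strengths must be nonnegative")
        if self.ordering_mode not in ("natural", "entropic"):
            raise ParameterError(f"unknown ordering_mode {self.ordering_mode!r}")


@dataclass
class TrainingReport:
    """Per-rank optimizer diagnostics collected during training."""

    nll_per_rank: list[float]
    iterations_per_rank: list[int]
    meff: float
    ordering: list[int]

    @property
    def total_nll(self) -> float:
        return float(sum(self.nll_per_rank))


def parameter_count(L: int, q: int, d: int) -> int:
    """Total scalar parameters: L(L-1)q^2/2 couplings + L(q + dq) fields/embeddings."""
    if L < 1 or q < 2 or d < 0:
        raise ParameterError("require L >= 1, q >= 2, d >= 0")
    return L * (L - 1) * q * q // 2 + L * (q + d * q)


def conditional_logits(
    params: ModelParams, prefix: Sequence[int], y: np.ndarray, k: int
) -> np.ndarray:
    """Negative energies of the q symbols at rank k given the rank-ordered prefix."""
    if not (0 <= k < params.L):
        raise ParameterError(f"rank k={k} out of range")
    prefix = np.asarray(prefix, dtype=np.int64)
    if prefix.shape != (k,):
        raise AlignmentShapeError(f"prefix has shape {prefix.shape}, expected ({k},)")
    y = np.asarray(y, dtype=float).reshape(-1)
    if y.shape != (params.d,):
        raise AlignmentShapeError(f"y has shape {y.shape}, expected ({params.d},)")
    logits = params.h[k] + params.G[k] @ y
    for i in range(k):
        logits = logits + params.J[k][i][:, prefix[i]]
    return logits


def conditional_distribution(
    params: ModelParams, prefix: Sequence[int], y: np.ndarray, k: int
) -> np.ndarray:
    """Softmax of the conditional logits: P(a_k | a_<k, y)."""
    logits = conditional_logits(params, prefix, y, k)
    logits = logits - logits.max()
    p = np.exp(logits)
    return p / p.sum()


def log_prob_batch(params: ModelParams, seqs: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Conditional log-probabilities log P(a | y) of N sequences (vectorized).

    ``seqs`` is (N, L) in alignment column order; ``Y`` is (N, d) or a single
    (d,) vector broadcast to all sequences.
    """
    seqs = np.atleast_2d(np.asarray(seqs, dtype=np.int64))
    N, L = seqs.shape
    if L != params.L:
        raise AlignmentShapeError(f"sequences have L={L}, model has L={params.L}")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = np.broadcast_to(Y, (N, params.d))
    if Y.shape != (N, params.d):
        raise AlignmentShapeError(f"Y has shape {Y.shape}, expected ({N}, {params.d})")
    ranked = seqs[:, params.ordering]
    total = np.zeros(N)
    rows = np.arange(N)
    for k in range(L):
        logits = params.h[k] + Y @ params.G[k].T
        for i in range(k):
            logits = logits + params.J[k][i][:, ranked[:, i]].T
        total += logits[rows, ranked[:, k]] - logsumexp(logits, axis=1)
    return total


def sequence_log_prob(params: ModelParams, a: Sequence[int], y: np.ndarray) -> float:
    """log P(a | y): sum of per-rank conditional log-probabilities."""
    return float(log_prob_batch(params, np.asarray(a)[None, :], np.asarray(y))[0])


def joint_log_prob(
    params: ModelParams,
    density: FeatureDensity | None,
    a: Sequence[int],
    y: np.ndarray,
    flat_density: bool = False,
) -> float:
    """log P(a, y) = log P(y) + log P(a | y).

    With ``flat_density=True`` (or ``density is None``) an improper flat
    P(y) is assumed and the conditional log-probability is returned.
    """
    lp = sequence_log_prob(params, a, y)
    if flat_density or density is None:
        return lp
    return log_density(density, np.asarray(y, dtype=float)) + lp


# --- per-rank convex objective ------------------------------------------------

def _rank_value_grad(
    theta: np.ndarray,
    Xprev: np.ndarray,
    Y: np.ndarray,
    targets: np.ndarray,
    wn: np.ndarray,
    q: int,
    k: int,
    d: int,
    lam_J: float,
    lam_h: float,
    lam_G: float,
):
    """Weighted-mean NLL + L2 penalties and its gradient for one rank."""
    n_J = k * q * q
    Jmat = theta[:n_J].reshape(q, k * q)
    h = theta[n_J : n_J + q]
    G = theta[n_J + q :].reshape(q, d)
    logits = Xprev @ Jmat.T + Y @ G.T + h
    lse = logsumexp(logits, axis=1)
    rows = np.arange(len(targets))
    ll = logits[rows, targets] - lse
    value = -float(wn @ ll)
    value += lam_J * float((Jmat**2).sum()) + lam_h * float((h**2).sum())
    value += lam_G * float((G**2).sum())
    P = np.exp(logits - lse[:, None])
    P[rows, targets] -= 1.0
    D = P * wn[:, None]
    grad_J = D.T @ Xprev + 2 * lam_J * Jmat
    grad_h = D.sum(axis=0) + 2 * lam_h * h
    grad_G = D.T @ Y + 2 * lam_G * G
    grad = np.concatenate([grad_J.ravel(), grad_h, grad_G.ravel()])
    return value, grad


def _prefix_features(ranked: np.ndarray, q: int) -> np.ndarray:
    """One-hot encoding of all ranks, (M, L*q); rank-k prefix is the first k*q columns."""
    M, L = ranked.shape
    X = np.zeros((M, L * q))
    X[np.arange(M)[:, None], np.arange(L) * q + ranked] = 1.0
    return X


def _resolve_ordering(aln: Alignment, weights: SequenceWeights | None, mode: str) -> np.ndarray:
    if mode == "natural":
        return np.arange(aln.L, dtype=np.int64)
    # entropic: ranks sorted by increasing single-site entropy
    stats = frequencies(aln, weights=weights, pseudocount=1e-6)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(stats.f1 > 0, stats.f1 * np.log(stats.f1), 0.0)
    entropy = -plogp.sum(axis=1)
    return np.argsort(entropy, kind="stable").astype(np.int64)


def negative_log_likelihood(
    params: ModelParams,
    aln: Alignment,
    Y: np.ndarray,
    weights: SequenceWeights | None = None,
    config: TrainingConfig | None = None,
):
    """Regularized objective and analytic gradients for all parameter blocks.

    Returns ``(value, grads)`` where ``grads`` holds per-block arrays
    ("J": list of (k, q, q), "h": (L, q), "G": (L, q, d)).  The value is the
    weighted mean of -log P(a | y) plus the L2 penalties, and decomposes as
    a sum of L independent per-rank terms.
    """
    config = config or TrainingConfig()
    M, L = aln.data.shape
    q = aln.alphabet.q
    Y = np.asarray(Y, dtype=float).reshape(M, -1)
    if Y.shape[0] != M:
        raise AlignmentShapeError("Y rows must match alignment rows")
    d = params.d
    w = weights.weights if weights is not None else np.ones(M)
    wn = w / w.sum()
    ranked = aln.data[:, params.ordering]
    X = _prefix_features(ranked, q)
    total = 0.0
    grads = {"J": [], "h": np.zeros((L, q)), "G": np.zeros((L, q, d))}
    for k in range(L):
        theta = np.concatenate(
            [params.J[k].reshape(k, q, q).transpose(1, 0, 2).reshape(q, k * q).ravel(),
             params.h[k], params.G[k].ravel()]
        )
        value, grad = _rank_value_grad(
            theta, X[:, : k * q], Y, ranked[:, k], wn, q, k, d,
            config.lambda_J, config.lambda_h, config.lambda_G,
        )
        total += value
        n_J = k * q * q
        grads["J"].append(grad[:n_J].reshape(q, k, q).transpose(1, 0, 2).copy())
        grads["h"][k] = grad[n_J : n_J + q]
        grads["G"][k] = grad[n_J + q :].reshape(q, d)
    return total, grads


def train(
    aln: Alignment,
    Y: np.ndarray | None,
    config: TrainingConfig | None = None,
    weights: SequenceWeights | None = None,
    full_output: bool = False,
):
    """Fit the model by per-rank L2-regularized maximum likelihood.

    ``Y`` holds one conditioning vector per alignment row (or ``None`` /
    zero columns for the unconditioned d = 0 model).  Each rank is an
    independent convex problem solved by L-BFGS from a zero start, so the
    result is deterministic given the configuration.
    """
    config = config or TrainingConfig()
    M, L = aln.data.shape
    q = aln.alphabet.q
    if M < 2:
        raise ParameterError("need at least 2 sequences to train")
    if Y is None:
        Y = np.zeros((M, 0))
    Y = np.asarray(Y, dtype=float).reshape(M, -1)
    d = Y.shape[1]
    if config.standardize_features and d > 0:
        y_mean = Y.mean(axis=0)
        y_std = Y.std(axis=0)
        y_std[y_std == 0] = 1.0
        Yfit = (Y - y_mean) / y_std
    else:
        y_mean = np.zeros(d)
        y_std = np.ones(d)
        Yfit = Y
    if weights is None and config.use_sequence_weights:
        weights = compute_weights(aln, config.similarity_threshold)
    w = weights.weights if weights is not None else np.ones(M)
    wn = w / w.sum()
    ordering = _resolve_ordering(aln, weights, config.ordering_mode)
    ranked = aln.data[:, ordering]
    X = _prefix_features(ranked, q)
    J: list[np.ndarray] = []
    h = np.zeros((L, q))
    G = np.zeros((L, q, d))
    nll_per_rank: list[float] = []
    iters: list[int] = []
    for k in range(L):
        n_theta = k * q * q + q + q * d
        res = minimize(
            _rank_value_grad,
            np.zeros(n_theta),
            args=(X[:, : k * q], Yfit, ranked[:, k], wn, q, k, d,
                  config.lambda_J, config.lambda_h, config.lambda_G),
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": config.max_iterations,
                "gtol": config.gradient_tolerance,
                "ftol": 1e-12,
            },
        )
        if not np.isfinite(res.fun):
            raise ParameterError(f"non-finite objective at rank {k}")
        n_J = k * q * q
        Jmat = res.x[:n_J].reshape(q, k * q)
        J.append(Jmat.reshape(q, k, q).transpose(1, 0, 2).copy())
        h[k] = res.x[n_J : n_J + q]
        G[k] = res.x[n_J + q :].reshape(q, d)
        nll_per_rank.append(float(res.fun))
        iters.append(int(res.nit))
    if config.standardize_features and d > 0:
        # fold the z-scoring back so the stored model consumes raw y
        G = G / y_std[None, None, :]
        h = h - G @ y_mean
    params = ModelParams(
        L=L, q=q, d=d, ordering=ordering, J=J, h=h, G=G,
        reg={"lambda_J": config.lambda_J, "lambda_h": config.lambda_h,
             "lambda_G": config.lambda_G,
             "similarity_threshold": config.similarity_threshold},
        alphabet=aln.alphabet,
    )
    if full_output:
        report = TrainingReport(
            nll_per_rank=nll_per_rank,
            iterations_per_rank=iters,
            meff=float(w.sum()),
            ordering=ordering.tolist(),
        )
        return params, report
    return params


def sample(
    params: ModelParams,
    y: np.ndarray,
    n_per_condition: int = 1,
    seed: int = 0,
    id_prefix: str = "gen",
) -> Alignment:
    """Draw sequences autoregressively, conditioned on feature vector(s).

    ``y`` is a single length-d vector or an (C, d) matrix; one block of
    ``n_per_condition`` sequences is drawn per row.  Columns are returned in
    original alignment order, and the output is reproducible given ``seed``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[None, :] if params.d > 0 else y.reshape(1, 0)
    if y.shape[1] != params.d:
        raise AlignmentShapeError(f"y has d={y.shape[1]}, model has d={params.d}")
    if not np.all(np.isfinite(y)):
        raise ValueError("conditioning vectors must be finite")
    C = y.shape[0]
    N = C * n_per_condition
    Ybig = np.repeat(y, n_per_condition, axis=0)
    rng = np.random.default_rng(seed)
    ranked = np.empty((N, params.L), dtype=np.int64)
    rows = np.arange(N)
    for k in range(params.L):
        logits = params.h[k] + Ybig @ params.G[k].T
        for i in range(k):
            logits = logits + params.J[k][i][:, ranked[:, i]].T
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(N)
        ranked[:, k] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    data = np.empty_like(ranked)
    data[:, params.ordering] = ranked
    ids = []
    for c in range(C):
        ytag = ",".join(f"{v:.6g}" for v in y[c])
        for j in range(n_per_condition):
            ids.append(f"{id_prefix}_{c * n_per_condition + j}|y={ytag}|seed={seed}")
    return Alignment(ids=ids, data=data, alphabet=params.alphabet)


# --- serialization ------------------------------------------------------------

def save_model(
    params: ModelParams,
    basis: PCABasis | None,
    density: FeatureDensity | None,
    path: str | Path,
) -> None:
    """Write a single-file .npz archive with named arrays and JSON metadata."""
    arrays: dict[str, np.ndarray] = {
        "h": params.h,
        "ordering": params.ordering,
    }
    for k, Jk in enumerate(params.J):
        arrays[f"J_{k}"] = Jk
    if params.d > 0:
        arrays["G"] = params.G
    if basis is not None:
        arrays["pca_mean"] = basis.mean
        arrays["pca_components"] = basis.components
        arrays["pca_explained_variance"] = basis.explained_variance
    if density is not None:
        arrays["density_mean"] = density.mean
        arrays["density_cov"] = density.covariance
        arrays["density_shrinkage"] = np.array(density.shrinkage)
    meta = {
        "format_version": FORMAT_VERSION,
        "alphabet": params.alphabet.symbols,
        "L": params.L,
        "q": params.q,
        "d": params.d,
        "ordering": params.ordering.tolist(),
        "lambda_J": params.reg.get("lambda_J"),
        "lambda_h": params.reg.get("lambda_h"),
        "lambda_G": params.reg.get("lambda_G"),
        "similarity_threshold": params.reg.get("similarity_threshold"),
    }
    arrays["meta"] = np.array(json.dumps(meta))
    np.savez(Path(path), **arrays)


def load_model(path: str | Path):
    """Load a model archive; returns ``(params, basis | None, density | None)``.

    Validation is all-or-nothing: inconsistent metadata or missing arrays
    raise :class:`ModelFormatError` and nothing is partially constructed.
    """
    with np.load(Path(path), allow_pickle=False) as npz:
        names = set(npz.files)
        if "meta" not in names:
            raise ModelFormatError("archive has no metadata block")
        meta = json.loads(str(npz["meta"]))
        if meta.get("format_version") != FORMAT_VERSION:
            raise ModelFormatError(
                f"unsupported format version {meta.get('format_version')!r}"
            )
        L, q, d = int(meta["L"]), int(meta["q"]), int(meta["d"])
        alphabet = Alphabet(meta["alphabet"])
        if alphabet.q != q:
            raise ModelFormatError(
                f"metadata q={q} does not match alphabet of size {alphabet.q}"
            )
        if "h" not in names or npz["h"].shape != (L, q):
            raise ModelFormatError("field array 'h' missing or mis-shaped")
        J = []
        for k in range(L):
            key = f"J_{k}"
            if key not in names or npz[key].shape != (k, q, q):
                raise ModelFormatError(f"coupling array {key!r} missing or mis-shaped")
            J.append(npz[key])
        if d > 0:
            if "G" not in names or npz["G"].shape != (L, q, d):
                raise ModelFormatError("embedding array 'G' missing or mis-shaped")
            G = npz["G"]
        else:
            G = np.zeros((L, q, 0))
        params = ModelParams(
            L=L, q=q, d=d, ordering=npz["ordering"], J=J, h=npz["h"], G=G,
            reg={k: meta.get(k) for k in
                 ("lambda_J", "lambda_h", "lambda_G", "similarity_threshold")},
            alphabet=alphabet,
        )
        basis = None
        if "pca_mean" in names:
            basis = PCABasis(
                mean=npz["pca_mean"],
                components=npz["pca_components"],
                explained_variance=npz["pca_explained_variance"],
                L=L, q=q,
            )
        density = None
        if "density_mean" in names:
            density = FeatureDensity(
                mean=npz["density_mean"],
                covariance=npz["density_cov"],
                shrinkage=float(npz["density_shrinkage"]),
            )
    return params, basis, density
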