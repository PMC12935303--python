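"""Generative-quality metrics: correlation fidelity, Sinkhorn divergence,
diversity and conditioned-sampling reports.

Statistical fidelity is the Pearson correlation between the two-site
connected correlations of a natural and a generated alignment.  The match
of the two point clouds in principal-component space is quantified by the
debiased entropic optimal-transport (Sinkhorn) divergence

    S(alpha, beta) = OT_eps(alpha, beta)
                     - (OT_eps(alpha, alpha) + OT_eps(beta, beta)) / 2

with squared-Euclidean ground cost and uniform weights, computed with
log-domain stabilized Sinkhorn iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .alignment import Alignment, FrequencyStats, connected_correlations, hamming_fraction
from .errors import AlignmentShapeError, ParameterError
from .features import PCABasis, project

__all__ = [
    "FidelityReport",
    "SinkhornResult",
    "ConditioningReport",
    "correlation_fidelity",
    "sinkhorn_divergence",
    "conditioned_sampling_report",
]


@dataclass(frozen=True)
class FidelityReport:
    """Pearson correlation of connected correlations between two MSAs."""

    pearson_cij: float
    n_pairs: int          # number of C_ij entries compared
    pseudocount_used: float
    gap_included: bool


@dataclass(frozen=True)
class SinkhornResult:
    """Debiased Sinkhorn divergence with convergence metadata."""

    value: float
    epsilon: float
    converged: bool
    iterations: int

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class TargetRecord:
    target_id: str
    hamming_mean: float
    hamming_sd: float
    euclidean_pc2_mean: float
    euclidean_full_mean: float


@dataclass(frozen=True)
class ConditioningReport:
    """Per-target distance summaries for conditioned sampling."""

    targets: list[TargetRecord]
    cross_hamming: np.ndarray  # (n_targets, n_targets) mean Hamming fractions


def correlation_fidelity(
    natural: FrequencyStats,
    generated: FrequencyStats,
    include_gap: bool = True,
    gap_index: int = 0,
) -> FidelityReport:
    """Pearson correlation over the flattened {C_ij(a, b)}_{i<j} vectors."""
    if natural.f1.shape != generated.f1.shape:
        raise AlignmentShapeError("frequency statistics have mismatched (L, q)")
    C_nat = connected_correlations(natural)
    C_gen = connected_correlations(generated)
    if not include_gap:
        keep = np.ones(natural.q, dtype=bool)
        keep[gap_index] = False
        C_nat = C_nat[:, keep][:, :, keep]
        C_gen = C_gen[:, keep][:, :, keep]
    x = C_nat.ravel()
    y = C_gen.ravel()
    r = float(pearsonr(x, y).statistic)
    return FidelityReport(
        pearson_cij=r,
        n_pairs=x.size,
        pseudocount_used=natural.pseudocount,
        gap_included=include_gap,
    )


def _entropic_ot(
    C: np.ndarray, epsilon: float, max_iter: int, tol: float
) -> tuple[float, bool, int]:
    """OT_eps between uniform measures for cost matrix C.

    Stabilized Sinkhorn scaling: multiplicative u/v updates on the Gibbs
    kernel, with the potentials absorbed into the kernel whenever the
    scalings grow large (which keeps the iterations exact in log space while
    letting the common case run as plain matrix-vector products).  Returns
    the converged dual value <a, f> + <b, g>, a convergence flag and the
    number of iterations used.
    """
    n, m = C.shape
    f = np.zeros(n)
    g = np.zeros(m)
    with np.errstate(under="ignore"):
        K = np.exp((f[:, None] + g[None, :] - C) / epsilon)
    u = np.ones(n)
    v = np.ones(m)
    absorb_at = 1e30
    tiny = np.finfo(float).tiny
    converged = False
    it = 0
    with np.errstate(under="ignore", over="ignore", divide="ignore"):
        for it in range(1, max_iter + 1):
            u = m / np.maximum(K @ v, tiny)
            v = n / np.maximum(K.T @ u, tiny)
            np.clip(u, None, absorb_at, out=u)
            np.clip(v, None, absorb_at, out=v)
            if max(u.max(), v.max()) >= absorb_at or min(u.min(), v.min()) <= 1 / absorb_at:
                f = f + epsilon * np.log(u)
                g = g + epsilon * np.log(v)
                K = np.exp((f[:, None] + g[None, :] - C) / epsilon)
                u = np.ones(n)
                v = np.ones(m)
                continue
            if it % 5 == 0 or it == max_iter:
                # row-marginal L1 violation of the implied plan
                row = u * (K @ v) / (n * m)
                if np.abs(row - 1.0 / n).sum() < tol:
                    converged = True
                    break
    f = f + epsilon * np.log(u)
    g = g + epsilon * np.log(v)
    return float(f.mean() + g.mean()), converged, it


def default_epsilon(X: np.ndarray, Yp: np.ndarray, fraction: float = 0.05) -> float:
    """0.05 x mean pairwise squared distance of the pooled clouds."""
    Z = np.vstack([np.atleast_2d(X), np.atleast_2d(Yp)])
    mean_sq = 2 * float((Z**2).sum(axis=1).mean() - (Z.mean(axis=0) ** 2).sum())
    return max(fraction * mean_sq, 1e-12)


def sinkhorn_divergence(
    X: np.ndarray,
    Yp: np.ndarray,
    epsilon: float | None = None,
    max_iter: int = 5000,
    tol: float = 1e-6,
    max_points: int = 20000,
    seed: int = 0,
) -> SinkhornResult:
    """Debiased Sinkhorn divergence between two point clouds.

    Uniform weights, squared-Euclidean cost; clouds larger than
    ``max_points`` are subsampled with the given seed.  Non-convergence
    within ``max_iter`` is recorded in the result metadata (the value is
    still returned) and raised as a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Yp = np.atleast_2d(np.asarray(Yp, dtype=float))
    if X.shape[1] != Yp.shape[1]:
        raise AlignmentShapeError("point clouds have different dimensions")
    rng = np.random.default_rng(seed)
    if X.shape[0] > max_points:
        X = X[rng.choice(X.shape[0], max_points, replace=False)]
    if Yp.shape[0] > max_points:
        Yp = Yp[rng.choice(Yp.shape[0], max_points, replace=False)]
    if epsilon is None:
        epsilon = default_epsilon(X, Yp)
    if epsilon <= 0:
        raise ParameterError("epsilon must be positive")
    C_xy = cdist(X, Yp, metric="sqeuclidean")
    C_xx = cdist(X, X, metric="sqeuclidean")
    C_yy = cdist(Yp, Yp, metric="sqeuclidean")
    ot_xy, conv_xy, it_xy = _entropic_ot(C_xy, epsilon, max_iter, tol)
    ot_xx, conv_xx, it_xx = _entropic_ot(C_xx, epsilon, max_iter, tol)
    ot_yy, conv_yy, it_yy = _entropic_ot(C_yy, epsilon, max_iter, tol)
    converged = conv_xy and conv_xx and conv_yy
    if not converged:
        warnings.warn(
            f"Sinkhorn iterations did not reach tol={tol} within {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    value = ot_xy - 0.5 * (ot_xx + ot_yy)
    return SinkhornResult(
        value=float(max(value, 0.0) if abs(value) < 1e-12 else value),
        epsilon=float(epsilon),
        converged=converged,
        iterations=max(it_xy, it_xx, it_yy),
    )


def conditioned_sampling_report(
    targets: list[tuple[np.ndarray, np.ndarray]],
    sample_blocks: list[Alignment],
    basis: PCABasis | None = None,
    target_ids: list[str] | None = None,
) -> ConditioningReport:
    """Distance summaries of conditioned samples around their targets.

    ``targets`` is a list of ``(sequence, y)`` pairs and ``sample_blocks``
    the per-target sampled alignments.  Reports per-target mean/sd Hamming
    fraction to the own target, mean Euclidean distance of the projected
    samples to the target's y (in the first two components and in full d),
    and the full cross-target mean-Hamming matrix.
    """
    if len(targets) != len(sample_blocks):
        raise AlignmentShapeError("one sample block required per target")
    if any(block.M == 0 for block in sample_blocks):
        raise ValueError("empty sample block")
    n_t = len(targets)
    target_ids = target_ids or [f"target_{t}" for t in range(n_t)]
    records: list[TargetRecord] = []
    cross = np.zeros((n_t, n_t))
    for t, ((seq_t, y_t), block) in enumerate(zip(targets, sample_blocks)):
        seq_t = np.asarray(seq_t, dtype=np.int64)
        y_t = np.asarray(y_t, dtype=float)
        ham = np.array([hamming_fraction(block.data[m], seq_t) for m in range(block.M)])
        if basis is not None:
            Ys = project(basis, block)
            diffs = Ys - y_t[None, : Ys.shape[1]]
            eu_full = float(np.linalg.norm(diffs, axis=1).mean())
            k2 = min(2, diffs.shape[1])
            eu_pc2 = float(np.linalg.norm(diffs[:, :k2], axis=1).mean())
        else:
            eu_full = eu_pc2 = float("nan")
        records.append(
            TargetRecord(
                target_id=target_ids[t],
                hamming_mean=float(ham.mean()),
                hamming_sd=float(ham.std()),
                euclidean_pc2_mean=eu_pc2,
                euclidean_full_mean=eu_full,
            )
        )
        for u, (seq_u, _) in enumerate(targets):
            seq_u = np.asarray(seq_u, dtype=np.int64)
            cross[t, u] = float(
                np.mean(block.data != seq_u[None, :])
            )
    return ConditioningReport(targets=records, cross_hamming=cross)
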