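"""PCA embedding of one-hot encoded alignments and the feature-vector density.

Each sequence is one-hot encoded into a binary vector of length L*q; the
conditioning features y are the coordinates of that vector on the top-d
principal axes of the (column-centered) one-hot matrix of the training MSA.
A single full-covariance Gaussian models the marginal density P(y) of the
conditioning vectors; it only enters joint probabilities and mutational
scores, never the conditional sequence model itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .alignment import Alignment, SequenceWeights
from .errors import AlignmentShapeError, ParameterError

__all__ = [
    "PCABasis",
    "FeatureDensity",
    "one_hot",
    "decode_one_hot",
    "fit_pca",
    "project",
    "fit_feature_density",
    "log_density",
]


@dataclass(frozen=True)
class PCABasis:
    """Column mean and top-d orthonormal axes of the one-hot space."""

    mean: np.ndarray            # (L*q,)
    components: np.ndarray      # (d, L*q), orthonormal rows
    explained_variance: np.ndarray  # (d,), nonincreasing
    L: int
    q: int

    @property
    def d(self) -> int:
        return self.components.shape[0]


@dataclass(frozen=True)
class FeatureDensity:
    """Full-covariance Gaussian model of the conditioning vectors."""

    mean: np.ndarray        # (d,)
    covariance: np.ndarray  # (d, d), symmetric positive definite
    shrinkage: float

    @property
    def d(self) -> int:
        return self.mean.shape[0]


def one_hot(aln: Alignment) -> np.ndarray:
    """M x (L*q) binary matrix; entry (m, i*q + a) = 1 iff a_i^m = a."""
    M, L = aln.data.shape
    q = aln.alphabet.q
    X = np.zeros((M, L * q))
    X[np.arange(M)[:, None], np.arange(L) * q + aln.data] = 1.0
    return X


def _encode_rows(data: np.ndarray, q: int) -> np.ndarray:
    M, L = data.shape
    X = np.zeros((M, L * q))
    X[np.arange(M)[:, None], np.arange(L) * q + data] = 1.0
    return X


def decode_one_hot(X: np.ndarray, L: int, q: int) -> np.ndarray:
    """Invert :func:`one_hot`: argmax within each length-q block."""
    return X.reshape(-1, L, q).argmax(axis=2)


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|entry| of each axis positive."""
    out = components.copy()
    for r in range(out.shape[0]):
        k = np.argmax(np.abs(out[r]))
        if out[r, k] < 0:
            out[r] = -out[r]
    return out


def fit_pca(
    aln: Alignment,
    d: int,
    weights: SequenceWeights | None = None,
) -> PCABasis:
    """Fit the top-d principal axes of the centered one-hot matrix.

    By default the PCA is unweighted (plain SVD of the centered matrix).
    When ``weights`` is given, means and the covariance are computed under
    the normalized sequence weights (rows scaled by sqrt(w) after weighted
    centering).
    """
    M, L = aln.data.shape
    q = aln.alphabet.q
    if not (1 <= d <= min(M, L * q)):
        raise ParameterError(f"d={d} out of range [1, min(M, L*q)={min(M, L * q)}]")
    X = one_hot(aln)
    if weights is None:
        mean = X.mean(axis=0)
        Xc = X - mean
        denom = max(M - 1, 1)
    else:
        wn = weights.weights / weights.weights.sum()
        mean = wn @ X
        Xc = (X - mean) * np.sqrt(wn)[:, None]
        denom = 1.0
    # economy SVD; d never exceeds min(M, L*q)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    components = _fix_signs(Vt[:d])
    explained = (s[:d] ** 2) / denom
    return PCABasis(mean=mean, components=components, explained_variance=explained, L=L, q=q)


def project(basis: PCABasis, seq_or_aln: np.ndarray | Alignment) -> np.ndarray:
    """Project sequences onto the basis: y = components @ (one_hot(a) - mean).

    Accepts a single integer sequence (returns a length-d vector) or an
    :class:`Alignment` / M x L integer matrix (returns M x d).
    """
    if isinstance(seq_or_aln, Alignment):
        data = seq_or_aln.data
        single = False
    else:
        data = np.asarray(seq_or_aln, dtype=np.int64)
        single = data.ndim == 1
        if single:
            data = data[None, :]
    if data.shape[1] != basis.L:
        raise AlignmentShapeError(
            f"sequence length {data.shape[1]} does not match basis L={basis.L}"
        )
    X = _encode_rows(data, basis.q)
    Y = (X - basis.mean) @ basis.components.T
    return Y[0] if single else Y


def fit_feature_density(Y: np.ndarray, shrinkage: float = 0.01) -> FeatureDensity:
    """Gaussian fit of the conditioning vectors with covariance shrinkage.

    The empirical covariance is shrunk toward a scaled identity,
    ``(1 - s) * Sigma + s * (tr(Sigma)/d) * I``, guaranteeing positive
    definiteness for small or collinear projection sets.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    M, d = Y.shape
    if M < 2:
        raise ParameterError("need at least 2 points to fit a feature density")
    if not (0.0 <= shrinkage < 1.0):
        raise ParameterError("shrinkage must be in [0, 1)")
    mean = Y.mean(axis=0)
    Sigma = np.cov(Y, rowvar=False, bias=False).reshape(d, d)
    scale = np.trace(Sigma) / d
    if scale <= 0:
        scale = 1e-8  # degenerate cloud: fall back to a tiny isotropic floor
    Sigma = (1 - shrinkage) * Sigma + shrinkage * scale * np.eye(d)
    # symmetrize against roundoff
    Sigma = (Sigma + Sigma.T) / 2
    if np.linalg.eigvalsh(Sigma).min() <= 0:
        Sigma = Sigma + 1e-10 * scale * np.eye(d)
    return FeatureDensity(mean=mean, covariance=Sigma, shrinkage=shrinkage)


def log_density(dens: FeatureDensity, y: np.ndarray) -> float:
    """Multivariate Gaussian log-density of a conditioning vector."""
    y = np.asarray(y, dtype=float)
    if y.shape != dens.mean.shape:
        raise AlignmentShapeError(
            f"feature vector shape {y.shape} does not match density d={dens.d}"
        )
    return float(
        sps.multivariate_normal.logpdf(y, mean=dens.mean, cov=dens.covariance)
    )
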