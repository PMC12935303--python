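"""Aligned-sequence containers, reweighting and frequency statistics.

The central object is :class:`Alignment`: an integer-encoded multiple
sequence alignment (MSA) of M rows and L columns over a q-letter alphabet
(by default the 20 amino acids plus the gap symbol, q = 21).  On top of it
this module provides the standard DCA preprocessing steps:

* identity-based sequence reweighting and the effective depth Meff,
* weighted, pseudocount-smoothed single-site and pairwise frequencies,
* two-site connected correlations C_ij(a, b) = f_ij(a, b) - f_i(a) f_j(b),
* Hamming fractions between aligned sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentShapeError, EmptyInputError, ParameterError

logger = logging.getLogger(__name__)

#: Canonical symbol order: gap first, then the 20 amino acids alphabetically.
DEFAULT_SYMBOLS = "-ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-standard residue codes mapped to the gap state on read.
AMBIGUOUS_RESIDUES = frozenset("BZXUOJ")


@dataclass(frozen=True)
class Alphabet:
    """Ordered residue alphabet with symbol <-> integer maps."""

    symbols: str = DEFAULT_SYMBOLS

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ParameterError("alphabet symbols must be unique")

    @property
    def q(self) -> int:
        return len(self.symbols)

    @property
    def gap_index(self) -> int:
        return self.symbols.index("-") if "-" in self.symbols else -1

    def index_of(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def symbol_of(self, index: int) -> str:
        return self.symbols[index]

    def encode(self, sequence: str, *, record_id: str = "?") -> np.ndarray:
        """Encode a string into integer indices; ambiguity codes become gaps."""
        out = np.empty(len(sequence), dtype=np.int64)
        n_ambiguous = 0
        for pos, ch in enumerate(sequence.upper()):
            if ch == ".":
                ch = "-"
            if ch not in self.symbols and ch in AMBIGUOUS_RESIDUES:
                n_ambiguous += 1
                ch = "-"
            try:
                out[pos] = self.symbols.index(ch)
            except ValueError as exc:
                raise ParameterError(
                    f"record {record_id!r}: unknown symbol {ch!r} at position {pos}"
                ) from exc
        if n_ambiguous:
            logger.warning(
                "record %r: %d ambiguous residue(s) mapped to gap", record_id, n_ambiguous
            )
        return out

    def decode(self, indices: Iterable[int]) -> str:
        return "".join(self.symbols[i] for i in indices)


@dataclass
class Alignment:
    """Integer-encoded MSA: M sequence ids and an M x L index matrix."""

    ids: list[str]
    data: np.ndarray
    alphabet: Alphabet = field(default_factory=Alphabet)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int64)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise AlignmentShapeError("alignment matrix must be M x L with M, L >= 1")
        if len(self.ids) != self.data.shape[0]:
            raise AlignmentShapeError("number of ids does not match number of rows")
        if self.data.min() < 0 or self.data.max() >= self.alphabet.q:
            raise ParameterError("alignment entries outside [0, q)")

    @property
    def M(self) -> int:
        return self.data.shape[0]

    @property
    def L(self) -> int:
        return self.data.shape[1]

    def sequence(self, m: int) -> str:
        return self.alphabet.decode(self.data[m])

    @classmethod
    def from_sequences(
        cls,
        sequences: Sequence[str],
        ids: Sequence[str] | None = None,
        alphabet: Alphabet | None = None,
    ) -> "Alignment":
        alphabet = alphabet or Alphabet()
        if not sequences:
            raise EmptyInputError("no sequences given")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise AlignmentShapeError(f"unequal sequence lengths: {sorted(lengths)}")
        ids = list(ids) if ids is not None else [f"seq_{i}" for i in range(len(sequences))]
        data = np.stack(
            [alphabet.encode(s, record_id=i) for s, i in zip(sequences, ids)]
        )
        return cls(ids=ids, data=data, alphabet=alphabet)


@dataclass(frozen=True)
class SequenceWeights:
    """Per-sequence weights w_m = 1 / |{m': identity(m, m') >= threshold}|."""

    weights: np.ndarray
    similarity_threshold: float

    @property
    def meff(self) -> float:
        """Effective number of sequences, Meff = sum_m w_m."""
        return float(self.weights.sum())


@dataclass(frozen=True)
class FrequencyStats:
    """Single-site and pairwise frequencies of an alignment.

    ``f1`` has shape (L, q); ``f2`` has shape (P, q, q) with one block per
    unordered column pair listed in ``pairs`` (P = L(L-1)/2, i < j).
    """

    f1: np.ndarray
    f2: np.ndarray
    pairs: np.ndarray
    pseudocount: float
    weighted: bool

    @property
    def L(self) -> int:
        return self.f1.shape[0]

    @property
    def q(self) -> int:
        return self.f1.shape[1]


def read_fasta_alignment(path: str | Path, alphabet: Alphabet | None = None) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    '.' is treated as a gap; ambiguity codes (B, Z, X, U, O, J) are mapped to
    the gap state with a logged warning.  Unequal row lengths raise
    :class:`AlignmentShapeError` naming the offending record.
    """
    alphabet = alphabet or Alphabet()
    ids: list[str] = []
    seqs: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        seqs.append(str(record.seq))
    if not ids:
        raise EmptyInputError(f"no FASTA records in {path}")
    L = len(seqs[0])
    for rid, s in zip(ids, seqs):
        if len(s) != L:
            raise AlignmentShapeError(
                f"record {rid!r} has length {len(s)}, expected {L}"
            )
    return Alignment.from_sequences(seqs, ids=ids, alphabet=alphabet)


def write_fasta(aln: Alignment, path: str | Path, width: int = 60) -> None:
    """Write an alignment as FASTA, wrapping sequence lines at ``width``."""
    records = [
        SeqRecord(Seq(aln.sequence(m)), id=aln.ids[m], description="")
        for m in range(aln.M)
    ]
    writer_path = Path(path)
    with writer_path.open("w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def _identity_counts(data: np.ndarray, threshold: float, block: int = 1024) -> np.ndarray:
    """Number of neighbors (incl. self) with fractional identity >= threshold."""
    M, L = data.shape
    q = int(data.max()) + 1
    # one-hot Gram matrix gives pairwise match counts
    X = np.zeros((M, L * q), dtype=np.float32)
    X[np.arange(M)[:, None], np.arange(L) * q + data] = 1.0
    min_matches = threshold * L
    counts = np.empty(M, dtype=np.int64)
    for start in range(0, M, block):
        stop = min(start + block, M)
        matches = X[start:stop] @ X.T
        counts[start:stop] = (matches >= min_matches - 1e-9).sum(axis=1)
    return counts


def compute_weights(aln: Alignment, similarity_threshold: float = 0.8) -> SequenceWeights:
    """Standard DCA reweighting: w_m is the reciprocal neighborhood size.

    A sequence's neighborhood contains every sequence (itself included) whose
    fractional identity to it is at least ``similarity_threshold``; gap-gap
    matches count as matches.
    """
    if not (0.0 < similarity_threshold <= 1.0):
        raise ParameterError("similarity_threshold must be in (0, 1]")
    counts = _identity_counts(aln.data, similarity_threshold)
    return SequenceWeights(
        weights=1.0 / counts, similarity_threshold=similarity_threshold
    )


def effective_depth_fraction(aln: Alignment, similarity_threshold: float = 0.8) -> float:
    """Meff / M: the fraction of effectively unique sequences."""
    return compute_weights(aln, similarity_threshold).meff / aln.M


def pair_list(L: int) -> np.ndarray:
    """All unordered column pairs (i, j) with i < j, in lexicographic order."""
    return np.array([(i, j) for i in range(L) for j in range(i + 1, L)], dtype=np.int64)


def frequencies(
    aln: Alignment,
    weights: SequenceWeights | None = None,
    pseudocount: float = 0.0,
) -> FrequencyStats:
    """Weighted, pseudocount-smoothed single and pairwise frequencies.

    With mixing weight ``alpha = pseudocount``::

        f1[i, a] = (1 - alpha) * sum_m w_m 1[a_i^m = a] / W + alpha / q
        f2[i, j, a, b] analogously with alpha / q**2
    """
    if pseudocount < 0:
        raise ParameterError("pseudocount must be >= 0")
    M, L = aln.data.shape
    q = aln.alphabet.q
    w = weights.weights if weights is not None else np.ones(M)
    wn = w / w.sum()
    # per-column one-hot indicators, weighted once on the left factor
    onehot = np.zeros((M, L, q))
    onehot[np.arange(M)[:, None], np.arange(L), aln.data] = 1.0
    f1 = np.einsum("m,mlq->lq", wn, onehot)
    pairs = pair_list(L)
    f2 = np.empty((len(pairs), q, q))
    weighted_onehot = onehot * wn[:, None, None]
    for p, (i, j) in enumerate(pairs):
        f2[p] = weighted_onehot[:, i, :].T @ onehot[:, j, :]
    alpha = pseudocount
    f1 = (1 - alpha) * f1 + alpha / q
    f2 = (1 - alpha) * f2 + alpha / q**2
    return FrequencyStats(
        f1=f1, f2=f2, pairs=pairs, pseudocount=pseudocount, weighted=weights is not None
    )


def connected_correlations(stats: FrequencyStats) -> np.ndarray:
    """Two-site connected correlations C_ij(a, b) = f_ij(a, b) - f_i(a) f_j(b).

    Returns an array of shape (P, q, q) aligned with ``stats.pairs``.
    """
    C = np.empty_like(stats.f2)
    for p, (i, j) in enumerate(stats.pairs):
        C[p] = stats.f2[p] - np.outer(stats.f1[i], stats.f1[j])
    return C


def hamming_fraction(a: np.ndarray | Sequence[int], b: np.ndarray | Sequence[int]) -> float:
    """Fraction of positions at which two equal-length sequences differ."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise AlignmentShapeError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(a != b))


def export_correlations_tsv(stats: FrequencyStats, path: str | Path, alphabet: Alphabet | None = None) -> None:
    """Write connected correlations as TSV (i, j, a, b, C_ij) with 0-based columns."""
    alphabet = alphabet or Alphabet()
    C = connected_correlations(stats)
    with Path(path).open("w") as fh:
        fh.write("i\tj\ta\tb\tC_ij\n")
        for p, (i, j) in enumerate(stats.pairs):
            for a in range(stats.q):
                for b in range(stats.q):
                    fh.write(
                        f"{i}\t{j}\t{alphabet.symbol_of(a)}\t{alphabet.symbol_of(b)}\t"
                        f"{C[p, a, b]:.10g}\n"
                    )
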