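"""In-silico deep mutational scanning and benchmarking against experiments.

A single-residue substitution a_i -> b_i is scored by the change in the
model's joint log-probability,

    Delta_E(a_i -> b_i) = -log [ P(mutant, y_tilde) / P(wild type, y) ],

where y and y_tilde are the feature-space (PCA) projections of the wild
type and the mutant.  Lower Delta_E means the mutant is more probable under
the model, which is the standard proxy for higher fitness; rank correlation
against experimental scans is therefore computed on -Delta_E.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .alignment import Alphabet
from .errors import (
    CoordinateMappingError,
    InsufficientOverlapError,
    ParameterError,
)
from .features import FeatureDensity, PCABasis, log_density, project
from .model import ModelParams, sequence_log_prob

logger = logging.getLogger(__name__)

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True)
class Mutation:
    """A single substitution at a 0-based alignment column."""

    column: int
    wt_symbol: str
    mut_symbol: str

    def label(self) -> str:
        return f"{self.wt_symbol}{self.column}{self.mut_symbol}"


@dataclass
class MutationScoreTable:
    """Per-substitution Delta_E values and mutant feature vectors."""

    table: pd.DataFrame  # columns: mutation, column, wt, mut, delta_E, y_mut_*
    wild_type_id: str
    include_density_term: bool

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def mutation_delta_energy(
    params: ModelParams,
    density: FeatureDensity | None,
    basis: PCABasis | None,
    wt: np.ndarray,
    mutation: Mutation,
    include_density_term: bool = True,
) -> tuple[float, np.ndarray]:
    """Delta_E of one substitution and the mutant's reprojected feature vector.

    The mutant sequence is rebuilt, reprojected onto the PCA basis (so
    y_tilde differs from y), and scored as the negative joint log-probability
    ratio.  With ``include_density_term=False`` the P(y) factor is dropped
    and conditional log-probabilities are compared instead.
    """
    wt = np.asarray(wt, dtype=np.int64)
    alphabet = params.alphabet
    col = mutation.column
    if not (0 <= col < params.L):
        raise ParameterError(f"column {col} out of range for L={params.L}")
    if alphabet.symbol_of(wt[col]) != mutation.wt_symbol:
        raise CoordinateMappingError(
            f"column {col}: wild type has {alphabet.symbol_of(wt[col])!r}, "
            f"mutation expects {mutation.wt_symbol!r}"
        )
    mutant = wt.copy()
    mutant[col] = alphabet.index_of(mutation.mut_symbol)
    if basis is not None:
        y_wt = project(basis, wt)
        y_mut = project(basis, mutant)
    else:
        y_wt = np.zeros(params.d)
        y_mut = np.zeros(params.d)
    if mutation.mut_symbol == mutation.wt_symbol:
        return 0.0, y_mut
    lp_wt = sequence_log_prob(params, wt, y_wt)
    lp_mut = sequence_log_prob(params, mutant, y_mut)
    if include_density_term and density is not None:
        lp_wt += log_density(density, y_wt)
        lp_mut += log_density(density, y_mut)
    return float(-(lp_mut - lp_wt)), y_mut


def full_scan(
    params: ModelParams,
    density: FeatureDensity | None,
    basis: PCABasis | None,
    wt: np.ndarray,
    include_density_term: bool = True,
    allow_gap_substitutions: bool = False,
    wild_type_id: str = "wt",
) -> MutationScoreTable:
    """Score every single-residue substitution of the wild type.

    By default substitutions run over the 19 non-wild-type amino acids
    (no mutation to gap), giving L*19 rows; with gap substitutions enabled,
    L*(q-1) rows.
    """
    wt = np.asarray(wt, dtype=np.int64)
    alphabet = params.alphabet
    gap = alphabet.gap_index
    rows = []
    d = params.d
    for col in range(params.L):
        wt_sym = alphabet.symbol_of(wt[col])
        for b in range(params.q):
            if b == wt[col]:
                continue
            if not allow_gap_substitutions and b == gap:
                continue
            mut = Mutation(column=col, wt_symbol=wt_sym, mut_symbol=alphabet.symbol_of(b))
            dE, y_mut = mutation_delta_energy(
                params, density, basis, wt, mut, include_density_term
            )
            row = {
                "mutation": f"{wt_sym}{col}{mut.mut_symbol}",
                "column": col,
                "wt": wt_sym,
                "mut": mut.mut_symbol,
                "delta_E": dE,
            }
            for a in range(d):
                row[f"y_mut_{a + 1}"] = y_mut[a]
            rows.append(row)
    return MutationScoreTable(
        table=pd.DataFrame(rows),
        wild_type_id=wild_type_id,
        include_density_term=include_density_term,
    )


def map_mutation_coordinates(
    mutation: str,
    wt_row: np.ndarray,
    alphabet: Alphabet | None = None,
    offset: int = 0,
) -> Mutation:
    """Map a mutation in ungapped reference numbering onto alignment columns.

    ``mutation`` is of the form "A42G" (wild-type symbol, 1-based ungapped
    position, mutant symbol); ``offset`` shifts the reference numbering
    (position - offset is the 1-based index into the ungapped wild type).
    The wild-type symbol is cross-checked against the alignment row.
    """
    alphabet = alphabet or Alphabet()
    m = _MUTATION_RE.match(mutation.strip())
    if m is None:
        raise CoordinateMappingError(f"malformed mutation {mutation!r}")
    wt_sym, pos_str, mut_sym = m.group(1).upper(), m.group(2), m.group(3).upper()
    pos = int(pos_str) - offset
    wt_row = np.asarray(wt_row, dtype=np.int64)
    gap = alphabet.gap_index
    non_gap_cols = np.where(wt_row != gap)[0]
    if not (1 <= pos <= len(non_gap_cols)):
        raise CoordinateMappingError(
            f"position {pos} outside the {len(non_gap_cols)}-residue ungapped wild type"
        )
    col = int(non_gap_cols[pos - 1])
    actual = alphabet.symbol_of(wt_row[col])
    if actual != wt_sym:
        raise CoordinateMappingError(
            f"position {pos} (column {col}): wild type has {actual!r}, "
            f"mutation says {wt_sym!r}"
        )
    return Mutation(column=col, wt_symbol=wt_sym, mut_symbol=mut_sym)


def parse_dms_tsv(path: str | Path) -> pd.DataFrame:
    """Read an experimental DMS table: header "mutation<TAB>score".

    Malformed rows are skipped with a logged count.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"mutation": str})
    if "mutation" not in raw.columns or "score" not in raw.columns:
        raise ParameterError("DMS table must have columns 'mutation' and 'score'")
    ok = raw["mutation"].astype(str).str.match(_MUTATION_RE) & pd.to_numeric(
        raw["score"], errors="coerce"
    ).notna()
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("skipped %d malformed DMS rows", n_skipped)
    out = raw[ok].copy()
    out["score"] = out["score"].astype(float)
    out.attrs["n_skipped"] = n_skipped
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class SpearmanBenchmark:
    rho: float
    n_matched: int
    n_unmatched: int
    n_skipped: int


def spearman_vs_experiment(
    table: MutationScoreTable,
    dms: pd.DataFrame,
    wt_row: np.ndarray,
    alphabet: Alphabet | None = None,
    offset: int = 0,
) -> SpearmanBenchmark:
    """Spearman rank correlation between -Delta_E and experimental fitness.

    Experimental rows are mapped from ungapped reference numbering to
    alignment columns, joined on (column, mutant symbol), and correlated
    with average ranks for ties; positive rho means the model orders
    mutations like the experiment.
    """
    alphabet = alphabet or Alphabet()
    mapped_rows = []
    n_unmatched = 0
    for _, row in dms.iterrows():
        try:
            mut = map_mutation_coordinates(row["mutation"], wt_row, alphabet, offset)
        except CoordinateMappingError:
            n_unmatched += 1
            continue
        mapped_rows.append(
            {"column": mut.column, "mut": mut.mut_symbol, "score": row["score"]}
        )
    if not mapped_rows:
        raise InsufficientOverlapError("no experimental mutations could be mapped")
    mapped = pd.DataFrame(mapped_rows)
    joined = mapped.merge(table.table[["column", "mut", "delta_E"]], on=["column", "mut"])
    n_unmatched += len(mapped) - len(joined)
    if len(joined) < 3:
        raise InsufficientOverlapError(
            f"only {len(joined)} matched mutations; need at least 3"
        )
    rho = float(spearmanr(-joined["delta_E"], joined["score"]).statistic)
    return SpearmanBenchmark(
        rho=rho,
        n_matched=len(joined),
        n_unmatched=n_unmatched,
        n_skipped=int(dms.attrs.get("n_skipped", 0)),
    )
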