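"""Binary community matrices and the checkerboard (C-score) statistic.

A community is represented as a binary site-by-species occupancy matrix.
For each species pair (i, j) the number of *checkerboard units* is

    C_ij = (r_i - X_ij) * (r_j - X_ij)

where r_i and r_j are the species' total occurrence counts (column sums,
the Stone & Roberts convention) and X_ij is the number of sites occupied
by both.  The normalized C-score averages C_ij over all P = S(S-1)/2
species pairs and N = n(n-1)/2 site pairs:

    Cn = sum_{i<j} C_ij / (P * N)

Cn is 0 when every pair fully co-occurs and reaches 1 for a perfect
two-species checkerboard ([[1,0],[0,1]]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PresenceAbsenceMatrix",
    "PairCheckerboard",
    "CScoreResult",
    "read_occurrence",
    "checkerboard_units",
    "c_score",
]


class OccurrenceFormatError(ValueError):
    """Malformed occurrence table (duplicate ids, non-numeric cells)."""


class InsufficientDataError(ValueError):
    """Too few sites or species for a pairwise co-occurrence statistic."""


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    """Binary site x species occupancy matrix.

    Sites are rows, species are columns.  Cells are exactly 0 or 1.
    """

    site_ids: tuple
    species_ids: tuple
    cells: np.ndarray

    def __post_init__(self):
        cells = np.asarray(self.cells)
        if cells.ndim != 2:
            raise OccurrenceFormatError("cells must be a 2-D array")
        if not np.isin(cells, (0, 1)).all():
            raise OccurrenceFormatError("cells must contain only 0 and 1")
        object.__setattr__(self, "cells", cells.astype(np.int8))
        object.__setattr__(self, "site_ids", tuple(self.site_ids))
        object.__setattr__(self, "species_ids", tuple(self.species_ids))
        if len(set(self.site_ids)) != len(self.site_ids):
            raise OccurrenceFormatError("duplicate site ids")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise OccurrenceFormatError("duplicate species ids")
        if cells.shape != (len(self.site_ids), len(self.species_ids)):
            raise OccurrenceFormatError(
                f"cells shape {cells.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.species_ids)} species"
            )

    @property
    def n(self) -> int:
        """Number of sites (replicate plots)."""
        return len(self.site_ids)

    @property
    def S(self) -> int:
        """Number of species."""
        return len(self.species_ids)

    @property
    def row_sums(self) -> np.ndarray:
        """Per-site richness."""
        return self.cells.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        """Per-species occurrence totals."""
        return self.cells.sum(axis=0)

    def species_index(self, species) -> int:
        try:
            return self.species_ids.index(species)
        except ValueError:
            raise KeyError(f"species {species!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cells, index=list(self.site_ids), columns=list(self.species_ids)
        )

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("site").to_csv(path)


@dataclass(frozen=True)
class PairCheckerboard:
    """Checkerboard units for one species pair."""

    species_i: object
    species_j: object
    r_i: int
    r_j: int
    X_ij: int
    C_ij: int

    def __post_init__(self):
        if not (0 <= self.X_ij <= min(self.r_i, self.r_j)):
            raise ValueError("co-occurrence count exceeds an occurrence total")
        if self.C_ij < 0:
            raise ValueError("checkerboard units cannot be negative")


@dataclass(frozen=True)
class CScoreResult:
    """Observed normalized C-score with its per-pair decomposition."""

    pair_scores: tuple
    P: int
    N: int
    Cn: float

    def to_dict(self) -> dict:
        return {
            "Cn": self.Cn,
            "P": self.P,
            "N": self.N,
            "pairs": [
                {
                    "i": p.species_i,
                    "j": p.species_j,
                    "r_i": p.r_i,
                    "r_j": p.r_j,
                    "X": p.X_ij,
                    "C": p.C_ij,
                }
                for p in self.pair_scores
            ],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def read_occurrence(path, binarize_threshold: float = 0.0) -> PresenceAbsenceMatrix:
    """Read a site x species abundance table and binarize it.

    The first CSV column holds site ids; the header row holds species ids.
    A cell becomes present (1) when its abundance is strictly greater than
    ``binarize_threshold`` (default 0, so any positive abundance counts).
    """
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        raise OccurrenceFormatError(f"duplicate site id in {path}")
    if df.columns.has_duplicates:
        raise OccurrenceFormatError(f"duplicate species id in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise OccurrenceFormatError(f"non-numeric cell in {path}: {exc}") from None
    if np.isnan(values).any():
        raise OccurrenceFormatError(f"non-numeric or missing cell in {path}")
    cells = (values > binarize_threshold).astype(np.int8)
    return PresenceAbsenceMatrix(
        site_ids=tuple(df.index), species_ids=tuple(df.columns), cells=cells
    )


def checkerboard_units(
    mat: PresenceAbsenceMatrix, i, j, exclusive_counts: bool = False
) -> PairCheckerboard:
    """Checkerboard units C_ij for one species pair.

    With the default convention r_i is species i's total occurrence count.
    ``exclusive_counts=True`` instead counts occurrences *without* the
    partner species (r_i - X_ij) before the subtraction, a stricter variant
    that double-discounts co-occurrence; it is provided for comparison only.
    """
    if i == j:
        raise ValueError("checkerboard units need two distinct species")
    ci = mat.species_index(i)
    cj = mat.species_index(j)
    col_i = mat.cells[:, ci]
    col_j = mat.cells[:, cj]
    x = int((col_i & col_j).sum())
    r_i = int(col_i.sum())
    r_j = int(col_j.sum())
    if exclusive_counts:
        # each factor floored at 0: a pair cannot checkerboard "negatively"
        c = max(r_i - 2 * x, 0) * max(r_j - 2 * x, 0)
    else:
        c = (r_i - x) * (r_j - x)
    return PairCheckerboard(species_i=i, species_j=j, r_i=r_i, r_j=r_j, X_ij=x, C_ij=c)


def c_score(mat: PresenceAbsenceMatrix, exclusive_counts: bool = False) -> CScoreResult:
    """Normalized C-score over all species pairs.

    Cn = sum_{i<j} C_ij / (P * N) with P = S(S-1)/2 species pairs and
    N = n(n-1)/2 site pairs.
    """
    if mat.S < 2 or mat.n < 2:
        raise InsufficientDataError(
            f"need >=2 sites and >=2 species, got n={mat.n}, S={mat.S}"
        )
    pairs = []
    total = 0
    for a in range(mat.S):
        for b in range(a + 1, mat.S):
            pc = checkerboard_units(
                mat,
                mat.species_ids[a],
                mat.species_ids[b],
                exclusive_counts=exclusive_counts,
            )
            pairs.append(pc)
            total += pc.C_ij
    P = mat.S * (mat.S - 1) // 2
    N = mat.n * (mat.n - 1) // 2
    return CScoreResult(pair_scores=tuple(pairs), P=P, N=N, Cn=total / (P * N))


def c_score_value(cells: np.ndarray) -> float:
    """Fast normalized C-score on a raw 0/1 array (sites x species).

    Vectorized equivalent of :func:`c_score` used in null-model loops.
    """
    cells = np.asarray(cells, dtype=np.int64)
    n, S = cells.shape
    r = cells.sum(axis=0)
    X = cells.T @ cells
    D = r[:, None] - X
    iu = np.triu_indices(S, k=1)
    total = (D[iu] * D.T[iu]).sum()
    P = S * (S - 1) // 2
    N = n * (n - 1) // 2
    return float(total) / (P * N)
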