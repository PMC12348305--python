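"""Fixed-fixed null models for binary community matrices.

Both samplers preserve every row sum (per-site richness) and column sum
(per-species occurrence total) of the observed matrix exactly — the
"fixed-fixed" constraint, which is conservative against type I errors in
co-occurrence tests.

Two samplers are provided:

* ``trialswap``: a sequential Markov chain.  Each step draws a random
  2x2 submatrix and, if it is a checkerboard, flips it; otherwise the
  step is a no-op (the "trial" that makes the chain's stationary
  distribution uniform over admissible matrices).  Samples are taken
  after a burn-in and then every ``thin`` steps.
* ``quasiswap``: each sample is built independently.  A random integer
  contingency table with the target margins is drawn, repair moves
  (adding a checkerboard pattern to a 2x2 submatrix whenever it reduces
  excess counts) are applied until the table is binary, and ``thin``
  trial swaps then mix the result.  The mixing step matters: the bare
  fill-and-repair construction is measurably non-uniform over the
  admissible matrices, and the trailing swaps (the "swaps between
  samples" of the reference protocol) restore uniformity while keeping
  samples mutually independent.

The standardized effect size compares the observed normalized C-score to
the null distribution: z = (Cn - mu) / sigma, two-tailed significant at
|z| > 1.96.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .occurrence import CScoreResult, PresenceAbsenceMatrix, c_score_value

__all__ = [
    "NullModelConfig",
    "NullDistribution",
    "SESResult",
    "trialswap_step",
    "sample_null_trialswap",
    "sample_null_quasiswap",
    "build_null_distribution",
    "ses_test",
    "cscore_ses",
]


class InfeasibleMarginsError(ValueError):
    """No binary matrix realizes the requested row/column sums."""


class DegenerateNullError(ValueError):
    """Null distribution has zero spread (single admissible matrix)."""


@dataclass(frozen=True)
class NullModelConfig:
    """Configuration of the fixed-fixed randomization.

    ``burn_in`` applies to the sequential trialswap sampler only.
    ``thin`` is the swap count between sequential trialswap samples and,
    for quasiswap, the number of mixing swaps applied within each
    independently constructed sample.
    """

    method: str = "quasiswap"
    n_null: int = 1000
    burn_in: int = 30_000
    thin: int = 30_000
    seed: int | None = None

    def __post_init__(self):
        if self.method not in ("quasiswap", "trialswap"):
            raise ValueError(f"unknown null-model method {self.method!r}")
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if self.burn_in < 0 or self.thin < 0:
            raise ValueError("burn_in and thin must be >= 0")


@dataclass(frozen=True)
class NullDistribution:
    """Null C-score sample with its summary moments (sample-SD sigma)."""

    scores: np.ndarray
    mu: float
    sigma: float

    @classmethod
    def from_scores(cls, scores, ddof: int = 1) -> "NullDistribution":
        scores = np.asarray(scores, dtype=float)
        sigma = float(scores.std(ddof=ddof)) if scores.size > 1 else 0.0
        return cls(scores=scores, mu=float(scores.mean()), sigma=sigma)


@dataclass(frozen=True)
class SESResult:
    """Standardized effect size verdict for an observed C-score."""

    observed_Cn: float
    z: float
    p_normal: float
    p_empirical: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "observed_Cn": self.observed_Cn,
            "z": self.z,
            "p_normal": self.p_normal,
            "p_empirical": self.p_empirical,
            "significant": self.significant,
        }


def _wrap_like(mat: PresenceAbsenceMatrix, cells: np.ndarray) -> PresenceAbsenceMatrix:
    return PresenceAbsenceMatrix(
        site_ids=mat.site_ids, species_ids=mat.species_ids, cells=cells
    )


def _trialswap_step_inplace(cells: np.ndarray, rng: np.random.Generator) -> bool:
    """One trial-swap attempt on a raw 0/1 array; True if a swap happened."""
    n, S = cells.shape
    r1, r2 = rng.choice(n, size=2, replace=False)
    c1, c2 = rng.choice(S, size=2, replace=False)
    a, b = cells[r1, c1], cells[r1, c2]
    c, d = cells[r2, c1], cells[r2, c2]
    if a == d and b == c and a != b:  # checkerboard submatrix
        cells[r1, c1], cells[r1, c2] = b, a
        cells[r2, c1], cells[r2, c2] = d, c
        return True
    return False


def trialswap_step(
    mat: PresenceAbsenceMatrix, rng: np.random.Generator
) -> PresenceAbsenceMatrix:
    """One trial swap: flip a random 2x2 checkerboard submatrix if drawn.

    Margins are conserved whether or not the drawn submatrix is swappable.
    """
    cells = mat.cells.copy()
    _trialswap_step_inplace(cells, rng)
    return _wrap_like(mat, cells)


def _trialswap_many(cells: np.ndarray, n_steps: int, rng: np.random.Generator) -> None:
    """Run many trial-swap steps in place (tight loop on python lists)."""
    if n_steps <= 0:
        return
    n, S = cells.shape
    grid = cells.tolist()
    rows = rng.integers(0, n, size=(2, n_steps)).tolist()
    cols = rng.integers(0, S, size=(2, n_steps)).tolist()
    r1s, r2s = rows
    c1s, c2s = cols
    for k in range(n_steps):
        i1, i2, j1, j2 = r1s[k], r2s[k], c1s[k], c2s[k]
        if i1 == i2 or j1 == j2:
            continue
        gi1, gi2 = grid[i1], grid[i2]
        a, b = gi1[j1], gi1[j2]
        c, d = gi2[j1], gi2[j2]
        if a == d and b == c and a != b:
            gi1[j1], gi1[j2] = b, a
            gi2[j1], gi2[j2] = d, c
    cells[:] = grid


def _has_swappable(cells: np.ndarray) -> bool:
    """Whether any 2x2 checkerboard submatrix exists."""
    X = cells.T.astype(np.int64) @ cells
    r = cells.sum(axis=0)
    # pair (i, j) swappable iff some site has i-only and some has j-only
    only = r[:, None] - X
    iu = np.triu_indices(cells.shape[1], k=1)
    return bool(((only[iu] > 0) & (only.T[iu] > 0)).any())


def sample_null_trialswap(
    mat: PresenceAbsenceMatrix, config: NullModelConfig
) -> list[PresenceAbsenceMatrix]:
    """Sequential fixed-fixed samples from the trial-swap Markov chain."""
    rng = np.random.default_rng(config.seed)
    cells = mat.cells.copy()
    if not _has_swappable(cells):
        warnings.warn(
            "matrix has no swappable 2x2 submatrix; all null samples equal input",
            stacklevel=2,
        )
        return [_wrap_like(mat, cells.copy()) for _ in range(config.n_null)]
    _trialswap_many(cells, config.burn_in, rng)
    samples = [_wrap_like(mat, cells.copy())]
    while len(samples) < config.n_null:
        _trialswap_many(cells, max(config.thin, 1), rng)
        samples.append(_wrap_like(mat, cells.copy()))
    return samples


def _gale_ryser_feasible(row_sums: np.ndarray, col_sums: np.ndarray) -> bool:
    """Gale-Ryser condition for a binary matrix with the given margins."""
    row_sums = np.sort(np.asarray(row_sums))[::-1]
    col_sums = np.asarray(col_sums)
    if row_sums.sum() != col_sums.sum():
        return False
    if row_sums.size and (row_sums.max() > col_sums.size):
        return False
    if (row_sums < 0).any() or (col_sums < 0).any():
        return False
    for k in range(1, row_sums.size + 1):
        lhs = row_sums[:k].sum()
        rhs = np.minimum(col_sums, k).sum()
        if lhs > rhs:
            return False
    return True


def _random_contingency_fill(
    row_sums: np.ndarray, col_sums: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Random nonnegative integer table with exact margins.

    Pairs a shuffled multiset of row labels with a multiset of column
    labels, which samples the two-way hypergeometric table distribution.
    """
    rows = np.repeat(np.arange(len(row_sums)), row_sums)
    cols = np.repeat(np.arange(len(col_sums)), col_sums)
    rng.shuffle(rows)
    table = np.zeros((len(row_sums), len(col_sums)), dtype=np.int64)
    np.add.at(table, (rows, cols), 1)
    return table


def _quasiswap_one(
    row_sums: np.ndarray,
    col_sums: np.ndarray,
    rng: np.random.Generator,
    mix_steps: int = 0,
) -> np.ndarray:
    """One independent quasiswap sample: random integer fill + repair.

    Repair move on a random 2x2 submatrix [[a, b], [c, d]]: replace with
    [[a-1, b+1], [c+1, d-1]] when a, d >= 1 and a + d - b - c >= 2, so the
    sum of squared entries never increases and excess counts drain away.
    ``mix_steps`` trailing trial swaps then erase the repair path's bias.
    """
    m = _random_contingency_fill(row_sums, col_sums, rng)
    nr, nc = m.shape
    while (m > 1).any():
        rr = rng.integers(0, nr, size=2048)
        r2 = rng.integers(0, nr, size=2048)
        cc = rng.integers(0, nc, size=2048)
        c2 = rng.integers(0, nc, size=2048)
        for i in range(2048):
            i1, i2, j1, j2 = rr[i], r2[i], cc[i], c2[i]
            if i1 == i2 or j1 == j2:
                continue
            a, b = m[i1, j1], m[i1, j2]
            c, d = m[i2, j1], m[i2, j2]
            if a > 0 and d > 0 and a + d - b - c >= 2:
                m[i1, j1] -= 1
                m[i2, j2] -= 1
                m[i1, j2] += 1
                m[i2, j1] += 1
            elif b > 0 and c > 0 and b + c - a - d >= 2:
                m[i1, j2] -= 1
                m[i2, j1] -= 1
                m[i1, j1] += 1
                m[i2, j2] += 1
            if not (m > 1).any():
                break
    m = m.astype(np.int8)
    _trialswap_many(m, mix_steps, rng)
    return m


def sample_null_quasiswap(
    mat: PresenceAbsenceMatrix, config: NullModelConfig
) -> list[PresenceAbsenceMatrix]:
    """Independent fixed-fixed samples via the quasiswap construction.

    Each sample uses its own RNG substream, so samples are mutually
    independent and the full set is reproducible from the single seed.
    """
    row_sums = mat.cells.sum(axis=1)
    col_sums = mat.cells.sum(axis=0)
    if not _gale_ryser_feasible(row_sums, col_sums):
        raise InfeasibleMarginsError("margins violate the Gale-Ryser condition")
    streams = np.random.SeedSequence(config.seed).spawn(config.n_null)
    out = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        out.append(
            _wrap_like(
                mat,
                _quasiswap_one(row_sums, col_sums, rng, mix_steps=config.thin),
            )
        )
    return out


def build_null_distribution(
    mat: PresenceAbsenceMatrix, config: NullModelConfig
) -> NullDistribution:
    """Sample null matrices and score each with the normalized C-score."""
    if config.method == "quasiswap":
        samples = sample_null_quasiswap(mat, config)
    else:
        samples = sample_null_trialswap(mat, config)
    scores = np.array([c_score_value(s.cells) for s in samples])
    return NullDistribution.from_scores(scores)


def ses_test(observed: CScoreResult, nulls: NullDistribution) -> SESResult:
    """Standardized effect size of the observed C-score against the null.

    z = (Cn - mu) / sigma.  The primary p-value is the two-tailed
    standard-normal tail mass; an empirical rank p-value (add-one
    corrected, mirroring the observed score about the null mean) is
    reported alongside.
    """
    if nulls.sigma <= 0:
        raise DegenerateNullError(
            "null distribution has zero standard deviation "
            "(margins admit a single configuration?)"
        )
    cn = observed.Cn
    z = (cn - nulls.mu) / nulls.sigma
    p_normal = float(2.0 * stats.norm.sf(abs(z)))
    mirrored = 2.0 * nulls.mu - cn
    lo, hi = min(cn, mirrored), max(cn, mirrored)
    extreme = int(((nulls.scores >= hi) | (nulls.scores <= lo)).sum())
    p_empirical = (1 + extreme) / (nulls.scores.size + 1)
    return SESResult(
        observed_Cn=cn,
        z=float(z),
        p_normal=min(p_normal, 1.0),
        p_empirical=float(p_empirical),
        significant=abs(z) > 1.96,
    )


def cscore_ses(
    mat: PresenceAbsenceMatrix, config: NullModelConfig
) -> tuple[SESResult, NullDistribution]:
    """Full co-occurrence test: observed C-score vs a fixed-fixed null."""
    from .occurrence import c_score

    observed = c_score(mat)
    nulls = build_null_distribution(mat, config)
    return ses_test(observed, nulls), nulls
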