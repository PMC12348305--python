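"""Functional trait space: aggregation, imputation, ordination, tests.

Six globally dominant plant functional traits span the table: total
canopy leaf area (LA), stem density (SD), seed mass (SM), height (H),
specific leaf area (SLA), and leaf nitrogen per dry mass (N).  Records
from heterogeneous sources are averaged per (species, source), gaps are
completed by regularized iterative PCA, species are ordinated by PCA on
standardized traits, and species separation is tested by one-way ANOVA
on PC scores and by PERMANOVA on the raw multivariate trait space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TRAITS",
    "TraitRecord",
    "PCAResult",
    "PermanovaResult",
    "aggregate_traits",
    "read_trait_records",
    "impute_iterative_pca",
    "pca_traits",
    "anova_pc_scores",
    "permanova",
]

TRAITS = ("LA", "SD", "SM", "H", "SLA", "N")


class TraitDataError(ValueError):
    """Malformed trait records (unknown trait code, non-numeric value)."""


class ImputationError(RuntimeError):
    """Iterative PCA completion failed to converge."""


class DegenerateDistanceError(ValueError):
    """All points identical; the distance matrix carries no signal."""


@dataclass(frozen=True)
class TraitRecord:
    """A single trait measurement attributed to a species and a source."""

    species: str
    source: str
    trait: str
    value: float

    def __post_init__(self):
        if self.trait not in TRAITS:
            raise TraitDataError(
                f"trait {self.trait!r} not in the six-trait set {TRAITS}"
            )
        try:
            object.__setattr__(self, "value", float(self.value))
        except (TypeError, ValueError):
            raise TraitDataError(f"non-numeric trait value {self.value!r}") from None


def read_trait_records(path) -> list[TraitRecord]:
    """Read long-format trait CSV {species, source, trait, value}."""
    df = pd.read_csv(path)
    required = {"species", "source", "trait", "value"}
    if not required.issubset(df.columns):
        raise TraitDataError(f"trait CSV must have columns {sorted(required)}")
    return [
        TraitRecord(str(r.species), str(r.source), str(r.trait), r.value)
        for r in df.itertuples()
    ]


def aggregate_traits(records) -> pd.DataFrame:
    """Mean trait value per (species, source) row; absent cells are NaN.

    Returns a DataFrame indexed by a (species, source) MultiIndex with the
    six trait columns.  Rows or columns with no observed value at all are
    dropped with a warning, since they cannot anchor imputation.
    """
    records = list(records)
    if not records:
        raise TraitDataError("no trait records supplied")
    long = pd.DataFrame(
        {
            "species": [r.species for r in records],
            "source": [r.source for r in records],
            "trait": [r.trait for r in records],
            "value": [r.value for r in records],
        }
    )
    table = (
        long.pivot_table(
            index=["species", "source"],
            columns="trait",
            values="value",
            aggfunc="mean",
        )
        .reindex(columns=list(TRAITS))
    )
    table.columns.name = None
    empty_rows = table.index[table.isna().all(axis=1)]
    if len(empty_rows):
        warnings.warn(f"dropping {len(empty_rows)} all-missing rows", stacklevel=2)
        table = table.drop(index=empty_rows)
    empty_cols = table.columns[table.isna().all(axis=0)]
    if len(empty_cols):
        warnings.warn(
            f"dropping all-missing trait columns {list(empty_cols)}", stacklevel=2
        )
        table = table.drop(columns=empty_cols)
    return table


def impute_iterative_pca(
    table: pd.DataFrame,
    ncomp: int = 3,
    regularized: bool = True,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> pd.DataFrame:
    """Complete missing trait cells by regularized iterative PCA.

    Columns are standardized; missing cells start at the column mean
    (zero on the standardized scale); each iteration reconstructs the
    table from its leading ``ncomp`` principal components — with singular
    values shrunk towards the noise floor when ``regularized`` — and
    overwrites only the missing cells, until the summed squared change of
    the imputed cells falls below ``tol`` (the usual stopping rule for
    iterative-PCA imputation).  Observed cells are returned bit-identical.
    """
    X = table.to_numpy(dtype=float)
    mask = np.isnan(X)
    if not mask.any():
        return table.copy()
    n, p = X.shape
    if not (1 <= ncomp < min(n, p)):
        raise ValueError(f"ncomp must be in [1, {min(n, p) - 1}], got {ncomp}")
    if mask.all(axis=1).any() or mask.all(axis=0).any():
        raise TraitDataError("a row or column has no observed value")

    col_mean = np.nanmean(X, axis=0)
    col_std = np.nanstd(X, axis=0, ddof=1)
    col_std[col_std == 0] = 1.0
    Z = (X - col_mean) / col_std
    Z[mask] = 0.0

    for _ in range(max_iter):
        center = Z.mean(axis=0)
        U, d, Vt = np.linalg.svd(Z - center, full_matrices=False)
        if regularized:
            # noise variance from the discarded components
            tail = d[ncomp:] ** 2
            sigma2 = tail.sum() / max((n - 1) * p - (n - 1) * ncomp, 1)
            shrunk = np.maximum(d[:ncomp] - sigma2 * (n - 1) / np.maximum(d[:ncomp], 1e-12), 0.0)
        else:
            shrunk = d[:ncomp]
        recon = (U[:, :ncomp] * shrunk) @ Vt[:ncomp] + center
        delta = float(((recon[mask] - Z[mask]) ** 2).sum())
        Z[mask] = recon[mask]
        if delta < tol:
            break
    else:
        raise ImputationError(f"no convergence in {max_iter} iterations (last step {delta:.2e})")

    out = Z * col_std + col_mean
    out[~mask] = X[~mask]  # observed cells untouched
    return pd.DataFrame(out, index=table.index, columns=table.columns)


@dataclass(frozen=True)
class PCAResult:
    """Scores, orthonormal loadings, and variance fractions per component."""

    scores: pd.DataFrame
    loadings: pd.DataFrame  # traits x components
    var_explained: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.var_explained)


def pca_traits(table: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of the column-standardized (correlation-scale) trait table.

    Traits carry incommensurable units, so each column is standardized
    before decomposition.  Zero-variance columns are dropped with a
    warning.  Loadings are sign-fixed so each component's largest-
    magnitude trait weight is positive.
    """
    if table.isna().any().any():
        raise TraitDataError("PCA requires a completed (gap-free) table")
    X = table.to_numpy(dtype=float)
    std = X.std(axis=0, ddof=1)
    keep = std > 0
    if not keep.all():
        dropped = list(table.columns[~keep])
        warnings.warn(f"dropping zero-variance columns {dropped}", stacklevel=2)
        X = X[:, keep]
    cols = list(table.columns[keep])
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    k = min(Z.shape[0] - 1, Z.shape[1])
    if n_components is not None:
        k = min(k, n_components)
    U, d, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic orientation: largest-magnitude loading positive
    for comp in range(k):
        lead = np.argmax(np.abs(Vt[comp]))
        if Vt[comp, lead] < 0:
            Vt[comp] *= -1
            U[:, comp] *= -1
    var = d**2 / (d**2).sum()
    scores = pd.DataFrame(
        (U[:, :k] * d[:k]),
        index=table.index,
        columns=[f"PC{c + 1}" for c in range(k)],
    )
    loadings = pd.DataFrame(
        Vt[:k].T, index=cols, columns=[f"PC{c + 1}" for c in range(k)]
    )
    return PCAResult(scores=scores, loadings=loadings, var_explained=var[:k])


def anova_pc_scores(scores: pd.DataFrame, species_labels) -> pd.DataFrame:
    """One-way ANOVA of each PC axis across species groups."""
    labels = np.asarray(species_labels)
    if len(labels) != len(scores):
        raise ValueError("labels and scores differ in length")
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two species groups")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        small = list(counts[counts < 2].index)
        raise ValueError(f"groups with fewer than two observations: {small}")
    rows = []
    for axis in scores.columns:
        samples = [scores.loc[labels == g, axis].to_numpy() for g in groups]
        f, p = stats.f_oneway(*samples)
        rows.append({"axis": axis, "F": float(f), "p": float(p)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PermanovaResult:
    """Pseudo-F partition of a distance matrix with a permutation p-value."""

    pseudo_F: float
    df_between: int
    df_within: int
    p_perm: float
    n_perm: int

    def to_dict(self) -> dict:
        return {
            "F": self.pseudo_F,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p": self.p_perm,
            "n_perm": self.n_perm,
        }


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    """Anderson's pseudo-F from squared distances.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums the same quantity
    within each group; F = (SS_among/df_a) / (SS_within/df_w).
    """
    n = len(labels)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_a = len(groups) - 1
    df_w = n - len(groups)
    return (ss_among / df_a) / (ss_within / df_w)


def permanova(
    table: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    standardize: bool = True,
) -> PermanovaResult:
    """PERMANOVA on Euclidean distances in raw multivariate trait space.

    Distances are Euclidean on column-standardized traits; the pseudo-F
    statistic partitions the squared-distance matrix among and within
    species; the p-value counts permuted statistics at least as large as
    the observed one under unrestricted relabeling, with the add-one
    correction p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    """
    if table.isna().any().any():
        raise TraitDataError("PERMANOVA requires a completed table")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels = np.asarray(groups)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    X = table.to_numpy(dtype=float)
    if standardize:
        std = X.std(axis=0, ddof=1)
        std[std == 0] = 1.0
        X = (X - X.mean(axis=0)) / std
    diff = X[:, None, :] - X[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    if np.allclose(d2, 0):
        raise DegenerateDistanceError("all points identical")
    f_obs = _pseudo_f(d2, labels, uniq)
    rng = np.random.default_rng(seed)
    count = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _pseudo_f(d2, perm, uniq) >= f_obs:
            count += 1
    n = len(labels)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        df_between=len(uniq) - 1,
        df_within=n - len(uniq),
        p_perm=(1 + count) / (n_perm + 1),
        n_perm=n_perm,
    )
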