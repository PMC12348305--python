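"""Diversity-productivity (DP) slope analysis.

Productivity (leaf litter mass, wood basal area increment, or fine-root
in-growth mass) is modelled against planted species richness treated as a
continuous covariate, with planting density as a categorical factor and —
for repeatedly measured tissues — year as a categorical factor.
Measurement units (trees or litter-trap stations) nested in replicate
blocks enter as random intercepts.  A flat DP slope (95% CI covering
zero) is read as absence of niche complementarity.

Wood production uses basal area increment (BAI), the cross-sectional
area of one annual growth ring: BAI_t = pi * (r_t^2 - r_{t-1}^2) with
r_t the cumulative stem radius through year t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "RingSeries",
    "DPFitResult",
    "bai_from_rings",
    "read_rings",
    "fit_dp_model",
    "slope_vs_zero",
]

TISSUES = ("leaf", "wood", "root")


class RingDataError(ValueError):
    """Invalid ring-width series (negative widths, non-consecutive years)."""


class SlopeEstimationError(ValueError):
    """DP slope cannot be estimated (e.g., a single richness level)."""


@dataclass(frozen=True)
class RingSeries:
    """Annual ring widths for one tree, ordered by calendar year."""

    tree_id: object
    years: tuple
    widths: tuple
    initial_radius: float = 0.0

    def __post_init__(self):
        years = tuple(int(y) for y in self.years)
        widths = tuple(float(w) for w in self.widths)
        if len(years) != len(widths):
            raise RingDataError("years and widths differ in length")
        if any(w < 0 for w in widths):
            raise RingDataError(f"negative ring width for tree {self.tree_id!r}")
        if any(b - a != 1 for a, b in zip(years, years[1:])):
            raise RingDataError("years must be strictly increasing and consecutive")
        if self.initial_radius < 0:
            raise RingDataError("initial radius must be >= 0")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "widths", widths)


def bai_from_rings(series: RingSeries) -> pd.Series:
    """Per-year basal area increment (mm^2/yr) from ring widths (mm).

    The cumulative radius after year t is initial_radius + sum of widths
    through t; BAI_t is the annulus area pi * (r_t^2 - r_{t-1}^2).
    """
    radii = series.initial_radius + np.cumsum(series.widths)
    prev = np.concatenate([[series.initial_radius], radii[:-1]])
    bai = np.pi * (radii**2 - prev**2)
    return pd.Series(bai, index=list(series.years), name=str(series.tree_id))


def read_rings(path) -> list[RingSeries]:
    """Read a long-format ring CSV {tree_id, year, width_mm} into series."""
    df = pd.read_csv(path)
    required = {"tree_id", "year", "width_mm"}
    if not required.issubset(df.columns):
        raise RingDataError(f"ring CSV must have columns {sorted(required)}")
    out = []
    for tree_id, grp in df.groupby("tree_id", sort=False):
        grp = grp.sort_values("year")
        out.append(
            RingSeries(
                tree_id=tree_id,
                years=tuple(grp["year"]),
                widths=tuple(grp["width_mm"]),
            )
        )
    return out


@dataclass(frozen=True)
class DPFitResult:
    """Type-III ANOVA rows, per-stratum diversity slopes, and model kind."""

    anova_rows: tuple  # of dicts {term, F, df_num, df_den, p}
    slopes: tuple  # of dicts {density, year, estimate, SE, CI95}
    model_kind: str  # "mixed" or "fixed-fallback"
    tissue: str
    df_method: str  # "residual" (flagged Satterthwaite fallback)
    diversity_slope: dict | None = None  # overall richness coefficient {estimate, SE, CI95}

    def anova_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.anova_rows))

    def to_dict(self) -> dict:
        return {
            "tissue": self.tissue,
            "model_kind": self.model_kind,
            "df_method": self.df_method,
            "anova": list(self.anova_rows),
            "slopes": list(self.slopes),
            "diversity_slope": self.diversity_slope,
        }


def _validate_table(table: pd.DataFrame, tissue: str) -> pd.DataFrame:
    if tissue not in TISSUES:
        raise ValueError(f"tissue must be one of {TISSUES}")
    sub = table[table["tissue"] == tissue].copy()
    if sub.empty:
        raise SlopeEstimationError(f"no rows for tissue {tissue!r}")
    if sub["richness"].nunique() < 2:
        raise SlopeEstimationError(
            "diversity slope needs at least two richness levels"
        )
    sub["block"] = sub["block"].astype(str)
    sub["density"] = sub["density"].astype(str)
    sub["unit_id"] = sub["unit_id"].astype(str)
    if "year" in sub.columns:
        sub["year"] = sub["year"].astype("Int64").astype(str)
    return sub


def _term_order(with_year: bool) -> list[str]:
    if with_year:
        return [
            "Diversity",
            "Density",
            "Year",
            "Diversity x Density",
            "Diversity x Year",
            "Density x Year",
            "Diversity x Density x Year",
        ]
    return ["Diversity", "Density", "Diversity x Density"]


def _match_term(exog_name: str) -> frozenset:
    """Canonical factor set of a design-matrix column name."""
    factors = []
    for piece in exog_name.split(":"):
        piece = piece.strip()
        if piece.startswith("C(") or "richness" in piece:
            if "density" in piece:
                factors.append("density")
            elif "year" in piece:
                factors.append("year")
            elif "richness" in piece:
                factors.append("richness")
    return frozenset(factors)


_TERM_FACTORS = {
    "Diversity": frozenset({"richness"}),
    "Density": frozenset({"density"}),
    "Year": frozenset({"year"}),
    "Diversity x Density": frozenset({"richness", "density"}),
    "Diversity x Year": frozenset({"richness", "year"}),
    "Density x Year": frozenset({"density", "year"}),
    "Diversity x Density x Year": frozenset({"richness", "density", "year"}),
}


def _anova_from_result(result, terms: list[str], df_den: float) -> list[dict]:
    """Joint Wald F test per model term, with the supplied denominator df.

    With sum-to-zero contrasts and a balanced design these Wald F values
    coincide with type-III sums-of-squares F tests.
    """
    exog_names = list(result.model.exog_names)
    params = np.asarray(result.params)[: len(exog_names)]
    cov = np.asarray(result.cov_params())[: len(exog_names), : len(exog_names)]
    rows = []
    for term in terms:
        want = _TERM_FACTORS[term]
        idx = [
            k
            for k, name in enumerate(exog_names)
            if name != "Intercept" and _match_term(name) == want
        ]
        if not idx:
            raise RuntimeError(f"no design columns matched term {term!r}")
        L = np.zeros((len(idx), len(exog_names)))
        for r, k in enumerate(idx):
            L[r, k] = 1.0
        est = L @ params
        vcv = L @ cov @ L.T
        fstat = float(est @ np.linalg.solve(vcv, est) / len(idx))
        p = float(stats.f.sf(fstat, len(idx), df_den))
        rows.append(
            {
                "term": term,
                "F": fstat,
                "df_num": len(idx),
                "df_den": float(df_den),
                "p": p,
            }
        )
    return rows


def _stratum_slopes(sub: pd.DataFrame, response: str) -> list[dict]:
    """Per (density, year) OLS diversity slope with 95% CI."""
    strata = ["density"] + (["year"] if "year" in sub.columns and sub["year"].notna().any() else [])
    slopes = []
    for key, grp in sub.groupby(strata, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        if grp["richness"].nunique() < 2:
            continue
        X = sm.add_constant(grp["richness"].astype(float))
        fit = sm.OLS(grp[response].astype(float), X).fit()
        est = float(fit.params["richness"])
        se = float(fit.bse["richness"])
        ci = fit.conf_int().loc["richness"]
        rec = {
            "density": key[0],
            "estimate": est,
            "SE": se,
            "CI95": [float(ci[0]), float(ci[1])],
        }
        rec["year"] = key[1] if len(key) > 1 else None
        slopes.append(rec)
    return slopes


def fit_dp_model(
    table: pd.DataFrame, tissue: str, log10_response: bool = False
) -> DPFitResult:
    """Fit the diversity-productivity model for one tissue.

    Fixed effects: richness (continuous) x density (categorical), crossed
    with year (categorical) for leaf and wood.  Random intercepts: units
    (trees or trap stations) nested in blocks.  Returns type-III Wald F
    tests; denominator df use the residual-df approximation (flagged in
    ``df_method``).  If the mixed fit fails or is singular, an ordinary
    least-squares model with block as a fixed term is fit instead and
    ``model_kind`` is set to ``"fixed-fallback"``.
    """
    sub = _validate_table(table, tissue)
    with_year = tissue in ("leaf", "wood") and sub["year"].nunique() > 1
    terms = _term_order(with_year)

    sub = sub.copy()
    if log10_response:
        if (sub["value"] <= 0).any():
            sub["value"] = np.log10(sub["value"] + 1.0)
        else:
            sub["value"] = np.log10(sub["value"])

    rhs = "richness * C(density, Sum)"
    if with_year:
        rhs += " * C(year, Sum)"
    formula = f"value ~ {rhs}"

    n_obs = len(sub)
    model_kind = "mixed"
    result = None
    # unique unit labels across blocks for the nesting
    sub["unit_in_block"] = sub["block"] + "/" + sub["unit_id"]
    # a unit variance component is identifiable only under repeated measures
    repeated = sub["unit_in_block"].duplicated().any()
    vc = {"unit": "0 + C(unit_in_block)"} if repeated else None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(
                formula,
                sub,
                groups=sub["block"],
                re_formula="1",
                vc_formula=vc,
            )
            mixed = md.fit(reml=True, method=["lbfgs", "cg"])
        singular = not np.isfinite(np.asarray(mixed.bse_fe)).all()
        if not mixed.converged or singular:
            raise RuntimeError("mixed model did not converge cleanly")
        result = mixed
        n_fe = len(mixed.fe_params)
        df_den = max(n_obs - n_fe, 1)
    except Exception:
        model_kind = "fixed-fallback"

    if model_kind == "fixed-fallback":
        ols_formula = formula + " + C(block, Sum)"
        result = smf.ols(ols_formula, sub).fit()
        df_den = float(result.df_resid)

    anova = _anova_from_result(result, terms, df_den)
    slopes = _stratum_slopes(sub if with_year else sub.drop(columns=["year"], errors="ignore"), "value")

    # richness main effect: the density-averaged diversity slope (sum coding)
    exog_names = list(result.model.exog_names)
    k = exog_names.index("richness")
    est = float(np.asarray(result.params)[k])
    se = float(np.asarray(result.bse)[k])
    tcrit = stats.t.ppf(0.975, df_den)
    diversity_slope = {
        "estimate": est,
        "SE": se,
        "CI95": [est - tcrit * se, est + tcrit * se],
    }
    return DPFitResult(
        anova_rows=tuple(anova),
        slopes=tuple(slopes),
        model_kind=model_kind,
        tissue=tissue,
        df_method="residual",
        diversity_slope=diversity_slope,
    )


def slope_vs_zero(fit: DPFitResult) -> list[dict]:
    """Mark each per-stratum diversity slope whose 95% CI contains zero."""
    if not fit.slopes:
        raise SlopeEstimationError("fit holds no stratum slopes")
    out = []
    for s in fit.slopes:
        lo, hi = s["CI95"]
        out.append({**s, "crosses_zero": bool(lo <= 0.0 <= hi)})
    return out
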