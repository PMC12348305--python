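"""Synthetic data generators emulating the three evidence streams.

Each generator is bit-reproducible from (spec, seed) and writes/returns
the same containers the analysis stages consume:

* ``gen_community`` — binary site x species matrices with controlled
  spatial structure (random, segregated, aggregated) at a target fill.
* ``gen_productivity`` — a balanced replacement-series common-garden
  design: 7 species mixtures x 3 planting densities x 3 blocks (63
  plots), with a specified diversity-productivity slope and variance
  components for blocks, measurement units, and residual noise.
* ``gen_traits`` — long-format trait records with per-species mean
  offsets, between-source noise, and missing-at-random gaps.

Helper design arithmetic (stems per hectare from grid spacing, forest
inventory plot area) also lives here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .occurrence import PresenceAbsenceMatrix
from .traits import TRAITS, TraitRecord

__all__ = [
    "SyntheticCommunitySpec",
    "SyntheticDPSpec",
    "SyntheticTraitSpec",
    "gen_community",
    "gen_productivity",
    "gen_traits",
    "stems_per_hectare",
    "fia_plot_area_m2",
    "SPECIES_POOL",
]

SPECIES_POOL = ("Pserotina", "Qrubra", "Cdentata")


def stems_per_hectare(spacing_m: float) -> int:
    """Planting density for a square grid with the given spacing.

    1 m -> 10000, 2 m -> 2500, 3 m -> 1111 stems per hectare.
    """
    if spacing_m <= 0:
        raise ValueError("spacing must be positive")
    return int(10_000 / spacing_m**2)


def fia_plot_area_m2(subplot_radius_m: float = 7.3, n_subplots: int = 4) -> float:
    """Total area of a forest-inventory plot of circular subplots (m^2)."""
    return n_subplots * math.pi * subplot_radius_m**2


@dataclass(frozen=True)
class SyntheticCommunitySpec:
    """Binary community with controlled co-occurrence structure.

    structure:
        random      independent Bernoulli(fill) occupancy
        segregated  species paired off; each pair shares a site pool but
                    occupies it exclusively (a classic checkerboard) with
                    probability ``effect`` per pool site
        aggregated  species share a preference for the same site subset

    Segregation is deliberately *pairwise* exclusion on shared site
    pools rather than a partition of sites among species: a partition
    only reshapes the margins, which a fixed-fixed null conditions away,
    whereas checkerboard pairs shift co-occurrence at fixed margins —
    the signal the C-score is built to see.
    """

    n_sites: int = 30
    n_species: int = 3
    structure: str = "random"
    fill: float = 0.3
    effect: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.structure not in ("random", "segregated", "aggregated"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if not (0.0 < self.fill < 1.0):
            raise ValueError("fill must be in (0, 1)")
        if not (0.0 <= self.effect <= 1.0):
            raise ValueError("effect must be in [0, 1]")
        if self.n_sites < 2 or self.n_species < 2:
            raise ValueError("need at least 2 sites and 2 species")


def _community_cells(spec: SyntheticCommunitySpec, rng: np.random.Generator) -> np.ndarray:
    n, S = spec.n_sites, spec.n_species
    if spec.structure == "random":
        return (rng.random((n, S)) < spec.fill).astype(np.int8)
    if spec.structure == "segregated":
        # checkerboard pairs: each pair shares a site pool; a pool site is
        # exclusive (one species, coin flip) w.p. effect, else independent
        # 50/50 draws.  Either way each species' expected fill stays `fill`.
        cells = np.zeros((n, S), dtype=np.int8)
        for a in range(0, S - 1, 2):
            b = a + 1
            pool = rng.random(n) < min(2.0 * spec.fill, 1.0)
            exclusive = rng.random(n) < spec.effect
            coin = rng.random(n) < 0.5
            free_a = rng.random(n) < 0.5
            free_b = rng.random(n) < 0.5
            cells[:, a] = pool & np.where(exclusive, coin, free_a)
            cells[:, b] = pool & np.where(exclusive, ~coin, free_b)
        if S % 2:
            cells[:, S - 1] = rng.random(n) < spec.fill
        return cells
    # aggregated: common "good site" indicator shared by all species
    good = rng.random(n) < spec.fill
    p_good = spec.fill + spec.effect * (1.0 - spec.fill)
    p_bad = spec.fill * (1.0 - spec.effect)
    probs = np.where(good[:, None], p_good, p_bad)
    return (rng.random((n, S)) < probs).astype(np.int8)


def gen_community(
    spec: SyntheticCommunitySpec, max_retries: int = 20
) -> PresenceAbsenceMatrix:
    """Generate a presence/absence matrix with the requested structure.

    Draws that leave a species entirely absent (or omnipresent, which is
    equally uninformative for checkerboard analysis) are regenerated a
    bounded number of times with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    for attempt in range(max_retries):
        cells = _community_cells(spec, rng)
        col = cells.sum(axis=0)
        if (col > 0).all() and (col < spec.n_sites).all():
            break
        if attempt == 0:
            warnings.warn(
                "degenerate species column drawn; regenerating", stacklevel=2
            )
    else:
        raise RuntimeError(
            f"could not draw a non-degenerate community in {max_retries} tries"
        )
    return PresenceAbsenceMatrix(
        site_ids=tuple(f"site{i:03d}" for i in range(spec.n_sites)),
        species_ids=tuple(
            SPECIES_POOL[j] if j < len(SPECIES_POOL) else f"sp{j:02d}"
            for j in range(spec.n_species)
        ),
        cells=cells,
    )


def _all_mixtures(species=SPECIES_POOL) -> list[tuple]:
    """All 7 nonempty subsets of the 3-species pool, by richness."""
    out = []
    for k in (1, 2, 3):
        out.extend(combinations(species, k))
    return out


@dataclass(frozen=True)
class SyntheticDPSpec:
    """Replacement-series common-garden productivity design.

    The mean structure is baseline + beta_diversity * richness; block,
    unit (tree or trap station), and residual effects are independent
    Gaussian draws with the given SDs.  Values are truncated at zero
    (they are masses or areas).
    """

    n_blocks: int = 3
    densities: tuple = ("1m", "2m", "3m")
    years: tuple = (2019,)
    tissue: str = "root"
    beta_diversity: float = 0.0
    baseline: float = 10.0
    sd_block: float = 1.0
    sd_unit: float = 1.0
    sd_resid: float = 2.0
    n_units_per_plot: int = 3
    seed: int | None = None

    def __post_init__(self):
        for name in ("sd_block", "sd_unit", "sd_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tissue not in ("leaf", "wood", "root"):
            raise ValueError("tissue must be leaf, wood, or root")


def gen_productivity(spec: SyntheticDPSpec) -> pd.DataFrame:
    """Balanced productivity table over blocks x densities x 7 mixtures.

    Returns the long format the DP fit consumes: one row per measurement
    unit per year, with columns {block, plot, mixture, richness, density,
    year, tissue, unit_id, value}.
    """
    rng = np.random.default_rng(spec.seed)
    mixtures = _all_mixtures()
    rows = []
    plot_counter = 0
    for b in range(spec.n_blocks):
        block_eff = rng.normal(0.0, spec.sd_block)
        for dens in spec.densities:
            for mix in mixtures:
                plot_counter += 1
                plot_id = f"plot{plot_counter:03d}"
                richness = len(mix)
                for u in range(spec.n_units_per_plot):
                    unit_eff = rng.normal(0.0, spec.sd_unit)
                    unit_id = f"{plot_id}-u{u + 1}"
                    for year in spec.years:
                        value = (
                            spec.baseline
                            + spec.beta_diversity * richness
                            + block_eff
                            + unit_eff
                            + rng.normal(0.0, spec.sd_resid)
                        )
                        rows.append(
                            {
                                "block": f"B{b + 1}",
                                "plot": plot_id,
                                "mixture": "+".join(mix),
                                "richness": richness,
                                "density": dens,
                                "year": year,
                                "tissue": spec.tissue,
                                "unit_id": unit_id,
                                "value": max(value, 0.0),
                            }
                        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SyntheticTraitSpec:
    """Species x source trait records with controlled separation and gaps.

    species_offsets maps species -> per-trait mean shift (length-6 array
    or scalar).  Cells go missing independently with probability
    missing_fraction, re-drawn for any row or column that would lose all
    its observations.
    """

    n_sources_per_species: int = 8
    species: tuple = SPECIES_POOL
    species_offsets: dict | None = None
    global_means: tuple = (50.0, 0.55, 2.0, 20.0, 15.0, 2.2)
    within_sd: float = 1.0
    missing_fraction: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.missing_fraction <= 0.8):
            raise ValueError("missing_fraction must be in [0, 0.8]")
        if self.n_sources_per_species < 1:
            raise ValueError("need at least one source per species")


def gen_traits(spec: SyntheticTraitSpec) -> list[TraitRecord]:
    """Draw trait records per species x source x trait with MAR gaps."""
    rng = np.random.default_rng(spec.seed)
    offsets = spec.species_offsets or {}
    records = []
    for sp in spec.species:
        off = np.broadcast_to(
            np.asarray(offsets.get(sp, 0.0), dtype=float), (len(TRAITS),)
        )
        for s in range(spec.n_sources_per_species):
            src = f"{sp}-src{s + 1:02d}"
            values = (
                np.asarray(spec.global_means)
                + off
                + rng.normal(0.0, spec.within_sd, size=len(TRAITS))
            )
            present = rng.random(len(TRAITS)) >= spec.missing_fraction
            if not present.any():  # keep every row anchored
                present[rng.integers(len(TRAITS))] = True
            for t, trait in enumerate(TRAITS):
                if present[t]:
                    records.append(TraitRecord(sp, src, trait, float(values[t])))
    return records
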