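"""Diet-derived community uptake bounds and randomized uptake ensembles.

Two complementary ways of constraining what the community can eat:

* :func:`diet_to_uptake_bounds` converts a daily diet (food mass, molar
  composition, host absorption per macronutrient category) into
  community uptake bounds in mmol h^-1 per ``X0`` gdw of microbial
  biomass.

* :func:`sample_uptake_bounds` draws ensembles of *organism-specific*
  maximum uptake rates for carbon sources: each organism's total carbon
  uptake capacity (C-mmol gdw^-1 h^-1) is drawn from an exponential or
  uniform law with a chosen mean and partitioned across carbon sources
  proportionally to i.i.d. positive draws.  :func:`run_ensemble` solves
  the community under each draw and summarizes the resulting abundance
  distributions — a way to probe composition predictions without
  measured uptake kinetics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import CommunityModel, SolverStatus
from .solver import SolverOptions, solve_joint_fba, solve_steadycom

__all__ = [
    "DietTable",
    "UptakeBoundSet",
    "EnsembleSummary",
    "DEFAULT_ABSORPTION",
    "diet_to_uptake_bounds",
    "sample_uptake_bounds",
    "run_ensemble",
]

log = logging.getLogger(__name__)

#: Host absorption fractions per macronutrient category: the fraction of
#: each dietary category removed by the host before it reaches the
#: microbial community.  Carbohydrate alternatives 0.95/0.99 can be
#: passed explicitly.
DEFAULT_ABSORPTION: dict[str, float] = {
    "carbohydrate": 0.97,
    "amino acid": 0.90,
    "fiber": 0.00,
    "fatty acid": 0.90,
}

_CATEGORIES = frozenset(DEFAULT_ABSORPTION)

#: Default total microbial dry weight (gdw) used to normalize dietary
#: fluxes to per-community-biomass rates.
DEFAULT_TOTAL_BIOMASS = 10.0


@dataclass
class DietTable:
    """A daily diet: rows of (component, category, mass, composition, metabolite).

    ``rows`` columns: ``component`` (label), ``category`` (one of
    carbohydrate / amino acid / fiber / fatty acid), ``mass_g_per_day``,
    ``mmol_per_g``, ``metabolite`` (community metabolite id).
    ``total_biomass`` is the microbial dry weight (gdw) the daily fluxes
    are spread over.
    """

    rows: pd.DataFrame
    absorption: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ABSORPTION))
    total_biomass: float = DEFAULT_TOTAL_BIOMASS

    REQUIRED = ("component", "category", "mass_g_per_day", "mmol_per_g", "metabolite")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.rows.columns)
        if missing:
            raise ValueError(f"diet table missing columns {sorted(missing)}")
        bad_cat = set(self.rows["category"]) - _CATEGORIES
        if bad_cat:
            raise ValueError(
                f"unknown diet categories {sorted(bad_cat)}; expected {sorted(_CATEGORIES)}"
            )
        for cat, frac in self.absorption.items():
            if cat not in _CATEGORIES:
                raise ValueError(f"absorption for unknown category {cat!r}")
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"absorption fraction for {cat!r} outside [0, 1]: {frac}")
        if (self.rows["mass_g_per_day"] < 0).any():
            raise ValueError("negative daily mass in diet table")
        if self.total_biomass <= 0:
            raise ValueError("total_biomass must be > 0")

    @classmethod
    def from_tsv(
        cls,
        path,
        absorption: Optional[Mapping[str, float]] = None,
        total_biomass: float = DEFAULT_TOTAL_BIOMASS,
    ) -> "DietTable":
        rows = pd.read_csv(path, sep="\t")
        kwargs = {} if absorption is None else {"absorption": dict(absorption)}
        return cls(rows=rows, total_biomass=total_biomass, **kwargs)


_HOURS_PER_DAY = 24.0


def diet_to_uptake_bounds(diet: DietTable, X0: float = 1.0) -> dict[str, float]:
    """Community uptake bounds (mmol h^-1 per X0 gdw) from a daily diet.

    For each metabolite:

        bound = sum_rows mass (g/day) * composition (mmol/g)
                * (1 - absorption[category]) / 24 (h/day)
                / (total_biomass / X0)
    """
    absorption = {**DEFAULT_ABSORPTION, **dict(diet.absorption)}
    bounds: dict[str, float] = {}
    for row in diet.rows.itertuples(index=False):
        surviving = row.mass_g_per_day * row.mmol_per_g * (1.0 - absorption[row.category])
        rate = surviving / _HOURS_PER_DAY / (diet.total_biomass / X0)
        bounds[row.metabolite] = bounds.get(row.metabolite, 0.0) + rate
    return bounds


@dataclass(frozen=True)
class UptakeBoundSet:
    """One randomized assignment of per-organism carbon uptake caps.

    ``bounds`` maps ``(organism, metabolite) -> max specific uptake rate``
    in mmol gdw^-1 h^-1.  For each organism the carbon-weighted total of
    these rates equals a draw from the named distribution with mean
    ``mean_total_c`` (C-mmol gdw^-1 h^-1).
    """

    bounds: Mapping[tuple[str, str], float]
    seed: int
    distribution: str
    mean_total_c: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "bounds", dict(self.bounds))
        if any(v < 0 for v in self.bounds.values()):
            raise ValueError("uptake bounds must be >= 0")


def sample_uptake_bounds(
    cm: CommunityModel,
    carbon_sources: Mapping[str, int],
    mean_total_c: float,
    distribution: str = "exponential",
    n_sets: int = 1,
    seed: int = 0,
) -> list[UptakeBoundSet]:
    """Draw ``n_sets`` randomized per-organism uptake-bound assignments.

    For each set and organism a total carbon uptake capacity ``T`` is
    drawn (exponential with mean ``mean_total_c``, or uniform on
    ``[0, 2 * mean_total_c]``) and split over the organism's carbon
    sources proportionally to i.i.d. Exp(1) draws; the per-source bound
    is the allotted carbon divided by the source's carbon count, so the
    C-weighted sum of the bounds equals ``T`` exactly.  Only sources the
    organism can actually exchange receive a bound.  Deterministic given
    *seed* (numpy PCG64).
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if mean_total_c <= 0:
        raise ValueError("mean_total_c must be > 0")
    if distribution not in ("exponential", "uniform"):
        raise ValueError(f"unknown distribution {distribution!r}")
    for met, ncar in carbon_sources.items():
        if ncar < 1:
            raise ValueError(f"carbon count for {met!r} must be >= 1")

    rng = np.random.default_rng(seed)
    sets: list[UptakeBoundSet] = []
    for _ in range(n_sets):
        bounds: dict[tuple[str, str], float] = {}
        for org in cm.organisms:
            sources = [m for m in carbon_sources if m in org.exchange_map]
            if not sources:
                continue
            if distribution == "exponential":
                total = rng.exponential(mean_total_c)
            else:
                total = rng.uniform(0.0, 2.0 * mean_total_c)
            shares = rng.exponential(1.0, size=len(sources))
            shares /= shares.sum()
            for met, share in zip(sources, shares):
                bounds[(org.id, met)] = total * share / carbon_sources[met]
        sets.append(
            UptakeBoundSet(
                bounds=bounds,
                seed=seed,
                distribution=distribution,
                mean_total_c=mean_total_c,
            )
        )
    return sets


@dataclass
class EnsembleSummary:
    """Abundance distributions over an ensemble of uptake-bound draws.

    ``abundances`` is organisms x sets (biomass fractions of X0; one
    column per successfully solved set); ``summary`` holds per-organism
    mean/std/quantiles; ``by_taxon`` aggregates sets by an
    organism -> taxon map when one was given.
    """

    abundances: pd.DataFrame
    summary: pd.DataFrame
    n_total: int
    n_failed: int
    method: str
    by_taxon: Optional[pd.DataFrame] = None


_QUANTILES = (0.025, 0.25, 0.5, 0.75, 0.975)


def run_ensemble(
    cm: CommunityModel,
    sets: Sequence[UptakeBoundSet],
    method: str = "steadycom",
    taxon_map: Optional[Mapping[str, str]] = None,
    opts: Optional[SolverOptions] = None,
) -> EnsembleSummary:
    """Solve the community under each uptake-bound set and summarize.

    ``method='steadycom'`` records biomass fractions at the maximal
    community growth rate; ``method='joint_fba'`` records each
    organism's share of the total biomass flux (the joint-FBA analog of
    abundance).  Zero-growth or failed sets are counted in ``n_failed``
    and excluded from the distributions.
    """
    if method not in ("steadycom", "joint_fba"):
        raise ValueError(f"unknown method {method!r}")
    org_ids = list(cm.organism_ids)
    columns: dict[int, list[float]] = {}
    n_failed = 0
    for idx, bset in enumerate(sets):
        merged = {**cm.organism_uptake_ub, **dict(bset.bounds)}
        cm_i = cm.with_organism_uptake_ub(merged)
        try:
            if method == "steadycom":
                res = solve_steadycom(cm_i, opts)
                if res.status is not SolverStatus.OPTIMAL:
                    raise RuntimeError(f"status {res.status.value}")
                fracs = res.abundance_fractions
            else:
                jfba = solve_joint_fba(cm_i)
                total = jfba.total_biomass_flux
                if jfba.status != "optimal" or total <= 0:
                    raise RuntimeError(f"status {jfba.status}, total {total}")
                fracs = {k: v / total for k, v in jfba.biomass_flux.items()}
        except Exception as exc:  # per-set failures are logged, never fatal
            n_failed += 1
            log.warning("ensemble set %d failed: %s", idx, exc)
            continue
        columns[idx] = [fracs.get(k, 0.0) for k in org_ids]

    abund = pd.DataFrame(columns, index=org_ids)
    if abund.shape[1]:
        summary = pd.DataFrame(
            {
                "mean": abund.mean(axis=1),
                "std": abund.std(axis=1, ddof=1) if abund.shape[1] > 1 else 0.0,
                **{f"q{q:g}": abund.quantile(q, axis=1) for q in _QUANTILES},
            }
        )
    else:
        summary = pd.DataFrame(
            index=org_ids, columns=["mean", "std", *[f"q{q:g}" for q in _QUANTILES]]
        )
    by_taxon = None
    if taxon_map is not None and abund.shape[1]:
        taxa = pd.Series({k: taxon_map.get(k, "unassigned") for k in org_ids})
        by_taxon = abund.groupby(taxa).sum().mean(axis=1).to_frame("mean")
    return EnsembleSummary(
        abundances=abund,
        summary=summary,
        n_total=len(sets),
        n_failed=n_failed,
        method=method,
        by_taxon=by_taxon,
    )
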