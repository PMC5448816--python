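"""Domain types and linear-program assembly for community metabolic models.

A community model couples several organism-level stoichiometric models
through a shared pool of extracellular ("community") metabolites.  Two
formulations are assembled here:

* **Joint FBA** — the direct multi-organism extension of flux balance
  analysis: per-organism steady state on specific fluxes ``v^k_j``
  (mmol gdw^-1 h^-1), a community mass balance summing the organisms'
  exchange fluxes, and a weighted sum of biomass fluxes as objective.

* **Community steady state (SteadyCom)** — every organism is assigned an
  explicit biomass variable ``X^k`` (gdw) and the model is written in
  *aggregate* fluxes ``V^k_j = X^k * v^k_j`` (mmol h^-1).  Flux bounds
  scale with biomass (``LB^k_j X^k <= V^k_j <= UB^k_j X^k``), every
  organism grows at the common community rate mu
  (``V^k_biomass = mu X^k``), and total biomass is fixed at ``X0``.
  At fixed mu the problem is a linear program; the growth-rate search
  lives in :mod:`steadycom.solver`.

Sign convention: an organism exchange flux is negative for uptake from
the community space and positive for export into it, matching common
SBML practice.  The community balance for metabolite i reads
``u_i - e_i + sum_k V^k_ex(i) = 0`` with uptake ``u_i`` and export
``e_i`` both nonnegative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

__all__ = [
    "OrganismModel",
    "CommunityModel",
    "LinearProgram",
    "SteadyComResult",
    "SolverStatus",
    "FVARange",
    "ModelValidationError",
    "build_community",
    "assemble_steadycom_lp",
    "assemble_joint_fba_lp",
    "specific_fluxes",
]

_INF = math.inf

#: default biomass threshold (gdw) below which an organism is treated as
#: absent from an optimal solution — on the scale of LP solver tolerances.
DEFAULT_ZERO_TOL = 1e-8


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


class SolverStatus(str, Enum):
    OPTIMAL = "optimal"
    ZERO_GROWTH = "zero_growth"
    INFEASIBLE = "infeasible"


@dataclass(frozen=True)
class OrganismModel:
    """One organism's stoichiometric model.

    Parameters
    ----------
    id
        Unique organism identifier.
    metabolites, reactions
        Identifier lists; order is not significant.
    stoichiometry
        Sparse map ``(metabolite, reaction) -> coefficient``.
    lb, ub
        Flux bounds per reaction, mmol gdw^-1 h^-1 (the biomass reaction
        is in h^-1).  Use ``math.inf`` for unbounded.
    biomass_reaction
        Reaction whose flux is the specific growth rate.
    atpm_reaction
        Optional non-growth-associated ATP maintenance reaction (its
        lower bound is the maintenance demand).
    exchange_map
        ``community metabolite id -> exchange reaction id``; each
        exchange reaction must involve exactly one metabolite of this
        organism (its extracellular copy of the community metabolite).
    """

    id: str
    metabolites: tuple[str, ...]
    reactions: tuple[str, ...]
    stoichiometry: Mapping[tuple[str, str], float]
    lb: Mapping[str, float]
    ub: Mapping[str, float]
    biomass_reaction: str
    exchange_map: Mapping[str, str]
    atpm_reaction: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))
        object.__setattr__(self, "lb", dict(self.lb))
        object.__setattr__(self, "ub", dict(self.ub))
        object.__setattr__(self, "exchange_map", dict(self.exchange_map))
        self.validate()

    def validate(self) -> None:
        rxns = set(self.reactions)
        mets = set(self.metabolites)
        if self.biomass_reaction not in rxns:
            raise ModelValidationError(
                f"{self.id}: biomass reaction {self.biomass_reaction!r} not declared"
            )
        if self.atpm_reaction is not None and self.atpm_reaction not in rxns:
            raise ModelValidationError(
                f"{self.id}: ATPM reaction {self.atpm_reaction!r} not declared"
            )
        for j in self.reactions:
            lo, hi = self.lb.get(j, -_INF), self.ub.get(j, _INF)
            if lo > hi:
                raise ModelValidationError(f"{self.id}/{j}: lb {lo} > ub {hi}")
        for (i, j), coef in self.stoichiometry.items():
            if i not in mets:
                raise ModelValidationError(f"{self.id}: undeclared metabolite {i!r}")
            if j not in rxns:
                raise ModelValidationError(f"{self.id}: undeclared reaction {j!r}")
            if not math.isfinite(coef):
                raise ModelValidationError(f"{self.id}: non-finite coefficient S[{i},{j}]")
        for cmet, j in self.exchange_map.items():
            if j not in rxns:
                raise ModelValidationError(
                    f"{self.id}: exchange reaction {j!r} for {cmet!r} not declared"
                )
            touched = [i for (i, jj) in self.stoichiometry if jj == j]
            if len(touched) != 1:
                raise ModelValidationError(
                    f"{self.id}: exchange reaction {j!r} involves {len(touched)} "
                    "metabolites; exactly one extracellular metabolite expected"
                )

    def reaction_metabolites(self, rxn: str) -> dict[str, float]:
        return {i: c for (i, j), c in self.stoichiometry.items() if j == rxn}


@dataclass(frozen=True)
class CommunityModel:
    """A set of organisms sharing a pool of community metabolites.

    ``uptake_ub`` bounds the community uptake rate ``u_i`` (mmol h^-1
    per ``X0`` gdw of total biomass); metabolites missing from it cannot
    be taken up (bound 0) but may still be exported.
    ``organism_uptake_ub`` optionally caps the *specific* uptake rate of
    one organism for one community metabolite (mmol gdw^-1 h^-1).
    """

    organisms: tuple[OrganismModel, ...]
    community_metabolites: tuple[str, ...]
    uptake_ub: Mapping[str, float]
    X0: float = 1.0
    organism_uptake_ub: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "organisms", tuple(self.organisms))
        object.__setattr__(self, "community_metabolites", tuple(self.community_metabolites))
        object.__setattr__(self, "uptake_ub", dict(self.uptake_ub))
        object.__setattr__(self, "organism_uptake_ub", dict(self.organism_uptake_ub))
        self.validate()

    def validate(self) -> None:
        ids = [o.id for o in self.organisms]
        if len(set(ids)) != len(ids):
            raise ModelValidationError(f"duplicate organism ids: {sorted(ids)}")
        if not (self.X0 > 0):
            raise ModelValidationError(f"total biomass X0 must be > 0, got {self.X0}")
        declared = set(self.community_metabolites)
        for org in self.organisms:
            missing = set(org.exchange_map) - declared
            if missing:
                raise ModelValidationError(
                    f"{org.id}: exchange map references undeclared community "
                    f"metabolites {sorted(missing)}"
                )
        for met, bound in self.uptake_ub.items():
            if bound < 0:
                raise ModelValidationError(f"negative uptake bound for {met!r}: {bound}")
        for (org_id, met), bound in self.organism_uptake_ub.items():
            if org_id not in ids:
                raise ModelValidationError(f"uptake override for unknown organism {org_id!r}")
            if bound < 0:
                raise ModelValidationError(
                    f"negative specific uptake bound for ({org_id}, {met}): {bound}"
                )

    @property
    def organism_ids(self) -> tuple[str, ...]:
        return tuple(o.id for o in self.organisms)

    def organism(self, org_id: str) -> OrganismModel:
        for o in self.organisms:
            if o.id == org_id:
                return o
        raise KeyError(org_id)

    def with_organism_uptake_ub(
        self, bounds: Mapping[tuple[str, str], float]
    ) -> "CommunityModel":
        """Return a copy with ``organism_uptake_ub`` replaced by *bounds*."""
        return replace(self, organism_uptake_ub=dict(bounds))


# --------------------------------------------------------------------------
# Linear-program container
# --------------------------------------------------------------------------

# Variable identifiers are tuples:
#   ("V", org, rxn)  aggregate flux, mmol h^-1
#   ("v", org, rxn)  specific flux, mmol gdw^-1 h^-1   (joint FBA)
#   ("X", org)       biomass, gdw
#   ("u", met)       community uptake, mmol h^-1
#   ("e", met)       community export, mmol h^-1
VarId = tuple


@dataclass
class LinearProgram:
    """A generic LP: variables with bounds, rows, and one linear objective."""

    variables: list[tuple[VarId, float, float]] = field(default_factory=list)
    rows: list[tuple[dict, str, float]] = field(default_factory=list)
    objective: tuple[dict, str] = field(default_factory=lambda: ({}, "max"))

    def add_variable(self, vid: VarId, lb: float = -_INF, ub: float = _INF) -> None:
        self.variables.append((vid, lb, ub))

    def add_row(self, coeffs: Mapping[VarId, float], sense: str, rhs: float) -> None:
        if sense not in ("=", "<=", ">="):
            raise ValueError(f"bad row sense {sense!r}")
        self.rows.append((dict(coeffs), sense, rhs))

    def set_objective(self, coeffs: Mapping[VarId, float], direction: str = "max") -> None:
        if direction not in ("max", "min"):
            raise ValueError(f"bad objective direction {direction!r}")
        self.objective = (dict(coeffs), direction)

    def validate(self) -> None:
        declared = {vid for vid, _, _ in self.variables}
        if len(declared) != len(self.variables):
            raise ModelValidationError("duplicate LP variable ids")
        for coeffs, _, _ in self.rows:
            for vid in coeffs:
                if vid not in declared:
                    raise ModelValidationError(f"row references undeclared variable {vid}")
        for vid in self.objective[0]:
            if vid not in declared:
                raise ModelValidationError(f"objective references undeclared variable {vid}")


@dataclass
class SteadyComResult:
    """Outcome of the community growth-rate maximization."""

    mu_max: float
    abundance: dict[str, float]
    aggregate_flux: dict[tuple[str, str], float]
    community_uptake: dict[str, float]
    community_export: dict[str, float]
    iterations: int
    status: SolverStatus
    X0: float = 1.0

    @property
    def abundance_fractions(self) -> dict[str, float]:
        return {k: x / self.X0 for k, x in self.abundance.items()}


@dataclass(frozen=True)
class FVARange:
    """Min/max of a weighted linear target at a fixed community growth rate.

    ``target`` maps LP variable ids — ``("X", org)`` and
    ``("V", org, rxn)`` — to weights.
    """

    target: Mapping[VarId, float]
    mu0: float
    min: float
    max: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "target", dict(self.target))
        if self.min > self.max + 1e-9:
            raise ModelValidationError(f"FVA range inverted: [{self.min}, {self.max}]")


# --------------------------------------------------------------------------
# Construction
# --------------------------------------------------------------------------


def build_community(
    models: Sequence[OrganismModel],
    uptake_ub: Optional[Mapping[str, float]] = None,
    X0: float = 1.0,
    organism_uptake_ub: Optional[Mapping[tuple[str, str], float]] = None,
) -> CommunityModel:
    """Assemble a validated :class:`CommunityModel`.

    The community metabolite set is the union of the organisms'
    exchange-map keys.  Metabolites absent from *uptake_ub* get an
    uptake bound of 0 (export stays free).
    """
    uptake_ub = dict(uptake_ub or {})
    shared: list[str] = []
    seen: set[str] = set()
    for org in models:
        for met in org.exchange_map:
            if met not in seen:
                seen.add(met)
                shared.append(met)
    unknown = set(uptake_ub) - seen
    if unknown:
        # tolerated: an uptake bound for a metabolite no organism exchanges
        # is inert, but keep the metabolite so the balance row exists.
        shared.extend(sorted(unknown))
    return CommunityModel(
        organisms=tuple(models),
        community_metabolites=tuple(shared),
        uptake_ub={m: uptake_ub.get(m, 0.0) for m in shared},
        X0=X0,
        organism_uptake_ub=dict(organism_uptake_ub or {}),
    )


def _exchanging_organisms(cm: CommunityModel, met: str) -> list[tuple[OrganismModel, str]]:
    return [(o, o.exchange_map[met]) for o in cm.organisms if met in o.exchange_map]


def assemble_steadycom_lp(
    cm: CommunityModel,
    mu: float,
    include_total_biomass: bool = True,
) -> LinearProgram:
    """Build the community steady-state LP at a fixed growth rate *mu*.

    Variables: aggregate fluxes ``V^k_j``, biomasses ``X^k >= 0``,
    community uptakes ``u_i in [0, uptake_ub_i]`` and exports
    ``e_i >= 0``.  Rows:

    * per-organism steady state       sum_j S^k_ij V^k_j = 0
    * flux capacity                   V^k_j - UB^k_j X^k <= 0
                                      V^k_j - LB^k_j X^k >= 0
      (one-sided rows; infinite bounds are omitted, so both directions
      of a reversible reaction scale with X^k and X^k = 0 forces
      V^k_j = 0)
    * growth coupling                 V^k_biomass - mu X^k = 0
    * community balance               u_i - e_i + sum_k V^k_ex(i) = 0
    * organism-specific uptake cap    V^k_ex(i) + r_max X^k >= 0
      (uptake is negative flux, so this bounds specific uptake by r_max)
    * total biomass                   sum_k X^k = X0   (optional)

    The objective is left empty for the caller to set.
    """
    if mu < 0:
        raise ValueError(f"community growth rate must be >= 0, got {mu}")
    lp = LinearProgram()
    for org in cm.organisms:
        lp.add_variable(("X", org.id), 0.0, _INF)
        for j in org.reactions:
            lp.add_variable(("V", org.id, j), -_INF, _INF)
    for met in cm.community_metabolites:
        lp.add_variable(("u", met), 0.0, cm.uptake_ub.get(met, 0.0))
        lp.add_variable(("e", met), 0.0, _INF)

    for org in cm.organisms:
        k = org.id
        # steady state per internal metabolite
        by_met: dict[str, dict[VarId, float]] = {}
        for (i, j), coef in org.stoichiometry.items():
            by_met.setdefault(i, {})[("V", k, j)] = (
                by_met.get(i, {}).get(("V", k, j), 0.0) + coef
            )
        for i in org.metabolites:
            coeffs = by_met.get(i, {})
            lp.add_row(coeffs, "=", 0.0)
        # scaled capacity rows
        for j in org.reactions:
            ub = org.ub.get(j, _INF)
            lb = org.lb.get(j, -_INF)
            if math.isfinite(ub):
                lp.add_row({("V", k, j): 1.0, ("X", k): -ub}, "<=", 0.0)
            if math.isfinite(lb):
                lp.add_row({("V", k, j): 1.0, ("X", k): -lb}, ">=", 0.0)
        # growth coupling
        lp.add_row({("V", k, org.biomass_reaction): 1.0, ("X", k): -mu}, "=", 0.0)

    for met in cm.community_metabolites:
        coeffs: dict[VarId, float] = {("u", met): 1.0, ("e", met): -1.0}
        for org, ex in _exchanging_organisms(cm, met):
            coeffs[("V", org.id, ex)] = coeffs.get(("V", org.id, ex), 0.0) + 1.0
        lp.add_row(coeffs, "=", 0.0)

    for (org_id, met), r_max in cm.organism_uptake_ub.items():
        org = cm.organism(org_id)
        if met not in org.exchange_map:
            continue  # organism cannot exchange this metabolite at all
        ex = org.exchange_map[met]
        lp.add_row({("V", org_id, ex): 1.0, ("X", org_id): r_max}, ">=", 0.0)

    if include_total_biomass:
        lp.add_row({("X", o.id): 1.0 for o in cm.organisms}, "=", cm.X0)

    lp.validate()
    return lp


def assemble_joint_fba_lp(
    cm: CommunityModel,
    weights: Optional[Mapping[str, float]] = None,
) -> LinearProgram:
    """Build the joint-FBA LP: specific fluxes, unscaled bounds.

    Every organism's exchange flux enters the community balance directly
    (implicitly assuming equal abundances), and the objective maximizes
    the weighted sum of biomass fluxes.  Default weights are 1.
    """
    weights = dict(weights or {o.id: 1.0 for o in cm.organisms})
    lp = LinearProgram()
    for org in cm.organisms:
        k = org.id
        for j in org.reactions:
            lb = org.lb.get(j, -_INF)
            ub = org.ub.get(j, _INF)
            lp.add_variable(("v", k, j), lb, ub)
    for met in cm.community_metabolites:
        lp.add_variable(("u", met), 0.0, cm.uptake_ub.get(met, 0.0))
        lp.add_variable(("e", met), 0.0, _INF)

    for org in cm.organisms:
        k = org.id
        by_met: dict[str, dict[VarId, float]] = {}
        for (i, j), coef in org.stoichiometry.items():
            by_met.setdefault(i, {})[("v", k, j)] = (
                by_met.get(i, {}).get(("v", k, j), 0.0) + coef
            )
        for i in org.metabolites:
            lp.add_row(by_met.get(i, {}), "=", 0.0)

    for met in cm.community_metabolites:
        coeffs: dict[VarId, float] = {("u", met): 1.0, ("e", met): -1.0}
        for org, ex in _exchanging_organisms(cm, met):
            coeffs[("v", org.id, ex)] = coeffs.get(("v", org.id, ex), 0.0) + 1.0
        lp.add_row(coeffs, "=", 0.0)

    # organism-specific uptake caps: v_ex >= -r_max
    for (org_id, met), r_max in cm.organism_uptake_ub.items():
        org = cm.organism(org_id)
        if met not in org.exchange_map:
            continue
        lp.add_row({("v", org_id, org.exchange_map[met]): 1.0}, ">=", -r_max)

    lp.set_objective(
        {("v", o.id, o.biomass_reaction): weights.get(o.id, 0.0) for o in cm.organisms},
        "max",
    )
    lp.validate()
    return lp


def specific_fluxes(
    res: SteadyComResult, zero_tol: float = DEFAULT_ZERO_TOL
) -> tuple[dict[tuple[str, str], float], set[str]]:
    """Convert aggregate fluxes back to specific rates, v^k_j = V^k_j / X^k.

    Organisms with biomass at or below *zero_tol* carry no flux (the
    scaled capacity rows force V^k_j = 0 when X^k = 0); they are
    reported with all-zero specific fluxes and returned in the second
    element as the set of absent organisms.
    """
    if res.status not in (SolverStatus.OPTIMAL, SolverStatus.ZERO_GROWTH):
        raise ValueError(f"no solution to convert (status={res.status.value})")
    absent = {k for k, x in res.abundance.items() if x <= zero_tol}
    out: dict[tuple[str, str], float] = {}
    for (k, j), V in res.aggregate_flux.items():
        out[(k, j)] = 0.0 if k in absent else V / res.abundance[k]
    return out, absent
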