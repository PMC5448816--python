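"""Synthetic community models with analytically known optima.

These generators produce the small communities used throughout the test
suite and the examples.  Units are abstract (biomass yield 1 gdw per
mmol substrate unless stated) since the fixtures target LP correctness
rather than physiology.

* :func:`make_single_organism_toy` — one organism on one substrate;
  the community reduces to single-organism FBA and
  ``mu_max = uptake * yield / X0``.
* :func:`make_atpm_toy` — n identical organisms with a non-growth ATP
  maintenance demand ``a``.  Under community steady state the demand is
  paid per unit biomass, giving ``mu_max = U - a`` independent of n,
  whereas joint FBA pays it once per organism:
  ``sum v_biomass = U - n*a``.
* :func:`make_auxotroph_ring` — n members in a cross-feeding ring, each
  requiring the amino acid produced only by its predecessor; every
  member is obligate at any positive growth rate.
* :func:`brute_force_mu_max` — an independent grid-scan oracle for the
  maximal community growth rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .core import CommunityModel, OrganismModel, build_community
from .linprog_backend import solve_lp

__all__ = [
    "ToySpec",
    "build_toy",
    "make_single_organism_toy",
    "make_atpm_toy",
    "make_auxotroph_ring",
    "make_converter_toy",
    "brute_force_mu_max",
]

_INF = math.inf

#: default flux bound magnitude (mmol gdw^-1 h^-1) for toy reactions.
#: Finite, as in genome-scale models, so that the scaled capacity rows
#: couple zero abundance to zero flux for every reaction.
_BIG = 1000.0


@dataclass
class ToySpec:
    """Declarative description of a toy community.

    ``crossfeed_edges`` entries are ``(producer, metabolite, consumer,
    stoichiometry)``: the producer's biomass reaction exports
    *stoichiometry* units of the metabolite per unit growth and the
    consumer's biomass reaction requires one unit per unit growth.
    """

    n_organisms: int
    yields: Mapping[str, float]
    atpm_lb: Mapping[str, float] = field(default_factory=dict)
    crossfeed_edges: Sequence[tuple[str, str, str, float]] = ()
    community_uptake: Mapping[str, float] = field(default_factory=dict)
    X0: float = 1.0

    def organism_ids(self) -> list[str]:
        return [f"org{i + 1}" for i in range(self.n_organisms)]


def _toy_organism(
    org_id: str,
    substrate: str,
    biomass_yield: float,
    atpm: float = 0.0,
    consumed: Sequence[tuple[str, float]] = (),
    produced: Sequence[tuple[str, float]] = (),
) -> OrganismModel:
    """One toy organism: substrate -> biomass (+ optional ATPM demand and
    cross-fed metabolites, all via the biomass reaction)."""
    if biomass_yield <= 0:
        raise ValueError(f"{org_id}: yield must be > 0")
    if atpm < 0:
        raise ValueError(f"{org_id}: ATPM lower bound must be >= 0")
    mets = [f"{substrate}_e"]
    reactions = ["biomass", f"EX_{substrate}"]
    stoich: dict[tuple[str, str], float] = {
        (f"{substrate}_e", f"EX_{substrate}"): -1.0,
        (f"{substrate}_e", "biomass"): -1.0 / biomass_yield,
    }
    lb = {"biomass": 0.0, f"EX_{substrate}": -_BIG}
    ub = {"biomass": _BIG, f"EX_{substrate}": _BIG}
    exchange = {substrate: f"EX_{substrate}"}

    for met, coef in consumed:
        mets.append(f"{met}_e")
        reactions.append(f"EX_{met}")
        stoich[(f"{met}_e", f"EX_{met}")] = -1.0
        stoich[(f"{met}_e", "biomass")] = stoich.get((f"{met}_e", "biomass"), 0.0) - coef
        lb[f"EX_{met}"] = -_BIG
        ub[f"EX_{met}"] = _BIG
        exchange[met] = f"EX_{met}"
    for met, coef in produced:
        if f"{met}_e" not in mets:
            mets.append(f"{met}_e")
            reactions.append(f"EX_{met}")
            stoich[(f"{met}_e", f"EX_{met}")] = -1.0
            lb[f"EX_{met}"] = -_BIG
            ub[f"EX_{met}"] = _BIG
            exchange[met] = f"EX_{met}"
        stoich[(f"{met}_e", "biomass")] = stoich.get((f"{met}_e", "biomass"), 0.0) + coef

    atpm_rxn = None
    if atpm > 0:
        mets.append("atp_c")
        reactions.extend(["ATPS", "ATPM"])
        # substrate -> ATP, plus a maintenance sink with a demand floor
        stoich[(f"{substrate}_e", "ATPS")] = -1.0
        stoich[("atp_c", "ATPS")] = 1.0
        stoich[("atp_c", "ATPM")] = -1.0
        lb.update({"ATPS": 0.0, "ATPM": atpm})
        ub.update({"ATPS": _BIG, "ATPM": _BIG})
        atpm_rxn = "ATPM"

    return OrganismModel(
        id=org_id,
        metabolites=tuple(mets),
        reactions=tuple(reactions),
        stoichiometry=stoich,
        lb=lb,
        ub=ub,
        biomass_reaction="biomass",
        atpm_reaction=atpm_rxn,
        exchange_map=exchange,
    )


def build_toy(spec: ToySpec, substrate: str = "s") -> CommunityModel:
    """Materialize a :class:`ToySpec` into a validated community model."""
    ids = spec.organism_ids()
    consumed: dict[str, list[tuple[str, float]]] = {k: [] for k in ids}
    produced: dict[str, list[tuple[str, float]]] = {k: [] for k in ids}
    for prod, met, cons, coef in spec.crossfeed_edges:
        if prod not in consumed or cons not in consumed:
            raise ValueError(f"cross-feed edge references unknown organism: {(prod, cons)}")
        produced[prod].append((met, coef))
        consumed[cons].append((met, 1.0))
    organisms = [
        _toy_organism(
            k,
            substrate,
            spec.yields.get(k, 1.0),
            atpm=spec.atpm_lb.get(k, 0.0),
            consumed=consumed[k],
            produced=produced[k],
        )
        for k in ids
    ]
    return build_community(organisms, uptake_ub=spec.community_uptake, X0=spec.X0)


def make_single_organism_toy(
    uptake: float = 10.0, biomass_yield: float = 1.0, X0: float = 1.0
) -> CommunityModel:
    """One organism, one substrate; mu_max = uptake * yield / X0."""
    spec = ToySpec(
        n_organisms=1,
        yields={"org1": biomass_yield},
        community_uptake={"s": uptake},
        X0=X0,
    )
    return build_toy(spec)


def make_atpm_toy(
    n: int = 2, atpm_lb: float = 1.0, uptake: float = 4.0, X0: float = 1.0
) -> CommunityModel:
    """n identical organisms (yield 1) with ATP maintenance demand.

    Community steady state: mu_max = uptake - atpm_lb (maintenance paid
    per unit biomass).  Joint FBA: total biomass flux
    = uptake - n * atpm_lb (paid once per organism), floored at 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ids = [f"org{i + 1}" for i in range(n)]
    spec = ToySpec(
        n_organisms=n,
        yields={k: 1.0 for k in ids},
        atpm_lb={k: atpm_lb for k in ids},
        community_uptake={"s": uptake},
        X0=X0,
    )
    return build_toy(spec)


def make_auxotroph_ring(
    n: int = 4,
    export_yield: float = 1.5,
    uptake: float = 1.0,
    X0: float = 1.0,
) -> CommunityModel:
    """n organisms in an obligate cross-feeding ring.

    Organism k consumes one unit of amino acid ``aa{k-1}`` per unit
    growth and exports ``export_yield`` units of ``aa{k}``; everyone
    draws the growth substrate from a shared pool with community uptake
    bound *uptake*.  Since each amino acid has a single producer, any
    positive growth rate requires every member, and removing any one
    collapses mu_max to 0.  With export_yield = 1 the composition at
    mu_max is the unique equal-abundance vector; export_yield > 1 leaves
    slack that widens the allowed abundance bands.
    """
    if n < 2:
        raise ValueError("a cross-feeding ring needs n >= 2")
    if export_yield <= 0:
        raise ValueError("export_yield must be > 0")
    ids = [f"org{i + 1}" for i in range(n)]
    edges = []
    for i, k in enumerate(ids):
        consumer = ids[(i + 1) % n]
        edges.append((k, f"aa{i + 1}", consumer, export_yield))
    spec = ToySpec(
        n_organisms=n,
        yields={k: 1.0 for k in ids},
        crossfeed_edges=edges,
        community_uptake={"s": uptake},
        X0=X0,
    )
    return build_toy(spec)


def make_converter_toy(
    uptake: float = 10.0,
    grower_yield: float = 5.0,
    converter_yield: float = 1.0,
    fds_per_biomass: float = 0.2,
    conv_max_rate: float = 20.0,
    X0: float = 1.0,
) -> CommunityModel:
    """A high-yield grower fed by a low-yield substrate converter.

    The grower (org1) needs *fds_per_biomass* units of a derived
    substrate ("fds") per unit growth; only the converter (org2) can
    make it, via a dedicated conversion reaction (1 substrate -> 1 fds)
    with a finite specific rate cap *conv_max_rate* (mmol gdw^-1 h^-1)
    that is independent of the converter's own growth.  Defaults make
    the grower's route the substrate-efficient one (1/(1/5 + 0.2) = 2.5
    gdw per mmol vs the converter's 1).  Joint FBA lets the converter
    work without growing, so all biomass flux lands on the high-yield
    grower; under community steady state a zero-abundance converter
    carries zero flux, so it must hold appreciable biomass for the
    community to grow at all — the qualitative difference between the
    two methods on communities with dedicated degrader species.
    """
    grower = _toy_organism(
        "org1", "s", grower_yield, consumed=[("fds", fds_per_biomass)]
    )
    converter = _toy_organism("org2", "s", converter_yield)
    mets = list(converter.metabolites) + ["fds_e"]
    reactions = list(converter.reactions) + ["CONV", "EX_fds"]
    stoich = dict(converter.stoichiometry)
    stoich[("s_e", "CONV")] = -1.0
    stoich[("fds_e", "CONV")] = 1.0
    stoich[("fds_e", "EX_fds")] = -1.0
    lb = {**converter.lb, "CONV": 0.0, "EX_fds": -_BIG}
    ub = {**converter.ub, "CONV": conv_max_rate, "EX_fds": _BIG}
    converter = OrganismModel(
        id="org2",
        metabolites=tuple(mets),
        reactions=tuple(reactions),
        stoichiometry=stoich,
        lb=lb,
        ub=ub,
        biomass_reaction="biomass",
        exchange_map={**converter.exchange_map, "fds": "EX_fds"},
    )
    return build_community([grower, converter], uptake_ub={"s": uptake}, X0=X0)


def _feasible_at(cm: CommunityModel, mu: float) -> bool:
    from .core import assemble_steadycom_lp

    lp = assemble_steadycom_lp(cm, mu, include_total_biomass=True)
    sol = solve_lp(lp, objective={}, direction="min")
    return sol.optimal


def brute_force_mu_max(
    cm: CommunityModel,
    mu_grid_step: float = 1e-4,
    mu_upper: Optional[float] = None,
) -> float:
    """Largest feasible mu found by grid-scanning LP feasibility.

    An independent oracle for :func:`steadycom.solver.solve_steadycom`:
    no bisection, no interpolation — each grid point is a single LP
    feasibility check at fixed mu.  The scan is multi-resolution (the
    surviving interval is re-gridded ten times finer each stage) so
    steps down to 1e-7 stay affordable; every stage is still a plain
    fixed-step sweep.  Returns 0.0 when even mu = mu_grid_step is
    infeasible but mu = 0 is, and -inf when mu = 0 itself is infeasible.
    """
    if mu_grid_step <= 0:
        raise ValueError("mu_grid_step must be > 0")
    if not _feasible_at(cm, 0.0):
        return -math.inf
    if mu_upper is None:
        mu_upper = 1.0
        while _feasible_at(cm, mu_upper) and mu_upper < 1e6:
            mu_upper *= 2.0
    lo, hi = 0.0, mu_upper
    step = max((hi - lo) / 10.0, mu_grid_step)
    while True:
        best = lo
        mu = lo
        while mu <= hi + 1e-15:
            if mu > lo and _feasible_at(cm, mu):
                best = mu
            elif mu > lo:
                break  # feasibility is monotone in mu
            mu += step
        lo = best
        hi = min(hi, best + step)
        if step <= mu_grid_step:
            return best
        step = max(step / 10.0, mu_grid_step)
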