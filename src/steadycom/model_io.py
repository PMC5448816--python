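"""Reading organism models and writing results.

SBML Level 3 (with FBC flux bounds) is handled through cobra/libsbml.
A lightweight JSON dialect covers toy models and round-trips the
in-memory types exactly.  Results go to JSON or TSV.

Community metabolite matching: by default an organism's extracellular
metabolite ids are matched across organisms after stripping a single
trailing compartment tag (``glc__D_e`` and ``glc__D[e]`` both become
``glc__D``), which fits BiGG-style naming; a mapping table
(organism metabolite id -> community metabolite id) covers models whose
ids do not line up.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .core import (
    CommunityModel,
    FVARange,
    ModelValidationError,
    OrganismModel,
    SolverStatus,
    SteadyComResult,
    build_community,
)

__all__ = [
    "CommunityConfig",
    "read_organism_sbml",
    "write_toy_sbml",
    "read_toy_json",
    "write_toy_json",
    "read_community",
    "write_result",
    "read_result",
    "strip_compartment_suffix",
]

log = logging.getLogger(__name__)

_INF = math.inf
# single trailing compartment tag: "_e", "[e]", "_e0"
_SUFFIX_RE = re.compile(r"(_e\d?|\[e\])$")


def strip_compartment_suffix(met_id: str) -> str:
    """Drop one trailing extracellular-compartment tag from a metabolite id."""
    return _SUFFIX_RE.sub("", met_id)


# --------------------------------------------------------------------------
# Toy JSON dialect
# --------------------------------------------------------------------------


def _organism_to_dict(org: OrganismModel) -> dict:
    def enc(x: float):
        if x == _INF:
            return "inf"
        if x == -_INF:
            return "-inf"
        return x

    return {
        "id": org.id,
        "metabolites": list(org.metabolites),
        "reactions": list(org.reactions),
        "stoichiometry": [[i, j, c] for (i, j), c in sorted(org.stoichiometry.items())],
        "lb": {j: enc(v) for j, v in org.lb.items()},
        "ub": {j: enc(v) for j, v in org.ub.items()},
        "biomass_reaction": org.biomass_reaction,
        "atpm_reaction": org.atpm_reaction,
        "exchange_map": dict(org.exchange_map),
    }


def _organism_from_dict(d: dict) -> OrganismModel:
    def dec(x):
        if x == "inf":
            return _INF
        if x == "-inf":
            return -_INF
        return float(x)

    return OrganismModel(
        id=d["id"],
        metabolites=tuple(d["metabolites"]),
        reactions=tuple(d["reactions"]),
        stoichiometry={(i, j): float(c) for i, j, c in d["stoichiometry"]},
        lb={j: dec(v) for j, v in d["lb"].items()},
        ub={j: dec(v) for j, v in d["ub"].items()},
        biomass_reaction=d["biomass_reaction"],
        atpm_reaction=d.get("atpm_reaction"),
        exchange_map=dict(d["exchange_map"]),
    )


def write_toy_json(model: Union[OrganismModel, CommunityModel], path) -> None:
    """Serialize an organism or community model to the toy JSON dialect."""
    if isinstance(model, OrganismModel):
        doc = {"type": "organism", **_organism_to_dict(model)}
    else:
        doc = {
            "type": "community",
            "organisms": [_organism_to_dict(o) for o in model.organisms],
            "community_metabolites": list(model.community_metabolites),
            "uptake_ub": dict(model.uptake_ub),
            "X0": model.X0,
            "organism_uptake_ub": [
                [k, m, v] for (k, m), v in sorted(model.organism_uptake_ub.items())
            ],
        }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_toy_json(path) -> Union[OrganismModel, CommunityModel]:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "organism":
        return _organism_from_dict(doc)
    if doc.get("type") == "community":
        return CommunityModel(
            organisms=tuple(_organism_from_dict(d) for d in doc["organisms"]),
            community_metabolites=tuple(doc["community_metabolites"]),
            uptake_ub=dict(doc["uptake_ub"]),
            X0=float(doc["X0"]),
            organism_uptake_ub={
                (k, m): float(v) for k, m, v in doc.get("organism_uptake_ub", [])
            },
        )
    raise ModelValidationError(f"{path}: not a toy-dialect model file")


# --------------------------------------------------------------------------
# SBML via cobra
# --------------------------------------------------------------------------

_BIOMASS_RE = re.compile(r"biomass", re.IGNORECASE)


def _find_biomass(cobra_model) -> str:
    objective = [
        r.id for r in cobra_model.reactions if r.objective_coefficient not in (0, 0.0)
    ]
    if len(objective) == 1:
        return objective[0]
    if len(objective) > 1:
        raise ModelValidationError(
            f"{cobra_model.id}: multiple objective reactions {objective}; "
            "cannot identify a unique biomass reaction"
        )
    candidates = [r.id for r in cobra_model.reactions if _BIOMASS_RE.search(r.id)]
    if len(candidates) >= 1:
        log.warning(
            "%s: no FBC objective; using reaction %r matched by id pattern 'biomass'",
            cobra_model.id, candidates[0],
        )
        return candidates[0]
    raise ModelValidationError(f"{cobra_model.id}: no biomass reaction identifiable")


_ATPM_RE = re.compile(r"^(ATPM|.*maintenance.*)$", re.IGNORECASE)


def read_organism_sbml(path, organism_id: Optional[str] = None) -> OrganismModel:
    """Read one organism from SBML (Level 3 + FBC).

    Exchange reactions are boundary reactions involving exactly one
    metabolite (or reactions prefixed ``EX_``); the community metabolite
    id is the exchanged metabolite id with its compartment tag stripped.
    The biomass reaction comes from the FBC objective, falling back to a
    case-insensitive id match on "biomass" (logged).
    """
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:
        raise ModelValidationError(f"cannot read SBML file {path}: {exc}") from exc

    biomass = _find_biomass(cm)
    stoich: dict[tuple[str, str], float] = {}
    lb: dict[str, float] = {}
    ub: dict[str, float] = {}
    for rxn in cm.reactions:
        lb[rxn.id] = float(rxn.lower_bound)
        ub[rxn.id] = float(rxn.upper_bound)
        for met, coef in rxn.metabolites.items():
            stoich[(met.id, rxn.id)] = float(coef)

    exchange_map: dict[str, str] = {}
    for rxn in cm.reactions:
        # exchanges are boundary reactions on an extracellular metabolite
        # or EX_-prefixed reactions; other boundary reactions (demands,
        # sinks on internal metabolites, e.g. ATP maintenance) are not
        if rxn.id.startswith("EX_"):
            if len(rxn.metabolites) != 1:
                raise ModelValidationError(
                    f"{path}: exchange reaction {rxn.id!r} involves "
                    f"{len(rxn.metabolites)} metabolites (exactly 1 expected)"
                )
        elif not (
            rxn.boundary
            and len(rxn.metabolites) == 1
            and next(iter(rxn.metabolites)).compartment == "e"
        ):
            continue
        met = next(iter(rxn.metabolites))
        exchange_map[strip_compartment_suffix(met.id)] = rxn.id

    atpm = None
    for rxn in cm.reactions:
        if _ATPM_RE.match(rxn.id) and rxn.lower_bound > 0:
            atpm = rxn.id
            break

    return OrganismModel(
        id=organism_id or cm.id or Path(path).stem,
        metabolites=tuple(m.id for m in cm.metabolites),
        reactions=tuple(r.id for r in cm.reactions),
        stoichiometry=stoich,
        lb=lb,
        ub=ub,
        biomass_reaction=biomass,
        atpm_reaction=atpm,
        exchange_map=exchange_map,
    )


def write_toy_sbml(org: OrganismModel, path) -> None:
    """Write an organism to SBML Level 3 + FBC (via cobra).

    Infinite bounds are written as FBC infinities, so the toy dialect
    round-trips exactly through :func:`read_organism_sbml`.
    """
    import cobra

    m = cobra.Model(org.id)
    mets = {}
    for mid in org.metabolites:
        compartment = "e" if strip_compartment_suffix(mid) != mid else "c"
        mets[mid] = cobra.Metabolite(mid, compartment=compartment)
    m.add_metabolites(list(mets.values()))
    rxns = []
    for j in org.reactions:
        r = cobra.Reaction(j)
        r.lower_bound = org.lb.get(j, -_INF)
        r.upper_bound = org.ub.get(j, _INF)
        rxns.append(r)
    m.add_reactions(rxns)
    for (i, j), coef in org.stoichiometry.items():
        m.reactions.get_by_id(j).add_metabolites({mets[i]: coef})
    m.objective = org.biomass_reaction
    import cobra.io

    cobra.io.write_sbml_model(m, str(path))


# --------------------------------------------------------------------------
# Community assembly from files
# --------------------------------------------------------------------------


@dataclass
class CommunityConfig:
    """Where the organism models live and how to join them.

    ``model_paths`` maps organism id -> SBML or toy-JSON file.
    ``shared_namespace_rule`` is ``by_metabolite_id`` (compartment-tag
    stripping) or ``by_mapping_table`` (explicit alias table, TSV with
    columns ``organism_metabolite`` and ``community_metabolite``).
    ``uptake_table_path`` is a TSV of (metabolite, mmol h^-1 per X0);
    metabolites not listed default to uptake bound 0.
    """

    model_paths: Mapping[str, Union[str, Path]]
    shared_namespace_rule: str = "by_metabolite_id"
    mapping_table_path: Optional[Union[str, Path]] = None
    uptake_table_path: Optional[Union[str, Path]] = None
    X0: float = 1.0
    organism_uptake_overrides: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shared_namespace_rule not in ("by_metabolite_id", "by_mapping_table"):
            raise ValueError(
                f"unknown shared_namespace_rule {self.shared_namespace_rule!r}"
            )
        if self.X0 <= 0:
            raise ValueError("X0 must be > 0")
        for p in self.model_paths.values():
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.shared_namespace_rule == "by_mapping_table" and not self.mapping_table_path:
            raise ValueError("by_mapping_table requires mapping_table_path")


def _read_any_organism(path, org_id: str) -> OrganismModel:
    p = Path(path)
    if p.suffix.lower() in (".xml", ".sbml"):
        org = read_organism_sbml(p, organism_id=org_id)
    else:
        model = read_toy_json(p)
        if not isinstance(model, OrganismModel):
            raise ModelValidationError(f"{p}: expected a single organism model")
        org = dataclasses.replace(model, id=org_id) if model.id != org_id else model
    return org


def read_community(config: CommunityConfig) -> CommunityModel:
    """Load organism models and join them into a community.

    Exchange-map keys are rewritten to community metabolite ids per the
    configured namespace rule before :func:`build_community` unions
    them.  A mapping table must cover every extracellular metabolite of
    every organism; unmatched entries raise.
    """
    mapping: Optional[dict[str, str]] = None
    if config.shared_namespace_rule == "by_mapping_table":
        tbl = pd.read_csv(config.mapping_table_path, sep="\t")
        need = {"organism_metabolite", "community_metabolite"}
        if not need <= set(tbl.columns):
            raise ModelValidationError(
                f"mapping table must have columns {sorted(need)}"
            )
        mapping = dict(zip(tbl["organism_metabolite"], tbl["community_metabolite"]))

    organisms = []
    for org_id, path in config.model_paths.items():
        org = _read_any_organism(path, org_id)
        if mapping is not None:
            new_map = {}
            for cmet, rxn in org.exchange_map.items():
                # the table keys are raw extracellular ids; try both the raw
                # id and the already-stripped key
                raw_candidates = [cmet, f"{cmet}_e"]
                hit = next((mapping[c] for c in raw_candidates if c in mapping), None)
                if hit is None:
                    raise ModelValidationError(
                        f"{org_id}: extracellular metabolite {cmet!r} not in mapping table"
                    )
                new_map[hit] = rxn
            org = dataclasses.replace(org, exchange_map=new_map)
        organisms.append(org)

    uptake_ub: dict[str, float] = {}
    if config.uptake_table_path is not None:
        tbl = pd.read_csv(
            config.uptake_table_path, sep="\t", header=None,
            names=["metabolite", "bound"], comment="#",
        )
        uptake_ub = {
            str(r.metabolite).strip(): float(r.bound) for r in tbl.itertuples(index=False)
        }

    return build_community(
        organisms,
        uptake_ub=uptake_ub,
        X0=config.X0,
        organism_uptake_ub=dict(config.organism_uptake_overrides),
    )


# --------------------------------------------------------------------------
# Results
# --------------------------------------------------------------------------


def write_result(
    res: Union[SteadyComResult, Sequence[FVARange]], path, format: str = "json"
) -> None:
    """Write a solver result (JSON or TSV) or a list of FVA ranges (TSV/JSON).

    SteadyCom TSV columns: ``section, key, value`` (sections: mu_max,
    abundance, aggregate_flux, uptake, export, meta).  FVA TSV columns:
    ``target, mu0, min, max`` — one row per target.
    """
    path = Path(path)
    if isinstance(res, SteadyComResult):
        if format == "json":
            doc = {
                "mu_max": res.mu_max,
                "status": res.status.value,
                "iterations": res.iterations,
                "X0": res.X0,
                "abundance": dict(res.abundance),
                "aggregate_flux": [[k, j, v] for (k, j), v in sorted(res.aggregate_flux.items())],
                "community_uptake": dict(res.community_uptake),
                "community_export": dict(res.community_export),
            }
            path.write_text(json.dumps(doc, indent=1, sort_keys=True))
        elif format == "tsv":
            rows = [("meta", "mu_max", res.mu_max),
                    ("meta", "status", res.status.value),
                    ("meta", "iterations", res.iterations),
                    ("meta", "X0", res.X0)]
            rows += [("abundance", k, v) for k, v in sorted(res.abundance.items())]
            rows += [("aggregate_flux", f"{k}:{j}", v)
                     for (k, j), v in sorted(res.aggregate_flux.items())]
            rows += [("uptake", m, v) for m, v in sorted(res.community_uptake.items())]
            rows += [("export", m, v) for m, v in sorted(res.community_export.items())]
            pd.DataFrame(rows, columns=["section", "key", "value"]).to_csv(
                path, sep="\t", index=False
            )
        else:
            raise ValueError(f"unknown format {format!r}")
        return

    # FVA range list
    records = [
        {
            "target": ";".join(
                f"{':'.join(map(str, vid))}={w:g}" for vid, w in sorted(r.target.items())
            ),
            "mu0": r.mu0,
            "min": r.min,
            "max": r.max,
        }
        for r in res
    ]
    frame = pd.DataFrame.from_records(records, columns=["target", "mu0", "min", "max"])
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif format == "json":
        path.write_text(frame.to_json(orient="records", indent=1))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_result(path) -> SteadyComResult:
    """Read back a JSON solver result written by :func:`write_result`."""
    doc = json.loads(Path(path).read_text())
    return SteadyComResult(
        mu_max=float(doc["mu_max"]),
        abundance={k: float(v) for k, v in doc["abundance"].items()},
        aggregate_flux={(k, j): float(v) for k, j, v in doc["aggregate_flux"]},
        community_uptake={k: float(v) for k, v in doc["community_uptake"].items()},
        community_export={k: float(v) for k, v in doc["community_export"].items()},
        iterations=int(doc["iterations"]),
        status=SolverStatus(doc["status"]),
        X0=float(doc["X0"]),
    )
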