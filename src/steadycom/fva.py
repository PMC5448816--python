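"""Flux-variability analysis at a fixed community growth rate.

Once mu is fixed the community steady-state constraint set is a
polytope, so any weighted linear combination of aggregate fluxes and
biomass variables can be minimized and maximized over it — including
the abundances themselves, which is the main use here: how much can a
member's biomass fraction vary while the community still grows at
``mu0``?  The pairwise scan fixes one member's abundance on a grid and
tracks the allowed range of another, classifying the dependency as
purely competitive (the partner's ceiling only falls as the fixed
abundance rises) or conditionally mutualistic (a region where it
rises).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import CommunityModel, FVARange, VarId, assemble_steadycom_lp
from .linprog_backend import solve_lp

__all__ = [
    "InfeasibleGrowthError",
    "PairwiseScan",
    "abundance_target",
    "steadycom_fva",
    "abundance_fva",
    "pairwise_fva",
]

#: finite-difference tolerance (times X0) when classifying pairwise
#: scans; absorbs LP degeneracy noise on flat segments.
SLOPE_TOL = 1e-6


class InfeasibleGrowthError(RuntimeError):
    """The requested growth rate exceeds what the community can sustain."""


def abundance_target(org_id: str, weight: float = 1.0) -> dict[VarId, float]:
    """Weight map selecting one organism's biomass variable."""
    return {("X", org_id): weight}


def _fva_one(lp, target: Mapping[VarId, float]) -> tuple[float, float]:
    lo = solve_lp(lp, objective=target, direction="min")
    hi = solve_lp(lp, objective=target, direction="max")
    if lo.status == "infeasible" or hi.status == "infeasible":
        raise InfeasibleGrowthError("constraints infeasible at the requested growth rate")
    vmin = -math.inf if lo.status == "unbounded" else lo.objective_value
    vmax = math.inf if hi.status == "unbounded" else hi.objective_value
    return vmin, vmax


def steadycom_fva(
    cm: CommunityModel,
    mu0: float,
    targets: Sequence[Mapping[VarId, float]],
    extra_rows: Sequence[tuple[Mapping[VarId, float], str, float]] = (),
) -> list[FVARange]:
    """Min/max each weighted target over the community polytope at mu0.

    Targets are weight maps over ``("X", org)`` and ``("V", org, rxn)``
    variables.  Unbounded directions are reported as +/-inf.
    *extra_rows* appends additional linear constraints (used by
    :func:`pairwise_fva` to pin one organism's abundance).
    """
    if mu0 < 0:
        raise ValueError(f"mu0 must be >= 0, got {mu0}")
    lp = assemble_steadycom_lp(cm, mu0, include_total_biomass=True)
    for coeffs, sense, rhs in extra_rows:
        lp.add_row(coeffs, sense, rhs)
    out = []
    for target in targets:
        vmin, vmax = _fva_one(lp, target)
        # clip solver chatter so min <= max always holds
        if vmin > vmax:
            vmin = vmax = 0.5 * (vmin + vmax)
        out.append(FVARange(target=dict(target), mu0=mu0, min=vmin, max=vmax))
    return out


def abundance_fva(
    cm: CommunityModel,
    mu_fracs: Sequence[float],
    mu_max: float,
) -> pd.DataFrame:
    """Per-organism abundance ranges at fractions of the maximal growth rate.

    Returns a tidy frame with columns ``organism, frac, mu, min, max``.
    """
    records = []
    for frac in mu_fracs:
        if not (0 <= frac <= 1):
            raise ValueError(f"growth fraction must be in [0, 1], got {frac}")
        mu0 = frac * mu_max
        targets = [abundance_target(o.id) for o in cm.organisms]
        ranges = steadycom_fva(cm, mu0, targets)
        for org, rng in zip(cm.organisms, ranges):
            records.append(
                {"organism": org.id, "frac": frac, "mu": mu0,
                 "min": rng.min, "max": rng.max}
            )
    return pd.DataFrame.from_records(records)


@dataclass
class PairwiseScan:
    """Dependency of one member's abundance range on another's.

    ``ranges[i]`` is ``(min, max)`` of the dependent organism's biomass
    with the fixed organism pinned at ``grid[i]``, or ``None`` where the
    community cannot grow at all with that pinned abundance.
    """

    fixed_organism: str
    dependent_organism: str
    grid: tuple[float, ...]
    mu_frac: float
    ranges: tuple[Optional[tuple[float, float]], ...]
    classification: str = field(init=False)

    def __post_init__(self) -> None:
        self.classification = self._classify()

    def _classify(self) -> str:
        feas = [(a, r) for a, r in zip(self.grid, self.ranges) if r is not None]
        if not feas:
            raise InfeasibleGrowthError(
                f"no feasible grid point fixing {self.fixed_organism}"
            )
        tol = SLOPE_TOL * max(1.0, max(a for a, _ in feas))
        maxima = [r[1] for _, r in feas]
        if all(b - a <= tol for a, b in zip(maxima, maxima[1:])):
            return "competitive"
        return "conditionally_mutualistic"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            [
                {
                    "fixed_value": a,
                    "dep_min": (r[0] if r else float("nan")),
                    "dep_max": (r[1] if r else float("nan")),
                    "feasible": r is not None,
                }
                for a, r in zip(self.grid, self.ranges)
            ]
        )


def default_pairwise_grid(X0: float = 1.0, n: int = 30) -> tuple[float, ...]:
    """30 log-spaced abundances from 1e-3*X0 to X0."""
    return tuple(np.geomspace(1e-3 * X0, X0, n))


def pairwise_fva(
    cm: CommunityModel,
    fixed_org: str,
    dependent_org: str,
    mu_frac: float,
    mu_max: float,
    grid: Optional[Sequence[float]] = None,
) -> PairwiseScan:
    """Scan the dependent organism's abundance range against the fixed one.

    At each grid value ``a`` the row ``X^fixed = a`` is appended and the
    dependent organism's biomass is min/maximized at
    ``mu = mu_frac * mu_max``.  Grid points where the pinned abundance
    makes the community infeasible are marked absent.
    """
    if fixed_org == dependent_org:
        raise ValueError("fixed and dependent organism must differ")
    for org in (fixed_org, dependent_org):
        if org not in cm.organism_ids:
            raise KeyError(org)
    if not (0 < mu_frac <= 1):
        raise ValueError(f"mu_frac must be in (0, 1], got {mu_frac}")
    grid = tuple(grid) if grid is not None else default_pairwise_grid(cm.X0)
    if any(a <= 0 or a > cm.X0 + 1e-12 for a in grid):
        raise ValueError("grid values must lie in (0, X0]")
    mu0 = mu_frac * mu_max
    target = abundance_target(dependent_org)
    ranges: list[Optional[tuple[float, float]]] = []
    for a in grid:
        pin = ({("X", fixed_org): 1.0}, "=", a)
        try:
            rng = steadycom_fva(cm, mu0, [target], extra_rows=[pin])[0]
        except InfeasibleGrowthError:
            ranges.append(None)
            continue
        ranges.append((rng.min, rng.max))
    return PairwiseScan(
        fixed_organism=fixed_org,
        dependent_organism=dependent_org,
        grid=grid,
        mu_frac=mu_frac,
        ranges=tuple(ranges),
    )
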