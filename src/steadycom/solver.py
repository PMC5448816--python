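"""Maximal community growth rate by iterated LP feasibility.

The community steady-state problem is nonlinear in (mu, X, V) but
becomes an LP once mu is fixed.  The scalar function used for the
search is

    X_T(mu) = max { sum_k X^k :  community constraints at growth mu,
                                 total-biomass row dropped }

which is nonnegative, non-increasing in mu, and satisfies
``X_T(mu) >= X0``  iff  the full problem (with ``sum_k X^k = X0``) is
feasible at mu (any larger-total solution scales down onto X0 because
every constraint is homogeneous in (V, X) except the fixed community
uptake bounds, which only relax when scaling down).  The maximal
community growth rate is ``mu_max = sup { mu : X_T(mu) >= X0 }``.

The search brackets mu_max and then refines by fitting a hyperbola
``X_T ~ c / (mu + d)`` through the bracket endpoints — exact whenever a
single resource bound limits growth, which is why convergence to 1e-6
typically takes well under ten LPs regardless of community size — with
plain bisection as fallback and a final ``+mu_tol`` probe to certify
the upper side of the bracket.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional

from .core import (
    CommunityModel,
    SolverStatus,
    SteadyComResult,
    assemble_joint_fba_lp,
    assemble_steadycom_lp,
)
from .linprog_backend import LPSolution, UnboundedLPError, solve_lp

__all__ = [
    "SolverOptions",
    "JointFBASolution",
    "max_total_biomass",
    "solve_steadycom",
    "solve_joint_fba",
    "max_individual_growth",
]

log = logging.getLogger(__name__)


@dataclass
class SolverOptions:
    """Tunables for the growth-rate search.

    mu_tol
        Absolute tolerance on mu_max, h^-1.
    feas_tol
        Slack when comparing X_T against X0 (LP solver tolerance scale).
    mu_guess
        Starting growth rate, h^-1.  The default 0.1 sits inside the
        0.02-0.25 h^-1 range reported for intestinal microbes.
    max_iter
        Cap on the number of LPs solved during the search.
    bracket_growth_factor
        Multiplicative step used when the hyperbolic guess is unusable
        during bracketing.
    """

    mu_tol: float = 1e-6
    feas_tol: float = 1e-9
    mu_guess: float = 0.1
    max_iter: int = 50
    bracket_growth_factor: float = 2.0

    def __post_init__(self) -> None:
        for name in ("mu_tol", "feas_tol", "mu_guess", "max_iter", "bracket_growth_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SolverOptions.{name} must be positive")


def max_total_biomass(cm: CommunityModel, mu: float) -> tuple[float, LPSolution]:
    """Solve the fixed-mu subproblem max X_T = sum_k X^k.

    Returns ``(X_T, solution)``; 0 for an infeasible/degenerate point.
    Raises :class:`UnboundedLPError` when X_T is unbounded, which means
    a growth-limiting resource has no community uptake bound.
    """
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu}")
    lp = assemble_steadycom_lp(cm, mu, include_total_biomass=False)
    sol = solve_lp(lp, objective={("X", o.id): 1.0 for o in cm.organisms}, direction="max")
    if sol.status == "unbounded":
        free = sorted(m for m in cm.community_metabolites
                      if not math.isfinite(cm.uptake_ub.get(m, 0.0)))
        raise UnboundedLPError(
            "total community biomass is unbounded at mu="
            f"{mu:g}; add a community uptake bound on a growth-limiting "
            f"resource (metabolites with unbounded uptake: {free or 'none'})"
        )
    if not sol.optimal:
        return 0.0, sol
    return max(sol.objective_value, 0.0), sol


def _extract_result(
    cm: CommunityModel, mu: float, sol: LPSolution, iterations: int, status: SolverStatus
) -> SteadyComResult:
    abundance = {o.id: sol.values.get(("X", o.id), 0.0) for o in cm.organisms}
    aggregate = {
        (o.id, j): sol.values.get(("V", o.id, j), 0.0)
        for o in cm.organisms
        for j in o.reactions
    }
    uptake = {m: sol.values.get(("u", m), 0.0) for m in cm.community_metabolites}
    export = {m: sol.values.get(("e", m), 0.0) for m in cm.community_metabolites}
    return SteadyComResult(
        mu_max=mu,
        abundance=abundance,
        aggregate_flux=aggregate,
        community_uptake=uptake,
        community_export=export,
        iterations=iterations,
        status=status,
        X0=cm.X0,
    )


def _final_solve(cm: CommunityModel, mu: float) -> LPSolution:
    """Abundances at mu with the total-biomass row restored.

    The abundance vector can be degenerate; to make the report
    reproducible across solvers the secondary objective minimizes total
    community uptake (max sum X is constant once the total row holds).
    """
    lp = assemble_steadycom_lp(cm, mu, include_total_biomass=True)
    sol = solve_lp(lp, objective={("u", m): 1.0 for m in cm.community_metabolites},
                   direction="min")
    return sol


def _hyperbola_root(lo, lo_x, hi, hi_x, X0, require_bracket=True):
    """mu where a hyperbola c/(mu+d) through the two points crosses X0.

    Expects lo < hi with lo_x > hi_x (X_T is non-increasing).  Returns
    None when the fit is degenerate, the root is non-finite, or — with
    *require_bracket* — the root leaves the open interval (lo, hi).
    """
    if lo_x <= hi_x or hi_x <= 0:
        return None
    d = (hi_x * hi - lo_x * lo) / (lo_x - hi_x)
    c = lo_x * (lo + d)
    if c <= 0:
        return None
    cand = c / X0 - d
    if not math.isfinite(cand):
        return None
    if require_bracket and not (lo < cand < hi):
        return None
    return cand


def solve_steadycom(
    cm: CommunityModel, opts: Optional[SolverOptions] = None
) -> SteadyComResult:
    """Find the maximal community growth rate and member abundances.

    Bracketing grows/shrinks mu from ``opts.mu_guess`` guided by the
    hyperbolic model of X_T(mu); refinement interpolates inside the
    bracket with bisection fallback.  ``iterations`` counts the LPs
    solved during the search (the final abundance solve excluded).
    """
    opts = opts or SolverOptions()
    X0 = cm.X0
    thresh = X0 - opts.feas_tol * max(1.0, X0)
    n_lp = 0

    def eval_xt(mu: float) -> float:
        nonlocal n_lp
        n_lp += 1
        xt, _ = max_total_biomass(cm, mu)
        log.debug("X_T(%.9g) = %.9g", mu, xt)
        return xt

    # ---- bracketing --------------------------------------------------
    mu = opts.mu_guess
    xt = eval_xt(mu)
    lo = hi = None  # (mu, X_T) pairs
    if xt >= thresh:
        lo = (mu, xt)
        prev = None  # previous distinct feasible point, for the 2-point fit
        stagnant = False  # last +mu_tol probe turned out feasible
        while n_lp < opts.max_iter:
            root = None
            if prev is not None:
                root = _hyperbola_root(prev[0], prev[1], mu, xt, X0,
                                       require_bracket=False)
            if root is None and xt > 0:
                root = mu * xt / X0  # 1-point c/mu fit
            if stagnant or root is None:
                nxt = mu * opts.bracket_growth_factor
                stagnant = False
            elif root > mu + opts.mu_tol:
                nxt = root
            else:
                # the fit says we are already at mu_max: certify by probing
                nxt = mu + opts.mu_tol
            xt_new = eval_xt(nxt)
            if xt_new < thresh:
                hi = (nxt, xt_new)
                break
            if nxt == mu + opts.mu_tol:
                stagnant = True  # probe was feasible: the fit underestimated
            prev, lo = (mu, xt), (nxt, xt_new)
            mu, xt = nxt, xt_new
        if hi is None:
            raise RuntimeError(
                f"exceeded max_iter={opts.max_iter} while bracketing upward; "
                f"last feasible mu={lo[0]:g}"
            )
    else:
        hi = (mu, xt)
        prev = None
        while n_lp < opts.max_iter:
            root = None
            if prev is not None:
                root = _hyperbola_root(mu, xt, prev[0], prev[1], X0,
                                       require_bracket=False)
            if root is None and xt > 0:
                root = mu * xt / X0
            if xt == 0.0:
                # nothing grows at mu at all; shrink aggressively
                nxt = mu / opts.bracket_growth_factor ** 4
            elif root is None or root >= mu * 0.99:
                nxt = mu / opts.bracket_growth_factor
            else:
                nxt = root
            if nxt < opts.mu_tol:
                xt_tol = eval_xt(opts.mu_tol)
                if xt_tol >= thresh:
                    lo = (opts.mu_tol, xt_tol)
                    break
                # no growth possible: distinguish zero growth from infeasible
                # via a feasibility solve at mu = 0 with the total-biomass
                # row in place (max sum X can be unbounded at mu = 0 when
                # nothing demands flux, so X_T is unusable here)
                n_lp += 1
                sol = _final_solve(cm, 0.0)
                if sol.optimal:
                    return _extract_result(cm, 0.0, sol, n_lp, SolverStatus.ZERO_GROWTH)
                empty = LPSolution(status="infeasible", objective_value=None, values={})
                return _extract_result(cm, 0.0, empty, n_lp, SolverStatus.INFEASIBLE)
            xt_new = eval_xt(nxt)
            if xt_new >= thresh:
                lo = (nxt, xt_new)
                break
            prev, hi = (mu, xt), (nxt, xt_new)
            mu, xt = nxt, xt_new
        if lo is None:
            raise RuntimeError(
                f"exceeded max_iter={opts.max_iter} while bracketing downward; "
                f"bracket upper end mu={hi[0]:g}"
            )

    # ---- refinement --------------------------------------------------
    # tiny relative slack absorbs rounding in (lo + mu_tol) - lo
    while hi[0] - lo[0] > opts.mu_tol * (1.0 + 1e-9):
        if n_lp >= opts.max_iter:
            raise RuntimeError(
                f"exceeded max_iter={opts.max_iter} during refinement; "
                f"bracket [{lo[0]:g}, {hi[0]:g}]"
            )
        width = hi[0] - lo[0]
        cand = _hyperbola_root(lo[0], lo[1], hi[0], hi[1], X0,
                               require_bracket=False)
        if cand is None or not math.isfinite(cand):
            cand = lo[0] + 0.5 * width
        # keep strictly interior; a candidate glued to lo becomes a
        # +mu_tol probe that can certify convergence in one LP
        cand = min(max(cand, lo[0] + min(opts.mu_tol, 0.25 * width)),
                   hi[0] - min(opts.mu_tol, 0.25 * width))
        xt_c = eval_xt(cand)
        if xt_c >= thresh:
            lo = (cand, xt_c)
        else:
            hi = (cand, xt_c)

    mu_max = lo[0]
    sol = _final_solve(cm, mu_max)
    if not sol.optimal:
        # numerically marginal at the bracket edge; back off by mu_tol
        mu_max = max(mu_max - opts.mu_tol, 0.0)
        sol = _final_solve(cm, mu_max)
    status = SolverStatus.OPTIMAL if mu_max > opts.mu_tol else SolverStatus.ZERO_GROWTH
    res = _extract_result(cm, mu_max, sol, n_lp, status)
    log.info("mu_max = %.8g h^-1 after %d LPs", mu_max, n_lp)
    return res


@dataclass
class JointFBASolution:
    """Joint-FBA optimum: specific fluxes with unscaled bounds."""

    objective: float
    biomass_flux: dict[str, float]
    flux: dict[tuple[str, str], float]
    community_uptake: dict[str, float]
    community_export: dict[str, float]
    status: str

    @property
    def total_biomass_flux(self) -> float:
        return sum(self.biomass_flux.values())


def solve_joint_fba(
    cm: CommunityModel, weights: Optional[Mapping[str, float]] = None
) -> JointFBASolution:
    """Maximize the weighted sum of biomass fluxes (joint FBA)."""
    lp = assemble_joint_fba_lp(cm, weights)
    sol = solve_lp(lp)
    if sol.status == "unbounded":
        free = sorted(m for m in cm.community_metabolites
                      if not math.isfinite(cm.uptake_ub.get(m, 0.0)))
        raise UnboundedLPError(
            "joint FBA objective is unbounded; add a community uptake bound "
            f"(metabolites with unbounded uptake: {free or 'none'})"
        )
    if not sol.optimal:
        return JointFBASolution(0.0, {}, {}, {}, {}, sol.status)
    return JointFBASolution(
        objective=sol.objective_value,
        biomass_flux={
            o.id: sol.values[("v", o.id, o.biomass_reaction)] for o in cm.organisms
        },
        flux={(o.id, j): sol.values[("v", o.id, j)]
              for o in cm.organisms for j in o.reactions},
        community_uptake={m: sol.values[("u", m)] for m in cm.community_metabolites},
        community_export={m: sol.values[("e", m)] for m in cm.community_metabolites},
        status="optimal",
    )


def max_individual_growth(cm: CommunityModel, org_id: str) -> float:
    """Maximal biomass flux of one organism under joint FBA.

    All other organisms get objective weight zero but may still carry
    flux (e.g. to feed the focal organism).
    """
    if org_id not in cm.organism_ids:
        raise KeyError(org_id)
    weights = {o.id: (1.0 if o.id == org_id else 0.0) for o in cm.organisms}
    sol = solve_joint_fba(cm, weights)
    if sol.status != "optimal":
        return 0.0
    return sol.biomass_flux[org_id]
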