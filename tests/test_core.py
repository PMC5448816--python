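"""Domain types, validation, and the structure of the assembled LPs."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from steadycom import (
    ModelValidationError,
    OrganismModel,
    SolverStatus,
    assemble_joint_fba_lp,
    assemble_steadycom_lp,
    build_community,
    solve_lp,
    specific_fluxes,
    solve_steadycom,
)
from steadycom import fixtures as fx


def _minimal_organism(org_id="org1", substrate="s"):
    return OrganismModel(
        id=org_id,
        metabolites=(f"{substrate}_e",),
        reactions=("biomass", f"EX_{substrate}"),
        stoichiometry={
            (f"{substrate}_e", f"EX_{substrate}"): -1.0,
            (f"{substrate}_e", "biomass"): -1.0,
        },
        lb={"biomass": 0.0, f"EX_{substrate}": -math.inf},
        ub={"biomass": math.inf, f"EX_{substrate}": math.inf},
        biomass_reaction="biomass",
        exchange_map={substrate: f"EX_{substrate}"},
    )


class TestValidation:
    def test_two_organisms_sharing_substrate(self):
        cm = build_community(
            [_minimal_organism("a"), _minimal_organism("b")], uptake_ub={"s": 5.0}
        )
        assert cm.community_metabolites == ("s",)
        assert len(cm.organisms) == 2

    def test_missing_uptake_bound_defaults_to_zero(self):
        cm = build_community([_minimal_organism()], uptake_ub={})
        assert cm.uptake_ub["s"] == 0.0

    def test_duplicate_organism_ids_rejected(self):
        with pytest.raises(ModelValidationError, match="duplicate"):
            build_community([_minimal_organism("a"), _minimal_organism("a")])

    def test_negative_uptake_bound_rejected(self):
        with pytest.raises(ModelValidationError, match="negative uptake"):
            build_community([_minimal_organism()], uptake_ub={"s": -1.0})

    def test_zero_total_biomass_rejected(self):
        with pytest.raises(ModelValidationError, match="X0"):
            build_community([_minimal_organism()], uptake_ub={"s": 1.0}, X0=0.0)

    def test_biomass_reaction_must_exist(self):
        with pytest.raises(ModelValidationError, match="biomass"):
            OrganismModel(
                id="bad",
                metabolites=("m",),
                reactions=("r",),
                stoichiometry={("m", "r"): 1.0},
                lb={"r": 0.0},
                ub={"r": 1.0},
                biomass_reaction="nope",
                exchange_map={},
            )

    def test_inverted_bounds_rejected(self):
        org = _minimal_organism()
        with pytest.raises(ModelValidationError, match="lb"):
            OrganismModel(
                id="bad",
                metabolites=org.metabolites,
                reactions=org.reactions,
                stoichiometry=org.stoichiometry,
                lb={"biomass": 2.0, "EX_s": 0.0},
                ub={"biomass": 1.0, "EX_s": 0.0},
                biomass_reaction="biomass",
                exchange_map=org.exchange_map,
            )

    def test_exchange_touching_two_metabolites_rejected(self):
        with pytest.raises(ModelValidationError, match="exactly one"):
            OrganismModel(
                id="bad",
                metabolites=("a_e", "b_e"),
                reactions=("biomass", "EX_a"),
                stoichiometry={
                    ("a_e", "EX_a"): -1.0,
                    ("b_e", "EX_a"): 1.0,
                    ("a_e", "biomass"): -1.0,
                },
                lb={"biomass": 0.0, "EX_a": -math.inf},
                ub={"biomass": math.inf, "EX_a": math.inf},
                biomass_reaction="biomass",
                exchange_map={"a": "EX_a"},
            )

    def test_fixture_roundtrips_through_build_community(self, atpm_toy):
        rebuilt = build_community(
            atpm_toy.organisms, uptake_ub=atpm_toy.uptake_ub, X0=atpm_toy.X0
        )
        assert rebuilt == atpm_toy


class TestSteadyComLP:
    def test_negative_mu_rejected(self, single_toy):
        with pytest.raises(ValueError, match=">= 0"):
            assemble_steadycom_lp(single_toy, -0.1)

    def test_zero_growth_feasible_with_full_biomass(self, single_toy):
        lp = assemble_steadycom_lp(single_toy, 0.0)
        sol = solve_lp(lp, objective={("X", "org1"): 1.0}, direction="max")
        assert sol.optimal
        assert sol.value(("X", "org1")) == pytest.approx(1.0)
        assert sol.value(("V", "org1", "biomass")) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("mu,feasible", [(3.0, True), (3.01, False)])
    def test_atpm_toy_feasibility_boundary(self, atpm_toy, mu, feasible):
        """mu_max = uptake - maintenance = 3 for the ATPM toy."""
        lp = assemble_steadycom_lp(atpm_toy, mu)
        sol = solve_lp(lp, objective={}, direction="min")
        assert sol.optimal is feasible

    def test_zero_abundance_forces_zero_flux(self, atpm_toy):
        """With X^k pinned to 0, every aggregate flux of k must vanish."""
        lp = assemble_steadycom_lp(atpm_toy, 1.0)
        lp.add_row({("X", "org2"): 1.0}, "=", 0.0)
        org2 = atpm_toy.organism("org2")
        for j in org2.reactions:
            for direction in ("max", "min"):
                sol = solve_lp(lp, objective={("V", "org2", j): 1.0}, direction=direction)
                assert sol.optimal
                assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_community_metabolite_conservation(self, ring4):
        res = solve_steadycom(ring4)
        assert res.status is SolverStatus.OPTIMAL
        for met in ring4.community_metabolites:
            total = res.community_uptake[met] - res.community_export[met]
            for org in ring4.organisms:
                if met in org.exchange_map:
                    total += res.aggregate_flux[(org.id, org.exchange_map[met])]
            assert total == pytest.approx(0.0, abs=1e-8)

    def test_abundances_sum_to_x0(self, ring4):
        res = solve_steadycom(ring4)
        assert sum(res.abundance.values()) == pytest.approx(ring4.X0, abs=1e-8)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=50.0))
    def test_scale_invariance(self, scale):
        """Scaling X0 and uptake bounds by c scales biomass, not mu_max."""
        base = fx.make_atpm_toy(2, 1.0, 4.0, X0=1.0)
        scaled = fx.make_atpm_toy(2, 1.0, 4.0 * scale, X0=scale)
        r1 = solve_steadycom(base)
        r2 = solve_steadycom(scaled)
        assert r2.mu_max == pytest.approx(r1.mu_max, abs=2e-6 * max(1, scale))
        assert sum(r2.abundance.values()) == pytest.approx(
            scale * sum(r1.abundance.values()), rel=1e-6
        )


class TestJointFBA:
    def test_single_organism_reduces_to_fba(self, single_toy):
        lp = assemble_joint_fba_lp(single_toy, {"org1": 1.0})
        sol = solve_lp(lp)
        assert sol.objective_value == pytest.approx(10.0)

    def test_atpm_paid_per_organism(self, atpm_toy):
        """Joint FBA pays maintenance once per organism: total = U - n*a = 2."""
        lp = assemble_joint_fba_lp(atpm_toy)
        sol = solve_lp(lp)
        assert sol.objective_value == pytest.approx(2.0, abs=1e-9)

    def test_zero_weight_silences_organism(self, atpm_toy):
        lp = assemble_joint_fba_lp(atpm_toy, {"org1": 1.0, "org2": 0.0})
        sol = solve_lp(lp)
        # only org1's biomass counts, but both organisms' maintenance
        # demands still bind: 4 - (own + partner ATPM) = 2
        assert sol.objective_value == pytest.approx(2.0, abs=1e-9)


class TestSpecificFluxes:
    def test_division_by_biomass(self, single_toy):
        res = solve_steadycom(single_toy)
        v, absent = specific_fluxes(res)
        assert not absent
        assert v[("org1", "biomass")] == pytest.approx(res.mu_max, rel=1e-6)

    def test_absent_organism_all_zero(self, atpm_toy):
        res = solve_steadycom(atpm_toy)
        v, absent = specific_fluxes(res)
        # degenerate optimum concentrates biomass; the absent organism
        # must report zero specific fluxes
        for org_id in absent:
            org = atpm_toy.organism(org_id)
            assert all(v[(org_id, j)] == 0.0 for j in org.reactions)

    def test_atpm_demand_met_per_unit_biomass(self, atpm_toy):
        res = solve_steadycom(atpm_toy)
        v, absent = specific_fluxes(res)
        for org in atpm_toy.organisms:
            if org.id in absent:
                continue
            assert v[(org.id, "ATPM")] >= 1.0 - 1e-8
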