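"""File round trips: toy JSON, SBML, community assembly, result writers."""

import json
import logging
import math

import pytest

from steadycom import (
    CommunityConfig,
    ModelValidationError,
    OrganismModel,
    SolverStatus,
    abundance_target,
    read_community,
    read_organism_sbml,
    read_result,
    read_toy_json,
    solve_steadycom,
    steadycom_fva,
    write_result,
    write_toy_json,
    write_toy_sbml,
)
from steadycom import fixtures as fx
from steadycom.model_io import strip_compartment_suffix


class TestToyJSON:
    def test_organism_round_trip(self, tmp_path, atpm_toy):
        org = atpm_toy.organisms[0]
        p = tmp_path / "org.json"
        write_toy_json(org, p)
        assert read_toy_json(p) == org

    def test_community_round_trip(self, tmp_path, ring4):
        p = tmp_path / "cm.json"
        write_toy_json(ring4, p)
        assert read_toy_json(p) == ring4

    def test_infinite_bounds_survive(self, tmp_path):
        org = OrganismModel(
            id="o",
            metabolites=("s_e",),
            reactions=("biomass", "EX_s"),
            stoichiometry={("s_e", "EX_s"): -1.0, ("s_e", "biomass"): -1.0},
            lb={"biomass": 0.0, "EX_s": -math.inf},
            ub={"biomass": math.inf, "EX_s": math.inf},
            biomass_reaction="biomass",
            exchange_map={"s": "EX_s"},
        )
        p = tmp_path / "org.json"
        write_toy_json(org, p)
        back = read_toy_json(p)
        assert back.lb["EX_s"] == -math.inf
        assert back.ub["biomass"] == math.inf

    def test_garbage_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(json.dumps({"hello": 1}))
        with pytest.raises(ModelValidationError):
            read_toy_json(p)


class TestSBML:
    def test_round_trip_identity(self, tmp_path, atpm_toy):
        """write_toy_sbml then read_organism_sbml reproduces the model,
        including ATPM detection and exchange mapping."""
        org = atpm_toy.organisms[0]
        p = tmp_path / "org.xml"
        write_toy_sbml(org, p)
        assert read_organism_sbml(p, organism_id=org.id) == org

    def test_biomass_fallback_by_id_pattern(self, tmp_path, caplog):
        import cobra

        m = cobra.Model("nofbc")
        met = cobra.Metabolite("s_e", compartment="e")
        m.add_metabolites([met])
        ex = cobra.Reaction("EX_s")
        growth = cobra.Reaction("R_Biomass_core")
        m.add_reactions([ex, growth])
        ex.add_metabolites({met: -1.0})
        ex.lower_bound, ex.upper_bound = -10.0, 1000.0
        growth.add_metabolites({met: -1.0})
        growth.upper_bound = 1000.0
        p = tmp_path / "nofbc.xml"
        cobra.io.write_sbml_model(m, str(p))
        with caplog.at_level(logging.WARNING, logger="steadycom.model_io"):
            org = read_organism_sbml(p)
        assert org.biomass_reaction == "R_Biomass_core"
        assert any("biomass" in rec.message for rec in caplog.records)

    def test_multimetabolite_exchange_rejected(self, tmp_path):
        import cobra

        m = cobra.Model("bad")
        a = cobra.Metabolite("a_e", compartment="e")
        b = cobra.Metabolite("b_e", compartment="e")
        m.add_metabolites([a, b])
        ex = cobra.Reaction("EX_glc")
        growth = cobra.Reaction("biomass")
        m.add_reactions([ex, growth])
        ex.add_metabolites({a: -1.0, b: 1.0})
        growth.add_metabolites({a: -1.0})
        growth.upper_bound = 1000.0
        m.objective = "biomass"
        p = tmp_path / "bad.xml"
        cobra.io.write_sbml_model(m, str(p))
        with pytest.raises(ModelValidationError, match="exactly 1"):
            read_organism_sbml(p)

    def test_unreadable_file_rejected(self, tmp_path):
        p = tmp_path / "junk.xml"
        p.write_text("<not-sbml/>")
        with pytest.raises(ModelValidationError, match="cannot read"):
            read_organism_sbml(p)


class TestSuffixStripping:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("glc__D_e", "glc__D"),
            ("glc__D[e]", "glc__D"),
            ("ac_e0", "ac"),
            ("internal_c", "internal_c"),  # only extracellular tags strip
        ],
    )
    def test_single_trailing_tag(self, raw, expected):
        assert strip_compartment_suffix(raw) == expected


class TestReadCommunity:
    def _write_pair(self, tmp_path):
        cm = fx.make_atpm_toy(2, 1.0, 4.0)
        paths = {}
        for org in cm.organisms:
            p = tmp_path / f"{org.id}.json"
            write_toy_json(org, p)
            paths[org.id] = p
        return cm, paths

    def test_matching_by_metabolite_id(self, tmp_path):
        cm, paths = self._write_pair(tmp_path)
        uptake = tmp_path / "uptake.tsv"
        uptake.write_text("s\t4.0\n")
        cfg = CommunityConfig(model_paths=paths, uptake_table_path=uptake)
        loaded = read_community(cfg)
        assert set(loaded.community_metabolites) == {"s"}
        assert loaded.uptake_ub["s"] == 4.0
        assert solve_steadycom(loaded).mu_max == pytest.approx(3.0, abs=2e-6)

    def test_uptake_table_parsing(self, tmp_path):
        cm, paths = self._write_pair(tmp_path)
        uptake = tmp_path / "uptake.tsv"
        uptake.write_text("# metabolite\tbound\ns\t12.5\n")
        cfg = CommunityConfig(model_paths=paths, uptake_table_path=uptake)
        assert read_community(cfg).uptake_ub["s"] == 12.5

    def test_mapping_table_aliases(self, tmp_path):
        """Two organisms naming the same substrate differently are joined
        through the alias table."""
        org_a = fx.make_single_organism_toy().organisms[0]
        import dataclasses

        org_b = dataclasses.replace(
            fx.make_single_organism_toy().organisms[0],
            id="orgB",
            metabolites=("glucose_e",),
            stoichiometry={
                ("glucose_e", "EX_s"): -1.0,
                ("glucose_e", "biomass"): -1.0,
            },
            exchange_map={"glucose": "EX_s"},
        )
        pa, pb = tmp_path / "a.json", tmp_path / "b.json"
        write_toy_json(org_a, pa)
        write_toy_json(org_b, pb)
        mapping = tmp_path / "map.tsv"
        mapping.write_text(
            "organism_metabolite\tcommunity_metabolite\ns\tglc__D\nglucose\tglc__D\n"
        )
        cfg = CommunityConfig(
            model_paths={"org1": pa, "orgB": pb},
            shared_namespace_rule="by_mapping_table",
            mapping_table_path=mapping,
        )
        loaded = read_community(cfg)
        assert set(loaded.community_metabolites) == {"glc__D"}

    def test_unmatched_mapping_entry_rejected(self, tmp_path):
        cm, paths = self._write_pair(tmp_path)
        mapping = tmp_path / "map.tsv"
        mapping.write_text("organism_metabolite\tcommunity_metabolite\nother\tx\n")
        cfg = CommunityConfig(
            model_paths=paths,
            shared_namespace_rule="by_mapping_table",
            mapping_table_path=mapping,
        )
        with pytest.raises(ModelValidationError, match="not in mapping"):
            read_community(cfg)

    def test_missing_model_file_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            CommunityConfig(model_paths={"a": tmp_path / "absent.json"})


class TestResultIO:
    def test_json_round_trip(self, tmp_path, atpm_toy):
        res = solve_steadycom(atpm_toy)
        p = tmp_path / "res.json"
        write_result(res, p)
        assert read_result(p) == res

    def test_zero_growth_result_written(self, tmp_path):
        res = solve_steadycom(fx.make_single_organism_toy(0.0, 1.0))
        assert res.status is SolverStatus.ZERO_GROWTH
        p = tmp_path / "res.json"
        write_result(res, p)
        back = read_result(p)
        assert back.status is SolverStatus.ZERO_GROWTH
        assert all(abs(v) < 1e-9 for v in back.aggregate_flux.values())

    def test_tsv_sections(self, tmp_path, atpm_toy):
        import pandas as pd

        res = solve_steadycom(atpm_toy)
        p = tmp_path / "res.tsv"
        write_result(res, p, format="tsv")
        frame = pd.read_csv(p, sep="\t")
        assert set(frame.columns) == {"section", "key", "value"}
        assert "abundance" in set(frame.section)

    def test_fva_tsv_one_row_per_target(self, tmp_path, atpm_toy):
        import pandas as pd

        ranges = steadycom_fva(
            atpm_toy, 1.0, [abundance_target("org1"), abundance_target("org2")]
        )
        p = tmp_path / "fva.tsv"
        write_result(ranges, p, format="tsv")
        frame = pd.read_csv(p, sep="\t")
        assert list(frame.columns) == ["target", "mu0", "min", "max"]
        assert len(frame) == 2
        assert (frame["min"] <= frame["max"]).all()

    def test_unknown_format_rejected(self, tmp_path, atpm_toy):
        res = solve_steadycom(atpm_toy)
        with pytest.raises(ValueError, match="format"):
            write_result(res, tmp_path / "x.bin", format="parquet")
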