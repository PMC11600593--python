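"""Parameter-space definition, validation, serialization and scenarios."""

import dataclasses

import pytest

from afibcea.params import (
    ParameterSet,
    Override,
    ScenarioError,
    ScenarioSpec,
    ValidationError,
    apply_scenario,
    builtin_scenarios,
    get_path,
    load_parameters,
    set_path,
)


class TestValidation:
    def test_base_case_unit_costs_are_the_published_values(self, base_params):
        c = base_params.costs
        assert c.ablation_procedure == 8121.0
        assert c.cv_hospitalization_per_cycle == 1464.0
        assert c.stroke_acute == {"non_disabling": 1204.0, "moderate": 2864.0, "severe": 5168.0}
        assert c.pharma_per_cycle == {"cryoablation": 69.0, "aad": 89.0}

    def test_lt_decrement_matches_st_decrement_in_base_case(self, base_params):
        u = base_params.utilities
        assert u.decrement_lt_persistent == u.decrement_st_episodic == 0.08
        assert u.decrement_permanent == 0.11

    def test_out_of_range_probability_names_the_field(self, base_params):
        p = base_params.copy()
        p.risks.recurrence["aad"] = 1.3
        with pytest.raises(ValidationError, match="risks.recurrence.aad"):
            p.validate()

    @pytest.mark.parametrize(
        "mutate, field",
        [
            (lambda p: setattr(p.demographics, "male_fraction", 1.2), "male_fraction"),
            (lambda p: setattr(p.demographics, "cohort_size", 0), "cohort_size"),
            (lambda p: setattr(p.settings, "max_total_ablations", 4), "max_total_ablations"),
            (lambda p: p.risks.stroke_severity_split.update(moderate=0.9), "stroke_severity_split"),
            (lambda p: setattr(p.costs, "ed_visit_per_cycle", -1.0), "costs"),
            (lambda p: p.risks.rr_recurrence_by_count.__setitem__(1, -0.5), "rr_recurrence_by_count"),
        ],
    )
    def test_invariant_violations_raise_with_field_name(self, base_params, mutate, field):
        p = base_params.copy()
        mutate(p)
        with pytest.raises(ValidationError, match=field):
            p.validate()

    def test_horizon_must_be_divisible_by_cycle_length(self, base_params):
        p = base_params.copy()
        p.settings.cycle_length = 0.3
        with pytest.raises(ValidationError):
            p.validate()

    def test_life_table_must_cover_cohort_lifespan(self, base_params):
        p = base_params.copy()
        p.demographics.baseline_age = 90.0
        with pytest.raises(ValidationError, match="life table"):
            p.validate()


class TestSerialization:
    @pytest.mark.parametrize("suffix", [".json", ".yaml"])
    def test_save_load_round_trip_is_identity(self, base_params, tmp_path, suffix):
        path = tmp_path / f"config{suffix}"
        base_params.save(path)
        loaded = load_parameters(path)
        assert loaded.to_dict() == base_params.to_dict()
        assert loaded.life_table.to_frame().equals(base_params.life_table.to_frame())

    def test_double_round_trip_is_stable(self, base_params, tmp_path):
        p1 = tmp_path / "a.json"
        p2 = tmp_path / "b.json"
        base_params.save(p1)
        load_parameters(p1).save(p2)
        t1 = p1.read_text().replace("a.lifetable.csv", "X")
        t2 = p2.read_text().replace("b.lifetable.csv", "X")
        assert t1 == t2

    def test_unparsable_config_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text("{not json")
        with pytest.raises(ValidationError, match="parse"):
            load_parameters(bad)

    def test_missing_fields_get_documented_defaults(self, base_params, tmp_path, caplog):
        import logging

        path = tmp_path / "partial.yaml"
        base_params.save(path)
        text = path.read_text()
        # drop the whole costs block: defaults must fill it back in
        import yaml

        data = yaml.safe_load(text)
        del data["costs"]
        path.write_text(yaml.safe_dump(data))
        with caplog.at_level(logging.INFO, logger="afibcea.params"):
            loaded = load_parameters(path)
        assert loaded.costs.ablation_procedure == 8121.0
        assert any("default used: costs.ablation_procedure" in r.message for r in caplog.records)


class TestScenarios:
    def test_empty_override_list_is_identity(self, base_params):
        out = apply_scenario(base_params, ScenarioSpec("noop"))
        assert out.to_dict() == base_params.to_dict()

    def test_multiply_override_scales_value(self, base_params):
        p = base_params.copy()
        p.risks.stroke_annual_by_score["2"] = 0.020
        out = apply_scenario(
            p, ScenarioSpec("s", (Override("risks.stroke_annual_by_score", "multiply", 0.7),))
        )
        assert out.risks.stroke_annual_by_score["2"] == pytest.approx(0.014)

    def test_multiply_on_rr_entry(self, base_params):
        p = base_params.copy()
        p.risks.rr_recurrence_by_count[1] = 1.20
        out = apply_scenario(
            p, ScenarioSpec("s", (Override("risks.rr_recurrence_by_count.1", "multiply", 1.10),))
        )
        assert out.risks.rr_recurrence_by_count[1] == pytest.approx(1.32)

    def test_apply_scenario_is_pure(self, base_params):
        spec = ScenarioSpec("s", (Override("risks.ablation_success", "multiply", 0.7),))
        before = base_params.to_dict()
        out1 = apply_scenario(base_params, spec)
        out2 = apply_scenario(base_params, spec)
        assert base_params.to_dict() == before
        assert out1.to_dict() == out2.to_dict()

    def test_unknown_path_lists_valid_keys(self, base_params):
        with pytest.raises(ScenarioError, match="valid"):
            apply_scenario(
                base_params, ScenarioSpec("s", (Override("risks.nonsense.x", "set", 1),))
            )

    def test_builtin_scenarios_are_the_seven_analyses(self, base_params):
        specs = builtin_scenarios()
        assert len(specs) == 7
        names = {s.name for s in specs}
        assert "blanking_period" in names and "literature_stroke_rr" in names
        for spec in specs:
            out = apply_scenario(base_params, spec)
            out.validate()  # every scenario composes with the base case

    def test_blanking_scenario_toggles_flag(self, base_params):
        spec = next(s for s in builtin_scenarios() if s.name == "blanking_period")
        out = apply_scenario(base_params, spec)
        assert out.settings.blanking_period_active is True
        assert base_params.settings.blanking_period_active is False

    def test_literature_stroke_rr_reads_from_config(self, base_params):
        spec = next(s for s in builtin_scenarios() if s.name == "literature_stroke_rr")
        out = apply_scenario(base_params, spec)
        assert out.risks.stroke_state_rr == base_params.risks.stroke_state_rr_literature

    def test_rr_scenarios_leave_reference_level_unchanged(self, base_params):
        for name in ("recurrence_rr_up10", "resolution_rr_up10"):
            spec = next(s for s in builtin_scenarios() if s.name == name)
            out = apply_scenario(base_params, spec)
            vec = (
                out.risks.rr_recurrence_by_count
                if "recurrence" in name
                else out.risks.rr_resolution_by_count
            )
            base_vec = (
                base_params.risks.rr_recurrence_by_count
                if "recurrence" in name
                else base_params.risks.rr_resolution_by_count
            )
            assert vec[0] == base_vec[0]
            for k in (1, 2, 3):
                assert vec[k] == pytest.approx(base_vec[k] * 1.10)


class TestDotPaths:
    def test_get_and_set_round_trip(self, base_params):
        p = base_params.copy()
        assert get_path(p, "costs.ablation_procedure") == 8121.0
        set_path(p, "risks.reablation.ST.aad", 0.2)
        assert p.risks.reablation["ST"]["aad"] == 0.2

    def test_every_field_is_reachable_by_path(self, base_params):
        # the scenario machinery must be able to address the whole tree
        def walk(obj, prefix):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                for f in dataclasses.fields(obj):
                    walk(getattr(obj, f.name), f"{prefix}.{f.name}" if prefix else f.name)
            elif isinstance(obj, dict):
                for k, v in obj.items():
                    walk(v, f"{prefix}.{k}")
            else:
                assert get_path(base_params, prefix) == obj

        for block in ("demographics", "settings", "costs", "utilities", "risks"):
            walk(getattr(base_params, block), block)
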