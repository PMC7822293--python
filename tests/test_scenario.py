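"""Scenario orchestration: laddering, policy rules, sweeps, reports, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from cleancook.params import PolicySpec, get_transition, save_parameters
from cleancook.scenario import (
    COMBINED_ID,
    LadderComponent,
    Scenario,
    ScenarioValidationError,
    combine_outcomes,
    run_scenario,
    run_single,
    subsidy_sweep,
    sweep_table,
    write_report,
)


def make_scenario(**kwargs) -> Scenario:
    defaults = dict(
        transitions=[LadderComponent(transition_id=5, share=1.0)],
        policy=PolicySpec(instrument="stove_subsidy"),
        subsidy_grid=[0.0, 0.6, 0.7, 0.85, 1.0],
    )
    defaults.update(kwargs)
    return Scenario(**defaults)


class TestScenarioValidation:
    def test_ladder_shares_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum"):
            make_scenario(
                transitions=[
                    LadderComponent(transition_id=1, share=0.6),
                    LadderComponent(transition_id=5, share=0.6),
                ]
            )

    def test_valid_half_half_ladder(self):
        sc = make_scenario(
            transitions=[
                LadderComponent(transition_id=1, share=0.5),
                LadderComponent(transition_id=5, share=0.5),
            ]
        )
        assert len(sc.transitions) == 2

    def test_fuel_subsidy_requires_eligible_target_fuel(self, nepal):
        # transition 1 targets an improved biomass stove: not a subsidisable fuel
        with pytest.raises(ScenarioValidationError, match="fuel subsidy"):
            run_single(
                nepal, get_transition(1), PolicySpec(instrument="fuel_subsidy"), 0.0
            )

    def test_fuel_subsidy_allowed_for_lpg(self, nepal):
        o = run_single(
            nepal, get_transition(5), PolicySpec(instrument="fuel_subsidy"), 0.0
        )
        # fuel subsidy flows to pre-existing LPG users even with no adoption
        assert o.target_coverage == 0.0
        assert o.pv_net_public_cost > 0.0

    def test_only_one_demand_side_instrument(self):
        # financing/fuel subsidy/BCC are a single choice by construction
        with pytest.raises(ValidationError):
            PolicySpec(instrument="financing+bcc")

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError, match="subsidy_grid"):
            make_scenario(subsidy_grid=[])

    def test_grid_bounds(self):
        with pytest.raises(ValidationError):
            make_scenario(subsidy_grid=[0.5, 1.2])


class TestLaddering:
    def test_combined_row_is_share_weighted_sum(self, nepal):
        sc = make_scenario(
            transitions=[
                LadderComponent(transition_id=1, share=0.5),
                LadderComponent(transition_id=5, share=0.5),
            ],
            subsidy_grid=[0.85],
        )
        outcomes = run_scenario(sc, nepal)
        assert len(outcomes) == 3
        combined = [o for o in outcomes if o.transition_id == COMBINED_ID][0]
        parts = [o for o in outcomes if o.transition_id != COMBINED_ID]
        # oracle: independently run the two single-transition cells
        solo = [
            run_single(nepal, get_transition(tid), sc.policy, 0.85, share=0.5)
            for tid in (1, 5)
        ]
        assert combined.pv_net_public_cost == pytest.approx(
            sum(o.pv_net_public_cost for o in solo), rel=1e-12
        )
        assert combined.dalys_avoided == pytest.approx(
            sum(o.dalys_avoided for o in solo), rel=1e-12
        )
        assert combined.pv_social_net_benefits == pytest.approx(
            sum(o.pv_social_net_benefits for o in solo), rel=1e-12
        )
        assert combined.target_population == pytest.approx(
            sum(p.target_population for p in parts)
        )

    def test_combined_per_capita_uses_union_population(self, nepal):
        sc = make_scenario(
            transitions=[
                LadderComponent(transition_id=1, share=0.5),
                LadderComponent(transition_id=5, share=0.5),
            ],
            subsidy_grid=[0.85],
        )
        outcomes = run_scenario(sc, nepal)
        combined = [o for o in outcomes if o.transition_id == COMBINED_ID][0]
        assert combined.per_capita_public_cost == pytest.approx(
            combined.pv_net_public_cost / combined.target_population
        )

    def test_single_transition_has_no_combined_row(self, nepal):
        outcomes = run_scenario(make_scenario(subsidy_grid=[0.85]), nepal)
        assert [o.transition_id for o in outcomes] == [5]

    def test_combine_requires_components(self, nepal):
        o = run_single(
            nepal, get_transition(5), PolicySpec(instrument="stove_subsidy"), 0.85
        )
        combined = combine_outcomes([o], 0.85)
        assert combined.dalys_avoided == o.dalys_avoided


class TestSweep:
    def test_grid_produces_one_row_per_level(self, nepal):
        df = subsidy_sweep(make_scenario(), nepal)
        assert len(df) == 5
        assert sorted(df["stove_subsidy"]) == [0.0, 0.6, 0.7, 0.85, 1.0]

    def test_singleton_grid(self, nepal):
        df = subsidy_sweep(make_scenario(subsidy_grid=[0.7]), nepal)
        assert len(df) == 1

    def test_zero_subsidy_zero_coverage_on_lpg_fixture(self, nepal):
        df = subsidy_sweep(make_scenario(), nepal)
        at0 = df[df["stove_subsidy"] == 0.0].iloc[0]
        assert at0["target_coverage"] == 0.0
        assert at0["cer"] == "n.a."
        assert at0["pv_social_net_benefits"] < 0.0

    def test_monotone_columns(self, nepal):
        df = subsidy_sweep(make_scenario(), nepal).sort_values("stove_subsidy")
        for col in ("target_coverage", "pv_net_public_cost", "dalys_avoided"):
            assert np.all(np.diff(df[col].to_numpy(float)) >= -1e-9), col

    def test_wide_table_layout(self, nepal):
        df = subsidy_sweep(make_scenario(), nepal)
        wide = sweep_table(df, transition_id=5)
        assert list(wide.columns) == ["0%", "60%", "70%", "85%", "100%"]
        assert "cer" in wide.index

    def test_clean_fixture_sweep_emits_no_monotonicity_warning(self, nepal):
        # with a linear demand curve coverage is nondecreasing in subsidy,
        # so the monotonicity check must stay silent
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("error")
            subsidy_sweep(make_scenario(), nepal)


class TestPolicyInstruments:
    def test_financing_expands_adoption(self, nepal):
        t5 = get_transition(5)
        plain = run_single(nepal, t5, PolicySpec(instrument="stove_subsidy"), 0.6)
        financed = run_single(
            nepal, t5, PolicySpec(instrument="financing", with_stove_subsidy=True), 0.6
        )
        assert plain.target_coverage == 0.0
        assert financed.target_coverage > 0.0

    def test_bcc_expands_less_than_financing(self, nepal):
        t5 = get_transition(5)
        fin = run_single(
            nepal, t5, PolicySpec(instrument="financing", with_stove_subsidy=True), 0.7
        )
        bcc = run_single(
            nepal, t5, PolicySpec(instrument="bcc", with_stove_subsidy=True), 0.7
        )
        assert fin.target_coverage > bcc.target_coverage > 0.0

    def test_fuel_subsidy_raises_uptake_and_cost(self, nepal):
        t5 = get_transition(5)
        plain = run_single(nepal, t5, PolicySpec(instrument="stove_subsidy"), 0.7)
        fuels = run_single(
            nepal, t5,
            PolicySpec(instrument="fuel_subsidy", with_stove_subsidy=True), 0.7,
        )
        assert fuels.target_coverage >= plain.target_coverage
        assert fuels.pv_net_public_cost > plain.pv_net_public_cost

    def test_ban_forces_max_coverage(self, nepal):
        t5 = get_transition(5)
        o = run_single(nepal, t5, PolicySpec(instrument="ban"), 0.0)
        assert o.target_coverage == nepal.interventions.stove_demand["lpg"].c_max


class TestReports:
    def _outcomes(self, nepal):
        return run_scenario(make_scenario(subsidy_grid=[0.7, 0.85]), nepal)

    def test_csv_round_trip(self, nepal, tmp_path):
        outcomes = self._outcomes(nepal)
        files = write_report(outcomes, tmp_path, fmt="csv", params=nepal, seed=1)
        df = pd.read_csv(files[0])
        assert len(df) == len(outcomes)
        assert df["pv_net_public_cost"].tolist() == pytest.approx(
            [o.pv_net_public_cost for o in outcomes]
        )

    def test_json_contains_provenance(self, nepal, tmp_path):
        outcomes = self._outcomes(nepal)
        (path,) = write_report(outcomes, tmp_path, fmt="json", params=nepal, seed=7)
        doc = json.loads(path.read_text())
        assert doc["provenance"]["seed"] == 7
        assert doc["provenance"]["parameters_digest"]
        assert len(doc["outcomes"]) == len(outcomes)

    def test_empty_outcomes_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no outcomes"):
            write_report([], tmp_path)

    def test_byte_identical_reports_for_identical_inputs(self, nepal, tmp_path):
        outcomes = self._outcomes(nepal)
        f1 = write_report(outcomes, tmp_path / "a", fmt="json", params=nepal, seed=1)
        f2 = write_report(outcomes, tmp_path / "b", fmt="json", params=nepal, seed=1)
        assert f1[0].read_bytes() == f2[0].read_bytes()

    def test_end_to_end_determinism(self, tmp_path):
        from cleancook import generate_fixture

        reports = []
        for sub in ("a", "b"):
            params = generate_fixture(11, "nepal_like")
            outcomes = run_scenario(make_scenario(subsidy_grid=[0.85]), params)
            (path,) = write_report(
                outcomes, tmp_path / sub, fmt="json", params=params, seed=11
            )
            reports.append(path.read_bytes())
        assert reports[0] == reports[1]


class TestCli:
    def test_fixture_validate_run_cycle(self, tmp_path):
        from click.testing import CliRunner

        from cleancook.cli import main

        runner = CliRunner()
        pfile = tmp_path / "params.json"
        r = runner.invoke(main, ["fixture", "--seed", "1", "--out", str(pfile)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["validate", str(pfile)])
        assert r.exit_code == 0, r.output

        scenario = {
            "transitions": [{"transition_id": 5, "share": 1.0}],
            "policy": {"instrument": "stove_subsidy"},
            "subsidy_grid": [0.0, 0.85],
        }
        sfile = tmp_path / "scenario.json"
        sfile.write_text(json.dumps(scenario))
        out = tmp_path / "out"
        r = runner.invoke(
            main,
            ["run", "--params", str(pfile), "--scenario", str(sfile),
             "--out-dir", str(out), "--format", "csv"],
        )
        assert r.exit_code == 0, r.output
        assert (out / "outcomes.csv").exists()
        assert (out / "provenance.json").exists()

    def test_validate_rejects_broken_file(self, nepal, tmp_path):
        from click.testing import CliRunner

        from cleancook.cli import main

        bad = nepal.model_copy(deep=True)
        bad.health.__dict__["usage_rate"] = 1.3  # bypass assignment validation
        pfile = tmp_path / "bad.json"
        save_parameters(bad, pfile)
        r = CliRunner().invoke(main, ["validate", str(pfile)])
        assert r.exit_code == 2
        assert "usage_rate" in r.output

    def test_demand_plot_writes_curve(self, nepal, tmp_path):
        from click.testing import CliRunner

        from cleancook.cli import main

        pfile = tmp_path / "params.json"
        save_parameters(nepal, pfile)
        out = tmp_path / "curve.csv"
        r = CliRunner().invoke(
            main,
            ["demand", "plot", "--params", str(pfile), "--tech", "lpg",
             "--out", str(out)],
        )
        assert r.exit_code == 0, r.output
        df = pd.read_csv(out)
        assert {"price", "coverage"} <= set(df.columns)
        assert df["coverage"].iloc[0] == nepal.interventions.stove_demand["lpg"].c_max
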