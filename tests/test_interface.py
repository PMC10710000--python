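"""Run configuration, data loading, CLI drivers and report files."""

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from penmpr.cli import main
from penmpr.interface import ConfigError, RunConfig, load_dataset
from penmpr.simulation import SimulationScenario, generate_dataset


@pytest.fixture()
def survival_csv(tmp_path):
    """Small simulated survival table with a categorical covariate."""
    scenario = SimulationScenario(n=150, n_covariates=3, seed=21,
                                  beta_true=np.array([-1.0, -0.8, 0.0, 0.4]),
                                  alpha_true=np.array([0.3, 0.2, 0.0, 0.0]))
    data = generate_dataset(scenario, 5)
    rng = np.random.default_rng(0)
    covs = data.scale_design[:, 1:] * data.scale_std.sd + data.scale_std.mean
    frame = pd.DataFrame(covs, columns=["x1", "x2", "x3"])
    frame["time"] = data.times
    frame["status"] = data.events.astype(int)
    frame["group"] = rng.choice(["ref", "a", "b"], size=len(frame))
    path = tmp_path / "data.csv"
    frame.to_csv(path, index=False)
    return path


def _config_dict(data_path, out_dir, **over):
    cfg = {
        "seed": 11,
        "output_dir": str(out_dir),
        "data": {
            "path": str(data_path),
            "time": "time",
            "status": "status",
            "scale_covariates": ["x1", "x2", "x3"],
            "shape_covariates": ["x1", "x2"],
        },
        "penalty": {"family": "lasso", "structure": "single"},
        "tuning": {
            "bounds": [[0.0, 1.0]],
            "de": {"popsize": 8, "maxiter": 8, "stall_generations": 3,
                   "stall_tol": 0.01},
        },
    }
    for key, val in over.items():
        cfg[key] = val
    return cfg


def _write_config(tmp_path, cfg):
    path = tmp_path / "config.yaml"
    path.write_text(yaml.safe_dump(cfg))
    return path


class TestRunConfig:
    def test_yaml_round_trip_materializes_defaults(self, tmp_path, survival_csv):
        cfg_path = _write_config(
            tmp_path, _config_dict(survival_csv, tmp_path / "out")
        )
        config = RunConfig.from_yaml(cfg_path)
        resolved = config.resolved()
        assert resolved["penalty"]["scad_a"] == 3.7
        assert resolved["penalty"]["epsilon"] == 1e-4
        reparsed = RunConfig.from_dict(yaml.safe_load(yaml.safe_dump(resolved)))
        assert reparsed.seed == config.seed
        assert reparsed.penalty == config.penalty

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            RunConfig.from_dict({"seed": "not-an-int"})
        with pytest.raises(ConfigError):
            RunConfig.from_dict({"penalty": {"family": "ridge"}})
        with pytest.raises(ConfigError):
            RunConfig.from_dict({"simulation": {"rho": 1.0}})


class TestLoadDataset:
    def test_loads_and_standardizes(self, tmp_path, survival_csv):
        config = RunConfig.from_dict(
            _config_dict(survival_csv, tmp_path / "out")
        )
        data = load_dataset(config)
        assert data.p == 3 and data.q == 2
        assert np.allclose(data.scale_design[:, 1:].mean(axis=0), 0, atol=1e-12)

    def test_categorical_one_hot_against_reference(self, tmp_path, survival_csv):
        cfg = _config_dict(survival_csv, tmp_path / "out")
        cfg["data"]["scale_covariates"] = ["x1", "group"]
        cfg["data"]["categorical"] = {"group": "ref"}
        data = load_dataset(RunConfig.from_dict(cfg))
        assert data.p == 3  # x1 + two dummies
        assert set(data.scale_names) == {"x1", "group[a]", "group[b]"}

    def test_unknown_column_and_bad_status(self, tmp_path, survival_csv):
        cfg = _config_dict(survival_csv, tmp_path / "out")
        cfg["data"]["scale_covariates"] = ["x1", "nope"]
        with pytest.raises(ConfigError, match="nope"):
            load_dataset(RunConfig.from_dict(cfg))
        cfg = _config_dict(survival_csv, tmp_path / "out")
        cfg["data"]["status"] = "x1"
        with pytest.raises(ConfigError, match="binary"):
            load_dataset(RunConfig.from_dict(cfg))

    def test_missing_reference_level(self, tmp_path, survival_csv):
        cfg = _config_dict(survival_csv, tmp_path / "out")
        cfg["data"]["categorical"] = {"group": "absent"}
        cfg["data"]["scale_covariates"] = ["group"]
        with pytest.raises(ConfigError, match="absent"):
            load_dataset(RunConfig.from_dict(cfg))


class TestCliFit:
    def test_end_to_end_fit_outputs(self, tmp_path, survival_csv):
        out = tmp_path / "out"
        cfg_path = _write_config(tmp_path, _config_dict(survival_csv, out))
        result = CliRunner().invoke(main, ["fit", str(cfg_path)])
        assert result.exit_code == 0, result.output
        table = pd.read_csv(out / "coefficients.csv")
        assert set(table["component"]) == {"scale", "shape"}
        assert len(table) == 4 + 3  # (p+1) + (q+1)
        summary = yaml.safe_load((out / "fit_summary.yaml").read_text())
        # single tuning structure -> one lambda, inside the box
        assert len(summary["lambda_star"]) == 1
        assert 0.0 <= summary["lambda_star"][0] <= 1.0
        # the reported BIC reproduces its own df / loglik arithmetic
        recomputed = (
            -2 * summary["loglik_unpenalized"]
            + summary["effective_df"] * np.log(summary["n"])
        )
        assert summary["bic"] == pytest.approx(recomputed, rel=1e-9)
        assert (out / "resolved_config.yaml").exists()

    def test_written_coefficients_round_trip_exactly(self, tmp_path,
                                                     survival_csv):
        out = tmp_path / "out"
        cfg_path = _write_config(tmp_path, _config_dict(survival_csv, out))
        assert CliRunner().invoke(main, ["fit", str(cfg_path)]).exit_code == 0
        first = pd.read_csv(out / "coefficients.csv")
        (out / "coefficients.csv").write_text(first.to_csv(index=False))
        second = pd.read_csv(out / "coefficients.csv")
        assert np.array_equal(first["estimate"], second["estimate"])
        assert np.array_equal(first["se"], second["se"])

    def test_separate_structure_reports_two_lambdas(self, tmp_path,
                                                    survival_csv):
        out = tmp_path / "out2"
        cfg = _config_dict(survival_csv, out)
        cfg["penalty"] = {"family": "alasso", "structure": "separate"}
        cfg["tuning"]["bounds"] = [[0.0, 1.0], [0.0, 1.0]]
        cfg_path = _write_config(tmp_path, cfg)
        assert CliRunner().invoke(main, ["fit", str(cfg_path)]).exit_code == 0
        summary = yaml.safe_load((out / "fit_summary.yaml").read_text())
        assert len(summary["lambda_star"]) == 2

    def test_config_error_exit_code(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump({"data": {"path": "missing.csv"}}))
        result = CliRunner().invoke(main, ["fit", str(bad)])
        assert result.exit_code == 2


class TestCliSimulate:
    def test_smoke_run_emits_reports_and_is_seed_stable(self, tmp_path):
        out = tmp_path / "sim"
        cfg = {
            "seed": 7,
            "output_dir": str(out),
            "simulation": {
                "n": 120,
                "n_replicates": 3,
                "seed": 7,
                "penalties": [["lasso", "single"]],
                "de": {"popsize": 8, "maxiter": 6, "stall_generations": 2,
                       "stall_tol": 0.05},
            },
        }
        cfg_path = _write_config(tmp_path, cfg)
        assert CliRunner().invoke(main, ["simulate", str(cfg_path)]).exit_code == 0
        sel = pd.read_csv(out / "selection_metrics.csv")
        assert {"C", "IC", "PT", "MSE"} <= set(sel.columns)
        assert set(sel["component"]) == {"scale", "shape"}
        first = (out / "selection_metrics.csv").read_bytes()
        assert CliRunner().invoke(main, ["simulate", str(cfg_path)]).exit_code == 0
        assert (out / "selection_metrics.csv").read_bytes() == first

    def test_invalid_scenario_rejected_before_compute(self, tmp_path):
        cfg = {"output_dir": str(tmp_path / "x"),
               "simulation": {"n": 120, "rho": 1.0}}
        cfg_path = _write_config(tmp_path, cfg)
        result = CliRunner().invoke(main, ["simulate", str(cfg_path)])
        assert result.exit_code == 2


class TestCliDiagnose:
    def test_adequacy_points_and_bic_surface(self, tmp_path, survival_csv):
        out = tmp_path / "diag"
        cfg = _config_dict(survival_csv, out)
        cfg["tuning"]["grid"] = [0.0, 0.05, 0.2]
        cfg_path = _write_config(tmp_path, cfg)
        assert CliRunner().invoke(main, ["diagnose", str(cfg_path)]).exit_code == 0
        pts = pd.read_csv(out / "weibull_adequacy.csv")
        assert {"log_time", "log_cumhaz", "lower_95", "upper_95"} == set(
            pts.columns
        )
        assert (pts["lower_95"] <= pts["log_cumhaz"]).all()
        surf = pd.read_csv(out / "bic_surface.csv")
        n = len(pd.read_csv(survival_csv))
        recomputed = -2 * surf["loglik"] + surf["df"] * np.log(n)
        assert np.allclose(surf["bic"], recomputed, rtol=1e-9)

    def test_no_grid_skips_surface(self, tmp_path, survival_csv):
        out = tmp_path / "diag2"
        cfg_path = _write_config(tmp_path, _config_dict(survival_csv, out))
        assert CliRunner().invoke(main, ["diagnose", str(cfg_path)]).exit_code == 0
        assert not (out / "bic_surface.csv").exists()

    def test_all_censored_is_convergence_failure_exit(self, tmp_path):
        frame = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0], "status": [0, 0, 0], "x1": [0.1, -0.2, 0.3]}
        )
        path = tmp_path / "cens.csv"
        frame.to_csv(path, index=False)
        cfg = _config_dict(path, tmp_path / "diag3")
        cfg["data"]["scale_covariates"] = ["x1"]
        cfg["data"]["shape_covariates"] = ["x1"]
        cfg_path = _write_config(tmp_path, cfg)
        result = CliRunner().invoke(main, ["diagnose", str(cfg_path)])
        assert result.exit_code == 3
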