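"""Run configuration, data loading, and report writing.

A run is described by a single YAML file with ``data``, ``penalty``,
``tuning``, ``simulation`` and top-level ``seed`` / ``output_dir`` sections.
Input tables are delimited text (CSV/TSV) with named columns; the
configuration names the time, status and covariate columns and, for
categorical covariates, the reference level used for one-hot encoding (each
dummy is standardized and penalized individually).  Coefficients are
reported on the original covariate scale; every run writes the fully
resolved configuration alongside its outputs so results are reproducible
from the output directory alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .estimation import fit_unpenalized
from .model import SurvivalDataset, km_log_cumhaz_points
from .penalties import PenaltyConfig
from .simulation import SimulationScenario, run_study
from .tuning import DESettings, bic, select_lambda_de, select_lambda_grid

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for malformed run configurations (CLI exit code 2)."""


class ConvergenceError(RuntimeError):
    """Raised when a requested fit fails to converge (CLI exit code 3)."""


@dataclass
class DataConfig:
    path: str = ""
    sep: Optional[str] = None          # None -> sniffed from the file
    missing: Optional[str] = None      # extra NA token
    time: str = "time"
    status: str = "status"
    scale_covariates: List[str] = field(default_factory=list)
    shape_covariates: List[str] = field(default_factory=list)
    categorical: Dict[str, str] = field(default_factory=dict)  # column -> reference


@dataclass
class TuningConfig:
    bounds: Optional[List[List[float]]] = None
    grid: Optional[List] = None
    de: DESettings = field(default_factory=DESettings)


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "penmpr_output"
    verbosity: str = "info"
    data: DataConfig = field(default_factory=DataConfig)
    penalty: PenaltyConfig = field(default_factory=lambda: PenaltyConfig())
    tuning: TuningConfig = field(default_factory=TuningConfig)
    simulation: Optional[SimulationScenario] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read configuration {path}: {exc}") from exc
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            data = DataConfig(**raw.get("data", {}))
            pen_raw = dict(raw.get("penalty", {}))
            penalty = PenaltyConfig(**pen_raw)
            tun_raw = dict(raw.get("tuning", {}))
            de = DESettings(**tun_raw.pop("de", {}))
            tuning = TuningConfig(de=de, **tun_raw)
            sim_raw = raw.get("simulation")
            simulation = None
            if sim_raw is not None:
                sim_raw = dict(sim_raw)
                sim_de = sim_raw.pop("de", None)
                penalties = sim_raw.pop("penalties", None)
                if penalties is not None:
                    sim_raw["penalties"] = [tuple(p) for p in penalties]
                if sim_de is not None:
                    sim_raw["de_settings"] = DESettings(**sim_de)
                simulation = SimulationScenario(**sim_raw)
            seed = raw.get("seed", 0)
            if not isinstance(seed, (int, np.integer)):
                raise ValueError("seed must be an integer")
            return cls(
                seed=int(seed),
                output_dir=str(raw.get("output_dir", "penmpr_output")),
                verbosity=str(raw.get("verbosity", "info")),
                data=data,
                penalty=penalty,
                tuning=tuning,
                simulation=simulation,
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc

    def resolved(self) -> dict:
        """All defaults materialized, suitable for YAML round-trip."""

        def _plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: _plain(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            return obj

        out = _plain(self)
        if self.simulation is not None:
            out["simulation"].pop("_censor_bound", None)
        return out


def load_dataset(config: RunConfig) -> SurvivalDataset:
    """Read the delimited input table and assemble a SurvivalDataset."""
    dc = config.data
    if not dc.path:
        raise ConfigError("data.path is required")
    try:
        na = [dc.missing] if dc.missing is not None else None
        frame = pd.read_csv(
            dc.path, sep=dc.sep, engine="python" if dc.sep is None else "c",
            na_values=na,
        )
    except (OSError, pd.errors.ParserError) as exc:
        raise ConfigError(f"cannot read {dc.path}: {exc}") from exc

    needed = (
        [dc.time, dc.status]
        + list(dc.scale_covariates)
        + list(dc.shape_covariates)
    )
    missing_cols = [c for c in dict.fromkeys(needed) if c not in frame.columns]
    if missing_cols:
        raise ConfigError(f"unknown column(s): {', '.join(missing_cols)}")

    frame = frame[list(dict.fromkeys(needed))]
    n_before = len(frame)
    frame = frame.dropna()
    if len(frame) < n_before:
        logger.warning("dropped %d row(s) with missing values", n_before - len(frame))

    status = frame[dc.status]
    if not set(pd.unique(status)).issubset({0, 1}):
        raise ConfigError(f"status column {dc.status!r} must be binary 0/1")

    def _encode(cols: Sequence[str]) -> Tuple[np.ndarray, List[str]]:
        blocks, names = [], []
        for col in cols:
            if col in dc.categorical:
                ref = dc.categorical[col]
                levels = [lv for lv in pd.unique(frame[col]) if lv != ref]
                if ref not in set(pd.unique(frame[col])):
                    raise ConfigError(
                        f"reference level {ref!r} absent from column {col!r}"
                    )
                for lv in levels:
                    blocks.append((frame[col] == lv).to_numpy(float))
                    names.append(f"{col}[{lv}]")
            else:
                vals = pd.to_numeric(frame[col], errors="coerce")
                if vals.isna().any():
                    raise ConfigError(
                        f"column {col!r} is non-numeric; declare it categorical"
                    )
                blocks.append(vals.to_numpy(float))
                names.append(col)
        mat = np.column_stack(blocks) if blocks else np.empty((len(frame), 0))
        return mat, names

    x, x_names = _encode(dc.scale_covariates)
    z, z_names = _encode(dc.shape_covariates)
    try:
        return SurvivalDataset.from_covariates(
            frame[dc.time].to_numpy(float),
            status.to_numpy(float),
            x, z, scale_names=x_names, shape_names=z_names,
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# run drivers
# ---------------------------------------------------------------------------

def _prepare_output(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(config.resolved()))
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logging.getLogger("penmpr").addHandler(handler)
    return out


def coefficient_table(fit, data: SurvivalDataset) -> pd.DataFrame:
    """Per-coefficient report: estimate (original scale), SE, flags.

    De-selected slopes are reported as 0; significance is a 5% Wald test
    from the sandwich standard errors, evaluated for active coefficients.
    """
    terms = (
        ["(intercept)"] + list(data.scale_names)
        + ["(intercept)"] + list(data.shape_names)
    )
    comps = ["scale"] * (data.p + 1) + ["shape"] * (data.q + 1)
    est = fit.coefficients(zero_inactive=True)
    est_std = fit.params_std.theta
    active = np.concatenate([fit.active_scale, fit.active_shape])
    se = np.where(active, fit.standard_errors, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
    return pd.DataFrame(
        {
            "component": comps,
            "term": terms,
            "estimate": est,
            "se": se,
            "estimate_std": est_std,
            "active": active,
            "significant_5pct": active & (np.abs(z) > 1.959963984540054),
        }
    )


def run_fit(config: RunConfig) -> pd.DataFrame:
    """Full pipeline: unpenalized fit -> weights -> DE tuning -> final fit.

    Writes ``coefficients.csv`` and ``fit_summary.yaml`` to the output
    directory and returns the coefficient table.
    """
    out = _prepare_output(config)
    data = load_dataset(config)
    unpen = fit_unpenalized(data)
    if not unpen.converged:
        raise ConvergenceError("unpenalized fit did not converge")
    result = select_lambda_de(
        data,
        config.penalty,
        bounds=config.tuning.bounds,
        de_settings=config.tuning.de,
        seed=config.seed,
        unpenalized=unpen,
    )
    fit = result.best_fit
    if not fit.converged:
        raise ConvergenceError("selected penalized fit did not converge")
    table = coefficient_table(fit, data)
    table.to_csv(out / "coefficients.csv", index=False)
    summary = {
        "lambda_star": result.lambda_star.tolist(),
        "bic": float(result.bic_star),
        "effective_df": float(fit.effective_df),
        "loglik_unpenalized": float(fit.loglik_unpenalized),
        "n": int(data.n),
        "tuning_evaluations": int(result.evaluations),
    }
    (out / "fit_summary.yaml").write_text(yaml.safe_dump(summary))
    logger.info(
        "fit complete: lambda*=%s, df=%.2f, l0=%.2f, BIC=%.2f",
        summary["lambda_star"], summary["effective_df"],
        summary["loglik_unpenalized"], summary["bic"],
    )
    return table


def run_simulate(config: RunConfig):
    """Run the replicated simulation study and write its report tables."""
    if config.simulation is None:
        raise ConfigError("configuration has no 'simulation' section")
    out = _prepare_output(config)
    scenario = config.simulation
    if scenario.seed == 0 and config.seed != 0:
        scenario = dataclasses.replace(scenario, seed=config.seed)
    report = run_study(scenario)
    report.save(out)
    report.selection_table().to_csv(out / "selection_table.csv", index=False)
    return report


def run_diagnose(config: RunConfig):
    """Weibull adequacy points and, when a grid is configured, a BIC surface."""
    out = _prepare_output(config)
    data = load_dataset(config)
    try:
        adequacy = km_log_cumhaz_points(data)
    except ValueError as exc:
        raise ConvergenceError(str(exc)) from exc
    adequacy.to_csv(out / "weibull_adequacy.csv", index=False)

    surface = None
    if config.tuning.grid is not None and len(config.tuning.grid):
        grid = config.tuning.grid
        if config.penalty.n_tuning == 2 and len(grid) == 2 \
                and isinstance(grid[0], (list, tuple)):
            grid = (np.asarray(grid[0], float), np.asarray(grid[1], float))
        result = select_lambda_grid(data, config.penalty, grid)
        surface = result.surface
        surface.to_csv(out / "bic_surface.csv", index=False)
    else:
        logger.info("no tuning grid configured; BIC surface step skipped")
    return adequacy, surface
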