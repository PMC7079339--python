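"""Run configuration, presets, and deterministic output formats.

Tabular outputs are long-format CSV ('.' decimal, header row); each output
file gets a JSON sidecar (``<name>.meta.json``) holding the fully resolved
configuration and seed so that any file can be regenerated from its own
header.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import bifurcation as _bif
from . import equilibria as _eq
from . import models as _models
from . import stochastic as _stoch
from . import therapy as _ther
from .models import BaseParams, NkCtlParams, SaturationParams, params_to_dict

__all__ = ["RunConfig", "load_config", "params_from_dict", "reproduce_figure", "write_table"]

log = logging.getLogger(__name__)

_MODEL_TYPES = {
    "base": BaseParams,
    "saturation": SaturationParams,
    "nkctl": NkCtlParams,
}

_OPERATIONS = ("equilibria", "bifurcation", "simulate", "grid")


class ConfigError(ValueError):
    """Raised for missing/unknown keys or unresolvable run configurations."""


def params_from_dict(spec: dict):
    """Build a parameter container from a flat ``{'model': ..., rates...}`` dict."""
    spec = dict(spec)
    try:
        model = spec.pop("model")
    except KeyError:
        raise ConfigError("missing required key 'model' (base|saturation|nkctl)")
    try:
        cls = _MODEL_TYPES[model]
    except KeyError:
        raise ConfigError(f"unknown model {model!r}; expected one of {sorted(_MODEL_TYPES)}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(spec) - known
    if unknown:
        raise ConfigError(f"unknown parameter keys for model {model!r}: {sorted(unknown)}")
    missing = known - set(spec)
    if missing:
        raise ConfigError(f"missing parameter keys for model {model!r}: {sorted(missing)}")
    try:
        return cls(**{k: float(v) for k, v in spec.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_params_file(path) -> "BaseParams | SaturationParams | NkCtlParams":
    """Read a flat YAML/JSON parameter file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or not data:
        raise ConfigError(f"{path}: expected a non-empty mapping with keys "
                          "'model' plus the model's named rates")
    return params_from_dict(data)


def resolve_params(preset: Optional[str] = None, params_file=None, overrides: Optional[dict] = None):
    """Resolve a parameter set from a preset name and/or a file, with overrides."""
    if preset is not None and params_file is not None:
        raise ConfigError("give either a preset or a params file, not both")
    if preset is not None:
        params = _models.get_preset(preset)
    elif params_file is not None:
        params = load_params_file(params_file)
    else:
        raise ConfigError("either a preset or a params file is required")
    if overrides:
        params = dataclasses.replace(params, **overrides)
    return params


@dataclass
class RunConfig:
    """A fully resolved, serializable description of one run."""

    operation: str
    params: dict
    settings: dict
    seed: Optional[int] = None
    out: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "operation": self.operation,
            "params": self.params,
            "settings": self.settings,
            "seed": self.seed,
            "out": self.out,
        }


def load_config(path) -> RunConfig:
    """Load and validate a run configuration file (YAML dialect).

    Required keys: ``operation`` plus either ``preset`` or ``params``.
    Unknown top-level keys are rejected.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or not data:
        raise ConfigError(
            f"{path}: empty or invalid config; required keys: 'operation' "
            f"(one of {_OPERATIONS}) and 'preset' or 'params'"
        )
    allowed = {"operation", "preset", "params", "settings", "seed", "out"}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    op = data.get("operation")
    if op not in _OPERATIONS:
        raise ConfigError(f"{path}: 'operation' must be one of {_OPERATIONS}, got {op!r}")
    if "preset" in data:
        params = _models.get_preset(data["preset"])
    elif "params" in data:
        params = params_from_dict(data["params"])
    else:
        raise ConfigError(f"{path}: one of 'preset' or 'params' is required")
    settings = data.get("settings") or {}
    if not isinstance(settings, dict):
        raise ConfigError(f"{path}: 'settings' must be a mapping")
    return RunConfig(
        operation=op,
        params=params_to_dict(params),
        settings=settings,
        seed=data.get("seed"),
        out=data.get("out"),
    )


def write_table(df: pd.DataFrame, path, meta: dict) -> None:
    """Write a CSV table plus a JSON metadata sidecar (provenance header)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def equilibria_frame(params) -> pd.DataFrame:
    """Equilibrium table with columns (T*, E*, [N*], stability, method, eigen_real_max)."""
    if isinstance(params, BaseParams):
        eqs = _eq.base_equilibria(params)
    elif isinstance(params, SaturationParams):
        eqs = _eq.saturation_equilibria(params)
    else:
        eqs = _eq.nkctl_equilibria(params)
    rows = []
    for eq in eqs:
        row = {"T_star": eq.state[0]}
        if len(eq.state) == 3:
            row["N_star"] = eq.state[1]
        row["E_star"] = eq.state[-1]
        row.update(
            stability=eq.stability,
            method=eq.method,
            eigen_real_max=eq.max_real_eig,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def trajectory_frame(traj: _stoch.Trajectory) -> pd.DataFrame:
    df = pd.DataFrame(traj.states, columns=list(traj.species))
    df.insert(0, "time", traj.times)
    return df


def grid_frames(res: _ther.GridResult):
    """Long-format replicate table and summarized median matrix table."""
    rows = []
    for i, dk in enumerate(res.delta_k_values):
        for j, dE in enumerate(res.delta_E_values):
            for r in range(res.final_T.shape[2]):
                rows.append(
                    {
                        "delta_k": dk,
                        "delta_E": dE,
                        "rep": r,
                        "seed": int(res.seeds[r]),
                        "final_T": int(res.final_T[i, j, r]),
                    }
                )
    long_df = pd.DataFrame(rows)
    med_rows = [
        {
            "delta_k": dk,
            "delta_E": dE,
            "median_final_T": res.median_T[i, j],
        }
        for i, dk in enumerate(res.delta_k_values)
        for j, dE in enumerate(res.delta_E_values)
    ]
    return long_df, pd.DataFrame(med_rows)


# ---------------------------------------------------------------------------
# Figure-data regeneration pipelines
# ---------------------------------------------------------------------------

FIGURE_TAGS = ("fig2", "fig3a", "fig3b", "fig4")


def reproduce_figure(tag: str, out_dir, *, seed: int = 1, scale: float = 1.0) -> list:
    """Regenerate the data behind one of the headline figures.

    ``fig2``: killing-efficacy branch table of the base model (d = 2e-2
    preset) with detected bifurcation intervals.  ``fig3a``: untreated
    growth trajectory from (T, E) = (100, 1000).  ``fig3b``: the combined
    21-day antibody / 28-day transfer protocol started at day 50.
    ``fig4``: the single-day combination dose grid evaluated at day 120
    (axis sizes scale with ``scale``; defaults are documented, the source
    axis ranges are not printed anywhere).  Returns the written file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def _emit(df, name, meta):
        p = out_dir / name
        write_table(df, p, meta)
        written.append(p)

    if tag == "fig2":
        params = _models.FIG2
        k_l, k_u = _eq.base_k_thresholds(params)
        grid = np.geomspace(k_l / 10.0, 10.0 * k_u, 200)
        table = _bif.sweep(params, "k", grid)
        _emit(
            table.to_frame(),
            "fig2_branches.csv",
            {
                "figure": tag,
                "params": params_to_dict(params),
                "k_l": k_l,
                "k_u": k_u,
                "bifurcation_intervals": _bif.detect_bifurcations(table),
            },
        )
    elif tag == "fig3a":
        params = _models.TABLE1
        system = _stoch.build_base_reactions(params)
        traj = _stoch.simulate(system, (100, 1000), 80.0, seed, 1.0)
        _emit(
            trajectory_frame(traj),
            "fig3a_trajectory.csv",
            {"figure": tag, "params": params_to_dict(params), "seed": seed},
        )
    elif tag == "fig3b":
        params = _models.TABLE1
        sched = _ther.TreatmentSchedule(
            tau_k=50.0, delta_tau_k=21, delta_k=1e-1,
            tau_E=50.0, delta_tau_E=28, delta_E=1e5,
        )
        traj = _ther.run_treatment(params, (100, 1000), sched, 120.0, seed)
        _emit(
            trajectory_frame(traj),
            "fig3b_trajectory.csv",
            {
                "figure": tag,
                "params": params_to_dict(params),
                "schedule": dataclasses.asdict(sched),
                "seed": seed,
            },
        )
    elif tag == "fig4":
        params = _models.TABLE1
        n_dk = max(2, int(round(8 * scale)))
        n_dE = max(2, int(round(8 * scale)))
        dk = np.concatenate([[0.0], np.geomspace(1e-2, 30.0, n_dk - 1)])
        dE = np.concatenate([[0.0], np.geomspace(1e4, 1e8, n_dE - 1)])
        res = _ther.combination_grid(
            params, (100, 1000), dk, dE, eval_day=120.0, n_reps=5, base_seed=seed
        )
        long_df, med_df = grid_frames(res)
        meta = {
            "figure": tag,
            "params": params_to_dict(params),
            "eval_day": 120.0,
            "seed": seed,
        }
        _emit(long_df, "fig4_grid_long.csv", meta)
        _emit(med_df, "fig4_grid_median.csv", meta)
    else:
        raise ConfigError(f"unknown figure tag {tag!r}; expected one of {FIGURE_TAGS}")
    return written
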