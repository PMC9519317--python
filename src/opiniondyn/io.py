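"""Config parsing, result writers, and run manifests.

Config files are flat ``key: value`` text (a YAML-compatible subset): one
mapping of scalars, no nesting. Unknown keys are rejected outright; a
missing contact rate ``gamma_star`` is filled with the documented default
0.5 and logged at warning level. All CSV output is comma-separated with
``.`` decimals, LF line endings, and a mandatory header row.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .dynamics import SolverConfig
from .errors import ConfigError, ParameterValidationError
from .params import DEFAULT_GAMMA_STAR, InterventionParams
from .scenarios import SWEEPABLE, ScenarioConfig

log = logging.getLogger("opiniondyn")

__all__ = ["read_config", "write_config", "scenario_from_config",
           "RunManifest", "write_json"]

_PARAM_KEYS = set(InterventionParams.field_names())
_RUN_KEYS = {"name", "i0", "t_end", "t_start", "dense_grid", "rel_tol",
             "abs_tol", "max_step", "method", "strict", "variant",
             "sweep_param", "sweep_values", "scale", "dispersion", "seed"}
_KNOWN_KEYS = _PARAM_KEYS | _RUN_KEYS


def read_config(path, strict: bool | None = None) -> dict:
    """Parse and validate a flat key:value config file.

    Returns a dict with keys ``params`` (:class:`InterventionParams`),
    ``solver`` (:class:`SolverConfig`), and ``run`` (remaining settings).
    Parse failures, unknown keys, and range violations are signalled as
    distinct errors.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse {path}: {e}") from e
    if raw is None:
        raw = {}
    if not isinstance(raw, dict) or any(isinstance(v, (dict, list))
                                        and k != "sweep_values"
                                        for k, v in raw.items()):
        raise ConfigError(f"{path} must be a flat key: value mapping")
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"unknown config key(s) in {path}: "
                          f"{', '.join(unknown)}")

    pkw = {k: float(v) for k, v in raw.items() if k in _PARAM_KEYS}
    if "gamma_star" not in pkw:
        log.warning("config %s omits gamma_star; applying documented "
                    "default %.3g", path, DEFAULT_GAMMA_STAR)
        pkw["gamma_star"] = DEFAULT_GAMMA_STAR
    params = InterventionParams(**pkw)
    run = {k: raw[k] for k in raw if k in _RUN_KEYS}
    use_strict = bool(run.get("strict", True)) if strict is None else strict
    try:
        params.validate(strict=use_strict)
    except ParameterValidationError as e:
        raise ParameterValidationError(f"{path}: {e}") from e

    skw = {}
    if "t_end" in run or "t_start" in run:
        skw["t_span"] = (float(run.get("t_start", 0.0)),
                         float(run.get("t_end", 30.0)))
    for src, dst in (("dense_grid", "dense_grid"), ("rel_tol", "rel_tol"),
                     ("abs_tol", "abs_tol"), ("max_step", "max_step"),
                     ("method", "method")):
        if src in run:
            skw[dst] = (int(run[src]) if dst == "dense_grid"
                        else run[src] if dst == "method"
                        else float(run[src]))
    solver = SolverConfig(**skw)
    for k, v in params.to_dict().items():
        log.info("parameter %s = %g", k, v)
    return {"params": params, "solver": solver, "run": run,
            "strict": use_strict}


def write_config(cfg: dict, path) -> None:
    """Write a config back as flat key:value text (round-trips through
    :func:`read_config` to identical values)."""
    path = Path(path)
    lines = [f"{k}: {v!r}" if isinstance(v, str) else f"{k}: {v}"
             for k, v in cfg["params"].to_dict().items()]
    run = dict(cfg.get("run", {}))
    sc = cfg.get("solver")
    if sc is not None:
        run.setdefault("t_start", sc.t_span[0])
        run.setdefault("t_end", sc.t_span[1])
        run.setdefault("dense_grid", sc.dense_grid)
        run.setdefault("rel_tol", sc.rel_tol)
        run.setdefault("abs_tol", sc.abs_tol)
    for k in sorted(run):
        v = run[k]
        if k == "sweep_values" and isinstance(v, (list, tuple)):
            v = "[" + ", ".join(str(x) for x in v) + "]"
        lines.append(f"{k}: {v}")
    path.write_text("\n".join(lines) + "\n")


def scenario_from_config(cfg: dict) -> ScenarioConfig:
    """Build a ScenarioConfig from a parsed config dict."""
    run = cfg["run"]
    sweep_param = run.get("sweep_param")
    values = run.get("sweep_values", ())
    if isinstance(values, str):
        values = [float(x) for x in values.strip("[]").split(",") if x.strip()]
    if sweep_param is not None and sweep_param not in SWEEPABLE:
        raise ConfigError(f"sweep_param must be one of {SWEEPABLE}")
    return ScenarioConfig(
        name=str(run.get("name", "scenario")), params=cfg["params"],
        sweep_param=sweep_param, sweep_values=tuple(float(v) for v in values),
        i0=float(run.get("i0", 1e-3)), solver=cfg["solver"],
        strict=cfg["strict"], variant=str(run.get("variant", "faithful")))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one CLI run: command, config echo, version,
    seed, timestamps, and output checksums sufficient to reproduce the
    run exactly."""

    command: str
    config_echo: dict
    seed: int | None = None
    software_version: str = __version__
    started: str = ""
    finished: str = ""
    outputs: dict = field(default_factory=dict)

    def start(self):
        self.started = datetime.now(timezone.utc).isoformat()
        return self

    def finish(self, output_paths):
        self.finished = datetime.now(timezone.utc).isoformat()
        self.outputs = {str(p): _sha256(p) for p in output_paths}
        return self

    def write(self, path):
        write_json({
            "command": self.command, "config_echo": self.config_echo,
            "seed": self.seed, "software_version": self.software_version,
            "started": self.started, "finished": self.finished,
            "outputs": self.outputs,
        }, path)
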