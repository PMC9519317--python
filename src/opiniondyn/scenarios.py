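"""Intervention scenario sweeps, engagement series, and calibration.

The scenario study varies one intervention parameter at a time around the
baseline (all offsets zero): the susceptible-control offset ``alpha_bar``,
the spreader-removal offset ``beta_bar``, the latent-activation offset
``xi_bar``, the latent-removal offset ``eta_bar``, and the direct-immunizer
rate ``epsilon``. Default sweep grids are symmetric five-point grids around
zero for the offsets and an ascending grid within ``(0, alpha]`` for
``epsilon``; neither is tabulated anywhere authoritative, so both are
plain package choices and are config-overridable.

Engagement series (daily retweet+comment+like tallies) are the observable
proxy for the spreader fraction: counts are compared against
``scale * I(day)`` — prevalence, not incidence, since visible engagement
volume tracks the current spreader pool. A packaged fixture carries the
handful of counts published for the December 2020 Taihe insurance-fraud
episode (demonstration only; the source phrasing is internally
inconsistent and each number carries a provenance note), and
:func:`synthesize_engagement` generates overdispersed synthetic series for
calibration experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dynamics import (SolverConfig, Trajectory, default_initial_state,
                       integrate)
from .errors import CalibrationError, ParameterValidationError
from .model_zoo import build_seir_intervention
from .params import InterventionParams

__all__ = [
    "ScenarioConfig", "EngagementSeries", "SweepResult", "CalibrationResult",
    "SWEEPABLE", "builtin_cases", "run_sweep", "taihe_fixture",
    "synthesize_engagement", "calibrate", "DEFAULT_SEED",
]

#: Parameters a scenario may sweep (one at a time).
SWEEPABLE = ("alpha_bar", "beta_bar", "xi_bar", "eta_bar", "epsilon")

#: Default RNG seed: the event date of the motivating case study.
DEFAULT_SEED = 20201214

_DEFAULT_OFFSET_GRID = (-0.01, -0.005, 0.0, 0.005, 0.01)
_DEFAULT_EPSILON_GRID = (0.005, 0.01, 0.015, 0.02)


@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario: base parameters plus at most one swept parameter."""

    name: str
    params: InterventionParams = InterventionParams()
    sweep_param: str | None = None
    sweep_values: tuple = ()
    i0: float = 1e-3
    solver: SolverConfig = field(default_factory=SolverConfig)
    strict: bool = True
    variant: str = "faithful"

    def __post_init__(self):
        if self.sweep_param is not None and self.sweep_param not in SWEEPABLE:
            raise ParameterValidationError(
                f"sweep parameter {self.sweep_param!r} not one of {SWEEPABLE}")

    def swept_params(self):
        """Yield (value, InterventionParams) pairs for the sweep."""
        if self.sweep_param is None:
            yield None, self.params
            return
        for v in self.sweep_values:
            yield float(v), self.params.replace(**{self.sweep_param: float(v)})


def builtin_cases() -> list[ScenarioConfig]:
    """The baseline and the five one-parameter intervention cases.

    Fixed values are the baseline row (A=0.02, alpha*=0.02, beta*=0.03,
    xi*=0.05, eta*=0.03, epsilon=0.02, offsets 0, contact rate default).
    The susceptible-control case runs permissively: positive alpha_bar
    pushes the effective alpha below epsilon, exactly as the published
    sweep does, so the alpha >= epsilon bound is demoted to a warning
    there.
    """
    base = InterventionParams()
    cases = [ScenarioConfig(name="baseline", params=base)]
    for k, pname in enumerate(SWEEPABLE, start=1):
        grid = (_DEFAULT_EPSILON_GRID if pname == "epsilon"
                else _DEFAULT_OFFSET_GRID)
        cases.append(ScenarioConfig(
            name=f"case{k}", params=base, sweep_param=pname,
            sweep_values=grid, strict=(pname != "alpha_bar")))
    return cases


@dataclass
class SweepResult:
    """Per-sweep-value trajectory summaries plus qualitative diagnostics."""

    config: ScenarioConfig
    table: pd.DataFrame            # sweep_value, peak_I, t_peak, cumulative_I, final_R
    trajectories: dict             # sweep value -> Trajectory
    monotonicity: dict
    asymmetry: float | None

    def to_dict(self):
        return {
            "name": self.config.name,
            "sweep_param": self.config.sweep_param,
            "gamma_star": self.config.params.gamma_star,
            "gamma_bar": self.config.params.gamma_bar,
            "table": self.table.to_dict(orient="records"),
            "monotonicity": self.monotonicity,
            "asymmetry": self.asymmetry,
        }


def run_sweep(cfg: ScenarioConfig) -> SweepResult:
    """Integrate every sweep value from one shared initial condition.

    Summaries per value: spreader peak and its time, cumulative spreader
    mass, final removed share. Diagnostics: whether the peak is
    non-increasing in the intervention parameter over its nonnegative
    range, and the asymmetry statistic — the absolute cumulative-spreader
    response to the largest positive offset minus that to the largest
    negative one, both relative to the zero-offset run (positive means
    intervention beats anti-intervention of equal size).
    """
    y0 = default_initial_state(cfg.params, i0=cfg.i0,
                               n_compartments=4 if cfg.variant != "reduced"
                               else 3)
    rows, trajs = [], {}
    for value, p in cfg.swept_params():
        viol = p.violations()
        if viol and cfg.strict:
            raise ParameterValidationError(
                f"sweep value {cfg.sweep_param}={value!r} invalid: "
                + "; ".join(viol))
        model = build_seir_intervention(p, variant=cfg.variant,
                                        strict=cfg.strict)
        traj = integrate(model, y0, cfg.solver)
        s = traj.summaries
        rows.append({
            "sweep_value": value if value is not None else 0.0,
            "peak_I": s["peak_I"],
            "t_peak": s["time_to_peak"],
            "cumulative_I": s["cumulative_I"],
            "final_R": (s["final_state"].get("R", 0.0)),
        })
        trajs[value] = traj
    table = pd.DataFrame(rows)

    mono, asym = {}, None
    if cfg.sweep_param is not None and len(table) > 1:
        t = table.sort_values("sweep_value").reset_index(drop=True)
        nonneg = t[t["sweep_value"] >= 0]
        mono["peak_I_nonincreasing_over_nonneg"] = bool(
            np.all(np.diff(nonneg["peak_I"].to_numpy()) <= 1e-12))
        mono["peak_I_nonincreasing_overall"] = bool(
            np.all(np.diff(t["peak_I"].to_numpy()) <= 1e-12))
        vals = t["sweep_value"].to_numpy()
        if (vals.min() < 0 < vals.max()) and (0.0 in vals):
            cum = dict(zip(vals, t["cumulative_I"].to_numpy()))
            c0 = cum[0.0]
            plus, minus = vals.max(), vals.min()
            asym = float(abs(cum[plus] - c0) - abs(cum[minus] - c0))
    return SweepResult(config=cfg, table=table, trajectories=trajs,
                       monotonicity=mono, asymmetry=asym)


# ======================================================================
# Engagement series
# ======================================================================

@dataclass
class EngagementSeries:
    """Daily engagement tallies (retweets + comments + likes proxy)."""

    days: np.ndarray               # integer offsets from event start
    counts: np.ndarray             # nonnegative tallies
    source: str                    # fixture | synthetic
    notes: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=int)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.days, "count": self.counts})

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path, source="fixture"):
        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["day", "count"]:
            raise ValueError("engagement CSV must have header 'day,count'")
        return cls(days=df["day"].to_numpy(), counts=df["count"].to_numpy(),
                   source=source)


def taihe_fixture() -> EngagementSeries:
    """Engagement series for the December 14-20, 2020 insurance-fraud
    episode, assembled only from the handful of published counts.

    Published figures: 2,800 short-comment/retweet engagements and 4,800
    likes, 642 retweets and 835 short comments on the day-1 follow-up
    post; 22 retweets, 101 compliments and 30 comments once attention
    subsided on day 6. The source narrative double-counts and contradicts
    itself for day 1 (flagged ``garbled_in_source``); intermediate days
    carry no published counts and are stored as zero with a note. For
    demonstration only — never used as a quantitative target.
    """
    days = np.arange(7)            # Dec 14 .. Dec 20 inclusive
    counts = np.array([0, 2800 + 4800 + 642 + 835, 0, 0, 0, 0,
                       22 + 101 + 30])
    notes = {
        0: "event first reported; no engagement count published",
        1: ("sum of published day-1 figures (2800 comment/retweet, 4800 "
            "likes, 642 retweets, 835 short comments); source phrasing "
            "double-counts these and is internally inconsistent"),
        2: "no count published", 3: "no count published",
        4: "no count published", 5: "no count published",
        6: "22 retweets + 101 compliments + 30 comments after resolution",
        "garbled_in_source": True,
    }
    return EngagementSeries(days=days, counts=counts, source="fixture",
                            notes=notes)


def _spreader_curve(p: InterventionParams, days, i0, solver=None,
                    strict=True):
    """I(day) of the reduced model at the requested integer days."""
    days = np.asarray(days, dtype=float)
    cfg = solver or SolverConfig(t_span=(0.0, max(days.max(), 1.0)),
                                 dense_grid=max(int(days.max()) * 20 + 1, 41))
    model = build_seir_intervention(p, variant="reduced", strict=strict)
    y0 = default_initial_state(p, i0=i0, n_compartments=3)
    traj = integrate(model, y0, cfg)
    return np.interp(days, traj.times, traj["I"])


def synthesize_engagement(traj: Trajectory, scale: float, dispersion: float,
                          seed: int = DEFAULT_SEED,
                          days=None) -> EngagementSeries:
    """Draw an overdispersed synthetic engagement series from a trajectory.

    Daily counts are negative-binomial with mean ``scale * I(day)`` and
    variance ``mean + dispersion * mean**2`` (Poisson-gamma mixture);
    ``dispersion == 0`` is the noiseless limit and returns the rounded
    means. Deterministic given ``seed``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be nonnegative")
    if days is None:
        days = np.arange(int(np.ceil(traj.times[0])),
                         int(np.floor(traj.times[-1])) + 1)
    days = np.asarray(days, dtype=int)
    spreader = "I" if "I" in traj.compartments else "spreader"
    mu = scale * np.interp(days, traj.times, traj[spreader])
    mu = np.clip(mu, 0.0, None)
    if dispersion == 0:
        counts = np.rint(mu).astype(int)
    else:
        rng = np.random.default_rng(seed)
        n = 1.0 / dispersion
        p = n / (n + np.clip(mu, 1e-12, None))
        counts = rng.negative_binomial(n, p)
    return EngagementSeries(
        days=days, counts=counts, source="synthetic",
        metadata={"scale": scale, "dispersion": dispersion, "seed": seed})


# ======================================================================
# Calibration
# ======================================================================

#: Parameters calibrate() may fit ('scale' is the engagement scale factor).
CALIBRATABLE = ("gamma_star", "alpha_bar", "beta_bar", "xi_bar", "eta_bar",
                "epsilon", "scale")

_DEFAULT_BOUNDS = {
    "gamma_star": (0.0, 1.0), "alpha_bar": (-0.5, 0.5),
    "beta_bar": (-0.5, 0.5), "xi_bar": (-0.5, 0.5), "eta_bar": (-0.5, 0.5),
    "epsilon": (0.0, 0.5), "scale": (1e-6, 1e9),
}


@dataclass
class CalibrationResult:
    fitted: dict
    objective: float
    success: bool
    message: str
    n_evaluations: int
    loss: str

    def to_dict(self):
        return {"fitted": {k: float(v) for k, v in self.fitted.items()},
                "objective": float(self.objective), "success": self.success,
                "message": self.message,
                "n_evaluations": self.n_evaluations, "loss": self.loss}


def calibrate(series: EngagementSeries, free=("gamma_star",),
              base: InterventionParams = InterventionParams(),
              scale: float = 5000.0, bounds: dict | None = None,
              x0: dict | None = None, i0: float = 1e-3,
              weights=None, loss: str = "ls",
              strict: bool = False) -> CalibrationResult:
    """Fit model parameters (and/or the engagement scale) to daily counts.

    Least squares of ``scale * I(day; params)`` against the observed
    counts, optionally weighted; ``loss='poisson'`` uses the signed square
    root of the unit Poisson deviance as residuals instead. Deterministic
    given the starting point and bounds. Raises
    :class:`CalibrationError` (carrying the best iterate) on
    non-convergence.

    Parameters
    ----------
    free : sequence of names from ``CALIBRATABLE`` (at least one).
    base : fixed parameter values for everything not fitted.
    scale : engagement scale when 'scale' is not being fitted.
    """
    free = tuple(free)
    if not free:
        raise ValueError("need at least one free parameter")
    for f in free:
        if f not in CALIBRATABLE:
            raise ValueError(f"{f!r} is not calibratable; choose from "
                             f"{CALIBRATABLE}")
    if len(series.days) < len(free) + 1:
        raise ValueError(
            f"series has {len(series.days)} points; need at least "
            f"{len(free) + 1} for {len(free)} free parameter(s)")
    counts = series.counts.astype(float)
    w = np.ones_like(counts) if weights is None else np.asarray(
        weights, dtype=float)
    bnds = dict(_DEFAULT_BOUNDS)
    bnds.update(bounds or {})
    lo = np.array([bnds[f][0] for f in free])
    hi = np.array([bnds[f][1] for f in free])
    start = {"scale": scale, **{f: getattr(base, f) for f in free
                                if f != "scale"}}
    start.update(x0 or {})
    v0 = np.clip(np.array([start[f] for f in free]), lo, hi)

    def predict(vec):
        kw = dict(zip(free, vec))
        sc = kw.pop("scale", scale)
        p = base.replace(**kw) if kw else base
        return sc * _spreader_curve(p, series.days, i0, strict=strict)

    def residuals(vec):
        mu = predict(vec)
        if loss == "ls":
            return w * (mu - counts)
        if loss == "poisson":
            mu_ = np.clip(mu, 1e-12, None)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(counts > 0,
                                counts * np.log(counts / mu_), 0.0)
            dev = 2.0 * (term - (counts - mu_))
            return np.sign(counts - mu_) * np.sqrt(np.clip(dev, 0.0, None))
        raise ValueError(f"unknown loss {loss!r}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # permissive sweeps may warn
        sol = least_squares(residuals, v0, bounds=(lo, hi), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
    fitted = dict(zip(free, sol.x))
    result = CalibrationResult(
        fitted=fitted, objective=float(sol.cost), success=bool(sol.success),
        message=str(sol.message), n_evaluations=int(sol.nfev), loss=loss)
    if not sol.success:
        raise CalibrationError(
            f"calibration did not converge: {sol.message}",
            best_iterate=result)
    return result
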