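"""Parameter vectors for the intervention-aware SE-IR opinion model.

The model distinguishes *natural* transfer rates (starred: ``alpha_star`` ...)
from additive *government intervention* offsets (barred: ``alpha_bar`` ...).
Signs are chosen so that positive offsets suppress spreading: interventions
lower the susceptible-to-spreader and latent-to-spreader rates (``alpha``,
``xi``) and raise the removal rates (``beta``, the latent drain ``eta_bar``).
``epsilon`` is the direct-immunizer rate: the fraction of susceptibles per
unit time who move straight to the removed class without ever engaging
(education-driven immunity). ``A`` is the inflow of new netizens per unit
time, expressed as a fraction of the initial population per day.

The contact rate ``gamma_star`` (with offset ``gamma_bar``) governs the
bilinear susceptible-spreader infection term. It has no tabulated reference
value in the scenario study, so it is a required configuration field with a
documented default of 0.5/day (offset 0); every scenario output echoes the
value actually used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, replace, fields

from .errors import ParameterValidationError

#: Documented default contact rate (no tabulated value exists for it).
DEFAULT_GAMMA_STAR = 0.5
DEFAULT_GAMMA_BAR = 0.0


@dataclass(frozen=True)
class InterventionParams:
    """Full parameter vector of the intervention SE-IR model.

    Defaults are the baseline scenario of the case study: all intervention
    offsets zero and the natural rates
    ``A=0.02, alpha*=0.02, beta*=0.03, xi*=0.05, eta*=0.03, epsilon=0.02``.
    """

    A: float = 0.02
    alpha_star: float = 0.02
    alpha_bar: float = 0.0
    beta_star: float = 0.03
    beta_bar: float = 0.0
    xi_star: float = 0.05
    xi_bar: float = 0.0
    eta_star: float = 0.03
    eta_bar: float = 0.0
    epsilon: float = 0.02
    gamma_star: float = DEFAULT_GAMMA_STAR
    gamma_bar: float = DEFAULT_GAMMA_BAR

    # ---- derived effective rates -------------------------------------
    @property
    def alpha(self) -> float:
        return self.alpha_star - self.alpha_bar

    @property
    def beta(self) -> float:
        return self.beta_star + self.beta_bar

    @property
    def xi(self) -> float:
        return self.xi_star - self.xi_bar

    @property
    def gamma(self) -> float:
        return self.gamma_star - self.gamma_bar

    # ---- validation ---------------------------------------------------
    def violations(self) -> list[str]:
        """Return human-readable descriptions of every violated bound."""
        v = []

        def _in(name, x, lo, hi):
            if not (lo <= x <= hi):
                v.append(f"{name}={x:g} outside [{lo}, {hi}]")

        _in("A", self.A, 0.0, 1.0)
        for name in ("alpha_star", "beta_star", "xi_star", "eta_star",
                     "gamma_star", "epsilon"):
            _in(name, getattr(self, name), 0.0, 1.0)
        for name in ("alpha_bar", "beta_bar", "xi_bar", "eta_bar",
                     "gamma_bar"):
            _in(name, getattr(self, name), -1.0, 1.0)
        # Bounds on the effective (intervened) rates.
        _in("alpha_star - alpha_bar", self.alpha, 0.0, 1.0)
        _in("beta_star + beta_bar", self.beta, 0.0, 1.0)
        _in("xi_star - xi_bar", self.xi, -1.0, 1.0)
        _in("eta_star + eta_bar", self.eta_star + self.eta_bar, 0.0, 1.0)
        _in("gamma_star - gamma_bar", self.gamma, 0.0, 1.0)
        if self.alpha < self.epsilon:
            v.append(
                f"alpha_star - alpha_bar = {self.alpha:g} < epsilon = "
                f"{self.epsilon:g} (effective alpha must dominate the "
                "direct-immunizer rate)")
        return v

    def validate(self, strict: bool = True) -> "InterventionParams":
        """Check every bound; raise in strict mode, warn otherwise."""
        v = self.violations()
        if v:
            msg = "; ".join(v)
            if strict:
                raise ParameterValidationError(msg)
            warnings.warn(f"parameter bounds violated (permissive mode): {msg}")
        return self

    def replace(self, **kw) -> "InterventionParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


#: Baseline scenario parameters (all intervention offsets zero).
BASELINE = InterventionParams()


@dataclass(frozen=True)
class EffectiveRates:
    """Post-intervention rates of the reduced 3-equation opinion model.

    ``alpha = alpha* - alpha_bar``, ``beta = beta* + beta_bar``,
    ``xi = xi* - xi_bar``, ``gamma = gamma* - gamma_bar``;
    ``eta_star``, ``eta_bar``, ``epsilon`` and the inflow ``A`` pass through
    unchanged (the latent drain is ``(xi + eta_bar) E`` so ``eta_bar`` stays
    separate from ``xi``).
    """

    alpha: float
    beta: float
    xi: float
    gamma: float
    eta_star: float
    eta_bar: float
    epsilon: float
    A: float

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "EffectiveRates":
        return replace(self, **kw)


def effective_rates(p: InterventionParams, strict: bool = True) -> EffectiveRates:
    """Collapse natural rates and intervention offsets into effective rates.

    Parameters
    ----------
    p : InterventionParams
    strict : bool
        If True (default), any violated bound raises
        :class:`ParameterValidationError` naming the offending bound;
        otherwise a warning is emitted and the rates are returned anyway.
    """
    p.validate(strict=strict)
    return EffectiveRates(
        alpha=p.alpha, beta=p.beta, xi=p.xi, gamma=p.gamma,
        eta_star=p.eta_star, eta_bar=p.eta_bar,
        epsilon=p.epsilon, A=p.A,
    )
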