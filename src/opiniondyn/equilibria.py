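"""Steady states of the reduced (S, E, I) intervention opinion model.

Two notions of steady state coexist here and are deliberately kept apart:

* the *constrained* equilibria of the source analysis, which replace the
  latent balance equation by the side identity ``epsilon*S = eta_star*E``
  (sum the S and E balance lines, then impose the identity). These have
  closed forms but do **not** in general zero the latent RHS line — the
  per-line residuals are reported honestly rather than hidden;
* the *exact* equilibrium: a simultaneous root of all three RHS lines found
  numerically, with residuals verified below 1e-10.

The constrained nonzero point solves the linear system

    A - (xi + eta_bar) E - (alpha + epsilon) S = 0
    alpha S + xi E - beta I = 0
    epsilon S = eta_star E

whose solution is ``S* = A eta* / (eps (xi + eta_bar + eta*) + alpha eta*)``
(a widely circulated variant of this denominator drops the factor of
``eps`` on two terms; the linear solve is authoritative and the variant is
archived in the result notes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from .errors import DegenerateParameterError, RootFindingError
from .params import EffectiveRates

__all__ = [
    "EquilibriumPoint", "model2_rhs",
    "zero_propagation_equilibrium", "nonzero_constrained_equilibrium",
    "nonzero_exact_equilibrium",
]

#: Residual tolerance for exact equilibria (states are O(1) fractions).
EXACT_RESIDUAL_TOL = 1e-10


def model2_rhs(r: EffectiveRates, state) -> np.ndarray:
    """RHS of the reduced three-equation model at a state (S, E, I)."""
    S, E, I = state
    force = (1.0 - r.epsilon) * r.gamma * S * I
    return np.array([
        r.A - force - (r.alpha + r.epsilon) * S,
        force - (r.xi + r.eta_bar) * E,
        r.alpha * S + r.xi * E - r.beta * I,
    ])


@dataclass
class EquilibriumPoint:
    """A candidate steady state with honest residual reporting.

    residuals : value of each reduced-model RHS line at the state.
    constraint_residual : ``|epsilon*S - eta_star*E|``.
    """

    state: np.ndarray
    kind: str                      # zero_propagation | nonzero_constrained | nonzero_exact
    residuals: np.ndarray
    constraint_residual: float
    method: str                    # closed_form | linear_solve | root_finding
    notes: dict = field(default_factory=dict)

    @property
    def S(self): return float(self.state[0])

    @property
    def E(self): return float(self.state[1])

    @property
    def I(self): return float(self.state[2])

    def to_dict(self):
        return {
            "kind": self.kind, "method": self.method,
            "S": self.S, "E": self.E, "I": self.I,
            "residuals": [float(x) for x in self.residuals],
            "constraint_residual": float(self.constraint_residual),
            "notes": self.notes,
        }


def _make_point(r, state, kind, method, notes=None):
    state = np.asarray(state, dtype=float)
    res = model2_rhs(r, state)
    cres = abs(r.epsilon * state[0] - r.eta_star * state[1])
    return EquilibriumPoint(state=state, kind=kind, residuals=res,
                            constraint_residual=float(cres), method=method,
                            notes=dict(notes or {}))


def zero_propagation_equilibrium(r: EffectiveRates) -> EquilibriumPoint:
    """Spreader-free steady state ``(A/(a+e), e A/(eta* (a+e)), 0)``.

    With ``epsilon > 0`` the latent RHS line is nonzero at this point (its
    balance is replaced by the ``epsilon*S = eta_star*E`` identity); the
    residual vector reports this honestly. ``epsilon = 0`` recovers the
    classical spreader-free point ``(A/alpha, 0, 0)``.
    """
    ae = r.alpha + r.epsilon
    if ae <= 0:
        raise DegenerateParameterError("alpha + epsilon must be positive")
    if r.eta_star <= 0:
        raise DegenerateParameterError("eta_star must be positive")
    S = r.A / ae
    E = r.epsilon * r.A / (r.eta_star * ae)
    pt = _make_point(r, (S, E, 0.0), "zero_propagation", "closed_form")
    pt.notes["latent_line_nonzero"] = bool(abs(pt.residuals[1]) > 1e-14)
    return pt


def nonzero_constrained_equilibrium(r: EffectiveRates) -> EquilibriumPoint:
    """Persistent-spreading steady state under ``epsilon*S = eta_star*E``.

    Solves the 3x3 linear system (S+E balance summed, spreader balance,
    side identity) exactly. Closed form:
    ``S* = A eta* / (eps (xi + eta_bar + eta*) + alpha eta*)``,
    ``E* = eps S* / eta*``, ``I* = (alpha S* + xi E*) / beta``.
    """
    if r.eta_star <= 0:
        raise DegenerateParameterError("eta_star must be positive")
    if r.beta <= 0:
        raise DegenerateParameterError("beta must be positive")
    M = np.array([
        [-(r.alpha + r.epsilon), -(r.xi + r.eta_bar), 0.0],
        [r.alpha, r.xi, -r.beta],
        [r.epsilon, -r.eta_star, 0.0],
    ])
    b = np.array([-r.A, 0.0, 0.0])
    if abs(np.linalg.det(M)) < 1e-300:
        raise DegenerateParameterError(
            "constrained equilibrium system is singular")
    state = np.linalg.solve(M, b)
    denom = r.epsilon * (r.xi + r.eta_bar + r.eta_star) + r.alpha * r.eta_star
    notes = {
        "closed_form_denominator": denom,
        "closed_form_S": r.A * r.eta_star / denom if denom else None,
        "variant_denominator_without_eps_factor":
            r.epsilon * r.xi + r.eta_star + r.epsilon * r.eta_bar
            + r.alpha * r.eta_star,
        "linear_system_residual": [float(x) for x in (M @ state - b)],
    }
    return _make_point(r, state, "nonzero_constrained", "linear_solve", notes)


def nonzero_exact_equilibrium(r: EffectiveRates, guess=None
                              ) -> EquilibriumPoint:
    """Simultaneous root of all three reduced RHS lines.

    Starts from ``guess`` (default: the constrained point, or a small
    positive state if that is degenerate) and polishes with a hybrid
    Newton method; residuals are verified below ``1e-10 * max(1, A)``.
    Also reports the Euclidean distance to the constrained point.
    """
    if guess is None:
        try:
            guess = nonzero_constrained_equilibrium(r).state
        except DegenerateParameterError:
            guess = np.array([0.1, 0.1, 0.1])
    guess = np.asarray(guess, dtype=float)
    if np.any(guess < 0):
        raise ValueError("guess must lie in the nonnegative orthant")
    sol = root(lambda y: model2_rhs(r, y), guess, method="hybr",
               tol=1e-13)
    res = model2_rhs(r, sol.x)
    tol = EXACT_RESIDUAL_TOL * max(1.0, r.A)
    # the residual is authoritative: hybr can report lack of progress
    # after it has already landed on a machine-precision root
    if np.max(np.abs(res)) > tol:
        raise RootFindingError(
            f"equilibrium root finding failed (max residual "
            f"{np.max(np.abs(res)):.3e}): {sol.message}",
            last_iterate=sol.x)
    pt = _make_point(r, sol.x, "nonzero_exact", "root_finding")
    try:
        constrained = nonzero_constrained_equilibrium(r)
        pt.notes["distance_to_constrained"] = float(
            np.linalg.norm(pt.state - constrained.state))
    except DegenerateParameterError:
        pt.notes["distance_to_constrained"] = None
    return pt
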