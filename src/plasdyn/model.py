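"""Core three-compartment plasmid population model.

The model tracks relative densities of plasmid-free bacteria ``F``,
non-adapted plasmid bearers ``P`` and adapted plasmid bearers ``A`` in a
well-mixed habitat with logistic resource limitation.  All processes are
mass-action reactions whose rates are modulated by resource availability
``f = 1 - (F + P + A)/k``:

* growth at maximal rate ``psi``, discounted by the plasmid cost ``alpha``
  for P and by the residual cost ``alpha * (1 - beta)`` for A;
* mortality/washout at rate ``omega`` for everyone, plus antibiotic killing
  ``upsilon`` acting on plasmid-free (sensitive) cells only;
* segregational plasmid loss at probability ``tau`` per division;
* conjugative transfer at rate ``gamma`` (second order in donor and
  recipient density);
* compensatory mutation at probability ``chi`` per replication event.

Two mutation variants differ in where the compensatory mutation resides.
A *chromosomal* mutation is inherited only vertically: conjugation from an
adapted donor produces a non-adapted transconjugant.  A *plasmid* mutation
travels with the plasmid: transconjugants of adapted donors are adapted,
and replication during transfer itself can generate the mutation
(rate ``f * chi * gamma * F * P``).  The *no-mutation* variant is the same
system with ``chi = 0`` and serves as the baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable

import numpy as np

__all__ = [
    "ModelVariant",
    "ModelParams",
    "PopulationState",
    "RateBreakdown",
    "DEFAULT_PARAMS",
    "resource_availability",
    "reaction_rates",
    "rhs",
    "make_rhs",
    "make_jacobian",
]


class ModelVariant(str, Enum):
    """Genomic location of the compensatory mutation."""

    NO_MUTATION = "no_mutation"
    CHROMOSOMAL = "chromosomal"
    PLASMID = "plasmid"


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class ModelParams:
    """Immutable parameter set for one model run.

    Defaults are the reference values used throughout: a plasmid costing
    20% of the maximal growth rate whose cost can be ameliorated by 90%,
    in a habitat diluted at 0.1/h, with no antibiotic.

    Parameters
    ----------
    k : float
        Carrying capacity (relative density; 1 by convention).
    psi : float
        Maximal growth rate, 1/h.
    alpha : float
        Plasmid cost, as a fraction of ``psi`` (0..1).
    beta : float
        Amelioration strength: fraction of ``alpha`` removed by the
        compensatory mutation (0..1).
    omega : float
        Dilution rate (washout + mortality + predation), 1/h.
    upsilon : float
        Antibiotic killing rate on plasmid-free cells, 1/h.
    tau : float
        Segregational loss probability per division (0..1).
    gamma : float
        Conjugation rate, per (relative density * h).
    chi : float
        Compensatory mutation probability per replication event (0..1).
    variant : ModelVariant
        Which model variant the parameters drive.
    """

    k: float = 1.0
    psi: float = 1.0
    alpha: float = 0.2
    beta: float = 0.9
    omega: float = 0.1
    upsilon: float = 0.0
    tau: float = 0.001
    gamma: float = 0.02
    chi: float = 1e-6
    variant: ModelVariant = ModelVariant.NO_MUTATION

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _require(self.k > 0, f"k must be > 0, got {self.k}")
        _require(0.0 <= self.alpha <= 1.0, f"alpha must be in [0, 1], got {self.alpha}")
        _require(0.0 <= self.beta <= 1.0, f"beta must be in [0, 1], got {self.beta}")
        _require(0.0 <= self.tau <= 1.0, f"tau must be in [0, 1], got {self.tau}")
        _require(0.0 <= self.chi <= 1.0, f"chi must be in [0, 1], got {self.chi}")
        for name in ("psi", "omega", "upsilon", "gamma"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("k", "psi", "alpha", "beta", "omega", "upsilon", "tau", "gamma", "chi"):
            _require(math.isfinite(getattr(self, name)), f"{name} must be finite")
        if not isinstance(self.variant, ModelVariant):
            # accept the string spelling for convenience
            object.__setattr__(self, "variant", ModelVariant(self.variant))

    @property
    def residual_cost(self) -> float:
        """Effective cost of adapted bearers, ``alpha * (1 - beta)``."""
        return self.alpha * (1.0 - self.beta)

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "k": self.k, "psi": self.psi, "alpha": self.alpha, "beta": self.beta,
            "omega": self.omega, "upsilon": self.upsilon, "tau": self.tau,
            "gamma": self.gamma, "chi": self.chi, "variant": self.variant.value,
        }


DEFAULT_PARAMS = ModelParams()


@dataclass(frozen=True)
class PopulationState:
    """Relative densities of the three compartments at one time point."""

    F: float
    P: float
    A: float

    def __post_init__(self) -> None:
        for name in ("F", "P", "A"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"state component {name} is not finite: {getattr(self, name)}")

    @property
    def total(self) -> float:
        return self.F + self.P + self.A

    @property
    def plasmid_fraction(self) -> float:
        """Combined density of plasmid bearers, ``P + A``."""
        return self.P + self.A

    def as_array(self) -> np.ndarray:
        return np.array([self.F, self.P, self.A], dtype=float)

    @classmethod
    def from_array(cls, y) -> "PopulationState":
        return cls(float(y[0]), float(y[1]), float(y[2]))


@dataclass(frozen=True)
class RateBreakdown:
    """Per-process reaction rates evaluated at one state.

    ``mutation_growth`` is the replication-coupled mutation flux P -> A;
    ``mutation_transfer`` is the transfer-coupled flux, nonzero only when
    the mutation rides on the plasmid.
    """

    f: float
    growth_F: float
    growth_P: float
    growth_A: float
    mortality_F: float
    mortality_P: float
    mortality_A: float
    segregation_P: float
    segregation_A: float
    conjugation_FP: float
    conjugation_FA: float
    mutation_growth: float
    mutation_transfer: float


def resource_availability(state: PopulationState, k: float) -> float:
    """Fraction of unused capacity, ``f = 1 - (F + P + A)/k``.

    Passed through unclamped: a total above ``k`` yields a negative value,
    which reverses the growth terms and restores the mass bound.
    """
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    total = state.total  # PopulationState guarantees finiteness
    return 1.0 - total / k


def reaction_rates(state: PopulationState, params: ModelParams) -> RateBreakdown:
    """Evaluate every process rate of the reaction matrix at ``state``."""
    f = resource_availability(state, params.k)
    F, P, A = state.F, state.P, state.A
    psi, alpha, beta = params.psi, params.alpha, params.beta
    g_P = 1.0 - alpha                    # growth discount of non-adapted bearers
    g_A = 1.0 - alpha * (1.0 - beta)     # growth discount of adapted bearers

    chi = 0.0 if params.variant is ModelVariant.NO_MUTATION else params.chi
    return RateBreakdown(
        f=f,
        growth_F=f * psi * F,
        growth_P=f * psi * g_P * P,
        growth_A=f * psi * g_A * A,
        mortality_F=(params.omega + params.upsilon) * F,
        mortality_P=params.omega * P,
        mortality_A=params.omega * A,
        segregation_P=f * params.tau * psi * g_P * P,
        segregation_A=f * params.tau * psi * g_A * A,
        conjugation_FP=f * params.gamma * F * P,
        conjugation_FA=f * params.gamma * F * A,
        mutation_growth=f * chi * psi * g_P * P,
        mutation_transfer=(
            f * chi * params.gamma * F * P
            if params.variant is ModelVariant.PLASMID else 0.0
        ),
    )


def rhs(state: PopulationState, params: ModelParams) -> tuple[float, float, float]:
    """Time derivatives ``(dF/dt, dP/dt, dA/dt)``.

    Stoichiometry-weighted sum of the process rates.  The destination of
    conjugation from adapted donors and the presence of the
    transfer-coupled mutation flux are the only points where the variants
    differ.
    """
    r = reaction_rates(state, params)
    dF = (r.growth_F - r.mortality_F + r.segregation_P + r.segregation_A
          - r.conjugation_FP - r.conjugation_FA)
    dP = (r.growth_P - r.mortality_P - r.segregation_P + r.conjugation_FP
          - r.mutation_growth)
    dA = r.growth_A - r.mortality_A - r.segregation_A + r.mutation_growth
    v = params.variant
    if v is ModelVariant.CHROMOSOMAL or v is ModelVariant.NO_MUTATION:
        dP += r.conjugation_FA
    elif v is ModelVariant.PLASMID:
        dA += r.conjugation_FA
        dP -= r.mutation_transfer
        dA += r.mutation_transfer
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown model variant: {v!r}")
    return dF, dP, dA


def make_rhs(params: ModelParams) -> Callable[[float, np.ndarray], list[float]]:
    """Compile the vector field into a lean ``fun(t, y)`` closure.

    Equivalent to :func:`rhs` (tested against it) but avoids per-call
    dataclass construction; this is the hot path of every integration.
    """
    k = params.k
    psi, omega, upsilon = params.psi, params.omega, params.upsilon
    tau, gamma = params.tau, params.gamma
    g_P = 1.0 - params.alpha
    g_A = 1.0 - params.alpha * (1.0 - params.beta)
    v = params.variant
    chi = 0.0 if v is ModelVariant.NO_MUTATION else params.chi
    plasmid = v is ModelVariant.PLASMID

    def fun(t: float, y) -> list[float]:
        F, P, A = y[0], y[1], y[2]
        f = 1.0 - (F + P + A) / k
        seg_P = f * tau * psi * g_P * P
        seg_A = f * tau * psi * g_A * A
        conj_FP = f * gamma * F * P
        conj_FA = f * gamma * F * A
        mut_g = f * chi * psi * g_P * P
        dF = f * psi * F - (omega + upsilon) * F + seg_P + seg_A - conj_FP - conj_FA
        dP = f * psi * g_P * P - omega * P - seg_P + conj_FP - mut_g
        dA = f * psi * g_A * A - omega * A - seg_A + mut_g
        if plasmid:
            mut_t = f * chi * gamma * F * P
            dA += conj_FA + mut_t
            dP -= mut_t
        else:
            dP += conj_FA
        return [dF, dP, dA]

    return fun


def make_jacobian(params: ModelParams) -> Callable[[float, np.ndarray], np.ndarray]:
    """Analytic Jacobian of the vector field, for the stiff solver.

    Verified against a finite-difference Jacobian in the test suite.
    """
    k = params.k
    psi, omega, upsilon = params.psi, params.omega, params.upsilon
    tau, gamma = params.tau, params.gamma
    g_P = 1.0 - params.alpha
    g_A = 1.0 - params.alpha * (1.0 - params.beta)
    v = params.variant
    chi = 0.0 if v is ModelVariant.NO_MUTATION else params.chi
    plasmid = v is ModelVariant.PLASMID
    fx = -1.0 / k  # d f / d(any compartment)

    def jac(t: float, y) -> np.ndarray:
        F, P, A = y[0], y[1], y[2]
        f = 1.0 - (F + P + A) / k
        seg_sum = tau * psi * (g_P * P + g_A * A)   # segregation / f
        conj_F = gamma * F * (P + A)                 # total conjugation / f

        # dF/dt = f*psi*F - (omega+upsilon)*F + f*seg_sum - f*conj_F
        dF_dF = psi * (fx * F + f) - (omega + upsilon) + fx * seg_sum \
            - gamma * (fx * F * (P + A) + f * (P + A))
        dF_dP = psi * fx * F + fx * seg_sum + f * tau * psi * g_P \
            - gamma * (fx * F * (P + A) + f * F)
        dF_dA = psi * fx * F + fx * seg_sum + f * tau * psi * g_A \
            - gamma * (fx * F * (P + A) + f * F)

        # base dP/dt = f*psi*g_P*P - omega*P - f*tau*psi*g_P*P
        #            + f*gamma*F*P - f*chi*psi*g_P*P
        c_P = psi * g_P * (1.0 - tau - chi)          # (growth - seg - mut)/f per P
        dP_dF = fx * c_P * P + gamma * (fx * F * P + f * P)
        dP_dP = f * c_P + fx * c_P * P - omega + gamma * (fx * F * P + f * F)
        dP_dA = fx * c_P * P + gamma * fx * F * P

        # base dA/dt = f*psi*g_A*A - omega*A - f*tau*psi*g_A*A + f*chi*psi*g_P*P
        c_A = psi * g_A * (1.0 - tau)
        dA_dF = fx * (c_A * A + chi * psi * g_P * P)
        dA_dP = fx * (c_A * A + chi * psi * g_P * P) + f * chi * psi * g_P
        dA_dA = f * c_A + fx * (c_A * A + chi * psi * g_P * P) - omega

        if plasmid:
            # conj_FA feeds A; transfer-mutation flux chi*gamma*F*P moves P->A
            m = chi * gamma
            dA_dF += gamma * (fx * F * A + f * A) + m * (fx * F * P + f * P)
            dA_dP += gamma * fx * F * A + m * (fx * F * P + f * F)
            dA_dA += gamma * (fx * F * A + f * F) + m * fx * F * P
            dP_dF -= m * (fx * F * P + f * P)
            dP_dP -= m * (fx * F * P + f * F)
            dP_dA -= m * fx * F * P
        else:
            # conj_FA feeds P
            dP_dF += gamma * (fx * F * A + f * A)
            dP_dP += gamma * fx * F * A
            dP_dA += gamma * (fx * F * A + f * F)

        return np.array([
            [dF_dF, dF_dP, dF_dA],
            [dP_dF, dP_dP, dP_dA],
            [dA_dF, dA_dP, dA_dA],
        ])

    return jac
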