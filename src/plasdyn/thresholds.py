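"""Analytic transmission-fitness coordinates and the conjugation threshold.

A plasmid's fate in the absence of positive selection is framed by two
dimensionless fitness components, both normalised to the maximal growth
rate ``psi``:

* vertical transmission fitness ``(1 - alpha) * (1 - tau)`` — growth of
  bearers relative to plasmid-free cells, discounted by segregational
  loss;
* horizontal transmission fitness ``gamma / psi`` — conjugation relative
  to the rate at which new susceptible cells are produced.

Balancing the two gives a lower conjugation threshold
``gamma_low = alpha * psi * (1 - tau)``: a costly plasmid conjugating more
slowly than this cannot persist without antibiotic selection.  The
threshold is an exclusion criterion, not a stability guarantee — plasmids
above it may still be lost to dilution.  Compensation reduces the
operative cost to ``alpha * (1 - beta)`` and shifts the threshold down
accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import ModelParams

__all__ = [
    "FitnessCoordinates",
    "gamma_low",
    "fitness_coordinates",
    "adjust_conjugation_rate",
    "to_relative_conjugation_rate",
    "transfer_fitness_inequality",
]


@dataclass(frozen=True)
class FitnessCoordinates:
    """Position of a parameter set in the transmission-fitness plane."""

    vertical: float
    horizontal: float
    gamma_low: float
    gamma_low_compensated: float

    def to_dict(self) -> dict:
        return {
            "vertical": self.vertical,
            "horizontal": self.horizontal,
            "gamma_low": self.gamma_low,
            "gamma_low_compensated": self.gamma_low_compensated,
        }


def gamma_low(alpha: float, psi: float, tau: float) -> float:
    """Lowest conjugation rate that can sustain a costly plasmid.

    ``gamma_low = alpha * psi * (1 - tau)``.  For the compensated cost,
    pass ``alpha * (1 - beta)`` as the cost.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    if psi < 0:
        raise ValueError(f"psi must be >= 0, got {psi}")
    return alpha * psi * (1.0 - tau)


def fitness_coordinates(params: ModelParams) -> FitnessCoordinates:
    """Vertical/horizontal fitness plus both conjugation thresholds."""
    if params.psi == 0:
        raise ValueError("fitness coordinates are undefined for psi = 0 (normalisation)")
    return FitnessCoordinates(
        vertical=(1.0 - params.alpha) * (1.0 - params.tau),
        horizontal=params.gamma / params.psi,
        gamma_low=gamma_low(params.alpha, params.psi, params.tau),
        gamma_low_compensated=gamma_low(params.residual_cost, params.psi, params.tau),
    )


def adjust_conjugation_rate(gamma_relative: float, k_absolute: float) -> float:
    """Convert a relative-density conjugation rate to absolute units.

    Relative rates (per relative density per hour) divide by the absolute
    carrying capacity to give ml/(cells*h); e.g. gamma=0.02 at k=1e9
    cells/ml gives 2e-11.
    """
    if k_absolute <= 0:
        raise ValueError(f"k_absolute must be > 0, got {k_absolute}")
    return gamma_relative / k_absolute


def to_relative_conjugation_rate(gamma_absolute: float, k_absolute: float) -> float:
    """Inverse of :func:`adjust_conjugation_rate`: multiply by capacity."""
    if k_absolute <= 0:
        raise ValueError(f"k_absolute must be > 0, got {k_absolute}")
    return gamma_absolute * k_absolute


def transfer_fitness_inequality(params: ModelParams) -> bool:
    """Diagnostic flag: ``1 - alpha*(1-beta)*(1-tau) < gamma/psi``.

    An alternative way of writing the persistence condition that is not
    algebraically consistent with ``gamma_low``; exposed for inspection
    only.  The operative threshold everywhere in this package is
    :func:`gamma_low`.
    """
    if params.psi == 0:
        raise ValueError("undefined for psi = 0")
    lhs = 1.0 - params.alpha * (1.0 - params.beta) * (1.0 - params.tau)
    return lhs < params.gamma / params.psi
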