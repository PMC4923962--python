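"""Closed-form physics and move probabilities.

Two independent pieces live here:

* Stokes sedimentation of a small sphere at low Reynolds number — the drag
  force ``F = 6*pi*R*eta*v`` and the terminal settling velocity obtained by
  balancing drag against the apparent weight,
  ``v = (2/9) r_c^2 (rho_c - rho_m) g / eta``. These are reporting
  utilities: they describe why a suspended cell drifts downward, but the
  automaton moves by the probability ladder below, not by this velocity.

* The gravity-biased move-probability ladder of the descent phase. The
  four axial neighbors of a suspended cell are grouped into three levels —
  one position above, two lateral, one below — with probabilities a/2, a
  and 2a. Normalization a/2 + a + 2a = 1 gives a = 2/7, hence level
  probabilities 1/7, 2/7 and 4/7. The lateral total is split equally
  between left and right (no stated asymmetry), so the per-position
  probabilities are (1/7, 1/7, 1/7, 4/7) for (up, left, right, down).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from .model_core import ConfigError

STANDARD_GRAVITY_M_S2 = 9.8


@dataclass(frozen=True)
class StokesParams:
    """Parameters of the settling-velocity formula (SI units).

    r_c: cell radius [m]; rho_c, rho_m: cell and medium densities [kg/m^3];
    eta: medium dynamic viscosity [Pa s]; g: gravitational acceleration.
    """

    r_c: float
    rho_c: float
    rho_m: float
    eta: float
    g: float = STANDARD_GRAVITY_M_S2

    def __post_init__(self):
        if self.r_c <= 0:
            raise ConfigError(f"cell radius must be positive, got {self.r_c}")
        if self.eta <= 0:
            raise ConfigError(f"viscosity must be positive, got {self.eta}")
        if self.g <= 0:
            raise ConfigError(f"gravity must be positive, got {self.g}")
        if self.rho_c <= 0 or self.rho_m <= 0:
            raise ConfigError("densities must be positive")


def stokes_drag(R: float, eta: float, v: float) -> float:
    """Drag force [N] on a sphere of radius ``R`` [m] moving at ``v`` [m/s]
    through a fluid of viscosity ``eta`` [Pa s]: ``6*pi*R*eta*v``."""
    if R <= 0 or eta <= 0:
        raise ConfigError(f"R and eta must be positive, got R={R}, eta={eta}")
    return 6.0 * math.pi * R * eta * v


def stokes_velocity(p: StokesParams) -> float:
    """Terminal settling velocity [m/s] of a small sphere.

    Negative for a buoyant cell (rho_c < rho_m); returned as-is.
    """
    return (2.0 / 9.0) * p.r_c**2 * (p.rho_c - p.rho_m) * p.g / p.eta


def apparent_weight(p: StokesParams) -> float:
    """Weight minus buoyancy [N]: ``(4/3)*pi*r_c^3*(rho_c - rho_m)*g``.

    At terminal velocity this equals the Stokes drag.
    """
    return (4.0 / 3.0) * math.pi * p.r_c**3 * (p.rho_c - p.rho_m) * p.g


@dataclass(frozen=True)
class ProbabilityLadder:
    """Three-level move probabilities of a suspended cell, exact rationals.

    Level 1 (one site above): smallest, upward motion is rare. Level 2
    (two lateral sites): intermediate. Level 3 (one site below): largest,
    gravity dominates.
    """

    p_up: Fraction
    p_lateral_total: Fraction
    p_down: Fraction

    def __post_init__(self):
        if self.p_up + self.p_lateral_total + self.p_down != 1:
            raise ConfigError("ladder levels must sum to 1 exactly")
        if not (self.p_up < self.p_lateral_total < self.p_down):
            raise ConfigError("ladder must be ordered p_up < p_lateral_total < p_down")

    @property
    def per_position(self) -> tuple[Fraction, Fraction, Fraction, Fraction]:
        """(up, left, right, down) with the lateral level split equally."""
        half = self.p_lateral_total / 2
        return (self.p_up, half, half, self.p_down)


def compute_level_probabilities() -> ProbabilityLadder:
    """The ladder implied by a/2 + a + 2a = 1, i.e. a = 2/7.

    Levels: up a/2 = 1/7, lateral a = 2/7, down 2a = 4/7.
    """
    a = Fraction(2, 7)
    return ProbabilityLadder(p_up=a / 2, p_lateral_total=a, p_down=2 * a)
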