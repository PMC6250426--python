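"""Worked desk-scale examples: fitness functions and endpoint profiles.

Four n = 10 public-goods games, each payoff of the form
``base + 2 (i/n)^k``:

* ``linear_weak_assortment`` / ``linear_strong_assortment`` — the linear
  (equal-gains) game ``pi_C(i) = 0.6 + 2(i/10)``, ``pi_D(i) = 1 + 2(i/10)``
  under a weakly and a strongly assorted endpoint profile.  Hamilton's rule
  agrees exactly with the direction of selection here, for any structure.
* ``quadratic_synergy`` — ``pi_C(i) = 0.5 + 2(i/10)^2``,
  ``pi_D(i) = 1 + 2(i/10)^2``: unambiguous synergy (benefits rise, costs
  fall with the number of cooperators); violations of Hamilton's rule are
  possible out of equilibrium but never in equilibrium.
* ``sqrt_antisynergy`` — ``pi_C(i) = 0.5 + 2(i/10)^0.5``,
  ``pi_D(i) = 1 + 2(i/10)^0.5``: anti-synergy, the shape that permits
  in-equilibrium violations.

The endpoint profiles attached to the first three examples are minimal-
support reconstructions, moment-matched to the selection differentials the
games are known to produce at the boundaries: the linear games depend on the
profile only through its mean cooperator count E[i], and the quadratic game
only through E[i^2], so the printed differentials pin the profiles down
given mirror symmetry (ubar_i = u_{n-i}).  They are synthetic stand-ins for
fully specified assortment processes, not outputs of one.  The anti-synergy
example carries no profiles; its interesting behaviour (a mixed equilibrium
where inclusive fitness is non-zero) needs an interior structure, which the
2-player games in :func:`synergy_game`/:func:`antisynergy_game` provide in
closed form.

Also provided are the two 2-player prisoner's-dilemma variants used for
whole-trajectory analysis under constant-relatedness structures:
``synergy_game`` (cooperation pays off only with a cooperating partner) and
``antisynergy_game`` (the second cooperator adds less than the first).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .fitness import FitnessFunction, GameMatrix
from .structures import StructureProfile


@dataclass(frozen=True)
class WorkedExample:
    """A named fitness function with optional endpoint profiles."""

    name: str
    fitness: FitnessFunction
    u: Optional[StructureProfile]
    ubar: Optional[StructureProfile]


def linear_game(n: int = 10) -> FitnessFunction:
    """pi_C(i) = 0.6 + 2(i/n), pi_D(i) = 1 + 2(i/n): equal gains."""
    return FitnessFunction.power_payoff(n, 0.6, 1.0, coef=2.0, exponent=1.0)


def quadratic_game(n: int = 10) -> FitnessFunction:
    """pi_C(i) = 0.5 + 2(i/n)^2, pi_D(i) = 1 + 2(i/n)^2: synergy."""
    return FitnessFunction.power_payoff(n, 0.5, 1.0, coef=2.0, exponent=2.0)


def sqrt_game(n: int = 10) -> FitnessFunction:
    """pi_C(i) = 0.5 + 2(i/n)^0.5, pi_D(i) = 1 + 2(i/n)^0.5: anti-synergy."""
    return FitnessFunction.power_payoff(n, 0.5, 1.0, coef=2.0, exponent=0.5)


def synergy_game() -> GameMatrix:
    """2-player dilemma with synergy: cooperation mostly pays against C."""
    return GameMatrix(piC1=0.1, piC2=3.0, piD0=2.0, piD1=3.1)


def antisynergy_game() -> GameMatrix:
    """2-player dilemma with anti-synergy: the first cooperator matters most."""
    return GameMatrix(piC1=1.9, piC2=3.0, piD0=2.0, piD1=4.9)


def _mirrored(n: int, support, masses) -> tuple[StructureProfile, StructureProfile]:
    u = StructureProfile.from_support(n, "zero", support, masses)
    return u, u.mirror()


def worked_examples(n: int = 10) -> list[WorkedExample]:
    """The four worked group games with their reconstructed profiles."""
    u_a, ubar_a = _mirrored(n, (1, 2), (0.64, 0.36))
    u_b, ubar_b = _mirrored(n, (2, 3), (0.2, 0.8))
    u_c, ubar_c = _mirrored(n, (2, 3, 4), (0.45, 0.30, 0.25))
    return [
        WorkedExample("linear_weak_assortment", linear_game(n), u_a, ubar_a),
        WorkedExample("linear_strong_assortment", linear_game(n), u_b, ubar_b),
        WorkedExample("quadratic_synergy", quadratic_game(n), u_c, ubar_c),
        WorkedExample("sqrt_antisynergy", sqrt_game(n), None, None),
    ]
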