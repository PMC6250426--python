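"""Fitness functions for cooperator/defector games in groups of size n.

A group of size ``n`` contains ``i`` cooperators, the focal individual
included.  ``pi_C(i)`` is the fitness of a cooperator in such a group,
defined for ``i = 1..n``; ``pi_D(i)`` is the fitness of a defector in a
group containing ``i`` cooperators, defined for ``i = 0..n-1``.  The two
undefined corners — a cooperator in a group without cooperators, a defector
in an all-cooperator group — are never readable.

The module also provides the counterfactual switch effects: the cost a
cooperator in composition ``i`` pays for cooperating (what it would gain by
defecting) and the aggregate benefit its cooperation confers on the other
``n - 1`` group members, plus the synergy/anti-synergy diagnostics built
from them.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd


class FitnessDomainError(ValueError):
    """A fitness value was requested outside its domain of definition."""


def _as_array(values: Union[Mapping[int, float], Sequence[float]],
              keys: range, name: str) -> np.ndarray:
    if isinstance(values, Mapping):
        missing = [k for k in keys if k not in values]
        extra = [k for k in values if k not in keys]
        if missing or extra:
            raise ValueError(
                f"{name} must be defined exactly on {keys.start}..{keys.stop - 1}; "
                f"missing {missing}, extraneous {extra}")
        arr = np.array([float(values[k]) for k in keys])
    else:
        arr = np.asarray(values, dtype=float)
        if arr.shape != (len(keys),):
            raise ValueError(
                f"{name} must have length {len(keys)} (for i = "
                f"{keys.start}..{keys.stop - 1}), got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class FitnessFunction:
    """Payoffs of cooperators and defectors by group composition.

    Parameters
    ----------
    n : int
        Group size (>= 2).
    piC : mapping or sequence
        Cooperator fitness pi_C(i) for i = 1..n (sequence of length n).
    piD : mapping or sequence
        Defector fitness pi_D(i) for i = 0..n-1 (sequence of length n).
    """

    n: int
    piC_values: np.ndarray = field(repr=False)
    piD_values: np.ndarray = field(repr=False)

    def __init__(self, n: int,
                 piC: Union[Mapping[int, float], Sequence[float]],
                 piD: Union[Mapping[int, float], Sequence[float]]):
        if int(n) != n or n < 2:
            raise ValueError(f"group size n must be an integer >= 2, got {n}")
        n = int(n)
        object.__setattr__(self, "n", n)
        pc = _as_array(piC, range(1, n + 1), "piC")
        pd_ = _as_array(piD, range(0, n), "piD")
        pc.setflags(write=False)
        pd_.setflags(write=False)
        object.__setattr__(self, "piC_values", pc)
        object.__setattr__(self, "piD_values", pd_)

    # -- point access -----------------------------------------------------

    def piC(self, i: int) -> float:
        """Fitness of a cooperator in a group with ``i`` cooperators."""
        if not 1 <= i <= self.n:
            raise FitnessDomainError(
                f"pi_C({i}) is undefined; cooperators exist for i = 1..{self.n}")
        return float(self.piC_values[i - 1])

    def piD(self, i: int) -> float:
        """Fitness of a defector in a group with ``i`` cooperators."""
        if not 0 <= i <= self.n - 1:
            raise FitnessDomainError(
                f"pi_D({i}) is undefined; defectors exist for i = 0..{self.n - 1}")
        return float(self.piD_values[i])

    # -- counterfactual switch effects ------------------------------------

    def switch_effects(self, i: int) -> tuple[float, float]:
        """Cost and aggregate benefit of the focal switch at composition ``i``.

        For a cooperator in a group with ``i`` cooperators (itself included),
        the cost of cooperating is what it would earn by defecting instead::

            c_i = pi_D(i-1) - pi_C(i)

        and the aggregate benefit its cooperation confers on the other
        ``n - 1`` group members is::

            b_i = (i-1) [pi_C(i) - pi_C(i-1)] + (n-i) [pi_D(i) - pi_D(i-1)]

        Identically, these are the effects of a defector in a group with
        ``i - 1`` cooperators switching to cooperation — the counterfactual
        pair is the same.  ``i = 1`` gives the lone-switch expressions
        ``c = pi_D(0) - pi_C(1)``, ``b = (n-1)[pi_D(1) - pi_D(0)]``; ``i = n``
        gives ``c = pi_D(n-1) - pi_C(n)``, ``b = (n-1)[pi_C(n) - pi_C(n-1)]``.
        """
        n = self.n
        if not 1 <= i <= n:
            raise FitnessDomainError(
                f"switch effects are defined for compositions i = 1..{n}, got {i}")
        c = self.piD(i - 1) - self.piC(i)
        b = 0.0
        if i > 1:
            b += (i - 1) * (self.piC(i) - self.piC(i - 1))
        if i < n:
            b += (n - i) * (self.piD(i) - self.piD(i - 1))
        return float(c), float(b)

    def costs(self) -> np.ndarray:
        """Vector of c_i for i = 1..n."""
        return np.array([self.switch_effects(i)[0] for i in range(1, self.n + 1)])

    def benefits(self) -> np.ndarray:
        """Vector of b_i for i = 1..n."""
        return np.array([self.switch_effects(i)[1] for i in range(1, self.n + 1)])

    # -- synergy diagnostics ----------------------------------------------

    def cooperator_synergy_margins(self) -> np.ndarray:
        """pi_C(i) minus its equal-gains extrapolation from the i = 1 corner.

        The margin at composition ``i`` is
        ``pi_C(i) - {pi_C(1) + (i-1)[pi_D(1) - pi_D(0)]}`` for i = 1..n.
        All margins >= 0 is the first synergy condition (no in-equilibrium
        violation of Hamilton's rule at p = 0).
        """
        i = np.arange(1, self.n + 1)
        delta = self.piD(1) - self.piD(0)
        return self.piC_values - (self.piC(1) + (i - 1) * delta)

    def defector_synergy_margins(self) -> np.ndarray:
        """pi_D(i) minus its equal-gains extrapolation from the i = n corner.

        The margin at composition ``i`` is
        ``pi_D(i) - {pi_D(n-1) - (n-i-1)[pi_C(n) - pi_C(n-1)]}`` for
        i = 0..n-1.  All margins >= 0 is the second synergy condition.
        """
        n = self.n
        i = np.arange(0, n)
        delta = self.piC(n) - self.piC(n - 1)
        return self.piD_values - (self.piD(n - 1) - (n - i - 1) * delta)

    def is_equal_gains(self, tol: float = 1e-9) -> bool:
        """True if the fitness effects of a switch do not depend on others.

        Equal gains from switching holds when both synergy margins vanish
        identically, i.e. both payoff schedules are linear in ``i`` with the
        same slope.  Then c_i and b_i are constant in ``i`` and the
        counterfactual Hamilton's rule agrees exactly with the direction of
        selection for every population structure.
        """
        return bool(np.max(np.abs(self.cooperator_synergy_margins())) <= tol
                    and np.max(np.abs(self.defector_synergy_margins())) <= tol)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_callable(cls, n: int, piC: Callable[[int], float],
                      piD: Callable[[int], float]) -> "FitnessFunction":
        """Tabulate payoff callables over their respective domains."""
        return cls(n, [piC(i) for i in range(1, n + 1)],
                   [piD(i) for i in range(0, n)])

    @classmethod
    def power_payoff(cls, n: int, base_C: float, base_D: float,
                     coef: float = 2.0, exponent: float = 1.0) -> "FitnessFunction":
        """Payoffs ``base + coef * (i/n) ** exponent`` for either type.

        ``exponent = 1`` gives a linear (equal-gains) public-goods game,
        ``exponent > 1`` a synergistic one, ``exponent < 1`` an
        anti-synergistic one.
        """
        return cls.from_callable(
            n,
            lambda i: base_C + coef * (i / n) ** exponent,
            lambda i: base_D + coef * (i / n) ** exponent,
        )

    # -- CSV round trip ----------------------------------------------------

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "FitnessFunction":
        """Read a fitness table with columns ``i, pi_C, pi_D``.

        ``pi_C`` is empty for i = 0 and ``pi_D`` is empty for i = n.
        """
        df = pd.read_csv(path)
        required = {"i", "pi_C", "pi_D"}
        if not required.issubset(df.columns):
            raise ValueError(f"fitness CSV needs columns {sorted(required)}, "
                             f"got {list(df.columns)}")
        df = df.set_index("i").sort_index()
        n = int(df.index.max())
        if set(df.index) != set(range(0, n + 1)):
            raise ValueError("fitness CSV must have one row per i = 0..n")
        piC = {i: df.loc[i, "pi_C"] for i in range(1, n + 1)}
        piD = {i: df.loc[i, "pi_D"] for i in range(0, n)}
        for k, v in list(piC.items()) + list(piD.items()):
            if pd.isna(v):
                raise ValueError(f"missing payoff at composition {k}")
        if not pd.isna(df.loc[0, "pi_C"]) or not pd.isna(df.loc[n, "pi_D"]):
            raise ValueError("pi_C(0) and pi_D(n) do not exist and must be empty")
        return cls(n, piC, piD)

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write the ``i, pi_C, pi_D`` table (undefined corners left blank)."""
        rows = []
        for i in range(0, self.n + 1):
            rows.append({
                "i": i,
                "pi_C": self.piC(i) if i >= 1 else np.nan,
                "pi_D": self.piD(i) if i <= self.n - 1 else np.nan,
            })
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class GameMatrix:
    """2-player game payoffs, a convenience wrapper around n = 2.

    ``piC1``/``piC2`` are a cooperator's payoffs against a defector and a
    cooperator; ``piD0``/``piD1`` are a defector's payoffs against a defector
    and a cooperator.
    """

    piC1: float
    piC2: float
    piD0: float
    piD1: float

    def to_fitness(self) -> FitnessFunction:
        """Lossless conversion to the general group-game representation."""
        return FitnessFunction(2, {1: self.piC1, 2: self.piC2},
                               {0: self.piD0, 1: self.piD1})

    @classmethod
    def from_fitness(cls, fitness: FitnessFunction) -> "GameMatrix":
        if fitness.n != 2:
            raise ValueError("GameMatrix requires a 2-player fitness function")
        return cls(fitness.piC(1), fitness.piC(2), fitness.piD(0), fitness.piD(1))
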