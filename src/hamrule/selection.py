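"""Direction of selection and the counterfactual Hamilton's rule.

Given a population structure ``f_i(p)`` and a fitness function
(``pi_C``, ``pi_D``), :class:`SelectionAnalysis` evaluates, exactly:

* the mean fitness of cooperators and defectors, and their difference
  ``S(p)`` (the direction of selection) at any frequency ``p``;
* invasion conditions at both boundaries;
* relatedness ``r(p) = P(C|C) - P(C|D)``, the excess probability that a
  cooperator's group-mate cooperates, relative to a defector's;
* counterfactual costs, benefits, and the Hamilton value ``rb - c``;
* the boundary rewritings of Hamilton's rule, the three synergy conditions
  that preclude in-equilibrium violations, interior equilibria with their
  stability, and the map of frequencies where Hamilton's rule disagrees
  with the direction of selection.

Cost/benefit bookkeeping
------------------------
At ``p = 0`` the relevant counterfactual switch is that of an individual in
the resident all-defector background: ``c = pi_D(0) - pi_C(1)`` and
``b = (n-1)[pi_D(1) - pi_D(0)]``.  Symmetrically at ``p = 1``:
``c = pi_D(n-1) - pi_C(n)``, ``b = (n-1)[pi_C(n) - pi_C(n-1)]``.  With these
the boundary Hamilton's rule is algebraically identical to the boundary
rewriting evaluated by :meth:`SelectionAnalysis.hamilton_at_endpoint`.  At
interior ``p`` the population-level cost and benefit average the per-
composition switch effects ``c_i``, ``b_i`` over a conditional composition
distribution — by default the cooperators' (``vC``), which is what the
mixed-equilibrium analyses in this package use; averaging over defectors or
over the whole population is available behind the same contract.  Under
equal gains from switching all conventions coincide and ``rb - c = S(p)``
exactly, for every structure.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import DEFAULT_TOL, Tolerances
from .fitness import FitnessFunction, GameMatrix
from .structures import PopulationStructure, StructureProfile, constant_r_2player


class DegenerateSystemWarning(UserWarning):
    """The selection differential is identically ~0; dynamics are neutral."""


# ---------------------------------------------------------------------------
# report containers


@dataclass(frozen=True)
class SelectionReport:
    """Mean fitnesses by type and their difference at one frequency."""

    p: float
    mean_fitness_C: float
    mean_fitness_D: float

    @property
    def S(self) -> float:
        """Selection differential: mean cooperator minus defector fitness."""
        return self.mean_fitness_C - self.mean_fitness_D


@dataclass(frozen=True)
class CBR:
    """Counterfactual cost, aggregate benefit and relatedness at one p."""

    p: float
    r: float
    c: float
    b: float

    @property
    def hr(self) -> float:
        """The Hamilton value rb - c."""
        return self.r * self.b - self.c


@dataclass(frozen=True)
class InvasionReport:
    """Boundary invasion comparison (strict inequality; ties are neutral)."""

    end: str
    lhs: float
    rhs: float
    invades: bool
    neutral: bool


@dataclass(frozen=True)
class EndpointHamiltonReport:
    """Boundary rewriting of Hamilton's rule with its rb - c equivalent.

    At ``end='zero'`` the inequality compares
    ``sum_i u_i {pi_C(1) + (i-1)[pi_D(1) - pi_D(0)]}`` with ``pi_D(0)``;
    ``lhs > rhs`` iff ``rb > c``.  At ``end='one'`` it compares
    ``sum_i ubar_i {pi_D(n-1) - (n-i-1)[pi_C(n) - pi_C(n-1)]}`` with
    ``pi_C(n)``; there ``lhs > rhs`` iff ``rb < c``.
    """

    end: str
    lhs: float
    rhs: float
    r: float
    b: float
    c: float

    @property
    def rb_minus_c(self) -> float:
        return self.r * self.b - self.c

    @property
    def holds(self) -> bool:
        """Whether Hamilton's rule rb > c holds at this boundary."""
        return self.rb_minus_c > 0


@dataclass(frozen=True)
class Equilibrium:
    p: float
    stability: str            # "stable" | "unstable"
    slope_sign: int           # sign of dS/dp across the root
    hr: float


@dataclass(frozen=True)
class EndpointState:
    end: str
    stable: bool
    invasion: bool
    neutral: bool
    hr: float


@dataclass
class EquilibriumReport:
    equilibria: list[Equilibrium]
    endpoint_states: dict[str, EndpointState]
    degenerate: bool = False

    def stable_points(self) -> list[float]:
        pts = [e.p for e in self.equilibria if e.stability == "stable"]
        if self.endpoint_states["zero"].stable:
            pts.append(0.0)
        if self.endpoint_states["one"].stable:
            pts.append(1.0)
        return sorted(pts)


@dataclass(frozen=True)
class SystemClassification:
    """Fig-style road map verdict built from the three synergy conditions.

    ``synergy_cond1``: pi_C(i) >= pi_C(1) + (i-1)[pi_D(1) - pi_D(0)] for all i.
    ``synergy_cond2``: pi_D(i) >= pi_D(n-1) - (n-i-1)[pi_C(n) - pi_C(n-1)].
    ``synergy_cond3``: S(p) non-decreasing in p (structure-dependent; checked
    on a grid).  Equal gains (both payoff margins identically zero) makes
    Hamilton's rule exact everywhere; all three conditions together rule out
    violations in any stable state; otherwise in-equilibrium violations are
    possible.
    """

    equal_gains: bool
    synergy_cond1: bool
    synergy_cond2: bool
    synergy_cond3: bool

    @property
    def verdict(self) -> str:
        if self.equal_gains:
            return "no_violation_possible"
        if self.synergy_cond1 and self.synergy_cond2 and self.synergy_cond3:
            return "violations_only_out_of_equilibrium"
        return "in_equilibrium_violations_possible"

    def to_dict(self) -> dict:
        return {"equal_gains": self.equal_gains,
                "synergy_cond1": self.synergy_cond1,
                "synergy_cond2": self.synergy_cond2,
                "synergy_cond3": self.synergy_cond3,
                "verdict": self.verdict}


@dataclass
class ViolationSummary:
    """Where Hamilton's rule and the direction of selection disagree."""

    disagreement_intervals: list[tuple[float, float]]
    stable_states: list[float]
    stable_states_in_disagreement: list[float]

    @property
    def in_equilibrium_violation(self) -> bool:
        return bool(self.stable_states_in_disagreement)


# ---------------------------------------------------------------------------
# the engine


class SelectionAnalysis:
    """Exact selection and Hamilton's-rule analysis for one system.

    Parameters
    ----------
    structure : PopulationStructure
    fitness : FitnessFunction
        Must share the structure's group size ``n``.
    tol : Tolerances, optional
    """

    def __init__(self, structure: PopulationStructure, fitness: FitnessFunction,
                 tol: Optional[Tolerances] = None):
        if structure.n != fitness.n:
            raise ValueError(
                f"dimension mismatch: structure has n = {structure.n}, "
                f"fitness has n = {fitness.n}")
        self.structure = structure
        self.fitness = fitness
        self.n = structure.n
        self.tol = tol or DEFAULT_TOL

    # -- mean fitnesses ----------------------------------------------------

    def mean_fitnesses(self, p: float) -> SelectionReport:
        """Mean fitness of each type at frequency p.

        At the boundaries the rare type's mean is taken over its endpoint
        profile while the resident sits in monomorphic groups; at interior p
        both types average over their conditional composition distributions.
        """
        n, fit = self.n, self.fitness
        if p == 0.0:
            u, _ = self.structure.profiles()
            mC = float(u.weights[1:] @ fit.piC_values)
            mD = fit.piD(0)
        elif p == 1.0:
            _, ubar = self.structure.profiles()
            mC = fit.piC(n)
            mD = float(ubar.weights[:n] @ fit.piD_values)
        else:
            vC, vD = self.structure.conditional(p)
            mC = float(vC.weights[1:] @ fit.piC_values)
            mD = float(vD.weights[:n] @ fit.piD_values)
        return SelectionReport(p=p, mean_fitness_C=mC, mean_fitness_D=mD)

    def selection_differential(self, p: float) -> float:
        """S(p): mean cooperator fitness minus mean defector fitness."""
        return self.mean_fitnesses(p).S

    # -- invasion ----------------------------------------------------------

    def can_invade(self, end: str) -> InvasionReport:
        """Strict boundary invasion condition for the rare type at ``end``."""
        n, fit = self.n, self.fitness
        u, ubar = self.structure.profiles()
        if end == "zero":
            lhs = float(u.weights[1:] @ fit.piC_values)
            rhs = fit.piD(0)
        elif end == "one":
            lhs = float(ubar.weights[:n] @ fit.piD_values)
            rhs = fit.piC(n)
        else:
            raise ValueError(f"end must be 'zero' or 'one', got {end!r}")
        neutral = abs(lhs - rhs) <= self.tol.equality
        return InvasionReport(end=end, lhs=lhs, rhs=rhs,
                              invades=bool(lhs > rhs and not neutral),
                              neutral=neutral)

    # -- relatedness -------------------------------------------------------

    def relatedness(self, p: float) -> float:
        """r(p) = P(C|C) - P(C|D).

        ``P(C|C)`` is the probability that a random group-mate of a random
        cooperator is a cooperator, ``P(C|D)`` the same for a defector.  At
        p = 0 only the cooperators' term survives (a rare defector's mates
        are all defectors); at p = 1 the cooperators' term is 1.
        """
        if self.n < 2:
            raise ValueError("relatedness is undefined for groups of size 1")
        i = np.arange(self.n + 1)
        if p == 0.0:
            u, _ = self.structure.profiles()
            return float(u.weights @ ((i - 1) / (self.n - 1)))
        if p == 1.0:
            _, ubar = self.structure.profiles()
            return float(1.0 - ubar.weights @ (i / (self.n - 1)))
        vC, vD = self.structure.conditional(p)
        p_c_given_c = float(vC.weights @ ((i - 1) / (self.n - 1)))
        p_c_given_d = float(vD.weights @ (i / (self.n - 1)))
        return p_c_given_c - p_c_given_d

    # -- counterfactual costs and benefits ----------------------------------

    def population_cb(self, p: float, averaging: str = "cooperators") -> CBR:
        """Population-level counterfactual cost, benefit and relatedness.

        At the boundaries the cost and benefit are those of the switch in
        the resident background (composition 1 at p = 0, composition n at
        p = 1) — the values under which the boundary inequality reports of
        :meth:`hamilton_at_endpoint` are exact rewritings of ``rb > c``.  At
        interior p the per-composition switch effects are averaged over a
        conditional composition distribution chosen by ``averaging``:
        ``"cooperators"`` (default, the convention used for the equilibrium
        analyses here), ``"defectors"``, or ``"population"`` (the p-weighted
        blend of the two, which is the continuous interpolation of the two
        boundary conventions).
        """
        fit = self.fitness
        if p == 0.0:
            c, b = fit.switch_effects(1)
            return CBR(p=p, r=self.relatedness(0.0), c=c, b=b)
        if p == 1.0:
            c, b = fit.switch_effects(self.n)
            return CBR(p=p, r=self.relatedness(1.0), c=c, b=b)
        vC, vD = self.structure.conditional(p)
        ci = fit.costs()       # c_i, i = 1..n
        bi = fit.benefits()
        coop_c = float(vC.weights[1:] @ ci)
        coop_b = float(vC.weights[1:] @ bi)
        # a defector at composition i switching lands at i+1: effects c_{i+1}
        def_c = float(vD.weights[: self.n] @ ci)
        def_b = float(vD.weights[: self.n] @ bi)
        if averaging == "cooperators":
            c, b = coop_c, coop_b
        elif averaging == "defectors":
            c, b = def_c, def_b
        elif averaging == "population":
            c = p * coop_c + (1 - p) * def_c
            b = p * coop_b + (1 - p) * def_b
        else:
            raise ValueError(f"unknown averaging rule {averaging!r}")
        r = self.relatedness(p)
        return CBR(p=p, r=r, c=c, b=b)

    def hamilton_value(self, p: float, averaging: str = "cooperators") -> float:
        """rb - c at frequency p."""
        return self.population_cb(p, averaging=averaging).hr

    # -- boundary rewritings -------------------------------------------------

    def hamilton_at_endpoint(self, end: str) -> EndpointHamiltonReport:
        """The boundary inequality form of Hamilton's rule.

        The report's ``rb_minus_c`` equals ``population_cb(p).hr`` at the
        corresponding boundary up to float roundoff (both are exact
        rewritings of the same inequality).
        """
        n, fit = self.n, self.fitness
        u, ubar = self.structure.profiles()
        i = np.arange(n + 1)
        if end == "zero":
            delta = fit.piD(1) - fit.piD(0)
            lhs = float(u.weights @ (fit.piC(1) + (i - 1) * delta))
            rhs = fit.piD(0)
            c, b = fit.switch_effects(1)
            r = self.relatedness(0.0)
        elif end == "one":
            delta = fit.piC(n) - fit.piC(n - 1)
            lhs = float(ubar.weights @ (fit.piD(n - 1) - (n - i - 1) * delta))
            rhs = fit.piC(n)
            c, b = fit.switch_effects(n)
            r = self.relatedness(1.0)
        else:
            raise ValueError(f"end must be 'zero' or 'one', got {end!r}")
        return EndpointHamiltonReport(end=end, lhs=lhs, rhs=rhs, r=r, b=b, c=c)

    # -- classification -------------------------------------------------------

    def synergy_conditions(self, grid_size: int = 101) -> SystemClassification:
        """Evaluate the three synergy conditions and the road-map verdict."""
        if grid_size < 11:
            raise ValueError("classification grid must have at least 11 points")
        tol = self.tol.equality
        m1 = self.fitness.cooperator_synergy_margins()
        m2 = self.fitness.defector_synergy_margins()
        cond1 = bool(np.min(m1) >= -tol)
        cond2 = bool(np.min(m2) >= -tol)
        equal_gains = bool(np.max(np.abs(m1)) <= tol and np.max(np.abs(m2)) <= tol)
        grid = np.linspace(0.0, 1.0, grid_size)
        s = np.array([self.selection_differential(p) for p in grid])
        cond3 = bool(np.min(np.diff(s)) >= -tol)
        return SystemClassification(equal_gains=equal_gains, synergy_cond1=cond1,
                                    synergy_cond2=cond2, synergy_cond3=cond3)

    # -- equilibria -------------------------------------------------------------

    def find_equilibria(self, grid_size: int = 1001,
                        tol: Optional[float] = None) -> EquilibriumReport:
        """Interior roots of S(p) with stability, plus boundary states.

        Scans an evenly spaced grid for sign changes of ``S`` and refines
        each bracket with Brent's method.  A root is stable when ``S``
        passes from positive to negative across it.  Boundary states come
        from the strict invasion conditions.
        """
        if grid_size < 101:
            raise ValueError("equilibrium scan needs a grid of at least 101")
        root_tol = self.tol.root if tol is None else tol
        grid = np.linspace(0.0, 1.0, grid_size)
        s = np.array([self.selection_differential(p) for p in grid])
        degenerate = bool(np.max(np.abs(s)) <= self.tol.equality)
        equilibria: list[Equilibrium] = []
        if degenerate:
            warnings.warn("selection differential is identically ~0; the "
                          "system is neutral and no roots are reported",
                          DegenerateSystemWarning)
        else:
            roots: list[float] = []
            # grid nodes sitting exactly on a root are candidates themselves
            for k in range(1, grid_size - 1):
                if abs(s[k]) <= root_tol:
                    roots.append(float(grid[k]))
            for k in range(grid_size - 1):
                if s[k] == 0.0 or s[k + 1] == 0.0:
                    continue
                if np.sign(s[k]) != np.sign(s[k + 1]):
                    root = brentq(self.selection_differential,
                                  grid[k], grid[k + 1], xtol=1e-14)
                    if 0.0 < root < 1.0 and abs(
                            self.selection_differential(root)) <= max(
                                root_tol, 1e-9):
                        roots.append(float(root))
            roots = sorted(roots)
            dedup: list[float] = []
            for root in roots:
                if not dedup or root - dedup[-1] > 1e-9:
                    dedup.append(root)
            h = (grid[1] - grid[0]) / 2.0
            for root in dedup:
                left = self.selection_differential(max(root - h, root / 2.0))
                right = self.selection_differential(
                    min(root + h, (1.0 + root) / 2.0))
                stable = left > 0 > right
                slope = int(np.sign(right - left))
                equilibria.append(Equilibrium(
                    p=root, stability="stable" if stable else "unstable",
                    slope_sign=slope, hr=self.hamilton_value(root)))
        endpoint_states = {}
        for end, pval in (("zero", 0.0), ("one", 1.0)):
            inv = self.can_invade(end)
            endpoint_states[end] = EndpointState(
                end=end, stable=not inv.invades, invasion=inv.invades,
                neutral=inv.neutral, hr=self.hamilton_value(pval))
        return EquilibriumReport(equilibria=equilibria,
                                 endpoint_states=endpoint_states,
                                 degenerate=degenerate)

    # -- violation map ------------------------------------------------------------

    def violation_map(self, grid_size: int = 201
                      ) -> tuple[pd.DataFrame, ViolationSummary]:
        """Grid table of S, rb - c and their agreement, plus a summary.

        The summary lists maximal frequency intervals where the sign of
        ``rb - c`` disagrees with the sign of ``S``, every stable state of
        the dynamics, and which stable states carry a genuine disagreement
        (|rb - c| above the violation tolerance at an interior equilibrium,
        or a boundary Hamilton verdict opposing the realised invasion
        outcome) — the in-equilibrium violations.
        """
        vt = self.tol.violation
        grid = np.linspace(0.0, 1.0, grid_size)
        rows = []
        for p in grid:
            s_val = self.selection_differential(p)
            cbr = self.population_cb(p)
            sign_s = 0 if abs(s_val) <= vt else int(np.sign(s_val))
            sign_hr = 0 if abs(cbr.hr) <= vt else int(np.sign(cbr.hr))
            rows.append({"p": p, "S": s_val, "hr": cbr.hr, "r": cbr.r,
                         "c": cbr.c, "b": cbr.b,
                         "agree": bool(sign_s == sign_hr)})
        df = pd.DataFrame(rows, columns=["p", "S", "hr", "r", "c", "b", "agree"])

        intervals: list[tuple[float, float]] = []
        start = None
        for k, ok in enumerate(df["agree"]):
            if not ok and start is None:
                start = grid[k]
            if ok and start is not None:
                intervals.append((start, grid[k - 1]))
                start = None
        if start is not None:
            intervals.append((start, grid[-1]))

        eq = self.find_equilibria(grid_size=max(grid_size, 1001))
        stable = eq.stable_points()
        violated: list[float] = []
        for e in eq.equilibria:
            if e.stability == "stable" and abs(e.hr) > vt:
                violated.append(e.p)
        for end, pval in (("zero", 0.0), ("one", 1.0)):
            st = eq.endpoint_states[end]
            if not st.stable:
                continue
            s_end = self.selection_differential(pval)
            # at a stable boundary the resident resists invasion; Hamilton
            # disagrees when rb - c points the other way
            sign_s = 0 if abs(s_end) <= vt else int(np.sign(s_end))
            sign_hr = 0 if abs(st.hr) <= vt else int(np.sign(st.hr))
            if sign_s != sign_hr:
                violated.append(pval)
        summary = ViolationSummary(disagreement_intervals=intervals,
                                   stable_states=stable,
                                   stable_states_in_disagreement=sorted(violated))
        return df, summary


# ---------------------------------------------------------------------------
# constant-relatedness scans for 2-player games


def scan_constant_r(game: GameMatrix, r_grid: Sequence[float],
                    p_grid: Sequence[float],
                    averaging: str = "cooperators") -> pd.DataFrame:
    """Region data for a 2-player game over (relatedness, frequency) grids.

    For every constant-relatedness structure in ``r_grid`` and every
    frequency in ``p_grid`` the table reports the selection differential,
    the Hamilton value and their ingredients, with the same columns as the
    violation map (``p S hr r c b agree``); rows are ordered by (r, p).
    """
    fitness = game.to_fitness()
    frames = []
    for r in r_grid:
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"relatedness grid values must lie in [0, 1]: {r}")
        analysis = SelectionAnalysis(constant_r_2player(r), fitness)
        df, _ = _grid_frame(analysis, p_grid, averaging)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _grid_frame(analysis: SelectionAnalysis, p_grid: Sequence[float],
                averaging: str) -> tuple[pd.DataFrame, None]:
    vt = analysis.tol.violation
    rows = []
    for p in p_grid:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"frequency grid values must lie in [0, 1]: {p}")
        s_val = analysis.selection_differential(p)
        cbr = analysis.population_cb(p, averaging=averaging)
        sign_s = 0 if abs(s_val) <= vt else int(np.sign(s_val))
        sign_hr = 0 if abs(cbr.hr) <= vt else int(np.sign(cbr.hr))
        rows.append({"p": p, "S": s_val, "hr": cbr.hr, "r": cbr.r,
                     "c": cbr.c, "b": cbr.b, "agree": bool(sign_s == sign_hr)})
    return pd.DataFrame(rows, columns=["p", "S", "hr", "r", "c", "b", "agree"]), None


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a region table as TSV with the canonical column header."""
    df.to_csv(path, sep="\t", index=False)
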