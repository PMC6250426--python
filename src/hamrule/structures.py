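"""Assortative population structures over group compositions.

A population structure for groups of size ``n`` is a family ``f_i(p)``,
``i = 0..n``, giving the fraction of groups that contain ``i`` cooperators
when the overall cooperator frequency is ``p``.  Consistency requires, for
every ``p`` in [0, 1]::

    sum_i f_i(p) = 1          (the group-type frequencies are a distribution)
    sum_i (i/n) f_i(p) = p    (p really is the cooperator frequency)

The behaviour of a structure at the boundaries is summarised by its
*population structure profiles*: the distribution over group compositions
experienced by a rare cooperator as p -> 0,

    u_i = lim_{p -> 0} (i/n) f_i(p) / p,

and by a rare defector as p -> 1,

    ubar_i = lim_{p -> 1} ((n-i)/n) f_i(p) / (1-p).

These profiles, combined with a fitness function, decide whether cooperators
(or defectors) can invade, and whether Hamilton's rule agrees with the
direction of selection at the boundary.

Built-in families (all satisfying the constraints exactly):

``constant_r_2player``
    n = 2 with constant relatedness r:
    f0 = (1-r)(1-p)^2 + r(1-p), f1 = (1-r) 2p(1-p), f2 = (1-r)p^2 + rp.
``clonal_or_binomial``
    With probability r a group is clonal (all-C with probability p, all-D
    otherwise); with probability 1-r it is assembled binomially at frequency
    p.  Relatedness is r for any n.
``mixture``
    A convex combination of valid structures (the constraints are linear in
    f, so mixtures remain valid; profiles combine with the same weights).
``endpoint_profiles``
    A structure engineered to reproduce user-supplied endpoint profiles
    (u, ubar); its interior path is explicitly arbitrary.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.stats import binom

from .config import DEFAULT_TOL, Tolerances


class InvalidStructureError(ValueError):
    """A population structure violates its consistency constraints."""


class LimitConvergenceError(RuntimeError):
    """A numerical endpoint limit failed to converge."""


# ---------------------------------------------------------------------------
# profiles


@dataclass(frozen=True)
class StructureProfile:
    """Distribution over group compositions experienced by one type.

    ``end`` tags which limit (or interior frequency) the profile refers to:
    ``"zero"`` for a rare cooperator at p = 0, ``"one"`` for a rare defector
    at p = 1, ``"interior"`` for the conditional composition distribution of
    a type at 0 < p < 1.  ``weights[i]`` is the probability that the focal
    individual's group contains ``i`` cooperators in total.
    """

    n: int
    end: str
    weights: np.ndarray = field(repr=False)
    p: float = 0.0

    def __post_init__(self):
        if self.end not in ("zero", "one", "interior"):
            raise ValueError(f"unknown profile end tag {self.end!r}")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.n + 1,):
            raise ValueError(
                f"profile needs {self.n + 1} weights (i = 0..n), got {w.shape}")
        if np.any(w < -1e-12):
            raise ValueError("profile weights must be non-negative")
        s = w.sum()
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"profile weights must sum to 1, got {s}")
        w = np.clip(w, 0.0, None)
        if self.end == "zero" and w[0] != 0.0:
            raise ValueError(
                "a focal cooperator's group contains at least one cooperator "
                "(weight at i = 0 must be 0)")
        if self.end == "one" and w[self.n] != 0.0:
            raise ValueError(
                "a focal defector's group contains at most n-1 cooperators "
                "(weight at i = n must be 0)")
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_support(cls, n: int, end: str, support: Sequence[int],
                     masses: Sequence[float], p: float = 0.0) -> "StructureProfile":
        """Build a profile from (composition, mass) pairs; the rest is zero."""
        w = np.zeros(n + 1)
        for i, m in zip(support, masses):
            w[int(i)] += m
        target = {"zero": 0.0, "one": 1.0}.get(end, p)
        return cls(n=n, end=end, weights=w, p=target)

    def mean_cooperators(self) -> float:
        """Expected number of cooperators in the focal individual's group."""
        return float(np.arange(self.n + 1) @ self.weights)

    def second_moment(self) -> float:
        return float((np.arange(self.n + 1) ** 2) @ self.weights)

    def mirror(self) -> "StructureProfile":
        """The composition-reversed profile (i -> n - i), swapping ends."""
        end = {"zero": "one", "one": "zero"}.get(self.end, "interior")
        return StructureProfile(self.n, end, self.weights[::-1].copy(),
                                p=1.0 - self.p)

    def to_dict(self) -> dict:
        return {"end": self.end, "p": self.p, "weights": self.weights.tolist()}


# ---------------------------------------------------------------------------
# the structure object


@dataclass
class ValidationReport:
    """Worst-case constraint violations of a structure over a p-grid."""

    passed: bool
    max_sum_deviation: float
    max_mean_deviation: float
    min_frequency: float
    grid_size: int
    tolerance: float
    failures: list[str] = field(default_factory=list)


class PopulationStructure:
    """A family f_i(p) of group-composition distributions.

    Parameters
    ----------
    n : int
        Group size.
    f : callable
        Maps a frequency p in [0, 1] to the length-(n+1) vector of group-type
        frequencies.
    family_tag : str
        Identifier of the built-in family, or ``"custom"``.
    params : dict
        Family parameters (e.g. ``{"r": 0.3}``).
    analytic_profiles : (StructureProfile, StructureProfile), optional
        Closed-form endpoint profiles (u, ubar) when known; otherwise the
        profiles are obtained by a numerical one-sided limit.
    """

    def __init__(self, n: int, f: Callable[[float], np.ndarray],
                 family_tag: str = "custom", params: Optional[dict] = None,
                 analytic_profiles: Optional[tuple] = None,
                 metadata: Optional[dict] = None):
        if int(n) != n or n < 2:
            raise ValueError(f"group size n must be an integer >= 2, got {n}")
        self.n = int(n)
        self._f = f
        self.family_tag = family_tag
        self.params = dict(params or {})
        self._analytic_profiles = analytic_profiles
        self.metadata = dict(metadata or {})

    def __repr__(self):
        return (f"PopulationStructure(n={self.n}, family={self.family_tag!r}, "
                f"params={self.params})")

    # -- evaluation -------------------------------------------------------

    def frequencies(self, p: float) -> np.ndarray:
        """Group-type frequencies (f_0, ..., f_n) at cooperator frequency p."""
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"frequency p must lie in [0, 1], got {p}")
        f = np.asarray(self._f(p), dtype=float)
        if f.shape != (self.n + 1,):
            raise InvalidStructureError(
                f"f({p}) returned shape {f.shape}, expected ({self.n + 1},)")
        if not np.all(np.isfinite(f)):
            raise InvalidStructureError(f"f(p) is non-finite at p = {p}")
        return f

    # -- validation -------------------------------------------------------

    def validate(self, grid_size: int = 101,
                 tol: Optional[float] = None) -> ValidationReport:
        """Check the simplex and mean-frequency constraints on a p-grid."""
        if grid_size < 3:
            raise ValueError("validation grid must have at least 3 points")
        tol = DEFAULT_TOL.structure if tol is None else tol
        grid = np.linspace(0.0, 1.0, grid_size)
        i_over_n = np.arange(self.n + 1) / self.n
        max_sum = 0.0
        max_mean = 0.0
        min_freq = np.inf
        failures: list[str] = []
        for p in grid:
            f = self.frequencies(p)
            ds = abs(f.sum() - 1.0)
            dm = abs(i_over_n @ f - p)
            mn = f.min()
            if ds > max_sum:
                max_sum = ds
            if dm > max_mean:
                max_mean = dm
            if mn < min_freq:
                min_freq = mn
            if ds > tol:
                failures.append(f"sum f_i != 1 at p={p:.6g} (dev {ds:.3g})")
            if dm > tol:
                failures.append(f"sum (i/n) f_i != p at p={p:.6g} (dev {dm:.3g})")
            if mn < -tol:
                failures.append(f"negative frequency at p={p:.6g} ({mn:.3g})")
        return ValidationReport(passed=not failures, max_sum_deviation=max_sum,
                                max_mean_deviation=max_mean, min_frequency=min_freq,
                                grid_size=grid_size, tolerance=tol,
                                failures=failures)

    # -- endpoint profiles -------------------------------------------------

    def profiles(self, tol: Optional[Tolerances] = None
                 ) -> tuple[StructureProfile, StructureProfile]:
        """The endpoint profiles (u, ubar) of the structure.

        Uses closed forms for built-in families and a numerical one-sided
        limit with one-step Richardson extrapolation for custom structures.
        """
        tol = tol or DEFAULT_TOL
        if self._analytic_profiles is not None:
            return self._analytic_profiles
        u_w = self._numeric_endpoint_limit("zero", tol)
        ubar_w = self._numeric_endpoint_limit("one", tol)
        u = StructureProfile(self.n, "zero", u_w, p=0.0)
        ubar = StructureProfile(self.n, "one", ubar_w, p=1.0)
        return u, ubar

    def _endpoint_quotient(self, end: str, eps: float) -> np.ndarray:
        """(i/n) f_i(p)/p near 0, or ((n-i)/n) f_i(p)/(1-p) near 1."""
        i = np.arange(self.n + 1)
        if end == "zero":
            f = self.frequencies(eps)
            return (i / self.n) * f / eps
        f = self.frequencies(1.0 - eps)
        return ((self.n - i) / self.n) * f / eps

    def _numeric_endpoint_limit(self, end: str, tol: Tolerances,
                                eps0: float = 1e-3, max_halvings: int = 20
                                ) -> np.ndarray:
        # one-step Richardson: for g(eps) = L + C eps + O(eps^2),
        # 2 g(eps/2) - g(eps) = L + O(eps^2)
        eps = eps0
        g_prev = self._endpoint_quotient(end, eps)
        extrap_prev = None
        for _ in range(max_halvings):
            eps /= 2.0
            g = self._endpoint_quotient(end, eps)
            extrap = 2.0 * g - g_prev
            if extrap_prev is not None:
                if np.max(np.abs(extrap - extrap_prev)) < tol.limit_convergence:
                    w = np.clip(extrap, 0.0, None)
                    s = w.sum()
                    if abs(s - 1.0) > tol.profile_numeric:
                        raise LimitConvergenceError(
                            f"endpoint limit at p={'0' if end == 'zero' else '1'} "
                            f"converged to a non-normalised vector (sum {s:.6g})")
                    return w / s
            extrap_prev = extrap
            g_prev = g
        raise LimitConvergenceError(
            f"endpoint limit at p={'0' if end == 'zero' else '1'} did not "
            f"converge after {max_halvings} halvings (last eps {eps:.3g}, "
            f"last extrapolant change "
            f"{np.max(np.abs(extrap - extrap_prev)):.3g})")

    # -- interior conditional distributions --------------------------------

    def conditional(self, p: float) -> tuple[StructureProfile, StructureProfile]:
        """Composition distributions of cooperators and defectors at interior p.

        ``vC_i = (i/n) f_i(p) / p`` is the probability that a random
        cooperator sits in a group with ``i`` cooperators; ``vD_i =
        ((n-i)/n) f_i(p) / (1-p)`` the same for a random defector.  Both sum
        to one by the structure constraints.  At the boundaries these
        converge to the endpoint profiles; use :meth:`profiles` there.
        """
        if not 0.0 < p < 1.0:
            raise ValueError(
                "conditional distributions require 0 < p < 1; use profiles() "
                "for the endpoint limits")
        f = self.frequencies(p)
        i = np.arange(self.n + 1)
        vC = (i / self.n) * f / p
        vD = ((self.n - i) / self.n) * f / (1.0 - p)
        vC = np.clip(vC, 0.0, None)
        vD = np.clip(vD, 0.0, None)
        return (StructureProfile(self.n, "interior", vC / vC.sum(), p=p),
                StructureProfile(self.n, "interior", vD / vD.sum(), p=p))

    # -- serialisation ------------------------------------------------------

    def to_config(self) -> dict:
        cfg = {"family": self.family_tag, "n": self.n, "params": dict(self.params)}
        if self.family_tag == "mixture":
            cfg["params"] = {
                "weights": list(self.params["weights"]),
                "components": [c.to_config() for c in self.params["components"]],
            }
        return cfg


# ---------------------------------------------------------------------------
# built-in families


def constant_r_2player(r: float) -> PopulationStructure:
    """2-player structure with constant relatedness r for every p."""
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"relatedness r must lie in [0, 1], got {r}")

    def f(p: float) -> np.ndarray:
        return np.array([
            (1 - r) * (1 - p) ** 2 + r * (1 - p),
            (1 - r) * 2 * p * (1 - p),
            (1 - r) * p ** 2 + r * p,
        ])

    u = StructureProfile(2, "zero", np.array([0.0, 1 - r, r]), p=0.0)
    ubar = StructureProfile(2, "one", np.array([r, 1 - r, 0.0]), p=1.0)
    return PopulationStructure(2, f, "constant_r_2player", {"r": r},
                               analytic_profiles=(u, ubar))


def clonal_or_binomial(n: int, r: float) -> PopulationStructure:
    """Groups clonal with probability r, binomially assembled otherwise.

    Relatedness equals r at every p, for any group size n; at n = 2 this
    coincides with :func:`constant_r_2player`.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"relatedness r must lie in [0, 1], got {r}")
    n = int(n)
    idx = np.arange(n + 1)

    def f(p: float) -> np.ndarray:
        out = (1 - r) * binom.pmf(idx, n, p)
        out[0] += r * (1 - p)
        out[n] += r * p
        return out

    u_w = np.zeros(n + 1)
    u_w[1] += 1 - r          # binomial part: a rare cooperator is alone
    u_w[n] += r              # clonal part: or in an all-cooperator group
    ubar_w = np.zeros(n + 1)
    ubar_w[n - 1] += 1 - r
    ubar_w[0] += r
    u = StructureProfile(n, "zero", u_w, p=0.0)
    ubar = StructureProfile(n, "one", ubar_w, p=1.0)
    return PopulationStructure(n, f, "clonal_or_binomial", {"r": r},
                               analytic_profiles=(u, ubar))


def mixture(components: Sequence[PopulationStructure],
            weights: Sequence[float]) -> PopulationStructure:
    """Convex combination of valid structures (valid by linearity)."""
    weights = np.asarray(weights, dtype=float)
    if len(components) != len(weights) or len(components) == 0:
        raise ValueError("need one weight per component")
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must form a probability simplex")
    n = components[0].n
    if any(c.n != n for c in components):
        raise ValueError("all mixture components must share the group size n")

    def f(p: float) -> np.ndarray:
        return sum(w * c.frequencies(p) for w, c in zip(weights, components))

    analytic = None
    if all(c._analytic_profiles is not None for c in components):
        u_w = sum(w * c._analytic_profiles[0].weights
                  for w, c in zip(weights, components))
        ubar_w = sum(w * c._analytic_profiles[1].weights
                     for w, c in zip(weights, components))
        analytic = (StructureProfile(n, "zero", u_w, p=0.0),
                    StructureProfile(n, "one", ubar_w, p=1.0))
    return PopulationStructure(
        n, f, "mixture",
        {"weights": weights.tolist(), "components": list(components)},
        analytic_profiles=analytic)


def _pinned_component(n: int, i: int) -> Callable[[float], np.ndarray]:
    """A valid structure whose groups are pinned to composition i.

    For p <= i/n the population mixes composition-i groups with all-defector
    groups; for p >= i/n with all-cooperator groups.  The simplex and
    mean-frequency constraints hold exactly at every p, the structure is
    continuous and piecewise linear in p, and its endpoint profiles are point
    masses: u = delta_i (delta_n for i = 0) and ubar = delta_i (delta_0 for
    i = n).
    """
    def f(p: float) -> np.ndarray:
        out = np.zeros(n + 1)
        if i == 0:
            out[0], out[n] = 1.0 - p, p          # clonal split
            return out
        if i == n:
            out[0], out[n] = 1.0 - p, p
            return out
        if p <= i / n:
            out[i] = p * n / i
            out[0] = 1.0 - out[i]
        else:
            out[i] = n * (1.0 - p) / (n - i)
            out[n] = 1.0 - out[i]
        return out

    return f


def endpoint_profiles(n: int, u: StructureProfile,
                      ubar: StructureProfile) -> PopulationStructure:
    """A valid structure reproducing the requested endpoint profiles exactly.

    The structure crossfades, with the smoothstep weight
    ``w(p) = p^2 (3 - 2p)``, between a p->0 branch built from composition-
    pinned components weighted by ``u`` and a p->1 branch weighted by
    ``ubar``.  Because ``w = o(p)`` and ``1 - w = o(1 - p)``, the endpoint
    limits are exactly the requested profiles, while every intermediate
    state remains a valid structure.  The interior path is an arbitrary
    choice among the many structures sharing these endpoints (only endpoint
    behaviour matters for invasion analysis); this is flagged in
    ``metadata["interior_path"]``.
    """
    if u.end != "zero" or ubar.end != "one":
        raise InvalidStructureError(
            "endpoint_profiles needs a 'zero'-end profile u and a 'one'-end "
            "profile ubar")
    if u.n != n or ubar.n != n:
        raise InvalidStructureError("profile group sizes must match n")
    comps = [_pinned_component(n, i) for i in range(n + 1)]
    u_w = u.weights
    ubar_w = ubar.weights

    def f(p: float) -> np.ndarray:
        w = p * p * (3.0 - 2.0 * p)
        lo = sum(u_w[i] * comps[i](p) for i in range(1, n + 1))
        hi = sum(ubar_w[i] * comps[i](p) for i in range(0, n))
        return (1.0 - w) * lo + w * hi

    return PopulationStructure(
        n, f, "endpoint_profiles",
        {"u": u_w.tolist(), "ubar": ubar_w.tolist()},
        analytic_profiles=(u, ubar),
        metadata={"interior_path": "arbitrary smoothstep crossfade; only the "
                                   "endpoint limits are contractual"})


_FAMILIES = ("constant_r_2player", "clonal_or_binomial", "mixture",
             "endpoint_profiles")


def make_structure(family: str, n: int, params: Optional[dict] = None
                   ) -> PopulationStructure:
    """Construct a built-in structure family from a parameter dict."""
    params = dict(params or {})
    if family == "constant_r_2player":
        if n != 2:
            raise ValueError("constant_r_2player requires n = 2")
        return constant_r_2player(params["r"])
    if family == "clonal_or_binomial":
        return clonal_or_binomial(n, params["r"])
    if family == "mixture":
        comps = [c if isinstance(c, PopulationStructure) else from_config(c)
                 for c in params["components"]]
        return mixture(comps, params["weights"])
    if family == "endpoint_profiles":
        u = params["u"]
        ubar = params["ubar"]
        if not isinstance(u, StructureProfile):
            u = StructureProfile(n, "zero", np.asarray(u, dtype=float), p=0.0)
        if not isinstance(ubar, StructureProfile):
            ubar = StructureProfile(n, "one", np.asarray(ubar, dtype=float), p=1.0)
        return endpoint_profiles(n, u, ubar)
    raise ValueError(f"unknown structure family {family!r}; "
                     f"available: {_FAMILIES}")


def from_config(config: Union[dict, str, Path]) -> PopulationStructure:
    """Build a structure from a config dict or a JSON file path."""
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    return make_structure(config["family"], int(config["n"]),
                          config.get("params", {}))


def generate_random_structure(seed: int, n: int, k_components: int = 3
                              ) -> PopulationStructure:
    """Seeded random convex mixture of constant-relatedness components.

    Always passes :meth:`PopulationStructure.validate`; identical seeds give
    identical structures.
    """
    if k_components < 1:
        raise ValueError("need at least one mixture component")
    rng = np.random.default_rng(seed)
    rs = rng.uniform(0.0, 1.0, size=k_components)
    weights = rng.dirichlet(np.ones(k_components))
    comps = [clonal_or_binomial(n, r) for r in rs]
    out = mixture(comps, weights)
    out.metadata["seed"] = int(seed)
    return out


# ---------------------------------------------------------------------------
# spec-level functional aliases


def validate_structure(structure: PopulationStructure, grid_size: int = 101,
                       tol: Optional[float] = None) -> ValidationReport:
    """Functional alias for :meth:`PopulationStructure.validate`."""
    return structure.validate(grid_size=grid_size, tol=tol)


def profiles_from_structure(structure: PopulationStructure
                            ) -> tuple[StructureProfile, StructureProfile]:
    """Functional alias for :meth:`PopulationStructure.profiles`."""
    return structure.profiles()


def conditional_distributions(structure: PopulationStructure, p: float
                              ) -> tuple[StructureProfile, StructureProfile]:
    """Functional alias for :meth:`PopulationStructure.conditional`."""
    return structure.conditional(p)
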