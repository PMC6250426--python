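"""Hamilton's rule with regression-defined costs and benefits.

The regression method regresses individual fitness ``w`` on the
individual's own cooperativeness ``x_se`` and on the (aggregated)
cooperativeness of its partners by relationship class — e.g. siblings
``x_si`` and cousins ``x_co``.  Minus the coefficient of ``x_se`` is the
cost ``c``; the coefficient of class ``k`` is the benefit ``b_k``; the
relatedness to class ``k`` is ``r_k = cov(x_k, x_se) / var(x_se)``.

For *any* linear specification, ordinary-least-squares orthogonality plus
the Price equation give the exact bookkeeping identity

    delta_xbar = (var(x_se) / wbar) * (sum_k r_k b_k - c),

where ``delta_xbar = cov(w, x_se) / wbar`` is the one-generation change in
mean cooperativeness under faithful transmission (offspring copy the
parental trait, fitness = offspring count).  The sign of
``sum_k r_k b_k - c`` therefore always equals the sign of the change in
mean cooperativeness: under the regression method Hamilton's rule cannot be
violated, whichever linear specification is chosen — but its ``b`` and
``c`` values are specification-dependent, so the rule is not uniquely
defined.  Note the rule is often quoted as the bare equality
``delta_xbar = rb - c``; the exact statement carries the positive factor
``var(x_se)/wbar``, which changes magnitudes but never signs.  Results
objects store the factor explicitly and report both forms.

Non-linear terms (interactions, quadratics) break the identity's
interpretation — which is precisely why empirical tests of the
counterfactual Hamilton's rule must fit models that allow such terms and
test them (see :func:`nonlinearity_test` and
:func:`estimate_pi_from_groups`).
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from .fitness import FitnessFunction


class CollinearityError(ValueError):
    """The design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            f"design matrix is rank deficient; offending columns: {self.columns}")


# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class Specification:
    """Which regressors enter the fitness regression.

    ``included_classes`` are relationship-class names whose aggregated
    partner cooperativeness enters linearly.  ``interaction_terms`` are
    pairs of regressor names (``"self"`` stands for own cooperativeness)
    whose product is added; ``quadratic_terms`` are regressor names whose
    square is added.  A specification is *linear* when it has neither.
    """

    id: str
    included_classes: tuple[str, ...]
    interaction_terms: tuple[tuple[str, str], ...] = ()
    quadratic_terms: tuple[str, ...] = ()

    @property
    def is_linear(self) -> bool:
        return not self.interaction_terms and not self.quadratic_terms

    # canonical specifications: siblings only; siblings and cousins;
    # an interaction term; a quadratic term
    @classmethod
    def I(cls) -> "Specification":
        return cls("I", ("sib",))

    @classmethod
    def II(cls) -> "Specification":
        return cls("II", ("sib", "cou"))

    @classmethod
    def III(cls) -> "Specification":
        return cls("III", ("sib",), interaction_terms=(("self", "sib"),))

    @classmethod
    def IV(cls) -> "Specification":
        return cls("IV", ("sib",), quadratic_terms=("sib",))

    @classmethod
    def by_name(cls, name: str) -> "Specification":
        try:
            return {"I": cls.I, "II": cls.II, "III": cls.III, "IV": cls.IV}[name]()
        except KeyError:
            raise ValueError(f"unknown canonical specification {name!r}")


_PARTNER_COL = re.compile(r"^(?P<cls>[A-Za-z]+)_(?P<idx>\d+)$")


def aggregate_partner_classes(data: pd.DataFrame, how: str = "mean"
                              ) -> pd.DataFrame:
    """Collapse per-partner columns (``sib_1``, ``sib_2``, ...) by class.

    Returns a frame with one column per relationship class holding the mean
    (default) or sum of that class's partner cooperativeness.  Means keep
    the benefit coefficient interpretable as "effect of a fully cooperative
    class" and comparable across class sizes.
    """
    if how not in ("mean", "sum"):
        raise ValueError("aggregation must be 'mean' or 'sum'")
    groups: dict[str, list[str]] = {}
    for col in data.columns:
        m = _PARTNER_COL.match(col)
        if m:
            groups.setdefault(m.group("cls"), []).append(col)
    out = {}
    for cls_name, cols in groups.items():
        block = data[cols].astype(float)
        out[cls_name] = block.mean(axis=1) if how == "mean" else block.sum(axis=1)
    return pd.DataFrame(out, index=data.index)


def design_matrix(data: pd.DataFrame, spec: Specification,
                  trait_col: str = "x_se", aggregation: str = "mean"
                  ) -> pd.DataFrame:
    """Build the regression design (intercept first) for a specification."""
    agg = aggregate_partner_classes(data, how=aggregation)
    cols: dict[str, np.ndarray] = {"const": np.ones(len(data))}
    cols[trait_col] = data[trait_col].to_numpy(dtype=float)

    def regressor(name: str) -> np.ndarray:
        if name in ("self", trait_col):
            return cols[trait_col]
        if name not in agg.columns:
            raise ValueError(
                f"relationship class {name!r} has no partner columns in the data "
                f"(available: {sorted(agg.columns)})")
        return agg[name].to_numpy(dtype=float)

    for cls_name in spec.included_classes:
        cols[cls_name] = regressor(cls_name)
    for a, b in spec.interaction_terms:
        cols[f"{a}:{b}"] = regressor(a) * regressor(b)
    for a in spec.quadratic_terms:
        cols[f"{a}^2"] = regressor(a) ** 2
    X = pd.DataFrame(cols, index=data.index)
    if not np.all(np.isfinite(X.to_numpy())):
        raise ValueError("design matrix contains non-finite values")
    return X


# ---------------------------------------------------------------------------
# the OLS primitive


def ols_fit(X: pd.DataFrame, y: np.ndarray) -> pd.Series:
    """Exact least squares via the normal equations, with a rank check.

    Raises :class:`CollinearityError` naming the offending columns when the
    design is rank deficient.  The returned coefficients leave residuals
    orthogonal to every regressor (checked by the caller's contract tests).
    """
    A = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    # column-pivoted QR identifies which columns exceed the rank
    _, R, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank_tol = max(A.shape) * np.finfo(float).eps * (diag[0] if len(diag) else 0.0)
    rank = int(np.sum(diag > rank_tol))
    if rank < A.shape[1]:
        offending = [X.columns[j] for j in piv[rank:]]
        raise CollinearityError(offending)
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    return pd.Series(beta, index=X.columns)


def _pcov(a: np.ndarray, b: np.ndarray) -> float:
    """Population covariance (ddof = 0), the Price-equation convention."""
    return float(np.mean((a - a.mean()) * (b - b.mean())))


# ---------------------------------------------------------------------------
# model / results


class HamiltonRegression:
    """Regression-method Hamilton's rule as a fittable model.

    Parameters
    ----------
    data : DataFrame
        One row per individual, with own cooperativeness ``trait_col``,
        fitness ``fitness_col`` and per-partner columns named
        ``<class>_<j>`` (e.g. ``sib_1``, ``cou_2``).
    spec : Specification
    """

    def __init__(self, data: pd.DataFrame, spec: Specification,
                 fitness_col: str = "w", trait_col: str = "x_se",
                 aggregation: str = "mean"):
        if fitness_col not in data.columns or trait_col not in data.columns:
            raise ValueError(
                f"data must contain columns {fitness_col!r} and {trait_col!r}")
        self.data = data
        self.spec = spec
        self.fitness_col = fitness_col
        self.trait_col = trait_col
        self.aggregation = aggregation

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: Specification = None,
                       **kwargs) -> "HamiltonRegression":
        return cls(data, spec or Specification.I(), **kwargs)

    def fit(self) -> "HamiltonRegressionResults":
        X = design_matrix(self.data, self.spec, trait_col=self.trait_col,
                          aggregation=self.aggregation)
        x_se = X[self.trait_col].to_numpy()
        if _pcov(x_se, x_se) == 0.0:
            raise ValueError(
                "own cooperativeness has zero variance; relatedness (and the "
                "regression Hamilton's rule) is undefined")
        y = self.data[self.fitness_col].to_numpy(dtype=float)
        params = ols_fit(X, y)
        return HamiltonRegressionResults(self, X, y, params)


class HamiltonRegressionResults:
    """Costs, benefits, relatednesses and the Price/OLS bookkeeping identity."""

    def __init__(self, model: HamiltonRegression, X: pd.DataFrame,
                 y: np.ndarray, params: pd.Series):
        self.model = model
        self.X = X
        self.y = y
        self.params = params
        self.resid = y - X.to_numpy() @ params.to_numpy()

        spec = model.spec
        x_se = X[model.trait_col].to_numpy()
        self.c = -float(params[model.trait_col])
        self.b = {k: float(params[k]) for k in spec.included_classes}
        self.var_xse = _pcov(x_se, x_se)
        self.r = {k: _pcov(X[k].to_numpy(), x_se) / self.var_xse
                  for k in spec.included_classes}
        self.mean_w = float(np.mean(y))
        # Price equation under faithful transmission: the offspring pool's
        # mean trait shift is the fitness-trait covariance over mean fitness
        self.delta_xbar = _pcov(y, x_se) / self.mean_w
        self.hr_sum = sum(self.r[k] * self.b[k]
                          for k in spec.included_classes) - self.c
        self.price_factor = self.var_xse / self.mean_w
        self.identity_residual = self.delta_xbar - self.price_factor * self.hr_sum

    # -- diagnostics -------------------------------------------------------

    def max_orthogonality_violation(self) -> float:
        """Largest |cov(residual, regressor)| — ~0 for a correct OLS fit."""
        return max(abs(_pcov(self.resid, self.X[c].to_numpy()))
                   for c in self.X.columns)

    @property
    def hamilton_holds(self) -> bool:
        """sum_k r_k b_k - c > 0 (equivalently, mean cooperativeness rises)."""
        return self.hr_sum > 0

    def to_dict(self) -> dict:
        return {
            "spec": self.model.spec.id,
            "linear": self.model.spec.is_linear,
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "c": self.c,
            "b": self.b,
            "r": self.r,
            "hr_sum": self.hr_sum,
            "delta_xbar": self.delta_xbar,
            "price_factor": self.price_factor,
            "identity_residual": self.identity_residual,
            "note": "b and c are specification-dependent; the sign identity "
                    "sign(sum_k r_k b_k - c) = sign(delta_xbar) holds for "
                    "every linear specification",
        }

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Regression-method Hamilton's rule",
            "=" * 48,
            f"specification: {spec.id} "
            f"({'linear' if spec.is_linear else 'non-linear'})",
            f"observations:  {len(self.y)}",
            "",
            f"{'term':<12}{'coef':>12}",
            "-" * 24,
        ]
        for name, val in self.params.items():
            lines.append(f"{name:<12}{val:>12.6f}")
        lines += ["", f"cost c            = {self.c:.6f}"]
        for k in spec.included_classes:
            lines.append(f"benefit b[{k}]   = {self.b[k]:.6f}   "
                         f"relatedness r[{k}] = {self.r[k]:.6f}")
        lines += [
            f"sum r_k b_k - c   = {self.hr_sum:.6f}",
            f"delta xbar        = {self.delta_xbar:.6f}",
            f"identity residual = {self.identity_residual:.3e}",
            "",
            "b and c depend on the specification chosen; for every linear",
            "specification sign(sum r_k b_k - c) = sign(delta xbar).",
        ]
        return "\n".join(lines)


def regression_hr(data: pd.DataFrame, spec: Specification,
                  **kwargs) -> HamiltonRegressionResults:
    """Fit the regression Hamilton's rule for one specification."""
    return HamiltonRegression(data, spec, **kwargs).fit()


# ---------------------------------------------------------------------------
# non-linearity testing


@dataclass(frozen=True)
class NonlinearityReport:
    f_stat: float
    df_num: int
    df_den: int
    pvalue: float
    alpha: float

    @property
    def verdict(self) -> str:
        return ("non-linearity detected" if self.pvalue < self.alpha
                else "linear adequate")


def nonlinearity_test(data: pd.DataFrame, base_spec: Specification,
                      extended_spec: Specification, alpha: float = 0.05,
                      fitness_col: str = "w", trait_col: str = "x_se"
                      ) -> NonlinearityReport:
    """Nested-model F test of a base specification against an extension.

    The extended specification must strictly nest the base one.  A small
    p-value rejects the base (typically linear) model — the kind of evidence
    an empirical test of the counterfactual Hamilton's rule needs before
    trusting linear cost/benefit estimates.
    """
    Xb = design_matrix(data, base_spec, trait_col=trait_col)
    Xe = design_matrix(data, extended_spec, trait_col=trait_col)
    if not set(Xb.columns) < set(Xe.columns):
        raise ValueError(
            "extended specification must strictly nest the base one "
            f"(base columns {list(Xb.columns)}, extended {list(Xe.columns)})")
    y = data[fitness_col].to_numpy(dtype=float)
    if len(y) - Xe.shape[1] <= 0:
        raise ValueError("insufficient residual degrees of freedom for the "
                         "extended specification")
    res_b = sm.OLS(y, Xb.to_numpy()).fit()
    res_e = sm.OLS(y, Xe.to_numpy()).fit()
    f_stat, pvalue, df_num = res_e.compare_f_test(res_b)
    return NonlinearityReport(f_stat=float(f_stat), df_num=int(df_num),
                              df_den=int(res_e.df_resid), pvalue=float(pvalue),
                              alpha=alpha)


# ---------------------------------------------------------------------------
# estimating the group fitness function from composition data


@dataclass
class PiEstimateReport:
    """Composition-mean payoff estimates plus the equal-gains test."""

    n: int
    pi_C: dict[int, float]
    pi_D: dict[int, float]
    counts: dict[tuple[str, int], int]
    gaps: list[tuple[str, int]]
    f_stat: Optional[float]
    pvalue: Optional[float]
    alpha: float

    @property
    def complete(self) -> bool:
        return not self.gaps

    @property
    def equal_gains_rejected(self) -> Optional[bool]:
        if self.pvalue is None:
            return None
        return self.pvalue < self.alpha

    def fitness(self) -> FitnessFunction:
        if self.gaps:
            raise ValueError(f"cannot build a full fitness function; missing "
                             f"composition cells: {self.gaps}")
        return FitnessFunction(self.n,
                               {i: self.pi_C[i] for i in range(1, self.n + 1)},
                               {i: self.pi_D[i] for i in range(0, self.n)})


def estimate_pi_from_groups(group_records: pd.DataFrame,
                            n: Optional[int] = None,
                            alpha: float = 0.05) -> PiEstimateReport:
    """Estimate pi_C(i), pi_D(i) from per-individual group records.

    ``group_records`` has columns ``i`` (cooperators in the focal's group,
    focal included), ``type`` (``"C"`` or ``"D"``) and ``w`` (fitness); a
    ``group_id`` column is accepted and ignored.  Cell means estimate the
    payoffs.  A saturated-versus-restricted F test probes *generalized equal
    gains from switching*: under the restriction, fitness is
    ``a + g*1{C} + d*(number of cooperating partners)``, exactly the class
    of fitness functions for which the counterfactual Hamilton's rule is
    exact.  Rejection means the system can, in principle, violate it.
    """
    df = group_records
    for col in ("i", "type", "w"):
        if col not in df.columns:
            raise ValueError(f"group records need column {col!r}")
    if n is None:
        n = int(df["i"].max())
    bad_type = set(df["type"].unique()) - {"C", "D"}
    if bad_type:
        raise ValueError(f"unknown focal types {sorted(bad_type)}")

    pi_C: dict[int, float] = {}
    pi_D: dict[int, float] = {}
    counts: dict[tuple[str, int], int] = {}
    gaps: list[tuple[str, int]] = []
    for i in range(1, n + 1):
        sub = df[(df["type"] == "C") & (df["i"] == i)]["w"]
        counts[("C", i)] = len(sub)
        if len(sub):
            pi_C[i] = float(sub.mean())
        else:
            gaps.append(("C", i))
    for i in range(0, n):
        sub = df[(df["type"] == "D") & (df["i"] == i)]["w"]
        counts[("D", i)] = len(sub)
        if len(sub):
            pi_D[i] = float(sub.mean())
        else:
            gaps.append(("D", i))
    if gaps:
        warnings.warn(f"missing composition cells; payoff estimates are "
                      f"partial: {gaps}")

    # equal-gains F test: saturated cell means vs additive 3-parameter model
    f_stat = pvalue = None
    cells = df.groupby(["type", "i"])["w"]
    k_cells = cells.ngroups
    n_obs = len(df)
    if n_obs > k_cells and k_cells > 3:
        rss_full = float(((df["w"] - cells.transform("mean")) ** 2).sum())
        is_c = (df["type"] == "C").to_numpy(dtype=float)
        others = df["i"].to_numpy(dtype=float) - is_c
        X = np.column_stack([np.ones(n_obs), is_c, others])
        beta, *_ = np.linalg.lstsq(X, df["w"].to_numpy(dtype=float), rcond=None)
        rss_restr = float(np.sum((df["w"].to_numpy() - X @ beta) ** 2))
        df_num = k_cells - 3
        df_den = n_obs - k_cells
        if rss_full <= 1e-300:
            f_stat = np.inf
            pvalue = 0.0 if rss_restr > 1e-12 else 1.0
        else:
            f_stat = ((rss_restr - rss_full) / df_num) / (rss_full / df_den)
            pvalue = float(scipy.stats.f.sf(f_stat, df_num, df_den))
    return PiEstimateReport(n=n, pi_C=pi_C, pi_D=pi_D, counts=counts,
                            gaps=gaps, f_stat=f_stat, pvalue=pvalue,
                            alpha=alpha)
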