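"""Seeded synthetic data for the regression engine.

The generators emulate the minimal observational setting the regression
method assumes: a cross-section of individuals with a binary cooperation
trait, partner traits by relationship class correlated with the focal trait
at a pedigree relatedness, and fitness that is (by default) linear in own
and partners' cooperation plus Gaussian noise.  Group-game records emulate
an experiment that fixes group compositions and measures per-individual
fitness with noise.
"""
from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fitness import FitnessFunction


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _correlated_trait(rng: np.random.Generator, x_focal: np.ndarray,
                      relatedness: float, p_coop: float) -> np.ndarray:
    """Partner trait equal to the focal's with probability ``relatedness``,
    otherwise an independent draw — giving cov(x_partner, x_focal) =
    relatedness * var(x_focal) exactly in expectation."""
    copy = rng.random(len(x_focal)) < relatedness
    indep = (rng.random(len(x_focal)) < p_coop).astype(float)
    return np.where(copy, x_focal, indep)


def sibling_population(seed: Union[int, np.random.Generator],
                       n_individuals: int,
                       classes: Optional[Mapping[str, tuple[int, float]]] = None,
                       p_coop: float = 0.5,
                       baseline: float = 4.0,
                       cost: float = 0.8,
                       benefits: Optional[Mapping[str, float]] = None,
                       sigma: float = 1.0,
                       interaction: float = 0.0,
                       quadratic: float = 0.0) -> pd.DataFrame:
    """Cross-sectional records with sibling/cousin partner columns.

    Parameters
    ----------
    classes : mapping class -> (k_partners, relatedness)
        Defaults to one sibling at relatedness 0.5 and one cousin at 0.125.
    baseline, cost, benefits, sigma
        Fitness is ``baseline - cost * x_se + sum_k benefit_k * mean(x_k)``
        plus optional ``interaction * x_se * mean(x_sib)`` and
        ``quadratic * mean(x_sib)^2`` terms and N(0, sigma) noise.
    """
    rng = _rng(seed)
    classes = dict(classes) if classes else {"sib": (1, 0.5), "cou": (1, 0.125)}
    benefits = dict(benefits) if benefits else {"sib": 2.0, "cou": 0.5}
    x_se = (rng.random(n_individuals) < p_coop).astype(float)
    data: dict[str, np.ndarray] = {"x_se": x_se}
    class_means: dict[str, np.ndarray] = {}
    for cls_name, (k, rel) in classes.items():
        cols = []
        for j in range(1, k + 1):
            col = _correlated_trait(rng, x_se, rel, p_coop)
            data[f"{cls_name}_{j}"] = col
            cols.append(col)
        class_means[cls_name] = np.mean(cols, axis=0)
    w = baseline - cost * x_se
    for cls_name, mean_x in class_means.items():
        w = w + benefits.get(cls_name, 0.0) * mean_x
    if interaction and "sib" in class_means:
        w = w + interaction * x_se * class_means["sib"]
    if quadratic and "sib" in class_means:
        w = w + quadratic * class_means["sib"] ** 2
    w = w + rng.normal(0.0, sigma, n_individuals)
    data["w"] = w
    return pd.DataFrame(data)


def group_records(seed: Union[int, np.random.Generator],
                  fitness: FitnessFunction, n_per_cell: int = 50,
                  sigma: float = 0.1) -> pd.DataFrame:
    """Per-individual fitness records across all feasible compositions.

    For every composition ``i`` and feasible focal type, ``n_per_cell``
    individuals are recorded with fitness equal to the true payoff plus
    N(0, sigma) noise — the design of a group-composition experiment.
    """
    rng = _rng(seed)
    rows = []
    gid = 0
    for i in range(1, fitness.n + 1):
        w = fitness.piC(i) + rng.normal(0.0, sigma, n_per_cell)
        for val in w:
            rows.append({"group_id": gid, "i": i, "type": "C", "w": float(val)})
            gid += 1
    for i in range(0, fitness.n):
        w = fitness.piD(i) + rng.normal(0.0, sigma, n_per_cell)
        for val in w:
            rows.append({"group_id": gid, "i": i, "type": "D", "w": float(val)})
            gid += 1
    return pd.DataFrame(rows)


def spurious_violation_sim(seed: int,
                           sample_sizes: Sequence[int] = (20, 80, 320),
                           true_r: float = 0.5,
                           effect_b: float = 2.0,
                           effect_c: float = 0.8,
                           reps: int = 1000,
                           sigma: float = 1.0,
                           baseline: float = 4.0,
                           p_coop: float = 0.5) -> pd.DataFrame:
    """How often phenotypic and pedigree relatedness flip Hamilton's verdict.

    Each replicate simulates sibling pairs with pedigree relatedness
    ``true_r`` and linear fitness (benefit ``effect_b``, cost ``effect_c``),
    then evaluates ``rb - c`` twice: with the regression-method relatedness
    ``cov(x_se, x_si)/var(x_se)`` estimated from the sample, and with the
    pedigree value.  The first always agrees in sign with the realised
    change in mean cooperativeness; the second is what a marker- or
    pedigree-based study would plug in.  A sign disagreement between the two
    is an *apparent* violation of Hamilton's rule.  Sampling noise makes the
    phenotypic estimate wander, so the disagreement fraction shrinks as the
    sample grows.

    Returns one row per sample size with the disagreement fraction, its
    Monte-Carlo standard error, and the number of usable replicates
    (replicates with a degenerate trait column are dropped).
    """
    if reps < 1:
        raise ValueError("need at least one replicate")
    rng = _rng(seed)
    out = []
    for n in sample_sizes:
        disagreements = 0
        valid = 0
        for _ in range(reps):
            x_se = (rng.random(n) < p_coop).astype(float)
            x_si = _correlated_trait(rng, x_se, true_r, p_coop)
            w = (baseline - effect_c * x_se + effect_b * x_si
                 + rng.normal(0.0, sigma, n))
            var_xse = np.var(x_se)
            if var_xse == 0.0:
                continue
            X = np.column_stack([np.ones(n), x_se, x_si])
            if np.linalg.matrix_rank(X) < 3:
                continue
            beta, *_ = np.linalg.lstsq(X, w, rcond=None)
            c_hat, b_hat = -beta[1], beta[2]
            r_phen = np.mean((x_se - x_se.mean()) * (x_si - x_si.mean())) / var_xse
            hr_phen = r_phen * b_hat - c_hat
            hr_ped = true_r * b_hat - c_hat
            valid += 1
            if (hr_phen > 0) != (hr_ped > 0):
                disagreements += 1
        frac = disagreements / valid if valid else np.nan
        mc_se = (np.sqrt(frac * (1 - frac) / valid) if valid else np.nan)
        out.append({"sample_size": int(n), "disagreement_fraction": frac,
                    "mc_se": mc_se, "n_valid": valid})
    return pd.DataFrame(out)
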