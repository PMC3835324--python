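"""Calcium-overload classification and the cohort statistics.

Overload is defined against the control population: the per-compartment
threshold is the 95th percentile (linear interpolation) of control mean YC
ratios, and a structure is overloaded when its ratio strictly exceeds the
threshold of its compartment.  Genotype effects on overload are tested with
a mixed-effects logistic regression (random intercept per animal, see
:mod:`ycquant.glmm`); spine-density group differences with per-animal-mean
Student t-tests; the density-vs-calcium relationship with ordinary least
squares (R^2) and Spearman rank correlation.  Analyses run in ratio space;
conversion to concentration happens only afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glmm import MixedLogit, SeparationError

__all__ = [
    "OverloadThresholds",
    "GroupComparison",
    "DensityComparison",
    "CorrelationResult",
    "compute_thresholds",
    "classify_overload",
    "fit_overload_model",
    "check_normality",
    "compare_density",
    "correlate_density_ratio",
    "SeparationError",
]

COMPARTMENTS = ("dendrite", "spine")


@dataclass(frozen=True)
class OverloadThresholds:
    """95th-percentile control YC-ratio thresholds, one per compartment."""

    thr_dend: float
    thr_spine: float

    def for_compartment(self, compartment: str) -> float:
        if compartment == "dendrite":
            return self.thr_dend
        if compartment == "spine":
            return self.thr_spine
        raise KeyError(compartment)


@dataclass(frozen=True)
class GroupComparison:
    """Fixed-effect of genotype on overload from the mixed logistic model."""

    effect_estimate: float  # log-odds, tau vs control
    std_error: float
    p_value: float
    n_groups: dict
    model_descriptor: str


@dataclass(frozen=True)
class DensityComparison:
    """Per-animal-mean spine density comparison between genotypes."""

    mean_density_control: float
    mean_density_tau: float
    percent_reduction: float  # 100 * (1 - tau/control)
    t_statistic: float
    p_value: float
    n_animals: dict


@dataclass(frozen=True)
class CorrelationResult:
    """OLS R^2 and Spearman rho for density vs parent-dendrite ratio."""

    r_squared: float
    ols_slope: float
    ols_p_value: float
    spearman_rho: float
    p_value: float
    n: int


def compute_thresholds(control_measurements: pd.DataFrame, q: float = 95.0) -> OverloadThresholds:
    """Per-compartment overload thresholds from pooled control measurements.

    The threshold is the ``q``-th percentile (linear interpolation between
    order statistics) of control mean ratios, pooled across control animals.

    Raises
    ------
    ValueError
        If either compartment has fewer than 20 control measurements.
    """
    thr = {}
    for comp in COMPARTMENTS:
        vals = control_measurements.loc[
            control_measurements["compartment"] == comp, "mean_ratio"
        ].dropna().to_numpy()
        if vals.size < 20:
            raise ValueError(
                f"insufficient control data for compartment {comp!r}: "
                f"{vals.size} measurements (need >= 20)"
            )
        thr[comp] = float(np.percentile(vals, q))
    return OverloadThresholds(thr_dend=thr["dendrite"], thr_spine=thr["spine"])


def classify_overload(
    measurements: pd.DataFrame, thresholds: OverloadThresholds
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag each measurement as overloaded (ratio strictly above its
    compartment's threshold; ties count as non-overloaded).

    Returns the flagged copy and a per-genotype x compartment table of
    overload fractions and counts.
    """
    out = measurements.copy()
    thr = out["compartment"].map({"dendrite": thresholds.thr_dend, "spine": thresholds.thr_spine})
    out["overload"] = out["mean_ratio"] > thr
    frac = (
        out.groupby(["genotype", "compartment"], sort=True)["overload"]
        .agg(n="size", n_overload="sum", fraction="mean")
        .reset_index()
    )
    return out, frac


def fit_overload_model(
    flags: np.ndarray | pd.Series,
    genotype: np.ndarray | pd.Series,
    animal_id: np.ndarray | pd.Series,
    n_quad: int = 25,
) -> GroupComparison:
    """Mixed-effects logistic regression of overload on genotype.

    Fits ``overload ~ genotype + (1 | animal)`` by Gauss-Hermite ML and
    returns the genotype fixed effect (log-odds of overload, tau vs control)
    with its Wald p-value.

    Raises
    ------
    ValueError
        Fewer than 2 animals in a genotype.
    SeparationError
        All flags identical or quasi-separated outcomes.
    """
    y = np.asarray(flags, dtype=float)
    g = np.asarray(genotype)
    a = np.asarray(animal_id)
    n_groups = {
        geno: int(np.unique(a[g == geno]).size) for geno in ("control", "tau")
    }
    for geno, n in n_groups.items():
        if n < 2:
            raise ValueError(f"genotype {geno!r} has {n} animal(s); need >= 2")
    X = np.column_stack([np.ones_like(y), (g == "tau").astype(float)])
    model = MixedLogit(y, X, groups=a, exog_names=["intercept", "genotype[tau]"], n_quad=n_quad)
    res = model.fit()
    return GroupComparison(
        effect_estimate=float(res.params[1]),
        std_error=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
        n_groups=n_groups,
        model_descriptor=(
            "mixed-effects logistic regression: overload ~ genotype + (1|animal), "
            f"Gauss-Hermite ML, sigma_u={res.sigma:.3f}"
        ),
    )


def check_normality(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (statistic, p-value) for 3 <= n <= 5000."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def compare_density(records: pd.DataFrame, equal_var: bool = True) -> DensityComparison:
    """Two-sample t-test on per-animal mean spine densities.

    Each animal contributes the mean density of its included dendrites; the
    genotype groups are compared with a two-sided Student t-test (Welch via
    ``equal_var=False``).  Percent reduction is
    ``100 * (1 - mean_tau / mean_control)``.

    Raises
    ------
    ValueError
        If a genotype has fewer than 2 animals with included dendrites.
    """
    inc = records[records["included"]]
    per_animal = inc.groupby(["genotype", "animal_id"])["density_per_um"].mean()
    means = {}
    groups = {}
    for geno in ("control", "tau"):
        vals = per_animal.get(geno, pd.Series(dtype=float)).to_numpy()
        if vals.size < 2:
            raise ValueError(
                f"genotype {geno!r} has {vals.size} animal(s) with included dendrites; need >= 2"
            )
        groups[geno] = vals
        means[geno] = float(vals.mean())
    t, p = sps.ttest_ind(groups["tau"], groups["control"], equal_var=equal_var)
    return DensityComparison(
        mean_density_control=means["control"],
        mean_density_tau=means["tau"],
        percent_reduction=100.0 * (1.0 - means["tau"] / means["control"]),
        t_statistic=float(t),
        p_value=float(p),
        n_animals={g: int(v.size) for g, v in groups.items()},
    )


def correlate_density_ratio(records: pd.DataFrame) -> CorrelationResult:
    """OLS and Spearman correlation of spine density vs parent-dendrite ratio.

    Applied to included dendrites of one group (the tau group, in the
    pipeline's report).  Raises if fewer than 3 usable records or either
    variable is constant.
    """
    df = records[records["included"]].dropna(subset=["density_per_um", "parent_ratio"])
    x = df["parent_ratio"].to_numpy(dtype=float)
    y = df["density_per_um"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError(f"need >= 3 records with density and parent ratio, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance in density or ratio")
    ols = sps.linregress(x, y)
    rho, p_rho = sps.spearmanr(x, y)
    return CorrelationResult(
        r_squared=float(ols.rvalue**2),
        ols_slope=float(ols.slope),
        ols_p_value=float(ols.pvalue),
        spearman_rho=float(rho),
        p_value=float(p_rho),
        n=int(x.size),
    )
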