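"""Analysis of Monte Carlo campaign records.

Descriptive statistics and kernel densities of feasible vs infeasible
perturbations, and forward-stepwise logistic regression of feasibility on
centred perturbations (with pairwise interactions), selected by the
adjusted McFadden pseudo-R-squared criterion and reported as odds ratios
with Wald confidence intervals.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from hillmc.perturbation_campaign import COLUMN_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptiveRow",
    "RegressionTerm",
    "RegressionReport",
    "centre_perturbations",
    "descriptive_stats",
    "kernel_density",
    "mcfadden_adjusted_r2",
    "stepwise_logistic",
    "odds_ratio_ci",
]


def centre_perturbations(percentages):
    """Centre perturbation percentages about the unperturbed value:
    x = p - 100, so 0 means unperturbed and -40 a 40-point reduction."""
    if isinstance(percentages, pd.DataFrame):
        return percentages - 100.0
    return np.asarray(percentages, dtype=float) - 100.0


@dataclass(frozen=True)
class DescriptiveRow:
    """Descriptives of one group x parameter column within one class."""

    feasible_class: bool
    group: str
    parameter: str
    median: float
    iqr: float
    ci_low: float
    ci_high: float
    minimum: float
    maximum: float


def _median_bootstrap_ci(values, n_resamples: int = 2000, level: float = 0.95,
                         seed: int = 0):
    rng = np.random.default_rng(seed)
    v = np.asarray(values, dtype=float)
    meds = np.median(
        v[rng.integers(0, len(v), size=(n_resamples, len(v)))], axis=1)
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(meds, alpha)),
            float(np.quantile(meds, 1.0 - alpha)))


def descriptive_stats(records, n_resamples: int = 2000,
                      seed: int = 0) -> pd.DataFrame:
    """Median, IQR (Q3 - Q1, linear-interpolation quartiles), percentile
    bootstrap 95% CI of the median, min and max of each of the 15
    perturbation columns, separately for feasible and infeasible records.

    Classes with fewer than 5 records are skipped with a warning.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    rows = []
    for feas in (True, False):
        sub = df[df["feasible"] == feas]
        if len(sub) < 5:
            warnings.warn(
                f"fewer than 5 {'feasible' if feas else 'infeasible'} "
                "records; class skipped")
            continue
        for col in COLUMN_NAMES:
            v = sub[col].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            lo, hi = _median_bootstrap_ci(v, n_resamples, seed=seed)
            group, param = col.split("_")
            rows.append(DescriptiveRow(
                feasible_class=feas, group=group, parameter=param,
                median=float(med), iqr=float(q3 - q1),
                ci_low=lo, ci_high=hi,
                minimum=float(v.min()), maximum=float(v.max())))
    return pd.DataFrame([r.__dict__ for r in rows])


def kernel_density(values, grid, bandwidth_floor: float = 1e-3):
    """Gaussian kernel density with Silverman bandwidth on the given grid.

    Degenerate (near-zero variance) inputs fall back to a fixed-bandwidth
    Gaussian spike so the estimate stays a proper density.
    """
    v = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if len(v) < 5:
        raise ValueError("kernel density needs at least 5 values")
    if np.std(v) < bandwidth_floor:
        bw = bandwidth_floor
        dens = np.exp(-0.5 * ((grid[:, None] - v[None, :]) / bw) ** 2)
        return dens.sum(axis=1) / (len(v) * bw * np.sqrt(2.0 * np.pi))
    kde = scipy.stats.gaussian_kde(v, bw_method="silverman")
    return kde(grid)


def mcfadden_adjusted_r2(loglik: float, loglik_null: float,
                         n_params: int) -> float:
    """Adjusted McFadden pseudo-R-squared:
    1 - (loglik - n_params) / loglik_null, with ``n_params`` the number of
    estimated covariates beyond the intercept."""
    if loglik_null >= 0:
        raise ValueError("null log-likelihood must be negative")
    return 1.0 - (loglik - n_params) / loglik_null


def odds_ratio_ci(log_odds: float, std_err: float, level: float = 0.99):
    """Odds ratio and Wald confidence interval on the log-odds scale."""
    if std_err <= 0:
        raise ValueError("standard error must be positive")
    z = scipy.stats.norm.ppf(0.5 + level / 2.0)
    return (float(np.exp(log_odds)),
            float(np.exp(log_odds - z * std_err)),
            float(np.exp(log_odds + z * std_err)))


@dataclass(frozen=True)
class RegressionTerm:
    name: str
    log_odds: float
    std_err: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    significant: bool   # CI excludes an odds ratio of 1


@dataclass
class RegressionReport:
    """Selected stepwise logistic model for one campaign."""

    terms: list                   # RegressionTerm, intercept first
    r2_trace: list                # adjusted pseudo-R2 after each step
    selected: list                # covariate names in selection order
    n: int
    n_feasible: int
    loglik: float
    loglik_null: float
    separation_warning: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.terms])


def _fit_logit(y, X):
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:
            res = model.fit(disp=0, method="bfgs", maxiter=500)
    return res


def stepwise_logistic(records, candidates=None, delta: float = 0.025,
                      include_interactions: bool = True,
                      hierarchy: bool = True, ci_level: float = 0.99,
                      feasible_col: str = "feasible") -> RegressionReport:
    """Forward-stepwise logistic regression of feasibility on centred
    perturbations.

    At each step the candidate giving the largest increase of the adjusted
    McFadden pseudo-R-squared enters the model; selection stops when no
    candidate adds at least ``delta`` (2.5 percentage points by default).
    Candidates default to the 15 centred main effects plus all pairwise
    interactions; with ``hierarchy=True`` an interaction is eligible only
    after both its parents entered. Ties break by candidate order.

    Coefficients are reported as log-odds and odds ratios per 1%
    perturbation with Wald CIs; a term is significant when its odds-ratio
    CI excludes 1.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    y = df[feasible_col].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both feasibility classes must be present")

    main = list(candidates) if candidates is not None else list(COLUMN_NAMES)
    X_main = centre_perturbations(df[main]).astype(float)
    cols = {c: X_main[c].to_numpy() for c in main}
    order = list(main)
    parents = {c: frozenset([c]) for c in main}
    if include_interactions and candidates is None:
        for a, b in itertools.combinations(main, 2):
            name = f"{a}:{b}"
            cols[name] = cols[a] * cols[b]
            parents[name] = frozenset([a, b])
            order.append(name)

    n = len(y)
    null_res = _fit_logit(y, np.ones((n, 1)))
    ll0 = float(null_res.llf)
    selected: list = []
    r2_trace = [mcfadden_adjusted_r2(ll0, ll0, 0)]
    current_ll = ll0
    separation = False

    while True:
        best = None
        for c in order:
            if c in selected:
                continue
            if hierarchy and not (parents[c] <= frozenset(selected + [c])
                                  if ":" not in c else
                                  parents[c] <= frozenset(selected)):
                continue
            X = np.column_stack(
                [np.ones(n)] + [cols[s] for s in selected] + [cols[c]])
            try:
                res = _fit_logit(y, X)
            except Exception:
                continue
            r2 = mcfadden_adjusted_r2(float(res.llf), ll0, len(selected) + 1)
            if best is None or r2 > best[1] + 1e-12:
                best = (c, r2, res)
        if best is None or best[1] - r2_trace[-1] < delta:
            break
        selected.append(best[0])
        r2_trace.append(best[1])
        current_ll = float(best[2].llf)
        final_res = best[2]

    if not selected:
        final_res = null_res

    if not np.all(np.isfinite(final_res.bse)) or np.any(final_res.bse > 1e3):
        separation = True
        warnings.warn("possible separation: unstable coefficient "
                      "standard errors in the selected model")

    terms = []
    names = ["intercept"] + selected
    for name, beta, se in zip(names, np.atleast_1d(final_res.params),
                              np.atleast_1d(final_res.bse)):
        if se > 0 and np.isfinite(se):
            or_, lo, hi = odds_ratio_ci(float(beta), float(se), ci_level)
        else:
            or_, lo, hi = float(np.exp(beta)), float("nan"), float("nan")
        terms.append(RegressionTerm(
            name=name, log_odds=float(beta), std_err=float(se),
            odds_ratio=or_, ci_low=lo, ci_high=hi,
            significant=bool(np.isfinite(lo) and (lo > 1.0 or hi < 1.0))))

    return RegressionReport(
        terms=terms, r2_trace=r2_trace, selected=selected,
        n=n, n_feasible=int(y.sum()),
        loglik=float(final_res.llf), loglik_null=ll0,
        separation_warning=separation)
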