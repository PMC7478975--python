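"""Power-law residence-time statistics and cohort comparisons.

Residence-time densities are heavy-tailed; on log-log axes they are close
to straight lines y = -a x - b, whose slope magnitude a is the power-law
exponent and intercept magnitude b the (base-10) density scale.  The fit is
an unweighted least-squares regression of log10(density) on log10(duration)
over a fixed duration band — equivalent to minimizing relative error, so
the rare long durations do not dominate.  Default bands: 0.3-5.0 s for the
active state, 1-50 s for the inactive state.

Group-level comparisons use the classic Student two-sample t-test (pooled
variance) and the Pearson chi-squared test of independence.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, InputError
from .residence import NormalizedProbabilityDensity, _npd_from_histogram

__all__ = [
    "PowerLawFit", "GroupComparison", "ACTIVE_FIT_RANGE", "INACTIVE_FIT_RANGE",
    "residence_npd", "fit_powerlaw", "student_t", "chi2_independence",
    "summarize_groups",
]

ACTIVE_FIT_RANGE = (0.3, 5.0)
INACTIVE_FIT_RANGE = (1.0, 50.0)


@dataclass
class PowerLawFit:
    """Log-log line fit y = -a x - b, i.e. density ~ 10^(-b) * t^(-a)."""

    a: float
    b: float
    fit_range: tuple[float, float]
    r_squared: float
    n_points: int


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    test: Literal["student_t", "chi2_independence"]
    group_labels: tuple[str, str]
    n_per_group: tuple[int, ...]
    degenerate: bool = False


def residence_npd(durations: Sequence[float],
                  binning: Literal["logarithmic", "linear"] = "logarithmic",
                  n_bins: int = 40) -> NormalizedProbabilityDensity:
    """Normalized probability density of residence times.

    Logarithmic binning by default: heavy tails leave linear bins almost
    empty past a few seconds.  Counts are divided by bin width and total
    mass, then renormalized to a unit trapezoid integral.
    """
    d = np.asarray(durations, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise InputError("no durations supplied")
    if d.size < 50:
        warnings.warn("fewer than 50 durations; density estimate is unstable",
                      stacklevel=2)
    lo, hi = d.min(), d.max()
    if lo <= 0:
        raise InputError("durations must be positive")
    if lo == hi:
        lo, hi = 0.9 * lo, 1.1 * hi
    if binning == "logarithmic":
        edges = np.geomspace(lo, hi * (1 + 1e-12), n_bins + 1)
    elif binning == "linear":
        edges = np.linspace(lo, hi * (1 + 1e-12), n_bins + 1)
    else:
        raise InputError(f"unknown binning: {binning!r}")
    return _npd_from_histogram(d, edges, binning)


def fit_powerlaw(npd: NormalizedProbabilityDensity,
                 fit_range: tuple[float, float] = ACTIVE_FIT_RANGE) -> PowerLawFit:
    """Least-squares line through (log10 t, log10 density) inside fit_range.

    Returns a = -slope and b = -intercept so density ~ 10^(-b) * t^(-a).
    Zero-density bins inside the range are excluded with a warning.
    """
    t_lo, t_hi = fit_range
    if not 0 < t_lo < t_hi:
        raise InputError("fit_range must satisfy 0 < t_lo < t_hi")
    t = npd.bin_centers
    y = npd.density
    in_range = (t >= t_lo) & (t <= t_hi)
    usable = in_range & (y > 0)
    if usable.sum() < in_range.sum():
        warnings.warn("zero-density bins inside fit range were excluded",
                      stacklevel=2)
    if usable.sum() < 3:
        raise FitError("need >= 3 nonzero-density bins inside fit_range")
    x = np.log10(t[usable])
    z = np.log10(y[usable])
    slope, intercept = np.polyfit(x, z, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((z - pred) ** 2))
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(a=-slope, b=-intercept, fit_range=(t_lo, t_hi),
                       r_squared=r2, n_points=int(usable.sum()))


def mle_powerlaw_exponent(durations: Sequence[float], t_min: float) -> float:
    """Continuous maximum-likelihood exponent (non-default cross-check).

    Hill-type estimator a = 1 + n / sum(ln(t/t_min)) for t >= t_min.  The
    regression fit above defines the reported exponents; this estimator is
    offered only for sanity checks.
    """
    d = np.asarray(durations, dtype=float)
    d = d[d >= t_min]
    if d.size < 10:
        raise InputError("too few durations above t_min")
    return 1.0 + d.size / float(np.sum(np.log(d / t_min)))


def student_t(group_a: Sequence[float], group_b: Sequence[float],
              labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Classic Student two-sample t-test (pooled variance, two-sided)."""
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InputError("each group needs n >= 2")
    degenerate = x.std(ddof=1) == 0 and y.std(ddof=1) == 0
    if degenerate and np.isclose(x.mean(), y.mean()):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.ttest_ind(x, y, equal_var=True)
    return GroupComparison(statistic=float(stat), p_value=float(p),
                           test="student_t", group_labels=labels,
                           n_per_group=(x.size, y.size), degenerate=degenerate)


def chi2_independence(table, labels: tuple[str, str] = ("rows", "cols"),
                      ) -> GroupComparison:
    """Pearson chi-squared test of independence (no continuity correction)."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise InputError("need a table of at least 2x2 counts")
    if np.any(tab < 0):
        raise InputError("counts must be non-negative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise InputError("zero row/column sums make expected counts undefined")
    res = stats.chi2_contingency(tab, correction=False)
    return GroupComparison(statistic=float(res.statistic),
                           p_value=float(res.pvalue),
                           test="chi2_independence", group_labels=labels,
                           n_per_group=tuple(int(s) for s in tab.sum(axis=1)))


def summarize_groups(per_animal: Mapping[str, Sequence[Mapping[str, float]]],
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean +/- sd of fit/spectrum parameters plus pairwise t-tests.

    ``per_animal`` maps a group label (e.g. "Long/high-motility/active") to
    one parameter dict per animal (e.g. {"a": 1.9, "b": 0.8}).  Returns a
    summary table (group x parameter -> mean, sd, n) and a comparison table
    of pairwise Student-t p-values per parameter.
    """
    rows = []
    values: dict[tuple[str, str], np.ndarray] = {}
    for group, dicts in per_animal.items():
        if len(dicts) < 1:
            raise InputError(f"group {group!r} is empty")
        params = sorted({k for d in dicts for k in d})
        for p in params:
            vals = np.asarray([d[p] for d in dicts if p in d], dtype=float)
            values[(group, p)] = vals
            sd = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
            if vals.size < 2:
                warnings.warn(f"singleton group {group!r}: sd undefined",
                              stacklevel=2)
            rows.append({"group": group, "parameter": p,
                         "mean": float(vals.mean()), "sd": sd,
                         "n": int(vals.size)})
    summary = pd.DataFrame(rows)

    comp_rows = []
    for (g1, p1), (g2, p2) in itertools.combinations(values, 2):
        if p1 != p2:
            continue
        v1, v2 = values[(g1, p1)], values[(g2, p2)]
        if v1.size < 2 or v2.size < 2:
            continue
        cmp = student_t(v1, v2, labels=(g1, g2))
        comp_rows.append({"parameter": p1, "group_a": g1, "group_b": g2,
                          "t_statistic": cmp.statistic, "p_value": cmp.p_value,
                          "n_a": v1.size, "n_b": v2.size})
    comparisons = pd.DataFrame(comp_rows)
    return summary, comparisons
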