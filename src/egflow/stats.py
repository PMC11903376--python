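"""Registry statistics: one-tailed tests and regression.

Group comparisons use one-tailed independent tests oriented in the
direction of the observed difference: a pooled-proportion z-test without
continuity correction for proportions, and a pooled-variance t-test
(df = n1 + n2 - 2) from summary statistics for continuous variables.  A
Welch t is available via a flag.  Linear regression reports the best-fit
line, r, r^2 and the p-value of the F-test for the slope (identical to the
two-sided slope t-test in simple regression).

``registry_report`` re-runs every comparison recorded in the bundled
cohort-table fixture and returns them as a data frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import stats as sst


@dataclass
class StatResult:
    statistic: float
    p_one_tailed: float
    df: float | None = None
    inputs_echo: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r_squared: float
    F_p: float


def two_prop_z(k1: int, n1: int, k2: int, n2: int) -> StatResult:
    """One-tailed two-proportion z-test, pooled variance, no continuity
    correction; p is the tail probability in the observed direction."""
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    echo = {"k1": k1, "n1": n1, "k2": k2, "n2": n2}
    if se == 0:
        return StatResult(statistic=0.0, p_one_tailed=0.5, inputs_echo=echo,
                          flags=["degenerate pooled proportion"])
    z = (p1 - p2) / se
    return StatResult(statistic=float(z), p_one_tailed=float(sst.norm.sf(abs(z))),
                      inputs_echo=echo)


def t_test_from_summary(m1: float, sd1: float, n1: int, m2: float, sd2: float,
                        n2: int, welch: bool = False) -> StatResult:
    """One-tailed independent t-test from summary statistics (pooled by
    default)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    echo = {"m1": m1, "sd1": sd1, "n1": n1, "m2": m2, "sd2": sd2, "n2": n2}
    if welch:
        se = np.sqrt(sd1**2 / n1 + sd2**2 / n2)
        if se == 0:
            return _degenerate_t(m1, m2, echo)
        df = (sd1**2 / n1 + sd2**2 / n2) ** 2 / (
            (sd1**2 / n1) ** 2 / (n1 - 1) + (sd2**2 / n2) ** 2 / (n2 - 1)
        )
    else:
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
        if se == 0:
            return _degenerate_t(m1, m2, echo)
    t = (m1 - m2) / se
    return StatResult(statistic=float(t), p_one_tailed=float(sst.t.sf(abs(t), df)),
                      df=float(df), inputs_echo=echo)


def _degenerate_t(m1, m2, echo) -> StatResult:
    if m1 == m2:
        return StatResult(statistic=0.0, p_one_tailed=0.5, inputs_echo=echo,
                          flags=["zero pooled variance, equal means"])
    return StatResult(statistic=float(np.inf) * np.sign(m1 - m2),
                      p_one_tailed=0.0, inputs_echo=echo,
                      flags=["zero pooled variance, unequal means"])


def linreg(x, y) -> RegressionResult:
    """Least-squares line of best fit with r, r^2 and the slope F-test p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need >= 3 points")
    if np.var(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sst.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r=float(res.rvalue), r_squared=float(res.rvalue**2),
                            F_p=float(res.pvalue))


# ---------------------------------------------------------------------------
# registry report from the bundled printed-tables fixture

def load_registry_tables() -> dict:
    """The printed cohort tables bundled with the package."""
    with resources.files("egflow.data").joinpath("registry_tables.json").open() as fh:
        return json.load(fh)


def registry_report(tables: dict | None = None) -> "pandas.DataFrame":
    """Recompute every comparison in the cohort tables.

    One row per comparison: test type, inputs, statistic, one-tailed p, and
    the table's printed p for reference.
    """
    import pandas as pd

    tables = tables or load_registry_tables()
    rows = []
    for cmp_ in tables["proportions"]:
        r = two_prop_z(cmp_["k1"], cmp_["n1"], cmp_["k2"], cmp_["n2"])
        rows.append({
            "name": cmp_["name"], "test": "two_prop_z",
            "inputs": f"{cmp_['k1']}/{cmp_['n1']} vs {cmp_['k2']}/{cmp_['n2']}",
            "statistic": r.statistic, "p": r.p_one_tailed,
            "printed_p": cmp_.get("printed_p"),
        })
    for cmp_ in tables["means"]:
        r = t_test_from_summary(cmp_["m1"], cmp_["sd1"], cmp_["n1"],
                                cmp_["m2"], cmp_["sd2"], cmp_["n2"])
        rows.append({
            "name": cmp_["name"], "test": "t_pooled",
            "inputs": (f"{cmp_['m1']}±{cmp_['sd1']} (n={cmp_['n1']}) vs "
                       f"{cmp_['m2']}±{cmp_['sd2']} (n={cmp_['n2']})"),
            "statistic": r.statistic, "p": r.p_one_tailed,
            "printed_p": cmp_.get("printed_p"),
        })
    return pd.DataFrame(rows)
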