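"""Tip-to-root regression for temporal signal and molecular age prediction.

Under a strict molecular clock, a tip's path distance from the root grows
linearly with elapsed time, so regressing root-to-tip distance on sampling
age (years before present, positive into the past) estimates the
substitution rate as the slope and the root age as the x-intercept.
Undated tips are assigned the age at which the fitted line attains their
observed distance, with prediction intervals propagated from the residual
variance and coefficient covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm


@dataclass
class TemporalRegression:
    slope: float  # substitutions (per bp if per-bp distances) per year
    intercept: float
    r_squared: float
    root_age_estimate: float
    residuals: dict[str, float]
    predicted_ages: pd.DataFrame  # tip, distance, age, age_lower, age_upper
    n_dated: int


def root_to_tip_distances(
    tree: dendropy.Tree, per_bp: bool = False, alignment_length: int | None = None
) -> dict[str, float]:
    """Sum of branch lengths on each root-to-tip path.

    With ``per_bp`` the distances are divided by ``alignment_length``.
    """
    if not tree.is_rooted:
        raise ValueError("a rooted tree is required")
    if per_bp and not alignment_length:
        raise ValueError("alignment_length required for per-bp distances")
    dist: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    out: dict[str, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            dist[nd] = dist[nd.parent_node] + (nd.edge.length or 0.0)
        if nd.is_leaf():
            d = dist[nd]
            out[nd.taxon.label] = d / alignment_length if per_bp else d
    return out


def fit_temporal_regression(
    distances: dict[str, float],
    tip_ages: dict[str, float],
    undated_tips: list[str] | tuple[str, ...] = (),
    alpha: float = 0.05,
) -> TemporalRegression:
    """OLS of distance on negative age, so the slope is the forward-in-time
    substitution rate.

    Requires dated tips with >= 2 distinct ages; two dated tips give the
    exact interpolating line (residual-based intervals are then undefined).
    ``undated_tips`` must be present in ``distances``; their ages are read
    off the inverted fitted line with (1-alpha) prediction intervals.
    """
    dated = [t for t in distances if t in tip_ages and t not in set(undated_tips)]
    if len(dated) < 2:
        raise ValueError("need at least 2 dated tips")
    ages = np.array([tip_ages[t] for t in dated], dtype=float)
    if len(np.unique(ages)) < 2:
        raise ValueError("all tip ages equal: no temporal signal to fit")
    y = np.array([distances[t] for t in dated], dtype=float)
    x = -ages
    X = sm.add_constant(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        fit = sm.OLS(y, X).fit()
        fit.scale  # force lazy residual-variance evaluation (0/0 at n=2)
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    resid = {t: float(r) for t, r in zip(dated, fit.resid)}

    rows = []
    if slope != 0:
        cov = fit.cov_params()
        s2 = float(fit.mse_resid)
        tq = scipy.stats.t.ppf(1 - alpha / 2, df=max(int(fit.df_resid), 1))
        for tip in undated_tips:
            if tip not in distances:
                raise ValueError(f"no distance for undated tip {tip!r}")
            d = distances[tip]
            x_hat = (d - intercept) / slope  # = -age
            var_x = (
                s2
                + cov[0, 0]
                + x_hat**2 * cov[1, 1]
                + 2 * x_hat * cov[0, 1]
            ) / slope**2
            se = float(np.sqrt(max(var_x, 0.0)))
            age = -x_hat
            rows.append(
                {
                    "tip": tip,
                    "distance": d,
                    "age": age,
                    "age_lower": age - tq * se,
                    "age_upper": age + tq * se,
                }
            )
    predicted = pd.DataFrame(rows, columns=["tip", "distance", "age", "age_lower", "age_upper"])
    return TemporalRegression(
        slope=slope,
        intercept=intercept,
        r_squared=float(fit.rsquared),
        root_age_estimate=intercept / slope if slope != 0 else float("nan"),
        residuals=resid,
        predicted_ages=predicted,
        n_dated=len(dated),
    )
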