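"""Downstream statistics on per-pair log Y values.

One-sample t-tests of mean log Y against zero, Spearman rank correlation of
log Y against log ΔRSCU, and an ordinary least squares model testing whether
the log Y ~ log ΔRSCU slope differs between gene categories (CAI or
expression bins) via a category × slope interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats


@dataclass
class PairObservation:
    """One directed amino-acid pair's statistics entering the tests."""

    pair_label: str
    log_y: float
    log_delta_rscu: float = math.nan
    degeneracy_class: str = ""
    category: int | None = None


@dataclass
class TestReport:
    test_name: str
    statistic: float
    p_value: float
    n: int
    estimate: dict = field(default_factory=dict)
    interaction_p: float | None = None


def _finite(obs: Sequence[PairObservation], need_delta: bool = False):
    keep = [
        o for o in obs
        if math.isfinite(o.log_y) and (not need_delta or math.isfinite(o.log_delta_rscu))
    ]
    return keep


def mean_log_y_test(
    obs: Sequence[PairObservation], sidedness: str = "two-sided"
) -> TestReport:
    """One-sample t-test of mean log Y against 0.

    ``sidedness`` is "two-sided" (default, the headline test) or "greater"
    (used by the power machinery).  Non-finite log Y values are excluded;
    fewer than 2 finite observations raise, and zero sample variance yields
    an undefined (NaN) p-value.
    """
    if sidedness not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    vals = np.array([o.log_y for o in _finite(obs)])
    if vals.size < 2:
        raise ValueError(f"need ≥2 finite observations, got {vals.size}")
    if np.ptp(vals) == 0:
        return TestReport("mean_log_y_t", math.nan, math.nan, int(vals.size),
                          {"mean": float(vals.mean()), "degenerate": True})
    res = stats.ttest_1samp(vals, 0.0, alternative=sidedness)
    return TestReport(
        "mean_log_y_t",
        float(res.statistic),
        float(res.pvalue),
        int(vals.size),
        {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))},
    )


def spearman_log_y_vs_delta(obs: Sequence[PairObservation]) -> TestReport:
    """Spearman rank correlation between log Y and log ΔRSCU (tie-corrected)."""
    keep = _finite(obs, need_delta=True)
    if len(keep) < 3:
        raise ValueError(f"need ≥3 finite paired observations, got {len(keep)}")
    x = np.array([o.log_delta_rscu for o in keep])
    y = np.array([o.log_y for o in keep])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestReport("spearman", math.nan, math.nan, len(keep),
                          {"rho": math.nan, "degenerate": True})
    rho, p = stats.spearmanr(x, y)
    return TestReport("spearman", float(rho), float(p), len(keep),
                      {"rho": float(rho)})


def category_interaction_model(obs: Sequence[PairObservation]) -> TestReport:
    """OLS of log Y on log ΔRSCU × category (unordered factor).

    Reports per-category slopes and the joint p-value of the interaction
    terms (F-test against the additive model).  Requires ≥2 categories each
    with ≥3 observations.  Rank deficiency is reported in the estimate dict.
    """
    keep = [o for o in _finite(obs, need_delta=True) if o.category is not None]
    df = pd.DataFrame(
        {
            "log_y": [o.log_y for o in keep],
            "log_delta": [o.log_delta_rscu for o in keep],
            "category": pd.Categorical([o.category for o in keep]),
        }
    )
    sizes = df.groupby("category", observed=True).size()
    if (sizes >= 3).sum() < 2 or len(sizes) < 2:
        raise ValueError(
            "need ≥2 categories with ≥3 observations each; "
            f"got sizes {dict(sizes)}"
        )
    full = smf.ols("log_y ~ log_delta * category", data=df).fit()
    reduced = smf.ols("log_y ~ log_delta + category", data=df).fit()
    comparison = sm.stats.anova_lm(reduced, full)
    inter_p = float(comparison["Pr(>F)"].iloc[1])

    cats = list(sizes.index)
    base = cats[0]
    slopes: dict = {}
    base_slope = full.params.get("log_delta", math.nan)
    for c in cats:
        if c == base:
            slopes[c] = float(base_slope)
        else:
            extra = full.params.get(f"log_delta:category[T.{c}]", 0.0)
            slopes[c] = float(base_slope + extra)
    rank_deficient = np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]
    est = {"slopes": slopes}
    if rank_deficient:
        est["rank_deficient"] = True
    return TestReport(
        "category_interaction_ols",
        float(comparison["F"].iloc[1]),
        inter_p,
        int(df.shape[0]),
        est,
        interaction_p=inter_p,
    )


def reports_frame(reports: Sequence[TestReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.test_name, r.statistic, r.p_value, r.n, repr(r.estimate),
             r.interaction_p)
            for r in reports
        ],
        columns=["test", "statistic", "p_value", "n", "estimate", "interaction_p"],
    )
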