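"""Host-plant attack incidence and Neu-method resource selection.

Given field survey tables of plants examined and plants attacked per
site and host taxon, this module provides: attack incidence, a
quasibinomial GLM comparison of incidence between two groups, and the
Neu method — an omnibus chi-square test of use versus availability
followed by per-category Bonferroni simultaneous confidence intervals
that classify each site or host taxon as *preference*, *proportional*
use, or *avoidance*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HostSurvey",
    "SelectionResult",
    "incidence",
    "compare_incidence",
    "availability_chi_square",
    "bonferroni_ci",
    "classify_use",
    "neu_analysis",
]


@dataclass
class HostSurvey:
    """Availability/attack counts keyed by (site, plant taxon).

    ``table`` must have columns ``site``, ``taxon``, ``available``,
    ``attacked`` with 0 <= attacked <= available.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"site", "taxon", "available", "attacked"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"survey table needs columns {sorted(need)}")
        t = self.table
        if (t["attacked"] < 0).any() or (t["attacked"] > t["available"]).any():
            raise ValueError("require 0 <= attacked <= available")

    @classmethod
    def from_csv(cls, path, **kwargs) -> "HostSurvey":
        return cls(pd.read_csv(path, **kwargs))

    def aggregate(self, by: str) -> pd.DataFrame:
        """Sum available/attacked over ``'site'`` or ``'taxon'``."""
        if by not in ("site", "taxon"):
            raise ValueError("by must be 'site' or 'taxon'")
        return (
            self.table.groupby(by, sort=False)[["available", "attacked"]]
            .sum()
            .reset_index()
        )


@dataclass
class SelectionResult:
    """Neu-method output for one analysis level."""

    level: str
    table: pd.DataFrame  # category, available, attacked, ppa, p_used, ci, class
    chi2: float
    df: int
    p_value: float


def incidence(attacked: int, examined: int) -> tuple[float, int]:
    """Attack incidence as a proportion and as a rounded percentage."""
    if examined <= 0:
        raise ValueError("examined must be positive")
    if attacked > examined or attacked < 0:
        raise ValueError("require 0 <= attacked <= examined")
    prop = attacked / examined
    return prop, int(round(100.0 * prop))


def compare_incidence(
    survey_a: pd.DataFrame, survey_b: pd.DataFrame
) -> dict:
    """Quasibinomial GLM comparison of per-site attack proportions.

    Each input is a per-site table with columns ``available`` and
    ``attacked``. A binomial GLM with logit link and a single group
    factor is fitted; dispersion is estimated from the Pearson statistic
    of the full model and the group effect is tested with an F statistic
    (deviance difference scaled by dispersion), as in R's
    ``anova(glm(..., family=quasibinomial), test="F")``.

    Complete separation (a group that is all-attacked or all-spared) is
    flagged and handled with a 0.5 continuity correction per group.
    """
    import statsmodels.api as sm

    frames = []
    for label, df in (("a", survey_a), ("b", survey_b)):
        d = df[["available", "attacked"]].copy()
        d["group"] = label
        frames.append(d)
    data = pd.concat(frames, ignore_index=True)
    if len(data) < 2:
        raise ValueError("need at least 2 sites in total")

    separated = False
    for _, d in data.groupby("group"):
        tot_att = d["attacked"].sum()
        tot_av = d["available"].sum()
        if tot_att == 0 or tot_att == tot_av:
            separated = True
    if separated:
        data = data.copy()
        data["attacked"] = data["attacked"] + 0.5
        data["available"] = data["available"] + 1.0

    endog = np.column_stack(
        [data["attacked"], data["available"] - data["attacked"]]
    )
    x_full = np.column_stack(
        [np.ones(len(data)), (data["group"] == "b").astype(float)]
    )
    x_null = x_full[:, :1]
    fam = sm.families.Binomial()
    full = sm.GLM(endog, x_full, family=fam).fit(tol=1e-12, maxiter=200)
    null = sm.GLM(endog, x_null, family=fam).fit(tol=1e-12, maxiter=200)
    df_resid = full.df_resid
    dispersion = full.pearson_chi2 / df_resid if df_resid > 0 else 1.0
    df_num = 1
    dev_diff = max(null.deviance - full.deviance, 0.0)
    if dispersion <= 0:
        # perfect fit in both models: no evidence of a group effect
        f_stat = 0.0 if dev_diff < 1e-10 else np.inf
        dispersion = 0.0
    else:
        f_stat = dev_diff / df_num / dispersion
    p = float(stats.f.sf(f_stat, df_num, df_resid)) if df_resid > 0 else np.nan
    return {
        "F": float(f_stat),
        "df": (df_num, int(df_resid)),
        "p_value": p,
        "dispersion": float(dispersion),
        "separation": separated,
        "prop_a": float(survey_a["attacked"].sum() / survey_a["available"].sum()),
        "prop_b": float(survey_b["attacked"].sum() / survey_b["available"].sum()),
    }


def availability_chi_square(
    used: np.ndarray, availability: np.ndarray
) -> tuple[float, int, float]:
    """Chi-square goodness of fit of use counts against availability shares.

    ``used`` are attack counts per category; ``availability`` the
    availability proportions (must sum to 1). Expected counts are
    ``sum(used) * availability``.
    """
    used = np.asarray(used, dtype=float)
    availability = np.asarray(availability, dtype=float)
    if used.shape != availability.shape:
        raise ValueError("used and availability must align")
    if not np.isclose(availability.sum(), 1.0):
        raise ValueError("availability proportions must sum to 1")
    total = used.sum()
    if total <= 0:
        raise ValueError("no attacks recorded")
    expected = total * availability
    if (expected <= 0).any():
        raise ValueError(
            "zero expected count in at least one category; merge sparse "
            "categories before testing"
        )
    chi2 = float(((used - expected) ** 2 / expected).sum())
    df = used.size - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def bonferroni_ci(
    p_hat: float, n: int, k: int, alpha: float = 0.05, clamp: bool = False
) -> tuple[float, float]:
    """Bonferroni simultaneous CI for one use proportion.

    ``p_hat +/- t_{alpha/(2k), n-1} * sqrt(p_hat (1 - p_hat) / n)`` with
    ``n`` the total number of attacked plants and ``k`` the number of
    simultaneous categories. By default the bounds are *not* truncated
    to [0, 1] (field reports quote negative lower bounds for rarely used
    hosts); pass ``clamp=True`` to truncate.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if k < 1:
        raise ValueError("need k >= 1")
    t = stats.t.ppf(1.0 - alpha / (2.0 * k), n - 1)
    half = t * np.sqrt(p_hat * (1.0 - p_hat) / n)
    lo, hi = p_hat - half, p_hat + half
    if clamp:
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return float(lo), float(hi)


def classify_use(ppa: float, ci: tuple[float, float]) -> str:
    """Classify host use against availability.

    ``preference`` when availability falls below the CI of the use
    proportion, ``proportional`` when it lies inside, ``avoidance``
    when it lies above.
    """
    lo, hi = ci
    if lo > hi:
        raise ValueError("invalid interval")
    if ppa < lo:
        return "preference"
    if ppa > hi:
        return "avoidance"
    return "proportional"


def neu_analysis(
    survey: HostSurvey,
    by: str = "taxon",
    alpha: float = 0.05,
    run_ci_always: bool = False,
) -> SelectionResult:
    """Full Neu-method analysis at the site or taxon level.

    Tests the omnibus null that attacks are proportional to availability
    (chi-square), then — when rejected, or when ``run_ci_always`` —
    computes each category's attack share, its Bonferroni simultaneous
    CI, and the preference/proportional/avoidance call.
    """
    agg = survey.aggregate(by)
    ppa = agg["available"] / agg["available"].sum()
    used = agg["attacked"].to_numpy(dtype=float)
    chi2, df, p = availability_chi_square(used, ppa.to_numpy())
    n_used = int(used.sum())
    k = len(agg)
    p_used = used / n_used
    rows = []
    do_ci = run_ci_always or p < alpha
    for j in range(k):
        if do_ci:
            ci = bonferroni_ci(float(p_used[j]), n_used, k, alpha=alpha)
            call = classify_use(float(ppa.iloc[j]), ci)
        else:
            ci = (np.nan, np.nan)
            call = "proportional"  # omnibus not rejected
        rows.append(
            {
                "category": agg[by].iloc[j],
                "available": int(agg["available"].iloc[j]),
                "attacked": int(agg["attacked"].iloc[j]),
                "ppa": float(ppa.iloc[j]),
                "p_used": float(p_used[j]),
                "ci_low": ci[0],
                "ci_high": ci[1],
                "classification": call,
            }
        )
    return SelectionResult(
        level=by, table=pd.DataFrame(rows), chi2=chi2, df=df, p_value=p
    )
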