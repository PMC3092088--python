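"""Genetic-load grouping and group comparisons of clinical traits.

Affected individuals are binned by their cumulative genetic risk (P-Hat)
into four load groups:

* high — P-Hat ≥ 0.95;
* medium — 0.75 ≤ P-Hat < 0.95;
* low — 0.5 ≤ P-Hat < 0.75;
* misclassified — P-Hat < 0.5 (cases the profile calls controls).

Categorical traits (carrier status, gender) are compared across groups by
the classical Pearson chi-square; quantitative traits (e.g. a severity
score, lesion volume, onset age) by ANCOVA — a linear model of the
(optionally transformed) outcome on group plus covariates, with the group
tested by the partial F after the covariates, and least-square group
means reported at the covariate sample means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "LOAD_GROUP_ORDER",
    "GroupTestResult",
    "assign_load_groups",
    "pearson_chi2",
    "group_ancova",
]

LOAD_GROUP_ORDER = ["high", "medium", "low", "misclassified"]

_TRANSFORMS = {
    "none": lambda x: x,
    "sqrt": np.sqrt,
    "cbrt": np.cbrt,
}


@dataclass
class GroupTestResult:
    kind: str  # "chisq" or "ancova"
    statistic: float
    df: tuple[int, int] | int
    p_value: float
    group_summaries: pd.DataFrame
    transform_applied: str = "none"


def assign_load_groups(
    scores: pd.DataFrame, *, cases_only: bool = True, truth: np.ndarray | None = None
) -> pd.DataFrame:
    """Bin scored samples into the four genetic-load groups.

    With ``cases_only`` (the standard analysis) ``truth`` must be given
    and only affected individuals are binned.  Bin edges are half-open
    with 0.95 and 0.5 on the inclusive side of the higher group, per the
    definitions above.
    """
    out = scores.copy()
    if cases_only:
        if truth is None:
            raise ValueError("truth is required when cases_only=True")
        out = out[np.asarray(truth) == 1].copy()
    p = out["p_hat"].to_numpy()
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("p_hat must lie strictly inside (0, 1)")
    group = np.select(
        [p >= 0.95, p >= 0.75, p >= 0.5],
        ["high", "medium", "low"],
        default="misclassified",
    )
    out["group"] = pd.Categorical(group, categories=LOAD_GROUP_ORDER)
    return out.reset_index(drop=True)


def pearson_chi2(contingency: np.ndarray | pd.DataFrame) -> GroupTestResult:
    """Classical Pearson chi-square on an r × c count table.

    No continuity correction; df = (r-1)(c-1).  A zero row/column margin
    makes expected counts zero and raises.
    """
    tab = np.asarray(contingency, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total: chi-square undefined")
    chi2, p, df, expected = stats.chi2_contingency(tab, correction=False)
    summaries = pd.DataFrame(
        {
            "count": tab.sum(axis=0),
            "percent": 100.0 * tab[0] / tab.sum(axis=0),
        }
    )
    return GroupTestResult(
        kind="chisq",
        statistic=float(chi2),
        df=int(df),
        p_value=float(p),
        group_summaries=summaries,
    )


def group_ancova(
    table: pd.DataFrame,
    outcome: str,
    *,
    transform: str = "none",
    covariates: tuple[str, ...] = ("gender",),
) -> GroupTestResult:
    """ANCOVA of a quantitative trait across the load groups.

    Fits ``transform(outcome) ~ group + covariates`` by OLS and tests the
    group factor by the partial F (group after covariates), which does not
    depend on the factor coding.  Least-square means are predictions per
    group at the covariate sample means.  ``gender`` as a covariate is
    coded female = 1.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"transform must be one of {sorted(_TRANSFORMS)}")
    data = table.dropna(subset=[outcome]).copy()
    groups = [g for g in LOAD_GROUP_ORDER if (data["group"] == g).any()]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    sizes = data["group"].value_counts()
    small = [g for g in groups if sizes.get(g, 0) < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 observations: {small}")

    yv = _TRANSFORMS[transform](data[outcome].to_numpy(dtype=float))
    n = len(data)

    cov_cols = []
    cov_means = []
    for c in covariates:
        if c == "gender":
            v = data["gender"].astype(str).str.upper().isin(["F", "FEMALE", "1"])
            v = v.to_numpy(dtype=float)
        else:
            v = data[c].to_numpy(dtype=float)
        cov_cols.append(v)
        cov_means.append(v.mean())

    gdum = [
        (data["group"] == g).to_numpy(dtype=float) for g in groups[1:]
    ]
    X_full = np.column_stack([np.ones(n)] + cov_cols + gdum)
    X_red = np.column_stack([np.ones(n)] + cov_cols) if cov_cols else np.ones((n, 1))

    full = sm.OLS(yv, X_full).fit()
    red = sm.OLS(yv, X_red).fit()
    df_group = len(groups) - 1
    df_resid = int(full.df_resid)
    total_ss = float(np.sum((yv - yv.mean()) ** 2))
    if red.ssr <= 1e-12 * max(total_ss, 1.0):
        # covariates already fit the outcome exactly: no group variance left
        F, p = 0.0, 1.0
    else:
        F = ((red.ssr - full.ssr) / df_group) / (full.ssr / df_resid)
        p = float(stats.f.sf(F, df_group, df_resid))

    # least-square means: prediction per group at the covariate means
    lsm = []
    for g in groups:
        row = [1.0] + cov_means + [1.0 if g == h else 0.0 for h in groups[1:]]
        lsm.append(float(np.dot(row, full.params)))
    summaries = pd.DataFrame(
        {"group": groups, "ls_mean": lsm, "n": [int(sizes[g]) for g in groups]}
    )
    return GroupTestResult(
        kind="ancova",
        statistic=float(F),
        df=(df_group, df_resid),
        p_value=p,
        group_summaries=summaries,
        transform_applied=transform,
    )
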