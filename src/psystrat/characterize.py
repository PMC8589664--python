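"""Group characterization: factor scores, item-level tests, outcome contrasts.

Factor scores follow the Wallwork five-factor grouping of PANSS items
(positive, negative, disorganized, excited, depressed); a factor score is
the *sum* of its constituent item scores.  Group-specific items are found
by two-sample Kolmogorov-Smirnov tests of each item's scores in one group
against the pooled remaining groups, Bonferroni-corrected over the full
family of (item, group) comparisons.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from .cohort import OUTCOME_BINARY, OUTCOME_CATEGORICAL, OUTCOME_CONTINUOUS, PANSS_ITEMS, Cohort

logger = logging.getLogger(__name__)

#: Wallwork five-factor item composition.
WALLWORK_FACTORS: dict[str, tuple[str, ...]] = {
    "positive": ("P1", "P3", "P5", "G9"),
    "negative": ("N1", "N2", "N3", "N4", "N6", "G7"),
    "disorganized": ("P2", "N5", "G11"),
    "excited": ("P4", "P7", "G8", "G14"),
    "depressed": ("G2", "G3", "G6"),
}

FACTOR_NAMES = tuple(WALLWORK_FACTORS)

GROUP_LABELS = ("A", "B", "C")
UNASSIGNED = "unassigned"


def wallwork_factors(panss: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Per-patient factor scores (sums of the mapped items)."""
    if isinstance(panss, np.ndarray):
        panss = pd.DataFrame(panss, columns=list(PANSS_ITEMS))
    out = {}
    for factor, items in WALLWORK_FACTORS.items():
        out[factor] = panss[list(items)].sum(axis=1)
    return pd.DataFrame(out, index=panss.index)


def ks_two_sample(a, b, method: str = "asymp") -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and two-sided p-value.

    D is the exact maximum ECDF difference evaluated over the pooled
    support (correct in the presence of ties, which are the norm on 1-7
    ordinal scores).  ``method="asymp"`` evaluates the one-sample KS null
    distribution at the effective sample size n_a n_b / (n_a + n_b) — the
    convention of scipy's two-sided asymptotic mode; "kolmogorov" uses the
    limiting Kolmogorov distribution instead, and "exact" delegates the
    small-sample null distribution to scipy (valid without ties, where it
    is conservative).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    support = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, support, side="right") / a.size
    cdf_b = np.searchsorted(b, support, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    en = a.size * b.size / (a.size + b.size)
    if method == "asymp":
        p = float(stats.kstwo.sf(d, max(1, int(round(en)))))
    elif method == "kolmogorov":
        p = float(special.kolmogorov(np.sqrt(en) * d))
    elif method == "exact":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.ks_2samp(a, b, method="exact").pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return d, min(max(p, 0.0), 1.0)


def group_specific_items(
    panss: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    alpha: float = 0.05,
    family: int | None = None,
) -> pd.DataFrame:
    """Group-vs-rest KS test for every (PANSS item, group) pair.

    Unassigned patients are excluded.  ``family`` defaults to the number
    of comparisons actually made (30 items x number of groups = 90 for
    three groups); corrected p = min(1, raw p x family); an item is
    flagged group-specific when the corrected p < alpha.
    """
    labels = pd.Series(np.asarray(labels), index=panss.index)
    keep = labels.isin(GROUP_LABELS)
    panss = panss.loc[keep]
    labels = labels.loc[keep]
    groups = [g for g in GROUP_LABELS if (labels == g).sum() >= 2]
    skipped = [g for g in GROUP_LABELS if g in labels.values and g not in groups]
    if skipped:
        logger.warning("groups skipped (fewer than 2 members): %s", skipped)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 members")
    if family is None:
        family = len(PANSS_ITEMS) * len(groups)
    rows = []
    for item in PANSS_ITEMS:
        for g in groups:
            in_g = panss.loc[labels == g, item].to_numpy()
            rest = panss.loc[labels != g, item].to_numpy()
            d, p = ks_two_sample(in_g, rest)
            p_adj = min(1.0, p * family)
            rows.append(
                {"item": item, "group": g, "D": d, "p_raw": p,
                 "p_bonferroni": p_adj, "flag": p_adj < alpha}
            )
    return pd.DataFrame(rows)


def _group_frame(cohort: Cohort, labels: pd.Series | np.ndarray) -> tuple[pd.DataFrame, pd.Series]:
    labels = pd.Series(np.asarray(labels), index=cohort.df.index)
    keep = labels.isin(GROUP_LABELS)
    return cohort.df.loc[keep], labels.loc[keep]


def compare_outcomes(cohort: Cohort, labels: pd.Series | np.ndarray, alpha: float = 0.05) -> dict:
    """Group comparisons of outcomes.

    Categorical outcomes (working, living independently, remission,
    diagnosis): chi-square test of independence on the group x category
    table, without continuity correction.  Continuous outcomes (GAF,
    SOFAS) and the five factor scores: one-way ANOVA across the groups
    plus pairwise Welch-free Student t-tests.  Effect sizes reported as
    per-group proportions / means with standard errors.
    """
    df, labels = _group_frame(cohort, labels)
    groups = [g for g in GROUP_LABELS if (labels == g).any()]
    report: dict = {"groups": groups, "alpha": alpha, "categorical": {}, "continuous": {}}

    for col in (*OUTCOME_BINARY, *OUTCOME_CATEGORICAL):
        if col not in df.columns or df[col].dropna().empty:
            logger.warning("outcome %s missing; skipped", col)
            continue
        sub = df[[col]].assign(group=labels).dropna(subset=[col])
        table = pd.crosstab(sub["group"], sub[col])
        if table.shape[1] < 2 or table.shape[0] < 2:
            continue
        chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        per_group = {}
        for g in groups:
            vals = sub.loc[sub["group"] == g, col]
            if col in OUTCOME_BINARY:
                per_group[g] = {"proportion": float(vals.mean()), "n": int(len(vals))}
            else:
                per_group[g] = {"counts": vals.value_counts().to_dict(), "n": int(len(vals))}
        report["categorical"][col] = {
            "chi2": float(chi2), "p": float(p), "dof": int(dof),
            "table": {str(k): v for k, v in table.to_dict(orient="index").items()},
            "per_group": per_group, "different": bool(p < alpha),
        }

    factors = wallwork_factors(df[list(PANSS_ITEMS)])
    continuous = {c: df[c] for c in OUTCOME_CONTINUOUS if c in df.columns}
    continuous.update({f: factors[f] for f in FACTOR_NAMES})
    for col, series in continuous.items():
        sub = pd.DataFrame({"y": series, "group": labels}).dropna()
        samples = [sub.loc[sub["group"] == g, "y"].to_numpy() for g in groups]
        if any(len(s) < 2 for s in samples):
            logger.warning("outcome %s has a group with < 2 observations; skipped", col)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, p_anova = stats.f_oneway(*samples)
        pairwise = {}
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                t, p = stats.ttest_ind(samples[i], samples[j])
                pairwise[f"{groups[i]}_vs_{groups[j]}"] = {"t": float(t), "p": float(p)}
        report["continuous"][col] = {
            "anova_F": float(f_stat), "anova_p": float(p_anova),
            "per_group": {
                g: {"mean": float(s.mean()), "se": float(s.std(ddof=1) / np.sqrt(len(s))), "n": int(len(s))}
                for g, s in zip(groups, samples)
            },
            "pairwise_t": pairwise, "different": bool(p_anova < alpha),
        }
    return report
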