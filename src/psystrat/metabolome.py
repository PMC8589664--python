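"""Per-group metabolite analysis.

Two complementary views of the metabolite panel:

* covariate-adjusted group contrasts — an OLS fit of each metabolite on
  group indicators plus age and sex, with pairwise group contrasts tested
  by t-tests on coefficient differences;
* per-group correlation networks — every unordered metabolite pair tested
  for a nonzero Pearson correlation within a group; pairs with raw
  p < alpha become network edges.  Edge p-values are deliberately NOT
  corrected for the number of pairs (the threshold is exploratory); an
  optional Benjamini-Hochberg flag is emitted alongside.

Edges are then classified by the exact set of groups in which they
appear ({A}, {B}, {C}, {A,B}, {A,C}, {B,C}, {A,B,C}), the group-overlap
view used to compare pathway-level regulation between groups.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .characterize import GROUP_LABELS
from .cohort import Cohort, sex_indicator

logger = logging.getLogger(__name__)

#: static pathway annotation for correlated pairs (biology lookup, not computed)
PATHWAY_ANNOTATION: dict[frozenset, str] = {
    frozenset(p): name
    for pairs, name in [
        (
            [("arginine", "ornithine"), ("arginine", "citrulline"), ("citrulline", "ornithine"),
             ("ornithine", "proline"), ("proline", "hydroxyproline")],
            "urea cycle / arginine, proline metabolism",
        ),
        ([("methionine", "sarcosine"), ("methionine", "cysteine"), ("cysteine", "taurine"),
          ("cysteine", "2-aminobutyrate"), ("GSH", "cysteine")], "methionine / transsulfuration"),
        ([("glutamate", "glutamine"), ("glutamate", "alanine"), ("glutamate", "aspartate"),
          ("glutamate", "proline")], "glutamate transamination"),
        ([("glycine", "serine"), ("serine", "threonine")], "glycine, serine metabolism"),
        ([("leucine", "isoleucine"), ("leucine", "valine"), ("isoleucine", "valine")],
         "branched-chain amino acids"),
        ([("phenylalanine", "tyrosine")], "phenylalanine / tyrosine"),
    ]
    for p in pairs
}


def pearson_with_p(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p-value from
    t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance sample")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def adjusted_group_contrast(
    panel: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    metabolite: str,
    age: pd.Series | np.ndarray | None = None,
    sex: pd.Series | np.ndarray | None = None,
) -> dict:
    """Pairwise group contrasts for one metabolite from an OLS model
    ``metabolite ~ group + age + sex`` (sex coded female = 1).

    Complete-case analysis; the number of dropped rows is logged and
    reported.  Raises on a singular design (e.g. a single-sex group
    perfectly collinear with its indicator).
    """
    labels = pd.Series(np.asarray(labels))
    y = panel[metabolite].to_numpy(dtype=float)
    groups = [g for g in GROUP_LABELS if (labels == g).any()]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    X_cols = {f"group_{g}": (labels == g).astype(float).to_numpy() for g in groups[1:]}
    if age is not None:
        X_cols["age"] = np.asarray(age, dtype=float)
    if sex is not None:
        sex = pd.Series(np.asarray(sex))
        X_cols["sex_female"] = (sex == "female").astype(float).to_numpy() if sex.dtype == object else np.asarray(sex, dtype=float)
    X = pd.DataFrame(X_cols)
    X.insert(0, "const", 1.0)
    mask = ~np.isnan(y) & labels.isin(groups).to_numpy() & ~X.isna().any(axis=1).to_numpy()
    dropped = int((~mask).sum())
    if dropped:
        logger.info("adjusted_group_contrast(%s): %d incomplete rows dropped", metabolite, dropped)
    for g in groups:
        if (labels[mask] == g).sum() < 3:
            raise ValueError(f"group {g} has < 3 complete cases for {metabolite}")
    Xm, ym = X[mask], y[mask]
    rank = np.linalg.matrix_rank(Xm.to_numpy())
    if rank < Xm.shape[1]:
        raise ValueError(f"singular design for {metabolite}: collinear columns in {list(Xm.columns)}")
    fit = sm.OLS(ym, Xm).fit()
    contrasts = {}
    for ga, gb in itertools.combinations(groups, 2):
        c = np.zeros(Xm.shape[1])
        cols = list(Xm.columns)
        if f"group_{ga}" in cols:
            c[cols.index(f"group_{ga}")] = 1.0
        if f"group_{gb}" in cols:
            c[cols.index(f"group_{gb}")] = -1.0
        tt = fit.t_test(c)
        contrasts[f"{ga}_vs_{gb}"] = {
            "estimate": float(np.atleast_1d(tt.effect)[0]),
            "se": float(np.atleast_1d(tt.sd).ravel()[0]),
            "t": float(np.atleast_1d(tt.tvalue).ravel()[0]),
            "p": float(np.atleast_1d(tt.pvalue).ravel()[0]),
        }
    adj_means = {}
    mean_age = float(Xm["age"].mean()) if "age" in Xm else None
    mean_sex = float(Xm["sex_female"].mean()) if "sex_female" in Xm else None
    for g in groups:
        row = dict.fromkeys(Xm.columns, 0.0)
        row["const"] = 1.0
        if f"group_{g}" in row:
            row[f"group_{g}"] = 1.0
        if mean_age is not None:
            row["age"] = mean_age
        if mean_sex is not None:
            row["sex_female"] = mean_sex
        adj_means[g] = float(np.dot(list(row.values()), fit.params))
    return {"metabolite": metabolite, "n_used": int(mask.sum()), "n_dropped": dropped,
            "adjusted_means": adj_means, "contrasts": contrasts,
            "params": dict(zip(Xm.columns, map(float, fit.params)))}


def correlation_network(
    panel: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    group: str,
    alpha: float = 0.05,
) -> dict:
    """Within-group Pearson correlation network over all metabolite pairs.

    Pairwise-complete observations per pair (n recorded per edge); edges
    kept at raw p < alpha.  Returns the edge list, the full r and p
    matrices, and Benjamini-Hochberg flags as an optional stricter view.
    """
    labels = pd.Series(np.asarray(labels))
    sub = panel.loc[(labels == group).to_numpy()]
    if len(sub) < 4:
        raise ValueError(f"group {group} has {len(sub)} patients with panel data; need >= 4")
    cols = list(panel.columns)
    m = len(cols)
    R = np.eye(m)
    P = np.zeros((m, m))
    edges = []
    for i, j in itertools.combinations(range(m), 2):
        x, y = sub[cols[i]].to_numpy(), sub[cols[j]].to_numpy()
        ok = ~(np.isnan(x) | np.isnan(y))
        try:
            r, p = pearson_with_p(x[ok], y[ok])
        except ValueError:
            r, p = np.nan, 1.0
        R[i, j] = R[j, i] = r
        P[i, j] = P[j, i] = p
        pair = tuple(sorted((cols[i], cols[j])))
        if p < alpha:
            edges.append({"pair": pair, "r": r, "p": p, "n": int(ok.sum())})
    pvals = [P[i, j] for i, j in itertools.combinations(range(m), 2)]
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    fdr_pairs = {
        tuple(sorted((cols[i], cols[j])))
        for (i, j), rej in zip(itertools.combinations(range(m), 2), reject) if rej
    }
    for e in edges:
        e["fdr_flag"] = e["pair"] in fdr_pairs
    return {
        "group": group, "alpha": alpha, "edges": edges,
        "r_matrix": pd.DataFrame(R, index=cols, columns=cols),
        "p_matrix": pd.DataFrame(P, index=cols, columns=cols),
        "n_patients": int(len(sub)),
    }


def classify_edges_by_group(networks: dict[str, dict]) -> pd.DataFrame:
    """Label every edge with the exact set of groups whose network
    contains it (the group-overlap color code of the pathway figure)."""
    membership: dict[tuple, set] = {}
    rs: dict[tuple, dict] = {}
    for g, net in networks.items():
        for e in net["edges"]:
            membership.setdefault(e["pair"], set()).add(g)
            rs.setdefault(e["pair"], {})[g] = e["r"]
    rows = []
    for pair in sorted(membership):
        groups = membership[pair]
        rows.append(
            {
                "metabolite_1": pair[0], "metabolite_2": pair[1],
                "groups": "".join(sorted(groups)),
                "pathway": PATHWAY_ANNOTATION.get(frozenset(pair), ""),
                **{f"r_{g}": rs[pair].get(g, np.nan) for g in sorted(networks)},
            }
        )
    return pd.DataFrame(rows)


def metabolome_report(cohort: Cohort, labels: pd.Series | np.ndarray, alpha: float = 0.05) -> dict:
    """Full panel analysis: adjusted contrasts for every metabolite plus
    per-group networks and the cross-group edge classification."""
    panel = cohort.metabolites()
    labels = pd.Series(np.asarray(labels), index=cohort.df.index)
    contrasts = {}
    for met in panel.columns:
        try:
            contrasts[met] = adjusted_group_contrast(
                panel, labels, met, age=cohort.df["age"], sex=cohort.df["sex"]
            )
        except ValueError as exc:
            logger.warning("contrast for %s skipped: %s", met, exc)
    networks = {}
    for g in GROUP_LABELS:
        try:
            networks[g] = correlation_network(panel, labels, g, alpha=alpha)
        except ValueError as exc:
            logger.warning("network for group %s skipped: %s", g, exc)
    edge_table = classify_edges_by_group(networks) if len(networks) >= 2 else pd.DataFrame()
    return {"contrasts": contrasts, "networks": networks, "edge_classification": edge_table}
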