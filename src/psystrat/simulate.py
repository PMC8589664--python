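"""Synthetic cohorts with planted three-group structure.

Real early-psychosis cohorts with item-level PANSS scores are not
publicly deposited, so all end-to-end exercises of the pipeline run on
synthetic cohorts that emulate the assumed statistical structure: three
latent patient groups with distinct symptom profiles at the Wallwork
factor level (A: overall mild symptoms; B: high positive, excited and
disorganized symptoms; C: high negative symptoms), group-linked
functional outcomes (good outcome most likely in A, least likely in B),
and group-linked metabolite shifts (GPx activity lowest in A and highest
in C; 2-aminobutyrate highest in A).

Item scores are generated as round-and-clamp of a Gaussian around the
group's factor-level mean — the simplest mechanism with a controllable
separation on an ordinal 1-7 scale.  Geometric point-cloud fixtures
(circle, blobs) for validating the Mapper construction live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .characterize import WALLWORK_FACTORS
from .cohort import PANSS_ITEMS, Cohort

GROUPS = ("A", "B", "C")

#: item -> Wallwork factor (items outside the five factors get the baseline mean)
ITEM_FACTOR: dict[str, str] = {
    item: factor for factor, items in WALLWORK_FACTORS.items() for item in items
}

#: metabolite panel: 4 redox markers + 28 amino acids and derivatives
REDOX_MARKERS = ("GPx", "GR", "Trx", "GSH")
AMINO_ACIDS = (
    "alanine", "arginine", "asparagine", "aspartate", "citrulline",
    "cysteine", "glutamate", "glutamine", "glycine", "histidine",
    "hydroxyproline", "isoleucine", "leucine", "lysine", "methionine",
    "ornithine", "phenylalanine", "proline", "sarcosine", "serine",
    "taurine", "threonine", "tryptophan", "tyrosine", "valine",
    "2-aminobutyrate", "beta-alanine", "alpha-aminoadipate",
)
METABOLITES = REDOX_MARKERS + AMINO_ACIDS


def _default_factor_means() -> dict[str, dict[str, float]]:
    # rows: group; columns: positive, negative, disorganized, excited, depressed
    return {
        "A": {"positive": 2.8, "negative": 1.8, "disorganized": 2.0, "excited": 2.2, "depressed": 2.0},
        "B": {"positive": 4.2, "negative": 3.5, "disorganized": 3.8, "excited": 3.8, "depressed": 3.0},
        "C": {"positive": 2.8, "negative": 4.0, "disorganized": 3.0, "excited": 2.4, "depressed": 3.2},
    }


def _default_metabolite_means() -> dict[str, dict[str, float]]:
    """Per-group metabolite means; flat across groups except the planted shifts."""
    baseline = {
        "GPx": 25.0, "GR": 7.5, "Trx": 30.0, "GSH": 950.0,
        "alanine": 350.0, "arginine": 80.0, "asparagine": 50.0, "aspartate": 20.0,
        "citrulline": 30.0, "cysteine": 220.0, "glutamate": 60.0, "glutamine": 550.0,
        "glycine": 230.0, "histidine": 80.0, "hydroxyproline": 12.0, "isoleucine": 60.0,
        "leucine": 120.0, "lysine": 180.0, "methionine": 25.0, "ornithine": 55.0,
        "phenylalanine": 55.0, "proline": 180.0, "sarcosine": 2.0, "serine": 110.0,
        "taurine": 60.0, "threonine": 130.0, "tryptophan": 55.0, "tyrosine": 60.0,
        "valine": 220.0, "2-aminobutyrate": 18.0, "beta-alanine": 5.0,
        "alpha-aminoadipate": 1.5,
    }
    means = {g: dict(baseline) for g in GROUPS}
    # planted group shifts: GPx lowest in A, highest in C; 2-aminobutyrate highest in A
    means["A"]["GPx"], means["B"]["GPx"], means["C"]["GPx"] = 23.3, 25.5, 28.1
    means["A"]["2-aminobutyrate"] = 21.4
    means["B"]["2-aminobutyrate"] = 17.9
    means["C"]["2-aminobutyrate"] = 16.8
    return means


def _default_metabolite_sds() -> dict[str, float]:
    sds = {m: 5.0 for m in METABOLITES}
    sds.update({"GPx": 8.0, "GR": 2.0, "Trx": 8.0, "GSH": 150.0,
                "glutamine": 80.0, "alanine": 60.0, "cysteine": 40.0,
                "valine": 40.0, "proline": 40.0, "glycine": 40.0,
                # low-concentration species: sd scaled to the mean so the
                # nonnegativity floor stays negligible
                "sarcosine": 0.6, "beta-alanine": 1.5,
                "alpha-aminoadipate": 0.45, "hydroxyproline": 3.0})
    return sds


#: planted within-group correlations (pairs absent here are independent):
#: an A-specific urea-cycle style edge, a C-specific glutamate hub edge,
#: and one edge shared by all three groups.
DEFAULT_PLANTED_CORR: dict[str, dict[tuple[str, str], float]] = {
    "A": {("arginine", "citrulline"): 0.7, ("glycine", "serine"): 0.7,
          ("citrulline", "ornithine"): 0.6, ("arginine", "ornithine"): 0.5},
    "B": {("glycine", "serine"): 0.7},
    "C": {("glycine", "serine"): 0.7, ("glutamate", "alanine"): 0.7,
          ("glutamate", "aspartate"): 0.6},
}


def _corr_matrix(planted: dict[tuple[str, str], float]) -> np.ndarray:
    m = len(METABOLITES)
    idx = {name: i for i, name in enumerate(METABOLITES)}
    corr = np.eye(m)
    for (a, b), rho in planted.items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    return corr


@dataclass
class GeneratorParams:
    """Knobs of the synthetic cohort generator.

    Defaults encode the published group structure: group proportions
    ~(21, 30, 43)/94, factor-level symptom profiles reproducing the
    reported orderings, GAF means giving good-outcome (GAF > 65)
    probabilities of roughly 0.75/0.20/0.35 for A/B/C, and the reported
    GPx / 2-aminobutyrate group means.
    """

    n_patients: int = 100
    group_probs: tuple[float, float, float] = (21 / 94, 30 / 94, 43 / 94)
    factor_means: dict[str, dict[str, float]] = field(default_factory=_default_factor_means)
    baseline_item_mean: float = 2.5  # items outside the five factors
    item_noise_sd: float = 0.8
    outcome_good_prob: dict[str, float] = field(
        default_factory=lambda: {"A": 0.75, "B": 0.20, "C": 0.35}
    )
    gaf_means: dict[str, float] = field(default_factory=lambda: {"A": 72.0, "B": 55.0, "C": 60.0})
    gaf_sd: float = 10.0
    metabolite_means: dict[str, dict[str, float]] = field(default_factory=_default_metabolite_means)
    metabolite_sds: dict[str, float] = field(default_factory=_default_metabolite_sds)
    planted_corr: dict[str, dict[tuple[str, str], float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_PLANTED_CORR.items()}
    )
    age_mean: float = 25.1
    age_sd: float = 4.0
    male_prob: float = 0.762
    missing_outcome_rate: float = 0.0
    with_metabolites: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 3:
            raise ValueError("n_patients must be >= 3")
        if abs(sum(self.group_probs) - 1.0) > 1e-12:
            raise ValueError("group_probs must sum to 1")
        if self.item_noise_sd < 0:
            raise ValueError("item_noise_sd must be >= 0")
        for g, planted in self.planted_corr.items():
            corr = _corr_matrix(planted)
            if not np.allclose(corr, corr.T):
                raise ValueError(f"correlation matrix for group {g} not symmetric")
            eig = np.linalg.eigvalsh(corr)
            if eig.min() < -1e-9:
                raise ValueError(f"correlation matrix for group {g} not positive semi-definite")


def default_params(**overrides) -> GeneratorParams:
    """Fully specified default generator parameters."""
    return GeneratorParams(**overrides)


def gaf_means_for_good_prob(probs: dict[str, float], sd: float, threshold: float = 65.0) -> dict[str, float]:
    """GAF group means such that P(Normal(mean, sd) > threshold) = prob."""
    return {g: float(threshold + sd * stats.norm.ppf(p)) for g, p in probs.items()}


def item_mean(group: str, item: str, params: GeneratorParams) -> float:
    factor = ITEM_FACTOR.get(item)
    if factor is None:
        return params.baseline_item_mean
    return params.factor_means[group][factor]


#: diagnosis mix per group: B dominated by schizophrenia, A by brief/
#: schizophreniform presentations, C intermediate.
DIAGNOSIS_PROBS = {
    "A": {"schizophrenia": 0.25, "schizophreniform": 0.35, "brief_psychotic_episode": 0.25, "other": 0.15},
    "B": {"schizophrenia": 0.75, "schizophreniform": 0.0, "brief_psychotic_episode": 0.0, "other": 0.25},
    "C": {"schizophrenia": 0.55, "schizophreniform": 0.15, "brief_psychotic_episode": 0.10, "other": 0.20},
}


def generate_cohort(params: GeneratorParams | None = None, seed: int | None = None) -> tuple[Cohort, pd.Series]:
    """Draw a cohort; returns ``(cohort, true_labels)``.

    True labels are returned separately and never written into the cohort
    table.  All draws flow from ``params.seed`` (or the ``seed`` override).
    """
    params = params or default_params()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_patients
    groups = rng.choice(len(GROUPS), size=n, p=list(params.group_probs))
    labels = pd.Series([GROUPS[g] for g in groups])

    means = np.array([[item_mean(g, item, params) for item in PANSS_ITEMS] for g in GROUPS])
    raw = means[groups] + rng.normal(0.0, params.item_noise_sd, size=(n, len(PANSS_ITEMS)))
    panss = np.clip(np.round(raw), 1, 7).astype(int)

    gaf = np.empty(n)
    sofas = np.empty(n)
    working = np.empty(n, dtype=object)
    living = np.empty(n, dtype=object)
    remission = np.empty(n, dtype=object)
    diagnosis = np.empty(n, dtype=object)
    for i, g_idx in enumerate(groups):
        g = GROUPS[g_idx]
        gaf[i] = np.clip(rng.normal(params.gaf_means[g], params.gaf_sd), 0.0, 100.0)
        sofas[i] = np.clip(gaf[i] + rng.normal(0.0, 5.0), 0.0, 100.0)
        p_good = params.outcome_good_prob[g]
        working[i] = bool(rng.random() < p_good)
        living[i] = bool(rng.random() < min(1.0, p_good + 0.15))
        remission[i] = bool(rng.random() < min(1.0, p_good + 0.10))
        dx = DIAGNOSIS_PROBS[g]
        diagnosis[i] = rng.choice(list(dx), p=list(dx.values()))

    age = np.maximum(rng.normal(params.age_mean, params.age_sd, size=n), 16.0)
    sex = np.where(rng.random(n) < params.male_prob, "male", "female")

    df = pd.DataFrame(panss, columns=list(PANSS_ITEMS))
    df.insert(0, "patient_id", [f"pt{i:04d}" for i in range(n)])
    df["age"] = np.round(age, 2)
    df["sex"] = sex
    df["gaf"] = np.round(gaf, 2)
    df["sofas"] = np.round(sofas, 2)
    df["working"] = working
    df["living_independently"] = living
    df["remission"] = remission
    df["diagnosis"] = diagnosis

    if params.with_metabolites:
        sds = np.array([params.metabolite_sds[m] for m in METABOLITES])
        panel = np.empty((n, len(METABOLITES)))
        for g_idx, g in enumerate(GROUPS):
            rows = np.flatnonzero(groups == g_idx)
            if rows.size == 0:
                continue
            mu = np.array([params.metabolite_means[g][m] for m in METABOLITES])
            cov = _corr_matrix(params.planted_corr.get(g, {})) * np.outer(sds, sds)
            draw = rng.multivariate_normal(mu, cov, size=rows.size, method="eigh")
            panel[rows] = draw
        panel = np.maximum(panel, 0.0)  # concentrations/activities are nonnegative
        for j, m in enumerate(METABOLITES):
            df[m] = np.round(panel[:, j], 4)

    if params.missing_outcome_rate > 0:
        for col in ("gaf", "sofas", "working", "living_independently", "remission", "diagnosis"):
            mask = rng.random(n) < params.missing_outcome_rate
            df.loc[mask, col] = np.nan

    return Cohort(df, metabolite_columns=METABOLITES if params.with_metabolites else ()), labels


def generate_circle(n: int, noise_sd: float = 0.05, seed: int = 0) -> np.ndarray:
    """Points uniform on the unit circle plus isotropic Gaussian noise."""
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    pts = np.column_stack([np.cos(theta), np.sin(theta)])
    return pts + rng.normal(0.0, noise_sd, size=pts.shape)


def generate_blobs(n_per_blob: int, centers, sd: float = 1.0, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian blobs around the given centers; returns (points, labels)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] < 2:
        raise ValueError("need at least 2 centers")
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for i, c in enumerate(centers):
        pts.append(c + rng.normal(0.0, sd, size=(n_per_blob, centers.shape[1])))
        labels.append(np.full(n_per_blob, i))
    return np.vstack(pts), np.concatenate(labels)
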