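"""End-to-end orchestration: cohorts in, graphs / groups / reports out.

The pipeline runs the full analysis sequence — Mapper graph on cohort 1,
stratification into groups A/B/C, group characterization, nearest-centroid
replication in cohort 2, outcome prediction (items vs groups, plus k-means
comparators), and the metabolite analysis — writing every stage's output
to disk.  All randomness derives from one top-level seed via per-stage
spawned seeds, so two runs with the same configuration are identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .characterize import compare_outcomes, group_specific_items, wallwork_factors
from .cohort import Cohort
from .mapper import MapperConfig, build_mapper_graph
from .metabolome import metabolome_report
from .predict import (
    PredictConfig,
    assign_by_centroid,
    compare_partitions,
    group_centroids,
    kmeans_partition,
    run_prediction_experiment,
)
from .simulate import GeneratorParams, default_params, generate_cohort
from .stratify import StratifyConfig, boundary_sensitivity, stratify

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    mapper: MapperConfig = field(default_factory=MapperConfig)
    stratify: StratifyConfig = field(default_factory=StratifyConfig)
    predict: PredictConfig = field(default_factory=PredictConfig)
    simulate: GeneratorParams | None = None
    seed: int = 0
    cohort1_path: str | None = None
    cohort2_path: str | None = None
    out_dir: str = "psystrat_out"


def load_config(path: str | Path) -> PipelineConfig:
    """Build a validated PipelineConfig from a YAML file with sections
    [mapper], [stratify], [predict], [simulate] and top-level keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(
        mapper=MapperConfig(**raw.get("mapper", {})),
        stratify=StratifyConfig(**raw.get("stratify", {})),
        predict=PredictConfig(**raw.get("predict", {})),
        simulate=GeneratorParams(**raw["simulate"]) if "simulate" in raw else None,
        seed=int(raw.get("seed", 0)),
        cohort1_path=raw.get("cohort1_path"),
        cohort2_path=raw.get("cohort2_path"),
        out_dir=raw.get("out_dir", "psystrat_out"),
    )
    return cfg


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Derive independent per-stage seeds (< 2**31) from the top seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and serialize the results under ``config.out_dir``.

    Returns the in-memory result bundle (graph, assignments, reports).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    results: dict = {"config": config, "seeds": seeds}
    logger.info("pipeline start; seed=%d, effective stage seeds=%s", config.seed, seeds)
    for name, cfg in (("mapper", config.mapper), ("stratify", config.stratify), ("predict", config.predict)):
        logger.info("effective %s parameters: %s", name, dataclasses.asdict(cfg))

    # -- stage: cohorts -------------------------------------------------
    try:
        if config.cohort1_path:
            cohort1 = io.read_cohort(config.cohort1_path)
            labels1_true = None
        elif config.simulate is not None or config.cohort1_path is None:
            params = config.simulate or default_params()
            cohort1, labels1_true = generate_cohort(params, seed=seeds[0])
            io.write_cohort(cohort1, out / "cohort1.csv")
            labels1_true.rename("group").rename_axis("row").to_csv(out / "cohort1_true_labels.csv")
        if config.cohort2_path:
            cohort2 = io.read_cohort(config.cohort2_path)
            labels2_true = None
        else:
            params = config.simulate or default_params()
            cohort2, labels2_true = generate_cohort(params, seed=seeds[1])
            io.write_cohort(cohort2, out / "cohort2.csv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("cohorts", exc) from exc
    results.update(cohort1=cohort1, cohort2=cohort2)

    # -- stage: mapper --------------------------------------------------
    try:
        graph = build_mapper_graph(cohort1.panss, config.mapper, patient_ids=cohort1.patient_ids)
        io.write_graph(graph, out / "mapper_graph.json", out / "mapper_graph.graphml")
    except Exception as exc:
        raise PipelineError("mapper", exc) from exc
    results["graph"] = graph

    # -- stage: stratify ------------------------------------------------
    try:
        assignment = stratify(graph, cohort1.panss, config.stratify)
        labels1 = assignment.labels
        labels1.index = cohort1.df.index
        io.write_assignment(
            labels1.set_axis(cohort1.patient_ids), out / "cohort1_groups.csv"
        )
        sensitivity = boundary_sensitivity(graph, cohort1.panss, assignment.node_groups, shift=3)
        io.write_json(
            [{k: v for k, v in row.items() if k != "labels"} for row in sensitivity],
            out / "boundary_sensitivity.json",
        )
    except Exception as exc:
        raise PipelineError("stratify", exc) from exc
    results.update(assignment=assignment, sensitivity=sensitivity)

    # -- stage: characterize --------------------------------------------
    try:
        factors = wallwork_factors(cohort1.panss_df)
        factors.to_csv(out / "cohort1_factors.csv", index=False)
        flags = group_specific_items(cohort1.panss_df, labels1)
        flags.to_csv(out / "item_flags.csv", index=False)
        outcomes = compare_outcomes(cohort1, labels1)
        io.write_json(outcomes, out / "cohort1_outcomes.json")
    except Exception as exc:
        raise PipelineError("characterize", exc) from exc
    results.update(factors=factors, item_flags=flags, outcome_report=outcomes)

    # -- stage: replicate -----------------------------------------------
    try:
        centroids = group_centroids(cohort1.panss, labels1, source="cohort1")
        labels2 = assign_by_centroid(cohort2.panss, centroids)
        labels2.index = cohort2.df.index
        io.write_assignment(labels2.set_axis(cohort2.patient_ids), out / "cohort2_groups.csv")
        centroids.means.to_csv(out / "centroids.csv")
        outcomes2 = compare_outcomes(cohort2, labels2)
        io.write_json(outcomes2, out / "cohort2_outcomes.json")
    except Exception as exc:
        raise PipelineError("replicate", exc) from exc
    results.update(centroids=centroids, labels2=labels2, outcome_report2=outcomes2)

    # -- stage: predict -------------------------------------------------
    try:
        pred_cfg = dataclasses.replace(config.predict, seed=seeds[2])
        reports = run_prediction_experiment(
            cohort1.panss, cohort1.df["gaf"].to_numpy(float),
            cohort2.panss, cohort2.df["gaf"].to_numpy(float),
            labels1, labels2, pred_cfg,
            feature_sets=("panss_items", "group_onehot", "kmeans_onehot", "kmeans_pca_onehot"),
        )
        serializable = {
            fs: {
                scheme: {k: (v.to_dict(orient="records") if hasattr(v, "to_dict") else v)
                         for k, v in rep.items()}
                if isinstance(rep, dict) else rep
                for scheme, rep in by_scheme.items()
            }
            for fs, by_scheme in reports.items()
        }
        io.write_json(serializable, out / "prediction_reports.json")
        km = kmeans_partition(cohort1.panss, 3, on_pca=False, seed=seeds[3])
        comparison = compare_partitions(labels1, km)
        io.write_json(
            {"ari": comparison["ari"], "matching": comparison["matching"],
             "table": comparison["table"].to_dict()},
            out / "kmeans_comparison.json",
        )
    except Exception as exc:
        raise PipelineError("predict", exc) from exc
    results.update(prediction=reports, kmeans_comparison=comparison)

    # -- stage: metabolome ----------------------------------------------
    if cohort1.metabolite_columns:
        try:
            metab = metabolome_report(cohort1, labels1)
            metab["edge_classification"].to_csv(out / "metabolite_edges.csv", index=False)
            for g, net in metab["networks"].items():
                net["r_matrix"].to_csv(out / f"correlation_matrix_{g}.csv")
            io.write_json(
                {m: {k: v for k, v in rep.items() if k != "params"}
                 for m, rep in metab["contrasts"].items()},
                out / "metabolite_contrasts.json",
            )
        except Exception as exc:
            raise PipelineError("metabolome", exc) from exc
        results["metabolome"] = metab

    logger.info("pipeline finished; outputs in %s", out)
    return results
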