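"""End-to-end pipeline: ingest -> trajectories -> distance -> subgroups ->
trends -> early identification, with a reproducible configuration echoed into
every output bundle.

Outputs written by :func:`run_pipeline` into the output directory:

* ``config_echo.json`` — the exact configuration used;
* ``distance_matrix.csv`` — square labeled distance matrix;
* ``dendrogram.nwk`` — Newick merge tree;
* ``subgroups.json`` — candidate screening report and final subgroups;
* ``trends.csv`` — overall and per-subgroup monthly frequencies with CIs;
* ``classifier_report.json`` — early-identification accuracies/importances;
* ``run.log`` — stage log.

All JSON is written with sorted keys and no timestamps, so a rerun with the
same configuration and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import early_id, ingest, simulate, subgroups, trajectories, trends
from .distance import pairwise_distance

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "run_simulate"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    # variable-selection thresholds (scaled to cohort size via the CLI/config)
    min_span_years: float = 1.0
    min_peak_freq: float = 0.20
    min_valid: int = 500
    min_visits: int = 2
    # clustering
    linkage: str = "average"
    dense_mode: str = "carried"
    criteria: subgroups.SubgroupCriteria = field(
        default_factory=subgroups.SubgroupCriteria
    )
    # trends
    ci_method: str = "wald"
    # early identification
    min_valid_first_visit: int = 100
    classifier: early_id.ClassifierConfig = field(
        default_factory=early_id.ClassifierConfig
    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "criteria" in d and isinstance(d["criteria"], dict):
            d["criteria"] = subgroups.SubgroupCriteria(**d["criteria"])
        if "classifier" in d and isinstance(d["classifier"], dict):
            d["classifier"] = early_id.ClassifierConfig(**d["classifier"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data or {})


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_simulate(spec: simulate.CohortSpec, outdir) -> dict[str, Path]:
    """Generate a synthetic cohort and write visits, first-visit features and
    truth labels as comma-separated text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    visits, truth = simulate.generate_cohort(spec)
    first = simulate.generate_first_visit_features(spec, truth, visits)
    paths = {
        "visits": outdir / "visits.csv",
        "first_visits": outdir / "first_visits.csv",
        "truth": outdir / "truth.csv",
    }
    ingest.write_visits(visits, paths["visits"])
    first.to_csv(paths["first_visits"], index=False)
    truth.to_frame().to_csv(paths["truth"])
    return paths


def run_pipeline(
    config: PipelineConfig,
    visits: pd.DataFrame,
    first_visits: pd.DataFrame | None = None,
    outdir=None,
) -> dict:
    """Run every stage on an in-memory visit table; optionally write the
    output bundle. Returns the in-memory results keyed by stage."""
    out: dict = {"config": config.to_dict()}
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logging.getLogger("behavclust").addHandler(handler)
    try:
        _run_stages(config, visits, first_visits, out)
    except PipelineError:
        raise
    finally:
        if outdir is not None:
            logging.getLogger("behavclust").removeHandler(handler)
            handler.close()
    if outdir is not None:
        _write_bundle(out, outdir)
    return out


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate with stage
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


@_stage("ingest")
def _ingest(config: PipelineConfig, visits: pd.DataFrame):
    v = ingest.add_derived_items(visits)
    specs = ingest.default_indicator_specs()
    specs = [s for s in specs if s.source_item in v.columns]
    b = ingest.binarize(v, specs)
    b = ingest.censor_post_hiv(b)
    b = ingest.filter_min_visits(b, config.min_visits)
    selected = ingest.select_longitudinal_variables(
        b, specs, config.min_span_years, config.min_peak_freq, config.min_valid
    )
    return b, selected


@_stage("trajectories")
def _trajectories(config: PipelineConfig, b: pd.DataFrame, selected):
    dates = pd.to_datetime(b["visit_date"]).dt.to_period("M")
    start, end = dates.min(), dates.max() + 1
    names = [s.name for s in selected]
    matrix = trajectories.build_status_matrix(b, names, start, end)
    counts = trajectories.monthly_valid_counts(matrix, config.dense_mode, b)
    period = trajectories.find_dense_period(counts)
    clustering = matrix.restrict(period)
    retained, coverage = trajectories.coverage_filter(clustering)
    clustering = clustering.subset_men(retained)
    return matrix, period, clustering, coverage


def _run_stages(config, visits, first_visits, out):
    b, selected = _ingest(config, visits)
    directions = {s.name: s.exposure_direction for s in selected}
    out["indicators"] = [dataclasses.asdict(s) for s in selected]

    matrix, period, clustering, coverage = _trajectories(config, b, selected)
    out["dense_period"] = {
        "start": str(clustering.start),
        "months": [int(period[0]), int(period[1])],
        "n_men_retained": len(clustering.men),
    }
    out["clustering_matrix"] = clustering

    try:
        dist = pairwise_distance(clustering)
        tree = subgroups.cluster_hierarchical(dist, config.linkage)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("distance/cluster", exc) from exc
    out["distance"] = dist
    out["tree"] = tree

    try:
        report = subgroups.screen_subgroups(tree, clustering, directions, config.criteria)
    except Exception as exc:
        raise PipelineError("subgroups", exc) from exc
    out["subgroups"] = report

    try:
        members = {k: v["members"] for k, v in report["subgroups"].items()}
        overall = trends.overall_trends(clustering, method=config.ci_method)
        per_sub = (
            trends.subgroup_trends(clustering, members, method=config.ci_method)
            if members else pd.DataFrame()
        )
    except Exception as exc:
        raise PipelineError("trends", exc) from exc
    overall.insert(0, "subgroup", "overall")
    out["trends"] = pd.concat([overall, per_sub], ignore_index=True)

    if first_visits is not None and members:
        try:
            feats = early_id.prepare_first_visit_table(
                first_visits, config.min_valid_first_visit
            )
            feats = feats.loc[feats.index.intersection(clustering.men)]
            out["classifier"] = early_id.train_subgroup_classifiers(
                feats, members, config.classifier
            )
        except Exception as exc:
            raise PipelineError("early_id", exc) from exc


def _write_bundle(out: dict, outdir: Path) -> None:
    _dump_json(out["config"], outdir / "config_echo.json")
    out["distance"].to_frame().to_csv(outdir / "distance_matrix.csv")
    (outdir / "dendrogram.nwk").write_text(subgroups.to_newick(out["tree"]) + "\n")
    _dump_json(
        {"dense_period": out["dense_period"], **out["subgroups"]},
        outdir / "subgroups.json",
    )
    out["trends"].to_csv(outdir / "trends.csv", index=False)
    if "classifier" in out:
        _dump_json(out["classifier"], outdir / "classifier_report.json")
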