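"""End-to-end orchestration: simulate -> construct -> metrics -> stats.

A single :class:`RunConfig` (round-trippable through YAML, unknown keys
rejected) drives the four stages with deterministic seeding; every stage
writes delimited-text outputs that the next stage (or a manual re-run)
reads back, and the run ends with a machine-readable JSON manifest
recording the config hash, seed, library versions, per-stage row counts,
dropped sites and any mixed-model fallbacks used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import ConnectivityMatrix, correlation_matrix, fisher_z, \
    overall_fc_strength, scrub_timepoints
from .inference import ModelSpec, contrast_all_outcomes, filter_sites, \
    map_significant_nodes, subgroup_contrast, symptom_association
from .metrics import DensityGrid, GLOBAL_METRICS, NODAL_METRICS, metric_curves
from .simulate import Cohort, SyntheticSpec, synthesize_cohort

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("fctopo")

CONTRAST_NAMES = ("mdd-vs-nc", "fedn-vs-nc", "rec-vs-nc", "rec-vs-fedn", "hamd")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    grid: DensityGrid = field(default_factory=DensityGrid)
    stages: tuple[str, ...] = ("simulate", "construct", "metrics", "stats")
    global_metrics: tuple[str, ...] = GLOBAL_METRICS
    nodal_metrics: tuple[str, ...] = NODAL_METRICS
    scrub: bool = False
    fd_threshold_mm: float = 0.2
    edge_sign: str = "positive"
    normalize_weights: bool = False
    random_structure: str = "slope"
    contrasts: tuple[str, ...] = ("mdd-vs-nc",)
    min_per_group: int = 10
    fdr_level: float = 0.05
    write_curves: bool = False
    out_dir: str = "fctopo_run"
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.stages) - {"simulate", "construct", "metrics", "stats"}
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        bad = set(self.contrasts) - set(CONTRAST_NAMES)
        if bad:
            raise ValueError(f"unknown contrasts: {sorted(bad)}")
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must lie in (0, 1)")

    # -- YAML round trip ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = dataclasses.asdict(self.synthetic)
        d["grid"] = dataclasses.asdict(self.grid)
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "synthetic" in d:
            syn = dict(d["synthetic"])
            syn_known = {f.name for f in dataclasses.fields(SyntheticSpec)}
            bad = set(syn) - syn_known
            if bad:
                raise ValueError(f"unknown synthetic keys: {sorted(bad)}")
            d["synthetic"] = SyntheticSpec(**syn)
        if "grid" in d:
            d["grid"] = DensityGrid(**d["grid"])
        for k in ("stages", "global_metrics", "nodal_metrics", "contrasts"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir")
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _construct_fc(cohort: Cohort, config: RunConfig, fc_dir: Path) -> pd.DataFrame:
    """Per-subject correlation -> Fisher z; returns overall-FC summary table."""
    rows = []
    node_ids = cohort.node_set.node_ids
    n_scrubbed_total = 0
    for s in cohort.subjects:
        ts = s.timeseries
        if ts is None:
            raise ValueError(f"subject {s.subject_id} has no time series")
        if config.scrub and s.fd_series is not None:
            ts, n_rm = scrub_timepoints(ts, s.fd_series, config.fd_threshold_mm)
            n_scrubbed_total += n_rm
        fc = fisher_z(correlation_matrix(ts), node_ids=node_ids)
        fc.to_csv(fc_dir / f"{s.subject_id}.csv")
        rows.append({"subject_id": s.subject_id,
                     "overall_fc": overall_fc_strength(fc)})
    logger.info("construct: %d matrices, %d timepoints scrubbed",
                len(rows), n_scrubbed_total)
    return pd.DataFrame(rows)


def _metric_stage(cohort: Cohort, config: RunConfig, fc_dir: Path,
                  met_dir: Path) -> pd.DataFrame:
    frames = []
    curve_frames = []
    for s in cohort.subjects:
        fc = ConnectivityMatrix.from_csv(fc_dir / f"{s.subject_id}.csv")
        mc = metric_curves(
            fc, config.grid, global_metrics=config.global_metrics,
            nodal_metrics=config.nodal_metrics, edge_sign=config.edge_sign,
            normalize=config.normalize_weights,
        )
        frames.append(mc.auc_frame(s.subject_id))
        if config.write_curves:
            curve_frames.append(mc.curve_frame(s.subject_id))
    auc_table = pd.concat(frames, ignore_index=True)
    auc_table.to_csv(met_dir / "auc.csv", index=False)
    if curve_frames:
        pd.concat(curve_frames, ignore_index=True).to_csv(
            met_dir / "curves.csv", index=False)
    return auc_table


def _stats_stage(auc_table, covariates, node_set, config: RunConfig,
                 stats_dir: Path) -> dict:
    spec = ModelSpec(random_structure=config.random_structure)
    filtered, dropped = filter_sites(covariates, config.min_per_group)
    info: dict = {"sites_dropped": dropped,
                  "n_subjects_after_filter": int(len(filtered))}
    table = auc_table[auc_table["subject_id"].isin(filtered["subject_id"])]
    fallbacks: dict[str, int] = {}
    for name in config.contrasts:
        if name == "mdd-vs-nc":
            res = contrast_all_outcomes(table, filtered, spec, config.fdr_level)
        elif name == "fedn-vs-nc":
            res = subgroup_contrast(table, filtered, "FEDN", "NC", spec,
                                    config.fdr_level, config.min_per_group)
        elif name == "rec-vs-nc":
            res = subgroup_contrast(table, filtered, "recurrent", "NC", spec,
                                    config.fdr_level, config.min_per_group)
        elif name == "rec-vs-fedn":
            res = subgroup_contrast(table, filtered, "recurrent", "FEDN", spec,
                                    config.fdr_level, config.min_per_group)
        else:  # hamd
            res = symptom_association(table, filtered, spec, config.fdr_level)
        res.to_csv(stats_dir / f"contrasts_{name}.csv", index=False)
        summary = map_significant_nodes(res, node_set)
        summary.to_csv(stats_dir / f"network_summary_{name}.csv", index=False)
        for used, cnt in res["random_structure_used"].value_counts().items():
            fallbacks[f"{name}:{used}"] = int(cnt)
        info[f"n_outcomes_{name}"] = int(len(res))
    info["random_structures_used"] = fallbacks
    return info


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write the run manifest.

    Returns the manifest dict. Any stage failure raises, naming the
    stage; partial outputs of completed stages remain on disk and are
    individually re-runnable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(
        logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "fctopo": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    cohort = None
    auc_table = None
    try:
        logger.info("run start: seed=%d hash=%s stages=%s", config.seed,
                    manifest["config_hash"][:12], ",".join(config.stages))
        if "simulate" in config.stages:
            syn = dataclasses.replace(config.synthetic, seed=config.seed)
            cohort = synthesize_cohort(syn)
            cohort.write(out / "cohort")
            manifest["stages"]["simulate"] = {"n_subjects": len(cohort)}
        else:
            cohort = Cohort.read(out / "cohort")
        if "construct" in config.stages:
            fc_dir = out / "fc"
            fc_dir.mkdir(exist_ok=True)
            overall = _construct_fc(cohort, config, fc_dir)
            overall.to_csv(out / "fc" / "overall_fc.csv", index=False)
            manifest["stages"]["construct"] = {"n_matrices": int(len(overall))}
        if "metrics" in config.stages:
            met_dir = out / "metrics"
            met_dir.mkdir(exist_ok=True)
            auc_table = _metric_stage(cohort, config, out / "fc", met_dir)
            manifest["stages"]["metrics"] = {"n_auc_rows": int(len(auc_table))}
        if "stats" in config.stages:
            if auc_table is None:
                auc_table = pd.read_csv(out / "metrics" / "auc.csv")
            stats_dir = out / "stats"
            stats_dir.mkdir(exist_ok=True)
            info = _stats_stage(auc_table, cohort.covariates_frame(),
                                cohort.node_set, config, stats_dir)
            manifest["stages"]["stats"] = info
    except Exception as exc:
        stage = next(
            (s for s in config.stages if s not in manifest["stages"]), "unknown"
        )
        logger.error("stage '%s' failed: %s", stage, exc)
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
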