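"""End-to-end orchestration: integrate -> train -> predict-st -> attribute -> stats.

A :class:`RunConfig` carries every path and threshold; stage outputs are
cached under the output directory keyed by a hash of the config fields the
stage (and its upstream stages) depends on, so rerunning with an unchanged
config skips completed stages and changing one threshold invalidates only
the stages downstream of it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, attribution, datafusion, diffstats, io, regression, spatial

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs, outputs and thresholds of a full pipeline run."""

    # inputs
    cohort_a_mrna: str = ""
    cohort_a_mirna: str = ""
    cohort_b_mrna: str = ""
    cohort_b_mirna: str = ""
    cohort_a_label: str = "cohortA"
    cohort_b_label: str = "cohortB"
    visium_dir: str = ""
    positions: Optional[str] = None
    abundance: str = ""
    pairs: Optional[str] = None
    genesets: Optional[str] = None
    out_dir: str = "stmir_out"
    # thresholds (defaults as stated wherever a stated default exists)
    max_zero_frac: float = 0.9
    max_total_counts: float = 38000.0
    min_cells_per_gene: int = 10
    hvg_n: int = 2000
    min_purity: float = 0.0
    min_spots: int = 10
    r_min: float = 0.3
    alpha: float = 0.05
    fdr: float = 0.1
    top_k: int = 40
    st_encoding: str = "rank-int"
    diff_group_type: str = ""  # dominant type forming group A of the diff test
    # model
    seed: int = 7
    learning_rate: float = 0.1
    max_depth: int = 5
    n_estimators: int = 300
    run_grid_search: bool = False
    cv_folds: int = 5

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        flat = {}
        for key, value in data.items():
            if isinstance(value, dict):  # sections are flattened
                flat.update(value)
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


# config fields each stage depends on (cumulative with upstream stages)
_STAGE_FIELDS = {
    "integrate": [
        "cohort_a_mrna", "cohort_a_mirna", "cohort_b_mrna", "cohort_b_mirna",
        "cohort_a_label", "cohort_b_label", "max_zero_frac",
    ],
    "train": ["seed", "learning_rate", "max_depth", "n_estimators", "run_grid_search", "cv_folds"],
    "predict_st": [
        "visium_dir", "positions", "max_total_counts", "min_cells_per_gene",
        "hvg_n", "st_encoding",
    ],
    "attribute": ["abundance", "min_purity", "min_spots"],
    "stats": ["pairs", "genesets", "r_min", "alpha", "fdr", "diff_group_type", "top_k"],
}
_STAGE_ORDER = ["integrate", "train", "predict_st", "attribute", "stats"]


def _stage_hash(cfg: RunConfig, stage: str) -> str:
    upto = _STAGE_ORDER[: _STAGE_ORDER.index(stage) + 1]
    relevant = {}
    for s in upto:
        for name in _STAGE_FIELDS[s]:
            relevant[name] = getattr(cfg, name)
    blob = json.dumps(relevant, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full chain with per-stage caching; returns a run report."""
    out = Path(cfg.out_dir)
    cache = out / "cache"
    cache.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software_version": __version__,
        "config": cfg.as_dict(),
        "stages": {},
    }

    def _stage(name, compute, artifact_suffix):
        t0 = time.time()
        key = _stage_hash(cfg, name)
        artifact = cache / f"{name}-{key}{artifact_suffix}"
        if artifact.exists():
            logger.info("stage %s: cache hit (%s)", name, artifact.name)
            report["stages"][name] = {
                "status": "cached", "artifact": str(artifact), "seconds": 0.0,
            }
            return artifact
        try:
            compute(artifact)
        except Exception as exc:
            report["stages"][name] = {"status": "error", "error": str(exc)}
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        report["stages"][name] = {
            "status": "computed",
            "artifact": str(artifact),
            "seconds": round(time.time() - t0, 3),
        }
        return artifact

    # -- integrate ----------------------------------------------------------
    def _integrate(artifact):
        mrna_a = io.read_expr_table(cfg.cohort_a_mrna, "mRNA", cfg.cohort_a_label)
        mirna_a = io.read_expr_table(cfg.cohort_a_mirna, "miRNA", cfg.cohort_a_label)
        mrna_b = io.read_expr_table(cfg.cohort_b_mrna, "mRNA", cfg.cohort_b_label)
        mirna_b = io.read_expr_table(cfg.cohort_b_mirna, "miRNA", cfg.cohort_b_label)
        ts = datafusion.integrate_pair(
            mrna_a, mirna_a, mrna_b, mirna_b, max_zero_frac=cfg.max_zero_frac
        )
        io.write_training_set(ts, artifact)

    ts_path = _stage("integrate", _integrate, ".h5")

    # -- train --------------------------------------------------------------
    def _train(artifact):
        ts = io.read_training_set(ts_path)
        if cfg.run_grid_search:
            hp, _, _ = regression.grid_search(
                ts, regression.DEFAULT_GRID, k=cfg.cv_folds, seed=cfg.seed
            )
        else:
            hp = regression.Hyperparams(
                cfg.learning_rate, cfg.max_depth, cfg.n_estimators
            )
        bundle = regression.train(ts, hp, seed=cfg.seed)
        regression.save_model(bundle, artifact)

    model_path = _stage("train", _train, ".stmir")

    # -- predict on spatial data -------------------------------------------
    def _predict_st(artifact):
        model = regression.load_model(model_path)
        sd = spatial.load_visium(cfg.visium_dir, positions=cfg.positions)
        sd, qc = spatial.qc_filter(
            sd,
            max_total_counts=cfg.max_total_counts,
            min_cells_per_gene=cfg.min_cells_per_gene,
        )
        (out / "qc_report.json").write_text(json.dumps(qc.as_dict(), indent=2))
        norm = spatial.normalize_st(sd)
        missing = pd.Index(model.feature_genes).difference(norm.feature_ids)
        if len(missing):
            raise ValueError(
                f"model feature genes missing from ST data: {list(missing[:5])}"
            )
        act = spatial.predict_spot_activity(model, norm, encoding=cfg.st_encoding)
        io.write_activity(act, artifact)
        norm.values.T.to_csv(cache / f"stexpr-{_stage_hash(cfg, 'predict_st')}.tsv", sep="\t")

    act_path = _stage("predict_st", _predict_st, ".h5")

    # -- attribute ----------------------------------------------------------
    def _attribute(artifact):
        act = io.read_activity(act_path)
        ab = io.read_abundance(cfg.abundance)
        da = attribution.assign_dominant(ab, min_purity=cfg.min_purity)
        da.to_csv(out / "dominant_assignment.tsv", sep="\t")
        profile, excluded = attribution.celltype_mirna_profile(
            act, da, min_spots=cfg.min_spots
        )
        if excluded:
            logger.info("cell types under min_spots: %s", excluded)
        profile.to_csv(artifact, sep="\t", index=False)

    profile_path = _stage("attribute", _attribute, ".tsv")

    # -- stats --------------------------------------------------------------
    def _stats(artifact):
        act = io.read_activity(act_path)
        da = pd.read_csv(out / "dominant_assignment.tsv", sep="\t", index_col=0)
        outputs = {}
        group_type = cfg.diff_group_type
        assigned = da[da["dominant_type"] != attribution.UNASSIGNED]
        if not group_type:
            group_type = assigned["dominant_type"].value_counts().idxmax()
        labels = pd.Series(
            ["A" if t == group_type else "B" for t in assigned["dominant_type"]],
            index=assigned.index,
        )
        diff = diffstats.differential_activity(act, labels, fdr=cfg.fdr)
        diff.to_csv(out / "differential_activity.tsv", sep="\t", index=False)
        outputs["differential_activity"] = str(out / "differential_activity.tsv")
        if cfg.pairs:
            pairs = io.read_pairs(cfg.pairs)
            st_expr = pd.read_csv(
                cache / f"stexpr-{_stage_hash(cfg, 'predict_st')}.tsv",
                sep="\t", index_col=0,
            )
            usable = [
                (m, g) for m, g in pairs
                if m in act.mirna_ids and g in st_expr.columns
            ]
            corr = diffstats.mirna_target_correlation(
                act, st_expr, usable, r_min=cfg.r_min, alpha=cfg.alpha
            )
            corr.to_csv(out / "target_correlation.tsv", sep="\t", index=False)
            outputs["target_correlation"] = str(out / "target_correlation.tsv")
            if cfg.genesets:
                sets = io.read_gmt(cfg.genesets)
                universe = list(st_expr.columns)
                sig = corr[corr["classification"] != diffstats.NOT_SIGNIFICANT]
                query = sorted(set(sig["gene"]) & set(universe))
                if query:
                    enr = diffstats.enrich(query, sets, universe, alpha=cfg.alpha)
                    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                    outputs["enrichment"] = str(out / "enrichment.tsv")
        artifact.write_text(json.dumps(outputs, indent=2))

    _stage("stats", _stats, ".json")

    report_path = out / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, default=str))
    logger.info("run report written to %s", report_path)
    return report
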