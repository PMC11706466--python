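"""End-to-end pipeline driver: validate -> features -> SPIs -> classify ->
null -> select, with every numeric output carrying the resolved
configuration and seeds needed to regenerate it exactly."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .cohort import CohortDataset, load_cohort, qc_filter
from .cv import make_fold_plan, run_repeated_cv
from .representations import build_representation
from .selection import pca_screen_spi_selection, per_fold_best_selection
from .spis import SPI_NAMES, compute_coupling_tensor
from .stats import bh_adjust, gaussian_tail_p, permutation_null
from .univariate import compute_feature_tensor

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    series_dir: str | None = None
    participants_path: str | None = None
    synthetic_spec: dict | None = None
    tr_seconds: float = 2.0
    fd_threshold_mm: float = 0.55
    drop_constant_regions: bool = False
    spi_names: list[str] = field(default_factory=lambda: ["Pearson"])
    families: list[str] = field(default_factory=lambda: ["A_uni_combo"])
    k: int = 10
    repeats: int = 10
    cv_seed: int = 0
    C: float = 1.0
    n_perm: int = 0
    null_seed: int = 1
    light_null: bool = False
    out_dir: str = "dynsig_out"

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_dataset(config: RunConfig) -> CohortDataset:
    if config.synthetic_spec is not None:
        spec = synthetic.CohortSpec(**config.synthetic_spec)
        return synthetic.generate_cohort(spec)
    if config.series_dir is None or config.participants_path is None:
        raise ValueError("config needs either synthetic_spec or series paths")
    series_dir = Path(config.series_dir)
    paths = sorted(
        p for p in series_dir.iterdir() if p.suffix.lower() in (".tsv", ".csv")
        and p.stem != "participants"
    )
    return load_cohort(paths, config.participants_path, config.tr_seconds)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; returns the result bundle and writes
    JSON/CSV outputs (plus the resolved config) under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": config.resolved(), "config_hash": config.config_hash()}
    (out / "config.json").write_text(json.dumps(meta, indent=2, default=str))

    def _stage(name, fn, *args, **kwargs):
        t0 = time.time()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage=%s elapsed=%.1fs", name, time.time() - t0)
        return result

    dataset = _stage("validate", _load_dataset, config)
    dataset = _stage(
        "qc", qc_filter, dataset, config.fd_threshold_mm, config.drop_constant_regions
    )
    feats = _stage("features", compute_feature_tensor, dataset)
    tensors = _stage("spis", compute_coupling_tensor, dataset, config.spi_names)
    by_spi = {t.spi_name: t for t in tensors}
    groups = dataset.group_labels()

    evaluations = {}
    reps = {}
    for family in config.families:
        if family == "A_uni_combo":
            reps["A_uni_combo"] = build_representation(
                "A_uni_combo", feature_tensor=feats, groups=groups
            )
        elif family == "A_region":
            for r in dataset.region_labels:
                rep = build_representation(
                    "A_region", feature_tensor=feats, groups=groups, region=r
                )
                reps[rep.tag] = rep
        elif family == "A_feature":
            for f in feats.feature_names:
                rep = build_representation(
                    "A_feature", feature_tensor=feats, groups=groups, feature=f
                )
                reps[rep.tag] = rep
        elif family in ("A_FC", "A_FC_combo"):
            for name, tensor in by_spi.items():
                rep = build_representation(
                    family,
                    feature_tensor=feats,
                    coupling_tensor=tensor,
                    groups=groups,
                )
                reps[rep.tag] = rep
        else:
            raise RuntimeError(f"pipeline stage 'represent' failed: unknown family {family!r}")

    plan = make_fold_plan(
        next(iter(reps.values())).y, k=config.k, repeats=config.repeats, seed=config.cv_seed
    )
    rows = []
    for tag, rep in reps.items():
        ev = _stage(f"classify:{tag}", run_repeated_cv, rep, plan=plan, C=config.C)
        evaluations[tag] = ev
        row = {
            "model": tag,
            "mean_balanced_accuracy": ev.mean_ba,
            "sd_balanced_accuracy": ev.sd_ba,
            "mean_auc": float(np.nanmean(ev.aucs)),
        }
        if config.n_perm >= 50:
            null = _stage(
                f"null:{tag}",
                permutation_null,
                rep,
                n_perm=config.n_perm,
                k=config.k,
                repeats=config.repeats,
                seed=config.null_seed,
                C=config.C,
                light=config.light_null,
            )
            row["null_mean"] = null.mu
            row["null_sd"] = null.sigma
            row["p_value"] = gaussian_tail_p(ev.mean_ba, null)
        rows.append(row)
    table = pd.DataFrame(rows)
    if "p_value" in table.columns:
        table["p_bh"] = bh_adjust(table["p_value"].to_numpy())
    table.insert(0, "config_hash", config.config_hash())
    table.to_csv(out / "model_results.csv", index=False)

    selection_rows = []
    for family in config.families:
        fam_reps = [r for t, r in reps.items() if t.startswith(family + "(")]
        if family in ("A_region", "A_feature") and len(fam_reps) > 1:
            sel = _stage(
                f"select:{family}", per_fold_best_selection, family, fam_reps, plan
            )
        elif family in ("A_FC", "A_FC_combo") and len(fam_reps) > 1:
            sel = _stage(
                f"select:{family}", pca_screen_spi_selection, family, fam_reps, plan
            )
        else:
            continue
        selection_rows.append(
            {"family": family, "mean_balanced_accuracy": sel.mean_ba,
             "n_tie_folds": len(sel.tie_folds)}
        )
    if selection_rows:
        pd.DataFrame(selection_rows).to_csv(out / "selection_results.csv", index=False)

    per_fold = pd.DataFrame(
        {tag: ev.balanced_accuracies for tag, ev in evaluations.items()}
    )
    per_fold.to_csv(out / "fold_metrics.csv", index=False)
    return {
        "dataset": dataset,
        "features": feats,
        "couplings": by_spi,
        "representations": reps,
        "evaluations": evaluations,
        "table": table,
    }
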