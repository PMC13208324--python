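"""End-to-end run orchestration from a single config.

Stage order is fixed: QC -> preprocessing -> unsupervised diagnostics ->
supervised LOOCV -> permutation test -> reports.  Class labels are
physically stripped from the objects handed to the QC, preprocessing and
unsupervised stages, so no stage before supervised modeling can see class
membership.  QC flags are reported but never auto-exclude samples.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_eval import (
    ModelConfig,
    discriminant_band_summary,
    loocv_run,
    permutation_test,
    reliability_and_brier,
    variant_grid,
)
from .preprocess import DEFAULT_PIPELINE, PreprocessConfig, apply_preprocess_pipeline
from .qc import QCConfig, build_qc_report
from .spectra import SpectrumSet, read_spectra_table, write_spectra_table
from .synthetic import SyntheticTruth, generate_cohort
from .unsupervised import agglomerative_cluster, classical_mds, cosine_distance_matrix

log = logging.getLogger("serumftir")


@dataclass
class RunConfig:
    """One of ``input_path`` / ``simulate`` must be set, never both."""

    input_path: str | None = None
    simulate: SyntheticTruth | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    preprocess: PreprocessConfig = field(default_factory=lambda: DEFAULT_PIPELINE)
    model: ModelConfig = field(default_factory=ModelConfig)
    n_permutations: int = 10
    out_dir: str = "runs/latest"
    seed: int = 0

    def __post_init__(self):
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("exactly one of input_path/simulate must be given")

    def config_hash(self) -> str:
        blob = repr(
            (self.input_path, self.simulate, self.qc, self.preprocess.provenance(),
             self.model, self.n_permutations, self.seed)
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; write artifacts under ``cfg.out_dir``.

    Returns a dict of the in-memory results (QC report, distance matrix,
    CV result, permutation result, band table, reliability + Brier).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    if cfg.simulate is not None:
        log.info("stage=simulate seed=%d", cfg.simulate.seed)
        sset, sidecar = generate_cohort(cfg.simulate)
        write_spectra_table(sset, out / "cohort.csv")
        (out / "truth_sidecar.json").write_text(json.dumps(sidecar, indent=1))
    else:
        sset = read_spectra_table(cfg.input_path)
    if sset.labels is None:
        raise ValueError("pipeline requires labeled spectra")

    unlabeled = sset.without_labels()  # QC/preprocess/unsupervised are label-blind

    log.info("stage=qc n=%d", sset.n_samples)
    qc_report = build_qc_report(unlabeled, cfg.qc)
    qc_df = qc_report.to_frame()
    qc_df.to_csv(out / "qc_report.csv", index=False)
    if qc_report.n_flagged:
        log.warning("qc flagged %d sample(s); none excluded", qc_report.n_flagged)

    log.info("stage=preprocess %s", cfg.preprocess.provenance())
    pp = apply_preprocess_pipeline(unlabeled, cfg.preprocess)

    log.info("stage=unsupervised")
    dist = cosine_distance_matrix(pp)
    pd.DataFrame(dist.values, index=dist.ids, columns=dist.ids).to_csv(
        out / "cosine_distance.csv"
    )
    dendro = agglomerative_cluster(dist)
    np.savetxt(out / "dendrogram_merges.txt", dendro.linkage_matrix(), fmt="%.10g")
    mds = classical_mds(dist)
    pd.DataFrame(mds, index=dist.ids).to_csv(out / "mds_coords.csv")

    log.info("stage=supervised selector=%s", cfg.model.selector)
    cv = loocv_run(sset, cfg.preprocess, cfg.model, seed=cfg.seed)
    oof = pd.DataFrame(
        {
            "sample_id": cv.sample_ids,
            "label": cv.labels,
            "oof_prob_positive": cv.oof_prob,
        }
    )
    oof.to_csv(out / "loocv_oof.csv", index=False)
    metrics = {**stamp, "loocv": cv.metrics, "resubstitution": cv.train_metrics}
    metrics["loocv"] = {k: v for k, v in cv.metrics.items() if k != "per_class"}
    metrics["resubstitution"] = {
        k: v for k, v in cv.train_metrics.items() if k != "per_class"
    }

    log.info("stage=permutation n=%d", cfg.n_permutations)
    perm = permutation_test(
        sset, cfg.preprocess, cfg.model, cfg.n_permutations, cfg.seed
    )
    pd.DataFrame(
        {
            "permutation": np.arange(perm.n_permutations),
            "loocv_auc": perm.perm_loocv_auc,
            "train_auc": perm.perm_train_auc,
        }
    ).to_csv(out / "permutations.csv", index=False)
    metrics["permutation"] = {
        "true_loocv_auc": perm.true_loocv_auc,
        "true_train_auc": perm.true_train_auc,
        "mean_perm_loocv_auc": float(perm.perm_loocv_auc.mean()),
        "mean_perm_train_auc": float(perm.perm_train_auc.mean()),
    }

    bands = discriminant_band_summary(cv)
    bands.to_csv(out / "discriminant_bands.csv", index=False)
    reliability, brier = reliability_and_brier(cv.oof_prob, cv.labels)
    reliability.to_csv(out / "reliability.csv", index=False)
    metrics["brier"] = brier
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
    log.info("run complete: %s", out)
    return {
        "spectra": sset,
        "qc": qc_report,
        "distance": dist,
        "dendrogram": dendro,
        "mds": mds,
        "cv": cv,
        "permutation": perm,
        "bands": bands,
        "reliability": reliability,
        "brier": brier,
        "metrics": metrics,
    }


def run_variant_grid(cfg: RunConfig, variant_names=None) -> pd.DataFrame:
    """Sensitivity grid over named preprocessing variants."""
    if cfg.simulate is not None:
        sset, _ = generate_cohort(cfg.simulate)
    else:
        sset = read_spectra_table(cfg.input_path)
    grid = variant_grid(sset, variant_names, cfg.model, seed=cfg.seed)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid.to_csv(out / "variant_grid.csv", index=False)
    return grid
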