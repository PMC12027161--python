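"""End-to-end experiment orchestration.

Runs the staged pipeline — QC, feature construction, stratified 70/30
split, training-set rebalancing, cross-validated k selection, KNN
training, thresholded classification, evaluation — for one experiment
specification or for the bundled seven-model matrix that crosses
sampling strategies (none / oversample / subsample), distance metrics
(Euclidean / Manhattan / cosine) and feature sets:

* ``snps_only`` — the per-SNP risk-oriented encoded matrix
  (``g + 1`` per SNP, column-scaled), models 1-5;
* ``combined`` — the 7-column feature matrix (control-standardized
  genetic score, APOE ordinal code, age, sex, smoking, diabetes,
  cholesterol), models 6-7.

Seed discipline: each stochastic stage consumes a sub-seed derived by
stable hashing of the stage name with the master seed, so e.g. changing
the sampling strategy does not perturb the split.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as ft
from . import knn
from .errors import InvalidParameterError
from .evaluation import EvalReport, evaluate
from .qc import apply_qc
from .synthetic import SimulatedCohort

logger = logging.getLogger(__name__)

TABLE1_COLUMNS = (
    "model", "sampling", "distance", "observations", "threshold",
    "test", "train", "cases", "controls", "SEN", "SPEC", "AUC",
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    digest = hashlib.blake2b(
        f"{int(master_seed)}:{stage}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)


@dataclass(frozen=True)
class ExperimentSpec:
    """One row of the experiment matrix."""

    model_id: str
    feature_set: str = "combined"        # snps_only | combined
    sampling: str = "none"               # none | oversample | subsample
    metric: str = "euclidean"
    threshold: float = 0.50
    k: int | str = "auto"
    seed: int = 0
    k_grid: tuple | None = None
    folds: int = 5
    test_fraction: float = 0.30
    stratified: bool = True
    observations: str = ""

    def validate(self) -> "ExperimentSpec":
        if self.feature_set not in ("snps_only", "combined"):
            raise InvalidParameterError(f"unknown feature set {self.feature_set!r}")
        if self.sampling not in ("none", "oversample", "subsample"):
            raise InvalidParameterError(f"unknown sampling {self.sampling!r}")
        if self.metric not in knn.METRICS:
            raise InvalidParameterError(f"unknown metric {self.metric!r}")
        if not 0.0 <= self.threshold <= 1.0:
            raise InvalidParameterError("threshold must lie in [0, 1]")
        return self


@dataclass
class RunManifest:
    """Everything needed to re-run one experiment bit-identically."""

    spec: dict
    seeds: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    selected_k: int | None = None
    timestamp: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _snps_only_features(cohort: SimulatedCohort, G: pd.DataFrame,
                        train_mask: np.ndarray) -> pd.DataFrame:
    """Per-SNP (g + 1) risk-oriented encoding; missing dosages imputed
    with the training-control mean oriented dosage of that SNP."""
    oriented, _beta = ft.oriented_dosages(G, cohort.stats[
        cohort.stats["snp_id"].isin(G.columns)
    ])
    vals = oriented.to_numpy(copy=True)
    labels = cohort.labels.loc[G.index].to_numpy()
    control_train = train_mask & (labels == 0)
    fill = np.nanmean(vals[control_train], axis=0)
    fill = np.nan_to_num(fill, nan=0.0)
    idx = np.where(np.isnan(vals))
    vals[idx] = fill[idx[1]]
    return pd.DataFrame(vals + 1.0, index=oriented.index, columns=oriented.columns)


def _combined_features(cohort: SimulatedCohort, G: pd.DataFrame,
                       ids: pd.Index, train_mask: np.ndarray) -> pd.DataFrame:
    """7-column feature matrix; score imputation and standardization use
    training controls only."""
    labels = cohort.labels.loc[ids].to_numpy()
    control_train = train_mask & (labels == 0)
    raw = ft.raw_weighted_scores(
        G.loc[ids],
        cohort.stats[cohort.stats["snp_id"].isin(G.columns)],
        missing_policy="control_mean",
        control_mask=control_train,
    )
    z, _std = ft.standardize_scores(raw, control_train)
    codes = ft.apoe_codes(cohort.apoe.loc[ids])
    encoded = ft.encode_phenotypes(cohort.phenotypes.loc[ids])
    X, _, dropped = ft.build_feature_matrix(z, codes, encoded, cohort.labels.loc[ids])
    if dropped:
        raise InvalidParameterError(
            "combined features must be complete-case before splitting"
        )
    return X


def run_experiment(
    spec: ExperimentSpec, cohort: SimulatedCohort
) -> tuple[EvalReport, RunManifest]:
    """Execute the staged pipeline for one experiment specification."""
    spec.validate()
    manifest = RunManifest(
        spec={**dataclasses.asdict(spec)},
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    seeds = {s: stage_seed(spec.seed, s) for s in ("split", "rebalance", "select_k")}
    manifest.seeds = seeds

    # 1. genotype QC
    G, qc_report = apply_qc(cohort.genotypes)
    manifest.counts["post_qc"] = {
        "individuals": G.shape[0], "snps": G.shape[1]
    }

    # 2. complete-case restriction (combined models only: phenotype NAs
    #    are dropped before the split, so test size reflects the drop)
    if spec.feature_set == "combined":
        encoded = ft.encode_phenotypes(cohort.phenotypes.loc[G.index])
        complete = encoded.notna().all(axis=1)
        ids = G.index[complete]
    else:
        ids = G.index
    labels = cohort.labels.loc[ids].to_numpy()
    manifest.counts["modeled"] = {
        "individuals": len(ids),
        "cases": int(labels.sum()),
        "controls": int((labels == 0).sum()),
    }

    # 3. stratified 70/30 split
    sp = knn.split(labels, test_fraction=spec.test_fraction,
                   seed=seeds["split"], stratified=spec.stratified)
    train_mask = np.zeros(len(ids), dtype=bool)
    train_mask[sp.train_idx] = True

    # 4. feature construction (train-fitted imputation/standardization)
    if spec.feature_set == "snps_only":
        X = _snps_only_features(cohort, G.loc[ids], train_mask)
    else:
        X = _combined_features(cohort, G, ids, train_mask)
    scaling = ft.fit_scaler(X.iloc[sp.train_idx])
    Xs = ft.apply_scaler(scaling, X).to_numpy()

    X_train, y_train = Xs[sp.train_idx], labels[sp.train_idx]
    X_test, y_test = Xs[sp.test_idx], labels[sp.test_idx]
    manifest.counts["split"] = {"train": len(y_train), "test": len(y_test)}

    # 5. training-set rebalancing (test prevalence untouched)
    X_train, y_train = knn.rebalance(
        X_train, y_train, strategy=spec.sampling, seed=seeds["rebalance"]
    )
    manifest.counts["rebalanced_train"] = {
        "train": len(y_train),
        "cases": int(y_train.sum()),
        "controls": int((y_train == 0).sum()),
    }

    # 6. k selection
    if spec.k == "auto":
        best_k, _cv = knn.select_k(
            X_train, y_train, metric=spec.metric, k_grid=spec.k_grid,
            folds=spec.folds, seed=seeds["select_k"],
        )
    else:
        best_k = int(spec.k)
    manifest.selected_k = best_k

    # 7. predict + evaluate at the spec threshold
    prob = knn.knn_probabilities(X_train, y_train, X_test, best_k, spec.metric)
    report = evaluate(y_test, prob, threshold=spec.threshold)
    logger.info(
        "%s: k=%d SEN=%.3f SPEC=%.3f AUC=%.3f",
        spec.model_id, best_k, report.sensitivity, report.specificity, report.auc,
    )
    return report, manifest


def table1_specs(seed: int = 0, k: int | str = "auto") -> list[ExperimentSpec]:
    """The bundled seven-model experiment matrix."""
    path = Path(__file__).parent / "data" / "table1.yaml"
    with open(path) as fh:
        rows = yaml.safe_load(fh)["models"]
    return [
        ExperimentSpec(
            model_id=r["model_id"],
            feature_set=r["feature_set"],
            sampling=r["sampling"],
            metric=r["metric"],
            threshold=float(r["threshold"]),
            observations=r.get("observations", ""),
            seed=seed,
            k=k,
        )
        for r in rows
    ]


def run_table1(
    cohort: SimulatedCohort, seed: int = 0, k: int | str = "auto"
) -> tuple[pd.DataFrame, list[tuple[ExperimentSpec, EvalReport, RunManifest]]]:
    """Run all seven models on one cohort; summary frame + full results."""
    results = []
    rows = []
    for spec in table1_specs(seed=seed, k=k):
        report, manifest = run_experiment(spec, cohort)
        results.append((spec, report, manifest))
        rows.append(
            {
                "model": spec.model_id,
                "sampling": spec.sampling,
                "distance": spec.metric,
                "observations": spec.observations,
                "threshold": spec.threshold,
                "test": manifest.counts["split"]["test"],
                "train": manifest.counts["rebalanced_train"]["train"],
                "cases": manifest.counts["rebalanced_train"]["cases"],
                "controls": manifest.counts["rebalanced_train"]["controls"],
                "SEN": report.sensitivity,
                "SPEC": report.specificity,
                "AUC": report.auc,
            }
        )
    summary = pd.DataFrame(rows, columns=list(TABLE1_COLUMNS))
    return summary, results


def write_report(
    results: list[tuple[ExperimentSpec, EvalReport, RunManifest]],
    summary: pd.DataFrame,
    out_dir,
    force: bool = False,
) -> None:
    """Summary TSV, one JSON report + manifest per model."""
    out = Path(out_dir)
    summary_path = out / "summary.tsv"
    if summary_path.exists() and not force:
        raise FileExistsError(f"{summary_path} exists; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    summary.to_csv(summary_path, sep="\t", index=False)
    for spec, report, manifest in results:
        report.to_json(out / f"{spec.model_id}_eval.json")
        manifest.to_json(out / f"{spec.model_id}_manifest.json")
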