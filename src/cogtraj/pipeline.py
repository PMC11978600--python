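"""End-to-end pipeline: simulate -> preprocess -> summarize -> cluster ->
eeg -> stats -> classify, with a round-trippable configuration and a run
manifest recording row counts and output hashes for reproducibility checks.

A single global seed fans out to per-stage seeds through a fixed offset
scheme so that stages stay reproducible when rerun independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import autoencode, classify, dtwcluster, eeg, preprocess, stats
from .cohort import (
    CohortConfig,
    SyntheticCohort,
    apply_missingness,
    direction_flags,
    generate_cohort,
    generate_eeg_signals,
)
from .io import write_json, write_long_table

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "composite_score"]

_STAGE_SEED_OFFSETS = {
    "simulate": 0, "preprocess": 101, "summarize": 211,
    "cluster": 307, "eeg": 401, "stats": 503, "classify": 601,
}


@dataclass
class PipelineConfig:
    """All stage parameters; round-trips losslessly through YAML."""

    seed: int = 0
    outdir: str = "cogtraj_run"
    stages: tuple[str, ...] = (
        "simulate", "preprocess", "summarize", "cluster", "eeg", "stats", "classify",
    )
    # simulate
    cohort: dict = field(default_factory=dict)  # overrides for CohortConfig fields
    # preprocess
    min_n: int = 75
    pct_lo: float = 5.0
    pct_hi: float = 95.0
    iqr_multiplier: float = 5.0
    # summarize
    latent_fraction: float = 0.65
    ae_epochs: int = 300
    ae_learning_rate: float = 1e-2
    ae_activation: str = "tanh"
    # cluster
    k_range: tuple[int, int] = (2, 8)
    fixed_k: int | None = None
    n_init: int = 10
    kmeans_max_iter: int = 50
    # eeg
    eeg_snr: float = 1.0
    eeg_duration_s: float = 8.0
    eeg_segment_s: float = 2.0
    # stats / classify
    merge_high_low: bool = True
    bh_adjust: bool = False
    classifier_cv: int | None = None

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = dataclasses.asdict(self)
        payload["stages"] = list(self.stages)
        payload["k_range"] = list(self.k_range)
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "stages" in payload:
            payload["stages"] = tuple(payload["stages"])
        if "k_range" in payload:
            payload["k_range"] = tuple(payload["k_range"])
        return cls(**payload)

    def cohort_config(self) -> CohortConfig:
        overrides = dict(self.cohort)
        known = {f.name for f in dataclasses.fields(CohortConfig)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown cohort keys: {sorted(unknown)}")
        overrides.setdefault("seed", self.stage_seed("simulate"))
        return CohortConfig(**overrides)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages_run: list[str]
    row_counts: dict
    output_hashes: dict
    summary: dict
    started: float
    finished: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def composite_score(cognitive: pd.DataFrame,
                    flags: pd.Series | None = None) -> pd.DataFrame:
    """Direction-corrected composite cognition per participant-visit: the mean
    of per-variable z-scores with higher-is-worse scores sign-flipped, so
    higher composite = better cognition."""
    flags = flags if flags is not None else direction_flags()
    df = cognitive.dropna(subset=["value"]).copy()
    stats_ = df.groupby("variable")["value"].agg(["mean", "std"])
    df = df.merge(stats_, left_on="variable", right_index=True)
    df["z"] = (df["value"] - df["mean"]) / df["std"].replace(0.0, np.nan)
    flag_of = flags.to_dict()
    sign = np.where([flag_of.get(v, False) for v in df["variable"]], -1.0, 1.0)
    df["z"] *= sign
    out = (df.groupby(["participant_id", "visit_index"])
           .agg(age=("age", "first"), value=("z", "mean"))
           .reset_index())
    return out


def _risk_to_long(risk: pd.DataFrame) -> tuple[pd.DataFrame, set[str]]:
    """Risk factors as a long numeric table (binary -> 0/1, categoricals
    one-hot), attributed to visit 1; returns (table, categorical variables)."""
    rows = []
    categorical: set[str] = set()
    enc = risk.copy()
    for col in risk.columns:
        vals = risk[col]
        if vals.dtype == object:
            uniq = set(vals.dropna().unique())
            if uniq <= {"yes", "no"}:
                enc[col] = vals.map({"yes": 1.0, "no": 0.0})
            else:
                dummies = pd.get_dummies(vals, prefix=col).astype(float)
                enc = enc.drop(columns=[col]).join(dummies)
            categorical.add(col)
    for col in enc.columns:
        for pid, v in enc[col].items():
            rows.append((pid, 1, np.nan, col, float(v)))
    return (pd.DataFrame(rows, columns=preprocess.LONG_COLUMNS), categorical)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages in the fixed order and persist outputs.

    Returns a manifest with per-stage row counts, output-file hashes, and a
    summary (selected k, archetype map, recovery ARI against the generator
    truth, modality AUCs).
    """
    started = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    row_counts: dict = {}
    summary: dict = {}
    outputs: dict[str, Path] = {}
    stages = list(config.stages)

    def _write_table(name: str, table: pd.DataFrame):
        outputs[name] = write_long_table(table, outdir / f"{name}.csv")
        row_counts[name] = len(table)

    # ---- simulate -------------------------------------------------------
    cohort: SyntheticCohort | None = None
    try:
        if "simulate" in stages:
            cohort = generate_cohort(config.cohort_config())
            mri = apply_missingness(cohort.mri, cohort.config.mri_missing_rate,
                                    config.stage_seed("simulate") + 1)
            _write_table("cognitive_raw", cohort.cognitive)
            _write_table("mri_raw", mri)
            cohort.truth.to_csv(outdir / "truth.csv")
            outputs["truth"] = outdir / "truth.csv"
            cohort.risk_factors.to_csv(outdir / "risk_factors.csv")
            outputs["risk_factors"] = outdir / "risk_factors.csv"
            row_counts["participants"] = len(cohort.participants)
        else:
            raise StageError("simulate", ValueError(
                "this pipeline entrypoint requires the simulate stage; load "
                "persisted tables with cogtraj.io for externally supplied data"))
    except StageError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("simulate", exc) from exc

    # ---- preprocess -----------------------------------------------------
    try:
        cognitive, qc = preprocess.preprocess_cognitive(
            cohort.cognitive, min_n=config.min_n, pct_lo=config.pct_lo,
            pct_hi=config.pct_hi, iqr_multiplier=config.iqr_multiplier,
        )
        mri_norm = preprocess.icv_normalize(mri, cohort.icv)
        mri_norm, _ = preprocess.filter_iqr_outliers(mri_norm, config.iqr_multiplier)
        cognitive, mri_norm = preprocess.match_modalities(cognitive, mri_norm)
        write_json(qc.to_dict(), outdir / "qc_report.json")
        _write_table("cognitive", cognitive)
        _write_table("mri", mri_norm)
        summary["n_participants_cognitive"] = int(cognitive["participant_id"].nunique())
        summary["n_cognitive_scores"] = int(cognitive["variable"].nunique())
    except Exception as exc:
        raise StageError("preprocess", exc) from exc

    # ---- summarize ------------------------------------------------------
    try:
        Z, params, meta = autoencode.standardize_features(cognitive)
        spec = autoencode.AutoencoderSpec(
            input_dim=Z.shape[1], latent_fraction=config.latent_fraction,
            epochs=config.ae_epochs, learning_rate=config.ae_learning_rate,
            activation=config.ae_activation, seed=config.stage_seed("summarize"),
        )
        model = autoencode.train_autoencoder(Z, spec)
        latent = autoencode.encode_table(model, Z, meta)
        latent.to_csv(outdir / "latent.csv", index=False)
        outputs["latent"] = outdir / "latent.csv"
        row_counts["latent"] = len(latent)
        summary["latent_dim"] = spec.latent_dim
        summary["reconstruction_mse"] = model.final_loss
    except Exception as exc:
        raise StageError("summarize", exc) from exc

    # ---- cluster --------------------------------------------------------
    try:
        trajs = dtwcluster.trajectories_from_latent(latent)
        seed_c = config.stage_seed("cluster")
        if config.fixed_k is not None:
            cl_model = dtwcluster.temporal_kmeans(
                trajs, config.fixed_k, seed=seed_c, n_init=config.n_init,
                max_iter=config.kmeans_max_iter)
            cl_model.db_index = dtwcluster.davies_bouldin(trajs, cl_model)
            db_curve = pd.DataFrame(
                [{"k": config.fixed_k, "db_index": cl_model.db_index}])
            best_k = config.fixed_k
        else:
            lo, hi = config.k_range
            best_k, db_curve, models = dtwcluster.select_k(
                trajs, range(lo, hi + 1), seed=seed_c, n_init=config.n_init,
                max_iter=config.kmeans_max_iter)
            cl_model = models[best_k]
        comp = composite_score(cognitive)
        archetype_map = dtwcluster.label_archetypes(cl_model, comp)
        labels = cl_model.labels.to_frame()
        labels["archetype"] = labels["cluster"].map(archetype_map)
        labels.to_csv(outdir / "cluster_labels.csv")
        db_curve.to_csv(outdir / "db_curve.csv", index=False)
        outputs["cluster_labels"] = outdir / "cluster_labels.csv"
        summary["selected_k"] = int(best_k)
        summary["db_index"] = float(cl_model.db_index)
        summary["archetype_map"] = {int(k): v for k, v in archetype_map.items()}
        summary["cluster_sizes"] = {
            int(k): int(v) for k, v in cl_model.labels.value_counts().items()}
        truth = cohort.truth.reindex(cl_model.labels.index)
        summary["recovery_ari"] = float(
            adjusted_rand_score(truth.to_numpy(), cl_model.labels.to_numpy()))
    except Exception as exc:
        raise StageError("cluster", exc) from exc

    # ---- eeg ------------------------------------------------------------
    eeg_table = None
    if "eeg" in stages:
        try:
            recordings = generate_eeg_signals(
                cohort, snr=config.eeg_snr, duration_s=config.eeg_duration_s)
            raw_powers = eeg.extract_regional_powers(
                recordings, stim_freqs_hz=cohort.config.stim_freqs_hz,
                segment_s=config.eeg_segment_s)
            keep = apply_missingness(
                raw_powers.rename(columns={"power": "value"})
                .assign(variable=lambda d: d["region"] + "_" + d["band"], age=np.nan),
                cohort.config.eeg_missing_rate, config.stage_seed("eeg"),
            )
            raw_powers = keep.rename(columns={"value": "power"})
            raw_powers["region"] = raw_powers["variable"].str.rsplit("_", n=1).str[0]
            raw_powers["band"] = raw_powers["variable"].str.rsplit("_", n=1).str[1]
            z = eeg.zscore_powers(raw_powers[
                ["participant_id", "visit_index", "region", "band", "power"]])
            eeg_table = eeg.regional_power_feature_table(z)
            (_, eeg_table) = preprocess.match_modalities(cognitive, eeg_table)[:2]
            _write_table("eeg_powers", eeg_table)
            summary["n_participants_eeg"] = int(eeg_table["participant_id"].nunique())
        except Exception as exc:
            raise StageError("eeg", exc) from exc

    # ---- stats ----------------------------------------------------------
    if "stats" in stages:
        try:
            labels4 = cl_model.labels
            risk_long, categorical = _risk_to_long(cohort.risk_factors)
            risk_for_stats = cohort.risk_factors.reset_index().melt(
                id_vars="participant_id", var_name="variable", value_name="value")
            feats = [risk_for_stats]
            if eeg_table is not None:
                feats.append(eeg_table[["participant_id", "variable", "value"]])
            feats.append(mri_norm[["participant_id", "variable", "value"]])
            all_feats = pd.concat(feats, ignore_index=True)
            res4 = stats.compare_all(all_feats, labels4, categorical=categorical,
                                     bh_adjust=config.bh_adjust)
            res4.to_csv(outdir / "group_stats_k4.csv", index=False)
            outputs["group_stats_k4"] = outdir / "group_stats_k4.csv"
            summary["n_significant_k4"] = int(res4["significant"].fillna(False).sum())
            if config.merge_high_low:
                merge = {"low": [c for c, a in archetype_map.items()
                                 if a.startswith("low")],
                         "high": [c for c, a in archetype_map.items()
                                  if a.startswith("high")]}
                res2 = stats.compare_all(all_feats, labels4, categorical=categorical,
                                         merge_map=merge, bh_adjust=config.bh_adjust)
                res2.to_csv(outdir / "group_stats_merged.csv", index=False)
                outputs["group_stats_merged"] = outdir / "group_stats_merged.csv"
                summary["n_significant_merged"] = int(
                    res2["significant"].fillna(False).sum())
        except Exception as exc:
            raise StageError("stats", exc) from exc

    # ---- classify -------------------------------------------------------
    if "classify" in stages:
        try:
            labeling = classify.merge_high_low(cl_model.labels, archetype_map)
            risk_long, _ = _risk_to_long(cohort.risk_factors)
            tables = {"cognitive": cognitive, "mri": mri_norm, "risk": risk_long}
            if eeg_table is not None:
                tables["eeg"] = eeg_table
            rocs = classify.modality_auc_comparison(
                tables, labeling, cv=config.classifier_cv,
                seed=config.stage_seed("classify"))
            summary["modality_auc"] = {r.modality: r.auc for r in rocs}
            pd.DataFrame([{"modality": r.modality, "auc": r.auc, "n": r.n_used}
                          for r in rocs]).to_csv(outdir / "modality_auc.csv", index=False)
            outputs["modality_auc"] = outdir / "modality_auc.csv"
            scan = classify.univariate_auc_scan(cognitive, labeling)
            scan.to_csv(outdir / "univariate_auc.csv", index=False)
            outputs["univariate_auc"] = outdir / "univariate_auc.csv"
            summary["top_univariate_score"] = str(scan.iloc[0]["score"])
        except Exception as exc:
            raise StageError("classify", exc) from exc

    config_payload = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_payload.encode()).hexdigest(),
        seed=config.seed,
        stages_run=stages,
        row_counts=row_counts,
        output_hashes={k: _hash_file(p) for k, p in outputs.items()},
        summary=summary,
        started=started,
        finished=time.time(),
    )
    write_json(manifest.to_dict(), outdir / "manifest.json")
    return manifest
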