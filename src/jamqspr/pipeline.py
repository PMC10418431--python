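"""Composed learn/test/predict workflow.

Ties the stages together: component descriptors -> mixture features ->
(optional) synthetic data generation -> seeded split -> architecture
search with multi-restart Levenberg--Marquardt training -> deviation
reports -> storage-stability statistics.  Every output directory gets a
manifest naming the seed, the configuration hash and the output hashes,
so a rerun with one master seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ann, simulate, stats
from .components import COMPONENT_ORDER, COMPONENT_SMILES
from .descriptors import compute_descriptors, descriptor_table
from .mixture import (
    FeatureConfig,
    JamRecord,
    MixtureComposition,
    MinMaxScaler,
    default_feature_config,
    feature_matrix,
)

__all__ = ["PipelineConfig", "run_pipeline", "records_from_frame", "prepare_features"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the composed pipeline (all stages)."""

    seed: int = 0
    records_csv: str | None = None          # skip generation when given
    generator: simulate.GeneratorConfig | None = None
    split: ann.SplitSpec = ann.SplitSpec(585, 55, 40)
    training: ann.TrainingConfig = ann.TrainingConfig(restarts=3)
    architectures: tuple[tuple[int, ...], ...] = ((10, 30, 10, 3),)
    feature_names: tuple[str, ...] | None = None  # default: variance-ranked

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in ("seed", "records_csv"):
            if key in raw:
                kwargs[key] = raw[key]
        if "generator" in raw:
            g = dict(raw["generator"])
            if "times" in g:
                g["times"] = tuple(g["times"])
            kwargs["generator"] = simulate.GeneratorConfig(**g)
        if "split" in raw:
            kwargs["split"] = ann.SplitSpec(**raw["split"])
        if "training" in raw:
            kwargs["training"] = ann.TrainingConfig(**raw["training"])
        if "architectures" in raw:
            kwargs["architectures"] = tuple(tuple(a) for a in raw["architectures"])
        if "feature_names" in raw:
            kwargs["feature_names"] = tuple(raw["feature_names"])
        return cls(**kwargs)


def records_from_frame(df: pd.DataFrame) -> list[JamRecord]:
    """Turn a record table into JamRecord objects (responses included)."""
    records = []
    for row in df.itertuples(index=False):
        records.append(
            JamRecord(
                formulation=row.formulation,
                time=float(row.time),
                pct_HM_pectin=float(row.HM),
                pct_LM_pectin=float(row.LM),
                pct_xanthan=float(row.xf),
                pH=float(row.pH),
                acidity=float(row.ac),
                composition=MixtureComposition(
                    fractions={c: getattr(row, f"frac_{c}") for c in COMPONENT_ORDER}
                ),
                hardness=float(row.hardness),
                water_activity=float(row.water_activity),
                adhesiveness=float(row.adhesiveness),
            )
        )
    return records


def prepare_features(
    df: pd.DataFrame, feature_names=None
) -> tuple[np.ndarray, np.ndarray, FeatureConfig, MinMaxScaler, MinMaxScaler]:
    """Build and scale the 10-feature matrix and 3-response matrix.

    Returns (X scaled, Y scaled, feature config, X scaler, Y scaler).
    """
    vectors = {c: compute_descriptors(s) for c, s in COMPONENT_SMILES.items()}
    records = records_from_frame(df)
    if feature_names is not None:
        cfg = FeatureConfig(features=tuple(feature_names))
    else:
        cfg = default_feature_config(records, vectors)
    X = feature_matrix(records, cfg, vectors)
    Y = df[list(simulate.RESPONSE_COLUMNS)].to_numpy(float)
    x_scaler = MinMaxScaler()
    y_scaler = MinMaxScaler()
    return (
        x_scaler.fit_transform(X),
        y_scaler.fit_transform(Y),
        cfg,
        x_scaler,
        y_scaler,
    )


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Execute the composed pipeline; write tables and a manifest.

    Returns the manifest dictionary.  Any stage failure propagates with
    the stage name prepended.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": [], "files": {}}

    def stage(name):
        manifest["stages"].append(name)

    try:
        stage("descriptors")
        table = descriptor_table(
            [(c, COMPONENT_SMILES[c]) for c in COMPONENT_ORDER]
        )
        table.to_csv(out / "component_descriptors.csv", float_format="%.6g")

        stage("dataset")
        if cfg.records_csv is not None:
            df = pd.read_csv(cfg.records_csv)
        else:
            gen = cfg.generator or simulate.GeneratorConfig(seed=cfg.seed)
            df = simulate.generate_dataset(cfg=gen)
            simulate.write_records_csv(df, out / "jam_records.csv")

        stage("features")
        Xs, Ys, feat_cfg, _, y_scaler = prepare_features(df, cfg.feature_names)
        manifest["features"] = list(feat_cfg.features)

        stage("split")
        split = ann.SplitSpec(
            cfg.split.n_learning, cfg.split.n_testing, cfg.split.n_prediction,
            seed=cfg.seed,
        )
        i_learn, i_test, i_pred = ann.random_split(len(df), split)

        stage("architecture_search")
        training = ann.TrainingConfig(
            tolerance=cfg.training.tolerance,
            max_iterations=cfg.training.max_iterations,
            restarts=cfg.training.restarts,
            seed=cfg.seed,
            damping_init=cfg.training.damping_init,
        )
        results = ann.architecture_search(
            [(*a[:-1], a[-1]) for a in cfg.architectures],
            Xs[i_learn], Ys[i_learn], Xs[i_test], Ys[i_test],
            Xs[i_pred], Ys[i_pred],
            training, target_scaler=y_scaler,
        )
        rows = []
        for r in results:
            rep = r["prediction_report"]
            rows.append(
                {
                    "rank": r["rank"],
                    "architecture": str(r["architecture"]),
                    "n_parameters": r["architecture"].n_parameters,
                    "winning_run": r["winning_run"],
                    **{
                        f"avg_dev_{v}": rep.average[k]
                        for k, v in enumerate(simulate.RESPONSE_COLUMNS)
                    },
                    **{
                        f"max_dev_{v}": rep.maximum[k]
                        for k, v in enumerate(simulate.RESPONSE_COLUMNS)
                    },
                }
            )
        pd.DataFrame(rows).to_csv(
            out / "architecture_ranking.csv", index=False, float_format="%.6g"
        )
        ann.save_checkpoint(results[0]["weights"], out / "best_network.txt")

        stage("stability_stats")
        stats.anova_table(df, simulate.PROPERTY_COLUMNS).to_csv(
            out / "anova_summary.csv"
        )
        stats.regression_table(df, simulate.PROPERTY_COLUMNS).to_csv(
            out / "regression_models.csv", index=False, float_format="%.6g"
        )
    except Exception as exc:  # annotate with the failing stage
        failed = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha(f)
    manifest["config_hash"] = hashlib.sha256(
        repr(cfg).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
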