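"""End-to-end pipeline: fingerprints -> similarity -> density -> KLD -> forest.

One :class:`PipelineConfig` (optionally loaded from YAML) drives the whole
chain; a single master seed fans out deterministically to per-stage seeds
so one integer reproduces a run.  Every artifact written to the output
directory embeds the config hash and seed, and the expensive stage (the
feature table) is cached: a rerun with an identical config reuses the
artifact, while any config change invalidates it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import model as dti
from .divergence import DEFAULT_EPSILON, kld_matrix, write_kld_matrix
from .errors import ConfigurationError
from .fpset import FingerprintCollection
from .similarity import DEFAULT_CAP
from .synthetic import SyntheticClassSpec, default_specs, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; see field comments for units and ranges."""

    # input: exactly one of fingerprints_tsv / ligand_table / synthetic
    fingerprints_tsv: str | None = None
    ligand_table: str | None = None
    synthetic: list[dict] | None = None  # SyntheticClassSpec kwargs per class

    mode: str = "3d"  # fingerprint mode for the ligand-table path
    n_bits: int = 1024
    conformers_per_ligand: int = 16
    cap: int = DEFAULT_CAP  # Q-Q resampling cap (conformers)
    bandwidth_rule: str = "scott"
    renormalize: bool = True
    epsilon: float = DEFAULT_EPSILON
    exclude_self: bool = True
    test_fraction: float = 0.25
    folds: int = 5
    n_estimators: int = 500
    tune: bool = False
    seed: int = 0  # master seed; per-stage seeds derive from it
    out_dir: str = "kld_dti_run"
    resume: bool = True

    def __post_init__(self) -> None:
        if self.cap < 1:
            raise ConfigurationError("cap must be >= 1")
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigurationError("test_fraction must be in (0, 1)")
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be positive")
        if self.mode not in ("3d", "2d"):
            raise ConfigurationError("mode must be '3d' or '2d'")
        sources = [self.fingerprints_tsv, self.ligand_table, self.synthetic]
        if sum(s is not None for s in sources) != 1:
            raise ConfigurationError(
                "exactly one of fingerprints_tsv, ligand_table or synthetic "
                "must be given"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineResult:
    config: PipelineConfig
    collection: FingerprintCollection = field(repr=False)
    target_models: dict = field(repr=False)
    qq_kld_matrix: pd.DataFrame = field(repr=False)
    feature_table: pd.DataFrame = field(repr=False)
    model: object = field(repr=False)
    report: dti.EvaluationReport = field(repr=False)
    fold_accuracies: np.ndarray
    cv_mean_accuracy: float
    analysis: dti.FeatureAnalysis = field(repr=False)
    out_dir: Path | None = None


def _load_collection(config: PipelineConfig) -> FingerprintCollection:
    if config.fingerprints_tsv is not None:
        return FingerprintCollection.read_tsv(config.fingerprints_tsv)
    if config.synthetic is not None:
        specs = [SyntheticClassSpec(**kw) for kw in config.synthetic]
        return generate_dataset(specs, seed=stage_seed(config.seed, "simulate"))
    # real-chemistry path
    from . import chem, fingerprints

    records = chem.read_ligand_table(config.ligand_table)
    labels = {r.ligand_id: r.target_label for r in records}
    if config.mode == "2d":
        return fingerprints.fingerprint_ligands_2d(records, n_bits=config.n_bits)
    sets = []
    conf_seed = stage_seed(config.seed, "conformers")
    for rec in records:
        try:
            sets.append(
                chem.generate_conformers(
                    rec, n_conf=config.conformers_per_ligand, seed=conf_seed
                )
            )
        except Exception as exc:
            logger.warning("ligand %s flagged: %s", rec.ligand_id, exc)
    return fingerprints.fingerprint_conformer_sets(
        sets, labels, n_bits=config.n_bits
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full chain and return all artifacts.

    Writes (under ``config.out_dir``): the feature table, the target-target
    KLD matrix, the evaluation report JSON, and the trained model bundle.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    collection = _load_collection(config)
    logger.info("loaded %d fingerprints across %d classes",
                len(collection), len(collection.class_ids))

    target_models = dti.fit_target_models(
        collection,
        cap=config.cap,
        seed=stage_seed(config.seed, "resample"),
        bandwidth_rule=config.bandwidth_rule,
        renormalize=config.renormalize,
    )
    labels = sorted(target_models)
    qq_kld = kld_matrix(
        [target_models[t].profile for t in labels], labels,
        epsilon=config.epsilon,
    )
    write_kld_matrix(out_dir / "qq_kld_matrix.tsv", qq_kld)

    features_path = out_dir / "features.csv"
    meta_path = out_dir / "features.meta.json"
    table = None
    if config.resume and features_path.exists() and meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if meta.get("config_hash") == chash:
            table = pd.read_csv(features_path, index_col="ligand_id")
            logger.info("reusing cached feature table (%s)", chash)
    if table is None:
        table = dti.build_feature_table(
            collection,
            target_models,
            exclude_self=config.exclude_self,
            epsilon=config.epsilon,
            bandwidth_rule=config.bandwidth_rule,
            renormalize=config.renormalize,
        )
        table.to_csv(features_path)
        meta_path.write_text(
            json.dumps({"config_hash": chash, "seed": config.seed})
        )

    out_of_set = tuple(
        sorted(set(table[dti.LABEL_COLUMN]) - set(labels))
    )
    in_set = table[~table[dti.LABEL_COLUMN].isin(out_of_set)]
    split_rng = stage_seed(config.seed, "split")
    train, test = dti.split_train_test(
        in_set, test_fraction=config.test_fraction, stratified=True,
        seed=split_rng,
    )
    if out_of_set:
        test = pd.concat([test, table[table[dti.LABEL_COLUMN].isin(out_of_set)]])
    rf = dti.train_rf(
        train, n_estimators=config.n_estimators,
        seed=stage_seed(config.seed, "forest"), tune=config.tune,
    )
    report = dti.evaluate(rf, test, out_of_set_labels=out_of_set)
    fold_accs, cv_mean = dti.cross_validate(
        in_set, folds=config.folds, seed=stage_seed(config.seed, "cv"),
        n_estimators=config.n_estimators,
    )
    analysis = dti.feature_analysis(
        rf, in_set, seed=stage_seed(config.seed, "analysis"),
        test_fraction=config.test_fraction,
    )

    _write_report(out_dir, config, chash, report, fold_accs, cv_mean, analysis)
    _write_model_bundle(out_dir, config, chash, rf, dti.feature_columns(table))

    return PipelineResult(
        config=config,
        collection=collection,
        target_models=target_models,
        qq_kld_matrix=qq_kld,
        feature_table=table,
        model=rf,
        report=report,
        fold_accuracies=fold_accs,
        cv_mean_accuracy=cv_mean,
        analysis=analysis,
        out_dir=out_dir,
    )


def _write_report(out_dir, config, chash, report, fold_accs, cv_mean, analysis):
    payload = {
        "config_hash": chash,
        "seed": config.seed,
        "accuracy": report.accuracy,
        "oob_score": report.oob_score,
        "n_out_of_set": report.n_out_of_set,
        "per_class": {
            lbl: {
                "precision": float(report.precision[lbl]),
                "recall": float(report.recall[lbl]),
                "f1": float(report.f1[lbl]),
                "support": int(report.support[lbl]),
                "auc": None
                if np.isnan(report.auc.get(lbl, np.nan))
                else float(report.auc[lbl]),
            }
            for lbl in report.labels
        },
        "confusion": report.confusion.to_dict(),
        "fold_accuracies": [float(a) for a in fold_accs],
        "cv_mean_accuracy": cv_mean,
        "importances": analysis.importances.to_dict(),
        "pruning": analysis.pruning.to_dict(orient="records"),
    }
    (Path(out_dir) / "report.json").write_text(json.dumps(payload, indent=2))


def _write_model_bundle(out_dir, config, chash, rf, feature_order):
    import joblib

    bundle = Path(out_dir) / "model"
    bundle.mkdir(exist_ok=True)
    joblib.dump(rf, bundle / "forest.joblib")
    (bundle / "meta.json").write_text(
        json.dumps(
            {
                "config": asdict(config),
                "config_hash": chash,
                "seed": config.seed,
                "feature_order": feature_order,
            },
            indent=2,
            default=str,
        )
    )


def default_synthetic_config(seed: int = 0, out_dir: str = "kld_dti_run",
                             **spec_kwargs) -> PipelineConfig:
    """Study conditions used throughout the docs: 5 well-separated classes,
    200 ligands x 4 conformers each, disjoint 48-bit cores, p_core = 0.9,
    p_noise = 0.02."""
    specs = [asdict(s) for s in default_specs(**spec_kwargs)]
    return PipelineConfig(synthetic=specs, seed=seed, out_dir=out_dir)
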