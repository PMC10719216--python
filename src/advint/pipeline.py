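"""End-to-end experiment orchestration.

``run_full_experiment`` chains every stage — simulate, (optional class
imbalance), normalize, split, train the standard classifier, sweep the
attack level, adversarially train, attribute both models with the full
method suite, vote a consensus, score key-gene recovery, run the DGE
baseline and compare rankings — and returns an in-memory bundle. When an
output directory is given, every tabular artifact is written with a
manifest of settings, seeds and content hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from . import attacks, classifier, consensus, interpret, preprocess, simdata
from .errors import StageError
from .io import ExperimentConfig, write_key_genes, write_matrix

__all__ = ["ExperimentBundle", "run_full_experiment", "seed_stream"]


def seed_stream(seed: int, n: int = 16) -> list[int]:
    """Independent integer substream seeds derived from one global seed."""
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class ExperimentBundle:
    """Everything one experiment run produces, keyed by stage."""

    config: ExperimentConfig
    data: ad.AnnData
    truth: pd.DataFrame
    train: ad.AnnData
    test: ad.AnnData
    standard_model: classifier.CellTypeMLP
    robust_model: classifier.CellTypeMLP
    standard_metrics: classifier.EvalMetrics
    robust_metrics: classifier.EvalMetrics
    sweep_standard: attacks.RobustnessCurve
    sweep_robust: attacks.RobustnessCurve
    attributions: dict[str, dict[str, interpret.AttributionMatrix]]
    consensus_tables: dict[str, consensus.ConsensusTable]
    recovery: dict[str, consensus.RecoveryReport]
    dge: pd.DataFrame
    overlap: pd.DataFrame
    attacked_accuracy: dict[str, float]
    manifest: dict = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn):
        try:
            return fn()
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_full_experiment(
    config: ExperimentConfig | None = None, out_dir: str | Path | None = None
) -> ExperimentBundle:
    cfg = config or ExperimentConfig()
    seeds = seed_stream(cfg.seed)
    out = Path(out_dir) if out_dir else (Path(cfg.out_dir) if cfg.out_dir else None)

    sim_cfg = simdata.SimConfig(**cfg.sim.model_dump(), seed=seeds[0])
    data, truth = _stage("simulate")(lambda: simdata.simulate_dataset(sim_cfg))
    if cfg.imbalance.enabled:
        data = _stage("subsample")(
            lambda: simdata.subsample_cell_types(
                data, cfg.imbalance.types, cfg.imbalance.removal_fraction, seeds[1]
            )
        )

    def do_preprocess():
        d = data
        if cfg.preprocess.apply_hvg:
            d, _ = preprocess.select_hvg(
                d, cfg.preprocess.n_top, cfg.preprocess.min_counts
            )
        train_raw, test_raw = preprocess.split_train_test(
            d, cfg.preprocess.train_fraction, seeds[2]
        )
        norm = preprocess.LogScaleNormalizer().fit(
            np.asarray(train_raw.X, dtype=np.float64)
        )
        train, _ = preprocess.normalize_log_scale(train_raw, norm)
        test, _ = preprocess.normalize_log_scale(test_raw, norm)
        return train, test

    train, test = _stage("preprocess")(do_preprocess)

    arch = tuple(cfg.classifier.hidden_layer_sizes)
    std_model = _stage("train_standard")(
        lambda: classifier.train_classifier(
            train,
            arch=arch,
            epochs=cfg.classifier.epochs,
            seed=seeds[3],
            batch_size=cfg.classifier.batch_size,
            learning_rate=cfg.classifier.learning_rate,
        )
    )
    std_metrics = classifier.evaluate(std_model, test)

    attack_cfg = attacks.AttackConfig(
        method=cfg.attack.method,
        epsilon=cfg.attack.epsilon,
        alpha=cfg.attack.alpha,
        n_iter=cfg.attack.n_iter,
    )
    robust_model = _stage("adversarial_train")(
        lambda: attacks.adversarial_train(
            train,
            arch=arch,
            attack=attack_cfg,
            mode=cfg.attack.mode,
            epochs=cfg.classifier.epochs,
            seed=seeds[4],
        )
    )
    robust_metrics = classifier.evaluate(robust_model, test)

    sweep_std = _stage("sweep_standard")(
        lambda: attacks.epsilon_sweep(
            std_model, test, cfg.attack.sweep_grid, cfg.attack.method,
            cfg.attack.k_neighbors,
        )
    )
    # both models face the same attack data, crafted against the standard
    # model — the comparison the robustness curves report
    sweep_rob = _stage("sweep_robust")(
        lambda: attacks.epsilon_sweep(
            robust_model, test, cfg.attack.sweep_grid, cfg.attack.method,
            cfg.attack.k_neighbors, attack_model=std_model,
        )
    )

    # attacked accuracy at the training epsilon, on held-out cells
    X_test, y_test = classifier._get_xy(test)
    X_adv = attacks.perturb(std_model, X_test, y_test, attack_cfg)
    attacked_acc = {
        name: float(np.mean(model.predict(X_adv) == y_test))
        for name, model in (("standard", std_model), ("adversarial", robust_model))
    }

    attributions: dict[str, dict[str, interpret.AttributionMatrix]] = {}
    tables: dict[str, consensus.ConsensusTable] = {}
    recovery: dict[str, consensus.RecoveryReport] = {}
    for i, (name, model) in enumerate(
        (("standard", std_model), ("adversarial", robust_model))
    ):
        attributions[name] = _stage(f"explain_{name}")(
            lambda m=model, k=i: interpret.attribution_suite(
                m,
                train,
                methods=cfg.interpret.methods,
                cells_per_type=cfg.interpret.cells_per_type,
                n_coalitions=cfg.interpret.n_coalitions,
                eg_samples=cfg.interpret.eg_samples,
                lime_perturbations=cfg.interpret.lime_perturbations,
                lime_features_kept=cfg.interpret.lime_features_kept,
                seed=seeds[5 + k],
            )
        )
        tables[name] = consensus.consensus_importance(
            attributions[name], cfg.consensus.top_n
        )
        recovery[name] = consensus.key_gene_recovery(
            tables[name], truth, cfg.consensus.top_n, condition=name
        )

    dge = _stage("dge")(lambda: consensus.wilcoxon_dge(train))
    k = min(cfg.consensus.overlap_k, data.n_vars)
    types = list(tables["adversarial"].votes.columns)
    overlap = consensus.overlap_report(
        {ct: tables["adversarial"].top_genes(ct, k) for ct in types},
        {ct: consensus.dge_top_genes(dge, ct, k) for ct in types},
        k,
        n_genes=data.n_vars,
    )

    bundle = ExperimentBundle(
        config=cfg,
        data=data,
        truth=truth,
        train=train,
        test=test,
        standard_model=std_model,
        robust_model=robust_model,
        standard_metrics=std_metrics,
        robust_metrics=robust_metrics,
        sweep_standard=sweep_std,
        sweep_robust=sweep_rob,
        attributions=attributions,
        consensus_tables=tables,
        recovery=recovery,
        dge=dge,
        overlap=overlap,
        attacked_accuracy=attacked_acc,
    )
    if out is not None:
        bundle.manifest = _write_bundle(bundle, out)
    return bundle


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_bundle(bundle: ExperimentBundle, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_tsv(frame: pd.DataFrame, name: str, index: bool = True) -> None:
        p = out / name
        frame.to_csv(p, sep="\t", index=index)
        written.append(p)

    write_matrix(bundle.data, out / "simulated")
    written.extend(sorted((out / "simulated").iterdir()))
    write_key_genes(bundle.truth, out / "key_genes.tsv")
    written.append(out / "key_genes.tsv")

    (out / "config.yaml").write_text(
        __import__("yaml").safe_dump(bundle.config.model_dump())
    )
    written.append(out / "config.yaml")

    save_tsv(bundle.standard_metrics.confusion, "confusion_standard.tsv")
    save_tsv(bundle.robust_metrics.confusion, "confusion_adversarial.tsv")
    save_tsv(bundle.sweep_standard.to_frame(), "sweep_standard.tsv", index=False)
    save_tsv(bundle.sweep_robust.to_frame(), "sweep_adversarial.tsv", index=False)
    for cond, table in bundle.consensus_tables.items():
        save_tsv(table.votes, f"consensus_votes_{cond}.tsv")
    for cond, rep in bundle.recovery.items():
        save_tsv(rep.per_type, f"recovery_{cond}.tsv", index=False)
    save_tsv(bundle.dge, "dge.tsv", index=False)
    save_tsv(
        bundle.overlap[["cell_type", "overlap"]], "overlap.tsv", index=False
    )

    metrics = {
        "clean_accuracy": {
            "standard": bundle.standard_metrics.accuracy,
            "adversarial": bundle.robust_metrics.accuracy,
        },
        "macro_f1": {
            "standard": bundle.standard_metrics.macro_f1,
            "adversarial": bundle.robust_metrics.macro_f1,
        },
        "attacked_accuracy": bundle.attacked_accuracy,
        "recommended_epsilon": bundle.sweep_standard.recommended_epsilon,
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    written.append(out / "metrics.json")

    manifest = {
        "seed": bundle.config.seed,
        "settings": bundle.config.model_dump(),
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
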