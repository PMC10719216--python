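"""Readers, writers and experiment configuration.

Matrices travel as either a Matrix Market triplet directory
(``matrix.mtx`` + ``genes.tsv`` + ``cells.tsv`` + ``labels.tsv``, 1-based
indices per the Matrix Market standard, cells in rows) or a dense TSV with
a header row of gene ids and a first column of cell ids. Configuration is
strict YAML validated through pydantic models; unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError
from scipy import io as spio
from scipy import sparse

from .errors import ConfigError, FormatError
from .simdata import LABEL_KEY

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_key_genes",
    "write_key_genes",
    "ExperimentConfig",
    "load_config",
]


# ------------------------------------------------------------------ matrices
def _check_mtx_header(path: Path) -> None:
    """Verify the declared entry count matches the body before parsing."""
    declared = None
    count = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            if declared is None:
                declared = int(line.split()[2])
                continue
            count += 1
    if declared is None:
        raise FormatError(f"{path}: no Matrix Market size header found")
    if count != declared:
        raise FormatError(
            f"{path}: header declares {declared} entries but file contains {count}"
        )


def write_matrix(data: ad.AnnData, path: str | Path, fmt: str = "mtx") -> None:
    """Write a labeled matrix as an MTX triplet directory or a dense TSV."""
    path = Path(path)
    X = np.asarray(data.X, dtype=np.float64)
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.coo_matrix(X))
        pd.Series(data.var_names).to_csv(
            path / "genes.tsv", sep="\t", index=False, header=False
        )
        pd.Series(data.obs_names).to_csv(
            path / "cells.tsv", sep="\t", index=False, header=False
        )
        if LABEL_KEY in data.obs:
            data.obs[LABEL_KEY].astype(str).to_csv(
                path / "labels.tsv", sep="\t", header=False
            )
    elif fmt == "dense":
        frame = pd.DataFrame(X, index=data.obs_names, columns=data.var_names)
        frame.to_csv(path, sep="\t")
        if LABEL_KEY in data.obs:
            data.obs[LABEL_KEY].astype(str).to_csv(
                Path(str(path) + ".labels.tsv"), sep="\t", header=False
            )
    else:
        raise FormatError(f"unknown matrix format {fmt!r}")


def _read_labels(path: Path, cells: pd.Index) -> pd.Categorical | None:
    if not path.exists():
        return None
    lab = pd.read_csv(path, sep="\t", header=None, index_col=0).iloc[:, 0]
    missing = set(cells) - set(lab.index)
    if missing:
        raise FormatError(f"{path}: labels missing for cells {sorted(missing)[:5]}")
    return pd.Categorical(lab.reindex(cells))


def read_matrix(path: str | Path, raw_counts: bool = False) -> ad.AnnData:
    """Read an MTX triplet directory or a dense TSV back into AnnData."""
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise FormatError(f"{path}: matrix.mtx not found")
        _check_mtx_header(mtx)
        try:
            X = np.asarray(spio.mmread(mtx).todense(), dtype=np.float64)
        except Exception as exc:
            raise FormatError(f"{mtx}: {exc}") from exc
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0]
        cells = pd.read_csv(path / "cells.tsv", sep="\t", header=None)[0]
        if X.shape != (len(cells), len(genes)):
            raise FormatError(
                f"{mtx}: matrix is {X.shape} but index files give "
                f"({len(cells)}, {len(genes)})"
            )
        obs = pd.DataFrame(index=pd.Index(cells.astype(str), name=None))
        labels = _read_labels(path / "labels.tsv", obs.index)
    else:
        frame = pd.read_csv(path, sep="\t", index_col=0)
        X = frame.to_numpy(dtype=np.float64)
        genes = frame.columns
        obs = pd.DataFrame(index=frame.index.astype(str))
        labels = _read_labels(Path(str(path) + ".labels.tsv"), obs.index)
    if raw_counts and X.min() < 0:
        raise FormatError("negative values in a matrix declared as raw counts")
    if labels is not None:
        obs[LABEL_KEY] = labels
    var = pd.DataFrame(index=pd.Index([str(g) for g in genes]))
    return ad.AnnData(X=X, obs=obs, var=var)


def write_key_genes(truth: pd.DataFrame, path: str | Path) -> None:
    truth[["gene", "cell_type"]].to_csv(path, sep="\t", index=False, header=False)


def read_key_genes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["gene", "cell_type"])


# -------------------------------------------------------------------- config
class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimSection(_Strict):
    n_cells: int = 2700
    n_genes: int = 1200
    n_types: int = 9
    n_key_genes: int = 65
    baseline_mean: float = Field(2.0, gt=0)
    fold_elevation: float = Field(5.0, gt=1)
    propagation_strength: float = Field(0.5, ge=0)
    nb_dispersion: float = Field(0.3, ge=0)
    dropout_rate: float = Field(0.3, ge=0, lt=1)


class ImbalanceSection(_Strict):
    enabled: bool = False
    types: list[str] = Field(default_factory=lambda: ["CT1", "CT2", "CT3"])
    removal_fraction: float = Field(0.8, ge=0, le=1)


class PreprocessSection(_Strict):
    apply_hvg: bool = False  # simulated data keeps all genes
    n_top: int = Field(2500, gt=0)
    min_counts: int = Field(30, ge=0)
    train_fraction: float = Field(0.8, gt=0, lt=1)


class ClassifierSection(_Strict):
    hidden_layer_sizes: list[int] = Field(default_factory=lambda: [256, 128])
    epochs: int = Field(30, ge=1)
    batch_size: int = Field(64, ge=1)
    learning_rate: float = Field(1e-3, gt=0)


class AttackSection(_Strict):
    method: str = "fgsm"
    epsilon: float = Field(1.0, ge=0)
    alpha: float | None = Field(None, gt=0)
    n_iter: int = Field(10, ge=1)
    mode: str = "static"
    sweep_grid: list[float] = Field(
        default_factory=lambda: [round(0.2 * i, 1) for i in range(17)]
    )
    k_neighbors: int = Field(15, ge=1)


class InterpretSection(_Strict):
    methods: list[str] = Field(
        default_factory=lambda: [
            "saliency",
            "actmax",
            "deeplift",
            "expgrad",
            "kernelshap",
            "lime",
        ]
    )
    cells_per_type: int = Field(5, ge=1)
    n_coalitions: int = Field(2048, ge=2)
    eg_samples: int = Field(100, ge=1)
    lime_perturbations: int = Field(1000, ge=10)
    lime_features_kept: int = Field(50, ge=1)


class ConsensusSection(_Strict):
    top_n: int = Field(20, ge=1)
    overlap_k: int = Field(100, ge=1)


class ExperimentConfig(_Strict):
    """Full nested experiment configuration with validated defaults."""

    seed: int = 0
    out_dir: str | None = None
    sim: SimSection = Field(default_factory=SimSection)
    imbalance: ImbalanceSection = Field(default_factory=ImbalanceSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    classifier: ClassifierSection = Field(default_factory=ClassifierSection)
    attack: AttackSection = Field(default_factory=AttackSection)
    interpret: InterpretSection = Field(default_factory=InterpretSection)
    consensus: ConsensusSection = Field(default_factory=ConsensusSection)


def load_config(path: str | Path | None = None) -> ExperimentConfig:
    """Parse and validate a YAML config; an empty/absent file means defaults."""
    payload = {}
    if path is not None:
        text = Path(path).read_text()
        payload = yaml.safe_load(text) or {}
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return ExperimentConfig(**payload)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
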