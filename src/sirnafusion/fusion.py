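"""Two-stage score-level fusion of the two siRNA representations.

Stage 1 fits one epsilon-SVR per representation: a linear-kernel SVR on the
selected quantitative features (standardized) and an RBF-kernel SVR on the raw
qualitative codes. Each maps its representation to a scalar predicted score
(S_Qt, S_Ql). Stage 2 fits a linear-kernel SVR on the score pair to produce
the final efficacy prediction.

To keep stage 2 from learning through leaked in-sample fits, its training
inputs are out-of-fold stage-1 scores: record i's score comes from a stage-1
model trained with fold(i) held out (k-fold, seeded assignment). The final
stage-1 models served at prediction time are refit on the full training data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .evaluation import pearson

SUPPORTED_KERNELS = ("linear", "poly", "polynomial", "rbf", "sigmoid")

DEFAULT_HYPER = {"C": 1.0, "epsilon": 0.1}


def _make_svr(kernel: str, hyper: dict | None = None, standardize: bool = False):
    hyper = {**DEFAULT_HYPER, **(hyper or {})}
    if kernel == "polynomial":
        kernel = "poly"
    if kernel not in ("linear", "poly", "rbf", "sigmoid"):
        raise ValueError(f"unsupported kernel {kernel!r}; expected one of "
                         f"{SUPPORTED_KERNELS}")
    svr = SVR(kernel=kernel, gamma=hyper.pop("gamma", "auto"), **hyper)
    if standardize:
        return Pipeline([("scale", StandardScaler()), ("svr", svr)])
    return svr


def train_stage1(
    features: np.ndarray,
    targets: Sequence[float],
    kernel: str = "linear",
    hyper: dict | None = None,
    standardize: bool = False,
):
    """Fit one epsilon-SVR branch. gamma defaults to 1/p ('auto') for RBF."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features and targets must align")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 training records")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in training data")
    model = _make_svr(kernel, hyper, standardize=standardize)
    model.fit(X, y)
    return model


def out_of_fold_scores(
    features: np.ndarray,
    targets: Sequence[float],
    kernel: str,
    hyper: dict | None = None,
    k: int = 10,
    seed: int = 0,
    standardize: bool = False,
) -> np.ndarray:
    """Cross-validated stage-1 scores: record i scored by a model that never
    saw fold(i). Fold assignment is a seeded shuffle, identical across calls
    with the same seed."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    n = X.shape[0]
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError(f"more folds ({k}) than records ({n})")
    scores = np.empty(n)
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in folds.split(X):
        model = _make_svr(kernel, dict(hyper or {}), standardize=standardize)
        model.fit(X[train_idx], y[train_idx])
        scores[test_idx] = model.predict(X[test_idx])
    return scores


@dataclass
class FusionModel:
    """The fitted two-stage predictor plus everything needed to apply it."""

    stage1_quant: object
    stage1_qual: object
    stage2: object
    selected_indices: np.ndarray
    hyperparameters: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def score_pair(self, quant: np.ndarray, qual: np.ndarray) -> np.ndarray:
        """Stage-1 scores (n x 2): columns S_Qt, S_Ql."""
        quant = np.atleast_2d(np.asarray(quant, dtype=float))
        qual = np.atleast_2d(np.asarray(qual, dtype=float))
        masked = quant[:, self.selected_indices]
        s_qt = self.stage1_quant.predict(masked)
        s_ql = self.stage1_qual.predict(qual)
        return np.column_stack([s_qt, s_ql])

    def predict(self, quant: np.ndarray, qual: np.ndarray) -> np.ndarray:
        """Fused efficacy prediction for full-width (275 / 103) inputs."""
        quant = np.atleast_2d(np.asarray(quant, dtype=float))
        qual = np.atleast_2d(np.asarray(qual, dtype=float))
        if quant.shape[0] != qual.shape[0]:
            raise ValueError("row mismatch between representations")
        if qual.shape[1] != self.metadata.get("qual_dim", qual.shape[1]):
            raise ValueError(
                f"qualitative vector width {qual.shape[1]} != "
                f"{self.metadata['qual_dim']}"
            )
        if quant.shape[1] <= int(self.selected_indices.max()):
            raise ValueError("quantitative vector narrower than the feature mask")
        return self.stage2.predict(self.score_pair(quant, qual))

    def save(self, path: str | Path) -> None:
        """Serialize as a bundle directory: JSON metadata + joblib regressors."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "selected_indices": self.selected_indices.tolist(),
            "hyperparameters": self.hyperparameters,
            "metadata": self.metadata,
        }
        (path / "fusion.json").write_text(json.dumps(meta, indent=1))
        joblib.dump(self.stage1_quant, path / "stage1_quant.joblib")
        joblib.dump(self.stage1_qual, path / "stage1_qual.joblib")
        joblib.dump(self.stage2, path / "stage2.joblib")

    @classmethod
    def load(cls, path: str | Path) -> "FusionModel":
        path = Path(path)
        meta = json.loads((path / "fusion.json").read_text())
        return cls(
            stage1_quant=joblib.load(path / "stage1_quant.joblib"),
            stage1_qual=joblib.load(path / "stage1_qual.joblib"),
            stage2=joblib.load(path / "stage2.joblib"),
            selected_indices=np.asarray(meta["selected_indices"], dtype=int),
            hyperparameters=meta["hyperparameters"],
            metadata=meta["metadata"],
        )


def train_fusion(
    quant: np.ndarray,
    qual: np.ndarray,
    targets: Sequence[float],
    selected_indices: Sequence[int] | None = None,
    kernels: tuple[str, str, str] = ("linear", "rbf", "linear"),
    hyper: dict | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> FusionModel:
    """Fit the full two-stage fusion model.

    ``quant`` is the full-width quantitative matrix; ``selected_indices``
    restricts it (default: all columns). Stage-1 models are refit on all
    training rows; stage 2 is fit on their out-of-fold score pairs.
    """
    quant = np.asarray(quant, dtype=float)
    qual = np.asarray(qual, dtype=float)
    y = np.asarray(targets, dtype=float)
    if not (quant.shape[0] == qual.shape[0] == y.shape[0]):
        raise ValueError("row mismatch between representations and targets")
    if selected_indices is None:
        selected_indices = np.arange(quant.shape[1])
    selected_indices = np.asarray(selected_indices, dtype=int)
    masked = quant[:, selected_indices]
    k_qt, k_ql, k_fuse = kernels

    oof_qt = out_of_fold_scores(masked, y, k_qt, hyper, k=n_folds, seed=seed,
                                standardize=True)
    oof_ql = out_of_fold_scores(qual, y, k_ql, hyper, k=n_folds, seed=seed)
    score_pairs = np.column_stack([oof_qt, oof_ql])

    model = FusionModel(
        stage1_quant=train_stage1(masked, y, k_qt, hyper, standardize=True),
        stage1_qual=train_stage1(qual, y, k_ql, hyper),
        stage2=train_stage1(score_pairs, y, k_fuse, hyper),
        selected_indices=selected_indices,
        hyperparameters={**DEFAULT_HYPER, **(hyper or {})},
        metadata={
            "kernels": list(kernels),
            "n_folds": n_folds,
            "seed": seed,
            "quant_dim": int(quant.shape[1]),
            "qual_dim": int(qual.shape[1]),
            "oof_scores": score_pairs.tolist(),
        },
    )
    return model


def kernel_sweep(
    features: np.ndarray,
    targets: Sequence[float],
    eval_features: np.ndarray,
    eval_targets: Sequence[float],
    kernels: Sequence[str] = ("linear", "polynomial", "rbf", "sigmoid"),
    input_name: str = "features",
    hyper: dict | None = None,
    standardize: bool = False,
) -> list[tuple[str, str, float]]:
    """Train one SVR per kernel and report held-out PCC per (input, kernel)."""
    if not kernels:
        raise ValueError("empty kernel list")
    rows = []
    for kernel in kernels:
        model = train_stage1(features, targets, kernel, hyper, standardize=standardize)
        predictions = model.predict(np.asarray(eval_features, dtype=float))
        try:
            pcc = pearson(predictions, eval_targets)
        except ValueError:  # degenerate (constant) predictions
            pcc = float("nan")
        rows.append((input_name, kernel, pcc))
    return rows
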