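"""Network ensembles, dual-output hit calling, and performance metrics.

Ten independently seeded networks are trained on the same matrix; a
compound is a virtual hit only when the (member-mean) active output clears
a high cutoff (default 0.95) AND the inactive output stays under a low one
(default 0.05). Requiring both outputs weights the screen for specificity,
which is what makes screening a multi-million-compound library practical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import scg
from .scg import MLPModel, MLPParams

logger = logging.getLogger("senscreen")


@dataclass
class ConfusionMatrix:
    """Binary classification counts with chance-corrected agreement."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def p_observed(self) -> float:
        return self.accuracy

    @property
    def p_expected(self) -> float:
        n = self.n
        pred_pos = (self.tp + self.fp) / n
        true_pos = (self.tp + self.fn) / n
        return pred_pos * true_pos + (1 - pred_pos) * (1 - true_pos)

    @property
    def kappa(self) -> float:
        pe = self.p_expected
        if pe == 1.0:
            return 0.0
        return (self.p_observed - pe) / (1.0 - pe)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def confusion(predictions, labels) -> ConfusionMatrix:
    """Counts from predicted and true binary labels (1 = active)."""
    predictions = np.asarray(predictions).astype(int)
    labels = np.asarray(labels).astype(int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    if predictions.size == 0:
        raise ValueError("empty input")
    return ConfusionMatrix(
        tp=int(np.sum((predictions == 1) & (labels == 1))),
        fp=int(np.sum((predictions == 1) & (labels == 0))),
        tn=int(np.sum((predictions == 0) & (labels == 0))),
        fn=int(np.sum((predictions == 0) & (labels == 1))),
    )


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc(scores, labels) -> ROCCurve:
    """ROC by threshold sweep over the unique scores (ties grouped).

    AUC by the trapezoid rule; equals the pairwise concordance probability
    (Mann-Whitney), with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # group ties: cumulative counts at each distinct threshold
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    cum_tp = np.cumsum(sorted_labels)[distinct]
    cum_fp = np.cumsum(1 - sorted_labels)[distinct]
    tpr = np.r_[0.0, cum_tp / n_pos]
    fpr = np.r_[0.0, cum_fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(
        thresholds=np.r_[np.inf, sorted_scores[distinct]], tpr=tpr, fpr=fpr, auc=auc
    )


# ---------------------------------------------------------------------------
# Ensemble


@dataclass
class EnsembleModel:
    members: list[MLPModel]
    theta_active: float = 0.95
    theta_inactive: float = 0.05
    aggregation: str = "mean_outputs"  # or "unanimous"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if not (0 < self.theta_inactive < self.theta_active < 1):
            raise ValueError("require 0 < theta_inactive < theta_active < 1")
        if self.aggregation not in {"mean_outputs", "unanimous"}:
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


def train_ensemble(
    X: np.ndarray,
    Y: np.ndarray,
    params: MLPParams,
    n_members: int = 10,
    base_seed: int = 0,
    theta_active: float = 0.95,
    theta_inactive: float = 0.05,
    aggregation: str = "mean_outputs",
) -> EnsembleModel:
    """Train ``n_members`` networks with seeds base_seed .. base_seed+n-1.

    A member whose training diverges is reported and dropped; the ensemble
    is still returned while at least one member trained.
    """
    members = []
    labels = (np.asarray(Y)[:, 0] >= np.asarray(Y)[:, 1]).astype(int)
    for i in range(n_members):
        import dataclasses

        member_params = dataclasses.replace(params, seed=base_seed + i)
        try:
            model = scg.fit(X, Y, member_params)
        except FloatingPointError as exc:
            logger.warning("ensemble member %d failed to train: %s", i, exc)
            continue
        out = scg.forward(model, X)
        cm = confusion((out[:, 0] >= out[:, 1]).astype(int), labels)
        logger.info(
            "member %d (seed %d): training accuracy %.3f, kappa %.3f",
            i, member_params.seed, cm.accuracy, cm.kappa,
        )
        members.append(model)
    if not members:
        raise RuntimeError("no ensemble member trained successfully")
    return EnsembleModel(
        members=members,
        theta_active=theta_active,
        theta_inactive=theta_inactive,
        aggregation=aggregation,
    )


def ensemble_scores(ensemble: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Member-mean outputs, shape (n, 2)."""
    outs = np.stack([scg.forward(m, X) for m in ensemble.members])
    return outs.mean(axis=0)


def classify_hits(ensemble: EnsembleModel, X: np.ndarray, ids=None) -> pd.DataFrame:
    """Score compounds and call hits under the dual-output cutoffs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    outs = np.stack([scg.forward(m, X) for m in ensemble.members])
    mean_out = outs.mean(axis=0)
    if ensemble.aggregation == "mean_outputs":
        is_hit = (mean_out[:, 0] >= ensemble.theta_active) & (
            mean_out[:, 1] <= ensemble.theta_inactive
        )
    else:  # unanimous: every member must pass both cutoffs
        is_hit = np.all(
            (outs[:, :, 0] >= ensemble.theta_active)
            & (outs[:, :, 1] <= ensemble.theta_inactive),
            axis=0,
        )
    return pd.DataFrame(
        {
            "id": list(ids) if ids is not None else list(range(X.shape[0])),
            "score_active": mean_out[:, 0],
            "score_inactive": mean_out[:, 1],
            "is_hit": is_hit,
        }
    )


def summed_cv_confusion(
    X: np.ndarray, Y: np.ndarray, ensemble: EnsembleModel, k: int = 10, seed: int = 0
) -> ConfusionMatrix:
    """Summed confusion matrix over all members' validation folds.

    Each member's architecture/seed is cross-validated and the per-fold
    confusions are summed across folds and members — a reporting
    convention: quadrant counts then total members x N.
    """
    total: ConfusionMatrix | None = None
    for member in ensemble.members:
        report = scg.kfold_cv(X, Y, member.params, k=k, seed=seed)
        for cm in report.fold_confusions:
            total = cm if total is None else total + cm
    assert total is not None
    return total


def screen_library(
    ensemble: EnsembleModel,
    library_matrix: np.ndarray,
    ids=None,
    batch_size: int = 2048,
) -> pd.DataFrame:
    """Stream a featurized library through the ensemble in batches."""
    X = np.asarray(library_matrix, dtype=float)
    if X.size and X.shape[1] != ensemble.members[0].params.n_inputs:
        raise ValueError("library descriptors do not match the training set")
    if ids is None:
        ids = list(range(X.shape[0]))
    frames = []
    for start in range(0, X.shape[0], batch_size):
        stop = min(start + batch_size, X.shape[0])
        frames.append(classify_hits(ensemble, X[start:stop], ids=list(ids)[start:stop]))
    if not frames:
        return pd.DataFrame(columns=["id", "score_active", "score_inactive", "is_hit"])
    table = pd.concat(frames, ignore_index=True)
    logger.info(
        "screened %d structures: %d hits (%.3f%%)",
        len(table), int(table.is_hit.sum()), 100 * table.is_hit.mean() if len(table) else 0.0,
    )
    return table
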