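"""Posterior-predictive classification of new subjects.

Each retained MCMC draw (alpha0, beta) is pushed through the logistic link
to give a draw of P(Y = 1 | x); the collection over draws is the subject's
predictive distribution, its mean the point estimate, and thresholding the
mean gives the label.

Test subjects are standardized per gene with the *pooled* training mean and
SD: the group-specific statistics used during training would require the
very label being predicted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ExpressionDataset, StandardizedDataset
from .screening import ScreenSet
from .ssl_posterior import PosteriorDraws

__all__ = [
    "PredictiveDistribution",
    "posterior_predictive",
    "classify_batch",
    "classification_metrics",
]


@dataclass(frozen=True)
class PredictiveDistribution:
    """Per-draw class-1 probabilities for one subject."""

    probabilities: np.ndarray
    cutoff: float = 0.5

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("predictive probabilities must lie in [0, 1]")

    @property
    def point_estimate(self) -> float:
        return float(self.probabilities.mean())

    @property
    def label(self) -> int:
        return int(self.point_estimate >= self.cutoff)

    def quantiles(self, q=(0.025, 0.975)) -> np.ndarray:
        return np.quantile(self.probabilities, q)


def posterior_predictive(
    draws: PosteriorDraws, design_row: np.ndarray, cutoff: float = 0.5
) -> PredictiveDistribution:
    """Predictive distribution for one subject's interaction products."""
    z = np.asarray(design_row, dtype=float).reshape(-1)
    beta = draws.beta_flat
    if z.shape[0] != beta.shape[1]:
        raise ValueError(
            f"design row has {z.shape[0]} products but the model has {beta.shape[1]}"
        )
    eta = draws.alpha0_flat + beta @ z
    return PredictiveDistribution(probabilities=1.0 / (1.0 + np.exp(-eta)), cutoff=cutoff)


def _standardize_test(
    test: ExpressionDataset, train: StandardizedDataset
) -> np.ndarray:
    """Map test genes onto training columns and z-score with pooled stats."""
    missing = [g for g in train.gene_names if g not in test.gene_names]
    if missing:
        raise ValueError(f"test data lacks training genes: {missing}")
    col = {g: i for i, g in enumerate(test.gene_names)}
    order = [col[g] for g in train.gene_names]
    values = test.values[:, order]
    return (values - train.pooled_means) / train.pooled_sds


def classify_batch(
    draws: PosteriorDraws,
    test_data: ExpressionDataset,
    screen: ScreenSet,
    train_standardization: StandardizedDataset,
    cutoff: float = 0.5,
) -> tuple[np.ndarray, list]:
    """Predict group labels for a batch of test subjects.

    Returns (labels, predictive distributions), one per subject, in the test
    data's row order.
    """
    x = _standardize_test(test_data, train_standardization)
    dists = []
    for i in range(x.shape[0]):
        row = np.array([x[i, j] * x[i, k] for j, k in screen.pairs])
        dists.append(posterior_predictive(draws, row, cutoff=cutoff))
    labels = np.array([d.label for d in dists], dtype=int)
    return labels, dists


def classification_metrics(predicted, truth) -> dict:
    """Accuracy and F1 (group 1 as the positive class).

    F1 = 2 TP / (2 TP + FP + FN); returns 0 when the denominator vanishes.
    """
    predicted = np.asarray(predicted, dtype=int).reshape(-1)
    truth = np.asarray(truth, dtype=int).reshape(-1)
    if predicted.size == 0:
        raise ValueError("empty predictions")
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth lengths differ")
    tp = int(np.sum((predicted == 1) & (truth == 1)))
    fp = int(np.sum((predicted == 1) & (truth == 0)))
    fn = int(np.sum((predicted == 0) & (truth == 1)))
    accuracy = float(np.mean(predicted == truth))
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return {"accuracy": accuracy, "F1": f1, "TP": tp, "FP": fp, "FN": fn}


def predictions_frame(test_data: ExpressionDataset, dists) -> pd.DataFrame:
    """Tabulate per-subject point probability, 95% predictive band, label."""
    rows = []
    for sid, d in zip(test_data.sample_ids, dists):
        lo, hi = d.quantiles()
        rows.append((sid, d.point_estimate, lo, hi, d.label))
    return pd.DataFrame(
        rows, columns=["subject", "probability", "q2.5", "q97.5", "label"]
    )
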