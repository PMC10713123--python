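"""Edge-recovery metrics for an estimated differential network.

The candidate universe is all phi = P(P-1)/2 gene pairs, so pairs that were
never screened still count as negatives (a missed true edge is a false
negative regardless of where it was lost).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .screening import n_pairs

__all__ = ["PerformanceReport", "recovery_metrics"]


@dataclass(frozen=True)
class PerformanceReport:
    """Confusion counts over all candidate pairs plus derived scores.

    Zero-denominator conventions (flagged via ``degenerate``): FDR = 0 when
    nothing is called, SEN = 0 when there are no true edges, SPE = 0 when
    every pair is a true edge, MCC = 0 when any confusion-matrix marginal
    vanishes.
    """

    TP: int
    FP: int
    FN: int
    TN: int
    SEN: float
    SPE: float
    FDR: float
    MCC: float
    F1: float
    degenerate: tuple = ()

    @property
    def phi(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("TP", "FP", "FN", "TN", "SEN", "SPE", "FDR", "MCC", "F1")
        }


def _normalize_pairs(pairs) -> set:
    out = set()
    for j, k in pairs:
        if j == k:
            raise ValueError(f"self-pair ({j}, {k})")
        out.add(tuple(sorted((j, k))))
    return out


def recovery_metrics(true_edges, estimated_edges, P: int) -> PerformanceReport:
    """Score an estimated edge set against the truth over all P(P-1)/2 pairs.

    F1 = 2 TP / (2 TP + FP + FN); SEN = TP/(TP+FN); SPE = TN/(TN+FP);
    FDR = FP/(TP+FP); MCC by its standard formula.
    """
    phi = n_pairs(P)
    truth = _normalize_pairs(true_edges)
    est = _normalize_pairs(estimated_edges)
    if len(truth) > phi or len(est) > phi:
        raise ValueError("edge set larger than the candidate universe")

    tp = len(truth & est)
    fp = len(est - truth)
    fn = len(truth - est)
    tn = phi - tp - fp - fn
    if tn < 0:
        raise ValueError("edge sets are not subsets of the P(P-1)/2 candidate pairs")

    degenerate = []

    def ratio(num, den, name):
        if den:
            return num / den
        degenerate.append(name)
        return 0.0

    sen = ratio(tp, tp + fn, "SEN")
    spe = ratio(tn, tn + fp, "SPE")
    fdr = ratio(fp, tp + fp, "FDR")
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = ratio(tp * tn - fp * fn, math.sqrt(mcc_den) if mcc_den else 0, "MCC")
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "F1")

    return PerformanceReport(
        TP=tp, FP=fp, FN=fn, TN=tn,
        SEN=sen, SPE=spe, FDR=fdr, MCC=mcc, F1=f1,
        degenerate=tuple(degenerate),
    )
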