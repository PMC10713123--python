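"""Stage 1: correlation-difference screening of candidate gene pairs.

For P genes there are phi = P(P-1)/2 candidate interactions. The screen
computes the sample Pearson correlation of every pair within each group,
ranks the pairs by the absolute between-group difference
Delta_jk = rho_jk(group 1) - rho_jk(group 0), and retains the top S. Only
the retained pairs enter the Bayesian interaction model, which keeps the
MCMC affordable while concentrating on pairs whose co-expression actually
rewires between conditions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import ExpressionDataset

__all__ = [
    "GroupCorrelations",
    "DeltaTable",
    "ScreenSet",
    "group_correlations",
    "correlation_difference",
    "choose_S",
    "screen_top_S",
    "n_pairs",
]


def n_pairs(p: int) -> int:
    """phi = P(P-1)/2, the number of candidate gene pairs."""
    return p * (p - 1) // 2


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class GroupCorrelations:
    """Per-group P x P sample Pearson correlation matrices."""

    rho1: np.ndarray
    rho0: np.ndarray
    n1: int
    n0: int

    def __post_init__(self):
        for name, rho in (("rho1", self.rho1), ("rho0", self.rho0)):
            if not np.allclose(rho, rho.T):
                raise ValueError(f"{name} not symmetric")
            if not np.allclose(np.diag(rho), 1.0):
                raise ValueError(f"{name} diagonal not 1")
            if np.any(np.abs(rho) > 1 + 1e-12):
                raise ValueError(f"{name} has entries outside [-1, 1]")


@dataclass(frozen=True)
class DeltaTable:
    """Between-group correlation differences over all candidate pairs.

    ``delta`` maps (j, k) with j < k (0-based gene indices) to
    Delta_jk = rho1_jk - rho0_jk.
    """

    delta: dict
    p: int

    @property
    def pair_count(self) -> int:
        return n_pairs(self.p)

    def __post_init__(self):
        if len(self.delta) != self.pair_count:
            raise ValueError(
                f"expected {self.pair_count} pairs for P={self.p}, got {len(self.delta)}"
            )
        for (j, k), d in self.delta.items():
            if not j < k:
                raise ValueError(f"pair {(j, k)} not ordered j < k")
            if abs(d) > 2 + 1e-12:
                raise ValueError(f"|Delta| > 2 for pair {(j, k)}")


@dataclass(frozen=True)
class ScreenSet:
    """The S retained pairs, ranked by |Delta| descending."""

    pairs: tuple
    deltas: tuple
    selection_strategy: str = "explicit"

    @property
    def S(self) -> int:
        return len(self.pairs)


def group_correlations(data: ExpressionDataset) -> GroupCorrelations:
    """Sample Pearson correlation matrices, one per group.

    Each group needs at least 3 subjects (2 degrees of freedom). Correlations
    are unaffected by the within-group standardization, so raw or
    standardized data give identical results.
    """
    mats = {}
    ns = {}
    for g in (0, 1):
        block = data.group_values(g)
        if block.shape[0] < 3:
            raise ValueError(f"group {g} has {block.shape[0]} samples; need >= 3")
        sd = block.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            bad = [data.gene_names[j] for j in np.flatnonzero(sd <= 0)]
            raise ValueError(f"zero variance within group {g} for genes: {bad}")
        rho = np.corrcoef(block, rowvar=False)
        np.fill_diagonal(rho, 1.0)
        mats[g] = np.clip(rho, -1.0, 1.0)
        ns[g] = block.shape[0]
    return GroupCorrelations(rho1=mats[1], rho0=mats[0], n1=ns[1], n0=ns[0])


def correlation_difference(corr: GroupCorrelations) -> DeltaTable:
    """Delta_jk = rho1_jk - rho0_jk for every pair j < k."""
    p = corr.rho1.shape[0]
    diff = corr.rho1 - corr.rho0
    delta = {(j, k): float(diff[j, k]) for j in range(p) for k in range(j + 1, p)}
    return DeltaTable(delta=delta, p=p)


def choose_S(
    strategy: str,
    N: int | None = None,
    P: int | None = None,
    fraction: float | None = None,
    S: int | None = None,
) -> int:
    """Number of pairs to retain.

    Strategies
    ----------
    ``n_ratio``
        Integer closest to N / P (round half up), pooled sample size over
        node count.
    ``sparsity_fraction``
        fraction * P(P-1)/2 rounded half up; the fraction reflects a prior
        bound on differential-network sparsity (typically 0.05 or 0.10).
    ``explicit``
        Use ``S`` directly.

    The result is clipped to [1, phi].
    """
    if P is None or P < 2:
        raise ValueError("P >= 2 required")
    phi = n_pairs(P)
    if strategy == "n_ratio":
        if N is None or N < 2:
            raise ValueError("n_ratio strategy needs the pooled sample size N >= 2")
        s = _round_half_up(N / P)
    elif strategy == "sparsity_fraction":
        if fraction is None or not (0 < fraction <= 1):
            raise ValueError("fraction must lie in (0, 1]")
        s = _round_half_up(fraction * phi)
    elif strategy == "explicit":
        if S is None or S < 1:
            raise ValueError("explicit strategy needs S >= 1")
        s = S
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return max(1, min(s, phi))


def screen_top_S(delta: DeltaTable, S: int, strategy: str = "explicit") -> ScreenSet:
    """Retain the S pairs with the largest |Delta_jk|.

    Ties in |Delta| are broken by lexicographic (j, k) order so the screen is
    deterministic. Asking for more pairs than exist returns all of them with
    a warning.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    phi = delta.pair_count
    if S > phi:
        warnings.warn(f"S={S} exceeds the {phi} candidate pairs; returning all")
        S = phi
    ranked = sorted(delta.delta.items(), key=lambda item: (-abs(item[1]), item[0]))
    top = ranked[:S]
    return ScreenSet(
        pairs=tuple(pair for pair, _ in top),
        deltas=tuple(d for _, d in top),
        selection_strategy=strategy,
    )
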