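"""Two-group Gaussian graphical model simulator with a known differential network.

Each group's expression vector is multivariate normal with mean zero and a
structured precision matrix Omega = Sigma^-1 built from an adjacency
structure and partial-correlation targets. Three families of scenarios are
supported, mirroring the standard ways a differential network arises:

* structural difference - one group's network lacks every edge incident to a
  chosen node (e.g. a knocked-out hub), so the differential edges are exactly
  that node's edges;
* intensity/sign difference - both groups share the structure but a subset of
  edges carries precision entries of opposite sign (+w vs -w), giving a true
  differential intensity of 2w;
* order difference - an AR(1) chain versus an AR(2) band, whose difference is
  exactly the set of second-order neighbor pairs.

``run_scenario`` drives the full pipeline (simulate -> screen -> Bayesian
model -> threshold -> score) over replicates.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg

from .data_model import ExpressionDataset, standardize_within_group
from .evaluation import PerformanceReport, recovery_metrics
from .screening import (
    choose_S,
    correlation_difference,
    group_correlations,
    screen_top_S,
)
from .ssl_posterior import (
    MCMCConfig,
    SSLPrior,
    build_interaction_design,
    sample_posterior,
    summarize_posterior,
)

__all__ = [
    "NetworkSpec",
    "AdjacencyPair",
    "ConstructionRecord",
    "PrecisionPair",
    "TrueDNet",
    "ScenarioConfig",
    "ScenarioReport",
    "make_adjacency",
    "adjacency_to_precision",
    "build_precision_pair",
    "sample_group_data",
    "true_dnet",
    "run_scenario",
    "jak_stat_like_network",
    "scenario_structural",
    "scenario_sign_flip",
    "scenario_ar",
]

PD_EIG_TOL = 1e-8


@dataclass(frozen=True)
class NetworkSpec:
    """Generative description of the group-1 network and its modification.

    structure : {"ar1", "ar2", "edge_list"}
    edges : required for edge_list, pairs of 0-based node indices
    modification : {"none", "remove_node_edges", "flip_sign"} - how group 0
        differs from group 1.
    mod_node : node index whose incident edges are removed (remove_node_edges)
    mod_edges : edge subset whose precision entries flip sign (flip_sign)
    weight : partial-correlation target for ordinary edges
    weight2 : second-order target (ar2 only)
    flip_weight : magnitude of the signed precision entry on flipped edges
    """

    P: int
    structure: str = "edge_list"
    edges: tuple = ()
    node_names: tuple = ()
    modification: str = "none"
    mod_node: int | None = None
    mod_edges: tuple = ()
    weight: float = 0.2
    weight2: float = 0.22
    flip_weight: float = 0.11

    def __post_init__(self):
        if self.structure not in ("ar1", "ar2", "edge_list"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.modification not in ("none", "remove_node_edges", "flip_sign"):
            raise ValueError(f"unknown modification {self.modification!r}")
        edges = tuple(tuple(sorted(e)) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "mod_edges", tuple(tuple(sorted(e)) for e in self.mod_edges))
        names = tuple(self.node_names) or tuple(f"g{i + 1}" for i in range(self.P))
        if len(names) != self.P:
            raise ValueError("node_names length must equal P")
        object.__setattr__(self, "node_names", names)
        for j, k in edges:
            if j == k:
                raise ValueError("self-loops are not allowed")
            if not (0 <= j < self.P and 0 <= k < self.P):
                raise ValueError(f"edge ({j}, {k}) references an unknown node")
        if len(set(edges)) != len(edges):
            raise ValueError("duplicate edges")

    def all_edges(self) -> tuple:
        """The group-1 edge set implied by the structure."""
        if self.structure == "ar1":
            return tuple((i, i + 1) for i in range(self.P - 1))
        if self.structure == "ar2":
            return tuple((i, i + 1) for i in range(self.P - 1)) + tuple(
                (i, i + 2) for i in range(self.P - 2)
            )
        return self.edges


@dataclass(frozen=True)
class AdjacencyPair:
    """Signed partial-correlation target matrices for the two groups."""

    weights1: np.ndarray  # P x P, zero off the edge pattern
    weights0: np.ndarray
    node_names: tuple


@dataclass(frozen=True)
class ConstructionRecord:
    """How a precision matrix was built and what was actually realized."""

    targets: np.ndarray
    adjusted: bool
    shift: float
    min_eigenvalue_before: float
    realized_partial_correlations: np.ndarray


@dataclass(frozen=True)
class PrecisionPair:
    omega1: np.ndarray
    omega0: np.ndarray
    record1: ConstructionRecord
    record0: ConstructionRecord
    node_names: tuple = ()

    def __post_init__(self):
        for name, om in (("omega1", self.omega1), ("omega0", self.omega0)):
            if not np.allclose(om, om.T):
                raise ValueError(f"{name} not symmetric")
            if scipy.linalg.eigvalsh(om)[0] <= 0:
                raise ValueError(f"{name} is not positive definite")


@dataclass(frozen=True)
class TrueDNet:
    """Ground-truth differential edges: where the two precisions differ."""

    edges: tuple  # (j, k) index pairs
    omega1_values: tuple
    omega0_values: tuple
    diff: tuple  # omega1 - omega0 per edge (signed)
    tol: float

    @property
    def intensity(self) -> tuple:
        """Absolute differential intensity |omega1_jk - omega0_jk| per edge."""
        return tuple(abs(d) for d in self.diff)


def _weights_matrix(P: int, edges, value) -> np.ndarray:
    w = np.zeros((P, P))
    for j, k in edges:
        w[j, k] = w[k, j] = value
    return w


def make_adjacency(spec: NetworkSpec) -> AdjacencyPair:
    """Signed partial-correlation targets for (group 1, group 0).

    ``remove_node_edges`` deletes every edge incident to ``mod_node`` from
    group 0; ``flip_sign`` keeps the structure but negates the target on
    ``mod_edges`` (magnitude ``flip_weight``) between groups.
    """
    edges = spec.all_edges()
    if spec.structure == "ar2":
        w1 = _weights_matrix(spec.P, [(i, i + 1) for i in range(spec.P - 1)], spec.weight)
        w1 += _weights_matrix(spec.P, [(i, i + 2) for i in range(spec.P - 2)], spec.weight2)
    else:
        w1 = _weights_matrix(spec.P, edges, spec.weight)

    if spec.modification == "none":
        w0 = w1.copy()
    elif spec.modification == "remove_node_edges":
        node = spec.mod_node
        if node is None or not (0 <= node < spec.P):
            raise ValueError(f"unknown node {node!r} for remove_node_edges")
        w0 = w1.copy()
        w0[node, :] = 0.0
        w0[:, node] = 0.0
    else:  # flip_sign
        if not spec.mod_edges:
            raise ValueError("flip_sign needs a non-empty mod_edges subset")
        edge_set = set(edges)
        for e in spec.mod_edges:
            if e not in edge_set:
                raise ValueError(f"flip edge {e} is not in the network")
        w0 = w1.copy()
        for j, k in spec.mod_edges:
            w1[j, k] = w1[k, j] = spec.flip_weight
            w0[j, k] = w0[k, j] = -spec.flip_weight
    return AdjacencyPair(weights1=w1, weights0=w0, node_names=spec.node_names)


def adjacency_to_precision(
    weights: np.ndarray, pd_adjust: str = "shift"
) -> tuple[np.ndarray, ConstructionRecord]:
    """Precision matrix from signed partial-correlation targets.

    With unit diagonal, the off-diagonal entry for target rho is
    omega_jk = -rho, so the realized partial correlation
    -omega_jk / sqrt(omega_jj * omega_kk) equals rho exactly whenever no
    positive-definiteness adjustment is needed.

    When the raw matrix is not PD and ``pd_adjust="shift"``, |lambda_min| +
    0.05 is added to the diagonal and the matrix rescaled back to unit
    diagonal, which shrinks all realized partial correlations by the same
    factor; the record carries the shift and realized values.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(np.abs(weights) >= 1):
        raise ValueError("partial-correlation targets must satisfy |rho| < 1")
    if not np.allclose(weights, weights.T):
        raise ValueError("weights must be symmetric")
    P = weights.shape[0]
    omega = np.eye(P) - weights
    np.fill_diagonal(omega, 1.0)
    min_eig = float(scipy.linalg.eigvalsh(omega)[0])
    shift = 0.0
    adjusted = False
    if min_eig <= PD_EIG_TOL:
        if pd_adjust == "none":
            raise ValueError(
                f"precision matrix not positive definite (min eigenvalue {min_eig:.4g}) "
                "and pd_adjust='none'"
            )
        if pd_adjust != "shift":
            raise ValueError(f"unknown pd_adjust policy {pd_adjust!r}")
        shift = abs(min_eig) + 0.05
        omega = (omega + shift * np.eye(P)) / (1.0 + shift)
        adjusted = True
    d = np.sqrt(np.diag(omega))
    realized = -omega / np.outer(d, d)
    np.fill_diagonal(realized, 0.0)
    record = ConstructionRecord(
        targets=weights,
        adjusted=adjusted,
        shift=shift,
        min_eigenvalue_before=min_eig,
        realized_partial_correlations=realized,
    )
    return omega, record


def build_precision_pair(spec: NetworkSpec, pd_adjust: str = "shift") -> PrecisionPair:
    adj = make_adjacency(spec)
    omega1, rec1 = adjacency_to_precision(adj.weights1, pd_adjust)
    omega0, rec0 = adjacency_to_precision(adj.weights0, pd_adjust)
    return PrecisionPair(
        omega1=omega1, omega0=omega0, record1=rec1, record0=rec0,
        node_names=adj.node_names,
    )


def sample_group_data(precision: np.ndarray, n: int, seed) -> np.ndarray:
    """n i.i.d. draws from MVN(0, Omega^-1) via the precision Cholesky factor."""
    if n < 2:
        raise ValueError("need n >= 2 subjects")
    precision = np.asarray(precision, dtype=float)
    try:
        chol = scipy.linalg.cholesky(precision, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("precision matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, precision.shape[0]))
    # x = L^-T z  has covariance (L L^T)^-1 = Omega^-1
    return scipy.linalg.solve_triangular(chol, z.T, lower=True, trans="T").T


def true_dnet(pair: PrecisionPair, tol: float = 1e-8) -> TrueDNet:
    """Pairs whose precision entries differ by more than tol between groups."""
    diff = pair.omega1 - pair.omega0
    P = diff.shape[0]
    edges, v1, v0, d = [], [], [], []
    for j in range(P):
        for k in range(j + 1, P):
            if abs(diff[j, k]) > tol:
                edges.append((j, k))
                v1.append(float(pair.omega1[j, k]))
                v0.append(float(pair.omega0[j, k]))
                d.append(float(diff[j, k]))
    return TrueDNet(
        edges=tuple(edges), omega1_values=tuple(v1), omega0_values=tuple(v0),
        diff=tuple(d), tol=tol,
    )


# ---------------------------------------------------------------------------
# Shipped scenario builders


def jak_stat_like_network() -> NetworkSpec:
    """A 32-node signaling-pathway-like structure with a degree-17 hub (STAT1).

    Shipped as a synthetic plain-TSV edge list whose topology imitates the
    JAK-STAT signaling pathway (one highly connected transcription factor,
    receptor chains feeding the kinases); it is constructed by hand, not
    fetched from any pathway database.
    """
    ref = importlib.resources.files("pride") / "data" / "jak_stat_like.tsv"
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    names = sorted(set(table["node_a"]) | set(table["node_b"]))
    index = {g: i for i, g in enumerate(names)}
    edges = tuple(
        tuple(sorted((index[a], index[b]))) for a, b in zip(table["node_a"], table["node_b"])
    )
    return NetworkSpec(
        P=len(names), structure="edge_list", edges=edges, node_names=tuple(names)
    )


def _hub_edges(spec: NetworkSpec, node: int) -> tuple:
    return tuple(e for e in spec.all_edges() if node in e)


def scenario_structural(weight: float = 0.2) -> NetworkSpec:
    """Structural-difference scenario: group 0 lacks the hub's 17 edges."""
    base = jak_stat_like_network()
    hub = base.node_names.index("STAT1")
    return replace(base, modification="remove_node_edges", mod_node=hub, weight=weight)


def scenario_sign_flip(flip_weight: float = 0.11, weight: float = 0.2) -> NetworkSpec:
    """Sign-flip scenario: the hub's edges carry +/-flip_weight precision targets."""
    base = jak_stat_like_network()
    hub = base.node_names.index("STAT1")
    return replace(
        base,
        modification="flip_sign",
        mod_edges=_hub_edges(base, hub),
        weight=weight,
        flip_weight=flip_weight,
    )


def scenario_ar(P: int = 25, weight: float = 0.3, weight2: float = 0.22) -> NetworkSpec:
    """AR(1)-vs-AR(2) scenario: group 1 is AR(2), group 0 is AR(1).

    Group 1 carries the extra second-order band; the true differential edges
    are exactly the P-2 second-order pairs.
    """
    return NetworkSpec(P=P, structure="ar2", weight=weight, weight2=weight2)


def _ar_pair(spec: NetworkSpec, pd_adjust: str = "shift") -> PrecisionPair:
    """For ar2 specs group 0 is the AR(1) restriction of the same chain."""
    adj = make_adjacency(spec)
    w0 = _weights_matrix(spec.P, [(i, i + 1) for i in range(spec.P - 1)], spec.weight)
    omega1, rec1 = adjacency_to_precision(adj.weights1, pd_adjust)
    omega0, rec0 = adjacency_to_precision(w0, pd_adjust)
    return PrecisionPair(
        omega1=omega1, omega0=omega0, record1=rec1, record0=rec0,
        node_names=spec.node_names,
    )


def precision_pair_for(spec: NetworkSpec, pd_adjust: str = "shift") -> PrecisionPair:
    if spec.structure == "ar2":
        return _ar_pair(spec, pd_adjust)
    return build_precision_pair(spec, pd_adjust)


# ---------------------------------------------------------------------------
# End-to-end scenario runner


@dataclass(frozen=True)
class ScenarioConfig:
    spec: NetworkSpec
    n_per_group: int = 250
    reps: int = 10
    seed: int = 0
    s_strategy: str = "n_ratio"
    s_fraction: float | None = None
    s_explicit: int | None = None
    prior: SSLPrior = field(default_factory=SSLPrior)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    threshold: float = 0.5
    dnet_tol: float = 0.05
    pd_adjust: str = "shift"


@dataclass(frozen=True)
class RepResult:
    rep: int
    report: PerformanceReport
    inclusion_prob: dict  # (j, k) -> posterior inclusion probability
    estimated_edges: tuple
    rank_sum_p: float | None


@dataclass(frozen=True)
class ScenarioReport:
    config: ScenarioConfig
    truth: TrueDNet
    reps: tuple
    mean: dict
    se: dict

    def metric_values(self, name: str) -> np.ndarray:
        return np.array([getattr(r.report, name) for r in self.reps])


def _rank_sum_p(inclusion: dict, truth_edges: set, P: int) -> float | None:
    """One-sided Mann-Whitney p that true edges out-rank null pairs.

    Unscreened pairs enter with probability 0 (they were never candidates,
    so they are maximally un-supported).
    """
    from scipy.stats import mannwhitneyu

    true_p, null_p = [], []
    for j in range(P):
        for k in range(j + 1, P):
            p = inclusion.get((j, k), 0.0)
            (true_p if (j, k) in truth_edges else null_p).append(p)
    if not true_p or not null_p:
        return None
    return float(mannwhitneyu(true_p, null_p, alternative="greater").pvalue)


def run_scenario(config: ScenarioConfig) -> ScenarioReport:
    """Simulate, screen, fit, threshold, and score over replicates."""
    spec = config.spec
    pair = precision_pair_for(spec, config.pd_adjust)
    truth = true_dnet(pair, tol=config.dnet_tol)
    truth_edges = set(truth.edges)
    P = spec.P
    n = config.n_per_group
    N = 2 * n

    S = choose_S(
        config.s_strategy, N=N, P=P,
        fraction=config.s_fraction, S=config.s_explicit,
    )

    rep_seeds = np.random.SeedSequence(config.seed).spawn(config.reps)
    results = []
    for r, ss in enumerate(rep_seeds):
        child = ss.spawn(3)
        x1 = sample_group_data(pair.omega1, n, child[0])
        x0 = sample_group_data(pair.omega0, n, child[1])
        data = ExpressionDataset(
            values=np.vstack([x0, x1]),
            gene_names=spec.node_names,
            sample_ids=tuple(f"s{i + 1}" for i in range(N)),
            labels=np.r_[np.zeros(n, dtype=int), np.ones(n, dtype=int)],
            label_mapping={0: 0, 1: 1},
        )
        std = standardize_within_group(data)
        delta = correlation_difference(group_correlations(std))
        screen = screen_top_S(delta, S, strategy=config.s_strategy)
        design = build_interaction_design(std, screen)
        mcmc_seed = int(np.random.default_rng(child[2]).integers(2**31))
        draws = sample_posterior(
            design, std.labels, config.prior,
            replace(config.mcmc, seed=mcmc_seed),
            diagnostics=False,
        )
        summary = summarize_posterior(draws)
        estimated = tuple(
            pr for pr, ip in zip(summary.pair_index, summary.inclusion_prob)
            if ip >= config.threshold
        )
        report = recovery_metrics(truth.edges, estimated, P)
        inclusion = dict(zip(summary.pair_index, summary.inclusion_prob))
        results.append(
            RepResult(
                rep=r,
                report=report,
                inclusion_prob={k: float(v) for k, v in inclusion.items()},
                estimated_edges=estimated,
                rank_sum_p=_rank_sum_p(inclusion, truth_edges, P),
            )
        )

    metrics = ("TP", "FP", "FN", "TN", "SEN", "SPE", "FDR", "MCC", "F1")
    stacked = {m: np.array([getattr(r.report, m) for r in results], dtype=float) for m in metrics}
    mean = {m: float(v.mean()) for m, v in stacked.items()}
    se = {
        m: float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        for m, v in stacked.items()
    }
    return ScenarioReport(config=config, truth=truth, reps=tuple(results), mean=mean, se=se)
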