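"""The five candidate-gene ranking strategies.

All strategies score candidates from a differential-expression vector and
(except the baseline) a gene association network, then sort candidates by
score magnitude.  Magnitude ordering is the default because knockout and
disease genes are typically *down*-regulated: a strongly negative log2 ratio
is strong evidence, and ranking by signed value would bury it.  A ``signed``
flag restores literal descending-value ordering.  Ties are broken
lexicographically by gene identifier so every ranking is deterministic.

Strategies
----------
simple_expression_ranking
    The standard genetic procedure: a candidate's own differential
    expression, nothing else.
kernel_ridge_regression_ranking
    Smooths each candidate's expression over its most similar genes in a
    centered graph-kernel similarity network via kernel ridge regression.
heat_kernel_diffusion_ranking
    Iterates a preference vector through the discrete heat-diffusion
    operator ``I - (alpha/N)(I - W)`` for N steps (random-walk Laplacian).
arnoldi_diffusion_ranking
    Approximates the same diffusion's action on the expression vector in an
    m-dimensional Krylov subspace (Arnoldi), avoiding any dense kernel.
direct_neighborhood_ranking
    A diffusion-free local score mixing a candidate's own expression with
    the mean expression of its direct neighbors above an edge threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .diffexpr import DifferentialExpression
from .kernels import KernelMatrix
from .network import Network, NetworkMatrices

log = logging.getLogger(__name__)

__all__ = [
    "Ranking",
    "RidgeConfig",
    "PreferenceVector",
    "simple_expression_ranking",
    "select_neighborhood",
    "ridge_solve",
    "ridge_smoothed_expression",
    "kernel_ridge_regression_ranking",
    "build_preference_vector",
    "heat_kernel_rank",
    "heat_kernel_diffusion_ranking",
    "arnoldi_expv",
    "arnoldi_diffusion_ranking",
    "direct_neighborhood_score",
    "direct_neighborhood_ranking",
]


@dataclass
class Ranking:
    """Ordered candidates (best first) with the score each was sorted on."""

    strategy: str
    genes: tuple[str, ...]
    scores: np.ndarray
    signed: bool = False
    _pos: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.genes),):
            raise ValueError("scores must align with genes")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing in rank order")
        self._pos = {g: i for i, g in enumerate(self.genes)}

    def rank_of(self, gene: str) -> int:
        """1-based position of a gene."""
        return self._pos[gene] + 1

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rank": np.arange(1, len(self.genes) + 1), "gene": self.genes,
             "score": self.scores}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _make_ranking(strategy: str, scores: dict[str, float], signed: bool) -> Ranking:
    if not scores:
        raise ValueError("empty candidate list")
    key = (lambda g: (-scores[g], g)) if signed else (lambda g: (-abs(scores[g]), g))
    order = sorted(scores, key=key)
    vals = np.array([scores[g] if signed else abs(scores[g]) for g in order])
    return Ranking(strategy, tuple(order), vals, signed=signed)


def _candidate_values(de: DifferentialExpression, candidates) -> dict[str, float]:
    out: dict[str, float] = {}
    missing = []
    for g in candidates:
        if g in de:
            out[g] = de.value(g)
        else:
            out[g] = 0.0
            missing.append(g)
    if missing:
        log.warning("%d candidate(s) without expression values scored 0", len(missing))
    return out


def simple_expression_ranking(
    de: DifferentialExpression, candidates, signed: bool = False
) -> Ranking:
    """Baseline: rank candidates by their own differential expression."""
    return _make_ranking("simple", _candidate_values(de, candidates), signed)


# ---------------------------------------------------------------------------
# Strategy 1: kernel ridge regression over the similarity network


@dataclass
class RidgeConfig:
    """Kernel ridge regression settings: penalty, neighborhood size, kernel."""

    lam: float = 1.0
    nn: int = 50
    kernel_kind: str = "LED"
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")
        if self.nn < 2:
            raise ValueError("neighborhood size must be >= 2")


def select_neighborhood(K_C: KernelMatrix, gene: str, nn: int = 50) -> list[str]:
    """The up-to-``nn`` most similar genes with positive centered similarity.

    Centered similarities can be negative; only strictly positive ones count
    as neighbors.  If fewer than two genes qualify, the two most similar
    genes are used regardless of sign — a neighborhood must always contain
    at least one gene besides the query.  Ties break lexicographically.
    """
    if gene not in K_C:
        raise KeyError(f"gene {gene!r} absent from kernel index")
    i = K_C.index_of(gene)
    sims = K_C.values[i]
    others = [(g, float(sims[j])) for j, g in enumerate(K_C.node_ids) if j != i]
    others.sort(key=lambda t: (-t[1], t[0]))
    positive = [g for g, s in others if s > 0]
    if len(positive) >= 2:
        return positive[:nn]
    return [g for g, _ in others[:2]]


def ridge_solve(K: np.ndarray, K_x: np.ndarray, Y: np.ndarray, lam: float) -> float:
    """Core kernel ridge regression: ``K_x^T (K + lam I)^{-1} Y``.

    For a one-gene neighborhood with unit self-similarity this reduces to
    ``y / (1 + lam)``; as ``lam`` grows the smoothed value shrinks to zero.
    """
    K = np.atleast_2d(np.asarray(K, dtype=float))
    Y = np.asarray(Y, dtype=float)
    K_x = np.asarray(K_x, dtype=float)
    A = K + lam * np.eye(K.shape[0])
    cond = np.linalg.cond(A)
    if cond > 1e12:
        log.warning("ridge system condition number %.3g", cond)
    return float(K_x @ scipy.linalg.solve(A, Y, assume_a="sym"))


def ridge_smoothed_expression(
    K_C: KernelMatrix,
    de: DifferentialExpression,
    gene: str,
    cfg: RidgeConfig = RidgeConfig(),
) -> float:
    """Kernel-ridge-smoothed differential expression of one candidate.

    With neighborhood N, ``a* = (K_NN + lambda I)^{-1} Y_N`` and
    ``y_hat = K_x^T a*`` where ``K_x`` holds the candidate's similarity to
    each neighborhood gene.  The neighborhood comprises the candidate itself
    plus its most similar other genes (up to ``nn`` genes in total, never
    fewer than two): a gene is always its own most similar gene, and
    including it keeps the smoothed value responsive to the candidate's own
    expression.  A candidate amid strongly differentially expressed similar
    genes gets a large smoothed value even if its own expression is modest.
    """
    nbrs = [gene] + select_neighborhood(K_C, gene, cfg.nn - 1)
    idx = [K_C.index_of(g) for g in nbrs]
    K = K_C.values[np.ix_(idx, idx)]
    Kx = K_C.values[K_C.index_of(gene), idx]
    Y = np.array([de.value(g, default=0.0) for g in nbrs])
    return ridge_solve(K, Kx, Y, cfg.lam)


def kernel_ridge_regression_ranking(
    K_C: KernelMatrix,
    de: DifferentialExpression,
    candidates,
    cfg: RidgeConfig = RidgeConfig(),
    signed: bool = False,
) -> Ranking:
    """Rank candidates by their kernel-ridge-smoothed expression values."""
    scores: dict[str, float] = {}
    missing = []
    for g in candidates:
        if g in K_C:
            scores[g] = ridge_smoothed_expression(K_C, de, g, cfg)
        else:
            scores[g] = 0.0
            missing.append(g)
    if missing:
        log.warning("%d candidate(s) absent from kernel scored 0", len(missing))
    return _make_ranking("ridge", scores, signed)


# ---------------------------------------------------------------------------
# Strategy 2: heat kernel diffusion


@dataclass
class PreferenceVector:
    """Initial per-node relevance signal for diffusion (also the Arnoldi
    start vector).  Scenario codes: 1 = binary candidates, 2 = candidate
    expression, 3 = all expression, 4 = binary differential significance."""

    values: np.ndarray
    scenario: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("preference vector must be finite")


def build_preference_vector(
    scenario: int,
    de: DifferentialExpression,
    candidates,
    node_ids: tuple[str, ...],
    alpha_p: float = 0.05,
) -> PreferenceVector:
    """Initialize the diffusion's preference vector p0 on the network nodes.

    Scenarios: (1) 1 at candidates, 0 elsewhere; (2) expression values at
    candidates only; (3) expression values at every gene with data — the
    default, which feeds the whole experiment into the diffusion; (4) 1 at
    every significantly differentially expressed gene (requires p-values).
    """
    if scenario not in (1, 2, 3, 4):
        raise ValueError("scenario must be 1, 2, 3 or 4")
    index = {g: i for i, g in enumerate(node_ids)}
    p0 = np.zeros(len(node_ids))
    if scenario == 1:
        for g in candidates:
            if g in index:
                p0[index[g]] = 1.0
    elif scenario == 2:
        for g in candidates:
            if g in index and g in de:
                p0[index[g]] = de.value(g)
    elif scenario == 3:
        for g, v in zip(de.genes, de.values):
            if g in index:
                p0[index[g]] = v
    else:
        if de.pvalues is None:
            raise ValueError("scenario 4 requires a measure with p-values")
        for g, p in zip(de.genes, de.pvalues):
            if g in index and p < alpha_p:
                p0[index[g]] = 1.0
    return PreferenceVector(p0, scenario)


def heat_kernel_rank(
    mats: NetworkMatrices,
    p0: PreferenceVector | np.ndarray,
    alpha: float = 0.5,
    n_steps: int = 2,
) -> np.ndarray:
    """Discrete heat diffusion: p0 row-multiplied N times by
    ``I - (alpha/N)(I - W)``.

    As N grows this converges (first order) to ``p0 exp(-alpha (I - W))``,
    the heat-kernel rank on the random-walk Laplacian.  Only sparse
    matrix-vector products are used, so large networks are fine.  ``N = 2``
    already yields stable rankings in practice.
    """
    if n_steps < 0:
        raise ValueError("number of steps must be >= 0")
    p = np.asarray(p0.values if isinstance(p0, PreferenceVector) else p0, dtype=float)
    if p.shape != (mats.n_nodes,):
        raise ValueError("preference vector does not match network size")
    if n_steps == 0 or alpha == 0:
        return p.copy()
    step = alpha / n_steps
    for _ in range(n_steps):
        p = p - step * (p - p @ mats.transition)
    return p


def heat_kernel_diffusion_ranking(
    mats: NetworkMatrices,
    de: DifferentialExpression,
    candidates,
    alpha: float = 0.5,
    n_steps: int = 2,
    scenario: int = 3,
    signed: bool = False,
) -> Ranking:
    """Rank candidates by their diffused score after N heat-kernel steps."""
    p0 = build_preference_vector(scenario, de, candidates, mats.node_ids)
    p_alpha = heat_kernel_rank(mats, p0, alpha=alpha, n_steps=n_steps)
    index = {g: i for i, g in enumerate(mats.node_ids)}
    scores: dict[str, float] = {}
    missing = []
    for g in candidates:
        if g in index:
            scores[g] = float(p_alpha[index[g]])
        else:
            scores[g] = 0.0
            missing.append(g)
    if missing:
        log.warning(
            "%d candidate(s) absent from network scored 0; consider "
            "augment_with_isolated_nodes before building matrices", len(missing),
        )
    return _make_ranking("heat", scores, signed)


# ---------------------------------------------------------------------------
# Strategy 3: Arnoldi (Krylov) approximation of the diffusion


def arnoldi_expv(
    mats: NetworkMatrices,
    v: PreferenceVector | np.ndarray,
    m: int = 2,
    alpha: float = 0.5,
    adjoint: bool = True,
    grow: bool = False,
) -> np.ndarray:
    """Krylov approximation of the diffusion operator's action on v.

    Builds an orthonormal basis V_m of span{v, Av, ..., A^{m-1} v} and the
    Hessenberg matrix H_m by the Arnoldi iteration, then returns
    ``||v|| * V_m expm(alpha H_m) e_1 ~= exp(alpha A) v``, using only
    matrix-vector products.  The operator is ``A = -(I - W)`` (diffusive
    decay); by default its adjoint is applied so that the result equals the
    row-vector heat diffusion ``v exp(-alpha(I - W))`` and the two diffusion
    strategies agree as m grows.  ``grow=True`` flips the sign to the
    growing exponential ``exp(+alpha(I - W))``.  A happy breakdown before m
    steps uses the subspace achieved (the result is then exact).
    """
    if m < 1:
        raise ValueError("Krylov dimension m must be >= 1")
    x = np.asarray(v.values if isinstance(v, PreferenceVector) else v, dtype=float)
    if x.shape != (mats.n_nodes,):
        raise ValueError("start vector does not match network size")
    beta = float(np.linalg.norm(x))
    if beta == 0:
        raise ValueError("zero start vector: no signal to diffuse")
    W = mats.transition.T if adjoint else mats.transition
    sign = 1.0 if grow else -1.0

    def matvec(y: np.ndarray) -> np.ndarray:
        return sign * (y - W @ y)

    n = mats.n_nodes
    m = min(m, n)
    V = np.zeros((n, m))
    H = np.zeros((m, m))
    V[:, 0] = x / beta
    k = m
    for j in range(m):
        w = matvec(V[:, j])
        for i in range(j + 1):
            H[i, j] = V[:, i] @ w
            w = w - H[i, j] * V[:, i]
        # one re-orthogonalization pass for numerical hygiene
        for i in range(j + 1):
            c = V[:, i] @ w
            H[i, j] += c
            w = w - c * V[:, i]
        if j + 1 == m:
            break
        h = float(np.linalg.norm(w))
        if h <= 1e-12 * beta:
            k = j + 1
            break
        H[j + 1, j] = h
        V[:, j + 1] = w / h
    Vk, Hk = V[:, :k], H[:k, :k]
    e1 = np.zeros(k)
    e1[0] = 1.0
    return beta * (Vk @ (scipy.linalg.expm(alpha * Hk) @ e1))


def arnoldi_diffusion_ranking(
    mats: NetworkMatrices,
    de: DifferentialExpression,
    candidates,
    m: int = 2,
    alpha: float = 0.5,
    signed: bool = False,
) -> Ranking:
    """Rank candidates by the Krylov-approximated diffusion of the full
    expression vector (the scenario-3 start vector)."""
    v = build_preference_vector(3, de, candidates, mats.node_ids)
    u = arnoldi_expv(mats, v, m=m, alpha=alpha)
    index = {g: i for i, g in enumerate(mats.node_ids)}
    scores: dict[str, float] = {}
    missing = []
    for g in candidates:
        if g in index:
            scores[g] = float(u[index[g]])
        else:
            scores[g] = 0.0
            missing.append(g)
    if missing:
        log.warning("%d candidate(s) absent from network scored 0", len(missing))
    return _make_ranking("arnoldi", scores, signed)


# ---------------------------------------------------------------------------
# Strategy 4: direct neighborhood (no diffusion)


def direct_neighborhood_score(
    net: Network,
    de: DifferentialExpression,
    gene: str,
    a: float = 0.5,
    eps: float = 0.15,
) -> float:
    """Local score ``a*|x_i| + (1-a) * mean(|x_j|)`` over direct neighbors
    with edge weight strictly above ``eps``.

    Expression magnitudes are used so down-regulated neighborhoods count.
    A gene without surviving neighbors (or absent from the network) scores
    ``a*|x_i|`` — its own signal, damped by the mixing weight.
    """
    if not 0 <= a <= 1:
        raise ValueError("weight a must lie in [0, 1]")
    xi = abs(de.value(gene, default=0.0))
    if gene not in net:
        log.warning("gene %s absent from network; isolated treatment", gene)
        return a * xi
    nbr_vals = [
        abs(de.value(j, default=0.0))
        for j, data in net.graph[gene].items()
        if data["weight"] > eps
    ]
    if not nbr_vals:
        return a * xi
    return a * xi + (1 - a) * float(np.mean(nbr_vals))


def direct_neighborhood_ranking(
    net: Network,
    de: DifferentialExpression,
    candidates,
    a: float = 0.5,
    eps: float = 0.15,
    signed: bool = False,
) -> Ranking:
    """Rank candidates by the direct-neighborhood score (descending)."""
    scores = {g: direct_neighborhood_score(net, de, g, a=a, eps=eps) for g in candidates}
    return _make_ranking("neighborhood", scores, signed)
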