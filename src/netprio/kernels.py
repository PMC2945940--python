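"""Graph kernels turning an association network into a similarity network.

Three node-similarity kernels are provided, all functions of the network's
matrices:

* Laplacian exponential diffusion kernel ``K_LED = exp(-alpha L)`` — the
  lazy-random-walk diffusion kernel of Kondor & Lafferty;
* regularized Laplacian kernel ``K_RL = (I + alpha L)^{-1}``;
* regularized commute-time kernel ``K_RCT = (D - alpha A)^{-1}``.

A kernel is then normalized (unit diagonal, cosine-style) and double-centered
to yield the similarity network consumed by kernel ridge regression.  Note
that centering necessarily produces negative entries; downstream neighborhood
selection keeps only positive centered similarities.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .network import NetworkMatrices

log = logging.getLogger(__name__)

__all__ = [
    "KernelMatrix",
    "KernelSizeError",
    "DENSE_NODE_CAP",
    "led_kernel",
    "regularized_laplacian_kernel",
    "regularized_commute_time_kernel",
    "normalize_kernel",
    "center_kernel",
    "similarity_network",
    "save_kernel",
    "load_kernel",
]

#: Default cap on dense kernel computation; larger networks should use the
#: matrix-free Arnoldi diffusion path instead.
DENSE_NODE_CAP = 3000


class KernelSizeError(ValueError):
    """Network too large for dense kernel computation."""


@dataclass
class KernelMatrix:
    """Symmetric node-by-node similarity matrix with provenance.

    ``kind`` is one of ``{"LED", "RL", "RCT", "normalized", "centered"}``;
    ``alpha`` is the diffusion/regularization parameter of the generating
    kernel.  The node index is shared with the originating network.
    """

    values: np.ndarray
    kind: str
    alpha: float
    node_ids: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kernel matrix must be square")
        if self.values.shape[0] != len(self.node_ids):
            raise ValueError("kernel size and node index disagree")
        self._index = {g: i for i, g in enumerate(self.node_ids)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index


def _check_dense(mats: NetworkMatrices, dense_cap: int) -> None:
    if mats.n_nodes > dense_cap:
        raise KernelSizeError(
            f"network has {mats.n_nodes} nodes, above the dense kernel cap "
            f"({dense_cap}); use the Arnoldi diffusion path or a subnetwork"
        )


def led_kernel(
    mats: NetworkMatrices, alpha: float = 0.5, dense_cap: int = DENSE_NODE_CAP
) -> KernelMatrix:
    """Laplacian exponential diffusion kernel ``exp(-alpha L)``.

    Computed via the symmetric eigendecomposition of L, which is exact and
    keeps the result symmetric positive semidefinite by construction.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    _check_dense(mats, dense_cap)
    L = mats.laplacian.toarray()
    w, U = scipy.linalg.eigh(L)
    K = (U * np.exp(-alpha * w)) @ U.T
    K = (K + K.T) / 2.0
    return KernelMatrix(K, "LED", alpha, mats.node_ids)


def regularized_laplacian_kernel(
    mats: NetworkMatrices, alpha: float = 1.0, dense_cap: int = DENSE_NODE_CAP
) -> KernelMatrix:
    """Regularized Laplacian kernel ``(I + alpha L)^{-1}``.

    Equals the Neumann series ``sum_k alpha^k (-L)^k`` where it converges.
    ``I + alpha L`` is positive definite for ``alpha > 0``, so the inverse
    always exists; severe ill-conditioning is logged.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    _check_dense(mats, dense_cap)
    n = mats.n_nodes
    M = np.eye(n) + alpha * mats.laplacian.toarray()
    cond = np.linalg.cond(M)
    if cond > 1e12:
        log.warning("regularized Laplacian system condition number %.3g", cond)
    K = scipy.linalg.solve(M, np.eye(n), assume_a="pos")
    K = (K + K.T) / 2.0
    return KernelMatrix(K, "RL", alpha, mats.node_ids)


def regularized_commute_time_kernel(
    mats: NetworkMatrices, alpha: float = 0.9, dense_cap: int = DENSE_NODE_CAP
) -> KernelMatrix:
    """Regularized commute-time kernel ``(D - alpha A)^{-1}`` (Fouss et al.).

    Requires ``alpha`` in (0, 1) so that ``D - alpha A`` is positive definite
    on graphs without isolated nodes.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    _check_dense(mats, dense_cap)
    if np.any(mats.degrees == 0):
        bad = [g for g, d in zip(mats.node_ids, mats.degrees) if d == 0]
        raise ValueError(
            "commute-time kernel undefined with isolated node(s) "
            f"{bad[:5]}; revisit edge thresholding or augmentation"
        )
    M = np.diag(mats.degrees) - alpha * mats.adjacency.toarray()
    K = scipy.linalg.solve(M, np.eye(mats.n_nodes), assume_a="pos")
    K = (K + K.T) / 2.0
    return KernelMatrix(K, "RCT", alpha, mats.node_ids)


def normalize_kernel(K: KernelMatrix) -> KernelMatrix:
    """Cosine normalization ``K[i,j] / sqrt(K[i,i] K[j,j])`` — unit diagonal."""
    d = np.diag(K.values)
    if np.any(d <= 0):
        bad = K.node_ids[int(np.argmin(d))]
        raise ValueError(f"non-positive kernel diagonal at node {bad!r}")
    s = 1.0 / np.sqrt(d)
    return KernelMatrix(K.values * np.outer(s, s), "normalized", K.alpha, K.node_ids)


def center_kernel(K: KernelMatrix) -> KernelMatrix:
    """Double-center a Gram matrix so row and column means vanish."""
    V = K.values
    rm = V.mean(axis=1, keepdims=True)
    cm = V.mean(axis=0, keepdims=True)
    C = V - rm - cm + V.mean()
    return KernelMatrix(C, "centered", K.alpha, K.node_ids)


_KERNELS = {
    "LED": led_kernel,
    "RL": regularized_laplacian_kernel,
    "RCT": regularized_commute_time_kernel,
}


def similarity_network(
    mats: NetworkMatrices,
    kind: str = "LED",
    alpha: float = 0.5,
    dense_cap: int = DENSE_NODE_CAP,
) -> KernelMatrix:
    """Kernel, then normalization, then centering: the similarity network.

    Normalization precedes centering; the centered matrix (which is no longer
    unit-diagonal and may be negative off the main mass) is what the ridge
    smoother consumes.
    """
    try:
        fn = _KERNELS[kind]
    except KeyError:
        raise ValueError(f"unknown kernel kind {kind!r}; choose from {sorted(_KERNELS)}")
    return center_kernel(normalize_kernel(fn(mats, alpha, dense_cap=dense_cap)))


def save_kernel(K: KernelMatrix, path) -> None:
    """Persist kernel values (.npy) with a JSON sidecar of metadata."""
    path = Path(path)
    np.save(path, K.values)
    npy = path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")
    digest = hashlib.sha256(npy.read_bytes()).hexdigest()
    meta = {
        "kind": K.kind,
        "alpha": K.alpha,
        "node_ids": list(K.node_ids),
        "sha256": digest,
    }
    npy.with_suffix(".json").write_text(json.dumps(meta), encoding="utf-8")


def load_kernel(path) -> KernelMatrix:
    path = Path(path)
    npy = path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")
    meta = json.loads(npy.with_suffix(".json").read_text(encoding="utf-8"))
    digest = hashlib.sha256(npy.read_bytes()).hexdigest()
    if digest != meta["sha256"]:
        raise ValueError(f"{npy}: content hash mismatch")
    values = np.load(npy)
    return KernelMatrix(values, meta["kind"], meta["alpha"], tuple(meta["node_ids"]))
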