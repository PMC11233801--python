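"""Supra-adjacency assembly, thresholding, and multi-layer metrics.

A multi-layer network over C channels and L sliding-window layers is stored
as one (C*L) x (C*L) supra-adjacency matrix: per-window PLI matrices on the
block diagonal, between-window PLI blocks off the diagonal (all-ones
inter-layer pattern).  Three multi-layer metrics are computed on it:

* **Q** — multilayer modularity (Mucha et al. null model): quality of a
  node-layer community partition with intra-layer Newman-Girvan null terms
  ``gamma_l * k_i k_j / (2 m_l)`` and uniform inter-layer coupling
  ``omega`` between copies of the same node, normalized by ``2 mu`` (total
  weight of intra-layer edges plus couplings).  Optimized by a seeded
  generalized Louvain with restarts.
* **MPC** — multiplex participation coefficient: homogeneity of a node's
  binary degree across layers; 1 when the degree is equal in every layer,
  0 when the node has degree only in one layer.
* **LLC** — layer-layer correlation: Pearson correlation between the
  vectorized upper triangles of two intra-layer blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .connectivity import ConnMatrix

__all__ = [
    "SupraAdjacency",
    "MultilayerPartition",
    "assemble_supra",
    "pool_threshold",
    "apply_threshold",
    "multilayer_modularity",
    "multiplex_participation",
    "layer_correlation",
]


@dataclass
class SupraAdjacency:
    """(C*L) x (C*L) multi-layer matrix with block accessors.

    Node-layer v = l*C + i holds channel i in layer l.  The matrix is
    symmetric with zero diagonal; block (m, l) is the transpose of block
    (l, m).
    """

    values: np.ndarray
    n_channels: int
    n_layers: int
    band: Optional[str] = None
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.n_channels * self.n_layers
        if self.values.shape != (n, n):
            raise ValueError(f"values must be ({n}, {n})")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("supra-adjacency must be symmetric")
        if np.any(np.diagonal(self.values) != 0):
            raise ValueError("supra-adjacency diagonal must be zero")

    def block(self, l: int, m: int) -> np.ndarray:
        """The C x C block coupling layer l's channels with layer m's."""
        C = self.n_channels
        return self.values[l * C:(l + 1) * C, m * C:(m + 1) * C]

    def intra_blocks(self) -> list[np.ndarray]:
        return [self.block(l, l) for l in range(self.n_layers)]

    def copy(self) -> "SupraAdjacency":
        return SupraAdjacency(
            self.values.copy(), self.n_channels, self.n_layers, self.band, self.condition
        )


@dataclass
class MultilayerPartition:
    """Node-layer community assignment and its modularity Q."""

    assignment: np.ndarray  # (L, C) community ids
    q: float
    gamma: float
    omega: float


def assemble_supra(
    intra: Sequence[ConnMatrix],
    inter: Sequence[ConnMatrix],
    band: Optional[str] = None,
    condition: Optional[str] = None,
) -> SupraAdjacency:
    """Stack L intra-layer and L(L-1)/2 inter-layer PLI blocks into one matrix.

    ``intra`` supplies the diagonal blocks in window order; ``inter``
    supplies each upper off-diagonal block (l < m), mirrored by transpose.
    """
    L = len(intra)
    C = intra[0].n_channels
    by_pair: dict[tuple[int, int], np.ndarray] = {}
    for cm in intra:
        l, m = cm.window_pair
        if l != m:
            raise ValueError("intra list contains an inter-layer matrix")
        by_pair[(l, l)] = cm.values
    for cm in inter:
        l, m = cm.window_pair
        if l == m:
            raise ValueError("inter list contains an intra-layer matrix")
        if l > m:
            l, m, vals = m, l, cm.values.T
        else:
            vals = cm.values
        by_pair[(l, m)] = vals
    values = np.zeros((C * L, C * L))
    for l in range(L):
        if (l, l) not in by_pair:
            raise ValueError(f"missing intra-layer block for window {l}")
        values[l * C:(l + 1) * C, l * C:(l + 1) * C] = by_pair[(l, l)]
        for m in range(l + 1, L):
            if (l, m) not in by_pair:
                raise ValueError(f"missing inter-layer block ({l}, {m})")
            values[l * C:(l + 1) * C, m * C:(m + 1) * C] = by_pair[(l, m)]
            values[m * C:(m + 1) * C, l * C:(l + 1) * C] = by_pair[(l, m)].T
    return SupraAdjacency(values, C, L, band, condition)


def pool_threshold(supras: Sequence[SupraAdjacency], percentile: float = 0.95) -> float:
    """Connectivity threshold from the pooled PLI distribution of one band.

    All upper-triangle entries of every supplied supra matrix — diagonal
    and off-diagonal blocks alike, so within- and between-window
    connections weigh equally — are pooled into one vector and its
    empirical ``percentile`` quantile is returned.
    """
    if not supras:
        raise ValueError("empty pool of supra matrices")
    if not (0 < percentile < 1):
        raise ValueError("percentile must lie in (0, 1)")
    vals = []
    for s in supras:
        iu = np.triu_indices(s.values.shape[0], k=1)
        vals.append(s.values[iu])
    return float(np.quantile(np.concatenate(vals), percentile))


def apply_threshold(supra: SupraAdjacency, threshold: float) -> SupraAdjacency:
    """Zero entries below the threshold; surviving edges keep their weights."""
    out = supra.copy()
    out.values[out.values < threshold] = 0.0
    return out


# ---------------------------------------------------------------------------
# Multilayer modularity (generalized Louvain)
# ---------------------------------------------------------------------------

def _modularity_matrix(
    supra: SupraAdjacency, gamma: float, omega: float
) -> tuple[np.ndarray, float]:
    """Build the (C*L)^2 modularity matrix B and the normalizer 2*mu.

    Intra-layer blocks get ``A_l - gamma * k k^T / (2 m_l)``; node copies in
    different layers are coupled by ``omega`` (all-to-all across layers).
    ``2 mu`` sums all intra-layer strengths plus all couplings.
    """
    C, L = supra.n_channels, supra.n_layers
    n = C * L
    B = np.zeros((n, n))
    two_mu = 0.0
    for l in range(L):
        A = supra.block(l, l)
        k = A.sum(axis=1)
        two_m = k.sum()
        two_mu += two_m
        block = A - (gamma * np.outer(k, k) / two_m if two_m > 0 else 0.0)
        B[l * C:(l + 1) * C, l * C:(l + 1) * C] = block
    if L > 1 and omega != 0:
        for l in range(L):
            for m in range(L):
                if l == m:
                    continue
                idx = np.arange(C)
                B[l * C + idx, m * C + idx] = omega
        two_mu += omega * C * L * (L - 1)
    return B, two_mu


def _louvain_dense(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Greedy Louvain on a dense (generalized) modularity matrix.

    Local node moves to the best-gaining community until convergence, then
    community aggregation, repeated until no further improvement.  Returns
    the community label per node of the original graph.
    """
    n0 = B.shape[0]
    labels = np.arange(n0)
    Bcur = B
    while True:
        n = Bcur.shape[0]
        comm = np.arange(n)
        moved_any = False
        improved = True
        while improved:
            improved = False
            for v in rng.permutation(n):
                cids, inv = np.unique(comm, return_inverse=True)
                S = np.zeros((n, len(cids)))
                S[np.arange(n), inv] = 1.0
                scores = Bcur[v] @ S  # sum of B[v, u] per community
                cur = inv[v]
                scores[cur] -= Bcur[v, v]  # exclude self-link from own score
                best = int(np.argmax(scores))
                if scores[best] > scores[cur] + 1e-12 and cids[best] != comm[v]:
                    comm[v] = cids[best]
                    improved = True
                    moved_any = True
        cids, inv = np.unique(comm, return_inverse=True)
        labels = inv[labels]
        if not moved_any or len(cids) == Bcur.shape[0]:
            return labels
        S = np.zeros((Bcur.shape[0], len(cids)))
        S[np.arange(Bcur.shape[0]), inv] = 1.0
        Bcur = S.T @ Bcur @ S


def partition_quality(
    supra: SupraAdjacency,
    assignment: np.ndarray,
    gamma: float = 1.0,
    omega: float = 1.0,
) -> float:
    """Modularity Q of an explicit (L, C) node-layer assignment."""
    B, two_mu = _modularity_matrix(supra, gamma, omega)
    labels = np.asarray(assignment).reshape(-1)
    same = labels[:, None] == labels[None, :]
    return float(B[same].sum() / two_mu)


def multilayer_modularity(
    supra: SupraAdjacency,
    gamma: float = 1.0,
    omega: float = 1.0,
    n_restarts: int = 100,
    seed: int = 0,
) -> MultilayerPartition:
    """Optimize multilayer modularity by seeded generalized Louvain.

    The best partition over ``n_restarts`` randomized runs is returned; Q is
    normalized by ``2 mu``, the total weight of intra-layer edges plus
    inter-layer couplings.  Q is not clamped: adversarial partitions can be
    negative, and the optimum of a sparse network may exceed intuition's
    [0, 1] reading.
    """
    if gamma <= 0 or omega < 0:
        raise ValueError("require gamma > 0 and omega >= 0")
    B, two_mu = _modularity_matrix(supra, gamma, omega)
    if two_mu <= 0:
        raise ValueError("modularity undefined on an empty (all-zero) network")
    rng = np.random.default_rng(seed)
    best_q = -np.inf
    best_labels = None
    for _ in range(max(1, n_restarts)):
        labels = _louvain_dense(B, rng)
        same = labels[:, None] == labels[None, :]
        q = float(B[same].sum() / two_mu)
        if q > best_q + 1e-15:
            best_q = q
            best_labels = labels
    assignment = np.asarray(best_labels).reshape(supra.n_layers, supra.n_channels)
    return MultilayerPartition(assignment, best_q, gamma, omega)


def modularity_sweep(
    supra: SupraAdjacency,
    gammas: Sequence[float] = (0.5, 0.75, 1.0, 1.25, 1.5),
    omegas: Sequence[float] = (0.1, 0.5, 1.0, 2.0),
    n_restarts: int = 20,
    seed: int = 0,
):
    """Sensitivity sweep of Q over the (gamma, omega) grid.

    Returns a DataFrame with one row per parameter pair: the optimized Q
    and the number of communities found.  The resolution gamma and
    coupling omega are not identifiable from data alone, so reporting Q's
    sensitivity to them is part of an honest analysis.
    """
    import pandas as pd

    rows = []
    for g in gammas:
        for w in omegas:
            part = multilayer_modularity(supra, g, w, n_restarts, seed)
            rows.append(
                {
                    "gamma": g, "omega": w, "Q": part.q,
                    "n_communities": len(np.unique(part.assignment)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MPC and LLC
# ---------------------------------------------------------------------------

def multiplex_participation(supra: SupraAdjacency) -> tuple[np.ndarray, float]:
    """Multiplex participation coefficient per node, and its network mean.

    Uses the binary degree k_i[l] on each (thresholded) intra-layer block:

        MPC_i = L/(L-1) * (1 - sum_l (k_i[l] / o_i)^2),   o_i = sum_l k_i[l].

    Nodes absent from every layer (o_i = 0) get MPC_i = 0.
    """
    L = supra.n_layers
    if L < 2:
        raise ValueError("MPC requires at least 2 layers")
    degrees = np.stack(
        [(blk > 0).sum(axis=1) for blk in supra.intra_blocks()]
    ).astype(float)  # (L, C)
    o = degrees.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(o > 0, degrees / o, 0.0)
    mpc = L / (L - 1) * (1.0 - (frac**2).sum(axis=0))
    mpc = np.where(o > 0, mpc, 0.0)
    return mpc, float(mpc.mean())


def layer_correlation(supra: SupraAdjacency) -> np.ndarray:
    """Layer-layer correlation matrix (L x L).

    Entry (i, j) is the Pearson correlation between the vectorized upper
    triangles (diagonal excluded) of intra-layer blocks A_i and A_j.  A
    block with zero variance yields NaN off-diagonal entries; the diagonal
    is 1 by definition.
    """
    L = supra.n_layers
    if L < 2:
        raise ValueError("LLC requires at least 2 layers")
    iu = np.triu_indices(supra.n_channels, k=1)
    vecs = np.stack([blk[iu] for blk in supra.intra_blocks()])
    centered = vecs - vecs.mean(axis=1, keepdims=True)
    sd = np.sqrt((centered**2).sum(axis=1))
    R = np.full((L, L), np.nan)
    for i in range(L):
        for j in range(L):
            if i == j:
                R[i, j] = 1.0
            elif sd[i] > 0 and sd[j] > 0:
                R[i, j] = float((centered[i] @ centered[j]) / (sd[i] * sd[j]))
    return R
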