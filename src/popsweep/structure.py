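"""Population structure: genotype PCA and bootstrapped neighbor joining.

PCA follows the standard genotype-matrix recipe used by PLINK-style tools:
missing entries are imputed to the variant mean, each variant is centered by
``2*p`` and scaled by ``sqrt(2*p*(1-p))`` (``p`` the allele frequency from
non-missing calls), the sample-by-sample kinship matrix is the scaled
matrix times its transpose over the variant count, and coordinates are the
top eigenvectors scaled by the square roots of their eigenvalues.

Trees are built by Saitou-Nei neighbor joining on the allele-sharing
distance ``d(i,j) = mean(|g_i - g_j|) / 2`` over shared called sites, with
bootstrap supports obtained by resampling variants (columns) with
replacement.  NJ is exact on additive distance matrices.  Trees are
scikit-bio ``TreeNode`` objects, so they serialize to Newick and round-trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import numpy as np
from skbio import TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "genotype_pca",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_tree",
    "write_newick",
    "read_newick",
]


@dataclass
class PCAResult:
    """Sample coordinates and spectrum of the genotype PCA."""

    coordinates: np.ndarray         # (n_samples, k)
    eigenvalues: np.ndarray         # k, non-increasing
    variance_fractions: np.ndarray  # k, eigenvalue / kinship trace
    kinship_trace: float


def _standardize(genotypes: np.ndarray) -> np.ndarray:
    """Mean-impute, center by 2p and scale by sqrt(2p(1-p)); drop monomorphic."""
    g = np.asarray(genotypes, dtype=float)
    g[g < 0] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    with np.errstate(invalid="ignore"):
        variance = np.nanvar(g, axis=0)
    keep = np.isfinite(p) & (p > 0.0) & (p < 1.0) & (variance > 0.0)
    if not keep.any():
        raise ValueError("no polymorphic variants after filtering")
    g = g[:, keep]
    p = p[keep]
    mean = 2.0 * p
    g = np.where(np.isnan(g), mean, g)
    return (g - mean) / np.sqrt(2.0 * p * (1.0 - p))


def genotype_pca(genotypes: np.ndarray, k: int = 2) -> PCAResult:
    """PCA of a samples x variants dosage matrix (-1 or NaN = missing).

    The sign of each component is fixed by forcing its largest-magnitude
    loading positive, so outputs are reproducible across eigensolvers.
    """
    g = np.asarray(genotypes, dtype=float)
    n_samples = g.shape[0]
    if k >= n_samples:
        raise ValueError(f"k = {k} must be smaller than the sample count "
                         f"{n_samples}")
    x = _standardize(g)
    m = x.shape[1]
    kinship = x @ x.T / m
    evals, evecs = np.linalg.eigh(kinship)
    order = np.argsort(evals)[::-1][:k]
    evals = evals[order]
    evecs = evecs[:, order]
    for j in range(k):
        lead = np.argmax(np.abs(evecs[:, j]))
        if evecs[lead, j] < 0:
            evecs[:, j] = -evecs[:, j]
    coords = evecs * np.sqrt(np.clip(evals, 0.0, None))
    trace = float(np.trace(kinship))
    return PCAResult(
        coordinates=coords,
        eigenvalues=evals,
        variance_fractions=evals / trace if trace > 0 else np.zeros_like(evals),
        kinship_trace=trace,
    )


def distance_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Allele-sharing distance: mean |g_i - g_j| / 2 over shared called sites."""
    g = np.asarray(genotypes, dtype=float)
    n = g.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    called = g >= 0
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = called[i] & called[j]
            if not shared.any():
                raise ValueError(f"samples {i} and {j} share no called sites")
            d[i, j] = d[j, i] = np.abs(g[i, shared] - g[j, shared]).mean() / 2.0
    return d


def neighbor_joining(d: np.ndarray, labels: list[str] | None = None) -> TreeNode:
    """Saitou-Nei neighbor joining; exact on additive distance matrices.

    Ties in the Q criterion are broken by the smallest (i, j) index pair.
    Negative branch-length estimates are clamped to zero with the deficit
    transferred to the sibling edge (logged).  The returned tree is unrooted
    (trifurcating root) for four or more taxa.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("need at least three taxa")
    labels = labels or [f"t{i + 1}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels length must match matrix size")

    nodes = [TreeNode(name=name) for name in labels]
    dist = d.copy()
    active = list(range(n))

    def _clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            logger.debug("clamping negative branch %.4g", li)
            lj += li
            li = 0.0
        if lj < 0:
            logger.debug("clamping negative branch %.4g", lj)
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        q[np.tril_indices(m)] = np.inf
        # smallest (a, b) among ties for the minimum Q
        ties = np.argwhere(q <= q.min() + 1e-12)
        a, b = min((int(x), int(y)) for x, y in ties)
        i, j = active[a], active[b]
        li = 0.5 * sub[a, b] + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = sub[a, b] - li
        li, lj = _clamp(li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        # new node distances: d(u, k) = (d_ik + d_jk - d_ij) / 2
        new_row = 0.5 * (dist[i, :] + dist[j, :] - dist[i, j])
        dist = np.vstack([dist, new_row])
        dist = np.hstack([dist, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    # star join of the last three nodes
    la = 0.5 * (dist[a, b] + dist[a, c] - dist[b, c])
    lb = 0.5 * (dist[a, b] + dist[b, c] - dist[a, c])
    lc = 0.5 * (dist[a, c] + dist[b, c] - dist[a, b])
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = float(max(length, 0.0))
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return root


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Canonical non-trivial bipartitions of an unrooted tree."""
    leaves = frozenset(t.name for t in tree.tips())
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        if len(side) < len(other) or (
                len(side) == len(other)
                and tuple(sorted(side)) < tuple(sorted(other))):
            parts.add(side)
        else:
            parts.add(frozenset(other))
    return parts


def bootstrap_tree(genotypes: np.ndarray, labels: list[str],
                   n_reps: int = 1000, seed: int = 0) -> TreeNode:
    """NJ tree with bootstrap supports from variant (column) resampling.

    Supports (percent of replicates containing each bipartition of the
    full-data tree) are stored as internal node names; ``n_reps = 0``
    returns the full-data tree without supports.
    """
    g = np.asarray(genotypes)
    tree = neighbor_joining(distance_matrix(g), labels)
    if n_reps == 0:
        return tree
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {p: 0 for p in _bipartitions(tree)}
    m = g.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, m, size=m)
        rep = neighbor_joining(distance_matrix(g[:, cols]), labels)
        for part in _bipartitions(rep):
            if part in counts:
                counts[part] += 1
    leaves = frozenset(labels)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = side if (len(side) < len(other) or (
            len(side) == len(other)
            and tuple(sorted(side)) < tuple(sorted(other)))) else frozenset(other)
        node.name = f"{100.0 * counts[canon] / n_reps:g}"
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> Path:
    """Serialize a tree to Newick (branch lengths; supports as labels)."""
    if tree.count(tips=True) == 0:
        raise ValueError("cannot write an empty tree")
    path = Path(path)
    tree.write(str(path), format="newick")
    return path


def read_newick(source: str | Path) -> TreeNode:
    """Parse a Newick file; raises a parse error naming the position."""
    try:
        return TreeNode.read(str(source), format="newick")
    except Exception as exc:
        raise ValueError(f"malformed Newick in {source}: {exc}") from exc
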