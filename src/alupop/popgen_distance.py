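"""Nei's DA distance, neighbor-joining trees and frequency-matrix PCA.

DA between two populations with allele frequency profiles x, y over r loci:

    DA = 1 - (1/r) * sum_loci sum_alleles sqrt(x_a * y_a)

Neighbor joining is the Saitou-Nei agglomeration on the Q-criterion; it
reconstructs additive distance matrices exactly.  PCA eigendecomposes the
correlation (default) or covariance matrix of a populations x variables
frequency matrix and reports per-component "contributions" (percent of
total variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_data import AlleleFrequencyTable, ValidationError

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PCAResult",
    "nei_da",
    "distance_matrix",
    "neighbor_joining",
    "pca_frequencies",
]

Profile = Mapping[str, Mapping[str, float]]  # locus -> allele -> frequency


def nei_da(x: Profile, y: Profile, loci: Sequence[str]) -> float:
    """Nei's DA distance between two allele-frequency profiles."""
    if not loci:
        raise ValidationError("need at least one locus")
    total = 0.0
    for locus in loci:
        if locus not in x or locus not in y:
            raise ValidationError(f"locus {locus!r} missing from a profile")
        xa, ya = x[locus], y[locus]
        for prof, name in ((xa, "x"), (ya, "y")):
            s = sum(prof.values())
            if abs(s - 1.0) > 0.01:
                raise ValidationError(
                    f"{name} frequencies at {locus} sum to {s:.4f}, not 1"
                )
        total += sum(
            (xa.get(a, 0.0) * ya.get(a, 0.0)) ** 0.5
            for a in set(xa) | set(ya)
        )
    da = 1.0 - total / len(loci)
    return min(max(da, 0.0), 1.0)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValidationError("distance matrix must be symmetric with zero diagonal")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def distance_matrix(freqs: AlleleFrequencyTable, loci: Sequence[str],
                    populations: Sequence[str]) -> DistanceMatrix:
    """Pairwise Nei DA over populations from an allele-frequency table."""
    profiles = {}
    for pop in populations:
        prof = freqs.profile(pop, loci)
        for locus in loci:
            if not prof[locus]:
                raise ValidationError(f"population {pop!r} lacks frequencies at {locus!r}")
        profiles[pop] = prof
    k = len(populations)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = nei_da(
                profiles[populations[i]], profiles[populations[j]], loci
            )
    return DistanceMatrix(labels=list(populations), values=d)


@dataclass
class TreeNode:
    """Unrooted tree node; ``length`` is the branch to the parent."""

    name: Optional[str] = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf():
            return [self.name or ""]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._newick() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.6g}"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions (one side per internal edge)."""
        all_leaves = frozenset(self.leaf_names())
        sides: set[frozenset[str]] = set()

        def walk(node: "TreeNode") -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.name or ""])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                sides.add(below)
                sides.add(all_leaves - below)
            return below

        for c in self.children:
            walk(c)
        return sides


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The Q-criterion minimum is resolved to the lowest (row, column) index
    pair; negative branch lengths are clamped to zero with the deficit
    transferred to the sibling branch.  Returns an unrooted tree as a
    trifurcating root node.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 labels")
    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best  # type: ignore[misc]
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        new = TreeNode(children=[child_i, child_j])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # join the last three around an unrooted internal node
    i, j, k = active
    vi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    vj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    vk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    lengths = [max(v, 0.0) for v in (vi, vj, vk)]
    for node, ln in zip((nodes[i], nodes[j], nodes[k]), lengths):
        node.length = ln
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


@dataclass
class PCAResult:
    scores: pd.DataFrame              # populations x components
    proportion_of_variance: np.ndarray  # percent per component, sums to 100
    convention: str
    variables: list[str]
    loadings: pd.DataFrame | None = None


def pca_frequencies(matrix: pd.DataFrame, convention: str = "correlation") -> PCAResult:
    """PCA of a populations x variables frequency matrix.

    ``convention`` selects the correlation (standardized variables; the
    default, matching classic social-statistics packages) or covariance
    matrix.  Under the correlation convention zero-variance variables are
    dropped with a warning; if every variable is constant this is an error.
    """
    if convention not in ("correlation", "covariance"):
        raise ValidationError(f"unknown PCA convention {convention!r}")
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 populations")
    sd = X.std(axis=0, ddof=1)
    # float roundoff leaves ~1e-17 "variance" on constant columns
    keep = sd > 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))
    if not keep.any():
        raise ValidationError("all variables are constant")
    variables = [v for v, k in zip(matrix.columns, keep) if k]
    if convention == "correlation":
        if not keep.all():
            import warnings
            dropped = [v for v, k in zip(matrix.columns, keep) if not k]
            warnings.warn(f"dropping zero-variance variables: {dropped}", stacklevel=2)
        X = X[:, keep]
        Xc = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        S = np.corrcoef(X, rowvar=False)
        S = np.atleast_2d(S)
    else:
        Xc = X - X.mean(axis=0)
        S = np.cov(X, rowvar=False)
        S = np.atleast_2d(S)
        variables = list(matrix.columns)
    eigval, eigvec = np.linalg.eigh(S)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-magnitude loading positive
    for c in range(eigvec.shape[1]):
        idx = np.argmax(np.abs(eigvec[:, c]))
        if eigvec[idx, c] < 0:
            eigvec[:, c] *= -1
    scores = Xc @ eigvec
    comp_names = [f"PC{i+1}" for i in range(eigvec.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        proportion_of_variance=100.0 * eigval / eigval.sum(),
        convention=convention,
        variables=variables,
        loadings=pd.DataFrame(eigvec, index=variables, columns=comp_names),
    )
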