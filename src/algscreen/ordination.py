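"""Distance matrices, neighbor-joining trees, UniFrac and PCoA.

Neighbor joining follows Saitou & Nei's agglomeration with the usual
non-negativity convention: a negative branch estimate is clamped to
zero and the deficit moved to its sibling so path lengths are
preserved; ties in the Q matrix break by label order for determinism.

UniFrac is computed by postorder accumulation of per-branch leaf masses
over a rooted (midpoint) tree. The unweighted distance is the branch
length unique to either community over the branch length covered by
their union; the weighted distance is the branch-wise L1 difference of
relative abundances, optionally normalized by the abundance-weighted
tree width so values lie in [0, 1]. Values are invariant to the
rooting chosen for traversal.

PCoA is classical metric scaling: double-center -D**2/2, take the
eigendecomposition, scale eigenvectors by the square roots of positive
eigenvalues, and report explained variance over positive eigenvalues.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .diversity import GroupComparison, mann_whitney_u

__all__ = [
    "DistanceMatrix",
    "pairwise_distance",
    "nj_tree",
    "unweighted_unifrac",
    "weighted_unifrac",
    "unifrac_matrix",
    "OrdinationResult",
    "pcoa",
    "group_distance_comparison",
]


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix with a zero diagonal."""

    labels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise ValueError(f"matrix shape {self.data.shape} != ({n}, {n})")
        if not np.allclose(self.data, self.data.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.data < -1e-12).any():
            raise ValueError("negative distances")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.data[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.labels, columns=self.labels)


def pairwise_distance(records) -> DistanceMatrix:
    """p-distance matrix of equal-length aligned sequences.

    Fraction of differing columns; columns where either sequence has a
    gap are excluded pairwise.
    """
    labels = [r.id for r in records]
    seqs = [r.sequence for r in records]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("aligned sequences must have equal length")
    arr = np.array([list(s) for s in seqs])
    gap = (arr == "-") | (arr == ".")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            comparable = int(ok.sum())
            if comparable == 0:
                raise ValueError(f"no comparable columns between {labels[i]} and {labels[j]}")
            d[i, j] = d[j, i] = (arr[i, ok] != arr[j, ok]).mean()
    return DistanceMatrix(labels, d)


def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted scikit-bio tree.

    Negative branch estimates are clamped to zero with the deficit
    transferred to the sibling branch; Q-matrix ties break on the
    lexicographically first label pair.
    """
    n = len(dist.labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    nodes = [TreeNode(name=lab) for lab in dist.labels]
    d = dist.data.astype(float).copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                key = (q[a, b], nodes[active[a]].name or "", nodes[active[b]].name or "")
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = d[i, j]
        li = 0.5 * dij + (totals[ai] - totals[bi]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li  # preserve the pair's path length
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        parent = TreeNode(children=[child_i, child_j])
        nodes.append(parent)
        new = len(nodes) - 1
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = 0.5 * (d[i, k] + d[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [new]
    i, j = active
    if nodes[i].is_tip() and not nodes[j].is_tip():
        i, j = j, i
    # attach the remaining node to the other with the leftover distance
    nodes[j].length = max(d[i, j], 0.0)
    if nodes[i].is_tip():
        root = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = 0.0
    else:
        nodes[i].append(nodes[j])
        root = nodes[i]
    return root


def _branch_masses(
    tree: TreeNode, weights_a: dict[str, float], weights_b: dict[str, float]
):
    """Per-branch (length, massA, massB) by postorder accumulation.

    Masses are the summed leaf weights descending through each branch.
    The root itself carries no branch.
    """
    masses: list[tuple[float, float, float]] = []
    acc: dict[int, tuple[float, float]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            a = float(weights_a.get(node.name, 0.0))
            b = float(weights_b.get(node.name, 0.0))
        else:
            a = sum(acc[id(c)][0] for c in node.children)
            b = sum(acc[id(c)][1] for c in node.children)
        acc[id(node)] = (a, b)
        if node.parent is not None:
            masses.append((float(node.length or 0.0), a, b))
    return masses


def _check_leaves(tree: TreeNode, names) -> None:
    tips = {t.name for t in tree.tips()}
    extra = set(names) - tips
    if extra:
        raise ValueError(f"sample taxa not in tree: {sorted(extra)}")


def unweighted_unifrac(tree: TreeNode, set_a, set_b) -> float:
    """Unweighted UniFrac from the branch-partition definition.

    Branch length leading exclusively to one community's taxa over the
    branch length leading to any observed taxon.
    """
    set_a, set_b = set(set_a), set(set_b)
    if not set_a or not set_b:
        raise ValueError("empty sample")
    _check_leaves(tree, set_a | set_b)
    wa = {t: 1.0 for t in set_a}
    wb = {t: 1.0 for t in set_b}
    unique = shared_total = 0.0
    for length, a, b in _branch_masses(tree, wa, wb):
        in_a, in_b = a > 0, b > 0
        if in_a or in_b:
            shared_total += length
            if in_a != in_b:
                unique += length
    if shared_total == 0:
        return 0.0
    return unique / shared_total


def weighted_unifrac(tree: TreeNode, abund_a, abund_b, normalized: bool = True) -> float:
    """Weighted UniFrac: branch-wise L1 difference of relative abundances.

    ``normalized=True`` divides by the abundance-weighted tree width
    (sum over branches of length times the two communities' combined
    relative mass) so the value lies in [0, 1].
    """
    abund_a, abund_b = dict(abund_a), dict(abund_b)
    ta = sum(abund_a.values())
    tb = sum(abund_b.values())
    if ta <= 0 or tb <= 0:
        raise ValueError("zero-total sample")
    if any(v < 0 for v in abund_a.values()) or any(v < 0 for v in abund_b.values()):
        raise ValueError("negative abundances")
    _check_leaves(tree, set(abund_a) | set(abund_b))
    raw = width = 0.0
    for length, a, b in _branch_masses(tree, abund_a, abund_b):
        pa, pb = a / ta, b / tb
        raw += length * abs(pa - pb)
        width += length * (pa + pb)
    if not normalized:
        return raw
    if width == 0:
        return 0.0
    return raw / width


def unifrac_matrix(
    tree: TreeNode,
    table: pd.DataFrame,
    mode: str = "unweighted",
    normalized: bool = True,
) -> DistanceMatrix:
    """All-pairs UniFrac over a samples x phylotypes count table."""
    samples = list(table.index)
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ri = table.iloc[i]
            rj = table.iloc[j]
            if mode == "unweighted":
                val = unweighted_unifrac(
                    tree, set(table.columns[ri > 0]), set(table.columns[rj > 0])
                )
            elif mode == "weighted":
                val = weighted_unifrac(tree, ri.to_dict(), rj.to_dict(), normalized)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            d[i, j] = d[j, i] = val
    return DistanceMatrix([str(s) for s in samples], d)


@dataclass
class OrdinationResult:
    labels: list[str]
    coordinates: np.ndarray  # n x k, axes ordered by eigenvalue
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    explained: np.ndarray  # fractions over positive eigenvalues


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Classical metric scaling of a distance matrix."""
    n = len(dist.labels)
    if n < 2:
        raise ValueError("need at least 2 points")
    d2 = dist.data**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-10
    pos = vals > tol
    vals_pos = vals[pos]
    coords = vecs[:, pos] * np.sqrt(vals_pos)
    # sign convention: first non-zero loading of each axis positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    explained = vals_pos / vals_pos.sum() if vals_pos.size else vals_pos
    return OrdinationResult(list(dist.labels), coords, vals_pos, explained)


def group_distance_comparison(
    dist: DistanceMatrix,
    groups: dict[str, str],
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> dict:
    """Within/within/between distance lists and their pairwise tests.

    Partitions the upper triangle into A-A, B-B and A-B lists and runs
    Mann-Whitney tests among the three lists at ``alpha``.
    """
    unknown = {s for s in dist.labels if s not in groups}
    if unknown:
        raise ValueError(f"samples without group labels: {sorted(unknown)}")
    idx = {group_a: [], group_b: []}
    for s in dist.labels:
        g = groups[s]
        if g not in idx:
            raise ValueError(f"sample {s!r} has unexpected group {g!r}")
        idx[g].append(dist.labels.index(s))
    for g, members in idx.items():
        if len(members) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    lists: dict[str, list[float]] = {"within_a": [], "within_b": [], "between": []}
    n = len(dist.labels)
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = groups[dist.labels[i]], groups[dist.labels[j]]
            val = float(dist.data[i, j])
            if gi == gj == group_a:
                lists["within_a"].append(val)
            elif gi == gj == group_b:
                lists["within_b"].append(val)
            else:
                lists["between"].append(val)
    tests = {}
    pairs = [
        ("within_a", "within_b"),
        ("within_a", "between"),
        ("within_b", "between"),
    ]
    for a, b in pairs:
        tests[f"{a}_vs_{b}"] = mann_whitney_u(
            lists[a], lists[b], alpha=alpha, group_a=a, group_b=b
        )
    return {"distances": lists, "tests": tests}
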