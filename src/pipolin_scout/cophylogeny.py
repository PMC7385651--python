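"""Tree congruence statistics.

Given a host-strain tree and an element tree with a one-to-one
host-to-element association, this module computes:

* cophenetic (patristic) distance matrices;
* the cophenetic correlation coefficient (CCC): the Pearson correlation
  between the two trees' matched pairwise-distance vectors;
* PACo, the Procrustean Approach to Cophylogeny: classical-scaling
  ordinations of both distance matrices are superimposed by
  least-squares Procrustes (translation, rotation, uniform scaling);
  the global fit m2_XY is the residual sum of squares — small when the
  host tree predicts the element tree — tested against a null that
  permutes the link assignment;
* leave-one-link-out jackknifed squared residuals, flagging which
  host-element links are congruent;
* tanglegram export tables with a link-crossing count.

Newick handling is delegated to scikit-bio.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.stats
from skbio import TreeNode

__all__ = [
    "DistanceMatrix",
    "PacoResult",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "cophenetic_matrix",
    "ccc",
    "pcoa",
    "paco_fit",
    "paco_jackknife",
    "tanglegram_export",
    "TanglegramTable",
]


class NewickParseError(ValueError):
    pass


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for these inputs (e.g. zero variance)."""


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string; duplicate labels or malformed syntax raise
    :class:`NewickParseError` with the parser's position message."""
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:  # skbio raises NewickFormatError subclasses
        raise NewickParseError(str(exc)) from exc
    labels = [t.name for t in tree.tips()]
    if any(lbl is None for lbl in labels):
        raise NewickParseError("unlabeled leaf in tree")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickParseError(f"duplicate leaf labels: {dupes}")
    return tree


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


@dataclass
class DistanceMatrix:
    labels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.data, self.data.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.data < -1e-12).any():
            raise ValueError("negative distances")

    def restrict(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.data[np.ix_(idx, idx)])


def _as_tree(tree: TreeNode | str) -> TreeNode:
    return parse_newick(tree) if isinstance(tree, str) else tree


def cophenetic_matrix(tree: TreeNode | str) -> DistanceMatrix:
    """Patristic distances: sum of branch lengths along the leaf-to-leaf
    path.  Missing branch lengths are an error (no unit-length fallback)."""
    tree = _as_tree(tree)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(f"missing branch length above {node.name or 'internal node'}")
    dm = tree.tip_tip_distances()
    labels = list(dm.ids)
    return DistanceMatrix(labels, np.asarray(dm.data, dtype=float))


def _matched_vectors(
    host_dm: DistanceMatrix, elem_dm: DistanceMatrix, association: dict[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    hosts = [h for h in host_dm.labels if h in association]
    elems = [association[h] for h in hosts]
    if len(hosts) < 3:
        raise ValueError("need at least 3 linked leaf pairs")
    if len(set(elems)) != len(elems):
        raise ValueError("association must be one-to-one")
    H = host_dm.restrict(hosts).data
    E = elem_dm.restrict(elems).data
    iu = np.tril_indices(len(hosts), k=-1)
    return H[iu], E[iu]


def ccc(
    tree_a: TreeNode | str,
    tree_b: TreeNode | str,
    association: Optional[dict[str, str]] = None,
) -> float:
    """Cophenetic correlation coefficient between two trees: Pearson
    correlation of the matched strictly-lower-triangle cophenetic
    distances.  Identity association (shared labels) when none given."""
    dm_a = cophenetic_matrix(tree_a)
    dm_b = cophenetic_matrix(tree_b)
    if association is None:
        common = [l for l in dm_a.labels if l in set(dm_b.labels)]
        association = {l: l for l in common}
    va, vb = _matched_vectors(dm_a, dm_b, association)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise UndefinedStatisticError(
            "cophenetic distances have zero variance; CCC undefined"
        )
    return float(np.corrcoef(va, vb)[0, 1])


def pcoa(dist: DistanceMatrix, eig_rtol: float = 1e-10) -> np.ndarray:
    """Classical scaling (principal coordinates): double-center -D**2/2,
    eigendecompose, keep axes with eigenvalue > eig_rtol * max eigenvalue
    (negative eigenvalues dropped), coordinates = eigenvectors *
    sqrt(eigenvalues)."""
    D = dist.data
    if not D.any():
        raise ValueError("all-zero distance matrix")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > eig_rtol * vals.max()
    return vecs[:, keep] * np.sqrt(vals[keep])


@dataclass
class PacoResult:
    m2_global: float
    p_value: Optional[float]
    n_permutations: int
    per_link_sq_residuals: dict[tuple[str, str], float]
    jackknife: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        total = sum(self.per_link_sq_residuals.values())
        if abs(total - self.m2_global) > 1e-9 * max(1.0, self.m2_global):
            raise ValueError("per-link residuals do not sum to m2_global")


def _pad_columns(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = max(X.shape[1], Y.shape[1])
    Xp = np.pad(X, ((0, 0), (0, k - X.shape[1])))
    Yp = np.pad(Y, ((0, 0), (0, k - Y.shape[1])))
    return Xp, Yp


def _procrustes_residuals(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Squared per-row residuals after least-squares superimposition of Y
    onto X (translation, rotation, uniform scaling)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    U, s, Vt = np.linalg.svd(Yc.T @ Xc)
    denom = (Yc ** 2).sum()
    if denom == 0:
        return (Xc ** 2).sum(axis=1)
    scale = s.sum() / denom
    Yfit = scale * Yc @ (U @ Vt)
    return ((Xc - Yfit) ** 2).sum(axis=1)


def _link_coordinates(
    host_dist: DistanceMatrix,
    elem_dist: DistanceMatrix,
    association: dict[str, str],
) -> tuple[list[tuple[str, str]], np.ndarray, np.ndarray]:
    hosts = [h for h in host_dist.labels if h in association]
    elems = [association[h] for h in hosts]
    if len(set(elems)) != len(elems) or len(elems) != len(set(hosts)):
        raise ValueError("association must be one-to-one")
    dropped = [h for h in host_dist.labels if h not in association]
    if dropped:
        import logging

        logging.getLogger(__name__).info("pruned unlinked host leaves: %s", dropped)
    X = pcoa(host_dist.restrict(hosts))
    Y = pcoa(elem_dist.restrict(elems))
    X, Y = _pad_columns(X, Y)
    links = list(zip(hosts, elems))
    return links, X, Y


def paco_fit(
    host_dist: DistanceMatrix,
    elem_dist: DistanceMatrix,
    association: dict[str, str],
    n_permutations: int = 999,
    seed: Optional[int] = None,
) -> PacoResult:
    """PACo global fit.

    X and Y are the PCoA ordinations of the host and element distance
    matrices, rows ordered by links and zero-padded to equal width; m2_XY
    is the Procrustes residual sum of squares of Y superimposed onto X.
    The null permutes the element-to-host link assignment; the p-value is
    (1 + #{m2_perm <= m2_obs}) / (n_permutations + 1)."""
    links, X, Y = _link_coordinates(host_dist, elem_dist, association)
    if len(links) < 4:
        raise ValueError("PACo requires at least 4 links")
    resid = _procrustes_residuals(X, Y)
    m2 = float(resid.sum())
    p_value: Optional[float] = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        n = len(links)
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            m2_perm = float(_procrustes_residuals(X, Y[perm]).sum())
            if m2_perm <= m2:
                count += 1
        p_value = (1 + count) / (n_permutations + 1)
    return PacoResult(
        m2_global=m2,
        p_value=p_value,
        n_permutations=n_permutations,
        per_link_sq_residuals={lk: float(r) for lk, r in zip(links, resid)},
        seed=seed,
    )


def paco_jackknife(
    host_dist: DistanceMatrix,
    elem_dist: DistanceMatrix,
    association: dict[str, str],
    confidence: float = 0.95,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Leave-one-link-out jackknife of each link's squared residual.

    For replicate i (link i removed) and every remaining link j, the
    pseudovalue is n*r_j - (n-1)*r_j^(-i); each link's jackknife mean and
    a t-based upper confidence bound are returned."""
    links, X, Y = _link_coordinates(host_dist, elem_dist, association)
    n = len(links)
    if n < 5:
        raise ValueError("jackknife requires at least 5 links")
    full = _procrustes_residuals(X, Y)
    pseudo = np.full((n, n), np.nan)  # [replicate i, link j]
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        r_sub = _procrustes_residuals(X[keep], Y[keep])
        pseudo[i, keep] = n * full[keep] - (n - 1) * r_sub
    out: dict[tuple[str, str], tuple[float, float]] = {}
    t_crit = scipy.stats.t.ppf(1 - (1 - confidence) / 2, n - 1)
    for j, link in enumerate(links):
        vals = pseudo[~np.isnan(pseudo[:, j]), j]
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        out[link] = (mean, mean + t_crit * se)
    return out


# ---------------------------------------------------------------------------
# Tanglegram
# ---------------------------------------------------------------------------

@dataclass
class TanglegramTable:
    left_order: list[str]
    right_order: list[str]
    links: list[tuple[str, str]]
    n_crossings: int


def _barycenter_pass(tree: TreeNode, position: dict[str, float]) -> list[str]:
    """One bottom-up barycenter pass: reorder each internal node's children
    by the mean linked position of their leaves; return leaf order."""

    def mean_pos(node: TreeNode) -> float:
        vals = [position[t.name] for t in node.tips() if t.name in position]
        if node.is_tip() and node.name in position:
            vals = [position[node.name]]
        return float(np.mean(vals)) if vals else float("inf")

    for node in tree.postorder(include_self=True):
        if not node.is_tip() and node.children:
            node.children = sorted(node.children, key=mean_pos)
    order = []
    for t in tree.tips():
        order.append(t.name)
    if tree.is_tip():
        order = [tree.name]
    return order


def count_crossings(links: list[tuple[int, int]]) -> int:
    """Number of crossing link pairs: (i, j) cross iff their left and right
    positions are oppositely ordered."""
    if not links:
        return 0
    a = np.array([l[0] for l in links])
    b = np.array([l[1] for l in links])
    da = a[:, None] - a[None, :]
    db = b[:, None] - b[None, :]
    return int(((da * db) < 0).sum() // 2)


def tanglegram_export(
    tree_a: TreeNode | str,
    tree_b: TreeNode | str,
    association: dict[str, str],
    untangle: bool = True,
) -> TanglegramTable:
    """Plot-ready tanglegram table: deterministic leaf orderings (the left
    tree as parsed; the right tree after a single barycenter-ordering pass
    when ``untangle``), the link list, and the crossing count."""
    ta = _as_tree(tree_a)
    tb = _as_tree(tree_b).copy()
    left_order = [t.name for t in ta.tips()]
    if not left_order:
        left_order = [ta.name]
    left_pos = {name: i for i, name in enumerate(left_order)}
    # linked position of each right leaf = position of its host leaf
    rev = {e: h for h, e in association.items()}
    right_target = {
        e: float(left_pos[h]) for e, h in rev.items() if h in left_pos
    }
    if untangle:
        right_order = _barycenter_pass(tb, right_target)
    else:
        right_order = [t.name for t in tb.tips()] or [tb.name]
    right_pos = {name: i for i, name in enumerate(right_order)}
    links = [
        (h, e) for h, e in association.items()
        if h in left_pos and e in right_pos
    ]
    idx_links = [(left_pos[h], right_pos[e]) for h, e in links]
    return TanglegramTable(
        left_order=left_order,
        right_order=right_order,
        links=links,
        n_crossings=count_crossings(idx_links),
    )
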