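"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written against the mathematical definition, in plain
Python, without reusing the package's alignment or Procrustes code paths.
"""

from __future__ import annotations

import numpy as np


def sw_affine_score(query: str, target: str, substitution, gap_open: float,
                    gap_extend: float) -> float:
    """Smith-Waterman local alignment score with affine gaps (Gotoh),
    quadratic space, O(nm) time.  A gap of length k costs
    gap_open + k * gap_extend (the first gap residue pays open+extend).

    ``substitution(a, b)`` returns the score of aligning letters a and b.
    """
    n, m = len(query), len(target)
    NEG = float("-inf")
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in target (query letter unmatched)
    F = np.full((n + 1, m + 1), NEG)  # gap in query
    first = gap_open + gap_extend
    best = 0.0
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            E[i, j] = max(H[i - 1, j] - first, E[i - 1, j] - gap_extend)
            F[i, j] = max(H[i, j - 1] - first, F[i, j - 1] - gap_extend)
            diag = H[i - 1, j - 1] + substitution(qi, target[j - 1])
            H[i, j] = max(0.0, diag, E[i, j], F[i, j])
            if H[i, j] > best:
                best = H[i, j]
    return best


def dna_substitution(match: float = 2.0, mismatch: float = -3.0):
    def sub(a: str, b: str) -> float:
        if a == "N" or b == "N":
            return mismatch
        return match if a == b else mismatch

    return sub


def blosum62_substitution():
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")

    def sub(a: str, b: str) -> float:
        return float(mat[a, b])

    return sub


def procrustes_m2_closed_form(X: np.ndarray, Y: np.ndarray) -> float:
    """Least-squares Procrustes (translation, rotation, uniform scaling of Y
    onto X) residual sum of squares via the closed form
    m2 = ||Xc||^2 - (sum of singular values of Yc'Xc)^2 / ||Yc||^2."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    s = np.linalg.svd(Yc.T @ Xc, compute_uv=False)
    return float((Xc ** 2).sum() - s.sum() ** 2 / (Yc ** 2).sum())


def crossing_count_bruteforce(links: list[tuple[int, int]]) -> int:
    """O(L^2) pair enumeration of tanglegram link crossings."""
    n = 0
    for i in range(len(links)):
        for j in range(i + 1, len(links)):
            (a1, b1), (a2, b2) = links[i], links[j]
            if (a1 - a2) * (b1 - b2) < 0:
                n += 1
    return n


def patristic_distances(newick: str) -> dict[frozenset, float]:
    """Leaf-to-leaf path-length distances computed by a small recursive
    Newick walk, independent of any tree library."""
    pos = 0

    def parse():
        nonlocal pos
        children = []
        if newick[pos] == "(":
            pos += 1
            while True:
                children.append(parse())
                if newick[pos] == ",":
                    pos += 1
                else:
                    break
            assert newick[pos] == ")"
            pos += 1
        label = ""
        while pos < len(newick) and newick[pos] not in ",():;":
            label += newick[pos]
            pos += 1
        length = 0.0
        if pos < len(newick) and newick[pos] == ":":
            pos += 1
            num = ""
            while pos < len(newick) and newick[pos] not in ",();":
                num += newick[pos]
                pos += 1
            length = float(num)
        return {"label": label, "length": length, "children": children}

    root = parse()
    dists: dict[frozenset, float] = {}

    def walk(node):
        """Return {leaf: distance to this node}; record cross-child pairs."""
        if not node["children"]:
            return {node["label"]: 0.0}
        maps = []
        for ch in node["children"]:
            below = {k: v + ch["length"] for k, v in walk(ch).items()}
            maps.append(below)
        merged: dict[str, float] = {}
        for below in maps:
            for k1, d1 in merged.items():
                for k2, d2 in below.items():
                    dists[frozenset((k1, k2))] = d1 + d2
            merged.update(below)
        return merged

    walk(root)
    return dists


def greedy_cluster_oracle(sequences: list[tuple[str, str]], identity_threshold: float,
                          min_coverage: float, align) -> list[set[str]]:
    """All-pairs greedy clustering oracle: sequences (seq, genome_id) sorted
    longest-first; each joins the first cluster whose representative meets
    the identity/coverage rule under the supplied aligner, else founds one.
    Returns per-cluster genome-id sets in founding order."""
    ordered = sorted(sequences, key=lambda t: (-len(t[0]), t[0], t[1]))
    reps: list[str] = []
    members: list[set[str]] = []
    for seq, gid in ordered:
        for k, rep in enumerate(reps):
            aln = align(seq, rep)
            if aln is None:
                continue
            shorter = min(len(seq), len(rep))
            cov = min(aln.query_end - aln.query_start,
                      aln.target_end - aln.target_start) / shorter
            if aln.identity >= identity_threshold and cov >= min_coverage:
                members[k].add(gid)
                break
        else:
            reps.append(seq)
            members.append({gid})
    return members
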