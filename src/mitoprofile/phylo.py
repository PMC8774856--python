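"""Pairwise distances (p, TN93), neighbour-joining trees and bootstrap supports.

The Tamura–Nei (1993) distance corrects the observed proportion of
differences for unequal base frequencies and the two transition classes
(A<->G among purines, C<->T among pyrimidines):

    d = -2 pA pG / pR * ln(1 - pR P1 / (2 pA pG) - Q / (2 pR))
        -2 pT pC / pY * ln(1 - pY P2 / (2 pT pC) - Q / (2 pY))
        -2 (pR pY - pA pG pY / pR - pT pC pR / pY) * ln(1 - Q / (2 pR pY))

with P1, P2 the purine- and pyrimidine-transition proportions, Q the
transversion proportion, pR = pA + pG, pY = pC + pT, and base frequencies
estimated from the pooled pair of sequences. A pair driving any logarithm
argument non-positive is flagged undefined rather than silently clipped.

Neighbour joining follows Saitou & Nei with a deterministic lexicographic
tie-break; negative branch lengths are clamped to zero with the deficit moved
to the sister branch (the Kuhner–Felsenstein adjustment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import AlignmentError, MitoprofileError
from .seq_io import MultipleAlignment


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    model: str  # "p" | "TN93"
    gap_mode: str = "pairwise_deletion"
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise MitoprofileError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, equal_nan=True):
            raise MitoprofileError("distance matrix is not symmetric")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


def _pair_counts(r1: np.ndarray, r2: np.ndarray) -> dict:
    valid = ~(np.isin(r1, ("-", "N")) | np.isin(r2, ("-", "N")))
    a, b = r1[valid], r2[valid]
    n = int(valid.sum())
    diff = a != b
    ts1 = int((((a == "A") & (b == "G")) | ((a == "G") & (b == "A"))).sum())
    ts2 = int((((a == "C") & (b == "T")) | ((a == "T") & (b == "C"))).sum())
    tv = int(diff.sum()) - ts1 - ts2
    pooled = np.concatenate([a, b])
    freqs = {x: float((pooled == x).sum()) / (2 * n) for x in "ACGT"} if n else {}
    return {"n": n, "ts1": ts1, "ts2": ts2, "tv": tv, "freqs": freqs}


def tn93_distance(counts: dict) -> float:
    """Evaluate the TN93 closed form from pair counts; NaN when undefined."""
    n = counts["n"]
    if n == 0:
        return math.nan
    f = counts["freqs"]
    pA, pC, pG, pT = f["A"], f["C"], f["G"], f["T"]
    pR, pY = pA + pG, pC + pT
    P1, P2, Q = counts["ts1"] / n, counts["ts2"] / n, counts["tv"] / n
    if min(pA * pG, pT * pC, pR, pY) <= 0:
        return math.nan
    x1 = 1.0 - pR * P1 / (2.0 * pA * pG) - Q / (2.0 * pR)
    x2 = 1.0 - pY * P2 / (2.0 * pT * pC) - Q / (2.0 * pY)
    x3 = 1.0 - Q / (2.0 * pR * pY)
    if min(x1, x2, x3) <= 0:
        return math.nan
    return (
        -2.0 * pA * pG / pR * math.log(x1)
        - 2.0 * pT * pC / pY * math.log(x2)
        - 2.0 * (pR * pY - pA * pG * pY / pR - pT * pC * pR / pY) * math.log(x3)
    )


def distance_matrix(
    aln: MultipleAlignment, model: str = "p", gap_mode: str = "pairwise_deletion"
) -> DistanceMatrix:
    """Pairwise p-distances or TN93 distances.

    ``pairwise_deletion`` removes ambiguous positions per pair (the usual
    convention of published pairwise-distance tables); ``complete_deletion``
    removes columns with any gap/N first.
    """
    if aln.n_rows < 2:
        raise AlignmentError("distance matrix requires >= 2 rows")
    if model not in ("p", "TN93"):
        raise MitoprofileError(f"unknown model {model!r}")
    cols = np.array([list(r) for r in aln.rows], dtype="U1")
    if gap_mode == "complete_deletion":
        keep = ~((cols == "-") | (cols == "N")).any(axis=0)
        cols = cols[:, keep]
    elif gap_mode != "pairwise_deletion":
        raise MitoprofileError(f"unknown gap_mode {gap_mode!r}")
    n = aln.n_rows
    values = np.zeros((n, n))
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            c = _pair_counts(cols[i], cols[j])
            if c["n"] == 0:
                raise AlignmentError(
                    f"pair ({aln.ids[i]}, {aln.ids[j]}) has zero considered sites"
                )
            if model == "p":
                d = (c["ts1"] + c["ts2"] + c["tv"]) / c["n"]
            else:
                d = tn93_distance(c)
                if math.isnan(d):
                    undefined.append((aln.ids[i], aln.ids[j]))
            values[i, j] = values[j, i] = d
    return DistanceMatrix(
        ids=list(aln.ids), values=values, model=model, gap_mode=gap_mode,
        undefined_pairs=undefined,
    )


def overall_mean_distance(matrix: DistanceMatrix) -> float:
    """Mean of the n(n-1)/2 off-diagonal entries."""
    n = len(matrix.ids)
    if n < 2:
        raise MitoprofileError("overall mean distance requires n >= 2")
    iu = np.triu_indices(n, k=1)
    return float(np.nanmean(matrix.values[iu]))


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for ch in self.children for lf in ch.leaves()]


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary trifurcating root."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return sorted(lf.name for lf in self.root.leaves())

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalised as the side not
        containing the alphabetically first leaf."""
        all_leaves = set(self.leaf_names())
        anchor = min(all_leaves)
        parts: set[frozenset] = set()

        def walk(node: TreeNode) -> set:
            if node.is_leaf:
                return {node.name}
            below = set()
            for ch in node.children:
                sub = walk(ch)
                below |= sub
                if 1 < len(sub) < len(all_leaves) - 1:
                    side = sub if anchor not in sub else all_leaves - sub
                    parts.add(frozenset(side))
            return below

        walk(self.root)
        return parts

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}:{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tokens = _tokenize_newick(text.strip())
        node, idx = _parse_newick(tokens, 0)
        return cls(root=node)


def _tokenize_newick(text: str) -> list[str]:
    out, buf = [], ""
    for ch in text:
        if ch in "(),:;":
            if buf:
                out.append(buf)
                buf = ""
            out.append(ch)
        elif not ch.isspace():
            buf += ch
    if buf:
        out.append(buf)
    return out


def _parse_newick(tokens: list[str], i: int) -> tuple[TreeNode, int]:
    node = TreeNode()
    if tokens[i] == "(":
        i += 1
        while True:
            child, i = _parse_newick(tokens, i)
            node.children.append(child)
            if tokens[i] == ",":
                i += 1
                continue
            break
        assert tokens[i] == ")", f"expected ')' at token {i}"
        i += 1
        if i < len(tokens) and tokens[i] not in "(),:;":
            node.support = float(tokens[i])
            i += 1
    else:
        node.name = tokens[i]
        i += 1
    if i < len(tokens) and tokens[i] == ":":
        node.length = float(tokens[i + 1])
        i += 2
    return node, i


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbour joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest pair
    of cluster labels (a cluster is labelled by its smallest member id).
    Negative branch lengths are clamped to zero and the deficit moved to the
    sister branch so path lengths are preserved.
    """
    n = len(matrix.ids)
    if n < 3:
        raise MitoprofileError("neighbour joining requires >= 3 taxa")
    if np.isnan(matrix.values).any():
        raise MitoprofileError("distance matrix contains undefined entries")
    nodes: dict[str, TreeNode] = {name: TreeNode(name=name) for name in matrix.ids}
    labels = list(matrix.ids)
    D = {
        (a, b): float(matrix.values[i, j])
        for i, a in enumerate(matrix.ids)
        for j, b in enumerate(matrix.ids)
        if i != j
    }

    def d(a: str, b: str) -> float:
        return 0.0 if a == b else D[(a, b)]

    while len(labels) > 3:
        r = len(labels)
        sums = {a: sum(d(a, b) for b in labels) for a in labels}
        best = None
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                q = (r - 2) * d(a, b) - sums[a] - sums[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        va = 0.5 * d(a, b) + (sums[a] - sums[b]) / (2.0 * (r - 2))
        vb = d(a, b) - va
        if va < 0:
            vb, va = vb + va, 0.0
        if vb < 0:
            va, vb = va + vb, 0.0
        parent = TreeNode()
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = va, vb
        parent.children = [na, nb]
        new_label = min(a, b)
        for c in labels:
            if c in (a, b):
                continue
            dc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
            D[(new_label, c)] = D[(c, new_label)] = max(dc, 0.0)
        labels = sorted(set(labels) - {a, b} | {new_label})
        nodes[new_label] = parent

    # final trifurcation: three-point formulas
    a, b, c = sorted(labels)
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    root = TreeNode()
    for lbl, ln in ((a, la), (b, lb), (c, lc)):
        node = nodes[lbl]
        node.length = max(ln, 0.0)
        root.children.append(node)
    return PhyloTree(root=root)


def bootstrap_support(
    aln: MultipleAlignment,
    model: str = "TN93",
    B: int = 1000,
    seed: int = 0,
    gap_mode: str = "pairwise_deletion",
) -> PhyloTree:
    """NJ tree with bootstrap supports from column-resampled replicates.

    Support of each internal edge of the point-estimate tree is the
    percentage of replicate trees containing the same bipartition.
    Deterministic given ``seed``; rows are re-sorted by id before resampling
    so supports are invariant to row order.
    """
    if aln.n_rows < 4:
        raise AlignmentError("bootstrap requires >= 4 rows")
    order = sorted(range(aln.n_rows), key=lambda i: aln.ids[i])
    sorted_aln = MultipleAlignment(
        ids=[aln.ids[i] for i in order],
        rows=[aln.rows[i] for i in order],
        reference_id=aln.ids[order[0]],
    )
    point = nj_tree(distance_matrix(sorted_aln, model=model, gap_mode=gap_mode))
    target = point.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    cols = np.array([list(r) for r in sorted_aln.rows], dtype="U1")
    L = cols.shape[1]
    for _ in range(B):
        idx = rng.integers(0, L, size=L)
        rep = MultipleAlignment(
            ids=list(sorted_aln.ids),
            rows=["".join(row) for row in cols[:, idx]],
            reference_id=sorted_aln.reference_id,
        )
        try:
            rep_tree = nj_tree(distance_matrix(rep, model=model, gap_mode=gap_mode))
        except MitoprofileError:
            continue  # replicate with undefined distances contributes nothing
        rep_parts = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_parts:
                counts[bp] += 1

    def annotate(node: TreeNode, all_leaves: set, anchor: str) -> set:
        if node.is_leaf:
            return {node.name}
        below = set()
        for ch in node.children:
            sub = annotate(ch, all_leaves, anchor)
            below |= sub
            if 1 < len(sub) < len(all_leaves) - 1:
                side = sub if anchor not in sub else all_leaves - sub
                ch.support = 100.0 * counts[frozenset(side)] / B
        return below

    leaves = set(point.leaf_names())
    annotate(point.root, leaves, min(leaves))
    return point


def write_newick(path, tree: PhyloTree) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
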