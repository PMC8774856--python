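"""Independent brute-force oracles used to cross-check the scanners and
statistics. Each oracle is a direct enumeration of the documented definition,
deliberately sharing no code with the implementation it checks."""

from __future__ import annotations

import itertools

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def primitive(unit: str) -> bool:
    return all(
        unit != unit[:d] * (len(unit) // d)
        for d in range(1, len(unit))
        if len(unit) % d == 0
    )


def ssr_oracle(seq, unit_min=1, unit_max=10, min_copies=3, min_length=6):
    """All maximal perfect primitive-unit runs as (start, end, unit) 1-based."""
    L = len(seq)
    hits = set()
    for p in range(unit_min, unit_max + 1):
        for a in range(L - p):
            # left-maximality of the single-character periodic run
            if a > 0 and seq[a - 1] == seq[a - 1 + p]:
                continue
            unit = seq[a : a + p]
            if not primitive(unit):
                continue
            e = a + p
            while e < L and seq[e] == seq[e - p]:
                e += 1
            copies = (e - a) // p
            if copies >= min_copies and copies * p >= min_length:
                hits.add((a + 1, a + copies * p, unit))
    return hits


def palindrome_oracle(seq, len_min=6, len_max=30, count_all=False):
    """All qualifying even-length self-reverse-complement windows (start, end)."""
    L = len(seq)
    len_max -= len_max % 2
    is_pal = {}
    for length in range(2, len_max + 1, 2):
        for i in range(L - length + 1):
            w = seq[i : i + length]
            if w == rc(w):
                is_pal[(i, length)] = True
    hits = set()
    for (i, length) in is_pal:
        if length < len_min:
            continue
        if not count_all:
            # maximal per center, capped at len_max
            center = i + length // 2
            bigger = (i - 1, length + 2)
            if length + 2 <= len_max and bigger in is_pal:
                continue
        hits.add((i + 1, i + length))
    return hits


def inverted_oracle(seq, arm_min=6, arm_max=50, gap_min=0, gap_max=20):
    """All maximal inverted-repeat hits as (start, end, arm, gap), 1-based.

    A hit is anchored at its innermost matched pair and extended outward to
    maximality; arms longer than arm_max are trimmed keeping the inner anchor.
    """
    L = len(seq)
    hits = set()
    for p_in in range(L):
        for gap in range(gap_min, gap_max + 1):
            q_in = p_in + gap + 1
            if q_in >= L:
                break
            if seq[p_in] != COMP[seq[q_in]]:
                continue
            # innermost pair of its run?
            if gap >= 2 and seq[p_in + 1] == COMP[seq[q_in - 1]]:
                continue
            t = 1
            while p_in - t >= 0 and q_in + t < L and seq[p_in - t] == COMP[seq[q_in + t]]:
                t += 1
            arm = min(t, arm_max)
            if arm < arm_min:
                continue
            hits.add((p_in - arm + 2, q_in + arm, arm, gap))
    return hits


def diversity_oracle(rows):
    """(pi, k, n_variable, n_singleton, n_informative, m) by direct pairwise
    enumeration over complete-deletion columns."""
    n = len(rows)
    keep = [
        c
        for c in range(len(rows[0]))
        if all(r[c] not in "-N" for r in rows)
    ]
    m = len(keep)
    total = 0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        pairs += 1
        total += sum(rows[i][c] != rows[j][c] for c in keep)
    k = total / pairs
    variable = singleton = informative = 0
    for c in keep:
        col = [r[c] for r in rows]
        states = sorted(set(col))
        if len(states) > 1:
            variable += 1
            counts = sorted(col.count(s) for s in states)
            if all(x == 1 for x in counts[:-1]):
                singleton += 1
            if sum(1 for x in counts if x >= 2) >= 2:
                informative += 1
    return k / m, k, variable, singleton, informative, m


def mst_union_oracle(dists: dict) -> set:
    """Edges belonging to at least one minimum spanning tree, by enumerating
    every spanning tree of the complete graph (tiny inputs only)."""
    nodes = sorted({x for e in dists for x in e})
    n = len(nodes)
    all_edges = sorted(dists)
    best_weight = None
    best_trees = []
    for combo in itertools.combinations(all_edges, n - 1):
        # connectivity check
        parent = {x: x for x in nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for a, b in combo:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if not ok:
            continue
        w = sum(dists[e] for e in combo)
        if best_weight is None or w < best_weight - 1e-12:
            best_weight, best_trees = w, [combo]
        elif abs(w - best_weight) <= 1e-12:
            best_trees.append(combo)
    return {e for tree in best_trees for e in tree}
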