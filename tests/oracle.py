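"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive quantities by the most transparent method
available (dense DP, transitive closure, pair enumeration) and share no code
with the implementation paths they check.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def gotoh_local_score(
    a: str,
    b: str,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
    matrix=None,
) -> float:
    """Optimal local alignment score by dense affine-gap DP.

    Gap convention: a gap of length L costs gap_open + (L-1) * gap_extend.
    """
    matrix = _BLOSUM62 if matrix is None else matrix
    n, m = len(a), len(b)
    # M: a[i-1] aligned to b[j-1]; X: gap in b (consumes a); Y: gap in a.
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = s + max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] + gap_open,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open,
                Y[i][j - 1] + gap_extend,
                X[i][j - 1] + gap_open,
            )
            if M[i][j] > best:
                best = M[i][j]
    return best


def transitive_closure_partition(
    nodes: list, edges: list[tuple]
) -> list[frozenset]:
    """Connected components by naive repeated expansion."""
    blocks = {n: {n} for n in nodes}
    changed = True
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    while changed:
        changed = False
        for n in nodes:
            grown = set(blocks[n])
            for member in list(blocks[n]):
                grown |= adj[member]
                grown |= blocks[member]
            if grown != blocks[n]:
                blocks[n] = grown
                changed = True
    seen = set()
    out = []
    for n in nodes:
        block = frozenset(blocks[n])
        if block not in seen:
            seen.add(block)
            out.append(block)
    return out


def rand_index_pairs(p1: dict, p2: dict) -> float:
    """Rand index by explicit enumeration of all label pairs."""
    labels = sorted(p1)
    assert sorted(p2) == labels
    agree = total = 0
    for x, y in itertools.combinations(labels, 2):
        total += 1
        if (p1[x] == p1[y]) == (p2[x] == p2[y]):
            agree += 1
    return agree / total if total else 1.0


def tree_path_distance(newick_tree, a: str, b: str) -> float:
    """Patristic distance by explicit root-path walk on a skbio TreeNode."""
    ta = newick_tree.find(a)
    tb = newick_tree.find(b)
    ancestors_a = [ta] + list(ta.ancestors())
    ancestors_b = [tb] + list(tb.ancestors())
    common = None
    for node in ancestors_a:
        if node in ancestors_b:
            common = node
            break
    dist = 0.0
    for node in ancestors_a:
        if node is common:
            break
        dist += node.length or 0.0
    for node in ancestors_b:
        if node is common:
            break
        dist += node.length or 0.0
    return dist
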