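"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — direct enumeration or closed-form
expectation — and shares no code path with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def window_means_bruteforce(values, w: int) -> np.ndarray:
    """Mean over index range max(0, k−w)..min(n−1, k+w) at every position."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    out = np.empty(n)
    for k in range(n):
        lo, hi = max(0, k - w), min(n - 1, k + w)
        out[k] = v[lo : hi + 1].mean()
    return out


def _score_alignment(cols_a: str, cols_b: str, score, gap_open: float, gap_extend: float) -> float:
    """Score one gapped alignment: substitution scores plus affine gap run
    costs (a run of length L costs open + (L−1)·extend)."""
    total = 0.0
    for row in (cols_a, cols_b):
        run = 0
        for c in row:
            if c == "-":
                run += 1
            else:
                if run:
                    total -= gap_open + (run - 1) * gap_extend
                run = 0
        if run:
            total -= gap_open + (run - 1) * gap_extend
    for x, y in zip(cols_a, cols_b):
        if x != "-" and y != "-":
            total += score(x, y)
    return total


def best_alignment_score_bruteforce(
    a: str, b: str, score, gap_open: float, gap_extend: float
) -> float:
    """Maximum score over ALL global alignments, by explicit enumeration.

    ``score(x, y)`` is the substitution score function. Feasible for
    sequences up to length ~6 (the number of alignments is the Delannoy
    number, ≤ 8989 at 6×6).
    """
    best = -np.inf
    stack = [(0, 0, "", "")]
    while stack:
        i, j, ca, cb = stack.pop()
        if i == len(a) and j == len(b):
            s = _score_alignment(ca, cb, score, gap_open, gap_extend)
            if s > best:
                best = s
            continue
        if i < len(a) and j < len(b):
            stack.append((i + 1, j + 1, ca + a[i], cb + b[j]))
        if i < len(a):
            stack.append((i + 1, j, ca + a[i], cb + "-"))
        if j < len(b):
            stack.append((i, j + 1, ca + "-", cb + b[j]))
    return best


def upgma_bruteforce(d: np.ndarray, labels: list[str]):
    """Plain UPGMA by repeated minimum search; returns a nested-tuple
    topology with lexicographic ordering inside each clade, e.g.
    ``(('A','B'),('C','D'))``."""
    clusters = {i: labels[i] for i in range(len(labels))}
    sizes = {i: 1 for i in range(len(labels))}
    dist = {
        frozenset((i, j)): float(d[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    nxt = len(labels)
    while len(clusters) > 1:
        pair = min(dist, key=lambda k: (dist[k], sorted(k)))
        i, j = sorted(pair)
        merged = tuple(sorted((clusters[i], clusters[j]), key=str))
        ni, nj = sizes[i], sizes[j]
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((nxt, k))] = (ni * dik + nj * djk) / (ni + nj)
        dist.pop(pair)
        del clusters[i], clusters[j], sizes[i], sizes[j]
        clusters[nxt] = merged
        sizes[nxt] = ni + nj
        nxt += 1
    (tree,) = clusters.values()
    return tree


def topology_from_newick(newick: str):
    """Parse a Newick string into the same nested-tuple form as
    :func:`upgma_bruteforce` (branch lengths ignored, clades sorted)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")

    def recurse(node):
        if node.is_leaf():
            return node.taxon.label
        kids = [recurse(c) for c in node.child_nodes()]
        return tuple(sorted(kids, key=str))

    return recurse(tree.seed_node)


def expected_aa_divergence(
    ancestor_codons: np.ndarray, p_a: float, p_b: float, aa_of_codon, stop_mask
) -> float:
    """Exact expected fraction of amino-acid differences between two leaves.

    The substitution process mutates each site independently with
    probability p (uniform over the 3 alternative bases) and reverts any
    codon that would become a stop, so a descendant codon distribution is

        P(c) = P0(c)            for non-stop c ≠ c0
        P(c0) = P0(c0) + Σ_stop P0(stop)

    with P0 the site-independent product. The two branches are independent
    given the ancestor.
    """

    def codon_distribution(c0: int, p: float) -> np.ndarray:
        b = [(c0 // 16) % 4, (c0 // 4) % 4, c0 % 4]
        dist = np.zeros(64)
        for t in range(64):
            tb = [(t // 16) % 4, (t // 4) % 4, t % 4]
            pr = 1.0
            for s in range(3):
                pr *= (1 - p) if tb[s] == b[s] else p / 3.0
            dist[t] = pr
        stop_mass = dist[stop_mask].sum()
        dist[stop_mask] = 0.0
        dist[c0] += stop_mass
        return dist

    idx = (
        16 * ancestor_codons[:, 0].astype(int)
        + 4 * ancestor_codons[:, 1].astype(int)
        + ancestor_codons[:, 2].astype(int)
    )
    aa = np.array([ord(c) for c in aa_of_codon])
    diff_given_c0: dict[int, float] = {}
    total = 0.0
    for c0 in idx:
        c0 = int(c0)
        if c0 not in diff_given_c0:
            da = codon_distribution(c0, p_a)
            db = codon_distribution(c0, p_b)
            same = 0.0
            for aa_val in np.unique(aa):
                mask = aa == aa_val
                same += da[mask].sum() * db[mask].sum()
            diff_given_c0[c0] = 1.0 - same
        total += diff_given_c0[c0]
    return total / len(idx)


def all_sequences(alphabet: str, max_len: int):
    for n in range(1, max_len + 1):
        for tup in itertools.product(alphabet, repeat=n):
            yield "".join(tup)
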