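"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: plain dicts,
integer arithmetic and exhaustive enumeration only.
"""

from __future__ import annotations

import itertools
import math
from math import comb

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(word: str) -> str:
    return "".join(_COMP[c] for c in reversed(word))


def count_kmers_dict(seq: str, k: int, canonical: bool = False) -> tuple[dict, int]:
    """Sliding-window dict counter; windows with non-ACGT skipped."""
    counts: dict[str, int] = {}
    n_windows = 0
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(c not in "ACGT" for c in w):
            continue
        if canonical:
            w = min(w, revcomp(w))
        counts[w] = counts.get(w, 0) + 1
        n_windows += 1
    return counts, n_windows


def letter_freqs(seq: str) -> dict[str, float]:
    valid = [c for c in seq if c in "ACGT"]
    return {b: valid.count(b) / len(valid) for b in "ACGT"}


def d2s_similarity_bruteforce(
    seq_x: str, seq_y: str, k: int, canonical: bool = False, all_words: bool = False
) -> float:
    """Direct evaluation of the D2S sum, word by word.

    ``all_words`` sums over every possible k-word instead of the union of
    observed words (the documented comparison variant).
    """
    cx, nx = count_kmers_dict(seq_x, k, canonical)
    cy, ny = count_kmers_dict(seq_y, k, canonical)
    fx, fy = letter_freqs(seq_x), letter_freqs(seq_y)

    def prob(word: str, f: dict[str, float]) -> float:
        p = 1.0
        for c in word:
            p *= f[c]
        if canonical and word != revcomp(word):
            q = 1.0
            for c in revcomp(word):
                q *= f[c]
            p += q
        return p

    if all_words:
        words = ["".join(t) for t in itertools.product("ACGT", repeat=k)]
        if canonical:
            words = sorted({min(w, revcomp(w)) for w in words})
    else:
        words = sorted(set(cx) | set(cy))
    total = 0.0
    for w in words:
        xt = cx.get(w, 0) - nx * prob(w, fx)
        yt = cy.get(w, 0) - ny * prob(w, fy)
        denom = math.sqrt(xt * xt + yt * yt)
        if denom > 0:
            total += xt * yt / denom
    return total


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Minimum-likelihood two-sided p by integer hypergeometric enumeration."""
    n1, K, N = a + b, a + c, a + b + c + d
    lo, hi = max(0, K - (N - n1)), min(n1, K)
    pmf = {x: comb(n1, x) * comb(N - n1, K - x) for x in range(lo, hi + 1)}
    obs = pmf[a]
    return sum(v for v in pmf.values() if v <= obs) / comb(N, K)


def fisher_one_sided_greater(a: int, b: int, c: int, d: int) -> float:
    """P(A >= a) under the hypergeometric null (enrichment direction)."""
    n1, K, N = a + b, a + c, a + b + c + d
    hi = min(n1, K)
    return sum(
        comb(n1, x) * comb(N - n1, K - x) for x in range(a, hi + 1)
    ) / comb(N, K)


def mann_whitney_exact_two_sided(x, y) -> tuple[float, float]:
    """U of x and two-sided p by full enumeration of rank assignments."""
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    combined = sorted(x + y)
    assert len(set(combined)) == len(combined), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    mean_u = n1 * n2 / 2
    count = 0
    total = 0
    for subset in itertools.combinations(range(1, n1 + n2 + 1), n1):
        u = sum(subset) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return u_obs, count / total


def random_binary_tree_newick(labels, rng: np.random.Generator) -> str:
    """Random binary topology with uniform(0.1, 1.0) branch lengths."""
    nodes = [f"{t}:{rng.uniform(0.1, 1.0):.6f}" for t in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.1, 1.0):.6f}"
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]});"


def patristic_distances(tree) -> dict[frozenset, float]:
    """Leaf-pair path lengths on a PhyloTree, by edge contributions."""
    tips = tree.tip_labels
    dist: dict[frozenset, float] = {
        frozenset(p): 0.0 for p in itertools.combinations(tips, 2)
    }
    for node, leafset in tree._leafsets():
        if node.parent_node is None:
            continue
        length = node.edge.length or 0.0
        inside, outside = leafset, tips - leafset
        for a in inside:
            for b in outside:
                dist[frozenset((a, b))] += length
    return dist
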