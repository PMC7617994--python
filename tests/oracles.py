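"""Independent brute-force reference implementations.

Deliberately written with plain loops and per-item rule application so
they share no code path with the package implementations they check.
"""

from collections import defaultdict

import numpy as np


def consensus_pairs_oracle(rows):
    """Exhaustive application of the tiered 1:1 consensus rule.

    ``rows``: iterable of (gene_a, gene_b, level) for one species pair
    (gene_a from side A, gene_b from side B). A pair (a, b) is called
    iff, at the most stringent level at which a has any partner, b is
    a's only partner - and symmetrically for b.
    """
    levels_a = defaultdict(set)  # gene_a -> set of levels
    levels_b = defaultdict(set)
    partners_a = defaultdict(set)  # (gene_a, level) -> set of gene_b
    partners_b = defaultdict(set)
    links = set()
    for ga, gb, lv in rows:
        levels_a[ga].add(lv)
        levels_b[gb].add(lv)
        partners_a[(ga, lv)].add(gb)
        partners_b[(gb, lv)].add(ga)
        links.add((ga, gb))

    called = set()
    for ga, gb in links:
        la = min(levels_a[ga])
        lb = min(levels_b[gb])
        if partners_a[(ga, la)] == {gb} and partners_b[(gb, lb)] == {ga}:
            called.add((ga, gb))
    return called


def gene_jaccard_oracle(on_sets):
    """Jaccard distance from per-species ON-class sets; None if union empty."""
    union = set()
    for s in on_sets:
        union |= set(s)
    if not union:
        return None
    inter = set(on_sets[0])
    for s in on_sets[1:]:
        inter &= set(s)
    return (len(union) - len(inter)) / len(union)


def edge_labels_oracle(adjacency_by_species):
    """Per-edge presence labels by exhaustive pairwise inspection."""
    species = list(adjacency_by_species)
    n = adjacency_by_species[species[0]].shape[0]
    labels = {}
    for i in range(n):
        for j in range(n):
            present = [sp for sp in species if adjacency_by_species[sp][i, j]]
            if not present:
                continue
            if len(present) == len(species):
                labels[(i, j)] = "core"
            elif len(present) == 1:
                labels[(i, j)] = f"specific:{present[0]}"
            else:
                labels[(i, j)] = "two_species"
    return labels


def receptivity_flags_oracle(counts_by_species):
    """Altered flag from raw per-species category counts (max>=2 & min==0)."""
    values = list(counts_by_species)
    return max(values) >= 2 and min(values) == 0


def hypergeom_upper_tail(M, n_success, N_draw, k):
    """Exact upper-tail hypergeometric probability by summation."""
    from math import comb

    total = comb(M, N_draw)
    acc = 0
    for x in range(k, min(n_success, N_draw) + 1):
        if N_draw - x > M - n_success:
            continue
        acc += comb(n_success, x) * comb(M - n_success, N_draw - x)
    return acc / total


def bh_adjust_oracle(pvals):
    """Closed-form Benjamini-Hochberg step-up adjustment."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, pvals[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj
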