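"""Independent brute-force oracles used by the test suite.

Each oracle re-derives the expected result by direct enumeration, deliberately
sharing no code path with the implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb


def brute_force_assign(read_seqs, gene_seqs, max_mismatches):
    """All-pairs, all-offsets recount of read assignment.

    Returns (counts_by_gene_index, n_assigned, n_ambiguous, n_unassigned),
    replicating the rules: best (minimum) Hamming distance over every offset
    of every gene; unique best gene within max_mismatches -> assigned; tie
    between genes -> ambiguous; otherwise unassigned.
    """
    counts: dict[int, int] = {}
    n_assigned = n_ambiguous = n_unassigned = 0
    for read in read_seqs:
        L = len(read)
        best_d = max_mismatches + 1
        best_genes: set[int] = set()
        for gi, gene in enumerate(gene_seqs):
            gene_best = None
            for start in range(len(gene) - L + 1):
                d = sum(a != b for a, b in zip(read, gene[start:start + L]))
                if gene_best is None or d < gene_best:
                    gene_best = d
            if gene_best is None:
                continue
            if gene_best < best_d:
                best_d = gene_best
                best_genes = {gi}
            elif gene_best == best_d:
                best_genes.add(gi)
        if best_d > max_mismatches or not best_genes:
            n_unassigned += 1
        elif len(best_genes) > 1:
            n_ambiguous += 1
        else:
            gi = best_genes.pop()
            counts[gi] = counts.get(gi, 0) + 1
            n_assigned += 1
    return counts, n_assigned, n_ambiguous, n_unassigned


def fisher_greater_p(count_bait, total_bait, count_empty, total_empty):
    """Exact one-sided (bait greater) Fisher p by full hypergeometric
    enumeration over all 2x2 tables with the observed margins."""
    n = count_bait + count_empty
    denom = comb(total_bait + total_empty, n)
    num = sum(
        comb(total_bait, x) * comb(total_empty, n - x)
        for x in range(count_bait, min(total_bait, n) + 1)
        if n - x <= total_empty
    )
    return Fraction(num, denom)


def sliding_window_tm_segments(seq, window, threshold, scale):
    """Naive O(n*w) re-computation of hydropathy segments."""
    seq = seq.strip().upper()
    n = len(seq)
    if n < window:
        return []
    above = []
    for s in range(n - window + 1):
        mean = sum(scale.get(c, 0.0) for c in seq[s:s + window]) / window
        above.append(mean > threshold)
    extents = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            extents.append((i + 1, j + window))
            i = j + 1
        else:
            i += 1
    merged = []
    for start, end in extents:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def hypergeom_tail_by_enumeration(universe, term_genes, hits):
    """P(overlap >= observed) by enumerating every possible hit set of the
    same size drawn from the universe (universes <= 15 only)."""
    universe = sorted(universe)
    term = set(term_genes) & set(universe)
    hits = set(hits)
    k_obs = len(term & hits)
    n = len(hits)
    total = 0
    favourable = 0
    for draw in combinations(universe, n):
        total += 1
        if len(term & set(draw)) >= k_obs:
            favourable += 1
    return Fraction(favourable, total)
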