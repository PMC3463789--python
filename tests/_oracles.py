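"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: descendants by
repeated edge expansion, obligate ancestors by exhaustive ancestry-path
enumeration, heterozygosity by dense positional grids, and Viterbi by
full path enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np


def descendants_by_closure(pedigree, ids):
    """Transitive closure of parent->child edges by repeated expansion."""
    edges = set()
    for ind in pedigree:
        for parent in (ind.sire, ind.dam):
            if parent is not None:
                edges.add((parent, ind.id))
    reach = set(ids)
    while True:
        new = {c for (p, c) in edges if p in reach and c not in reach}
        if not new:
            return reach - set(ids)
        reach |= new


def all_ancestry_paths(pedigree, start):
    """Every path (list of ids) from ``start`` up to a founder, by DFS."""
    paths = []
    stack = [[start]]
    while stack:
        path = stack.pop()
        ind = pedigree[path[-1]]
        if ind.is_founder:
            paths.append(path)
            continue
        for parent in (ind.sire, ind.dam):
            stack.append(path + [parent])
    return paths


def obligate_pairs_by_paths(pedigree, extant):
    """Exhaustively test every historical mating against every ancestry path."""
    paths = {e: all_ancestry_paths(pedigree, e) for e in extant}
    desc = {}

    def descends(animal, ancestor):
        key = (animal, ancestor)
        if key not in desc:
            desc[key] = any(ancestor in p for p in paths[animal])
        return desc[key]

    result = []
    for (sire, dam), offspring in pedigree.matings().items():
        if pedigree[sire].is_founder or pedigree[dam].is_founder:
            continue
        if not all(descends(e, sire) and descends(e, dam) for e in extant):
            continue
        off = set(offspring)
        ok = all(
            any(node in off for node in p) for e in extant for p in paths[e]
        )
        if ok:
            gen = max(pedigree[sire].generation, pedigree[dam].generation)
            result.append((gen, sire, dam))
    return sorted(result)


def het_percent_by_grid(regions, chrom_lengths, step_mb=0.1):
    """Per-position heterozygosity on a regular grid of midpoints."""
    het_cells = 0
    total_cells = 0
    for chrom, clen in chrom_lengths.items():
        n = int(round(clen / step_mb))
        pos = (np.arange(n) + 0.5) * step_mb
        covered = np.zeros(n, dtype=bool)
        for r in regions:
            if r.chrom == chrom:
                covered |= (pos >= r.start_mb) & (pos < r.end_mb)
        het_cells += int(covered.sum())
        total_cells += n
    return 100.0 * het_cells / total_cells


def sib_mating_het_series(n_generations, h0=1.0, h1=None):
    """Iterate H_t = H_{t-1}/2 + H_{t-2}/4 numerically.

    Returns the series [H_0, H_1, ..., H_n]; by default H_1 continues the
    recurrence from a constant pre-history at h0.
    """
    if h1 is None:
        h1 = h0 / 2.0 + h0 / 4.0
    series = [h0, h1]
    for _ in range(n_generations - 1):
        series.append(series[-1] / 2.0 + series[-2] / 4.0)
    return series[: n_generations + 1]


def viterbi_by_enumeration(log_emit, log_trans_steps):
    """Best state path by exhaustive enumeration (tiny instances only).

    ``log_emit`` is (n_markers, n_states); ``log_trans_steps`` a list of
    n_markers-1 transition matrices.  Returns (best_path, best_logp),
    tie-broken toward the lexicographically smallest path.
    """
    n, k = log_emit.shape
    best_path, best_logp = None, -np.inf
    for path in itertools.product(range(k), repeat=n):
        lp = log_emit[0, path[0]]
        for t in range(1, n):
            lp += log_trans_steps[t - 1][path[t - 1], path[t]] + log_emit[t, path[t]]
        if lp > best_logp + 1e-12:
            best_path, best_logp = path, lp
    return list(best_path), best_logp
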