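"""Independent reference implementations used only as test oracles.

Everything here is written with plain loops and from-first-principles
formulas, deliberately avoiding the vectorised code paths of the package,
so agreement between the two is informative.
"""

import numpy as np


# ---------------------------------------------------------------------------
# ROH: exhaustive enumerator over candidate (start, end) SNP pairs


def brute_force_roh(g, pos, params):
    """All ROH segments on one chromosome for one individual.

    Recomputes window passes, per-SNP hit rates, and candidate intervals by
    explicit enumeration: from each feasible start (an eligible homozygous
    call not yet consumed) every candidate end is tested against the full
    constraint set and the maximal valid interval kept; the segment is
    emitted when it also meets the count/length/density filters.
    Returns a list of (start_idx, end_idx) tuples.
    """
    g = list(g)
    pos = list(pos)
    m = len(g)
    w = min(params.window_snps, m)
    n_win = m - w + 1
    passing = []
    for i in range(n_win):
        win = g[i:i + w]
        n_het = sum(1 for x in win if x == 1)
        n_mis = sum(1 for x in win if x == -1)
        passing.append(n_het <= params.window_max_het
                       and n_mis <= params.window_max_missing)
    eligible = []
    for j in range(m):
        covering = [i for i in range(n_win) if i <= j <= i + w - 1]
        hits = sum(1 for i in covering if passing[i])
        eligible.append(hits / len(covering) > params.window_threshold)

    def interval_valid(s, e):
        for t in range(s, e + 1):
            if not eligible[t]:
                return False
        if g[s] in (1, -1) or g[e] in (1, -1):
            return False
        if sum(1 for t in range(s, e + 1) if g[t] == 1) > params.max_het_per_segment:
            return False
        for t in range(s, e):
            if pos[t + 1] - pos[t] > params.max_gap_bp:
                return False
        return True

    def passes_filters(s, e):
        n = e - s + 1
        length = pos[e] - pos[s] + 1
        if params.strict_min_snps:
            if n <= params.min_snps:
                return False
        elif n < params.min_snps:
            return False
        return (length >= params.min_length_bp
                and length / n <= params.min_density_bp_per_snp)

    segments = []
    cursor = 0
    while cursor < m:
        start = None
        for t in range(cursor, m):
            if eligible[t] and g[t] not in (1, -1):
                start = t
                break
        if start is None:
            break
        candidates = [e for e in range(start, m) if interval_valid(start, e)]
        best = max(candidates)
        if passes_filters(start, best):
            segments.append((start, best))
        cursor = best + 1
    return segments


# ---------------------------------------------------------------------------
# Pedigree: Wright's path-counting kinship


def wright_inbreeding(parents, x):
    """Inbreeding of ``x`` by Wright's path-counting formula.

    ``parents`` maps id -> (sire, dam) with None for unknown.  F_x is the
    kinship of x's parents: the sum over common ancestors A and over pairs
    of ancestor paths meeting only at A of (1/2)^(n1+n2+1) * (1 + F_A).
    """
    s, d = parents[x]
    if s is None or d is None:
        return 0.0
    return _path_kinship(parents, s, d)


def _paths_up(parents, u):
    res = [[u]]
    for p in parents[u]:
        if p is not None:
            for path in _paths_up(parents, p):
                res.append([u] + path)
    return res


def _path_kinship(parents, a, b):
    total = 0.0
    for p1 in _paths_up(parents, a):
        for p2 in _paths_up(parents, b):
            if p1[-1] != p2[-1]:
                continue
            anc = p1[-1]
            if set(p1) & set(p2) != {anc}:
                continue
            n_edges = (len(p1) - 1) + (len(p2) - 1)
            total += 0.5 ** (n_edges + 1) * (1.0 + wright_inbreeding(parents, anc))
    return total


# ---------------------------------------------------------------------------
# Contribution scores: explicit per-column correlation loop


def brute_force_gc(G_values, k):
    """gc_j via np.corrcoef one column at a time."""
    vals = np.asarray(G_values, dtype=float)
    n = vals.shape[0]
    U, s, _ = np.linalg.svd(vals)
    w = s[:k] / s[:k].sum()
    scores = np.zeros(n)
    for j in range(n):
        col = vals[:, j]
        if np.std(col) == 0:
            continue
        for i in range(k):
            u = U[:, i]
            if np.std(u) == 0:
                continue
            scores[j] += w[i] * abs(np.corrcoef(col, u)[0, 1])
    return scores
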