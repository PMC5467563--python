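"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: plain-Python dynamic
programmes and literal rule enumerations, slow but obviously correct on
small inputs.
"""

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def global_affine_score(a: str, b: str, open_total: int = 12, ext: int = 1):
    """Needleman–Wunsch with affine gaps: gap of length L costs
    open_total + (L-1)*ext.  Returns the optimal score."""
    la, lb = len(a), len(b)
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (b consumed)
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = -open_total - (i - 1) * ext
    for j in range(1, lb + 1):
        Y[0][j] = -open_total - (j - 1) * ext
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] - open_total, X[i - 1][j] - ext)
            Y[i][j] = max(M[i][j - 1] - open_total, Y[i][j - 1] - ext)
    return max(M[la][lb], X[la][lb], Y[la][lb])


def local_affine_score(a: str, b: str, open_total: int = 12, ext: int = 1):
    """Smith–Waterman with affine gaps; returns the optimal local score."""
    la, lb = len(a), len(b)
    best = 0.0
    M = [[0.0] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i][j] = max(
                0.0,
                s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]),
            )
            X[i][j] = max(M[i - 1][j] - open_total, X[i - 1][j] - ext)
            Y[i][j] = max(M[i][j - 1] - open_total, Y[i][j - 1] - ext)
            best = max(best, M[i][j])
    return best


def brute_cutoffs(scores, is_seed, drop_fraction=0.10):
    """Literal enumeration of the threshold-calibration rules.

    ``scores`` descending, ``is_seed`` parallel booleans.  Returns
    (tc, nc, ga) or None when neither candidate exists.  Implemented by
    exhaustive prefix enumeration, unlike the package's single-pass scan.
    """
    n = len(scores)
    # candidate 1: score before the first >= drop_fraction relative fall
    drop = None
    for i in range(n - 1):
        if scores[i] > 0 and scores[i] - scores[i + 1] >= drop_fraction * scores[i]:
            drop = scores[i]
            break
    # candidate 2: smallest prefix containing every seed
    total_seeds = sum(is_seed)
    seed_cap = None
    if total_seeds > 0:
        for k in range(n):
            if sum(is_seed[: k + 1]) == total_seeds:
                seed_cap = scores[k]
                break
    if drop is None and seed_cap is None:
        return None
    if drop is not None and seed_cap is not None:
        tc = min(drop, seed_cap)
    else:
        tc = drop if drop is not None else seed_cap
    below = [s for s in scores if s < tc]
    nc = below[0] if below else tc
    return tc, nc, (tc + nc) / 2.0


def brute_greedy_cluster(seqs, identity, pairwise):
    """Naive greedy clustering: (length desc, id asc) order, first-fit.

    ``pairwise`` is a callable giving the exact identity fraction.
    Returns a list of (representative_id, sorted member id list).
    """
    ordered = sorted(seqs, key=lambda s: (-len(s.sequence), s.id))
    clusters = []  # (rep record, [members])
    for s in ordered:
        for rep, members in clusters:
            if pairwise(s, rep) >= identity:
                members.append(s.id)
                break
        else:
            clusters.append((s, [s.id]))
    return [(rep.id, sorted(members)) for rep, members in clusters]
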