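"""Independent brute-force reference implementations used to validate the
package's optimized code paths.  These deliberately share no code with
src/idrsig beyond module constants."""

from itertools import combinations, permutations
from math import comb, sqrt

POSITIVE = set("KR")
NEGATIVE = set("DE")


def scd_brute(seq: str) -> float:
    """Pairwise double-loop sequence charge decoration."""
    q = [1 if c in POSITIVE else -1 if c in NEGATIVE else 0 for c in seq]
    total = 0.0
    for i in range(len(seq)):
        for j in range(i + 1, len(seq)):
            total += q[i] * q[j] * sqrt(j - i)
    return total / len(seq)


def _sigma(fa: float, fb: float, binary: bool) -> float:
    if binary:
        return (fa - fb) ** 2
    denom = fa + fb
    return 0.0 if denom == 0 else (fa - fb) ** 2 / denom


def groups_for(seq: str, split: str, residues: str = "") -> list[int]:
    if split == "kappa":
        return [1 if c in POSITIVE else -1 if c in NEGATIVE else 0 for c in seq]
    if split == "omega":
        grp = POSITIVE | NEGATIVE | {"P"}
        return [1 if c in grp else -1 for c in seq]
    if split == "set":
        grp = set(residues)
        return [1 if c in grp else -1 for c in seq]
    raise ValueError(split)


def delta_brute(groups, blob_sizes=(5, 6), binary=False) -> float:
    """Explicit sliding-blob enumeration of the demixing statistic."""
    L = len(groups)
    fa_g = sum(1 for g in groups if g > 0) / L
    fb_g = sum(1 for g in groups if g < 0) / L
    sigma_g = _sigma(fa_g, fb_g, binary)
    deltas = []
    for g in blob_sizes:
        if L < g:
            continue
        devs = []
        for start in range(L - g + 1):
            blob = groups[start: start + g]
            fa = sum(1 for x in blob if x > 0) / g
            fb = sum(1 for x in blob if x < 0) / g
            devs.append((_sigma(fa, fb, binary) - sigma_g) ** 2)
        deltas.append(sum(devs) / len(devs))
    if not deltas:
        return float("nan")
    return sum(deltas) / len(deltas)


def delta_max_brute(groups, blob_sizes=(5, 6), binary=False) -> float:
    """Exhaustive maximum of delta over all distinct rearrangements."""
    best = 0.0
    for perm in set(permutations(groups)):
        best = max(best, delta_brute(list(perm), blob_sizes, binary))
    return best


def kappa_brute(seq: str, blob_sizes=(5, 6)) -> float:
    groups = groups_for(seq, "kappa")
    d = delta_brute(groups, blob_sizes, binary=False)
    dmax = delta_max_brute(groups, blob_sizes, binary=False)
    if dmax == 0 or d != d:
        return float("nan")
    return min(d / dmax, 1.0)


def hypergeom_upper_brute(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by direct enumeration of draw counts."""
    total = comb(N, K)
    hits = 0
    for x in range(k, min(K, n) + 1):
        hits += comb(n, x) * comb(N - n, K - x)
    return hits / total


def upgma_brute(dist) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) UPGMA recomputing average distances from the original matrix.

    Returns merge history as (cluster A leaves, cluster B leaves, height).
    Ties broken by the smallest sorted leaf-set pair, matching a smallest-id
    first policy on this simple history representation.
    """
    n = len(dist)
    clusters = [frozenset([i]) for i in range(n)]
    history = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            ca, cb = clusters[a], clusters[b]
            d = sum(dist[i][j] for i in ca for j in cb) / (len(ca) * len(cb))
            key = (d, tuple(sorted(ca)), tuple(sorted(cb)))
            if best is None or key < best[0]:
                best = (key, a, b)
        (_, _, _), a, b = best[0], best[1], best[2]
        ca, cb = clusters[a], clusters[b]
        height = best[0][0]
        history.append((ca, cb, height))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(ca | cb)
    return history


def bh_brute(pvals) -> list[float]:
    """Step-up BH from the definition: q_i = min_{j: p_(j) >= p_i ranked}..."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    qs = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running = min(running, pvals[i] * m / rank)
        qs[i] = running
    return qs
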