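"""Independent brute-force oracles used to validate the fast implementations.

Everything here favours obviousness over speed: candidate-ball enumeration
for the minimum enclosing ball, itertools products for best matches, full
subset enumeration for the miner, and exact integer combinatorics for the
hypergeometric tails.  None of it shares code paths with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def meb_bruteforce(points: np.ndarray) -> float:
    """Minimum enclosing ball radius by enumerating 2/3/4-point support sets."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(pts)
    if n == 1:
        return 0.0
    candidates: list[tuple[np.ndarray, float]] = []
    for i, j in itertools.combinations(range(n), 2):
        c = (pts[i] + pts[j]) / 2.0
        candidates.append((c, float(np.linalg.norm(pts[i] - c))))
    for i, j, k in itertools.combinations(range(n), 3):
        c = _circumcenter_lstsq(pts[[i, j, k]])
        if c is not None:
            candidates.append((c, float(np.linalg.norm(pts[i] - c))))
    for quad in itertools.combinations(range(n), 4):
        c = _circumcenter_lstsq(pts[list(quad)])
        if c is not None:
            candidates.append((c, float(np.linalg.norm(pts[quad[0]] - c))))
    best = math.inf
    for c, r in candidates:
        if np.max(np.linalg.norm(pts - c, axis=1)) <= r + 1e-9 * (1.0 + r):
            best = min(best, r)
    return best


def _circumcenter_lstsq(pts: np.ndarray) -> np.ndarray | None:
    """Point equidistant from all given points, in their affine hull."""
    a = pts[0]
    rows = 2.0 * (pts[1:] - a)
    rhs = np.sum(pts[1:] ** 2, axis=1) - np.sum(a**2)
    if len(pts) == 3:
        # constrain the center to the triangle's plane
        normal = np.cross(pts[1] - a, pts[2] - a)
        rows = np.vstack([rows, normal])
        rhs = np.append(rhs, normal @ a)
    sol, residuals, rank, _sv = np.linalg.lstsq(rows, rhs, rcond=None)
    if rank < 3:
        return None  # degenerate (collinear/coplanar subset)
    # verify equidistance (lstsq may "solve" inconsistent systems)
    d = np.linalg.norm(pts - sol, axis=1)
    if np.max(d) - np.min(d) > 1e-7 * (1.0 + np.max(d)):
        return None
    return sol


def best_match_bruteforce(structure, labels) -> float | None:
    """Minimum MEB radius over all one-occurrence-per-label combinations."""
    idx_lists = [structure.occurrences(a) for a in labels]
    if any(len(ix) == 0 for ix in idx_lists):
        return None
    best = math.inf
    for combo in itertools.product(*idx_lists):
        best = min(best, meb_bruteforce(structure.coords[list(combo)]))
    return best


def best_match_exhaustive(structure, labels) -> float | None:
    """Exhaustive combination enumeration using the package's Welzl MEB.

    Independent of the pruned/vectorised search paths but shares the MEB
    primitive (which is itself validated against :func:`meb_bruteforce`).
    """
    from fresco.geometry import min_enclosing_ball

    idx_lists = [structure.occurrences(a) for a in labels]
    if any(len(ix) == 0 for ix in idx_lists):
        return None
    best = math.inf
    for combo in itertools.product(*idx_lists):
        best = min(best, min_enclosing_ball(structure.coords[list(combo)]).radius)
    return best


def mine_bruteforce(dataset, min_support, max_radius, max_size, min_size=2,
                    radius_fn=best_match_bruteforce):
    """Full enumeration of all label subsets, by the definitions alone.

    Returns {labels_tuple: (support, cohesive_radius)} for subsets passing
    both thresholds.
    """
    alphabet = sorted(dataset.alphabet)
    out = {}
    for k in range(min_size, max_size + 1):
        for combo in itertools.combinations(alphabet, k):
            supporting = [
                s for s in dataset if set(combo) <= s.label_set
            ]
            support = len(supporting) / len(dataset)
            if support < min_support:
                continue
            radii = [radius_fn(s, combo) for s in supporting]
            r = float(np.mean(radii)) if radii else math.nan
            if r <= max_radius:
                out[combo] = (support, r)
    return out


def hypergeom_tails_bruteforce(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """Exact tail sums of the hypergeometric pmf using integer combinatorics."""
    denom = math.comb(N, n)
    lo = max(0, n - (N - K))
    hi = min(n, K)
    upper = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(max(k, lo), hi + 1))
    lower = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(lo, min(k, hi) + 1))
    return upper / denom, lower / denom


def spearman_bruteforce(x, y) -> float:
    """Spearman rho as the Pearson correlation of average ranks."""

    def average_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = average_ranks(x), average_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))
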