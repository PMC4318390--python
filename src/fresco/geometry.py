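"""Exact smallest-enclosing-ball geometry and best-match search.

The cohesion score of a label pattern inside one structure is the minimum,
over all ways of picking one occurrence of each pattern label, of the radius
of the smallest enclosing ball (MEB) of the picked points.  Both pieces are
implemented exactly:

* :func:`min_enclosing_ball` — Welzl-style MEB for an arbitrary 3D point set
  (the MEB always exists and is unique; its support set has at most 4 points).
* :func:`best_match` — the global minimum-radius combination for a pattern in
  a structure, by vectorised exhaustive enumeration for small combination
  counts and an exact anchor-based branch-and-bound otherwise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import StructureObject

logger = logging.getLogger(__name__)

_EPS = 1e-10

#: Above this product of per-label occurrence counts, best_match switches from
#: exhaustive enumeration to branch-and-bound.  At or below it, enumeration is
#: both simple and an internal cross-check of the pruned search.
EXHAUSTIVE_COMBO_LIMIT = 5000


@dataclass(frozen=True)
class Ball:
    """A ball in 3-space: center (Å) and radius (Å)."""

    center: tuple[float, float, float]
    radius: float

    def contains(self, point: Sequence[float], tol: float = 1e-9) -> bool:
        d = float(np.linalg.norm(np.asarray(point, float) - np.asarray(self.center)))
        return d <= self.radius + tol


@dataclass(frozen=True)
class BestMatch:
    """The minimum-radius one-occurrence-per-label combination in a structure.

    ``radius`` is the per-structure radius R_g; ``point_indices`` maps each
    pattern label to the index of the chosen point within the structure.
    """

    radius: float
    ball: Ball
    point_indices: dict[str, int]


# ---------------------------------------------------------------------------
# circumscribed balls of 1..4 boundary points
# ---------------------------------------------------------------------------

def _ball_2(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    c = 0.5 * (a + b)
    return c, float(np.linalg.norm(a - c))


def _ball_3(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Circumscribed circle center of a (non-degenerate) triangle in 3D."""
    ab, ac = b - a, c - a
    u = np.cross(ab, ac)
    denom = 2.0 * float(u @ u)
    scale = max(float(ab @ ab), float(ac @ ac), 1.0)
    if denom <= _EPS * scale * scale:
        return None  # collinear
    center = a + (float(ab @ ab) * np.cross(ac, u) + float(ac @ ac) * np.cross(u, ab)) / denom
    return center, float(np.linalg.norm(a - center))


def _ball_4(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Circumscribed sphere of four (non-coplanar) points."""
    m = 2.0 * np.array([b - a, c - a, d - a])
    rhs = np.array([b @ b - a @ a, c @ c - a @ a, d @ d - a @ a])
    det = float(np.linalg.det(m))
    scale = max(1.0, float(np.max(np.abs(m)))) ** 3
    if abs(det) <= _EPS * scale:
        return None  # coplanar
    center = np.linalg.solve(m, rhs)
    return center, float(np.linalg.norm(a - center))


def _ball_boundary(boundary: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Smallest ball with all ``boundary`` points on its surface (len <= 4)."""
    k = len(boundary)
    if k == 0:
        return np.zeros(3), -1.0
    if k == 1:
        return boundary[0].copy(), 0.0
    if k == 2:
        return _ball_2(boundary[0], boundary[1])
    if k == 3:
        ball = _ball_3(*boundary)
        if ball is not None:
            return ball
        # collinear: fall back to the covering ball of the extreme pair
        return _min_ball_bruteforce(np.array(boundary))
    ball = _ball_4(*boundary)
    if ball is not None:
        return ball
    return _min_ball_bruteforce(np.array(boundary))


def _min_ball_bruteforce(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Direct support-set enumeration; used only for tiny/degenerate sets."""
    n = len(points)
    best: tuple[np.ndarray, float] | None = None
    candidates: list[tuple[np.ndarray, float]] = []
    if n == 1:
        return points[0].copy(), 0.0
    for i, j in itertools.combinations(range(n), 2):
        candidates.append(_ball_2(points[i], points[j]))
    for i, j, k in itertools.combinations(range(n), 3):
        b = _ball_3(points[i], points[j], points[k])
        if b is not None:
            candidates.append(b)
    for comb in itertools.combinations(range(n), 4):
        b = _ball_4(*(points[i] for i in comb))
        if b is not None:
            candidates.append(b)
    for center, radius in candidates:
        dmax = float(np.max(np.linalg.norm(points - center, axis=1)))
        if dmax <= radius + 1e-9 * (1.0 + radius):
            if best is None or radius < best[1]:
                best = (center, radius)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Welzl minimum enclosing ball
# ---------------------------------------------------------------------------

def _outside(center: np.ndarray, radius: float, p: np.ndarray) -> bool:
    return float(np.linalg.norm(p - center)) > radius + _EPS * (1.0 + radius)


def _meb_with_boundary(points: np.ndarray, boundary: list[np.ndarray]) -> tuple[np.ndarray, float]:
    center, radius = _ball_boundary(boundary)
    if len(boundary) == 4:
        return center, radius
    for i in range(len(points)):
        p = points[i]
        if radius < 0 or _outside(center, radius, p):
            center, radius = _meb_with_boundary(points[:i], boundary + [p])
    return center, radius


def min_enclosing_ball(points: Iterable[Sequence[float]], seed: int = 0) -> Ball:
    """Exact smallest enclosing ball of a 3D point set (Welzl's algorithm).

    The input order is randomised internally with a fixed seed so the result
    (and the running time) is deterministic for a given input.

    Raises
    ------
    ValueError
        On an empty input.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.size == 0:
        raise ValueError("min_enclosing_ball: empty point set")
    pts = pts.reshape(-1, 3)
    if not np.all(np.isfinite(pts)):
        raise ValueError("min_enclosing_ball: non-finite coordinates")
    if len(pts) > 1:
        rng = np.random.default_rng(seed)
        pts = pts[rng.permutation(len(pts))]
    center, radius = _meb_with_boundary(pts, [])
    return Ball(tuple(float(x) for x in center), max(float(radius), 0.0))


# ---------------------------------------------------------------------------
# batched MEB radii for combinations of k <= 4 points
# ---------------------------------------------------------------------------

def radius_from_pairwise(d12: np.ndarray, d13: np.ndarray, d23: np.ndarray) -> np.ndarray:
    """MEB radius of point triples from their three pairwise distances.

    If the triangle is right/obtuse at the vertex opposite its longest side
    the MEB is the ball on that side (radius = longest/2); otherwise it is the
    circumscribed circle, whose radius follows from Heron's formula.  Handles
    degenerate (collinear) triples, which always fall in the obtuse branch.
    """
    d12, d13, d23 = np.broadcast_arrays(d12, d13, d23)
    sq = np.stack([d12, d13, d23]) ** 2
    dmax2 = np.max(sq, axis=0)
    obtuse = dmax2 >= np.sum(sq, axis=0) - dmax2
    s = 0.5 * (d12 + d13 + d23)
    area2 = s * (s - d12) * (s - d13) * (s - d23)
    area = np.sqrt(np.maximum(area2, 1e-300))
    with np.errstate(divide="ignore", invalid="ignore"):
        circum = (d12 * d13 * d23) / (4.0 * area)
    return np.where(obtuse, 0.5 * np.sqrt(dmax2), circum)


def _pairwise(pts: np.ndarray, i: int, j: int) -> np.ndarray:
    return np.linalg.norm(pts[:, i, :] - pts[:, j, :], axis=1)


def _meb3_batch(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(m,3,3) point triples -> (centers, radii) of their MEBs, vectorised."""
    a, b, c = pts[:, 0], pts[:, 1], pts[:, 2]
    ab, ac = b - a, c - a
    u = np.cross(ab, ac)
    uu = np.sum(u * u, axis=1)
    ab2 = np.sum(ab * ab, axis=1)
    ac2 = np.sum(ac * ac, axis=1)
    denom = 2.0 * np.maximum(uu, 1e-300)
    circ_center = a + (ab2[:, None] * np.cross(ac, u) + ac2[:, None] * np.cross(u, ab)) / denom[:, None]
    d12, d13, d23 = _pairwise(pts, 0, 1), _pairwise(pts, 0, 2), _pairwise(pts, 1, 2)
    sq = np.stack([d12, d13, d23]) ** 2
    which = np.argmax(sq, axis=0)
    dmax2 = np.take_along_axis(sq, which[None], axis=0)[0]
    obtuse = dmax2 >= np.sum(sq, axis=0) - dmax2
    degenerate = uu <= _EPS * np.maximum(ab2, ac2) ** 2
    obtuse |= degenerate
    pair_i = np.array([0, 0, 1])[which]
    pair_j = np.array([1, 2, 2])[which]
    rows = np.arange(len(pts))
    mid = 0.5 * (pts[rows, pair_i] + pts[rows, pair_j])
    centers = np.where(obtuse[:, None], mid, circ_center)
    radii = np.where(obtuse, 0.5 * np.sqrt(dmax2), np.linalg.norm(a - circ_center, axis=1))
    return centers, radii


def _meb4_batch(pts: np.ndarray) -> np.ndarray:
    """(m,4,3) point quadruples -> MEB radii, by support-subset enumeration.

    The MEB of four points is either the MEB of one of the four triples
    (when it covers the remaining point) or the circumsphere of all four.
    """
    m = len(pts)
    best = np.full(m, np.inf)
    for drop in range(4):
        keep = [i for i in range(4) if i != drop]
        centers, radii = _meb3_batch(pts[:, keep, :])
        d4 = np.linalg.norm(pts[:, drop, :] - centers, axis=1)
        ok = d4 <= radii + 1e-9 * (1.0 + radii)
        best = np.where(ok, np.minimum(best, radii), best)
    # circumsphere of all four (valid where non-coplanar)
    a = pts[:, 0, :]
    mmat = 2.0 * (pts[:, 1:, :] - a[:, None, :])
    rhs = np.sum(pts[:, 1:, :] ** 2, axis=2) - np.sum(a**2, axis=1)[:, None]
    det = np.linalg.det(mmat)
    scale = np.maximum(np.max(np.abs(mmat), axis=(1, 2)), 1.0) ** 3
    valid = np.abs(det) > _EPS * scale
    if np.any(valid):
        centers = np.full((m, 3), np.nan)
        centers[valid] = np.linalg.solve(mmat[valid], rhs[valid][..., None])[..., 0]
        r = np.linalg.norm(a - centers, axis=1)
        best = np.where(valid, np.minimum(best, r), best)
    bad = ~np.isfinite(best)
    if np.any(bad):  # numerically marginal rows: exact fallback
        for i in np.nonzero(bad)[0]:
            best[i] = min_enclosing_ball(pts[i]).radius
    return best


def meb_radius_batch(pts: np.ndarray) -> np.ndarray:
    """MEB radii for an (m, k, 3) stack of point tuples (exact for k <= 4)."""
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 3:
        raise ValueError("expected (m, k, 3) array")
    k = pts.shape[1]
    if k == 1:
        return np.zeros(len(pts))
    if k == 2:
        return 0.5 * _pairwise(pts, 0, 1)
    if k == 3:
        return _meb3_batch(pts)[1]
    if k == 4:
        return _meb4_batch(pts)
    return np.array([min_enclosing_ball(row).radius for row in pts])


# ---------------------------------------------------------------------------
# spatial index
# ---------------------------------------------------------------------------

class SpatialIndex:
    """Per-label KD-trees over a structure, for radius/nearest queries."""

    def __init__(self, structure: StructureObject):
        if len(structure) < 1:
            raise ValueError("empty structure")
        self.structure = structure
        self._trees: dict[str, tuple[cKDTree, np.ndarray]] = {}
        coords = structure.coords
        for label, idx in structure.occurrence_index().items():
            self._trees[label] = (cKDTree(coords[idx]), idx)

    def labels(self) -> frozenset[str]:
        return frozenset(self._trees)

    def within(self, label: str, center: Sequence[float], radius: float) -> np.ndarray:
        """Indices (into the structure) of ``label`` points within ``radius``."""
        if label not in self._trees:
            return np.empty(0, dtype=np.intp)
        tree, idx = self._trees[label]
        if not np.isfinite(radius):
            return idx.copy()
        local = tree.query_ball_point(np.asarray(center, float), radius)
        return idx[np.asarray(sorted(local), dtype=np.intp)] if local else np.empty(0, dtype=np.intp)

    def nearest(self, label: str, point: Sequence[float]) -> tuple[float, int]:
        """(distance, structure point index) of the closest ``label`` point."""
        if label not in self._trees:
            raise KeyError(label)
        tree, idx = self._trees[label]
        d, local = tree.query(np.asarray(point, float))
        return float(d), int(idx[int(local)])


def build_spatial_index(structure: StructureObject) -> SpatialIndex:
    """Build per-label KD-trees supporting exact radius queries."""
    return SpatialIndex(structure)


# ---------------------------------------------------------------------------
# best match
# ---------------------------------------------------------------------------

def _pattern_labels(pattern) -> tuple[str, ...]:
    labels = tuple(getattr(pattern, "labels", pattern))
    if len(set(labels)) != len(labels):
        raise ValueError(f"pattern labels not distinct: {labels}")
    if not labels:
        raise ValueError("empty pattern")
    return labels


def _combo_coords(coords: np.ndarray, idx_lists: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """All one-per-label index combinations and the matching coordinate stack."""
    grids = np.meshgrid(*idx_lists, indexing="ij")
    combos = np.stack([g.ravel() for g in grids], axis=1)  # (m, k)
    return combos, coords[combos]


def _meb_small(pts: np.ndarray) -> Ball:
    """Closed-form MEB for up to 4 points (the support-set sizes of a match)."""
    n = len(pts)
    if n == 1:
        return Ball(tuple(map(float, pts[0])), 0.0)
    if n == 2:
        c, r = _ball_2(pts[0], pts[1])
        return Ball(tuple(map(float, c)), float(r))
    if n == 3:
        centers, radii = _meb3_batch(pts[None])
        return Ball(tuple(map(float, centers[0])), float(radii[0]))
    c, r = _min_ball_bruteforce(pts)
    return Ball(tuple(map(float, c)), float(r))


def _finish(structure: StructureObject, labels: Sequence[str], chosen: Sequence[int]) -> BestMatch:
    pts = structure.coords[np.asarray(chosen, dtype=np.intp)]
    ball = _meb_small(pts) if len(pts) <= 4 else min_enclosing_ball(pts)
    return BestMatch(ball.radius, ball, {a: int(i) for a, i in zip(labels, chosen)})


def _exhaustive_best(structure: StructureObject, labels: Sequence[str],
                     idx_lists: Sequence[np.ndarray]) -> BestMatch:
    combos, pts = _combo_coords(structure.coords, idx_lists)
    radii = meb_radius_batch(pts)
    return _finish(structure, labels, combos[int(np.argmin(radii))])


def _branch_and_bound(structure: StructureObject, labels: Sequence[str],
                      idx_lists: Sequence[np.ndarray], index: SpatialIndex) -> BestMatch:
    """Exact anchor-based search.

    Anchors on every occurrence of the rarest label.  Any combination
    containing a given anchor lies inside a ball through the anchor, so all
    its points are within twice the ball radius of the anchor; half the
    largest anchor-to-nearest-occurrence distance over the other labels is
    therefore a lower bound on the achievable radius.  Anchors are visited in
    bound order and pruned against the incumbent, which starts from the
    greedy nearest-occurrence combination.
    """
    coords = structure.coords
    counts = [len(ix) for ix in idx_lists]
    order = sorted(range(len(labels)), key=lambda i: (counts[i], labels[i]))
    anchor_pos = order[0]
    anchor_label = labels[anchor_pos]
    others = [i for i in range(len(labels)) if i != anchor_pos]
    anchors = idx_lists[anchor_pos]

    # lower bounds and greedy incumbent per anchor
    bounds = np.zeros(len(anchors))
    greedy = np.empty((len(anchors), len(labels)), dtype=np.intp)
    for ai, a_idx in enumerate(anchors):
        p = coords[a_idx]
        worst = 0.0
        greedy[ai, anchor_pos] = a_idx
        for li in others:
            d, j = index.nearest(labels[li], p)
            worst = max(worst, d)
            greedy[ai, li] = j
        bounds[ai] = 0.5 * worst

    best_ai = int(np.argmin(bounds))
    inc_radius = meb_radius_batch(coords[greedy[best_ai]][None])[0]
    inc_combo = greedy[best_ai]

    for ai in np.argsort(bounds, kind="stable"):
        if bounds[ai] >= inc_radius - 1e-12:
            continue
        a_idx = anchors[ai]
        p = coords[a_idx]
        sub_lists = []
        feasible = True
        for li in others:
            sub = index.within(labels[li], p, 2.0 * inc_radius + 1e-9)
            if len(sub) == 0:
                feasible = False
                break
            sub_lists.append(sub)
        if not feasible:
            continue
        full_lists: list[np.ndarray] = [None] * len(labels)  # type: ignore[list-item]
        full_lists[anchor_pos] = np.asarray([a_idx], dtype=np.intp)
        for li, sub in zip(others, sub_lists):
            full_lists[li] = sub
        combos, pts = _combo_coords(coords, full_lists)
        radii = meb_radius_batch(pts)
        j = int(np.argmin(radii))
        if radii[j] < inc_radius:
            inc_radius = float(radii[j])
            inc_combo = combos[j]
    return _finish(structure, labels, inc_combo)


def best_match(structure: StructureObject, pattern, spatial_index: SpatialIndex | None = None,
               combo_limit: int = EXHAUSTIVE_COMBO_LIMIT) -> BestMatch | None:
    """Globally optimal best match of a pattern within one structure.

    Returns ``None`` when any pattern label has no occurrence in the
    structure.  The result is the unconstrained global minimum radius over
    all one-occurrence-per-label combinations.
    """
    labels = _pattern_labels(pattern)
    idx_lists = [structure.occurrences(a) for a in labels]
    for a, ix in zip(labels, idx_lists):
        if len(ix) == 0:
            if a not in structure.label_set:
                logger.debug("label %s absent from %s", a, structure.structure_id)
            return None
    if len(labels) == 1:
        return _finish(structure, labels, [int(idx_lists[0][0])])
    n_combos = int(np.prod([len(ix) for ix in idx_lists], dtype=np.int64))
    if n_combos <= combo_limit:
        return _exhaustive_best(structure, labels, idx_lists)
    if spatial_index is None:
        spatial_index = build_spatial_index(structure)
    return _branch_and_bound(structure, labels, idx_lists, spatial_index)


def _emit(structure: StructureObject, labels: Sequence[str], chosen: Sequence[int],
          radius: float, radii_only: bool):
    if radii_only:
        return radius
    return _finish(structure, labels, chosen)


def batch_best_matches(structure: StructureObject, patterns: Sequence,
                       radii_only: bool = False,
                       combo_limit: int = EXHAUSTIVE_COMBO_LIMIT):
    """Best matches of many patterns within one structure.

    Shares the structure's cached pairwise-distance matrix across patterns
    and fuses all pair/triplet patterns into single vectorised computations,
    which makes level-wise mining and the permutation background fast.  With
    ``radii_only`` the return value maps each pattern to a float radius
    (``None`` for unsupported patterns); otherwise to a :class:`BestMatch`.
    """
    D = structure.dist_matrix()
    coords = structure.coords
    occ = structure.occurrence_index()
    out: dict = {}
    index: SpatialIndex | None = None
    pairs: list[tuple] = []  # (pattern, labels, i1, i2)
    triples: list[tuple] = []  # (pattern, labels, i1, i2, i3)
    for pattern in patterns:
        labels = _pattern_labels(pattern)
        idx_lists = [occ.get(a) for a in labels]
        if any(ix is None or len(ix) == 0 for ix in idx_lists):
            out[pattern] = None
            continue
        k = len(labels)
        n_combos = 1
        for ix in idx_lists:
            n_combos *= len(ix)
        if k == 1:
            out[pattern] = _emit(structure, labels, [int(idx_lists[0][0])], 0.0, radii_only)
        elif k == 2 and n_combos <= combo_limit:
            pairs.append((pattern, labels, *idx_lists))
        elif k == 3 and n_combos <= combo_limit:
            triples.append((pattern, labels, *idx_lists))
        elif k == 4 and n_combos <= combo_limit:
            combos, pts = _combo_coords(coords, idx_lists)
            radii = meb_radius_batch(pts)
            j = int(np.argmin(radii))
            out[pattern] = _emit(structure, labels, [int(x) for x in combos[j]],
                                 float(radii[j]), radii_only)
        else:
            if index is None and n_combos > combo_limit:
                index = build_spatial_index(structure)
            bm = best_match(structure, labels, spatial_index=index, combo_limit=combo_limit)
            out[pattern] = bm.radius if radii_only else bm

    if pairs:
        flats = [D[i1[:, None], i2[None, :]].ravel() for _, _, i1, i2 in pairs]
        big = np.concatenate(flats)
        offset = 0
        for (pattern, labels, i1, i2), flat in zip(pairs, flats):
            seg = big[offset:offset + flat.size]
            offset += flat.size
            j = int(np.argmin(seg))
            a, b = divmod(j, len(i2))
            out[pattern] = _emit(structure, labels, [int(i1[a]), int(i2[b])],
                                 0.5 * float(seg[j]), radii_only)

    if triples:
        segs12, segs13, segs23, shapes = [], [], [], []
        for _, _, i1, i2, i3 in triples:
            shape = (len(i1), len(i2), len(i3))
            shapes.append(shape)
            s12 = D[i1[:, None], i2[None, :]][:, :, None]
            s13 = D[i1[:, None], i3[None, :]][:, None, :]
            s23 = D[i2[:, None], i3[None, :]][None, :, :]
            segs12.append(np.broadcast_to(s12, shape).ravel())
            segs13.append(np.broadcast_to(s13, shape).ravel())
            segs23.append(np.broadcast_to(s23, shape).ravel())
        s12 = np.concatenate(segs12) ** 2
        s13 = np.concatenate(segs13) ** 2
        s23 = np.concatenate(segs23) ** 2
        tot = s12 + s13 + s23
        dmax2 = np.maximum(np.maximum(s12, s13), s23)
        # 16·Area² from the squared side lengths (Heron); right/obtuse and
        # degenerate triangles take the half-longest-side ball instead
        area16 = 2.0 * (s12 * s13 + s12 * s23 + s13 * s23) \
            - (s12 * s12 + s13 * s13 + s23 * s23)
        r2 = np.where(
            2.0 * dmax2 >= tot,
            0.25 * dmax2,
            (s12 * s13 * s23) / np.maximum(area16, 1e-300),
        )
        offset = 0
        for (pattern, labels, i1, i2, i3), shape in zip(triples, shapes):
            size = shape[0] * shape[1] * shape[2]
            seg = r2[offset:offset + size]
            offset += size
            j = int(np.argmin(seg))
            a, bc = divmod(j, shape[1] * shape[2])
            b, c = divmod(bc, shape[2])
            out[pattern] = _emit(structure, labels,
                                 [int(i1[a]), int(i2[b]), int(i3[c])],
                                 float(np.sqrt(seg[j])), radii_only)
    return out
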