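"""Level-wise Apriori-style mining of frequent spatially cohesive label sets.

A pattern X is a set of distinct labels (amino acids and/or bases).  Its
support S(X) is the fraction of structures containing every label of X at
least once; its cohesive radius R(X) is the mean, over supporting
structures, of the per-structure best-match MEB radius R_g.  The miner
reports every pattern with S(X) >= min_support and R(X) <= max_radius up to
a maximum size, enumerating the lattice level-wise and pruning by support
only (support is anti-monotone; the cohesive radius, an average over a
shrinking support set, is not, so by default it is applied as a report
filter rather than a search prune).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import geometry
from .structure_io import AMINO_ACIDS, BASES, StructureDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class Pattern:
    """A set of distinct labels, canonically sorted for identity."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise ValueError("pattern must contain at least one label")
        if tuple(sorted(set(self.labels))) != self.labels:
            object.__setattr__(self, "labels", tuple(sorted(set(self.labels))))

    @classmethod
    def of(cls, *labels: str) -> "Pattern":
        return cls(tuple(sorted(set(labels))))

    @property
    def size(self) -> int:
        return len(self.labels)

    def __str__(self) -> str:
        return "-".join(self.labels)

    @classmethod
    def parse(cls, text: str) -> "Pattern":
        return cls.of(*text.strip().split("-"))


@dataclass
class PatternStats:
    """Support and cohesion statistics of one mined pattern."""

    pattern: Pattern
    support: float
    supporting_ids: tuple[str, ...]
    per_structure_radius: dict[str, float]
    cohesive_radius: float
    best_matches: dict[str, geometry.BestMatch] = field(default_factory=dict)


@dataclass
class MiningConfig:
    """Mining thresholds.

    Protein-mode defaults: support 0.60, radius 4.5 Å (the Cα–Cα distance at
    which two residues are conventionally considered interacting).  Complex
    mode (protein + DNA): support 0.70, radius 7.0 Å, since the pattern must
    bridge two macromolecules, and only patterns featuring at least one base
    and one amino acid are reported.
    """

    min_support: float = 0.60
    max_radius: float = 4.5
    max_pattern_size: int = 4
    mode: str = "protein"
    report_min_size: int = 2
    lossy_radius_prune: bool = False
    radius_prune_slack: float = 2.0
    combo_limit: int = geometry.EXHAUSTIVE_COMBO_LIMIT

    def __post_init__(self) -> None:
        if not 0.0 < self.min_support <= 1.0:
            raise ValueError("min_support must be in (0, 1]")
        if self.max_radius <= 0.0:
            raise ValueError("max_radius must be positive")
        if self.mode not in ("protein", "complex"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.max_pattern_size < 1:
            raise ValueError("max_pattern_size must be >= 1")

    @classmethod
    def protein(cls, **overrides) -> "MiningConfig":
        return cls(**{"mode": "protein", **overrides})

    @classmethod
    def complex(cls, **overrides) -> "MiningConfig":
        defaults = {"min_support": 0.70, "max_radius": 7.0, "mode": "complex"}
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "MiningConfig":
        if mode == "complex":
            return cls.complex(**overrides)
        return cls.protein(**overrides)


def compute_support(pattern: Pattern, dataset: StructureDataset) -> tuple[float, tuple[str, ...]]:
    """Support of a pattern: fraction of structures containing all its labels."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    labels = set(pattern.labels)
    ids = tuple(s.structure_id for s in dataset if labels <= s.label_set)
    return len(ids) / len(dataset), ids


def compute_cohesive_radius(
    pattern: Pattern,
    dataset: StructureDataset,
    supporting_ids: Sequence[str],
) -> tuple[float, dict[str, float]]:
    """Mean best-match radius over the supporting structures (R(X)).

    The average runs over the pattern's support set N(X) only, and every
    supporting structure enters it — including those whose best ball is
    large.  An empty support set yields NaN (the pattern cannot be reported).
    """
    if not supporting_ids:
        return math.nan, {}
    per: dict[str, float] = {}
    for sid in supporting_ids:
        bm = geometry.best_match(dataset.get(sid), pattern)
        if bm is None:
            raise ValueError(f"{sid} does not support {pattern}")
        per[sid] = bm.radius
    return float(np.mean(list(per.values()))), per


def generate_candidates(frequent_k: Iterable[Pattern]) -> list[Pattern]:
    """Classic Apriori join + prune: (k+1)-sets all of whose k-subsets are frequent."""
    frequent = sorted(set(frequent_k))
    if not frequent:
        return []
    sizes = {p.size for p in frequent}
    if len(sizes) != 1:
        raise ValueError("all input patterns must have the same size")
    k = sizes.pop()
    fset = set(frequent)
    candidates: set[Pattern] = set()
    for i, p in enumerate(frequent):
        for q in frequent[i + 1:]:
            if p.labels[:-1] == q.labels[:-1]:
                joined = Pattern.of(*(p.labels + (q.labels[-1],)))
                if joined.size == k + 1 and all(
                    Pattern(sub) in fset for sub in combinations(joined.labels, k)
                ):
                    candidates.add(joined)
    return sorted(candidates)


def _is_reportable(pattern: Pattern, config: MiningConfig) -> bool:
    if pattern.size < config.report_min_size:
        return False
    if config.mode == "complex":
        labels = set(pattern.labels)
        if not (labels & BASES and labels & AMINO_ACIDS):
            return False
    return True


def mine(dataset: StructureDataset, config: MiningConfig | None = None) -> list[PatternStats]:
    """Mine all patterns with S(X) >= min_support and R(X) <= max_radius.

    Level-wise search with exact support pruning; cohesive radii are computed
    for every frequent pattern and the radius threshold applied when
    reporting.  With ``lossy_radius_prune``, patterns whose radius exceeds
    ``radius_prune_slack * max_radius`` are additionally not extended — a
    faster but potentially lossy variant.  Output is canonically sorted by
    (size, labels) and independent of input file ordering.
    """
    if config is None:
        config = MiningConfig.for_mode(dataset.mode)
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    n = len(dataset)
    ids = dataset.ids
    alphabet = sorted(dataset.alphabet)
    col = {a: j for j, a in enumerate(alphabet)}
    presence = np.zeros((n, len(alphabet)), dtype=bool)
    for i, s in enumerate(dataset):
        for a in s.label_set:
            presence[i, col[a]] = True

    def support_rows(pattern: Pattern) -> np.ndarray:
        cols = [col[a] for a in pattern.labels]
        return np.flatnonzero(presence[:, cols].all(axis=1))

    results: list[PatternStats] = []
    # level 1
    frequent: list[tuple[Pattern, np.ndarray]] = []
    for a in alphabet:
        p = Pattern.of(a)
        rows = support_rows(p)
        if len(rows) / n >= config.min_support:
            frequent.append((p, rows))
    if config.report_min_size <= 1:
        for p, rows in frequent:
            sids = tuple(ids[int(i)] for i in rows)
            per = {sid: 0.0 for sid in sids}  # a single point has a zero ball
            results.append(PatternStats(p, len(sids) / n, sids, per, 0.0))
    level = 1
    while frequent and level < config.max_pattern_size:
        candidates = generate_candidates([p for p, _ in frequent])
        next_frequent: list[tuple[Pattern, np.ndarray]] = []
        for p in candidates:
            rows = support_rows(p)
            if len(rows) / n >= config.min_support:
                next_frequent.append((p, rows))
        stats = _stats_for_level(dataset, next_frequent, config)
        reported = [
            st for st in stats.values()
            if _is_reportable(st.pattern, config) and st.cohesive_radius <= config.max_radius
        ]
        _attach_best_matches(dataset, reported, config)
        results.extend(reported)
        if config.lossy_radius_prune:
            cutoff = config.radius_prune_slack * config.max_radius
            next_frequent = [
                (p, rows) for p, rows in next_frequent
                if stats[p].cohesive_radius <= cutoff
            ]
        frequent = next_frequent
        level += 1
    results.sort(key=lambda st: (st.pattern.size, st.pattern.labels))
    return results


def _stats_for_level(
    dataset: StructureDataset,
    frequent: list[tuple[Pattern, np.ndarray]],
    config: MiningConfig,
) -> dict[Pattern, PatternStats]:
    """Per-structure radii for all frequent patterns of one level (radii only).

    Best matches (balls and point indices) are attached later, and only for
    the patterns that end up reported; the search itself needs just radii.
    """
    per_radius: dict[Pattern, dict[str, float]] = {p: {} for p, _ in frequent}
    by_row: dict[int, list[Pattern]] = {}
    for p, rows in frequent:
        for i in rows:
            by_row.setdefault(int(i), []).append(p)
    for i, plist in by_row.items():
        structure = dataset.structures[i]
        found = geometry.batch_best_matches(
            structure, plist, radii_only=True, combo_limit=config.combo_limit
        )
        for p, r in found.items():
            assert r is not None
            per_radius[p][structure.structure_id] = r
    out: dict[Pattern, PatternStats] = {}
    for p, rows in frequent:
        sids = tuple(dataset.ids[int(i)] for i in rows)
        radii = per_radius[p]
        r = float(np.mean([radii[s] for s in sids])) if sids else math.nan
        out[p] = PatternStats(
            pattern=p,
            support=len(sids) / len(dataset),
            supporting_ids=sids,
            per_structure_radius=radii,
            cohesive_radius=r,
        )
    return out


def _attach_best_matches(
    dataset: StructureDataset,
    stats: Sequence[PatternStats],
    config: MiningConfig,
) -> None:
    """Fill in full best matches for reported patterns, grouped by structure."""
    by_sid: dict[str, list[PatternStats]] = {}
    for st in stats:
        for sid in st.supporting_ids:
            by_sid.setdefault(sid, []).append(st)
    for sid, st_list in by_sid.items():
        structure = dataset.get(sid)
        found = geometry.batch_best_matches(
            structure, [st.pattern for st in st_list], combo_limit=config.combo_limit
        )
        for st in st_list:
            bm = found[st.pattern]
            assert bm is not None
            st.best_matches[sid] = bm


def pattern_stats(dataset: StructureDataset, pattern: Pattern) -> PatternStats:
    """Full statistics of a single pattern (support, radii, best matches)."""
    support, sids = compute_support(pattern, dataset)
    per: dict[str, float] = {}
    matches: dict[str, geometry.BestMatch] = {}
    for sid in sids:
        bm = geometry.best_match(dataset.get(sid), pattern)
        assert bm is not None
        per[sid] = bm.radius
        matches[sid] = bm
    r = float(np.mean(list(per.values()))) if per else math.nan
    return PatternStats(pattern, support, sids, per, r, matches)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_patterns_tsv(stats: Sequence[PatternStats], path: str | Path) -> None:
    lines = ["pattern\tsize\tsupport\tn_supporting\tcohesive_radius_A"]
    for st in stats:
        lines.append(
            f"{st.pattern}\t{st.pattern.size}\t{st.support:.6f}"
            f"\t{len(st.supporting_ids)}\t{st.cohesive_radius:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_matches_tsv(stats: Sequence[PatternStats], dataset: StructureDataset,
                      path: str | Path) -> None:
    lines = ["structure_id\tpattern\tmatch_radius_A\tresidues"]
    for st in stats:
        for sid in st.supporting_ids:
            bm = st.best_matches.get(sid)
            if bm is None:
                continue
            structure = dataset.get(sid)
            res = ",".join(
                f"{a}:{structure.points[i].chain_id}:{structure.points[i].seq_pos}"
                for a, i in sorted(bm.point_indices.items())
            )
            lines.append(f"{sid}\t{st.pattern}\t{bm.radius:.6f}\t{res}")
    Path(path).write_text("\n".join(lines) + "\n")


def stats_to_json(stats: Sequence[PatternStats]) -> str:
    payload = []
    for st in stats:
        payload.append(
            {
                "pattern": str(st.pattern),
                "size": st.pattern.size,
                "support": st.support,
                "supporting_ids": list(st.supporting_ids),
                "per_structure_radius": st.per_structure_radius,
                "cohesive_radius": st.cohesive_radius,
                "best_matches": {
                    sid: {
                        "radius": bm.radius,
                        "center": list(bm.ball.center),
                        "point_indices": bm.point_indices,
                    }
                    for sid, bm in st.best_matches.items()
                },
            }
        )
    return json.dumps(payload, indent=2)
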