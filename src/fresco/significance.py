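"""Label-permutation background model and pattern significance.

Patterns built from common labels have small cohesive radii by chance alone.
To correct for this, labels are shuffled within each structure while the
coordinates stay fixed: the per-structure label composition — and therefore
every pattern's support — is unchanged, but any genuine spatial clustering is
destroyed.  Repeating the permutation (ten rounds by default) gives a
background sample of cohesive radii per pattern; the background is well
approximated by a normal distribution, and the one-sided lower-tail normal
probability of the observed radius is the pattern's p-value (small radius =
more cohesive than chance).  Multiple testing is controlled by Bonferroni
over the patterns tested in the run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from . import geometry
from .miner import Pattern, PatternStats
from .structure_io import StructureDataset

logger = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 10
DEFAULT_ALPHA = 0.01


@dataclass
class SignificanceResult:
    pattern: Pattern
    observed_R: float
    background_Rs: tuple[float, ...]
    background_mean: float
    background_sd: float
    p_value: float
    significant: bool = False


def permute_labels(dataset: StructureDataset, seed: int) -> StructureDataset:
    """Shuffle labels over point positions within each structure.

    Coordinates, chain ids and sequence positions are untouched and the
    per-structure label multiset is preserved, so every pattern keeps its
    exact support.  In complex mode amino-acid labels shuffle only among
    protein points and base labels only among DNA points.  Deterministic for
    a given seed.
    """
    rng = np.random.default_rng(seed)
    permuted = []
    for structure in dataset:
        labels = list(p.label for p in structure.points)
        kinds = np.array([p.molecule_kind for p in structure.points])
        for kind in ("protein", "dna"):
            pos = np.flatnonzero(kinds == kind)
            if len(pos) > 1:
                perm = rng.permutation(len(pos))
                group = [labels[i] for i in pos]
                for j, i in enumerate(pos):
                    labels[i] = group[perm[j]]
        permuted.append(structure.with_labels(labels))
    return StructureDataset(permuted, mode=dataset.mode)


def _round_seed(master_seed: int, round_index: int) -> np.random.SeedSequence:
    # fixed counter scheme: independent, reproducible rounds
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(round_index,))


def background_distribution(
    dataset: StructureDataset,
    patterns: Sequence[Pattern],
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    combo_limit: int = geometry.EXHAUSTIVE_COMBO_LIMIT,
) -> dict[Pattern, np.ndarray]:
    """Cohesive radii of each pattern on ``n_perm`` label-permuted datasets.

    Support sets are recomputed on the permuted data (they are identical to
    the originals by the permutation invariant, which is asserted downstream
    in tests rather than assumed here silently).
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2 (sd undefined otherwise)")
    patterns = list(patterns)
    background: dict[Pattern, list[float]] = {p: [] for p in patterns}
    for round_i in range(n_perm):
        perm_ds = permute_labels(dataset, _round_seed(seed, round_i))
        per_pattern: dict[Pattern, list[float]] = {p: [] for p in patterns}
        for structure in perm_ds:
            present = structure.label_set
            supported = [p for p in patterns if set(p.labels) <= present]
            if not supported:
                continue
            radii = geometry.batch_best_matches(
                structure, supported, radii_only=True, combo_limit=combo_limit
            )
            for p, r in radii.items():
                per_pattern[p].append(r)
        for p in patterns:
            if not per_pattern[p]:
                raise ValueError(f"pattern {p} unsupported on permuted data")
            background[p].append(float(np.mean(per_pattern[p])))
    return {p: np.asarray(v) for p, v in background.items()}


def pattern_pvalue(
    observed_R: float,
    background_Rs: Sequence[float],
    pattern: Pattern | None = None,
) -> SignificanceResult:
    """Normal-approximation one-sided p-value of an observed cohesive radius.

    Fits mean and unbiased (n-1) standard deviation to the background radii
    and evaluates the lower-tail probability Phi((R_obs - mu) / sigma).  A
    degenerate background (sigma = 0) yields p = 1 when the observation is
    at or above the mean and p = 0 below it.
    """
    bg = np.asarray(background_Rs, dtype=float)
    if bg.size < 2:
        raise ValueError("need at least 2 background values")
    if not (np.all(np.isfinite(bg)) and math.isfinite(observed_R)):
        raise ValueError("non-finite input")
    mu = float(np.mean(bg))
    sd = float(np.std(bg, ddof=1))
    if sd == 0.0:
        p = 1.0 if observed_R >= mu else 0.0
    else:
        p = float(norm.cdf((observed_R - mu) / sd))
    return SignificanceResult(
        pattern=pattern if pattern is not None else Pattern.of("???"),
        observed_R=float(observed_R),
        background_Rs=tuple(float(x) for x in bg),
        background_mean=mu,
        background_sd=sd,
        p_value=p,
    )


def bonferroni_filter(
    results: Sequence[SignificanceResult], alpha: float = DEFAULT_ALPHA
) -> list[SignificanceResult]:
    """Set ``significant`` flags at the Bonferroni-corrected threshold alpha/m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    m = len(results)
    if m < 1:
        raise ValueError("no results to filter")
    threshold = alpha / m
    for res in results:
        res.significant = res.p_value <= threshold
    return list(results)


def evaluate_significance(
    dataset: StructureDataset,
    stats: Sequence[PatternStats],
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    combo_limit: int = geometry.EXHAUSTIVE_COMBO_LIMIT,
) -> list[SignificanceResult]:
    """Full significance pipeline over mined pattern statistics."""
    patterns = [st.pattern for st in stats]
    if not patterns:
        return []
    background = background_distribution(
        dataset, patterns, n_perm=n_perm, seed=seed, combo_limit=combo_limit
    )
    results = [
        pattern_pvalue(st.cohesive_radius, background[st.pattern], pattern=st.pattern)
        for st in stats
    ]
    return bonferroni_filter(results, alpha=alpha)


def write_significance_tsv(results: Sequence[SignificanceResult], path: str | Path) -> None:
    lines = ["pattern\tobserved_R_A\tbg_mean_A\tbg_sd_A\tp_value\tsignificant"]
    for res in results:
        lines.append(
            f"{res.pattern}\t{res.observed_R:.6f}\t{res.background_mean:.6f}"
            f"\t{res.background_sd:.6f}\t{res.p_value:.6e}\t{int(res.significant)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
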