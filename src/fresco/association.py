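"""Downstream association statistics for mined patterns.

Covers four analyses: enrichment/depletion of pattern match residues in
conserved-domain intervals (hypergeometric, residue level), enrichment of
tight pattern matches in gene-ontology annotated structures (hypergeometric,
structure level, counting only best matches with MEB radius below 3 Å),
Spearman correlation of per-structure cohesive radii against the source
organism's optimal growth temperature (OGT), and classification of best
matches by their mean separation along the protein sequence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .geometry import BestMatch
from .miner import Pattern, PatternStats
from .structure_io import PROTEIN, AnnotationTables, StructureDataset, StructureObject

logger = logging.getLogger(__name__)

GO_TIGHT_RADIUS = 3.0          # strict upper bound for a "tight" best match, Å
GO_MIN_STRUCTURES = 10         # minimum structures per GO term tested
OGT_EXCLUDED_TEMPERATURE = 37.0  # mesophile/pathogen temperature removed before ranking
SHORT_RANGE_MAX = 6            # mean separation < 6 residues: short-range
LONG_RANGE_MIN = 10            # mean separation > 10 residues: long-range
DEFAULT_ALPHA = 0.01


@dataclass
class EnrichmentResult:
    pattern: Pattern
    category: str
    k_overlap: int
    n_sample: int
    K_category: int
    N_population: int
    p_enriched: float
    p_depleted: float
    significant_enriched: bool = False
    significant_depleted: bool = False


@dataclass
class OgtResult:
    pattern: Pattern
    n_structures: int
    rho: float
    p_value: float
    direction: str = "none"  # low_T | high_T | none
    significant: bool = False


@dataclass
class SeparationResult:
    mean_separation: float
    category: str  # short_range | long_range | intermediate | cross_chain | undefined


def hypergeom_tails(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """Both tails of the hypergeometric overlap test.

    Drawing ``n`` items from a population of ``N`` containing ``K`` marked
    items, returns (P(X >= k), P(X <= k)).
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    if n - k > N - K:
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    dist = sps.hypergeom(N, K, n)
    p_enriched = float(dist.sf(k - 1))
    p_depleted = float(dist.cdf(k))
    return min(p_enriched, 1.0), min(p_depleted, 1.0)


def _bonferroni_enrichment(results: list[EnrichmentResult], alpha: float) -> list[EnrichmentResult]:
    m = max(len(results), 1)
    for res in results:
        res.significant_enriched = res.p_enriched <= alpha / m
        res.significant_depleted = res.p_depleted <= alpha / m
    return results


def domain_enrichment(
    stats: Sequence[PatternStats],
    tables: AnnotationTables,
    dataset: StructureDataset,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Residue-level overlap of best-match residues with conserved domains.

    Population: all protein residues of structures present in the domain
    table; category: residues inside any annotated interval; sample: the
    distinct residues chosen by a pattern's best matches.  Structures
    absent from the domain table are excluded from the population.
    """
    annotated = [s for s in dataset if s.structure_id in tables.domains]
    if not annotated:
        raise ValueError("no dataset structure appears in the domain table")
    skipped = len(dataset) - len(annotated)
    if skipped:
        logger.info("domain enrichment: %d structures lack domain annotations", skipped)

    in_domain: dict[str, np.ndarray] = {}
    N = K = 0
    for s in annotated:
        intervals = tables.domains[s.structure_id]
        flags = np.zeros(len(s), dtype=bool)
        for i, p in enumerate(s.points):
            if p.molecule_kind != PROTEIN:
                continue
            flags[i] = any(
                iv.chain_id == p.chain_id and iv.start <= p.seq_pos <= iv.end
                for iv in intervals
            )
        protein_mask = np.array([p.molecule_kind == PROTEIN for p in s.points])
        N += int(protein_mask.sum())
        K += int(flags.sum())
        in_domain[s.structure_id] = flags

    results = []
    for st in stats:
        sample: set[tuple[str, int]] = set()
        for sid, bm in st.best_matches.items():
            if sid in in_domain:
                sample.update((sid, i) for i in bm.point_indices.values())
        n = len(sample)
        k = sum(1 for sid, i in sample if in_domain[sid][i])
        p_enr, p_dep = hypergeom_tails(k, n, K, N)
        results.append(EnrichmentResult(st.pattern, "domain_residues", k, n, K, N, p_enr, p_dep))
    return _bonferroni_enrichment(results, alpha)


def go_enrichment(
    stats: Sequence[PatternStats],
    tables: AnnotationTables,
    dataset: StructureDataset,
    tight_radius: float = GO_TIGHT_RADIUS,
    min_structures: int = GO_MIN_STRUCTURES,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Structure-level enrichment of tight pattern matches in GO terms.

    Most patterns occur in almost every structure, so a structure counts as
    "having" the pattern only when its best-match radius is strictly below
    ``tight_radius`` (3 Å by default).  The population is the set of
    structures with any GO annotation; only terms annotated to at least
    ``min_structures`` of them are tested.
    """
    population = [sid for sid in dataset.ids if tables.go.get(sid)]
    N = len(population)
    if N == 0:
        raise ValueError("no dataset structure appears in the GO table")
    pop_set = set(population)
    term_members: dict[str, set[str]] = {}
    for sid in population:
        for term in tables.go[sid]:
            term_members.setdefault(term, set()).add(sid)
    tested_terms = {
        t: members for t, members in sorted(term_members.items())
        if len(members) >= min_structures
    }
    results = []
    for st in stats:
        tight = {
            sid for sid, r in st.per_structure_radius.items()
            if sid in pop_set and r < tight_radius  # strictly below
        }
        n = len(tight)
        for term, members in tested_terms.items():
            k = len(tight & members)
            p_enr, p_dep = hypergeom_tails(k, n, len(members), N)
            results.append(
                EnrichmentResult(st.pattern, term, k, n, len(members), N, p_enr, p_dep)
            )
    return _bonferroni_enrichment(results, alpha)


def ogt_correlation(
    stats: PatternStats,
    ogt: Mapping[str, float],
    alpha: float = DEFAULT_ALPHA,
    m_tests: int = 1,
    exclude_temperature: float = OGT_EXCLUDED_TEMPERATURE,
    min_pairs: int = 5,
) -> OgtResult:
    """Spearman correlation between per-structure radii and growth temperature.

    Structures with an OGT exactly equal to ``exclude_temperature`` (37 °C:
    predominantly pathogens, a compositionally biased group) are removed
    before ranking.  A positive rho (looser at higher temperature) marks a
    pattern more relevant at low temperatures; a negative rho the opposite.
    Fewer than ``min_pairs`` usable pairs yields an undefined (NaN) result.
    """
    pairs = [
        (stats.per_structure_radius[sid], ogt[sid])
        for sid in stats.supporting_ids
        if sid in ogt and ogt[sid] != exclude_temperature
    ]
    n = len(pairs)
    if n < min_pairs:
        return OgtResult(stats.pattern, n, math.nan, math.nan, "none", False)
    radii, temps = zip(*pairs)
    rho, p = sps.spearmanr(radii, temps)
    rho, p = float(rho), float(p)
    significant = bool(np.isfinite(p) and p <= alpha / max(m_tests, 1))
    if significant and rho > 0:
        direction = "low_T"
    elif significant and rho < 0:
        direction = "high_T"
    else:
        direction = "none"
    return OgtResult(stats.pattern, n, rho, p, direction, significant)


def ogt_screen(
    stats: Sequence[PatternStats],
    ogt: Mapping[str, float],
    alpha: float = DEFAULT_ALPHA,
    exclude_temperature: float = OGT_EXCLUDED_TEMPERATURE,
) -> list[OgtResult]:
    """OGT correlation for each pattern, Bonferroni-corrected over the screen."""
    m = max(len(stats), 1)
    return [
        ogt_correlation(st, ogt, alpha=alpha, m_tests=m,
                        exclude_temperature=exclude_temperature)
        for st in stats
    ]


def sequence_separation(
    match: BestMatch,
    structure: StructureObject,
    aggregate: str = "mean",
) -> SeparationResult:
    """Mean pairwise sequence separation of a best match, with range class.

    Separations are |Δseq_pos| over same-chain residue pairs of the match;
    the class is short_range below 6 residues, long_range above 10, else
    intermediate.  Any cross-chain pair makes the match cross_chain; a
    singleton match has no defined separation.
    """
    if aggregate not in ("mean", "max"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    idx = sorted(match.point_indices.values())
    if len(idx) < 2:
        return SeparationResult(math.nan, "undefined")
    pts = [structure.points[i] for i in idx]
    seps = []
    cross = False
    for a in range(len(pts)):
        for b in range(a + 1, len(pts)):
            if pts[a].chain_id != pts[b].chain_id:
                cross = True
            else:
                seps.append(abs(pts[a].seq_pos - pts[b].seq_pos))
    if cross:
        mean = float(np.mean(seps)) if seps else math.nan
        return SeparationResult(mean, "cross_chain")
    value = float(np.mean(seps)) if aggregate == "mean" else float(np.max(seps))
    if value < SHORT_RANGE_MAX:
        category = "short_range"
    elif value > LONG_RANGE_MIN:
        category = "long_range"
    else:
        category = "intermediate"
    return SeparationResult(value, category)


def separation_summary(
    stats: Sequence[PatternStats],
    dataset: StructureDataset,
    aggregate: str = "mean",
) -> dict[Pattern, dict[str, int]]:
    """Counts of separation classes over all best matches, per pattern."""
    out: dict[Pattern, dict[str, int]] = {}
    for st in stats:
        counts: dict[str, int] = {}
        for sid, bm in st.best_matches.items():
            res = sequence_separation(bm, dataset.get(sid), aggregate=aggregate)
            counts[res.category] = counts.get(res.category, 0) + 1
        out[st.pattern] = counts
    return out


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    lines = [
        "pattern\tcategory\tk_overlap\tn_sample\tK_category\tN_population"
        "\tp_enriched\tp_depleted\tsignificant_enriched\tsignificant_depleted"
    ]
    for r in results:
        lines.append(
            f"{r.pattern}\t{r.category}\t{r.k_overlap}\t{r.n_sample}\t{r.K_category}"
            f"\t{r.N_population}\t{r.p_enriched:.6e}\t{r.p_depleted:.6e}"
            f"\t{int(r.significant_enriched)}\t{int(r.significant_depleted)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_ogt_tsv(results: Sequence[OgtResult], path: str | Path) -> None:
    lines = ["pattern\tn_structures\trho\tp_value\tdirection\tsignificant"]
    for r in results:
        lines.append(
            f"{r.pattern}\t{r.n_structures}\t{r.rho:.6f}\t{r.p_value:.6e}"
            f"\t{r.direction}\t{int(r.significant)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_separation_tsv(summary: Mapping[Pattern, Mapping[str, int]], path: str | Path) -> None:
    classes = ["short_range", "intermediate", "long_range", "cross_chain", "undefined"]
    lines = ["pattern\t" + "\t".join(classes)]
    for pattern in sorted(summary):
        counts = summary[pattern]
        lines.append(str(pattern) + "\t" + "\t".join(str(counts.get(c, 0)) for c in classes))
    Path(path).write_text("\n".join(lines) + "\n")
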