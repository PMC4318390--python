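"""Synthetic PDB-like fixtures with controlled composition and planted effects.

The generator draws labeled point clouds that emulate the statistical
setting the miner and its permutation null operate in: labels exchangeable
given coordinates, with an optional planted cohesive motif (a label set
forced into a tight ball in a fraction of structures) and an optional
planted radius–temperature trend for the growth-temperature screen.  Points
are placed uniformly in a box with a minimum-separation constraint at the
Cα–Cα virtual-bond scale, so radii are on the same Å scale as real
structures; no attempt is made at chain connectivity or secondary structure
(the miner and the permutation null are agnostic to both).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .miner import Pattern
from .structure_io import (
    AMINO_ACIDS,
    BASES,
    DNA,
    DNA_RESIDUES,
    PROTEIN,
    LabeledPoint,
    StructureDataset,
    StructureObject,
)

logger = logging.getLogger(__name__)

#: Uniform composition over the 20 standard amino acids.
UNIFORM_COMPOSITION: dict[str, float] = {a: 1.0 / 20.0 for a in sorted(AMINO_ACIDS)}


@dataclass(frozen=True)
class PlantedMotif:
    pattern: Pattern
    plant_radius: float  # Å; best-match radius of the motif will not exceed this
    fraction: float = 1.0  # fraction of structures carrying the motif


@dataclass(frozen=True)
class OgtEffect:
    pattern: Pattern
    slope_sign: int  # -1: tighter at high T (high_T direction); +1: the opposite
    radius_range: tuple[float, float] = (1.0, 6.0)
    noise_sd: float = 0.25


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic dataset.

    Defaults mirror the planted-motif benchmark setting: 50 structures of
    120 residues, uniform amino-acid composition, a 40 Å box and a 3.8 Å
    minimum separation (the Cα–Cα virtual bond length), which puts random
    best-match radii well above the 4.5 Å mining threshold while planted
    motifs sit well below it.
    """

    n_structures: int = 50
    n_points: int = 120
    composition: Mapping[str, float] = field(default_factory=lambda: dict(UNIFORM_COMPOSITION))
    planted_motifs: tuple[PlantedMotif, ...] = ()
    box_size: float = 40.0
    min_separation: float = 3.8
    seed: int = 0
    ogt_effect: OgtEffect | None = None
    ogt_range: tuple[float, float] = (15.0, 95.0)
    ogt_excluded_band: tuple[float, float] = (36.5, 37.5)

    def __post_init__(self) -> None:
        freqs = np.array(list(self.composition.values()), dtype=float)
        if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("composition frequencies must be >= 0 and sum to 1")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        for m in self.planted_motifs:
            if m.plant_radius >= self.box_size:
                raise ValueError("plant_radius must be smaller than box_size")
            if not 0.0 <= m.fraction <= 1.0:
                raise ValueError("planted fraction must be in [0, 1]")
        if self.n_structures < 1 or self.n_points < 1:
            raise ValueError("need at least one structure and one point")


def _molecule_kind(label: str) -> str:
    if label in AMINO_ACIDS:
        return PROTEIN
    if label in BASES:
        return DNA
    raise ValueError(f"label {label!r} is neither an amino acid nor a base")


def _sample_points(rng: np.random.Generator, n: int, box: float, min_sep: float) -> np.ndarray:
    """Uniform points in [0, box]^3 rejected under the min-separation rule."""
    accepted = np.empty((n, 3))
    count = 0
    attempts = 0
    max_attempts = 500 * n
    while count < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} points with separation {min_sep} in a {box} Å box"
            )
        cand = rng.uniform(0.0, box, size=3)
        attempts += 1
        if count == 0 or np.min(np.linalg.norm(accepted[:count] - cand, axis=1)) >= min_sep:
            accepted[count] = cand
            count += 1
    return accepted


def generate_structure(spec: SyntheticSpec, index: int) -> StructureObject:
    """One synthetic structure, deterministic given (spec.seed, index)."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0, index)))
    labels_pool = sorted(spec.composition)
    freqs = np.array([spec.composition[a] for a in labels_pool])
    coords = _sample_points(rng, spec.n_points, spec.box_size, spec.min_separation)
    labels = rng.choice(labels_pool, size=spec.n_points, p=freqs)
    points = []
    seq = {PROTEIN: 0, DNA: 0}
    for label, coord in zip(labels, coords):
        kind = _molecule_kind(str(label))
        seq[kind] += 1
        chain = "A" if kind == PROTEIN else "B"
        points.append(
            LabeledPoint(str(label), tuple(float(x) for x in coord), chain, seq[kind], kind)
        )
    return StructureObject(f"SYN{index:04d}", points)


def plant_motif(
    structure: StructureObject,
    pattern: Pattern,
    plant_radius: float,
    rng: np.random.Generator,
) -> StructureObject:
    """Force a cohesive occurrence of ``pattern`` into a structure.

    Picks a random anchor point, moves the k nearest points (of the matching
    molecule kind) into a ball of radius ``plant_radius`` around it and
    relabels them with the pattern labels, guaranteeing a best-match radius
    of at most ``plant_radius``.  The minimum-separation rule is waived for
    the motif points themselves — they model a contact site.
    """
    k = pattern.size
    kinds = [_molecule_kind(a) for a in pattern.labels]
    coords = structure.coords
    kind_arr = np.array([p.molecule_kind for p in structure.points])
    anchor_i = int(rng.integers(len(structure)))
    center = coords[anchor_i]

    chosen: list[int] = []
    for kind in kinds:
        pool = np.flatnonzero(kind_arr == kind)
        pool = np.array([i for i in pool if i not in chosen], dtype=np.intp)
        if len(pool) == 0:
            raise ValueError(f"not enough {kind} points to plant {pattern}")
        order = pool[np.argsort(np.linalg.norm(coords[pool] - center, axis=1))]
        chosen.append(int(order[0]))

    new_points = list(structure.points)
    for label, i in zip(pattern.labels, chosen):
        direction = rng.normal(size=3)
        direction /= max(np.linalg.norm(direction), 1e-12)
        offset = direction * plant_radius * 0.98 * rng.uniform(0.55, 1.0)
        p = structure.points[i]
        new_points[i] = LabeledPoint(
            label, tuple(float(x) for x in center + offset), p.chain_id, p.seq_pos, p.molecule_kind
        )
    return StructureObject(structure.structure_id, new_points)


def generate_dataset(spec: SyntheticSpec) -> StructureDataset:
    """A full synthetic dataset with any planted motifs applied."""
    structures = [generate_structure(spec, i) for i in range(spec.n_structures)]
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))
    for motif in spec.planted_motifs:
        n_carry = int(round(motif.fraction * spec.n_structures))
        carriers = rng.choice(spec.n_structures, size=n_carry, replace=False)
        for i in sorted(int(c) for c in carriers):
            structures[i] = plant_motif(structures[i], motif.pattern, motif.plant_radius, rng)
    mode = "complex" if any(a in BASES for a in spec.composition) else "protein"
    return StructureDataset(structures, mode=mode)


def generate_ogt_fixture(spec: SyntheticSpec) -> tuple[StructureDataset, dict[str, float]]:
    """Dataset plus OGT table with a planted radius–temperature trend.

    Temperatures are uniform on ``spec.ogt_range`` with the band around
    37 °C excluded (so the pathogen filter removes nothing by construction).
    The effect pattern is planted in every structure with a plant radius
    that varies linearly with temperature in the direction of
    ``spec.ogt_effect.slope_sign`` plus Gaussian noise, so a rank
    correlation screen must recover the planted sign.
    """
    if spec.ogt_effect is None:
        raise ValueError("spec.ogt_effect must be set")
    effect = spec.ogt_effect
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(2,)))
    t_lo, t_hi = spec.ogt_range
    band_lo, band_hi = spec.ogt_excluded_band
    structures = []
    ogt: dict[str, float] = {}
    r_lo, r_hi = effect.radius_range
    for i in range(spec.n_structures):
        while True:
            temp = float(rng.uniform(t_lo, t_hi))
            if not band_lo < temp < band_hi:
                break
        frac = (temp - t_lo) / (t_hi - t_lo)
        if effect.slope_sign < 0:  # tighter at high temperature
            frac = 1.0 - frac
        radius = r_lo + (r_hi - r_lo) * frac + float(rng.normal(0.0, effect.noise_sd))
        radius = float(np.clip(radius, 0.2, r_hi))
        s = generate_structure(spec, i)
        s = plant_motif(s, effect.pattern, radius, rng)
        structures.append(s)
        ogt[s.structure_id] = round(temp, 2)
    mode = "complex" if any(a in BASES for a in spec.composition) else "protein"
    return StructureDataset(structures, mode=mode), ogt


# ---------------------------------------------------------------------------
# PDB and annotation-table output
# ---------------------------------------------------------------------------

_LABEL_TO_RESNAME = {a: a for a in AMINO_ACIDS} | {b: r for r, b in DNA_RESIDUES.items()}


def write_pdb(structure: StructureObject, path: str | Path) -> None:
    """Write minimal standard ATOM records (Cα / N1) round-trippable by the parser."""
    if len(structure) < 1:
        raise ValueError("cannot write an empty structure")
    lines = []
    serial = 0
    for p in structure.points:
        serial += 1
        resname = _LABEL_TO_RESNAME[p.label]
        atom_name, element = (" CA ", " C") if p.molecule_kind == PROTEIN else (" N1 ", " N")
        x, y, z = p.coord
        lines.append(
            f"ATOM  {serial:5d} {atom_name} {resname:>3s} {p.chain_id}{p.seq_pos:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_dataset(dataset: StructureDataset, directory: str | Path) -> list[Path]:
    """One PDB file per structure, named after the structure id."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in dataset:
        path = directory / f"{s.structure_id}.pdb"
        write_pdb(s, path)
        paths.append(path)
    return paths


def write_ogt_table(ogt: Mapping[str, float], path: str | Path) -> None:
    lines = ["structure_id\togt_celsius"]
    lines += [f"{sid}\t{temp}" for sid, temp in sorted(ogt.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def write_domain_table(domains: Mapping[str, Sequence], path: str | Path) -> None:
    lines = ["structure_id\tchain\tstart\tend\tdomain"]
    for sid in sorted(domains):
        for iv in domains[sid]:
            lines.append(f"{sid}\t{iv[0]}\t{iv[1]}\t{iv[2]}\t{iv[3]}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_go_table(go: Mapping[str, set[str]], path: str | Path) -> None:
    lines = ["structure_id\tgo_term"]
    for sid in sorted(go):
        for term in sorted(go[sid]):
            lines.append(f"{sid}\t{term}")
    Path(path).write_text("\n".join(lines) + "\n")
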