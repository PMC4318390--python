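"""Parsing of PDB-format structures into labeled point clouds, plus annotation tables.

The miner works on a reduced representation of a macromolecular structure:
each standard amino-acid residue contributes one labeled point at its
Cα position, and (optionally) each DNA nucleotide one point at its N1
position.  A :class:`StructureObject` is one such point cloud (typically one
chain); a :class:`StructureDataset` is the collection mined over.

Annotation tables (optimal growth temperature, conserved-domain intervals,
gene-ontology terms) are plain TSV files keyed by structure id.
"""

from __future__ import annotations

import io
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

logger = logging.getLogger(__name__)

#: Three-letter codes of the 20 standard amino acids (the protein label alphabet).
AMINO_ACIDS = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

#: PDB residue names of standard deoxyribonucleotides, mapped to base labels.
DNA_RESIDUES = {"DA": "A", "DC": "C", "DG": "G", "DT": "T"}

#: Single-letter base labels (the DNA label alphabet).
BASES = frozenset("ACGT")

PROTEIN = "protein"
DNA = "dna"


class StructureParseError(ValueError):
    """Raised when a PDB source yields no usable points or is malformed."""


@dataclass(frozen=True)
class LabeledPoint:
    """One (label, coordinate) pair: a residue Cα or a base N1.

    Attributes
    ----------
    label:
        Three-letter amino-acid code or single-letter base (A/C/G/T).
    coord:
        Cartesian coordinate in Å.
    chain_id:
        PDB chain identifier.
    seq_pos:
        Author residue number (insertion codes are ignored).
    molecule_kind:
        ``"protein"`` or ``"dna"``.
    """

    label: str
    coord: tuple[float, float, float]
    chain_id: str
    seq_pos: int
    molecule_kind: str = PROTEIN

    def __post_init__(self) -> None:
        if self.molecule_kind not in (PROTEIN, DNA):
            raise ValueError(f"unknown molecule_kind {self.molecule_kind!r}")
        if not all(math.isfinite(c) for c in self.coord):
            raise ValueError(f"non-finite coordinate {self.coord!r}")


class StructureObject:
    """An ordered collection of labeled points from one chain (or chain group).

    This is the data object the miner operates on.  Caches derived arrays
    (coordinates, per-label occurrence indices, pairwise distances) lazily;
    the caches are shared by label-permuted copies because permutation leaves
    the coordinates untouched.
    """

    def __init__(self, structure_id: str, points: Sequence[LabeledPoint]):
        if len(points) < 1:
            raise ValueError(f"structure {structure_id!r} has no points")
        seen: set[tuple[str, int, str]] = set()
        for p in points:
            key = (p.chain_id, p.seq_pos, p.molecule_kind)
            if key in seen:
                raise ValueError(
                    f"structure {structure_id!r}: duplicate point at {key}"
                )
            seen.add(key)
        self.structure_id = structure_id
        self.points: tuple[LabeledPoint, ...] = tuple(points)
        self._coords: np.ndarray | None = None
        self._by_label: dict[str, np.ndarray] | None = None
        self._dist: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.points)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"StructureObject({self.structure_id!r}, {len(self)} points)"

    @property
    def length(self) -> int:
        return len(self.points)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) float64 array of coordinates in file order."""
        if self._coords is None:
            self._coords = np.array([p.coord for p in self.points], dtype=float)
        return self._coords

    @property
    def label_set(self) -> frozenset[str]:
        return frozenset(self.occurrence_index())

    def occurrence_index(self) -> dict[str, np.ndarray]:
        """Mapping label -> indices of points carrying that label (file order)."""
        if self._by_label is None:
            by: dict[str, list[int]] = {}
            for i, p in enumerate(self.points):
                by.setdefault(p.label, []).append(i)
            self._by_label = {a: np.asarray(ix, dtype=np.intp) for a, ix in by.items()}
        return self._by_label

    def occurrences(self, label: str) -> np.ndarray:
        """Indices of the points labeled ``label`` (empty if absent)."""
        return self.occurrence_index().get(label, np.empty(0, dtype=np.intp))

    def dist_matrix(self) -> np.ndarray:
        """Cached (n, n) matrix of pairwise Euclidean distances in Å."""
        if self._dist is None:
            c = self.coords
            d2 = np.sum((c[:, None, :] - c[None, :, :]) ** 2, axis=-1)
            self._dist = np.sqrt(np.maximum(d2, 0.0))
        return self._dist

    def with_labels(self, labels: Sequence[str]) -> "StructureObject":
        """A copy with the same coordinates but new labels (used by permutation)."""
        if len(labels) != len(self.points):
            raise ValueError("label count mismatch")
        pts = [
            LabeledPoint(lbl, p.coord, p.chain_id, p.seq_pos, p.molecule_kind)
            for lbl, p in zip(labels, self.points)
        ]
        out = StructureObject(self.structure_id, pts)
        out._coords = self._coords
        out._dist = self._dist  # coordinates unchanged
        return out


class StructureDataset:
    """An ordered collection of structures sharing one label alphabet."""

    def __init__(self, structures: Sequence[StructureObject], mode: str = "protein"):
        if mode not in ("protein", "complex"):
            raise ValueError(f"unknown mode {mode!r}")
        ids = [s.structure_id for s in structures]
        if len(set(ids)) != len(ids):
            dup = [i for i, c in Counter(ids).items() if c > 1]
            raise ValueError(f"duplicate structure ids: {dup}")
        if mode == "protein":
            for s in structures:
                for p in s.points:
                    if p.molecule_kind != PROTEIN:
                        raise ValueError(
                            f"protein-mode dataset contains DNA point in {s.structure_id}"
                        )
        self.structures: tuple[StructureObject, ...] = tuple(structures)
        self.mode = mode
        self._by_id = {s.structure_id: s for s in self.structures}
        self._ids = tuple(s.structure_id for s in self.structures)

    def __len__(self) -> int:
        return len(self.structures)

    def __iter__(self):
        return iter(self.structures)

    @property
    def ids(self) -> tuple[str, ...]:
        return self._ids

    @property
    def alphabet(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.structures:
            out |= s.label_set
        return frozenset(out)

    def get(self, structure_id: str) -> StructureObject:
        return self._by_id[structure_id]


class DomainInterval(NamedTuple):
    chain_id: str
    start: int
    end: int
    name: str


@dataclass
class AnnotationTables:
    """External per-structure annotations used by the association analyses."""

    ogt: dict[str, float] = field(default_factory=dict)
    domains: dict[str, list[DomainInterval]] = field(default_factory=dict)
    go: dict[str, set[str]] = field(default_factory=dict)


def _select_atom(residue, atom_name: str):
    """Return the requested atom keeping only altloc ' ' or 'A'; None if absent."""
    if atom_name not in residue:
        return None
    atom = residue[atom_name]
    if atom.is_disordered():
        ids = atom.disordered_get_id_list()
        if "A" in ids:
            return atom.disordered_get("A")
        return None
    return atom


def parse_structure(
    pdb_text: str,
    chain_policy: str = "per_chain",
    include_dna: bool = False,
    structure_id: str | None = None,
    source: str = "<string>",
) -> list[StructureObject]:
    """Parse PDB-format text into one labeled point cloud per chain or per entry.

    One point is emitted per standard amino-acid residue possessing a Cα atom
    (label = three-letter code) and, when ``include_dna`` is set, per standard
    deoxyribonucleotide possessing an N1 atom (label = A/C/G/T).  Only the
    first model of multi-model files is read; HETATM records, waters,
    hydrogens and nonstandard residues are ignored, as are alternate
    conformers other than altloc ' '/'A'.

    Parameters
    ----------
    chain_policy:
        ``"per_chain"`` yields one :class:`StructureObject` per chain (ids
        suffixed ``_<chain>``); ``"whole_entry"`` one per file.
    structure_id:
        Base id; defaults to ``source`` file stem.

    Raises
    ------
    StructureParseError
        If no qualifying point is found, or the file is malformed.
    """
    if chain_policy not in ("per_chain", "whole_entry"):
        raise ValueError(f"unknown chain_policy {chain_policy!r}")
    base_id = structure_id if structure_id is not None else Path(source).stem
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        entity = parser.get_structure(base_id, io.StringIO(pdb_text))
    except (PDBConstructionException, ValueError) as exc:
        raise StructureParseError(f"{source}: {exc}") from exc
    models = list(entity)
    if not models:
        raise StructureParseError(f"{source}: no parseable ATOM record")
    model = models[0]  # first model only

    per_chain: dict[str, list[LabeledPoint]] = {}
    n_skipped = 0
    for chain in model:
        pts: list[LabeledPoint] = []
        seen: set[tuple[str, int, str]] = set()
        for residue in chain:
            hetflag, seq_pos, _icode = residue.id
            if hetflag != " ":
                continue
            resname = residue.get_resname().strip()
            if resname in AMINO_ACIDS:
                label, atom_name, kind = resname, "CA", PROTEIN
            elif include_dna and resname in DNA_RESIDUES:
                label, atom_name, kind = DNA_RESIDUES[resname], "N1", DNA
            else:
                n_skipped += 1
                continue
            atom = _select_atom(residue, atom_name)
            if atom is None:
                n_skipped += 1
                continue
            key = (chain.id, seq_pos, kind)
            if key in seen:  # insertion-code duplicate; keep the first
                n_skipped += 1
                continue
            seen.add(key)
            x, y, z = (float(v) for v in atom.get_coord())
            pts.append(LabeledPoint(label, (x, y, z), chain.id, int(seq_pos), kind))
        if pts:
            per_chain[chain.id] = pts
    if n_skipped:
        logger.debug("%s: skipped %d residues without a usable Cα/N1", source, n_skipped)
    if not per_chain:
        raise StructureParseError(f"{source}: no parseable ATOM record with a Cα/N1 atom")

    if chain_policy == "per_chain":
        return [
            StructureObject(f"{base_id}_{cid}", pts)
            for cid, pts in sorted(per_chain.items())
        ]
    all_points = [p for _cid, pts in sorted(per_chain.items()) for p in pts]
    return [StructureObject(base_id, all_points)]


def load_dataset(
    paths: Iterable[str | Path],
    chain_policy: str = "per_chain",
    include_dna: bool = False,
    on_error: str = "raise",
) -> StructureDataset:
    """Load a dataset from PDB files, deterministically sorted by structure id.

    ``on_error="skip"`` drops unreadable files with a warning instead of
    failing; a dataset with zero structures is always a fatal error.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError(f"unknown on_error {on_error!r}")
    paths = list(paths)
    if not paths:
        raise ValueError("no input paths given")
    structures: list[StructureObject] = []
    for path in paths:
        path = Path(path)
        try:
            text = path.read_text()
            structures.extend(
                parse_structure(
                    text,
                    chain_policy=chain_policy,
                    include_dna=include_dna,
                    source=str(path),
                )
            )
        except (OSError, StructureParseError) as exc:
            if on_error == "raise":
                raise
            logger.warning("skipping %s: %s", path, exc)
    if not structures:
        raise StructureParseError("no structures could be parsed from the given paths")
    structures.sort(key=lambda s: s.structure_id)
    mode = "complex" if include_dna else "protein"
    logger.info("loaded %d structures (%s mode)", len(structures), mode)
    return StructureDataset(structures, mode=mode)


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def load_annotations(
    ogt_path: str | Path | None = None,
    domains_path: str | Path | None = None,
    go_path: str | Path | None = None,
) -> AnnotationTables:
    """Read the OGT / domain-interval / GO annotation TSVs.

    Expected headers: ``structure_id, ogt_celsius`` | ``structure_id, chain,
    start, end, domain`` | ``structure_id, go_term``.  Unknown structure ids
    are retained (they are filtered against the dataset at use time);
    omitted paths yield empty tables.
    """
    tables = AnnotationTables()
    if ogt_path is not None:
        df = _read_tsv(ogt_path, ["structure_id", "ogt_celsius"])
        for row_i, row in df.iterrows():
            try:
                temp = float(row["ogt_celsius"])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{ogt_path}: row {row_i}: non-numeric temperature "
                    f"{row['ogt_celsius']!r}"
                ) from exc
            if not math.isfinite(temp):
                raise ValueError(f"{ogt_path}: row {row_i}: non-finite temperature")
            tables.ogt[str(row["structure_id"])] = temp
    if domains_path is not None:
        df = _read_tsv(domains_path, ["structure_id", "chain", "start", "end", "domain"])
        for row_i, row in df.iterrows():
            start, end = int(row["start"]), int(row["end"])
            if start > end:
                raise ValueError(f"{domains_path}: row {row_i}: start > end")
            tables.domains.setdefault(str(row["structure_id"]), []).append(
                DomainInterval(str(row["chain"]), start, end, str(row["domain"]))
            )
    if go_path is not None:
        df = _read_tsv(go_path, ["structure_id", "go_term"])
        for _, row in df.iterrows():
            tables.go.setdefault(str(row["structure_id"]), set()).add(str(row["go_term"]))
    return tables
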