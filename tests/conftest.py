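from __future__ import annotations

import numpy as np
import pytest

from fresco.structure_io import LabeledPoint, StructureDataset, StructureObject


def make_structure(spec, structure_id="S", chain="A", kind="protein"):
    """Build a structure from [(label, (x, y, z)), ...] with sequential numbering."""
    points = [
        LabeledPoint(label, tuple(float(v) for v in coord), chain, i + 1, kind)
        for i, (label, coord) in enumerate(spec)
    ]
    return StructureObject(structure_id, points)


def random_structure(rng, n_points=30, alphabet=("ALA", "GLY", "VAL", "LEU", "SER", "THR"),
                     box=25.0, structure_id="R"):
    spec = [
        (str(rng.choice(alphabet)), rng.uniform(0.0, box, size=3))
        for _ in range(n_points)
    ]
    return make_structure(spec, structure_id=structure_id)


def random_dataset(rng, n_structures=6, n_points=25, alphabet=("ALA", "GLY", "VAL", "LEU", "SER", "THR"),
                   box=25.0):
    structures = [
        random_structure(rng, n_points=n_points, alphabet=alphabet, box=box,
                         structure_id=f"R{i:03d}")
        for i in range(n_structures)
    ]
    return StructureDataset(structures)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_structure():
    return make_structure(
        [
            ("ALA", (0.0, 0.0, 0.0)),
            ("VAL", (4.0, 0.0, 0.0)),
            ("GLY", (0.0, 4.0, 0.0)),
            ("ALA", (10.0, 10.0, 10.0)),
            ("SER", (10.0, 10.0, 14.0)),
        ]
    )


@pytest.fixture
def toy_dataset():
    s1 = make_structure(
        [("ALA", (0, 0, 0)), ("VAL", (4, 0, 0)), ("GLY", (0, 4, 0))], structure_id="S1"
    )
    s2 = make_structure(
        [("ALA", (0, 0, 0)), ("VAL", (2, 0, 0)), ("SER", (0, 2, 0))], structure_id="S2"
    )
    s3 = make_structure(
        [("ALA", (0, 0, 0)), ("GLY", (8, 0, 0)), ("SER", (0, 8, 0))], structure_id="S3"
    )
    return StructureDataset([s1, s2, s3])
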