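"""Shared fixtures: hand-formatted MOL/SDF text and small reference geometries.

The molblock writer here is deliberately independent of the package's RDKit-
based I/O so that read/round-trip tests compare against a second, trivially
auditable implementation of the format.
"""

from __future__ import annotations

import numpy as np
import pytest


def make_molblock(
    name: str,
    atoms: list[tuple[str, float, float, float]],
    bonds: list[tuple[int, int, int]],
    dim: str = "3D",
) -> str:
    """Minimal MOL V2000 text. Bonds are 1-based (file convention)."""
    lines = [name, f"  {'tester':<8}          {dim}", ""]
    lines.append(f"{len(atoms):>3}{len(bonds):>3}  0  0  0  0  0  0  0  0999 V2000")
    for el, x, y, z in atoms:
        lines.append(f"{x:>10.4f}{y:>10.4f}{z:>10.4f} {el:<3}0  0  0  0  0  0  0  0  0  0  0  0")
    for a, b, order in bonds:
        lines.append(f"{a:>3}{b:>3}{order:>3}  0")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def hexagon_atoms(circumradius: float = 1.39, z: float = 0.0, element: str = "C"):
    return [
        (element,
         circumradius * np.cos(np.pi * k / 3),
         circumradius * np.sin(np.pi * k / 3),
         z)
        for k in range(6)
    ]


METHANE_ATOMS = [
    ("C", 0.0, 0.0, 0.0),
    ("H", 0.6291, 0.6291, 0.6291),
    ("H", -0.6291, -0.6291, 0.6291),
    ("H", -0.6291, 0.6291, -0.6291),
    ("H", 0.6291, -0.6291, -0.6291),
]
METHANE_BONDS = [(1, 2, 1), (1, 3, 1), (1, 4, 1), (1, 5, 1)]


@pytest.fixture
def methane_mol(tmp_path):
    p = tmp_path / "methane.mol"
    p.write_text(make_molblock("methane", METHANE_ATOMS, METHANE_BONDS))
    return p


@pytest.fixture
def benzene_mol(tmp_path):
    atoms = hexagon_atoms()
    bonds = [(k + 1, (k + 1) % 6 + 1, 4) for k in range(6)]
    p = tmp_path / "benzene.mol"
    p.write_text(make_molblock("benzene", atoms, bonds))
    return p


@pytest.fixture
def ethane_mol(tmp_path):
    atoms = [("C", 0.0, 0.0, 0.0), ("C", 1.54, 0.0, 0.1)]
    p = tmp_path / "ethane.mol"
    p.write_text(make_molblock("ethane", atoms, [(1, 2, 1)]))
    return p


@pytest.fixture
def naphthalene_mol(tmp_path):
    # two fused regular hexagons in the xy-plane, side 1.39 A
    p = tmp_path / "naphthalene.mol"
    p.write_text(make_molblock("naphthalene", _naphthalene_atoms(), _naphthalene_bonds()))
    return p


def _naphthalene_atoms():
    s = 1.39
    h = s * np.sqrt(3) / 2
    # shared edge atoms 0,1 on the y-axis; ring A to the left, ring B right
    pts = [
        (0.0, s / 2), (0.0, -s / 2),
        (-h, s), (-2 * h, s / 2), (-2 * h, -s / 2), (-h, -s),
        (h, s), (2 * h, s / 2), (2 * h, -s / 2), (h, -s),
    ]
    return [("C", x, y, 0.0) for x, y in pts]


def _naphthalene_bonds():
    # 1-based; ring A cycle 1-3-4-5-6-2-1, ring B cycle 1-7-8-9-10-2-1
    edges = [(1, 2),
             (1, 3), (3, 4), (4, 5), (5, 6), (6, 2),
             (1, 7), (7, 8), (8, 9), (9, 10), (10, 2)]
    return [(a, b, 4) for a, b in edges]


@pytest.fixture
def three_record_sdf(tmp_path):
    blocks = [
        make_molblock("methane", METHANE_ATOMS, METHANE_BONDS),
        make_molblock("ethane", [("C", 0.0, 0.0, 0.0), ("C", 1.54, 0.0, 0.1)], [(1, 2, 1)]),
        make_molblock("ammonia", [("N", 0.0, 0.0, 0.2)], []),
    ]
    p = tmp_path / "three.sdf"
    p.write_text("$$$$\n".join(blocks) + "$$$$\n")
    return p


def write_manifest_csv(tmp_path, rows, name="manifest.csv"):
    lines = ["id,activity,role"] + [f"{i},{a},{r}" for i, a, r in rows]
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


def benchmark_manifest_rows():
    """Synthetic stand-in manifest mirroring a 55-model / 38-external TdP panel.

    32 active + 23 inactive modeling compounds and 38 external compounds
    (19 active / 19 inactive); ids are synthetic placeholders.
    """
    rows = []
    rows += [(f"model_act_{k:02d}", 1, "model") for k in range(32)]
    rows += [(f"model_inact_{k:02d}", 0, "model") for k in range(23)]
    rows += [(f"ext_act_{k:02d}", 1, "external") for k in range(19)]
    rows += [(f"ext_inact_{k:02d}", 0, "external") for k in range(19)]
    return rows


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))
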