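"""Structure and manifest I/O plus the geometry used by every downstream stage.

Molecules enter as MOL V2000 / multi-record SDF files and are held as plain
:class:`MoleculeRecord` objects (elements, 3D coordinates in Å, bonds with
aromatic flags).  Atom order is preserved exactly as in the file because atom
indices are the join key for external chemical-shift tables; indices are
0-based internally and translated to/from the 1-based MOL convention only at
file boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateInputError, StructureParseError, ValidationError

RDLogger.DisableLog("rdApp.*")

VALID_ROLES = ("model", "external")


@dataclass
class MoleculeRecord:
    """One molecule: ordered atoms with 3D coordinates, bonds, aromatic flags.

    ``bonds`` holds 0-based ``(i, j, order)`` tuples; aromatic bonds carry
    order 4 in MOL files and are mirrored in ``aromatic_flags``.
    """

    id: str
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) float64, Å
    bonds: list[tuple[int, int, int]]
    aromatic_flags: list[bool]
    props: dict[str, str] = field(default_factory=dict)
    is_3d: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.elements)
        if self.coords.shape[0] != n:
            raise ValidationError(
                f"{self.id}: {n} elements but {self.coords.shape[0]} coordinate rows"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"{self.id}: non-finite coordinates")
        for a, b, _ in self.bonds:
            if not (0 <= a < n and 0 <= b < n):
                raise ValidationError(f"{self.id}: bond ({a},{b}) out of range")
        if len(self.aromatic_flags) != len(self.bonds):
            raise ValidationError(f"{self.id}: aromatic flags/bond count mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def atom_is_aromatic(self, index: int) -> bool:
        """True if any bond incident to ``index`` carries the aromatic flag."""
        return any(
            flag and index in (a, b)
            for (a, b, _), flag in zip(self.bonds, self.aromatic_flags)
        )

    def cn_indices(self) -> list[int]:
        """Indices of the carbon and nitrogen atoms (the only ones fingerprinted)."""
        return [i for i, el in enumerate(self.elements) if el in ("C", "N")]


@dataclass
class LabelManifest:
    """Validated activity/role table keyed by molecule id."""

    table: pd.DataFrame  # columns: id, activity, role[, report_count]

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def role_ids(self, role: str) -> list[str]:
        return list(self.table.loc[self.table["role"] == role, "id"])

    @property
    def model_ids(self) -> list[str]:
        return self.role_ids("model")

    @property
    def external_ids(self) -> list[str]:
        return self.role_ids("external")

    def activity_of(self, mol_id: str) -> int:
        row = self.table.loc[self.table["id"] == mol_id, "activity"]
        if row.empty:
            raise KeyError(mol_id)
        return int(row.iloc[0])

    def activities(self, ids: Sequence[str]) -> np.ndarray:
        lookup = dict(zip(self.table["id"], self.table["activity"]))
        return np.array([int(lookup[i]) for i in ids], dtype=int)

    def n_active(self, role: str | None = None) -> int:
        t = self.table if role is None else self.table[self.table["role"] == role]
        return int((t["activity"] == 1).sum())


@dataclass
class AromaticRing:
    """An aromatic ring: member atom indices and the centroid (mean) position."""

    member_indices: tuple[int, ...]
    centroid: np.ndarray  # (3,) Å

    @property
    def size(self) -> int:
        return len(self.member_indices)


# ---------------------------------------------------------------------------
# structure I/O


def _record_from_rdkit(
    mol: Chem.Mol, fallback_id: str, flagged_2d: bool
) -> MoleculeRecord:
    if mol.GetNumConformers() == 0:
        raise DegenerateInputError(f"{fallback_id}: no coordinates present")
    if mol.GetNumConformers() > 1:
        warnings.warn(
            f"{fallback_id}: multiple conformers; using the first", stacklevel=3
        )
    conf = mol.GetConformer(0)
    coords = np.array(conf.GetPositions(), dtype=float)
    mol_id = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
    mol_id = mol_id or fallback_id
    if flagged_2d and np.allclose(coords[:, 2], 0.0):
        raise DegenerateInputError(
            f"record {mol_id!r} has 2D-only coordinates (flagged 2D, all z == 0); "
            "fingerprinting requires a 3D conformer"
        )
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    bonds: list[tuple[int, int, int]] = []
    flags: list[bool] = []
    for b in mol.GetBonds():
        aromatic = b.GetBondType() == Chem.BondType.AROMATIC or b.GetIsAromatic()
        order = 4 if aromatic else int(b.GetBondTypeAsDouble())
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        flags.append(bool(aromatic))
    props = {k: mol.GetProp(k) for k in mol.GetPropNames()}
    return MoleculeRecord(
        id=mol_id,
        elements=elements,
        coords=coords,
        bonds=bonds,
        aromatic_flags=flags,
        props=props,
        is_3d=not flagged_2d,
    )


def _is_flagged_2d(molblock: str) -> bool:
    """Dimension code from MOL header line 2, columns 21-22 ('2D'/'3D')."""
    lines = molblock.split("\n")
    if len(lines) < 2:
        return False
    return lines[1][20:22] == "2D"


def read_structures(path: str | Path) -> list[MoleculeRecord]:
    """Read a MOL V2000 file or a multi-record SDF into MoleculeRecords.

    Atom order is preserved exactly as written.  A record whose coordinates
    are flagged 2D with every z equal to zero raises
    :class:`DegenerateInputError` naming the record.  Planar molecules marked
    3D (or carrying no dimension code) are accepted.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such structure file: {path}")
    text = path.read_text()
    # split multi-record SDF ourselves so the raw block (dimension flag,
    # property fields) stays available per record
    chunks = text.split("$$$$")
    blocks = [c.lstrip("\n") for c in chunks if c.strip()]
    records: list[MoleculeRecord] = []
    for i, block in enumerate(blocks):
        mol = Chem.MolFromMolBlock(block, sanitize=False, removeHs=False)
        if mol is None:
            raise StructureParseError(f"{path}: record {i} failed to parse")
        # property fields (">  <NAME>" blocks) are not parsed by
        # MolFromMolBlock; recover them from the raw text
        for prop_name, value in _parse_sdf_properties(block):
            mol.SetProp(prop_name, value)
        fallback = path.stem if len(blocks) == 1 and path.suffix.lower() == ".mol" \
            else f"record_{i}"
        records.append(
            _record_from_rdkit(mol, fallback_id=fallback,
                               flagged_2d=_is_flagged_2d(block))
        )
    return records


def _parse_sdf_properties(block: str) -> list[tuple[str, str]]:
    props = []
    lines = block.split("\n")
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(">") and "<" in line:
            name = line[line.index("<") + 1 : line.rindex(">")]
            values = []
            i += 1
            while i < len(lines) and lines[i].strip() != "":
                values.append(lines[i])
                i += 1
            props.append((name, "\n".join(values)))
        i += 1
    return props


def _to_rdkit(record: MoleculeRecord) -> Chem.RWMol:
    mol = Chem.RWMol()
    for el in record.elements:
        mol.AddAtom(Chem.Atom(el))
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                 3: Chem.BondType.TRIPLE, 4: Chem.BondType.AROMATIC}
    for (a, b, order), flag in zip(record.bonds, record.aromatic_flags):
        bt = Chem.BondType.AROMATIC if flag else order_map.get(order, Chem.BondType.SINGLE)
        mol.AddBond(a, b, bt)
        bond = mol.GetBondBetweenAtoms(a, b)
        bond.SetIsAromatic(bool(flag))
        if flag:
            mol.GetAtomWithIdx(a).SetIsAromatic(True)
            mol.GetAtomWithIdx(b).SetIsAromatic(True)
    conf = Chem.Conformer(record.n_atoms)
    for i, xyz in enumerate(record.coords):
        conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
    conf.Set3D(record.is_3d)
    mol.AddConformer(conf)
    mol.SetProp("_Name", record.id)
    mol.UpdatePropertyCache(strict=False)
    return mol


def write_structures(
    records: Iterable[MoleculeRecord],
    path: str | Path,
    extra_props: Mapping[str, Mapping[str, str]] | None = None,
) -> None:
    """Write records as an SDF, optionally with per-record property blocks.

    ``extra_props`` maps molecule id → {property name: value}; existing record
    props are written too.  Aromatic bonds are written as MOL bond type 4
    (no kekulization), so files round-trip the flags they came in with.
    """
    path = Path(path)
    blocks = []
    for rec in records:
        mol = _to_rdkit(rec)
        block = Chem.MolToMolBlock(mol, kekulize=False)
        props = dict(rec.props)
        if extra_props and rec.id in extra_props:
            props.update(extra_props[rec.id])
        prop_text = "".join(
            f">  <{key}>\n{value}\n\n" for key, value in props.items()
        )
        blocks.append(block + prop_text + "$$$$\n")
    path.write_text("".join(blocks))


# ---------------------------------------------------------------------------
# manifests


def read_manifest(path: str | Path) -> LabelManifest:
    """Read a comma- or tab-delimited label manifest.

    Required columns ``id,activity,role``; optional ``report_count`` (the
    number of post-marketing adverse-event reports behind an external label).
    Activity must be strictly binary and roles one of ``model``/``external``.
    """
    table = pd.read_csv(path, sep=None, engine="python", dtype={"id": str})
    missing = {"id", "activity", "role"} - set(table.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    dup = table["id"][table["id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate manifest ids: {sorted(set(dup))}")
    if not table["activity"].isin([0, 1]).all():
        bad = sorted(set(table["activity"]) - {0, 1})
        raise ValidationError(f"activity must be 0 or 1; found {bad}")
    table["activity"] = table["activity"].astype(int)
    table["role"] = table["role"].astype(str).str.strip()
    bad_roles = sorted(set(table["role"]) - set(VALID_ROLES))
    if bad_roles:
        raise ValidationError(f"unknown role tokens: {bad_roles}")
    if "report_count" in table.columns:
        counts = table["report_count"].dropna()
        if (counts < 0).any():
            raise ValidationError("report_count must be nonnegative")
    return LabelManifest(table=table.reset_index(drop=True))


def write_manifest(manifest: LabelManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# geometry


def distance_matrix(record: MoleculeRecord) -> np.ndarray:
    """Symmetric Euclidean interatomic distance matrix in Å.

    The diagonal is exactly zero; the matrix is invariant under any rigid
    rotation or translation of the input coordinates.
    """
    if record.n_atoms == 0:
        raise DegenerateInputError(f"{record.id}: no atoms")
    if record.n_atoms == 1:
        return np.zeros((1, 1))
    return squareform(pdist(record.coords))


def perceive_aromatic_rings(record: MoleculeRecord) -> list[AromaticRing]:
    """List the aromatic rings of a molecule with their centroids.

    A ring counts as aromatic when every one of its bonds carries the aromatic
    flag from the input file.  When the file carries no aromatic flags at all,
    the RDKit default aromaticity model is applied as a fallback.  Molecules
    without rings return an empty list.
    """
    mol = _to_rdkit(record)
    file_has_flags = any(record.aromatic_flags)
    if not file_has_flags:
        try:
            Chem.SanitizeMol(mol)
        except Exception:  # unsanitizable toy input: keep file bonds as-is
            pass
    ring_info = Chem.GetSymmSSSR(mol)
    flag_lookup = {}
    for (a, b, _), flag in zip(record.bonds, record.aromatic_flags):
        flag_lookup[frozenset((a, b))] = flag
    rings: list[AromaticRing] = []
    for ring in ring_info:
        members = tuple(int(i) for i in ring)
        if len(members) < 3:
            continue
        ring_bonds = [
            frozenset((members[k], members[(k + 1) % len(members)]))
            for k in range(len(members))
        ]
        if file_has_flags:
            aromatic = all(flag_lookup.get(rb, False) for rb in ring_bonds)
        else:
            aromatic = all(
                mol.GetBondBetweenAtoms(*tuple(rb)).GetIsAromatic()
                for rb in ring_bonds
            )
        if aromatic:
            centroid = record.coords[list(members)].mean(axis=0)
            rings.append(AromaticRing(member_indices=members, centroid=centroid))
    return rings


def ring_membership(rings: Sequence[AromaticRing], n_atoms: int) -> list[int | None]:
    """Map each atom index to the index of the first aromatic ring containing it."""
    membership: list[int | None] = [None] * n_atoms
    for ri, ring in enumerate(rings):
        for a in ring.member_indices:
            if membership[a] is None:
                membership[a] = ri
    return membership
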