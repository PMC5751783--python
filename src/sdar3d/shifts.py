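"""Pluggable per-atom ¹³C / ¹⁵N chemical-shift providers.

The method consumes isotropic chemical shifts (PPM) for every carbon and
nitrogen atom, but is agnostic to where they come from — in practice an
external HOSE-code or ab-initio predictor.  Real use supplies a shift table
(CSV ``id,atom_index,element,shift_ppm``, 1-based atom indices matching the
MOL file); a deterministic naive rule set exists so fixtures and synthetic
data need no external predictor.  Shifts follow the convention of positive
PPM values for carbon and negative values for nitrogen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chem_io import MoleculeRecord
from .errors import IncompleteAssignmentError, ValidationError

# plausibility windows used only for warnings, deliberately wider than the
# fingerprint bin windows
CARBON_SANITY_PPM = (-50.0, 250.0)
NITROGEN_SANITY_PPM = (-500.0, 100.0)


@dataclass
class ShiftAssignment:
    """Per-atom shifts (PPM) for the C and N atoms of one molecule.

    Keys are 0-based atom indices; only carbon and nitrogen appear.
    """

    molecule_id: str
    shifts: dict[int, float]
    elements: dict[int, str]

    def __post_init__(self) -> None:
        for i, el in self.elements.items():
            if el not in ("C", "N"):
                raise ValidationError(
                    f"{self.molecule_id}: shifted atom {i} is {el}, not C/N"
                )

    def __len__(self) -> int:
        return len(self.shifts)


@dataclass
class ShiftProviderSpec:
    """Declarative choice of shift source: an external table or naive rules."""

    kind: str = "naive_rules"  # "table" | "naive_rules"
    table_path: str | Path | None = None
    rules_version: str = "1"

    def __post_init__(self) -> None:
        if self.kind not in ("table", "naive_rules"):
            raise ValidationError(f"unknown shift provider kind {self.kind!r}")
        if self.kind == "table":
            if self.table_path is None or not Path(self.table_path).exists():
                raise ValidationError(
                    f"kind=table requires an existing table path, got {self.table_path!r}"
                )


# class centers for the naive fallback; these are typical-range placeholders
# with no claim of spectroscopic accuracy
_CARBON_AROMATIC_BASE = 128.5
_CARBON_ALIPHATIC_BASE = 29.0
_CARBON_HETERO_STEP = 18.0
_NITROGEN_AROMATIC_BASE = -128.0
_NITROGEN_ALIPHATIC_BASE = -330.0
_NITROGEN_HETERO_STEP = 25.0


def naive_rule_shift(element: str, aromatic: bool, n_hetero_neighbors: int) -> float:
    """Deterministic class-center shift for a C or N atom context.

    Aromatic carbons sit in the aromatic window (~128 PPM), aliphatic carbons
    near 29 PPM, each pushed downfield per heteroatom neighbor; nitrogens use
    the negative-PPM convention with aliphatic amines near the bottom of the
    window.  Same context → same value.
    """
    if element == "C":
        base = _CARBON_AROMATIC_BASE if aromatic else _CARBON_ALIPHATIC_BASE
        value = base + _CARBON_HETERO_STEP * n_hetero_neighbors
        return float(min(max(value, -4.0), 204.0))
    if element == "N":
        base = _NITROGEN_AROMATIC_BASE if aromatic else _NITROGEN_ALIPHATIC_BASE
        value = base + _NITROGEN_HETERO_STEP * n_hetero_neighbors
        return float(min(max(value, -356.0), -11.0))
    raise ValidationError(f"naive_rule_shift: element must be C or N, got {element!r}")


def _hetero_neighbor_count(record: MoleculeRecord, index: int) -> int:
    count = 0
    for a, b, _ in record.bonds:
        other = b if a == index else a if b == index else None
        if other is not None and record.elements[other] not in ("C", "H"):
            count += 1
    return count


def _sanity_check(molecule_id: str, index: int, element: str, shift: float) -> None:
    lo, hi = CARBON_SANITY_PPM if element == "C" else NITROGEN_SANITY_PPM
    if not (lo <= shift <= hi):
        warnings.warn(
            f"{molecule_id}: atom {index} ({element}) shift {shift} PPM outside "
            f"sanity window [{lo}, {hi}]; passed through",
            stacklevel=3,
        )


class ShiftTable:
    """Shift lookup backed by a CSV table keyed by (molecule id, atom index)."""

    def __init__(self, table: pd.DataFrame):
        required = {"id", "atom_index", "element", "shift_ppm"}
        missing = required - set(table.columns)
        if missing:
            raise ValidationError(f"shift table missing columns: {sorted(missing)}")
        self.table = table

    @classmethod
    def read_csv(cls, path: str | Path) -> "ShiftTable":
        return cls(pd.read_csv(path, sep=None, engine="python", dtype={"id": str}))

    def lookup(self, molecule_id: str) -> dict[int, float]:
        rows = self.table[self.table["id"] == molecule_id]
        # file indices are 1-based (MOL convention)
        return {
            int(r.atom_index) - 1: float(r.shift_ppm) for r in rows.itertuples()
        }


def shifts_from_sdf_properties(record: MoleculeRecord) -> dict[int, float] | None:
    """Decode the ``SDAR_SHIFTS`` SDF property (``index:shift;...``, 1-based)."""
    raw = record.props.get("SDAR_SHIFTS")
    if raw is None:
        return None
    out: dict[int, float] = {}
    for token in raw.strip().split(";"):
        token = token.strip()
        if not token:
            continue
        idx, _, val = token.partition(":")
        out[int(idx) - 1] = float(val)
    return out


def assign_shifts(
    record: MoleculeRecord, spec: ShiftProviderSpec, table: ShiftTable | None = None
) -> ShiftAssignment:
    """Resolve a shift for every C and N atom of ``record``.

    Atoms of other elements are absent from the result.  For ``kind=table``
    an entry must exist for every C/N atom; missing atoms raise
    :class:`IncompleteAssignmentError` listing the 0-based indices.  Values
    outside the element sanity window warn but pass through.  Embedded
    ``SDAR_SHIFTS`` SDF properties take precedence over the table.
    """
    cn = record.cn_indices()
    elements = {i: record.elements[i] for i in cn}
    embedded = shifts_from_sdf_properties(record)
    if embedded is not None:
        source = embedded
    elif spec.kind == "table":
        if table is None:
            table = ShiftTable.read_csv(spec.table_path)
        source = table.lookup(record.id)
    else:
        source = {
            i: naive_rule_shift(
                record.elements[i],
                record.atom_is_aromatic(i),
                _hetero_neighbor_count(record, i),
            )
            for i in cn
        }
    missing = [i for i in cn if i not in source]
    if missing:
        raise IncompleteAssignmentError(record.id, missing)
    shifts = {i: float(source[i]) for i in cn}
    for i, s in shifts.items():
        _sanity_check(record.id, i, elements[i], s)
    return ShiftAssignment(molecule_id=record.id, shifts=shifts, elements=elements)


def write_shift_csv(assignments: list[ShiftAssignment], path: str | Path) -> None:
    """Write assignments as the standard table format (1-based atom indices)."""
    rows = [
        {
            "id": a.molecule_id,
            "atom_index": i + 1,
            "element": a.elements[i],
            "shift_ppm": a.shifts[i],
        }
        for a in assignments
        for i in sorted(a.shifts)
    ]
    pd.DataFrame(rows, columns=["id", "atom_index", "element", "shift_ppm"]).to_csv(
        path, index=False
    )
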