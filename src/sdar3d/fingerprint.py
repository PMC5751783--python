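"""3D-SDAR fingerprints: tessellating atom-pair (shift, shift, distance) triplets.

Every unordered pair of C/N atoms contributes one point in a three-dimensional
abstract space — the two isotropic chemical shifts (PPM) and the interatomic
distance (Å).  The space is tessellated into boxes ("bins") and a molecule's
fingerprint counts the pairs falling in each box.  Because only shifts and
pairwise distances enter, the fingerprint is invariant under any rigid motion
of the Cartesian coordinates.

Bins are kept in disjoint id blocks per pair class (CC, CN, NN): the carbon
and nitrogen shift axes have different windows and bin widths (the nitrogen
bin width is the carbon width times a fixed ratio, default 2.5), so a mixed
grid would create meaningless cells.  Pair orientation is canonicalized —
smaller shift first for same-element pairs, carbon first for CN — making the
fingerprint independent of atom enumeration order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem_io import MoleculeRecord
from .errors import ContractError, DegenerateInputError, IncompleteAssignmentError, ValidationError
from .shifts import ShiftAssignment


class _OutOfWindow:
    """Sentinel for a shift or distance outside its binning window."""

    def __repr__(self) -> str:  # pragma: no cover
        return "OUT_OF_WINDOW"


OUT_OF_WINDOW = _OutOfWindow()

PAIR_CLASSES = ("CC", "CN", "NN")


@dataclass(frozen=True)
class BinningConfig:
    """Windows, bin widths and occupancy rules of the 3D bin space.

    Defaults: carbon shift window −4..+204 PPM (width 208, midpoint 100) and
    nitrogen window −356..−11 PPM (width 345, midpoint −183.5); the nitrogen
    bin width is ``cn_ratio`` (default 2.5) times the carbon bin width.  The
    carbon bin width defaults to 8 PPM (26 carbon bins; 18 nitrogen bins with
    the last truncated at −11 PPM).  Distances are binned at 1 Å over
    1–20 Å.  ``occupancy`` is ``binary`` (bin presence/absence, the default:
    sparse pair bins are best treated as indicators) or ``count`` (pair
    multiplicity); ``scaling`` controls the feature-matrix column transform
    (min–max by default; z-scoring gives rare bins outsized leverage).
    """

    carbon_window: tuple[float, float] = (-4.0, 204.0)
    nitrogen_window: tuple[float, float] = (-356.0, -11.0)
    carbon_bin_width: float = 8.0
    cn_ratio: float = 2.5
    distance_window: tuple[float, float] = (1.0, 20.0)
    distance_bin_width: float = 1.0
    occupancy: str = "binary"  # "binary" | "count"
    scaling: str = "minmax"  # "minmax" | "zscore" | "none"

    def __post_init__(self) -> None:
        if self.carbon_bin_width <= 0 or self.cn_ratio <= 0 or self.distance_bin_width <= 0:
            raise ValidationError("bin widths and ratio must be positive")
        if self.occupancy not in ("count", "binary"):
            raise ValidationError(f"unknown occupancy mode {self.occupancy!r}")
        if self.scaling not in ("zscore", "minmax", "none"):
            raise ValidationError(f"unknown scaling mode {self.scaling!r}")

    @property
    def nitrogen_bin_width(self) -> float:
        return self.cn_ratio * self.carbon_bin_width

    @property
    def carbon_window_width(self) -> float:
        return self.carbon_window[1] - self.carbon_window[0]

    @property
    def nitrogen_window_width(self) -> float:
        return self.nitrogen_window[1] - self.nitrogen_window[0]

    @property
    def carbon_window_midpoint(self) -> float:
        return 0.5 * (self.carbon_window[0] + self.carbon_window[1])

    @property
    def nitrogen_window_midpoint(self) -> float:
        return 0.5 * (self.nitrogen_window[0] + self.nitrogen_window[1])

    @property
    def n_carbon_bins(self) -> int:
        return math.ceil(self.carbon_window_width / self.carbon_bin_width)

    @property
    def n_nitrogen_bins(self) -> int:
        return math.ceil(self.nitrogen_window_width / self.nitrogen_bin_width)

    @property
    def n_distance_bins(self) -> int:
        return math.ceil(
            (self.distance_window[1] - self.distance_window[0]) / self.distance_bin_width
        )

    def axis_for(self, element: str) -> tuple[tuple[float, float], float]:
        if element == "C":
            return self.carbon_window, self.carbon_bin_width
        if element == "N":
            return self.nitrogen_window, self.nitrogen_bin_width
        raise ValidationError(f"no shift axis for element {element!r}")

    # --- bin id codec: disjoint blocks CC | CN | NN, row-major (i, j, d) ---

    def _block_dims(self, pair_class: str) -> tuple[int, int]:
        nC, nN = self.n_carbon_bins, self.n_nitrogen_bins
        return {"CC": (nC, nC), "CN": (nC, nN), "NN": (nN, nN)}[pair_class]

    def _block_offset(self, pair_class: str) -> int:
        nD = self.n_distance_bins
        sizes = {pc: d1 * d2 * nD for pc, (d1, d2) in
                 ((pc, self._block_dims(pc)) for pc in PAIR_CLASSES)}
        offsets = {"CC": 0, "CN": sizes["CC"], "NN": sizes["CC"] + sizes["CN"]}
        return offsets[pair_class]

    def encode_bin(self, pair_class: str, i: int, j: int, k: int) -> int:
        d1, d2 = self._block_dims(pair_class)
        nD = self.n_distance_bins
        if not (0 <= i < d1 and 0 <= j < d2 and 0 <= k < nD):
            raise ContractError(f"bin indices ({i},{j},{k}) out of range for {pair_class}")
        return self._block_offset(pair_class) + (i * d2 + j) * nD + k

    def decode_bin(self, bin_id: int) -> "BinDecode":
        nD = self.n_distance_bins
        for pc in PAIR_CLASSES:
            d1, d2 = self._block_dims(pc)
            off = self._block_offset(pc)
            size = d1 * d2 * nD
            if off <= bin_id < off + size:
                rel = bin_id - off
                i, rem = divmod(rel, d2 * nD)
                j, k = divmod(rem, nD)
                ax1 = self._axis_interval(pc[0], i)
                ax2 = self._axis_interval(pc[1], j)
                dlo = self.distance_window[0] + k * self.distance_bin_width
                dhi = min(dlo + self.distance_bin_width, self.distance_window[1])
                return BinDecode(bin_id, pc, (i, j, k), ax1, ax2, (dlo, dhi))
        raise ContractError(f"bin id {bin_id} outside the configured bin space")

    def _axis_interval(self, element: str, index: int) -> tuple[float, float]:
        (lo, hi), w = self.axis_for(element)
        a = lo + index * w
        return (a, min(a + w, hi))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BinningConfig":
        d = dict(d)
        for key in ("carbon_window", "nitrogen_window", "distance_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class BinDecode:
    """A bin id decoded to its pair class, shift intervals and distance range."""

    bin_id: int
    pair_class: str
    indices: tuple[int, int, int]
    axis1_interval: tuple[float, float]  # PPM
    axis2_interval: tuple[float, float]  # PPM
    distance_interval: tuple[float, float]  # Å

    def describe(self) -> str:
        a, b = self.pair_class
        return (
            f"{a}[{self.axis1_interval[0]:g}..{self.axis1_interval[1]:g} PPM] / "
            f"{b}[{self.axis2_interval[0]:g}..{self.axis2_interval[1]:g} PPM] @ "
            f"{self.distance_interval[0]:g}-{self.distance_interval[1]:g} Å"
        )


def bin_axis_index(shift: float, window: tuple[float, float], width: float):
    """Map a shift to its axis bin index, or OUT_OF_WINDOW.

    ``index = floor((shift − lo)/width)`` for lo ≤ shift < hi; the upper edge
    maps to the last bin.
    """
    if width <= 0:
        raise ValidationError("bin width must be positive")
    if not np.isfinite(shift):
        raise ValidationError(f"non-finite shift {shift!r}")
    lo, hi = window
    if shift < lo or shift > hi:
        return OUT_OF_WINDOW
    if shift == hi:
        return math.ceil((hi - lo) / width) - 1
    return int(math.floor((shift - lo) / width))


@dataclass
class SDARFingerprint:
    """Sparse bin→occupancy map for one molecule, plus the pair skip count."""

    molecule_id: str
    counts: dict[int, int] = field(default_factory=dict)
    n_pairs: int = 0
    n_skipped: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _pair_class_and_axes(
    el_i: str, shift_i: float, el_j: str, shift_j: float
) -> tuple[str, str, float, str, float]:
    """Canonical (pair class, axis1 element+shift, axis2 element+shift)."""
    if el_i == el_j:
        pc = el_i + el_j
        s1, s2 = sorted((shift_i, shift_j))
        return pc, el_i, s1, el_j, s2
    # CN pair: carbon always on axis 1
    if el_i == "C":
        return "CN", "C", shift_i, "N", shift_j
    return "CN", "C", shift_j, "N", shift_i


def compute_fingerprint(
    record: MoleculeRecord,
    shifts: ShiftAssignment,
    dm: np.ndarray,
    cfg: BinningConfig,
) -> SDARFingerprint:
    """Bin every unordered C/N atom pair of a molecule.

    A pair contributes when both shifts and the distance are inside their
    windows; otherwise it is skipped and counted in ``n_skipped``, so in count
    mode ``total + n_skipped`` equals the number of unordered C/N pairs.
    """
    cn = record.cn_indices()
    missing = [i for i in cn if i not in shifts.shifts]
    if missing:
        raise IncompleteAssignmentError(record.id, missing)
    fp = SDARFingerprint(molecule_id=record.id)
    for a in range(len(cn)):
        for b in range(a + 1, len(cn)):
            i, j = cn[a], cn[b]
            fp.n_pairs += 1
            pc, e1, s1, e2, s2 = _pair_class_and_axes(
                record.elements[i], shifts.shifts[i],
                record.elements[j], shifts.shifts[j],
            )
            w1, width1 = cfg.axis_for(e1)
            w2, width2 = cfg.axis_for(e2)
            i1 = bin_axis_index(s1, w1, width1)
            i2 = bin_axis_index(s2, w2, width2)
            k = bin_axis_index(float(dm[i, j]), cfg.distance_window, cfg.distance_bin_width)
            if OUT_OF_WINDOW in (i1, i2, k):
                fp.n_skipped += 1
                continue
            bin_id = cfg.encode_bin(pc, i1, i2, k)
            if cfg.occupancy == "binary":
                fp.counts[bin_id] = 1
            else:
                fp.counts[bin_id] = fp.counts.get(bin_id, 0) + 1
    return fp


@dataclass
class FeatureMatrix:
    """Compound × retained-bin matrix with frozen column scaling.

    The retained-bin set (bins nonzero in at least one modeling compound) and
    the per-column scaling statistics are determined from the modeling
    compounds only and frozen; external compounds are transformed with the
    frozen statistics.
    """

    ids: list[str]
    bin_ids: list[int]
    matrix: np.ndarray  # (n_compounds, n_bins) scaled
    raw: np.ndarray  # unscaled occupancies, same shape
    means: np.ndarray
    stds: np.ndarray  # std (zscore) or range (minmax); 0 marks constant columns
    mins: np.ndarray
    scaling: str
    config: BinningConfig

    @property
    def n_bins(self) -> int:
        return len(self.bin_ids)

    def row(self, mol_id: str) -> np.ndarray:
        return self.matrix[self.ids.index(mol_id)]

    def rows(self, ids: Sequence[str]) -> np.ndarray:
        index = {m: i for i, m in enumerate(self.ids)}
        return self.matrix[[index[m] for m in ids]]

    def _scale(self, raw: np.ndarray) -> np.ndarray:
        if self.scaling == "none":
            return raw.astype(float)
        safe = np.where(self.stds == 0, 1.0, self.stds)
        if self.scaling == "minmax":
            scaled = (raw - self.mins) / safe
        else:
            scaled = (raw - self.means) / safe
        scaled[:, self.stds == 0] = 0.0
        return scaled

    def transform(self, fps: Iterable[SDARFingerprint]) -> tuple[list[str], np.ndarray]:
        """Project new fingerprints onto the frozen retained-bin columns.

        Bins absent from the retained set are silently dropped (the frozen-
        columns contract); values may fall outside the training range.
        """
        fps = list(fps)
        col = {b: c for c, b in enumerate(self.bin_ids)}
        raw = np.zeros((len(fps), self.n_bins))
        for r, fp in enumerate(fps):
            for b, occ in fp.counts.items():
                if b in col:
                    raw[r, col[b]] = occ
        return [fp.molecule_id for fp in fps], self._scale(raw)


def build_feature_matrix(
    fps: Sequence[SDARFingerprint],
    modeling_ids: Iterable[str],
    cfg: BinningConfig,
) -> FeatureMatrix:
    """Assemble and scale the compound × bin matrix.

    Retains bins nonzero in ≥1 modeling compound; z-scores (or min-max maps)
    each retained column with modeling-compound statistics.  All-constant
    columns scale to zero.  External compounds present in ``fps`` are carried
    along, transformed with the frozen statistics.
    """
    if not fps:
        raise DegenerateInputError("no fingerprints supplied")
    modeling_ids = set(modeling_ids)
    fp_ids = {fp.molecule_id for fp in fps}
    if not modeling_ids <= fp_ids:
        raise ContractError(f"modeling ids missing fingerprints: {sorted(modeling_ids - fp_ids)}")
    retained: set[int] = set()
    for fp in fps:
        if fp.molecule_id in modeling_ids:
            retained.update(b for b, occ in fp.counts.items() if occ != 0)
    if not retained:
        raise DegenerateInputError("zero retained bins over the modeling compounds")
    bin_ids = sorted(retained)
    col = {b: c for c, b in enumerate(bin_ids)}
    ids = [fp.molecule_id for fp in fps]
    raw = np.zeros((len(fps), len(bin_ids)))
    for r, fp in enumerate(fps):
        for b, occ in fp.counts.items():
            if b in col:
                raw[r, col[b]] = occ
    model_rows = raw[[i for i, m in enumerate(ids) if m in modeling_ids]]
    means = model_rows.mean(axis=0)
    stds = model_rows.std(axis=0, ddof=0)
    mins = model_rows.min(axis=0)
    if cfg.scaling == "minmax":
        stds = model_rows.max(axis=0) - mins
    fm = FeatureMatrix(
        ids=ids, bin_ids=bin_ids, matrix=np.empty_like(raw), raw=raw,
        means=means, stds=stds, mins=mins, scaling=cfg.scaling, config=cfg,
    )
    fm.matrix = fm._scale(raw)
    return fm


# ---------------------------------------------------------------------------
# serialization


def write_fingerprints_csv(
    fps: Sequence[SDARFingerprint], path: str | Path, cfg: BinningConfig
) -> None:
    """Sparse triplet CSV ``id,bin_id,occupancy`` + JSON sidecar with the config."""
    rows = [
        {"id": fp.molecule_id, "bin_id": b, "occupancy": occ}
        for fp in fps
        for b, occ in sorted(fp.counts.items())
    ]
    pd.DataFrame(rows, columns=["id", "bin_id", "occupancy"]).to_csv(path, index=False)
    sidecar = Path(path).with_suffix(".config.json")
    sidecar.write_text(json.dumps(
        {"binning": cfg.to_dict(), "codec": "blocks CC|CN|NN, row-major (axis1, axis2, distance)"},
        indent=2,
    ))


def read_fingerprints_csv(path: str | Path) -> tuple[list[SDARFingerprint], BinningConfig]:
    table = pd.read_csv(path)
    cfg = BinningConfig.from_dict(
        json.loads(Path(path).with_suffix(".config.json").read_text())["binning"]
    )
    fps = []
    for mol_id, group in table.groupby("id", sort=False):
        fps.append(SDARFingerprint(
            molecule_id=str(mol_id),
            counts={int(r.bin_id): int(r.occupancy) for r in group.itertuples()},
        ))
    return fps, cfg


def write_feature_matrix_csv(fm: FeatureMatrix, path: str | Path) -> None:
    pd.DataFrame(fm.matrix, index=fm.ids, columns=fm.bin_ids).to_csv(
        path, index_label="id"
    )
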