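"""Synthetic molecule-like fixtures with a planted structure–activity rule.

The generator emulates the statistical shape of a small-molecule TdP dataset
without any chemistry: compounds are random C/N atom clouds (uniform in a
sphere with a minimum interatomic separation), shifts are drawn from
element-plausible class palettes inside the fingerprint windows, and activity
is planted as geometry — an active compound contains at least one
carbon/nitrogen pair whose shifts fall in given PPM intervals at a given
distance range (by default an aromatic-class carbon and an amine-class
nitrogen 7–8 Å apart), while inactive compounds are rejection-sampled to
contain none.  Optionally a planar hexagonal "aromatic ring" template is
planted so ring-centroid reporting can be exercised.  Labels may then be
flipped with a noise rate ε.  Everything is reproducible from one seed, and
the dataset can be emitted through the real file formats (SDF, shift CSV,
manifest CSV) so synthetic data exercises the production I/O path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .chem_io import LabelManifest, MoleculeRecord, distance_matrix, write_manifest, write_structures
from .ensemble import EnsembleModel, EvaluationReport, MLPConfig, evaluate, train_ensemble
from .errors import GenerationError, ValidationError
from .fingerprint import BinningConfig, build_feature_matrix, compute_fingerprint
from .sensitivity import (
    SensitivityReport,
    ToxicophoreFeature,
    aggregate_sensitivity,
    map_bins_to_atoms,
)
from .shifts import ShiftAssignment, write_shift_csv

RING_CIRCUMRADIUS = 1.39  # Å, benzene-like hexagon


@dataclass(frozen=True)
class ShiftClass:
    """A shift population: element, class mean and spread (PPM)."""

    name: str
    element: str
    mean: float
    sd: float


@dataclass(frozen=True)
class PlantedRule:
    """The ground-truth activity rule: a C/N shift pair at a distance range.

    All intervals are half-open ``[lo, hi)``, matching the bin convention, so
    a rule aligned with bin edges maps onto exactly one bin.
    """

    carbon_interval: tuple[float, float] = (124.0, 132.0)
    nitrogen_interval: tuple[float, float] = (-336.0, -316.0)
    distance_interval: tuple[float, float] = (7.0, 8.0)

    def matches(self, c_shift: float, n_shift: float, dist: float) -> bool:
        return (
            self.carbon_interval[0] <= c_shift < self.carbon_interval[1]
            and self.nitrogen_interval[0] <= n_shift < self.nitrogen_interval[1]
            and self.distance_interval[0] <= dist < self.distance_interval[1]
        )


DEFAULT_SHIFT_CLASSES = (
    ShiftClass("aliphatic_C", "C", 30.0, 12.0),
    ShiftClass("aromatic_C", "C", 128.0, 8.0),
    ShiftClass("amine_N", "N", -326.0, 8.0),
    ShiftClass("aromatic_N", "N", -120.0, 25.0),
)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_compounds: int = 60
    atoms_range: tuple[int, int] = (10, 16)
    nitrogen_fraction: float = 0.25  # of non-ring atoms
    aromatic_carbon_prob: float = 0.3  # non-ring carbons in the aromatic class
    amine_nitrogen_prob: float = 0.8
    shift_classes: tuple[ShiftClass, ...] = DEFAULT_SHIFT_CLASSES
    rule: PlantedRule = field(default_factory=PlantedRule)
    active_fraction: float = 0.5
    label_noise: float = 0.0
    external_fraction: float = 38 / 93  # mirrors a 55-model / 38-external split
    counts: tuple[int, int, int, int] | None = None  # (model+, model-, ext+, ext-)
    blob_radius: float = 6.0
    min_separation: float = 1.2
    plant_ring: bool = True
    seed: int = 0
    max_retries: int = 2000

    def __post_init__(self) -> None:
        if not (0.0 <= self.label_noise < 0.5):
            raise ValidationError("label noise must be in [0, 0.5)")
        if self.atoms_range[0] < 9 and self.plant_ring:
            raise ValidationError("ring template needs at least 9 atoms per compound")

    def class_named(self, name: str) -> ShiftClass:
        for c in self.shift_classes:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass
class SyntheticDataset:
    """Generated records, shifts, labels and the ground truth behind them."""

    records: list[MoleculeRecord]
    shifts: dict[str, ShiftAssignment]
    manifest: LabelManifest
    rule: PlantedRule
    rule_flags: dict[str, bool]  # ground truth: compound truly matches the rule

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Emit SDF + shift CSV + manifest CSV (the standard artifact formats)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "structures": directory / "compounds.sdf",
            "shifts": directory / "shifts.csv",
            "manifest": directory / "manifest.csv",
        }
        write_structures(self.records, paths["structures"])
        write_shift_csv([self.shifts[r.id] for r in self.records], paths["shifts"])
        write_manifest(self.manifest, paths["manifest"])
        return paths


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


def _sample_point(rng, radius, existing, min_sep, retries):
    for _ in range(retries):
        p = rng.uniform(-radius, radius, size=3)
        if p @ p > radius * radius:
            continue
        if existing.size == 0 or np.min(np.linalg.norm(existing - p, axis=1)) >= min_sep:
            return p
    raise GenerationError(
        "could not place an atom with the requested minimum separation; "
        "loosen blob_radius or min_separation"
    )


def _scan_rule_pairs(
    elements: list[str], coords: np.ndarray, shifts: dict[int, float], rule: PlantedRule
) -> list[tuple[int, int]]:
    """Brute-force enumeration of all (carbon, nitrogen) pairs matching the rule."""
    hits = []
    for i, el_i in enumerate(elements):
        if el_i != "C":
            continue
        for j, el_j in enumerate(elements):
            if el_j != "N":
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if rule.matches(shifts[i], shifts[j], d):
                hits.append((i, j))
    return hits


def _sample_shift(rng, cls: ShiftClass, window: tuple[float, float]) -> float:
    return float(np.clip(rng.normal(cls.mean, cls.sd), window[0], window[1]))


def _build_bonds(
    coords: np.ndarray, ring_atoms: list[int]
) -> tuple[list[tuple[int, int, int]], list[bool]]:
    """Ring bonds (aromatic) plus a nearest-neighbor spanning tree."""
    bonds: list[tuple[int, int, int]] = []
    flags: list[bool] = []
    ring_edges = set()
    for k in range(len(ring_atoms)):
        a, b = ring_atoms[k], ring_atoms[(k + 1) % len(ring_atoms)]
        bonds.append((a, b, 4))
        flags.append(True)
        ring_edges.add(frozenset((a, b)))
    n = coords.shape[0]
    if n > 1:
        dm = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        mst = minimum_spanning_tree(dm).tocoo()
        for a, b in zip(mst.row, mst.col):
            edge = frozenset((int(a), int(b)))
            if edge not in ring_edges:
                bonds.append((int(min(a, b)), int(max(a, b)), 1))
                flags.append(False)
    return bonds, flags


def _generate_compound(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    mol_id: str,
    active: bool,
    cfg_windows: tuple[tuple[float, float], tuple[float, float]],
) -> tuple[MoleculeRecord, ShiftAssignment]:
    c_window, n_window = cfg_windows
    n_atoms = int(rng.integers(spec.atoms_range[0], spec.atoms_range[1] + 1))
    elements: list[str] = []
    coords_list: list[np.ndarray] = []
    ring_atoms: list[int] = []

    if spec.plant_ring:
        center = _sample_point(rng, max(spec.blob_radius - 2.0, 1.0),
                               np.empty((0, 3)), 0.0, spec.max_retries)
        rot = _random_rotation(rng)
        for k in range(6):
            angle = np.pi * k / 3.0
            local = np.array([np.cos(angle), np.sin(angle), 0.0]) * RING_CIRCUMRADIUS
            coords_list.append(center + rot @ local)
            elements.append("C")
            ring_atoms.append(k)

    n_rest = n_atoms - len(elements)
    rest_elements = ["N" if rng.random() < spec.nitrogen_fraction else "C"
                     for _ in range(n_rest)]
    if "N" not in rest_elements:
        rest_elements[int(rng.integers(n_rest))] = "N"
    for el in rest_elements:
        existing = np.array(coords_list) if coords_list else np.empty((0, 3))
        coords_list.append(
            _sample_point(rng, spec.blob_radius, existing, spec.min_separation,
                          spec.max_retries)
        )
        elements.append(el)
    coords = np.array(coords_list)

    aromatic_c = spec.class_named("aromatic_C")
    aliphatic_c = spec.class_named("aliphatic_C")
    amine_n = spec.class_named("amine_N")
    aromatic_n = spec.class_named("aromatic_N")
    shifts: dict[int, float] = {}
    # symmetry-equivalent ring carbons share one shift, as in a real benzene ring
    ring_shift = _sample_shift(rng, aromatic_c, c_window) if ring_atoms else None
    for i, el in enumerate(elements):
        if el == "C":
            if i in ring_atoms:
                shifts[i] = ring_shift
            elif rng.random() < spec.aromatic_carbon_prob:
                shifts[i] = _sample_shift(rng, aromatic_c, c_window)
            else:
                shifts[i] = _sample_shift(rng, aliphatic_c, c_window)
        else:
            cls = amine_n if rng.random() < spec.amine_nitrogen_prob else aromatic_n
            shifts[i] = _sample_shift(rng, cls, n_window)

    nitrogen_indices = [i for i, el in enumerate(elements) if el == "N"]
    if active:
        # plant the rule: a ring (or any) carbon in the rule shift interval and
        # a nitrogen repositioned at a rule-interval distance from it
        if ring_atoms:
            c_idx = ring_atoms[int(rng.integers(6))]
            ring_shift = float(rng.uniform(*spec.rule.carbon_interval))
            for r_i in ring_atoms:
                shifts[r_i] = ring_shift
        else:
            c_idx = int(rng.choice([i for i, el in enumerate(elements) if el == "C"]))
            shifts[c_idx] = float(rng.uniform(*spec.rule.carbon_interval))
        n_idx = int(rng.choice(nitrogen_indices))
        shifts[n_idx] = float(rng.uniform(*spec.rule.nitrogen_interval))
        others = np.delete(coords, n_idx, axis=0)
        for _ in range(spec.max_retries):
            d = rng.uniform(*spec.rule.distance_interval)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            candidate = coords[c_idx] + d * u
            if np.min(np.linalg.norm(others - candidate, axis=1)) >= spec.min_separation:
                coords[n_idx] = candidate
                break
        else:
            raise GenerationError(f"{mol_id}: could not plant the rule pair")
    else:
        # de-plant: reposition offending nitrogens until no pair matches
        for _ in range(spec.max_retries):
            hits = _scan_rule_pairs(elements, coords, shifts, spec.rule)
            if not hits:
                break
            n_idx = hits[0][1]
            others = np.delete(coords, n_idx, axis=0)
            coords[n_idx] = _sample_point(
                rng, spec.blob_radius, others, spec.min_separation, spec.max_retries
            )
        else:
            raise GenerationError(f"{mol_id}: could not remove all rule pairs")

    bonds, flags = _build_bonds(coords, ring_atoms)
    record = MoleculeRecord(
        id=mol_id, elements=elements, coords=coords, bonds=bonds,
        aromatic_flags=flags,
    )
    assignment = ShiftAssignment(
        molecule_id=mol_id, shifts=shifts,
        elements={i: elements[i] for i in shifts},
    )
    return record, assignment


def role_counts(spec: SyntheticSpec) -> tuple[int, int, int, int]:
    """(model actives, model inactives, external actives, external inactives)."""
    if spec.counts is not None:
        return spec.counts
    n = spec.n_compounds
    n_active = int(round(spec.active_fraction * n))
    ext_active = int(round(spec.external_fraction * n_active))
    ext_inactive = int(round(spec.external_fraction * (n - n_active)))
    return (n_active - ext_active, n - n_active - ext_inactive, ext_active, ext_inactive)


def generate(spec: SyntheticSpec, seed: int | None = None) -> SyntheticDataset:
    """Generate a fully labelled synthetic dataset from the spec.

    Actives contain ≥1 planted rule pair by construction; inactives none
    (verified by a brute-force scan).  Labels are the rule flag XOR a
    Bernoulli(ε) flip; roles are assigned stratified by class.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cfg = BinningConfig()
    windows = (cfg.carbon_window, cfg.nitrogen_window)
    m_act, m_inact, e_act, e_inact = role_counts(spec)
    plan = (
        [("model", True)] * m_act + [("model", False)] * m_inact
        + [("external", True)] * e_act + [("external", False)] * e_inact
    )
    records, shifts, rows, rule_flags = [], {}, [], {}
    width = len(str(len(plan)))
    for idx, (role, active) in enumerate(plan):
        mol_id = f"syn_{idx:0{width}d}"
        record, assignment = _generate_compound(spec, rng, mol_id, active, windows)
        hits = _scan_rule_pairs(record.elements, record.coords, assignment.shifts, spec.rule)
        if active and not hits:
            raise GenerationError(f"{mol_id}: planted pair lost")
        if not active and hits:
            raise GenerationError(f"{mol_id}: inactive still matches the rule")
        flip = rng.random() < spec.label_noise
        label = int(active) ^ int(flip)
        row = {"id": mol_id, "activity": label, "role": role}
        if role == "external":
            row["report_count"] = int(rng.integers(26, 400))
        records.append(record)
        shifts[mol_id] = assignment
        rows.append(row)
        rule_flags[mol_id] = bool(active)
    table = pd.DataFrame(rows, columns=["id", "activity", "role", "report_count"])
    return SyntheticDataset(
        records=records, shifts=shifts, manifest=LabelManifest(table=table),
        rule=spec.rule, rule_flags=rule_flags,
    )


# ---------------------------------------------------------------------------
# end-to-end recovery harness


def rule_bins(rule: PlantedRule, cfg: BinningConfig, bin_ids: list[int]) -> list[int]:
    """Retained CN bins whose box intersects the planted rule box."""
    out = []
    for b in bin_ids:
        dec = cfg.decode_bin(b)
        if dec.pair_class != "CN":
            continue
        boxes = (dec.axis1_interval, dec.axis2_interval, dec.distance_interval)
        targets = (rule.carbon_interval, rule.nitrogen_interval, rule.distance_interval)
        if all(lo < t_hi and t_lo < hi for (lo, hi), (t_lo, t_hi) in zip(boxes, targets)):
            out.append(b)
    return out


@dataclass
class RecoverySummary:
    """Outcome of one generate → fingerprint → train → rank → map run."""

    seed: int
    n_model: int
    n_external: int
    n_retained_bins: int
    model_accuracy: float
    external_accuracy: float
    external_sensitivity: float | None
    external_auc: float | None
    mean_member_train_accuracy: float
    mean_member_holdout_accuracy: float
    planted_bins: list[int]
    planted_best_rank: int | None
    planted_rank_fraction: float | None
    top_feature: ToxicophoreFeature | None
    top_feature_distance: tuple[float, float] | None
    ensemble: EnsembleModel | None = None
    evaluation: EvaluationReport | None = None
    sensitivity: SensitivityReport | None = None
    features: list[ToxicophoreFeature] | None = None
    dataset: SyntheticDataset | None = None


def recovery_harness(
    spec: SyntheticSpec,
    bin_cfg: BinningConfig | None = None,
    mlp_cfg: MLPConfig | None = None,
    n_members: int = 200,
    holdout_fraction: float = 0.25,
    seed: int | None = None,
    keep_objects: bool = True,
) -> RecoverySummary:
    """Run the whole pipeline on a planted-rule dataset and measure recovery.

    Stage seeds derive from the one master seed by a counter scheme
    (``SeedSequence([seed, stage])``): stage 0 generates the data, stage 1
    trains the ensemble.  Reports held-out (external) accuracy and
    sensitivity, the aggregate-sensitivity rank of the bin(s) containing the
    planted rule, and the top back-projected toxicophore feature.
    """
    seed = spec.seed if seed is None else seed
    bin_cfg = bin_cfg or BinningConfig()
    mlp_cfg = mlp_cfg or MLPConfig()

    def stage_seed(stage: int) -> int:
        return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))

    dataset = generate(spec, seed=stage_seed(0))
    manifest = dataset.manifest
    fps = [
        compute_fingerprint(rec, dataset.shifts[rec.id], distance_matrix(rec), bin_cfg)
        for rec in dataset.records
    ]
    model_ids = manifest.model_ids
    external_ids = manifest.external_ids
    fm = build_feature_matrix(fps, model_ids, bin_cfg)
    X_model = fm.rows(model_ids)
    y_model = manifest.activities(model_ids)
    ensemble = train_ensemble(
        X_model, y_model, mlp_cfg, master_seed=stage_seed(1),
        n_members=n_members, holdout_fraction=holdout_fraction,
        feature_matrix=fm, modeling_ids=model_ids,
    )
    sets = {"training": (X_model, y_model)}
    if external_ids:
        sets["external"] = (fm.rows(external_ids), manifest.activities(external_ids))
    report = evaluate(ensemble, sets)
    sens = aggregate_sensitivity(ensemble, X_model, y_model)
    planted = rule_bins(dataset.rule, bin_cfg, fm.bin_ids)
    best_rank = sens.best_rank_overlapping(planted)
    actives = [
        (rec, dataset.shifts[rec.id], distance_matrix(rec))
        for rec in dataset.records
        if rec.id in model_ids and manifest.activity_of(rec.id) == 1
    ]
    features = map_bins_to_atoms(sens, actives, bin_cfg)
    top = next((f for f in features if f.support > 0), features[0] if features else None)
    ext = report.sets.get("external")
    return RecoverySummary(
        seed=seed,
        n_model=len(model_ids),
        n_external=len(external_ids),
        n_retained_bins=fm.n_bins,
        model_accuracy=report.sets["training"].accuracy,
        external_accuracy=ext.accuracy if ext else float("nan"),
        external_sensitivity=ext.sensitivity if ext else None,
        external_auc=ext.roc_auc if ext else None,
        mean_member_train_accuracy=report.mean_member_train_accuracy,
        mean_member_holdout_accuracy=report.mean_member_holdout_accuracy,
        planted_bins=planted,
        planted_best_rank=best_rank,
        planted_rank_fraction=(best_rank / fm.n_bins) if best_rank else None,
        top_feature=top,
        top_feature_distance=top.decode.distance_interval if top else None,
        ensemble=ensemble if keep_objects else None,
        evaluation=report if keep_objects else None,
        sensitivity=sens if keep_objects else None,
        features=features if keep_objects else None,
        dataset=dataset if keep_objects else None,
    )
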