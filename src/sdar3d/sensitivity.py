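"""Per-bin importance by mean-substitution sensitivity, and toxicophore mapping.

Sensitivity of an input variable for one network is the error-inflation
ratio ``E_b / E₀``: the member's sum-of-squares error on its own training
partition after replacing column *b* with its training-partition mean,
divided by the unperturbed error.  A ratio above 1 means the variable
carries information the network uses; a constant column (substitution is the
identity) scores exactly 1.  Ratios are averaged over the ensemble, bins are
ranked, and the most significant bins are decoded back to chemistry: a pair
class, two shift windows and a distance range, plus the atom pairs of active
compounds realizing the bin.  When a matched atom sits in an aromatic ring
the reported anchor is the ring centroid and the distance is recomputed to
that centroid — mirroring how ring features are presented to chemists
("a benzene ring and a nitrogen atom linked at 7–8 Å").
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem_io import (
    AromaticRing,
    MoleculeRecord,
    perceive_aromatic_rings,
    ring_membership,
)
from .ensemble import EnsembleModel, MLPMember, _act, _forward_raw
from .fingerprint import BinDecode, BinningConfig, SDARFingerprint, compute_fingerprint
from .shifts import ShiftAssignment

_EPS = np.finfo(float).eps


def member_sensitivity(
    member: MLPMember, X_train: np.ndarray, y_train: np.ndarray
) -> np.ndarray:
    """Per-column mean-substitution error ratios for one member.

    Substituting column *b* shifts the first hidden pre-activation by a
    rank-1 term, so the ratios are computed exactly without re-running the
    full input matmul per column.  A zero baseline error is replaced by
    machine epsilon (the member is flagged with a warning).
    """
    X = np.asarray(X_train, dtype=float)
    t = np.asarray(y_train, dtype=float).ravel()
    resid0 = _forward_raw(member, X) - t
    e0 = float(resid0 @ resid0)
    if e0 == 0.0:
        warnings.warn("member has zero training error; sensitivity uses eps baseline",
                      stacklevel=2)
        e0 = _EPS
    means = X.mean(axis=0)
    W1, b1 = member.weights[0], member.biases[0]
    Z1 = X @ W1 + b1
    ratios = np.empty(X.shape[1])
    for col in range(X.shape[1]):
        if np.ptp(X[:, col]) == 0.0:
            ratios[col] = 1.0  # substitution is the identity
            continue
        Zb = Z1 + np.outer(means[col] - X[:, col], W1[col])
        H = _act(member.hidden_activation, Zb)
        for W, b in zip(member.weights[1:-1], member.biases[1:-1]):
            H = _act(member.hidden_activation, H @ W + b)
        y = _act(member.output_activation, (H @ member.weights[-1] + member.biases[-1])).ravel()
        resid = y - t
        ratios[col] = float(resid @ resid) / e0
    return ratios


@dataclass
class SensitivityReport:
    """Aggregate bin importances across the ensemble.

    ``aggregate`` is the mean ratio over members; ``ranks`` permutes
    1..n_bins (rank 1 = most sensitive); ``significant_bins`` applies the
    selection rule (top fraction with a floor, or a ratio threshold).
    """

    bin_ids: list[int]
    per_member: np.ndarray  # (n_members, n_bins)
    aggregate: np.ndarray
    ranks: np.ndarray  # rank of each bin, aligned with bin_ids
    significant_bins: list[int]
    selection: dict = field(default_factory=dict)

    def rank_of(self, bin_id: int) -> int:
        return int(self.ranks[self.bin_ids.index(bin_id)])

    def best_rank_overlapping(self, bin_ids: list[int]) -> int | None:
        present = [b for b in bin_ids if b in self.bin_ids]
        return min((self.rank_of(b) for b in present), default=None)


def aggregate_sensitivity(
    ensemble: EnsembleModel,
    X: np.ndarray,
    y: np.ndarray,
    top_fraction: float = 0.05,
    min_significant: int = 3,
    ratio_threshold: float | None = None,
) -> SensitivityReport:
    """Mean sensitivity ratio per bin over all members, ranked.

    Each member's ratios are computed on its own training partition of the
    modeling matrix ``X``; columns constant on a member's partition
    contribute 1.0 for that member.  The significant set is the top
    ``top_fraction`` of bins (at least ``min_significant``), or every bin
    with aggregate ratio ≥ ``ratio_threshold`` when one is given.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(y, dtype=float).ravel()
    rows = []
    for m in ensemble.members:
        idx = m.train_indices if m.train_indices is not None else np.arange(X.shape[0])
        rows.append(member_sensitivity(m, X[idx], t[idx]))
    per_member = np.vstack(rows)
    aggregate = per_member.mean(axis=0)
    order = np.argsort(-aggregate, kind="stable")
    ranks = np.empty(len(aggregate), dtype=int)
    ranks[order] = np.arange(1, len(aggregate) + 1)
    bin_ids = ensemble.feature_matrix.bin_ids
    if ratio_threshold is not None:
        significant = [bin_ids[i] for i in range(len(bin_ids)) if aggregate[i] >= ratio_threshold]
        selection = {"rule": "threshold", "ratio_threshold": ratio_threshold}
    else:
        k = min(len(bin_ids), max(min_significant, int(np.ceil(top_fraction * len(bin_ids)))))
        significant = [bin_ids[i] for i in order[:k]]
        selection = {"rule": "top_fraction", "top_fraction": top_fraction,
                     "min_significant": min_significant, "k": k}
    return SensitivityReport(
        bin_ids=list(bin_ids), per_member=per_member, aggregate=aggregate,
        ranks=ranks, significant_bins=significant, selection=selection,
    )


# ---------------------------------------------------------------------------
# toxicophore back-projection


@dataclass
class MatchInstance:
    """One atom pair of an active compound realizing a significant bin.

    Anchors are atom indices, or ``("ring", ring_index)`` when the atom
    belongs to an aromatic ring and is therefore reported at the centroid.
    The raw atom-to-atom distance always lies inside the bin's distance
    interval; the anchor distance is recomputed from the anchor geometry.
    """

    compound_id: str
    atom_indices: tuple[int, int]
    anchor1: int | tuple[str, int]
    anchor2: int | tuple[str, int]
    raw_distance: float
    anchor_distance: float

    @property
    def display_distance(self) -> float:
        return round(self.anchor_distance, 1)


@dataclass
class ToxicophoreFeature:
    """A significant bin decoded to chemistry plus its matches in actives."""

    bin_id: int
    decode: BinDecode
    aggregate_sensitivity: float
    rank: int
    instances: list[MatchInstance]

    @property
    def support(self) -> int:
        return len({inst.compound_id for inst in self.instances})

    def describe(self) -> str:
        return (f"bin {self.bin_id} [{self.decode.describe()}] "
                f"sensitivity {self.aggregate_sensitivity:.3f} "
                f"rank {self.rank} support {self.support}")


def _anchor(
    atom: int, rings: list[AromaticRing], membership: list[int | None],
    coords: np.ndarray,
) -> tuple[int | tuple[str, int], np.ndarray]:
    ring_idx = membership[atom]
    if ring_idx is None:
        return atom, coords[atom]
    return ("ring", ring_idx), rings[ring_idx].centroid


def map_bins_to_atoms(
    report: SensitivityReport,
    actives: list[tuple[MoleculeRecord, ShiftAssignment, np.ndarray]],
    cfg: BinningConfig,
    rings: dict[str, list[AromaticRing]] | None = None,
) -> list[ToxicophoreFeature]:
    """Back-project significant bins onto atoms of active compounds.

    For each significant bin, every C/N atom pair of every active whose
    (shift, shift, distance) triplet encodes to that bin becomes a match.
    Matched atoms inside an aromatic ring are anchored at the ring centroid
    with the distance recomputed to the centroid.  Features are sorted by
    (aggregate sensitivity, support), both descending.  Output is invariant
    under rigid motion of any input compound.
    """
    if not actives:
        warnings.warn("no active compounds supplied; empty toxicophore result",
                      stacklevel=2)
        return []
    if rings is None:
        rings = {rec.id: perceive_aromatic_rings(rec) for rec, _, _ in actives}
    # index pairs of each active by bin id once
    pair_bins: dict[str, dict[int, list[tuple[int, int, float]]]] = {}
    for rec, shifts, dm in actives:
        fp_pairs: dict[int, list[tuple[int, int, float]]] = {}
        cn = rec.cn_indices()
        from .fingerprint import OUT_OF_WINDOW, _pair_class_and_axes, bin_axis_index

        for a in range(len(cn)):
            for b in range(a + 1, len(cn)):
                i, j = cn[a], cn[b]
                pc, e1, s1, e2, s2 = _pair_class_and_axes(
                    rec.elements[i], shifts.shifts[i],
                    rec.elements[j], shifts.shifts[j],
                )
                w1, width1 = cfg.axis_for(e1)
                w2, width2 = cfg.axis_for(e2)
                i1 = bin_axis_index(s1, w1, width1)
                i2 = bin_axis_index(s2, w2, width2)
                k = bin_axis_index(float(dm[i, j]), cfg.distance_window, cfg.distance_bin_width)
                if OUT_OF_WINDOW in (i1, i2, k):
                    continue
                fp_pairs.setdefault(cfg.encode_bin(pc, i1, i2, k), []).append(
                    (i, j, float(dm[i, j]))
                )
        pair_bins[rec.id] = fp_pairs

    agg = dict(zip(report.bin_ids, report.aggregate))
    features: list[ToxicophoreFeature] = []
    for bin_id in report.significant_bins:
        decode = cfg.decode_bin(bin_id)
        instances: list[MatchInstance] = []
        for rec, shifts, dm in actives:
            mol_rings = rings.get(rec.id, [])
            membership = ring_membership(mol_rings, rec.n_atoms)
            for i, j, dist in pair_bins[rec.id].get(bin_id, []):
                a1, p1 = _anchor(i, mol_rings, membership, rec.coords)
                a2, p2 = _anchor(j, mol_rings, membership, rec.coords)
                instances.append(MatchInstance(
                    compound_id=rec.id, atom_indices=(i, j),
                    anchor1=a1, anchor2=a2, raw_distance=dist,
                    anchor_distance=float(np.linalg.norm(p1 - p2)),
                ))
        features.append(ToxicophoreFeature(
            bin_id=bin_id, decode=decode,
            aggregate_sensitivity=float(agg.get(bin_id, float("nan"))),
            rank=report.rank_of(bin_id) if bin_id in report.bin_ids else -1,
            instances=instances,
        ))
    features.sort(key=lambda f: (-f.aggregate_sensitivity, -f.support))
    return features


# ---------------------------------------------------------------------------
# reporting


def toxicophore_report_dict(features: list[ToxicophoreFeature]) -> dict:
    return {
        "features": [
            {
                "bin_id": f.bin_id,
                "pair_class": f.decode.pair_class,
                "axis1_ppm": list(f.decode.axis1_interval),
                "axis2_ppm": list(f.decode.axis2_interval),
                "distance_A": list(f.decode.distance_interval),
                "aggregate_sensitivity": f.aggregate_sensitivity,
                "rank": f.rank,
                "support": f.support,
                "instances": [
                    {
                        "compound_id": m.compound_id,
                        "atom_indices": list(m.atom_indices),
                        "anchor1": list(m.anchor1) if isinstance(m.anchor1, tuple) else m.anchor1,
                        "anchor2": list(m.anchor2) if isinstance(m.anchor2, tuple) else m.anchor2,
                        "raw_distance_A": m.raw_distance,
                        "anchor_distance_A": m.anchor_distance,
                        "display_distance_A": m.display_distance,
                    }
                    for m in f.instances
                ],
            }
            for f in features
        ]
    }


def write_toxicophore_report(
    features: list[ToxicophoreFeature], json_path: str | Path,
    text_path: str | Path | None = None,
) -> None:
    Path(json_path).write_text(json.dumps(toxicophore_report_dict(features), indent=2))
    if text_path is not None:
        lines = ["rank  sens    support  feature"]
        for f in features:
            lines.append(
                f"{f.rank:>4}  {f.aggregate_sensitivity:<7.3f} {f.support:>7}  "
                f"{f.decode.describe()}"
            )
        Path(text_path).write_text("\n".join(lines) + "\n")


def annotation_properties(features: list[ToxicophoreFeature]) -> dict[str, dict[str, str]]:
    """Per-compound SDF properties listing matched atom indices and feature ids.

    Atom indices are written 1-based to match the MOL convention.
    """
    by_compound: dict[str, dict[int, set[int]]] = {}
    for f in features:
        for m in f.instances:
            entry = by_compound.setdefault(m.compound_id, {})
            entry.setdefault(f.bin_id, set()).update(i + 1 for i in m.atom_indices)
    props: dict[str, dict[str, str]] = {}
    for cid, feats in by_compound.items():
        props[cid] = {
            "SDAR_FEATURES": ";".join(str(b) for b in sorted(feats)),
            "SDAR_MATCHED_ATOMS": ";".join(
                f"{b}:{','.join(str(a) for a in sorted(atoms))}"
                for b, atoms in sorted(feats.items())
            ),
        }
    return props
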