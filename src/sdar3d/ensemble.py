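"""Ensemble of multilayer perceptrons over the 3D-SDAR feature matrix.

The classifier is deliberately simple and faithful to the training scheme it
models: an ensemble of (default) 200 small feed-forward networks, each trained
by full-batch gradient descent on the sum-of-squares error
``E = Σ(y_i − t_i)²`` plus an L2 weight-decay penalty, with a 25% random
holdout per member used for early stopping.  Hidden-unit counts and the
hidden/output activations (identity or tanh) are resampled per member, so the
ensemble spans a family of architectures rather than one tuned network.  The
aggregate prediction is the median of the member outputs, thresholded at 0.5
(ties predict the at-risk class: recall of torsadogenic positives is the
metric the screen must not sacrifice).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import ContractError, TrainingFailureError, ValidationError
from .fingerprint import FeatureMatrix

ACTIVATIONS = ("identity", "tanh")


def _act(name: str, z: np.ndarray) -> np.ndarray:
    return z if name == "identity" else np.tanh(z)


def _act_deriv(name: str, a: np.ndarray) -> np.ndarray:
    """Derivative expressed through the activation value ``a``."""
    return np.ones_like(a) if name == "identity" else 1.0 - a * a


@dataclass
class MLPConfig:
    """Training hyperparameters shared by all ensemble members."""

    hidden_units_range: tuple[int, int] = (3, 16)
    hidden_activations: tuple[str, ...] = ("identity", "tanh")
    output_activations: tuple[str, ...] = ("identity", "tanh")
    learning_rate: float = 0.1
    weight_decay: float = 1e-4
    max_epochs: int = 500
    patience: int = 20
    init_scale: float = 1.0
    hidden_layers: int = 1  # 1 or 2 trainable hidden layers before the output

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning rate must be positive")
        if self.hidden_units_range[0] < 1:
            raise ValidationError("hidden units must be >= 1")
        if self.weight_decay < 0:
            raise ValidationError("weight decay must be nonnegative")
        if self.hidden_layers not in (1, 2):
            raise ValidationError("hidden_layers must be 1 or 2")
        for a in (*self.hidden_activations, *self.output_activations):
            if a not in ACTIVATIONS:
                raise ValidationError(f"unknown activation {a!r}")

    def to_dict(self) -> dict:
        return {
            "hidden_units_range": list(self.hidden_units_range),
            "hidden_activations": list(self.hidden_activations),
            "output_activations": list(self.output_activations),
            "learning_rate": self.learning_rate,
            "weight_decay": self.weight_decay,
            "max_epochs": self.max_epochs,
            "patience": self.patience,
            "init_scale": self.init_scale,
            "hidden_layers": self.hidden_layers,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPConfig":
        d = dict(d)
        d["hidden_units_range"] = tuple(d["hidden_units_range"])
        d["hidden_activations"] = tuple(d["hidden_activations"])
        d["output_activations"] = tuple(d["output_activations"])
        return cls(**d)


@dataclass
class MLPMember:
    """One trained network: weights, its data partition, and training traces."""

    weights: list[np.ndarray]  # hidden layer(s) then output column vector
    biases: list[np.ndarray]
    hidden_activation: str
    output_activation: str
    train_indices: np.ndarray | None = None
    holdout_indices: np.ndarray | None = None
    train_trace: list[float] = field(default_factory=list)
    holdout_trace: list[float] = field(default_factory=list)
    final_train_error: float = float("nan")
    train_accuracy: float = float("nan")
    holdout_accuracy: float = float("nan")

    @property
    def n_hidden(self) -> int:
        return self.weights[0].shape[1]

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]


def _forward_raw(member: MLPMember, X: np.ndarray) -> np.ndarray:
    """Unclamped network output for a batch (n, d) → (n,)."""
    H = X
    for W, b in zip(member.weights[:-1], member.biases[:-1]):
        H = _act(member.hidden_activation, H @ W + b)
    z = H @ member.weights[-1] + member.biases[-1]
    return _act(member.output_activation, z).ravel()


def forward(member: MLPMember, x: np.ndarray) -> float | np.ndarray:
    """Network output clamped to [0, 1] (identity outputs may exceed it raw).

    Accepts a single feature vector or a batch of rows.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x.reshape(1, -1) if single else x
    if X.shape[1] != member.n_inputs:
        raise ContractError(
            f"feature dimension {X.shape[1]} != member input dimension {member.n_inputs}"
        )
    out = np.clip(_forward_raw(member, X), 0.0, 1.0)
    return float(out[0]) if single else out


def _sse(member: MLPMember, X: np.ndarray, t: np.ndarray) -> float:
    resid = _forward_raw(member, X) - t
    return float(resid @ resid)


def _init_member(
    n_inputs: int, n_hidden: int, hidden_act: str, output_act: str,
    cfg: MLPConfig, rng: np.random.Generator,
) -> MLPMember:
    dims = [n_inputs] + [n_hidden] * cfg.hidden_layers + [1]
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        scale = cfg.init_scale / np.sqrt(d_in)
        weights.append(rng.uniform(-scale, scale, size=(d_in, d_out)))
        biases.append(np.zeros(d_out))
    return MLPMember(weights=weights, biases=biases,
                     hidden_activation=hidden_act, output_activation=output_act)


def _gradients(
    member: MLPMember, X: np.ndarray, t: np.ndarray, weight_decay: float
) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    """Full-batch gradients of Σ(y−t)² + λΣw² (decay on weights, not biases)."""
    acts = [X]
    H = X
    for W, b in zip(member.weights[:-1], member.biases[:-1]):
        H = _act(member.hidden_activation, H @ W + b)
        acts.append(H)
    y = _act(member.output_activation, (H @ member.weights[-1] + member.biases[-1])).ravel()
    resid = y - t
    loss = float(resid @ resid) + weight_decay * sum(
        float(np.sum(W * W)) for W in member.weights
    )
    delta = (2.0 * resid * _act_deriv(member.output_activation, y)).reshape(-1, 1)
    grads_W: list[np.ndarray] = [None] * len(member.weights)
    grads_b: list[np.ndarray] = [None] * len(member.biases)
    for layer in range(len(member.weights) - 1, -1, -1):
        grads_W[layer] = acts[layer].T @ delta + 2.0 * weight_decay * member.weights[layer]
        grads_b[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = (delta @ member.weights[layer].T) * _act_deriv(
                member.hidden_activation, acts[layer]
            )
    return grads_W, grads_b, loss


def _gram_spectral_radius(X: np.ndarray, iterations: int = 30) -> float:
    """Largest eigenvalue of XᵀX by power iteration (deterministic start)."""
    d = X.shape[1]
    v = np.ones(d) / np.sqrt(d)
    lam = 0.0
    for _ in range(iterations):
        w = X.T @ (X @ v)
        norm = np.linalg.norm(w)
        if norm == 0.0:
            return 0.0
        v = w / norm
        lam = norm
    return float(lam)


def train_member(
    X: np.ndarray,
    y: np.ndarray,
    cfg: MLPConfig,
    seed: int | np.random.Generator,
    holdout: tuple[np.ndarray, np.ndarray] | None = None,
    n_hidden: int | None = None,
    hidden_activation: str | None = None,
    output_activation: str | None = None,
) -> MLPMember:
    """Train one network by full-batch gradient descent with early stopping.

    The learning rate is applied to the per-compound gradient (step
    ``η/n · ∇``), and additionally capped at 90% of the quadratic stability
    bound ``1/(2 (λ_max(XᵀX) + λ_decay))`` estimated by power iteration —
    without the cap the fixed rate diverges whenever the feature matrix is
    wide or the decay is strong.  When a
    holdout set is given, training stops once the holdout SSE fails to
    improve for ``patience`` consecutive epochs and the best-holdout weights
    are restored.  A non-finite loss still triggers one restart at a tenth
    of the rate before raising :class:`TrainingFailureError`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    t = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != t.shape[0]:
        raise ContractError("X and y row counts differ")
    if n_hidden is None:
        lo, hi = cfg.hidden_units_range
        n_hidden = int(rng.integers(lo, hi + 1))
    hidden_act = hidden_activation or cfg.hidden_activations[0]
    output_act = output_activation or cfg.output_activations[0]
    init = _init_member(X.shape[1], n_hidden, hidden_act, output_act, cfg, rng)
    # curvature bound: data Gram spectrum plus the decay term's 2λ
    curvature = 2.0 * (_gram_spectral_radius(X) + cfg.weight_decay)
    base_step = cfg.learning_rate / X.shape[0]
    if curvature > 0.0:
        base_step = min(base_step, 0.9 / curvature)

    for attempt, eta in enumerate((base_step, base_step / 10.0)):
        member = MLPMember(
            weights=[W.copy() for W in init.weights],
            biases=[b.copy() for b in init.biases],
            hidden_activation=hidden_act, output_activation=output_act,
        )
        diverged = False
        best_err = np.inf
        best_weights = None
        stale = 0
        for _ in range(cfg.max_epochs):
            gW, gb, loss = _gradients(member, X, t, cfg.weight_decay)
            if not np.isfinite(loss):
                diverged = True
                break
            member.train_trace.append(loss)
            for layer in range(len(member.weights)):
                member.weights[layer] -= eta * gW[layer]
                member.biases[layer] -= eta * gb[layer]
            if holdout is not None:
                herr = _sse(member, holdout[0], holdout[1])
                member.holdout_trace.append(herr)
                if herr < best_err - 1e-12:
                    best_err = herr
                    best_weights = ([W.copy() for W in member.weights],
                                    [b.copy() for b in member.biases])
                    stale = 0
                else:
                    stale += 1
                    if stale >= cfg.patience:
                        break
        if diverged or not np.isfinite(_sse(member, X, t)):
            if attempt == 0:
                continue
            raise TrainingFailureError("training diverged even after learning-rate restart")
        break

    if holdout is not None and best_weights is not None:
        member.weights, member.biases = best_weights
    member.final_train_error = _sse(member, X, t)
    member.train_accuracy = float(np.mean((forward(member, X) >= 0.5) == (t >= 0.5)))
    if holdout is not None and len(holdout[1]):
        member.holdout_accuracy = float(
            np.mean((forward(member, holdout[0]) >= 0.5) == (holdout[1] >= 0.5))
        )
    return member


@dataclass
class EnsembleModel:
    """Trained member networks plus the frozen featurization they consume."""

    members: list[MLPMember]
    feature_matrix: FeatureMatrix  # training-time matrix: frozen bins + scaling
    modeling_ids: list[str]
    master_seed: int
    threshold: float = 0.5

    @property
    def n_members(self) -> int:
        return len(self.members)

    def member_outputs(self, X: np.ndarray) -> np.ndarray:
        """(n_members, n_samples) clamped member outputs."""
        return np.vstack([forward(m, X) for m in self.members])

    def config_hash(self) -> str:
        import hashlib

        payload = json.dumps(
            {"bins": self.feature_matrix.bin_ids,
             "binning": self.feature_matrix.config.to_dict(),
             "seed": self.master_seed},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def train_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    cfg: MLPConfig,
    master_seed: int,
    n_members: int = 200,
    holdout_fraction: float = 0.25,
    feature_matrix: FeatureMatrix | None = None,
    modeling_ids: list[str] | None = None,
) -> EnsembleModel:
    """Train the subsampled ensemble.

    Each member draws an independent uniform-random holdout of
    ``round(holdout_fraction · n)`` modeling compounds (redrawn until the
    training partition keeps ≥2 compounds of each class), samples its
    hidden-unit count and activation pair, and trains with early stopping on
    its own holdout.  Everything is reproducibly seeded from ``master_seed``.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    classes = np.unique(t)
    if len(classes) < 2:
        raise ValidationError("modeling set must contain both classes")
    n_hold = int(round(holdout_fraction * n))
    seeds = np.random.SeedSequence(master_seed).spawn(n_members)
    members: list[MLPMember] = []
    for idx, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        for _ in range(200):
            hold = rng.choice(n, size=n_hold, replace=False)
            mask = np.ones(n, dtype=bool)
            mask[hold] = False
            if all(np.sum(t[mask] == c) >= 2 for c in (0.0, 1.0)):
                break
        else:
            raise TrainingFailureError(f"member {idx}: could not draw a valid holdout")
        train_idx = np.flatnonzero(mask)
        lo, hi = cfg.hidden_units_range
        n_hidden = int(rng.integers(lo, hi + 1))
        hidden_act = str(rng.choice(cfg.hidden_activations))
        output_act = str(rng.choice(cfg.output_activations))
        try:
            member = train_member(
                X[train_idx], t[train_idx], cfg, rng,
                holdout=(X[hold], t[hold]),
                n_hidden=n_hidden,
                hidden_activation=hidden_act,
                output_activation=output_act,
            )
        except TrainingFailureError as exc:
            raise TrainingFailureError(f"member {idx}: {exc}") from exc
        member.train_indices = train_idx
        member.holdout_indices = np.sort(hold)
        members.append(member)
    if feature_matrix is None:
        raise ContractError("train_ensemble requires the FeatureMatrix for freezing")
    return EnsembleModel(
        members=members,
        feature_matrix=feature_matrix,
        modeling_ids=list(modeling_ids) if modeling_ids else list(feature_matrix.ids[:n]),
        master_seed=int(master_seed),
    )


def predict(ensemble: EnsembleModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median member score per compound and the thresholded class.

    The score is the median of the 200 clamped member outputs; class 1 is
    predicted when the score reaches the threshold (ties go to the at-risk
    class).
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new.reshape(1, -1)
    outputs = ensemble.member_outputs(X_new)
    scores = np.median(outputs, axis=0)
    classes = (scores >= ensemble.threshold).astype(int)
    return scores, classes


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class SetMetrics:
    """Ensemble-median metrics for one evaluation set."""

    name: str
    n: int
    confusion: np.ndarray  # rows: true 0/1, cols: predicted 0/1
    accuracy: float
    sensitivity: float | None  # fraction of actives correct
    specificity: float | None
    roc_fpr: np.ndarray | None
    roc_tpr: np.ndarray | None
    roc_auc: float | None
    gain: dict[int, tuple[np.ndarray, np.ndarray]]  # class → (fraction examined, captured)
    scores: np.ndarray
    labels: np.ndarray


@dataclass
class EvaluationReport:
    """Per-member averages plus ensemble-median metrics per evaluation set."""

    mean_member_train_accuracy: float
    mean_member_holdout_accuracy: float
    sets: dict[str, SetMetrics]


def gain_curve(scores: np.ndarray, labels: np.ndarray, target: int) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative fraction of ``target``-class compounds captured vs fraction examined.

    Compounds are examined in order of decreasing evidence for the target
    class (descending score for class 1, ascending for class 0).
    """
    order = np.argsort(-scores if target == 1 else scores, kind="stable")
    hits = (labels[order] == target).astype(float)
    total = hits.sum()
    captured = np.cumsum(hits) / total if total else np.zeros_like(hits)
    examined = np.arange(1, len(scores) + 1) / len(scores)
    return examined, captured


def _set_metrics(name: str, scores: np.ndarray, labels: np.ndarray, threshold: float) -> SetMetrics:
    pred = (scores >= threshold).astype(int)
    cm = _sk_confusion(labels, pred, labels=[0, 1])
    accuracy = float(np.trace(cm) / cm.sum())
    n_active = int(cm[1].sum())
    n_inactive = int(cm[0].sum())
    sensitivity = float(cm[1, 1] / n_active) if n_active else None
    specificity = float(cm[0, 0] / n_inactive) if n_inactive else None
    if len(np.unique(labels)) == 2:
        fpr, tpr, _ = roc_curve(labels, scores)
        auc = float(roc_auc_score(labels, scores))
    else:  # ROC undefined for a single-class set
        fpr = tpr = auc = None
    gains = {c: gain_curve(scores, labels, c) for c in (0, 1)}
    return SetMetrics(
        name=name, n=len(labels), confusion=cm, accuracy=accuracy,
        sensitivity=sensitivity, specificity=specificity,
        roc_fpr=fpr, roc_tpr=tpr, roc_auc=auc, gain=gains,
        scores=scores, labels=labels,
    )


def evaluate(
    ensemble: EnsembleModel, sets: dict[str, tuple[np.ndarray, np.ndarray]]
) -> EvaluationReport:
    """Evaluate the ensemble on named sets (e.g. training / internal / external).

    Reports both the mean over members of each member's accuracy on its own
    training and holdout partitions (the headline subsampling metric) and the
    ensemble-median metrics per set: confusion matrix, accuracy, sensitivity
    on actives, ROC curve/area, and gain curves for both classes.
    """
    report_sets: dict[str, SetMetrics] = {}
    for name, (X, y) in sets.items():
        labels = np.asarray(y, dtype=int).ravel()
        scores, _ = predict(ensemble, X)
        report_sets[name] = _set_metrics(name, scores, labels, ensemble.threshold)
    return EvaluationReport(
        mean_member_train_accuracy=float(
            np.nanmean([m.train_accuracy for m in ensemble.members])
        ),
        mean_member_holdout_accuracy=float(
            np.nanmean([m.holdout_accuracy for m in ensemble.members])
        ),
        sets=report_sets,
    )


# ---------------------------------------------------------------------------
# persistence (JSON metadata + npz weight container)


def save_model(ensemble: EnsembleModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fm = ensemble.feature_matrix
    meta = {
        "config_hash": ensemble.config_hash(),
        "master_seed": ensemble.master_seed,
        "threshold": ensemble.threshold,
        "binning": fm.config.to_dict(),
        "bin_ids": fm.bin_ids,
        "scaling": fm.scaling,
        "means": fm.means.tolist(),
        "stds": fm.stds.tolist(),
        "mins": fm.mins.tolist(),
        "modeling_ids": ensemble.modeling_ids,
        "members": [
            {
                "hidden_activation": m.hidden_activation,
                "output_activation": m.output_activation,
                "n_layers": len(m.weights),
                "train_indices": m.train_indices.tolist() if m.train_indices is not None else None,
                "holdout_indices": m.holdout_indices.tolist() if m.holdout_indices is not None else None,
                "train_accuracy": m.train_accuracy,
                "holdout_accuracy": m.holdout_accuracy,
            }
            for m in ensemble.members
        ],
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))
    arrays = {}
    for i, m in enumerate(ensemble.members):
        for layer, (W, b) in enumerate(zip(m.weights, m.biases)):
            arrays[f"m{i}_W{layer}"] = W
            arrays[f"m{i}_b{layer}"] = b
    np.savez_compressed(directory / "weights.npz", **arrays)


def load_model(directory: str | Path) -> EnsembleModel:
    from .fingerprint import BinningConfig

    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    arrays = np.load(directory / "weights.npz")
    members = []
    for i, mm in enumerate(meta["members"]):
        n_layers = mm["n_layers"]
        members.append(MLPMember(
            weights=[arrays[f"m{i}_W{l}"] for l in range(n_layers)],
            biases=[arrays[f"m{i}_b{l}"] for l in range(n_layers)],
            hidden_activation=mm["hidden_activation"],
            output_activation=mm["output_activation"],
            train_indices=np.array(mm["train_indices"]) if mm["train_indices"] is not None else None,
            holdout_indices=np.array(mm["holdout_indices"]) if mm["holdout_indices"] is not None else None,
            train_accuracy=mm["train_accuracy"],
            holdout_accuracy=mm["holdout_accuracy"],
        ))
    cfg = BinningConfig.from_dict(meta["binning"])
    n_bins = len(meta["bin_ids"])
    fm = FeatureMatrix(
        ids=list(meta["modeling_ids"]),
        bin_ids=[int(b) for b in meta["bin_ids"]],
        matrix=np.zeros((0, n_bins)),
        raw=np.zeros((0, n_bins)),
        means=np.array(meta["means"]),
        stds=np.array(meta["stds"]),
        mins=np.array(meta["mins"]),
        scaling=meta["scaling"],
        config=cfg,
    )
    return EnsembleModel(
        members=members,
        feature_matrix=fm,
        modeling_ids=list(meta["modeling_ids"]),
        master_seed=int(meta["master_seed"]),
        threshold=float(meta["threshold"]),
    )
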