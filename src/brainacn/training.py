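"""Training loop, fine-tuning, prediction/BAG, feature extraction and probes."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .autodiff import Adam
from .io import PredictionRecord, SubjectRecord, Volume
from .model import (
    ACNConfig,
    ACNModel,
    age_loss_graph,
    confound_loss_graph,
    lambda_schedule,
)

logger = logging.getLogger("brainacn")

VolumesLike = Union[np.ndarray, Sequence[Volume]]


@dataclass
class TrainHistory:
    """Per-epoch losses and validation MAE, plus the run's seed and config."""

    age_loss: List[float] = field(default_factory=list)
    confound_loss: List[float] = field(default_factory=list)
    val_mae: List[float] = field(default_factory=list)
    best_epoch: int = -1
    seed: int = 0
    config: Dict = field(default_factory=dict)


def _stack(volumes: VolumesLike) -> np.ndarray:
    if isinstance(volumes, np.ndarray):
        return volumes.astype(np.float64, copy=False)
    return np.stack([v.voxels for v in volumes]).astype(np.float64, copy=False)


def _factor_labels(
    subjects: Sequence[SubjectRecord], factors: Sequence[Tuple[str, int]]
) -> Tuple[Dict[str, np.ndarray], Dict[str, List[str]]]:
    """Map each confound factor to integer class labels over the cohort."""
    labels: Dict[str, np.ndarray] = {}
    classes: Dict[str, List[str]] = {}
    for name, n_classes in factors:
        values = [getattr(s, name) for s in subjects]
        cls = sorted(set(values))
        if len(cls) > n_classes:
            raise ValueError(f"factor {name!r} has {len(cls)} observed classes but head expects {n_classes}")
        classes[name] = cls
        lut = {c: i for i, c in enumerate(cls)}
        labels[name] = np.array([lut[v] for v in values], dtype=int)
    return labels, classes


class _HeadRefitter:
    """Keeps the mixed modules at the optimal linear discriminator.

    Before each encoder update the confound heads are refit in closed form
    (ridge regression on +/-1 class indicators over a sliding buffer of recent
    embeddings, after standardisation).  The inner maximisation of the
    adversarial game is thereby solved exactly for the linear head family, so
    the encoder always faces a near-optimal adversary — a stochastic head
    lagging behind the moving embedding leaves confound directions it never
    finds, and therefore never removes.
    """

    def __init__(self, model: ACNModel, labels: Mapping[str, np.ndarray],
                 max_batches: int = 20, alpha: float = 1e-3) -> None:
        self.model = model
        self.labels = labels
        self.alpha = alpha
        self.max_batches = max_batches
        self._feats: List[np.ndarray] = []
        self._idx: List[np.ndarray] = []

    def push(self, feats: np.ndarray, idx: np.ndarray) -> None:
        self._feats.append(feats.copy())
        self._idx.append(idx)
        if len(self._feats) > self.max_batches:
            self._feats.pop(0)
            self._idx.pop(0)

    def refit(self) -> None:
        if not self._feats:
            return
        f = np.concatenate(self._feats)
        i = np.concatenate(self._idx)
        for name, n_classes in self.model.config.confound_factors:
            mu, sd = f.mean(axis=0), f.std(axis=0) + 1e-6
            self.model.bn_stats[f"head_{name}.mean"] = mu
            self.model.bn_stats[f"head_{name}.var"] = sd ** 2
            self.model.params[f"head_{name}.gamma"].data = np.ones(f.shape[1])
            self.model.params[f"head_{name}.beta"].data = np.zeros(f.shape[1])
            fs = (f - mu) / sd
            y = self.labels[name][i]
            targets = -np.ones((len(y), n_classes))
            targets[np.arange(len(y)), y] = 1.0
            gram = fs.T @ fs + self.alpha * len(y) * np.eye(fs.shape[1])
            self.model.params[f"head_{name}.w"].data = np.linalg.solve(gram, fs.T @ targets)
            self.model.params[f"head_{name}.b"].data = targets.mean(axis=0)


def _epoch_pass(
    model: ACNModel,
    opt: Adam,
    refitter: Optional[_HeadRefitter],
    x: np.ndarray,
    ages: np.ndarray,
    labels: Mapping[str, np.ndarray],
    order: np.ndarray,
    lam: float,
    batch_size: int,
    weight_decay: float = 0.0,
) -> Tuple[float, float]:
    """One optimisation epoch; returns per-subject mean age/confound losses."""
    a_tot, c_tot, n_batches = 0.0, 0.0, 0
    for start in range(0, len(order), batch_size):
        idx = order[start:start + batch_size]
        if refitter is not None and opt.lr > 0:
            refitter.refit()
        out = model.forward_graph(x[idx], lam=lam, train=True)
        la = age_loss_graph(ages[idx], out["age_probs"], model.config.sigma)
        lc = confound_loss_graph({k: v[idx] for k, v in labels.items()}, out)
        # optimise the per-subject mean of the age term so the two objectives
        # enter the encoder gradient on the same (batch-mean) scale
        loss = la * (1.0 / len(idx)) + lc
        opt.zero_grad()
        loss.backward()
        for p in opt.params:  # decoupled weight decay, scaled with the lr
            p.data *= 1.0 - opt.lr * weight_decay
        opt.step()
        if refitter is not None:
            refitter.push(out["features"].data, idx)
        a_tot += la.item() / len(idx)
        c_tot += lc.item()
        n_batches += 1
    return a_tot / n_batches, c_tot / n_batches


def train(
    model: ACNModel,
    volumes: VolumesLike,
    subjects: Sequence[SubjectRecord],
    config: Optional[ACNConfig] = None,
    split: Tuple[float, float] = (0.8, 0.2),
    seed: int = 0,
) -> Tuple[ACNModel, TrainHistory]:
    """Adversarial training with per-epoch validation and best-MAE selection.

    The gradient-reversal strength follows the DANN ramp over epochs; the
    checkpoint with the lowest validation MAE is returned.  Reproducible given
    the seed (all computation is single-threaded numpy).
    """
    config = config or model.config
    x = _stack(volumes)
    ages = np.array([s.age for s in subjects], dtype=np.float64)
    labels, classes = _factor_labels(subjects, config.confound_factors)

    rng = np.random.default_rng(seed)
    n = len(subjects)
    perm = rng.permutation(n)
    n_train = int(round(split[0] / sum(split) * n))
    train_idx, val_idx = perm[:n_train], perm[n_train:]
    if len(val_idx) == 0:
        raise ValueError("validation split is empty")

    for name, lab in labels.items():
        counts = np.bincount(lab[train_idx], minlength=len(classes[name]))
        missing = [classes[name][i] for i, c in enumerate(counts) if c < 2]
        if missing:
            raise ValueError(f"confound factor {name!r}: classes {missing} have < 2 training subjects")

    # encoder + age head learn by gradient; the confound heads are refit in
    # closed form each step (see _HeadRefitter), so they sit outside Adam
    grad_params = [p for p in model.parameters() if not p.name.startswith("head_")]
    opt = Adam(grad_params, lr=config.learning_rate)
    refitter = _HeadRefitter(model, labels) if config.confound_factors else None
    history = TrainHistory(seed=seed, config=asdict(config))
    best_mae, best_state = np.inf, None

    for epoch in range(config.epochs):
        progress = epoch / (config.epochs - 1) if config.epochs > 1 else 1.0
        lam = lambda_schedule(progress, config.lambda_max)
        # cosine learning-rate decay (floor 5%) so late epochs settle into the
        # adversarial equilibrium instead of oscillating around it
        opt.lr = config.learning_rate * (0.05 + 0.95 * 0.5 * (1.0 + np.cos(np.pi * progress)))
        order = rng.permutation(train_idx)
        a_mean, c_mean = _epoch_pass(model, opt, refitter, x, ages, labels, order, lam, config.batch_size,
                                     weight_decay=config.weight_decay)
        val_pred = model.forward(x[val_idx]).age_point
        val_mae = float(np.mean(np.abs(val_pred - ages[val_idx])))
        history.age_loss.append(a_mean)
        history.confound_loss.append(c_mean)
        history.val_mae.append(val_mae)
        if val_mae < best_mae:
            best_mae, best_state = val_mae, model.state_arrays()
            history.best_epoch = epoch
        logger.info("epoch %d: age_loss=%.4f confound_loss=%.4f val_mae=%.3f lam=%.3f",
                    epoch, a_mean, c_mean, val_mae, lam)

    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, history


def fine_tune(
    model: ACNModel,
    volumes: VolumesLike,
    subjects: Sequence[SubjectRecord],
    epochs: int = 100,
    learning_rate: Optional[float] = None,
    freeze_encoder: bool = False,
    split: Tuple[float, float] = (0.8, 0.2),
    seed: int = 0,
) -> ACNModel:
    """Transfer-learn onto a new cohort.

    Continues optimisation of all weights (or heads only with
    ``freeze_encoder``) at a reduced learning rate, 0.1x the original by
    default, keeping the best-validation-MAE checkpoint.  ``epochs=0`` is a
    no-op.
    """
    x = _stack(volumes)
    if x.shape[1:] != model.grid_shape:
        raise ValueError(f"volume grid {x.shape[1:]} does not match model grid {model.grid_shape}")
    if epochs == 0:
        return model
    lr = learning_rate if learning_rate is not None else 0.1 * model.config.learning_rate
    ft_config = ACNConfig(**{**asdict(model.config), "epochs": epochs, "learning_rate": lr})
    if freeze_encoder:
        # heads-only adaptation: the age head learns by gradient, the confound
        # heads by closed-form refit; encoder weights stay fixed
        ages = np.array([s.age for s in subjects], dtype=np.float64)
        labels, _ = _factor_labels(subjects, model.config.confound_factors)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(subjects))
        n_train = int(round(split[0] / sum(split) * len(subjects)))
        train_idx, val_idx = perm[:n_train], perm[n_train:]
        age_params = [p for p in model.parameters() if p.name.startswith("age.")]
        opt = Adam(age_params, lr=lr)
        refitter = _HeadRefitter(model, labels) if model.config.confound_factors else None
        best_mae, best_state = np.inf, None
        for epoch in range(epochs):
            lam = lambda_schedule(epoch / (epochs - 1) if epochs > 1 else 1.0, model.config.lambda_max)
            order = rng.permutation(train_idx)
            _epoch_pass(model, opt, refitter, x, ages, labels, order, lam, model.config.batch_size,
                        weight_decay=model.config.weight_decay)
            val_pred = model.forward(x[val_idx]).age_point
            val_mae = float(np.mean(np.abs(val_pred - ages[val_idx])))
            if val_mae < best_mae:
                best_mae, best_state = val_mae, model.state_arrays()
        if best_state is not None:
            model.load_state_arrays(best_state)
        return model
    model, _ = train(model, x, subjects, config=ft_config, split=split, seed=seed)
    return model


def predict(
    model: ACNModel,
    volumes: VolumesLike,
    subjects: Optional[Sequence[SubjectRecord]] = None,
) -> List[PredictionRecord]:
    """Predict brain age and BAG (predicted - chronological) per subject."""
    x = _stack(volumes)
    out = model.forward(x)
    records: List[PredictionRecord] = []
    for i, pred in enumerate(out.age_point):
        if subjects is not None and i < len(subjects):
            sid = subjects[i].subject_id
            chron = subjects[i].age
            if chron is None or not np.isfinite(chron):
                warnings.warn(f"subject {sid}: missing chronological age; BAG not computed", stacklevel=2)
                chron = None
        else:
            sid = _volume_id(volumes, i)
            chron = None
            warnings.warn(f"subject {sid}: missing chronological age; BAG not computed", stacklevel=2)
        records.append(PredictionRecord(subject_id=sid, chronological_age=chron, predicted_age=float(pred)))
    return records


def _volume_id(volumes: VolumesLike, i: int) -> str:
    if not isinstance(volumes, np.ndarray) and getattr(volumes[i], "subject_id", ""):
        return volumes[i].subject_id
    return f"sub-{i:04d}"


def extract_features(model: ACNModel, volumes: VolumesLike) -> np.ndarray:
    """Stratified features (encoder embeddings), (n_subjects, embedding_dim)."""
    return model.forward(_stack(volumes)).features


def evaluate(records: Sequence[PredictionRecord]) -> Dict[str, float]:
    """MAE, R^2 and Pearson correlation of predicted vs chronological age."""
    pairs = [(r.chronological_age, r.predicted_age) for r in records if r.chronological_age is not None]
    if len(pairs) < 2:
        raise ValueError("need >= 2 records with chronological age")
    chron = np.array([c for c, _ in pairs])
    pred = np.array([p for _, p in pairs])
    mae = float(np.mean(np.abs(pred - chron)))
    ss_res = float(np.sum((pred - chron) ** 2))
    ss_tot = float(np.sum((chron - chron.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    if np.std(chron) == 0 or np.std(pred) == 0:
        warnings.warn("zero variance in ages; PCC undefined", stacklevel=2)
        pcc = float("nan")
    else:
        pcc = float(np.corrcoef(chron, pred)[0, 1])
    return {"mae": mae, "r2": r2, "pcc": pcc}


def probe(
    features: np.ndarray,
    labels: Sequence,
    folds: int = 5,
    seed: int = 0,
) -> Tuple[float, float]:
    """Cross-validated linear-SVM accuracy on an embedding.

    Used both as the confound-leakage probe (labels = site or gender) and the
    diagnosis probe (labels = case/control).  Returns (mean, sd) over
    stratified folds.
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(f"every class needs >= {folds} members; smallest has {counts.min()}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(features, labels):
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
        clf.fit(features[tr], labels[tr])
        accs.append(float(np.mean(clf.predict(features[te]) == labels[te])))
    return float(np.mean(accs)), float(np.std(accs))
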