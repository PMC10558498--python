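"""Model-agnostic trainer for the fairness-aware protocol.

Three loss modes share one loop:

``bce``
    standard binary cross-entropy — the baseline.
``proposed``
    per batch, pairwise fairness per subgroup, worst group selected, and
    the marginal ranking loss minimised on that group's positives versus
    all batch negatives (see :mod:`fairdx.fairloss`).  Ineligible batches
    are skipped, never backfilled with cross-entropy.
``oversample``
    binary cross-entropy on a training multiset where the minority class
    is resampled with replacement to equal class counts.

Scorers are small numpy networks with hand-written gradients (a linear
scorer for feature vectors, a one-hidden-layer MLP for toy images); any
object implementing the same ``init_params/logits/backward`` surface can
be plugged in.  Predictions used for ranking are positive-class
probabilities (sigmoid of the logit), so the ranking margin lives on
[0, 1].  Optimisation is Adam.  A development set is carved from the
training data at patient level and the parameters from the epoch with the
highest dev AUC are returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fairloss import (
    NegativeBuffer,
    RankingLossInputs,
    marginal_ranking_loss_grad,
    select_worst_group,
)
from .metrics import ScoredSet, overall_auc
from .subgroups import GroupAssignment, SampleRecord

__all__ = [
    "TrainConfig",
    "TrainedScorer",
    "LinearScorer",
    "MLPScorer",
    "Adam",
    "train",
    "predict",
    "oversample_minority",
]

LOSS_MODES = ("proposed", "bce", "oversample")


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults follow the protocol this trainer implements: Adam with
    learning rate 1e-4, batch size 96, 20 epochs; ranking margin 0.1 on
    the probability scale.  ``dev_fraction`` of training *patients* is
    held out for model selection.
    """

    loss_mode: str = "bce"
    margin: float = 0.1
    learning_rate: float = 1e-4
    batch_size: int = 96
    epochs: int = 20
    dev_fraction: float = 0.1
    seed: int = 0
    negative_buffer: int = 0
    augment: bool = False
    scorer: str = "linear"  # "linear" | "mlp"
    hidden_units: int = 16

    def __post_init__(self):
        if self.loss_mode not in LOSS_MODES:
            raise ValueError(f"loss_mode must be one of {LOSS_MODES}")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if not 0 < self.dev_fraction < 1:
            raise ValueError("dev_fraction must be in (0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class LinearScorer:
    """Affine scorer on flattened payloads: logit = x·w + b."""

    def __init__(self, n_features: int, rng: np.random.Generator):
        self.params = {
            "w": rng.normal(0.0, 0.01, size=n_features),
            "b": np.zeros(1),
        }

    def logits(self, X: np.ndarray):
        z = X @ self.params["w"] + self.params["b"][0]
        return z, X

    def backward(self, cache, g_z: np.ndarray) -> dict:
        X = cache
        return {"w": X.T @ g_z, "b": np.array([g_z.sum()])}


class MLPScorer:
    """One-hidden-layer tanh network for toy images / nonlinear features."""

    def __init__(self, n_features: int, rng: np.random.Generator, hidden: int = 16):
        scale = 1.0 / np.sqrt(n_features)
        self.params = {
            "W1": rng.normal(0.0, scale, size=(n_features, hidden)),
            "b1": np.zeros(hidden),
            "w2": rng.normal(0.0, 1.0 / np.sqrt(hidden), size=hidden),
            "b2": np.zeros(1),
        }

    def logits(self, X: np.ndarray):
        h = np.tanh(X @ self.params["W1"] + self.params["b1"])
        z = h @ self.params["w2"] + self.params["b2"][0]
        return z, (X, h)

    def backward(self, cache, g_z: np.ndarray) -> dict:
        X, h = cache
        g_h = np.outer(g_z, self.params["w2"]) * (1.0 - h**2)
        return {
            "W1": X.T @ g_h,
            "b1": g_h.sum(axis=0),
            "w2": h.T @ g_z,
            "b2": np.array([g_z.sum()]),
        }


class Adam:
    """Adam optimiser over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class TrainedScorer:
    """A scorer plus its training history and the best-epoch bookkeeping."""

    scorer: object
    history: pd.DataFrame
    best_epoch: int
    config: TrainConfig
    selection_log: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# payload handling

def payload_vector(payload) -> np.ndarray:
    """Flatten a record payload into a float feature vector.

    Feature vectors pass through; image arrays are flattened, 8-bit ones
    scaled to [0, 1]; a string payload is read as an image file.
    """
    if isinstance(payload, str):
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(payload), dtype=float)
        return (arr / 255.0).ravel()
    arr = np.asarray(payload, dtype=float)
    if payload is None or arr.size == 0:
        raise ValueError("record has no payload")
    if np.asarray(payload).dtype == np.uint8:
        arr = arr / 255.0
    return arr.ravel()


def design_matrix(records: Sequence[SampleRecord]) -> np.ndarray:
    vecs = []
    bad = []
    for rec in records:
        try:
            vecs.append(payload_vector(rec.payload))
        except (ValueError, OSError) as exc:
            bad.append(f"{rec.sample_id}: {exc}")
    if bad:
        raise ValueError("malformed payload(s): " + "; ".join(bad[:5]))
    X = np.stack(vecs)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X


def _make_scorer(config: TrainConfig, n_features: int, rng: np.random.Generator):
    if config.scorer == "linear":
        return LinearScorer(n_features, rng)
    if config.scorer == "mlp":
        return MLPScorer(n_features, rng, hidden=config.hidden_units)
    raise ValueError(f"unknown scorer {config.scorer!r}")


# ---------------------------------------------------------------------------
# operations

def oversample_minority(
    records: Sequence[SampleRecord], seed: int
) -> np.ndarray:
    """Index multiset with the minority class resampled to equal counts.

    All original indices are kept; additional minority indices are drawn
    with replacement until both classes have the majority count.
    """
    labels = np.array([r.label for r in records])
    if labels.min() == labels.max():
        raise ValueError("oversampling needs both classes present")
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if n_pos == n_neg:
        return np.arange(len(records))
    minority = 1 if n_pos < n_neg else 0
    min_idx = np.flatnonzero(labels == minority)
    rng = np.random.default_rng(seed)
    extra = rng.choice(min_idx, size=abs(n_neg - n_pos), replace=True)
    return np.concatenate([np.arange(len(records)), extra])


def _dev_split(
    patient_ids: np.ndarray, dev_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Patient-level train/dev index split."""
    patients = np.unique(patient_ids)
    rng.shuffle(patients)
    n_dev = max(1, int(round(dev_fraction * len(patients))))
    dev_patients = set(patients[:n_dev].tolist())
    is_dev = np.array([p in dev_patients for p in patient_ids])
    return np.flatnonzero(~is_dev), np.flatnonzero(is_dev)


def train(
    records: Sequence[SampleRecord],
    assignment: GroupAssignment | None,
    config: TrainConfig,
) -> TrainedScorer:
    """Train a scorer under ``config`` and return the best dev-AUC epoch.

    ``assignment`` supplies the subgroups the proposed loss audits per
    batch; it is unused by the bce/oversample modes.  The run is fully
    deterministic given the config seed (dev split, init, batch order,
    oversampling draws).
    """
    labels = np.array([r.label for r in records])
    if len(records) < 2 or labels.min() == labels.max():
        raise ValueError("training needs both classes present")
    if config.loss_mode == "proposed":
        if assignment is None:
            raise ValueError("proposed mode needs a group assignment")
        if len(assignment.categories) < 2:
            raise ValueError("proposed mode needs >= 2 groups")

    ids = [r.sample_id for r in records]
    groups = (
        assignment.groups_for(ids)
        if assignment is not None
        else np.array(["all"] * len(records), dtype=object)
    )
    patient_ids = np.array([r.patient_id for r in records])
    X = design_matrix(records)

    children = np.random.SeedSequence(config.seed).spawn(4)
    split_rng = np.random.default_rng(children[0])
    init_rng = np.random.default_rng(children[1])
    order_rng = np.random.default_rng(children[2])
    over_seed = int(children[3].generate_state(1)[0] % (2**31))
    train_idx, dev_idx = _dev_split(patient_ids, config.dev_fraction, split_rng)
    if labels[train_idx].min() == labels[train_idx].max():
        raise ValueError("training side of the dev split is single-class")

    scorer = _make_scorer(config, X.shape[1], init_rng)
    optimizer = Adam(scorer.params, lr=config.learning_rate)
    neg_buffer = (
        NegativeBuffer(config.negative_buffer) if config.negative_buffer else None
    )

    if config.loss_mode == "oversample":
        pool = train_idx[
            oversample_minority([records[i] for i in train_idx], over_seed)
        ]
    else:
        pool = train_idx.copy()

    def dev_auc() -> float:
        if len(dev_idx) == 0 or labels[dev_idx].min() == labels[dev_idx].max():
            return float("nan")
        z, _ = scorer.logits(X[dev_idx])
        return overall_auc(
            ScoredSet(scores=_sigmoid(z), labels=labels[dev_idx], groups=groups[dev_idx])
        )

    history_rows = []
    selections = []
    best_auc, best_epoch = -np.inf, -1
    best_params = {k: v.copy() for k, v in scorer.params.items()}

    for epoch in range(config.epochs):
        order = pool.copy()
        order_rng.shuffle(order)
        losses, skipped = [], 0
        for b_start in range(0, len(order), config.batch_size):
            idx = order[b_start : b_start + config.batch_size]
            z, cache = scorer.logits(X[idx])
            p = _sigmoid(z)
            y = labels[idx]
            if config.loss_mode in ("bce", "oversample"):
                eps = 1e-12
                loss = float(
                    -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
                )
                g_z = (p - y) / len(idx)
            else:
                batch = ScoredSet(scores=p, labels=y, groups=groups[idx])
                selection = select_worst_group(batch)
                if selection.skipped:
                    skipped += 1
                    continue
                pos_mask = (batch.groups == selection.selected) & (y == 1)
                neg_mask = y == 0
                x_n = p[neg_mask]
                if neg_buffer is not None:
                    pooled_n = neg_buffer.pooled(x_n)
                    neg_buffer.extend(x_n)
                else:
                    pooled_n = x_n
                loss, g_p, g_n = marginal_ranking_loss_grad(
                    RankingLossInputs(
                        x_p=p[pos_mask], x_n=pooled_n, margin=config.margin
                    )
                )
                g_score = np.zeros_like(p)
                g_score[pos_mask] = g_p
                # buffered negatives came from earlier batches; only the
                # current batch's negatives receive gradient
                g_score[neg_mask] = g_n[: neg_mask.sum()]
                g_z = g_score * p * (1.0 - p)
                selections.append(
                    {
                        "epoch": epoch,
                        "batch": b_start // config.batch_size,
                        "category": selection.selected,
                        "batch_pf": selection.batch_pf[selection.selected],
                    }
                )
            grads = scorer.backward(cache, g_z)
            optimizer.step(scorer.params, grads)
            losses.append(loss)
        auc = dev_auc()
        history_rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)) if losses else float("nan"),
                "dev_auc": auc,
                "n_skipped": skipped,
                "n_steps": len(losses),
            }
        )
        if not np.isnan(auc) and auc > best_auc:
            best_auc, best_epoch = auc, epoch
            best_params = {k: v.copy() for k, v in scorer.params.items()}

    if best_epoch >= 0:
        scorer.params = best_params
    history = pd.DataFrame(
        history_rows,
        columns=["epoch", "train_loss", "dev_auc", "n_skipped", "n_steps"],
    )
    return TrainedScorer(
        scorer=scorer,
        history=history,
        best_epoch=best_epoch if best_epoch >= 0 else 0,
        config=config,
        selection_log=pd.DataFrame(
            selections, columns=["epoch", "batch", "category", "batch_pf"]
        ),
    )


def predict(
    trained: TrainedScorer | object,
    records: Sequence[SampleRecord],
    assignment: GroupAssignment | None = None,
    batch_size: int = 256,
) -> ScoredSet:
    """Score records (order-preserving, batch-size invariant).

    Groups come from ``assignment`` when given, else a single "all"
    category — making overall AUC the PF of the trivial partition.
    """
    scorer = trained.scorer if isinstance(trained, TrainedScorer) else trained
    ids = [r.sample_id for r in records]
    if not records:
        return ScoredSet(
            scores=np.empty(0),
            labels=np.empty(0, dtype=int),
            groups=np.empty(0, dtype=object),
            sample_ids=np.empty(0, dtype=object),
        )
    X = design_matrix(records)
    scores = np.empty(len(records))
    for start in range(0, len(records), batch_size):
        z, _ = scorer.logits(X[start : start + batch_size])
        scores[start : start + batch_size] = _sigmoid(z)
    groups = (
        assignment.groups_for(ids)
        if assignment is not None
        else np.array(["all"] * len(records), dtype=object)
    )
    return ScoredSet(
        scores=scores,
        labels=np.array([r.label for r in records]),
        groups=groups,
        sample_ids=np.array(ids, dtype=object),
    )
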