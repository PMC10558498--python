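"""Worst-group marginal ranking loss: the fairness training step.

Per batch, pairwise fairness is estimated for every subgroup that has at
least one positive in the batch (against all batch negatives), the group
with the *lowest* batch PF is selected (ties broken lexicographically),
and the marginal ranking loss

    L = (1/n) * sum over pairs of max(0, -x_p + x_n + margin)

is computed over that group's positive predictions x_p versus all batch
negative predictions x_n, where n = |x_p|·|x_n|.  Minimising L pushes
every positive of the worst-ranked group above every negative by at least
``margin``, directly raising that group's PF.

The full definition pools negatives over the whole training data; at step
time the batch negatives serve as the stochastic estimate, optionally
augmented by a FIFO buffer of recent negatives (:class:`NegativeBuffer`).

Degenerate batches (no positives anywhere, or no negatives) yield a *skip*
signal rather than an exception — the caller simply performs no update.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .metrics import ScoredSet, per_group_pf

__all__ = [
    "RankingLossInputs",
    "BatchSelection",
    "NegativeBuffer",
    "marginal_ranking_loss",
    "marginal_ranking_loss_grad",
    "select_worst_group",
    "fairness_training_step",
]


@dataclass(frozen=True)
class RankingLossInputs:
    """Positive/negative prediction vectors plus the margin."""

    x_p: np.ndarray
    x_n: np.ndarray
    margin: float

    def __post_init__(self):
        object.__setattr__(self, "x_p", np.asarray(self.x_p, dtype=float))
        object.__setattr__(self, "x_n", np.asarray(self.x_n, dtype=float))
        if self.margin < 0:
            raise ValueError("margin must be nonnegative")
        if self.x_p.size == 0 or self.x_n.size == 0:
            raise ValueError("x_p and x_n must be nonempty")
        if not (np.all(np.isfinite(self.x_p)) and np.all(np.isfinite(self.x_n))):
            raise ValueError("predictions must be finite")


@dataclass
class BatchSelection:
    """Outcome of worst-group selection on one batch.

    ``selected`` is None when the batch is ineligible (skip signal);
    otherwise it is the eligible category attaining the minimum batch PF.
    """

    selected: str | None
    batch_pf: dict
    eligible: dict

    @property
    def skipped(self) -> bool:
        return self.selected is None


def marginal_ranking_loss(inp: RankingLossInputs) -> float:
    """Mean hinge over all positive/negative pairs."""
    hinge = np.maximum(0.0, -inp.x_p[:, None] + inp.x_n[None, :] + inp.margin)
    return float(hinge.mean())


def marginal_ranking_loss_grad(
    inp: RankingLossInputs,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss plus its (sub)gradient w.r.t. x_p and x_n.

    For each pair with an active hinge (x_n + margin > x_p) the gradient is
    −1/n on the positive and +1/n on the negative; exactly-zero hinges take
    the zero subgradient.
    """
    diff = -inp.x_p[:, None] + inp.x_n[None, :] + inp.margin
    active = diff > 0
    n = inp.x_p.size * inp.x_n.size
    loss = float(np.where(active, diff, 0.0).mean())
    g_p = -active.sum(axis=1) / n
    g_n = active.sum(axis=0) / n
    return loss, g_p.astype(float), g_n.astype(float)


class NegativeBuffer:
    """FIFO buffer of recent negative predictions.

    Optional closer approximation of the "negatives from the whole training
    data" pool: batch negatives are augmented with up to ``size`` recent
    negative scores from previous steps.  Buffered scores are stale (they
    were produced by earlier parameters), so the buffer is off by default.
    """

    def __init__(self, size: int):
        if size < 0:
            raise ValueError("buffer size must be nonnegative")
        self._buf: deque = deque(maxlen=size) if size else None

    def extend(self, neg_scores: np.ndarray) -> None:
        if self._buf is not None:
            self._buf.extend(float(x) for x in neg_scores)

    def pooled(self, neg_scores: np.ndarray) -> np.ndarray:
        if self._buf is None or not self._buf:
            return neg_scores
        return np.concatenate([neg_scores, np.fromiter(self._buf, dtype=float)])


def select_worst_group(batch: ScoredSet) -> BatchSelection:
    """Pick the eligible category with the lowest batch PF.

    Eligibility = at least one positive in the batch; PF is computed
    against all batch negatives.  Ties break to the lexicographically
    first category.  Returns a skip-signalling selection (selected=None)
    when no category is eligible or the batch has no negatives.
    """
    eligible = {
        cat: bool(((batch.groups == cat) & (batch.labels == 1)).any())
        for cat in batch.categories
    }
    if not any(eligible.values()) or not (batch.labels == 0).any():
        return BatchSelection(selected=None, batch_pf={}, eligible=eligible)
    pf_map = per_group_pf(batch)
    # categories are already sorted; min() keeps the first on ties
    selected = min(pf_map, key=lambda c: (pf_map[c], c))
    return BatchSelection(selected=selected, batch_pf=pf_map, eligible=eligible)


def fairness_training_step(
    batch: ScoredSet,
    margin: float,
    negative_buffer: NegativeBuffer | None = None,
) -> tuple[float | None, BatchSelection]:
    """One step of the proposed objective on an already-scored batch.

    Returns ``(loss, selection)``; ``loss`` is None (skip signal) for
    ineligible batches.  The loss is the marginal ranking loss of the
    selected group's batch positives against all batch negatives (plus any
    buffered negatives).
    """
    selection = select_worst_group(batch)
    if selection.skipped:
        return None, selection
    x_p = batch.scores[(batch.groups == selection.selected) & (batch.labels == 1)]
    x_n = batch.scores[batch.labels == 0]
    if negative_buffer is not None:
        pooled = negative_buffer.pooled(x_n)
        negative_buffer.extend(x_n)
        x_n = pooled
    loss = marginal_ranking_loss(RankingLossInputs(x_p=x_p, x_n=x_n, margin=margin))
    return loss, selection
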