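"""Pairwise fairness, PFD, AUC, and relative change.

Pairwise Fairness of a subgroup is the probability that the model scores a
randomly chosen *positive from the subgroup* above a randomly chosen
*negative from the entire dataset*:

    PF(G_i) = P(f(x) > f(x') | (x, y) in G_i, y = 1, (x', y') in G, y' = 0)

i.e. a subgroup-conditioned bipartite-ranking AUC.  Ties receive half
credit so that PF coincides with the Mann–Whitney AUC when the subgroup is
the whole set.  The pairwise fairness difference (PFD) is max − min of PF
over subgroups that contain at least one positive; a large PFD means the
ranker treats positives from some subgroup systematically worse.

Both a rank-based O(N log N) computation and a brute-force O(n_pos·n_neg)
pair-count oracle are provided; they agree to machine precision and the
oracle exists so the fast path can be verified independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ScoredSet",
    "FairnessReport",
    "UndefinedMetricError",
    "pairwise_fairness",
    "pair_count_auc",
    "pfd",
    "overall_auc",
    "group_auc",
    "relative_change",
    "evaluate",
    "aggregate_reports",
]


class UndefinedMetricError(ValueError):
    """The requested metric has no value on this input (e.g. no positives)."""


@dataclass
class ScoredSet:
    """Parallel score / label / group arrays — the substrate of all metrics."""

    scores: np.ndarray
    labels: np.ndarray
    groups: np.ndarray
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.groups = np.asarray(self.groups, dtype=object)
        if not (len(self.scores) == len(self.labels) == len(self.groups)):
            raise ValueError("scores, labels and groups must have equal length")
        if len(self.scores) and not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if len(self.labels) and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def categories(self) -> list:
        return sorted(set(self.groups.tolist()))


def _rank_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    # Mann–Whitney via midranks: sum of positive ranks minus the minimum
    # possible, normalised by the number of pairs; ties get half credit.
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    ranks = rankdata(np.concatenate([pos_scores, neg_scores]))
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pair_count_auc(pos_scores, neg_scores) -> float:
    """Brute-force O(n·m) pair counting: wins + half credit for ties.

    The definitional oracle the rank-based computation must reproduce.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    diff_pos = pos[:, None]
    diff_neg = neg[None, :]
    wins = (diff_pos > diff_neg).sum() + 0.5 * (diff_pos == diff_neg).sum()
    return float(wins / (len(pos) * len(neg)))


def pairwise_fairness(s: ScoredSet, category) -> float:
    """PF of ``category``: its positives ranked against *all* negatives.

    The negative pool is global and includes the category's own negatives.
    Raises :class:`UndefinedMetricError` when the category has no positive
    or the set has no negative.
    """
    in_group = s.groups == category
    pos = s.scores[in_group & (s.labels == 1)]
    neg = s.scores[s.labels == 0]
    if len(pos) == 0:
        raise UndefinedMetricError(
            f"pairwise fairness undefined for {category!r}: no positives in group"
        )
    if len(neg) == 0:
        raise UndefinedMetricError(
            f"pairwise fairness undefined for {category!r}: no negatives in set"
        )
    return _rank_auc(pos, neg)


def pfd(s: ScoredSet) -> tuple[dict, float]:
    """Per-category PF and the pairwise fairness difference (max − min).

    Categories without positives are excluded (PF is undefined there);
    at least two eligible categories are required for the difference.
    Returns ``(pf_by_category, pfd_value)``.
    """
    neg = s.scores[s.labels == 0]
    if len(neg) == 0:
        raise UndefinedMetricError("PFD undefined: no negatives in set")
    pf_map = {}
    for cat in s.categories:
        pos = s.scores[(s.groups == cat) & (s.labels == 1)]
        if len(pos):
            pf_map[cat] = _rank_auc(pos, neg)
    if len(pf_map) < 2:
        raise UndefinedMetricError(
            f"PFD undefined: {len(pf_map)} categor(ies) with positives, need >= 2"
        )
    values = list(pf_map.values())
    return pf_map, float(max(values) - min(values))


def per_group_pf(s: ScoredSet) -> dict:
    """PF for every category with at least one positive (no min-count gate)."""
    neg = s.scores[s.labels == 0]
    if len(neg) == 0:
        raise UndefinedMetricError("PF undefined: no negatives in set")
    return {
        cat: _rank_auc(s.scores[(s.groups == cat) & (s.labels == 1)], neg)
        for cat in s.categories
        if ((s.groups == cat) & (s.labels == 1)).any()
    }


def overall_auc(s: ScoredSet) -> float:
    """Mann–Whitney AUC of the whole set (half tie credit).

    Identical to PF computed with the whole set as a single group.
    """
    pos = s.scores[s.labels == 1]
    neg = s.scores[s.labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedMetricError("AUC undefined: single-class input")
    return _rank_auc(pos, neg)


def group_auc(s: ScoredSet, category) -> float:
    """Within-group AUC: the category's positives vs the category's negatives."""
    in_group = s.groups == category
    pos = s.scores[in_group & (s.labels == 1)]
    neg = s.scores[in_group & (s.labels == 0)]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedMetricError(
            f"group AUC undefined for {category!r}: single-class group"
        )
    return _rank_auc(pos, neg)


def relative_change(x_baseline: float, x_proposed: float) -> float:
    """Signed fraction (proposed − baseline)/baseline; tables print it ×100."""
    if x_baseline == 0:
        raise ValueError("relative change undefined for zero baseline")
    return (x_proposed - x_baseline) / x_baseline


# ---------------------------------------------------------------------------
# reports

@dataclass
class FairnessReport:
    """Fairness audit of one scored evaluation set under one grouping.

    ``per_group`` columns: group, n_pos_in_group, n_neg_global,
    pairwise_fairness, group_auc (NaN when the group has a single class).
    """

    grouping: str
    per_group: pd.DataFrame
    overall_auc: float
    pfd: float
    excluded: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "overall_auc": self.overall_auc,
            "pfd": self.pfd,
            "excluded": list(self.excluded),
            "per_group": self.per_group.to_dict(orient="records"),
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "FairnessReport":
        return cls(
            grouping=d["grouping"],
            per_group=pd.DataFrame(d["per_group"]),
            overall_auc=d["overall_auc"],
            pfd=d["pfd"],
            excluded=list(d["excluded"]),
        )


def evaluate(s: ScoredSet, grouping_name: str = "group") -> FairnessReport:
    """Full audit: per-group PF and AUC, overall AUC, PFD."""
    neg_global = int((s.labels == 0).sum())
    pf_map, pfd_value = pfd(s)
    rows = []
    excluded = []
    for cat in s.categories:
        mask = s.groups == cat
        n_pos = int((mask & (s.labels == 1)).sum())
        if n_pos == 0:
            excluded.append(cat)
            continue
        try:
            g_auc = group_auc(s, cat)
        except UndefinedMetricError:
            g_auc = float("nan")
        rows.append(
            {
                "group": cat,
                "n_pos_in_group": n_pos,
                "n_neg_global": neg_global,
                "pairwise_fairness": pf_map[cat],
                "group_auc": g_auc,
            }
        )
    return FairnessReport(
        grouping=grouping_name,
        per_group=pd.DataFrame(rows),
        overall_auc=overall_auc(s),
        pfd=pfd_value,
        excluded=excluded,
    )


def aggregate_reports(reports: Sequence[FairnessReport]) -> pd.DataFrame:
    """Mean ± sample std (ddof=1) of PF/AUC/PFD over repeated evaluations.

    Returns one row per group plus an ``__overall__`` row carrying the
    overall AUC and PFD aggregates.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    per = pd.concat([r.per_group for r in reports], ignore_index=True)
    agg = (
        per.groupby("group")[["pairwise_fairness", "group_auc"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    agg.columns = ["group"] + [f"{a}_{b}" for a, b in agg.columns[1:]]
    aucs = np.array([r.overall_auc for r in reports])
    pfds = np.array([r.pfd for r in reports])
    overall = pd.DataFrame(
        [
            {
                "group": "__overall__",
                "pairwise_fairness_mean": np.nan,
                "pairwise_fairness_std": np.nan,
                "group_auc_mean": np.nan,
                "group_auc_std": np.nan,
            }
        ]
    )
    out = pd.concat([agg, overall], ignore_index=True)
    out["overall_auc_mean"] = aucs.mean()
    out["overall_auc_std"] = aucs.std(ddof=1) if len(aucs) > 1 else np.nan
    out["pfd_mean"] = pfds.mean()
    out["pfd_std"] = pfds.std(ddof=1) if len(pfds) > 1 else np.nan
    return out


def read_scores(path) -> pd.DataFrame:
    """Read a ``sample_id,score`` delimited file."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    if not {"sample_id", "score"} <= set(df.columns):
        raise ValueError("score file needs columns sample_id,score")
    return df
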