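"""Protected-attribute subgroups: binning, intersection, cohort summaries.

A fairness audit needs every sample assigned to exactly one category per
grouping (age bands, sex, race, genotype, ...).  Numeric attributes are
binned with half-open intervals ``[lo, hi)`` — the last bin is closed above
— so that bins always form a partition of the attribute's domain.
Categorical attributes pass through, optionally via a user-supplied
collapse map (e.g. pooling rare race categories into "Other races").
Unknown or missing attribute values are an error, never a silent pool:
silently dumping unknowns into a catch-all bin would corrupt the audit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord",
    "CategoricalBinning",
    "NumericBinning",
    "GroupingSpec",
    "GroupAssignment",
    "CohortSummary",
    "MissingAttributeError",
    "assign_groups",
    "cross",
    "summarize",
    "read_metadata",
    "write_metadata",
]

#: separator used for intersectional category labels, e.g. "<75 yrs×Female"
CROSS_SEP = "×"

METADATA_REQUIRED = ("sample_id", "patient_id", "label")


class MissingAttributeError(KeyError):
    """An attribute required by a grouping is absent or unbinnable.

    Carries the offending ``sample_id`` values so the caller can report
    which rows of the cohort are at fault.
    """

    def __init__(self, message: str, sample_ids: Sequence[str] = ()):
        super().__init__(message)
        self.sample_ids = list(sample_ids)

    def __str__(self) -> str:  # KeyError quotes its arg; we want plain text
        return self.args[0]


@dataclass
class SampleRecord:
    """One observation: ids, binary disease label, attributes, payload.

    ``payload`` is whatever the scorer consumes — a numeric feature vector,
    an in-memory image array, or a path string to an image file.
    """

    sample_id: str
    patient_id: str
    label: int
    attributes: dict = field(default_factory=dict)
    payload: object = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(
                f"label must be 0 or 1, got {self.label!r} for sample "
                f"{self.sample_id!r}"
            )
        if not self.patient_id:
            raise ValueError(f"empty patient_id for sample {self.sample_id!r}")


@dataclass(frozen=True)
class CategoricalBinning:
    """Pass a categorical attribute through, optionally collapsing values.

    ``category_map`` maps raw values to audit categories (e.g. several
    race codes to "Other races"); when None, values are used as-is.
    With a map, raw values absent from it are an error.
    """

    category_map: Mapping[str, str] | None = None

    def bin(self, value) -> str:
        if isinstance(value, float) and math.isnan(value):
            raise ValueError("NaN attribute value")
        value = str(value)
        if self.category_map is None:
            return value
        if value not in self.category_map:
            raise ValueError(f"category {value!r} not in category map")
        return self.category_map[value]


@dataclass(frozen=True)
class NumericBinning:
    """Threshold binning with half-open intervals [lo, hi), last bin closed above.

    ``thresholds`` are the interior cut points (strictly increasing);
    ``labels`` names the ``len(thresholds) + 1`` bins.  A value equal to a
    threshold belongs to the upper bin: with a single threshold of 75 the
    bins are ``(-inf, 75)`` and ``[75, inf)``.
    """

    thresholds: tuple
    labels: tuple

    def __post_init__(self):
        object.__setattr__(self, "thresholds", tuple(float(t) for t in self.thresholds))
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if len(self.labels) != len(self.thresholds) + 1:
            raise ValueError(
                f"{len(self.thresholds)} thresholds need "
                f"{len(self.thresholds) + 1} labels, got {len(self.labels)}"
            )
        if any(a >= b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")

    def bin(self, value) -> str:
        x = float(value)
        if not math.isfinite(x):
            raise ValueError(f"non-finite numeric attribute value {value!r}")
        # index of first threshold strictly above x == bin index
        idx = int(np.searchsorted(self.thresholds, x, side="right"))
        return self.labels[idx]


@dataclass(frozen=True)
class GroupingSpec:
    """How to turn one or two attributes into audit categories.

    ``binnings`` maps each source attribute to its binning rule; with two
    attributes the categories are the observed product, labelled
    ``"catA×catB"`` in the order the attributes are listed.
    """

    name: str
    binnings: Mapping[str, CategoricalBinning | NumericBinning]

    def __post_init__(self):
        object.__setattr__(self, "binnings", dict(self.binnings))
        if not 1 <= len(self.binnings) <= 2:
            raise ValueError("a grouping uses one or two source attributes")

    @property
    def source_attributes(self) -> tuple:
        return tuple(self.binnings)


@dataclass
class GroupAssignment:
    """Sample → category mapping under a grouping spec.

    ``categories`` is the lexicographically sorted list of *observed*
    categories; the stable ordering is what downstream tie-breaking
    (worst-group selection) relies on.
    """

    spec: GroupingSpec
    group_of: dict
    categories: list = field(default_factory=list)

    def __post_init__(self) -> None:
        observed = sorted(set(self.group_of.values()))
        if not self.categories:
            self.categories = observed
        elif sorted(self.categories) != observed:
            raise ValueError("categories do not match observed assignment values")

    def groups_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Category labels aligned to ``sample_ids`` (object array)."""
        return np.array([self.group_of[sid] for sid in sample_ids], dtype=object)


@dataclass
class CohortSummary:
    """Per-category positive/total counts with percent positive.

    ``table`` columns: group, positive, total, percent (percent rounded
    half-up to 2 decimals, as cohort tables print it).
    """

    grouping: str
    table: pd.DataFrame

    def __str__(self) -> str:
        return self.table.to_string(index=False)


def _percent(positive: int, total: int) -> float:
    """100·positive/total rounded half-up to 2 decimals."""
    frac = Decimal(100 * positive) / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def assign_groups(records: Sequence[SampleRecord], spec: GroupingSpec) -> GroupAssignment:
    """Assign every record to exactly one category under ``spec``.

    Raises :class:`MissingAttributeError` listing the offending sample ids
    when any record lacks a source attribute or carries an unbinnable value.
    """
    group_of: dict = {}
    bad: list = []
    msgs: list = []
    for rec in records:
        parts = []
        try:
            for attr, binning in spec.binnings.items():
                if attr not in rec.attributes:
                    raise ValueError(f"missing attribute {attr!r}")
                parts.append(binning.bin(rec.attributes[attr]))
        except ValueError as exc:
            bad.append(rec.sample_id)
            if len(msgs) < 5:
                msgs.append(f"{rec.sample_id}: {exc}")
            continue
        group_of[rec.sample_id] = CROSS_SEP.join(parts)
    if bad:
        raise MissingAttributeError(
            f"grouping {spec.name!r}: {len(bad)} record(s) could not be "
            "assigned (" + "; ".join(msgs) + ")",
            sample_ids=bad,
        )
    return GroupAssignment(spec=spec, group_of=group_of)


def cross(a: GroupAssignment, b: GroupAssignment) -> GroupAssignment:
    """Intersectional grouping: each sample's category is ``catA×catB``.

    Only observed combinations appear in ``categories``; empty product
    cells are absent.  Both assignments must cover the same sample ids.
    """
    if set(a.group_of) != set(b.group_of):
        raise ValueError(
            f"cannot cross {a.spec.name!r} and {b.spec.name!r}: "
            "sample sets differ"
        )
    merged = GroupingSpec(
        name=f"{a.spec.name}{CROSS_SEP}{b.spec.name}",
        binnings={**a.spec.binnings, **b.spec.binnings},
    )
    group_of = {
        sid: f"{a.group_of[sid]}{CROSS_SEP}{b.group_of[sid]}" for sid in a.group_of
    }
    return GroupAssignment(spec=merged, group_of=group_of)


def summarize(
    records: Sequence[SampleRecord], assignment: GroupAssignment
) -> CohortSummary:
    """Cohort characteristics table: positives, totals, percent per category."""
    pos: dict = {c: 0 for c in assignment.categories}
    tot: dict = {c: 0 for c in assignment.categories}
    for rec in records:
        cat = assignment.group_of[rec.sample_id]
        tot[cat] += 1
        pos[cat] += rec.label
    rows = [
        {
            "group": c,
            "positive": pos[c],
            "total": tot[c],
            "percent": _percent(pos[c], tot[c]) if tot[c] else 0.0,
        }
        for c in assignment.categories
    ]
    return CohortSummary(
        grouping=assignment.spec.name, table=pd.DataFrame(rows)
    )


# ---------------------------------------------------------------------------
# metadata IO

def read_metadata(path) -> list[SampleRecord]:
    """Read a cohort metadata CSV into records.

    Required columns ``sample_id, patient_id, label``; a ``path`` column
    becomes the payload; ``f0..fk`` columns become a feature-vector payload;
    everything else is an attribute.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "patient_id": str})
    missing = [c for c in METADATA_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing required column(s): {missing}")
    feat_cols = sorted(
        (c for c in df.columns if c.startswith("f") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    attr_cols = [
        c
        for c in df.columns
        if c not in METADATA_REQUIRED and c != "path" and c not in feat_cols
    ]
    records = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        if "path" in df.columns and isinstance(row["path"], str):
            payload = row["path"]
        elif feat_cols:
            payload = np.array([float(row[c]) for c in feat_cols])
        else:
            payload = None
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                patient_id=str(row["patient_id"]),
                label=int(row["label"]),
                attributes={c: row[c] for c in attr_cols},
                payload=payload,
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id values in metadata")
    return records


def write_metadata(records: Sequence[SampleRecord], path) -> None:
    """Write records to the metadata CSV format :func:`read_metadata` reads."""
    rows = []
    for rec in records:
        row = {
            "sample_id": rec.sample_id,
            "patient_id": rec.patient_id,
            "label": rec.label,
            **rec.attributes,
        }
        if isinstance(rec.payload, str):
            row["path"] = rec.payload
        elif isinstance(rec.payload, np.ndarray) and rec.payload.ndim == 1:
            row.update({f"f{i}": v for i, v in enumerate(rec.payload)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
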