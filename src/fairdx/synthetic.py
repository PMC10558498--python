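"""Synthetic biased cohorts with the bias structure seen in real audits.

Real diagnostic cohorts are unfair to models in three distinct ways:
per-group *prevalence* imbalance (one group is far more often positive),
per-group *sample-size* imbalance (one group is scarce), and per-group
*separability* disparity (the diagnostic signal is weaker in one group).
This generator produces cohorts exhibiting all three, with known ground
truth, so fairness metrics and the worst-group training objective can be
exercised end-to-end without any external data.

Per group g each patient is positive with probability ``prevalence_g``;
every image of a positive patient carries an informative signal of size
``separability_g`` (in noise-std units) plus unit Gaussian noise, so a
Bayes-optimal scorer on the informative dimension attains within-group
AUC ≈ Φ(d_g/√2).  An optional nuisance *group-marker* channel encodes
group membership (strength in noise units) — the analogue of the
group-identifying proxies real medical images carry, and the degree of
freedom a scorer needs in order to shift one group's scores relative to
another.  Patients contribute 1 + Poisson(1) images each, which makes
patient-level splitting non-trivial.

The ``paperlike`` benchmark has 3 race-like groups with image counts
proportional to 38,457 : 30,239 : 9,191 (scaled by 1/30), prevalences
0.37 / 0.70 / 0.40, and separabilities 1.8 / 1.8 / 1.0 — the smallest
group is also the hardest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .subgroups import SampleRecord

__all__ = [
    "GroupParams",
    "BiasScenario",
    "SplitPlan",
    "generate",
    "make_splits",
    "paperlike",
    "bayes_scorer",
    "gaussian_auc",
]


@dataclass(frozen=True)
class GroupParams:
    """One group's size (in images), prevalence, and class separability."""

    n: int
    prevalence: float
    separability: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.separability < 0:
            raise ValueError("separability must be >= 0")


@dataclass
class BiasScenario:
    """Full description of a synthetic biased cohort."""

    groups: dict  # name -> GroupParams
    attribute: str = "group"
    modality: str = "features"  # "features" | "images"
    n_noise_features: int = 7
    marker_strength: float = 0.0
    image_size: int = 32
    extra_images_per_patient: float = 1.0  # Poisson mean; total = 1 + Poisson
    seed: int = 0

    def __post_init__(self):
        if not self.groups:
            raise ValueError("scenario needs at least one group")
        if self.modality not in ("features", "images"):
            raise ValueError("modality must be 'features' or 'images'")
        self.groups = {k: v for k, v in sorted(self.groups.items())}

    @property
    def n_features(self) -> int:
        if self.modality == "images":
            return self.image_size**2
        return 1 + self.n_noise_features + len(self.groups)


@dataclass
class SplitPlan:
    """Repeated patient-level holdout splits."""

    n_repeats: int = 5
    test_fraction: float = 0.2
    patient_level: bool = True
    seed: int = 0
    repeat_seeds: list = field(default_factory=list)

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not self.repeat_seeds:
            children = np.random.SeedSequence(self.seed).spawn(self.n_repeats)
            self.repeat_seeds = [
                int(c.generate_state(1)[0] % (2**31)) for c in children
            ]
        if len(self.repeat_seeds) != self.n_repeats:
            raise ValueError("need one seed per repeat")


def gaussian_auc(d: float) -> float:
    """AUC of two unit-variance Gaussians separated by ``d``: Φ(d/√2)."""
    return float(norm.cdf(d / np.sqrt(2.0)))


def _disc_mask(size: int, radius_frac: float = 0.2) -> np.ndarray:
    yy, xx = np.mgrid[:size, :size]
    c = (size - 1) / 2.0
    return ((yy - c) ** 2 + (xx - c) ** 2) <= (radius_frac * size) ** 2


def _image_signal_template(size: int) -> np.ndarray:
    """Unit-norm centered disc: a positive with separability d adds d×template."""
    mask = _disc_mask(size).astype(float)
    return mask / np.sqrt(mask.sum())


def _image_marker_template(size: int, group_index: int) -> np.ndarray:
    """Unit-norm 2×2 corner patch; each group lights a different corner area."""
    t = np.zeros((size, size))
    row, col = divmod(group_index, size // 2)
    r0, c0 = 2 * row, (2 * col) % (size - 2)
    t[r0 : r0 + 2, c0 : c0 + 2] = 0.5
    return t


def generate(scenario: BiasScenario) -> list[SampleRecord]:
    """Draw a cohort from the scenario (deterministic under its seed).

    Patients are generated per group until the group's image budget ``n``
    is met (the last patient's images are truncated to fit, so group sizes
    are exact).  A patient's label and group are shared by all their
    images; each image is an independent noisy realisation.
    """
    rng = np.random.default_rng(scenario.seed)
    group_names = list(scenario.groups)
    records: list[SampleRecord] = []
    if scenario.modality == "images":
        signal_t = _image_signal_template(scenario.image_size)
        marker_ts = [
            _image_marker_template(scenario.image_size, gi)
            for gi in range(len(group_names))
        ]
    for gi, (gname, gp) in enumerate(scenario.groups.items()):
        n_emitted = 0
        pi = 0
        while n_emitted < gp.n:
            label = int(rng.random() < gp.prevalence)
            n_im = min(1 + rng.poisson(scenario.extra_images_per_patient),
                       gp.n - n_emitted)
            sex = "Male" if rng.random() < 0.5 else "Female"
            age = float(np.round(rng.uniform(20, 90), 1))
            patient_id = f"{gname}-p{pi:05d}"
            for j in range(n_im):
                if scenario.modality == "features":
                    x = rng.standard_normal(scenario.n_features)
                    x[0] += gp.separability * label
                    x[1 + scenario.n_noise_features + gi] += scenario.marker_strength
                else:
                    x = rng.standard_normal(
                        (scenario.image_size, scenario.image_size)
                    )
                    x += gp.separability * label * signal_t
                    x += scenario.marker_strength * marker_ts[gi]
                records.append(
                    SampleRecord(
                        sample_id=f"{patient_id}-i{j}",
                        patient_id=patient_id,
                        label=label,
                        attributes={
                            scenario.attribute: gname,
                            "sex": sex,
                            "age": age,
                        },
                        payload=x,
                    )
                )
            n_emitted += n_im
            pi += 1
    return records


def bayes_scorer(scenario: BiasScenario):
    """Bayes-optimal *ranking* scorer: matched filter on the informative signal.

    Ignores the marker channel (group membership carries prevalence
    information, but the scorer here targets the class signal only, which
    is what gives within-group AUC = Φ(d_g/√2)).
    """
    from .training import LinearScorer

    scorer = LinearScorer(scenario.n_features, np.random.default_rng(0))
    w = np.zeros(scenario.n_features)
    if scenario.modality == "features":
        w[0] = 1.0
    else:
        w = _image_signal_template(scenario.image_size).ravel()
    scorer.params["w"] = w
    scorer.params["b"] = np.zeros(1)
    return scorer


def make_splits(records, plan: SplitPlan) -> list[tuple[list, list]]:
    """Repeated holdout splits at patient level.

    Each repeat shuffles the patients with its own seed and holds out
    ``round(test_fraction × n_patients)`` patients; no patient ever
    appears on both sides.  Returns (train sample ids, test sample ids)
    per repeat.
    """
    patient_of = {r.sample_id: r.patient_id for r in records}
    patients = sorted(set(patient_of.values()))
    if len(patients) < 2:
        raise ValueError("patient-level splitting needs >= 2 patients")
    splits = []
    for rs in plan.repeat_seeds:
        rng = np.random.default_rng(rs)
        order = np.array(patients, dtype=object)
        rng.shuffle(order)
        n_test = int(round(plan.test_fraction * len(patients)))
        test_patients = set(order[:n_test].tolist())
        train_ids = [s for s, p in patient_of.items() if p not in test_patients]
        test_ids = [s for s, p in patient_of.items() if p in test_patients]
        splits.append((train_ids, test_ids))
    return splits


def paperlike(seed: int = 0, modality: str = "features") -> BiasScenario:
    """The default biased-cohort benchmark (see module docstring)."""
    return BiasScenario(
        groups={
            "white": GroupParams(n=1282, prevalence=0.37, separability=1.8),
            "black": GroupParams(n=1008, prevalence=0.70, separability=1.8),
            "other": GroupParams(n=306, prevalence=0.40, separability=1.0),
        },
        attribute="race",
        modality=modality,
        n_noise_features=7,
        marker_strength=1.0,
        seed=seed,
    )
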