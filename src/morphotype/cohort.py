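"""Synthetic cohorts of ROI-level cortical features with known ground truth.

The generator emulates a case-control morphometry study design: a control
group and a clinical group (two pooled developmental-disorder diagnoses,
optionally co-occurring), ROI-averaged cortical features under a chosen
parcellation, linear age and handedness covariate effects, and *planted*
clinical subtypes, each shifting its own subset of ROIs by a standardized
effect size. Every downstream stage of the pipeline can therefore be tested
against a known truth without any imaging data.

Default parameters mirror the emulated study design: 105 controls and 148
clinical males (99 primary ASD, 49 primary ADHD, 13 with both diagnoses),
400 ROIs, two subtypes with opposite-sign shifts on partially overlapping
ROI sets, and cortical-thickness-like feature scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .datatypes import FeatureTable, SubjectRecord

__all__ = [
    "CohortSpec", "GroundTruth", "AtlasMapping", "CrosswalkMatrix",
    "generate_cohort", "generate_atlas_mapping", "generate_crosswalk",
    "aggregate_features", "YEO7_NETWORKS",
]

#: Canonical names of the seven resting-state networks used for ROI summaries.
YEO7_NETWORKS = ("visual", "somatomotor", "dorsal_attention",
                 "ventral_attention", "limbic", "frontoparietal", "default")


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``effect_size`` is the standardized mean shift (Cohen's d units, i.e.
    multiples of ``noise_sd``) applied to each subtype's affected ROIs;
    ``effect_pattern`` controls the sign rule: ``"opposite"`` alternates
    +/- across subtypes (subtype 1 thicker, subtype 2 thinner — the
    inverse-alteration pattern), ``"same"`` shifts every subtype positively.
    ``diagnosis_mix`` is the probability of a primary ASD diagnosis, either
    one scalar (diagnosis independent of subtype — the default null
    structure) or one value per subtype (dependence, for power checks of the
    diagnosis-by-subtype test).
    """

    n_control: int = 105
    n_clinical: int = 148
    n_rois: int = 400
    n_subtypes: int = 2
    affected_fraction: float = 0.3
    effect_size: float = 1.5
    effect_pattern: str = "opposite"
    age_range: tuple[float, float] = (20.0, 50.0)
    age_slope: float = -0.005
    handedness_distribution: float = 0.9
    noise_sd: float = 0.15
    diagnosis_mix: Union[float, Sequence[float]] = 99.0 / 148.0
    dual_fraction: float = 13.0 / 148.0
    parameter: str = "CT"
    atlas_id: str = "functional"
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_control, self.n_clinical, self.n_rois) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_subtypes < 1:
            raise ValueError("n_subtypes must be >= 1")
        if self.n_subtypes > self.n_clinical:
            raise ValueError("n_subtypes cannot exceed n_clinical")
        if not (0.0 <= self.affected_fraction <= 1.0):
            raise ValueError("affected_fraction must lie in [0, 1]")
        if not (0.0 <= self.dual_fraction <= 1.0):
            raise ValueError("dual_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_size > 0 and self.affected_fraction * self.n_rois < 1:
            raise ValueError(
                "affected_fraction x n_rois < 1: a nonzero effect size has "
                "no ROI to act on")
        if self.effect_pattern not in ("opposite", "same"):
            raise ValueError(f"unknown effect_pattern {self.effect_pattern!r}")


@dataclass
class GroundTruth:
    """Planted truth of a generated cohort, for recovery tests.

    ``subtype_label`` maps each clinical subject id to its true subtype
    (1..k); ``affected_roi_sets`` lists, per subtype, the shifted ROI ids;
    ``covariate_coefficients`` holds the per-ROI age and handedness slopes
    actually used.
    """

    subtype_label: dict[str, int]
    affected_roi_sets: list[set[str]]
    covariate_coefficients: dict[str, np.ndarray]


@dataclass
class AtlasMapping:
    """ROI -> resting-state network assignment for one atlas."""

    roi_ids: list[str]
    networks: list[str]
    atlas_id: str = "atlas"

    def __post_init__(self) -> None:
        if len(self.roi_ids) != len(self.networks):
            raise ValueError("one network label per ROI required")
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("roi_ids must be unique")
        for net, rois in self.network_members().items():
            if not rois:  # pragma: no cover - construction forbids it
                raise ValueError(f"network {net!r} has no ROI")

    def network_members(self) -> dict[str, list[str]]:
        members: dict[str, list[str]] = {}
        for roi, net in zip(self.roi_ids, self.networks):
            members.setdefault(net, []).append(roi)
        return members


@dataclass
class CrosswalkMatrix:
    """Row-stochastic ROI overlap proportions from atlas A to atlas B."""

    values: np.ndarray
    source_roi_ids: list[str]
    target_roi_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.source_roi_ids), len(self.target_roi_ids)):
            raise ValueError("crosswalk shape inconsistent with ROI id lists")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("overlap proportions must lie in [0, 1]")
        if not np.allclose(self.values.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("crosswalk rows must sum to 1")


def _draw_diagnoses(rng: np.random.Generator, spec: CohortSpec,
                    subtype: np.ndarray) -> tuple[list[str], np.ndarray]:
    mix = spec.diagnosis_mix
    if np.isscalar(mix):
        p_asd = np.full(spec.n_subtypes, float(mix))
    else:
        p_asd = np.asarray(mix, dtype=float)
        if p_asd.shape != (spec.n_subtypes,):
            raise ValueError("diagnosis_mix must be scalar or one value per subtype")
    primary = np.where(rng.random(spec.n_clinical) < p_asd[subtype - 1], "ASD", "ADHD")
    dual = rng.random(spec.n_clinical) < spec.dual_fraction
    return list(primary), dual


def generate_cohort(spec: CohortSpec) -> tuple[FeatureTable, list[SubjectRecord], GroundTruth]:
    """Draw one cohort: features, subject metadata, and planted truth.

    Control features are a per-ROI baseline mean plus linear covariate
    effects plus Gaussian noise; clinical subjects additionally receive
    their subtype's mean shift of ``effect_size * noise_sd`` on that
    subtype's affected ROIs. Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_control + spec.n_clinical
    p = spec.n_rois
    roi_ids = [f"roi{i + 1:04d}" for i in range(p)]
    subject_ids = ([f"ntc{i + 1:04d}" for i in range(spec.n_control)]
                   + [f"clin{i + 1:04d}" for i in range(spec.n_clinical)])
    is_clinical = np.zeros(n, dtype=bool)
    is_clinical[spec.n_control:] = True

    # baseline scales are cosmetic: downstream fitting standardizes per ROI
    baseline = rng.uniform(1.5, 4.5, size=p)
    age = rng.uniform(*spec.age_range, size=n)
    right = rng.random(n) < spec.handedness_distribution
    handedness = np.where(right, rng.uniform(60.0, 100.0, size=n),
                          rng.uniform(-100.0, 20.0, size=n))

    age_coef = np.full(p, spec.age_slope)
    hand_coef = np.zeros(p)
    n_hand = max(1, int(round(0.1 * p)))
    hand_rois = rng.choice(p, size=n_hand, replace=False)
    hand_coef[hand_rois] = rng.normal(0.0, 0.002 * spec.noise_sd, size=n_hand)

    # planted subtypes: near-balanced random assignment, one affected ROI
    # set per subtype (sets overlap by chance => partially overlapping)
    subtype = rng.permuted(np.arange(spec.n_clinical) % spec.n_subtypes) + 1
    n_affected = int(round(spec.affected_fraction * p))
    affected_sets: list[np.ndarray] = []
    signs: list[float] = []
    for j in range(spec.n_subtypes):
        affected_sets.append(np.sort(rng.choice(p, size=n_affected, replace=False))
                             if n_affected else np.array([], dtype=int))
        signs.append(-1.0 if (spec.effect_pattern == "opposite" and j % 2 == 1) else 1.0)

    shift = np.zeros((n, p))
    for j in range(spec.n_subtypes):
        members = np.where(is_clinical)[0][subtype == j + 1]
        if affected_sets[j].size:
            shift[np.ix_(members, affected_sets[j])] = (
                signs[j] * spec.effect_size * spec.noise_sd)

    values = (baseline[None, :] + np.outer(age, age_coef)
              + np.outer(handedness, hand_coef) + shift
              + rng.normal(0.0, spec.noise_sd, size=(n, p)))

    primary, dual = _draw_diagnoses(rng, spec, subtype)
    iq = np.round(rng.normal(105.0, 12.0, size=n), 1)
    medication = rng.random(spec.n_clinical) < 0.5

    records: list[SubjectRecord] = []
    for i, sid in enumerate(subject_ids):
        if is_clinical[i]:
            j = i - spec.n_control
            records.append(SubjectRecord(
                sid, "clinical", primary[j], bool(dual[j]),
                age=float(age[i]), handedness=float(handedness[i]),
                iq=float(iq[i]), medication=bool(medication[j])))
        else:
            records.append(SubjectRecord(
                sid, "control", "none", False,
                age=float(age[i]), handedness=float(handedness[i]),
                iq=float(iq[i])))

    features = FeatureTable(values, subject_ids, roi_ids,
                            parameter=spec.parameter, atlas_id=spec.atlas_id)
    truth = GroundTruth(
        subtype_label={subject_ids[spec.n_control + j]: int(subtype[j])
                       for j in range(spec.n_clinical)},
        affected_roi_sets=[{roi_ids[r] for r in s} for s in affected_sets],
        covariate_coefficients={"age": age_coef, "handedness": hand_coef},
    )
    return features, records, truth


def generate_atlas_mapping(n_rois: int, n_networks: int = 7, seed: int = 0,
                           atlas_id: str = "atlas",
                           roi_ids: Optional[Sequence[str]] = None) -> AtlasMapping:
    """Assign every ROI to exactly one of ``n_networks`` networks.

    Each network receives at least one ROI; the remainder are assigned
    uniformly at random. Deterministic given ``seed``.
    """
    if n_networks > n_rois:
        raise ValueError("cannot have more networks than ROIs")
    if n_networks < 1:
        raise ValueError("need at least one network")
    rng = np.random.default_rng(seed)
    if roi_ids is None:
        roi_ids = [f"roi{i + 1:04d}" for i in range(n_rois)]
    elif len(roi_ids) != n_rois:
        raise ValueError("roi_ids length must equal n_rois")
    names = (list(YEO7_NETWORKS) if n_networks == 7
             else [f"net{i + 1}" for i in range(n_networks)])
    assignment = np.concatenate([
        np.arange(n_networks),                                # non-emptiness
        rng.integers(0, n_networks, size=n_rois - n_networks),
    ])
    assignment = rng.permuted(assignment)
    return AtlasMapping([str(r) for r in roi_ids],
                        [names[a] for a in assignment], atlas_id)


def generate_crosswalk(mapping_a: AtlasMapping, mapping_b: AtlasMapping,
                       seed: int = 0, boundary_fraction: float = 0.15) -> CrosswalkMatrix:
    """Row-stochastic ROI overlap matrix from atlas A to atlas B.

    Identical ROI id lists yield the identity. Otherwise the finer atlas's
    ROIs are grouped into contiguous blocks, one per coarser ROI (a nested
    partition), and a seeded subset of block-boundary ROIs is split between
    the two adjacent coarse ROIs to emulate partial spatial overlap between
    parcellations.
    """
    if not mapping_a.roi_ids or not mapping_b.roi_ids:
        raise ValueError("both atlas mappings must be non-empty")
    na, nb = len(mapping_a.roi_ids), len(mapping_b.roi_ids)
    if mapping_a.roi_ids == mapping_b.roi_ids:
        return CrosswalkMatrix(np.eye(na), list(mapping_a.roi_ids),
                               list(mapping_b.roi_ids))
    rng = np.random.default_rng(seed)
    if na >= nb:
        blocks = np.array_split(np.arange(na), nb)
        W = np.zeros((na, nb))
        for b, rows in enumerate(blocks):
            W[rows, b] = 1.0
        for b in range(1, nb):  # soften a fraction of block boundaries
            first = blocks[b][0]
            if rng.random() < boundary_fraction:
                w = rng.uniform(0.55, 0.85)
                W[first, b] = w
                W[first, b - 1] = 1.0 - w
    else:
        # coarse -> fine: each source ROI spreads uniformly over its block
        blocks = np.array_split(np.arange(nb), na)
        W = np.zeros((na, nb))
        for a, cols in enumerate(blocks):
            W[a, cols] = 1.0 / len(cols)
    return CrosswalkMatrix(W, list(mapping_a.roi_ids), list(mapping_b.roi_ids))


def aggregate_features(features: FeatureTable, crosswalk: CrosswalkMatrix,
                       atlas_id: str = "target") -> FeatureTable:
    """Project a feature table onto the crosswalk's target atlas.

    Each target ROI value is the overlap-weighted mean of the source ROI
    values mapping into it (weights renormalized per target column).
    """
    if features.roi_ids != crosswalk.source_roi_ids:
        raise ValueError("feature table ROIs do not match crosswalk source ROIs")
    col = crosswalk.values.sum(axis=0)
    if np.any(col <= 0):
        raise ValueError("crosswalk leaves some target ROI with zero overlap")
    projected = features.values @ (crosswalk.values / col[None, :])
    return FeatureTable(projected, list(features.subject_ids),
                        list(crosswalk.target_roi_ids),
                        parameter=features.parameter, atlas_id=atlas_id)
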