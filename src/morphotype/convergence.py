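"""Convergence of altered regions and membership consistency.

Conjunction analysis intersects the significant-ROI masks of several
analysis configurations (e.g., 2 atlases x 2 inclusion criteria) to find
regions consistently altered; masks defined on a different parcellation
are first projected onto the reference atlas through an ROI-overlap
crosswalk. Per-network summaries report the percentage of each of the
seven resting-state networks' ROIs inside a mask. Membership consistency
between two clustering solutions is quantified by subtype-wise dice
coefficients after the label bijection maximizing total overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cohort import AtlasMapping, CrosswalkMatrix

__all__ = [
    "ConjunctionResult", "conjunction_mask", "project_mask",
    "network_percentages", "dice_membership",
]


@dataclass
class ConjunctionResult:
    """Intersection of significant-ROI masks plus network summaries."""

    configuration_ids: list[str]
    intersection_mask: set[str]
    per_network_percentages: dict[str, float] = field(default_factory=dict)


def conjunction_mask(masks: Sequence[set], configuration_ids: Optional[Sequence[str]] = None,
                     ) -> ConjunctionResult:
    """Set intersection of >= 2 ROI masks on a shared atlas."""
    if len(masks) < 2:
        raise ValueError("conjunction needs at least 2 masks")
    inter = set(masks[0])
    for m in masks[1:]:
        inter &= set(m)
    ids = list(configuration_ids) if configuration_ids is not None else [
        f"config{i + 1}" for i in range(len(masks))]
    if len(ids) != len(masks):
        raise ValueError("one configuration id per mask required")
    return ConjunctionResult(ids, inter)


def project_mask(mask: set, crosswalk: CrosswalkMatrix,
                 threshold: float = 0.5) -> set[str]:
    """Project an ROI mask through a crosswalk onto the target atlas.

    A target ROI is included iff its summed overlap with the masked
    source ROIs reaches ``threshold`` (of its total incoming overlap).
    """
    source_pos = {r: i for i, r in enumerate(crosswalk.source_roi_ids)}
    unknown = [r for r in mask if str(r) not in source_pos]
    if unknown:
        raise ValueError(f"mask ROIs absent from crosswalk: {sorted(unknown)[:5]}")
    if not mask:
        return set()
    rows = [source_pos[str(r)] for r in mask]
    col_total = crosswalk.values.sum(axis=0)
    masked_overlap = crosswalk.values[rows].sum(axis=0)
    keep = np.zeros(len(crosswalk.target_roi_ids), dtype=bool)
    nz = col_total > 0
    keep[nz] = masked_overlap[nz] / col_total[nz] >= threshold
    return {crosswalk.target_roi_ids[j] for j in np.where(keep)[0]}


def network_percentages(mask: set, mapping: AtlasMapping) -> dict[str, float]:
    """Percentage of each network's ROIs inside the mask.

    ``100 * |mask ∩ network| / |network|`` per network (an empty mask
    gives 0 everywhere). Mask ROIs must exist in the mapping.
    """
    known = set(mapping.roi_ids)
    unknown = {str(r) for r in mask} - known
    if unknown:
        raise ValueError(f"mask ROIs absent from atlas mapping: {sorted(unknown)[:5]}")
    members = mapping.network_members()
    mask = {str(r) for r in mask}
    return {net: 100.0 * len(mask & set(rois)) / len(rois)
            for net, rois in sorted(members.items())}


def _best_bijection(t: np.ndarray, k: int) -> list[int]:
    """Column index matched to each row, maximizing total overlap.

    Exhaustive for k <= 4 (overlap ties broken by enumeration order,
    deterministic); Hungarian assignment for larger k.
    """
    if k <= 4:
        best, best_perm = -1, None
        for perm in permutations(range(k)):
            overlap = sum(int(t[i, perm[i]]) for i in range(k))
            if overlap > best:
                best, best_perm = overlap, perm
        return list(best_perm)
    rows, cols = linear_sum_assignment(t, maximize=True)
    return [int(c) for _, c in sorted(zip(rows, cols))]


def dice_membership(labels_ref: dict[str, int], labels_other: dict[str, int],
                    shared_subject_ids: Optional[Sequence[str]] = None,
                    ) -> tuple[dict[int, float], float]:
    """Subtype-wise dice overlap of two clustering solutions.

    Subjects present in both solutions (or the explicit
    ``shared_subject_ids``) are compared; the other solution's subtype
    names are aligned to the reference by the bijection maximizing total
    overlap, then per aligned pair ``dice = 2|A ∩ B| / (|A| + |B|)``.
    Returns per-reference-subtype dice and their size-weighted mean
    (pair sizes |A|+|B| as weights, which makes the overall value equal
    to total-matched-overlap / n and symmetric in the two solutions).
    Both solutions must use the same number of subtypes.
    """
    if shared_subject_ids is None:
        shared = [s for s in labels_ref if s in labels_other]
    else:
        shared = [str(s) for s in shared_subject_ids]
        missing = [s for s in shared if s not in labels_ref or s not in labels_other]
        if missing:
            raise ValueError(f"subjects missing from a labeling: {missing[:5]}")
    if not shared:
        raise ValueError("no shared subjects between the two solutions")
    a = np.array([labels_ref[s] for s in shared])
    b = np.array([labels_other[s] for s in shared])
    ka, kb = len(set(a.tolist())), len(set(b.tolist()))
    if ka != kb:
        raise ValueError(f"differing numbers of subtypes ({ka} vs {kb}); "
                         "dice alignment requires the same k")
    ref_names = sorted(set(a.tolist()))
    oth_names = sorted(set(b.tolist()))
    k = ka
    t = np.zeros((k, k), dtype=np.int64)
    for i, ra in enumerate(ref_names):
        for j, ob in enumerate(oth_names):
            t[i, j] = int(np.sum((a == ra) & (b == ob)))
    match = _best_bijection(t, k)
    per_subtype: dict[int, float] = {}
    weights = []
    for i, ra in enumerate(ref_names):
        size_a = int(np.sum(a == ra))
        size_b = int(np.sum(b == oth_names[match[i]]))
        inter = int(t[i, match[i]])
        per_subtype[int(ra)] = 2.0 * inter / (size_a + size_b)
        weights.append(size_a + size_b)
    overall = float(np.average([per_subtype[int(r)] for r in ref_names],
                               weights=weights))
    return per_subtype, overall
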