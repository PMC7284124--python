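"""End-to-end orchestration of the subtyping study.

One call runs the whole design reproducibly from a seed: simulate (or
ingest) a cohort, adjust nuisance covariates, sweep the number of
subtypes with cross-validated ARI, test its significance by permutation,
fit the final consensus solution per analysis cell (2 atlases x 2
inclusion criteria), characterize subtypes (diagnosis chi-square,
clinical and ROI-wise comparisons with FDR), intersect altered-ROI masks
across cells with per-network percentages, score membership consistency
by dice against the reference cell, and run the conventional three-group
diagnostic comparison. Every stage artifact is persisted; a fixed seed
reproduces the report bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (AtlasMapping, CohortSpec, CrosswalkMatrix, GroundTruth,
                     aggregate_features, generate_atlas_mapping,
                     generate_cohort, generate_crosswalk)
from .convergence import (conjunction_mask, dice_membership, network_percentages,
                          project_mask)
from .datatypes import (FeatureTable, SubjectRecord, frame_to_records,
                        records_to_frame)
from .hydra import ClusteringSolution, HydraConfig, adjust_covariates, fit_hydra
from .selection import StabilityReport, cv_stability_sweep, permutation_test
from .stats import (chi_square_diagnosis, anova_posthoc, fdr_bh, results_to_frame,
                    two_sample_tests)

__all__ = [
    "PipelineConfig", "RunReport", "read_cohort", "write_cohort",
    "read_atlas_mapping", "write_atlas_mapping", "write_crosswalk",
    "read_crosswalk", "run_pipeline", "write_report", "solution_to_dict",
]

logger = logging.getLogger(__name__)

CELLS = (("functional", "all"), ("functional", "nodual"),
         ("anatomical", "all"), ("anatomical", "nodual"))
REFERENCE_CELL = "functional_all"


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs."""

    cohort: Optional[CohortSpec] = None
    feature_path: Optional[str] = None
    metadata_path: Optional[str] = None
    parameter: str = "CT"
    hydra: HydraConfig = field(default_factory=HydraConfig)
    k_range: tuple[int, int] = (2, 10)
    n_folds: int = 10
    n_permutations: int = 199
    alpha: float = 0.05
    coarse_n_rois: int = 148
    n_networks: int = 7
    run_all_cells: bool = True
    permute_all_cells: bool = False
    out_dir: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        if self.cohort is None and (self.feature_path is None
                                    or self.metadata_path is None):
            raise ValueError("either a CohortSpec or input paths are required")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("significance level must lie in (0, 1)")
        if self.k_range[0] < 1 or self.k_range[0] > self.k_range[1]:
            raise ValueError("invalid k_range")


@dataclass
class RunReport:
    """Master record of one pipeline run (JSON-serializable)."""

    config: dict
    version: str
    seed: int
    stability: dict            # cell -> StabilityReport dict
    solutions: dict            # cell -> labels / counts summary
    diagnosis_tables: dict     # cell -> {table, chi2, p}
    clinical_comparisons: dict # cell -> list of rows
    roi_comparisons: dict      # cell -> per-subtype n significant
    conjunction: dict          # subtype -> mask + network percentages
    dice: dict                 # cell -> {per_subtype, overall}
    conventional: dict         # three-group ANOVA summaries
    elapsed_s: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _jsonify(asdict(self))


def _jsonify(obj):
    """Strict-JSON-safe copy: NaN/inf -> None, numpy scalars -> Python."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    return obj


# ---------------------------------------------------------------------------
# I/O

def write_cohort(features: FeatureTable, records: Sequence[SubjectRecord],
                 feature_path: str | Path, metadata_path: str | Path) -> None:
    # %.17g makes the float round trip bit-exact
    features.to_frame().to_csv(feature_path, sep="\t", float_format="%.17g")
    records_to_frame(records).to_csv(metadata_path, sep="\t", float_format="%.17g")


def read_cohort(feature_path: str | Path, metadata_path: str | Path,
                parameter: str = "CT", atlas_id: str = "atlas"
                ) -> tuple[FeatureTable, list[SubjectRecord]]:
    """Load and cross-validate the feature and metadata tables.

    All validation problems (duplicate ids, subjects present in only one
    file, non-numeric feature cells) are aggregated and reported together.
    """
    errors: list[str] = []
    feat = pd.read_csv(feature_path, sep="\t", index_col=0, dtype=str)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0,
                       float_precision="round_trip")
    feat.index = feat.index.astype(str)
    meta.index = meta.index.astype(str)
    for name, idx in (("feature", feat.index), ("metadata", meta.index)):
        dup = idx[idx.duplicated()].unique().tolist()
        if dup:
            errors.append(f"duplicate subject ids in {name} table: {dup[:5]}")
    only_feat = sorted(set(feat.index) - set(meta.index))
    only_meta = sorted(set(meta.index) - set(feat.index))
    if only_feat:
        errors.append(f"subjects missing from metadata: {only_feat[:5]}")
    if only_meta:
        errors.append(f"subjects missing from feature table: {only_meta[:5]}")
    numeric = feat.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    for i, j in bad[:10]:
        errors.append(f"non-numeric feature cell at subject "
                      f"{feat.index[i]!r}, ROI {feat.columns[j]!r}: "
                      f"{feat.iat[i, j]!r}")
    if errors:
        raise ValueError("cohort validation failed:\n  " + "\n  ".join(errors))
    records = frame_to_records(meta.loc[feat.index])
    table = FeatureTable(numeric.to_numpy(float), list(feat.index),
                         list(feat.columns), parameter, atlas_id)
    return table, records


def write_atlas_mapping(mapping: AtlasMapping, path: str | Path) -> None:
    pd.DataFrame({"roi_id": mapping.roi_ids, "network": mapping.networks}
                 ).to_csv(path, sep="\t", index=False)


def read_atlas_mapping(path: str | Path, atlas_id: str = "atlas") -> AtlasMapping:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return AtlasMapping(list(df["roi_id"]), list(df["network"]), atlas_id)


def write_crosswalk(crosswalk: CrosswalkMatrix, path: str | Path) -> None:
    pd.DataFrame(crosswalk.values, index=crosswalk.source_roi_ids,
                 columns=crosswalk.target_roi_ids).to_csv(
                     path, sep="\t", float_format="%.17g")


def read_crosswalk(path: str | Path) -> CrosswalkMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CrosswalkMatrix(df.to_numpy(float), list(df.index.astype(str)),
                           list(df.columns.astype(str)))


def solution_to_dict(solution: ClusteringSolution) -> dict:
    return {
        "labels": {s: int(l) for s, l in solution.labels.items()},
        "weights": solution.model.weights.tolist(),
        "intercepts": solution.model.intercepts.tolist(),
        "objective": solution.model.objective,
        "coassignment": solution.coassignment.tolist(),
        "clinical_ids": list(solution.clinical_ids),
        "converged": bool(solution.converged),
    }


def _versioned(path: Path) -> None:
    """Move an existing file aside (name.~N~) instead of clobbering it."""
    if not path.exists():
        return
    n = 1
    while (cand := path.with_name(f"{path.name}.~{n}~")).exists():
        n += 1
    path.rename(cand)


def _write_file(path: Path, writer) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    _versioned(path)
    writer(path)


def write_report(report: RunReport, out_dir: str | Path) -> list[Path]:
    """Persist the master JSON report plus per-table TSVs (stable ordering)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path, writer):
        _write_file(path, writer)
        written.append(path)

    emit(out / "report.json", lambda p: p.write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"))
    for cell, rows in report.clinical_comparisons.items():
        df = pd.DataFrame(rows, columns=["variable", "contrast", "statistic",
                                         "p", "q", "significant"])
        emit(out / f"clinical_comparisons_{cell}.tsv",
             lambda p, df=df: df.to_csv(p, sep="\t", index=False))
    return written


# ---------------------------------------------------------------------------
# orchestration

def _exclude_dual(features: FeatureTable, records: Sequence[SubjectRecord]
                  ) -> tuple[FeatureTable, list[SubjectRecord]]:
    keep = [r.subject_id for r in records if not r.dual_diagnosis]
    keep_set = set(keep)
    sub = [s for s in features.subject_ids if s in keep_set]
    return features.subset_subjects(sub), [r for r in records
                                           if r.subject_id in keep_set]


def _subtype_masks(features: FeatureTable, records: Sequence[SubjectRecord],
                   labels: dict[str, int], alpha: float) -> dict[int, set[str]]:
    """Significant-ROI mask per subtype from subtype-vs-control tests."""
    data = features.to_frame()
    control_ids = [r.subject_id for r in records if r.group == "control"
                   and r.subject_id in data.index]
    masks: dict[int, set[str]] = {}
    for j in sorted(set(labels.values())):
        ids = [s for s, l in labels.items() if l == j]
        if len(ids) < 2:   # degenerate subtype: nothing testable
            masks[j] = set()
            continue
        res = two_sample_tests(data, ids, control_ids,
                               contrast=f"subtype{j}_vs_control", alpha=alpha)
        masks[j] = {r.variable_id for r in res if r.significant}
    return masks


def _align_cell_labels(ref: dict[str, int], other: dict[str, int]) -> dict[str, int]:
    """Rename the other cell's subtypes to best match the reference."""
    shared = [s for s in ref if s in other]
    if not shared:
        return dict(other)
    ka = sorted(set(ref[s] for s in shared))
    kb = sorted(set(other[s] for s in shared))
    if len(ka) != len(kb):
        return dict(other)
    t = np.zeros((len(ka), len(kb)), dtype=np.int64)
    for s in shared:
        t[ka.index(ref[s]), kb.index(other[s])] += 1
    from .convergence import _best_bijection
    match = _best_bijection(t, len(ka))
    rename = {kb[match[i]]: ka[i] for i in range(len(ka))}
    return {s: rename.get(l, l) for s, l in other.items()}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages for every configured (atlas x inclusion) cell."""
    config.validate()
    t_all = time.perf_counter()
    elapsed: dict[str, float] = {}

    def tick(stage: str, t0: float) -> None:
        elapsed[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", stage, elapsed[stage])

    # --- cohort -----------------------------------------------------------
    t0 = time.perf_counter()
    if config.cohort is not None:
        spec = replace(config.cohort, seed=config.seed,
                       parameter=config.parameter)
        features_fn, records, truth = generate_cohort(spec)
    else:
        features_fn, records = read_cohort(config.feature_path,
                                           config.metadata_path,
                                           parameter=config.parameter,
                                           atlas_id="functional")
        truth = None
    n_fn = features_fn.n_rois
    mapping_fn = generate_atlas_mapping(n_fn, config.n_networks,
                                        seed=config.seed, atlas_id="functional",
                                        roi_ids=features_fn.roi_ids)
    coarse = min(config.coarse_n_rois, n_fn)
    mapping_an = generate_atlas_mapping(
        coarse, config.n_networks, seed=config.seed + 1, atlas_id="anatomical",
        roi_ids=[f"anat{i + 1:04d}" for i in range(coarse)])
    cw_fn_to_an = generate_crosswalk(mapping_fn, mapping_an, seed=config.seed)
    col = cw_fn_to_an.values.sum(axis=0)
    cw_an_to_fn = CrosswalkMatrix(
        (cw_fn_to_an.values / col[None, :]).T,
        list(mapping_an.roi_ids), list(mapping_fn.roi_ids))
    features_an = aggregate_features(features_fn, cw_fn_to_an, "anatomical")
    tick("cohort", t0)

    cells = CELLS if config.run_all_cells else (("functional", "all"),)
    cell_inputs: dict[str, tuple[FeatureTable, list[SubjectRecord]]] = {}
    for atlas, inclusion in cells:
        feats = features_fn if atlas == "functional" else features_an
        recs = list(records)
        if inclusion == "nodual":
            feats, recs = _exclude_dual(feats, recs)
        cell_inputs[f"{atlas}_{inclusion}"] = (feats, recs)

    # --- k sweep, permutation, final fit per cell -------------------------
    stability: dict[str, dict] = {}
    solutions: dict[str, ClusteringSolution] = {}
    k_values = range(config.k_range[0], config.k_range[1] + 1)
    for cell, (feats, recs) in cell_inputs.items():
        t0 = time.perf_counter()
        adj = adjust_covariates(feats, recs,
                                sample=config.hydra.covariate_sample)
        rep = cv_stability_sweep(adj, recs, k_values, config.n_folds,
                                 config.hydra, preadjusted=True)
        if cell == REFERENCE_CELL or config.permute_all_cells:
            p, _null = permutation_test(adj, recs, rep.selected_k,
                                        config.n_permutations, config.hydra,
                                        n_folds=config.n_folds, preadjusted=True)
            rep.permutation_p = p
            rep.n_permutations = config.n_permutations
        stability[cell] = rep.to_dict()
        solutions[cell] = fit_hydra(adj, recs, k=rep.selected_k,
                                    config=config.hydra, preadjusted=True)
        tick(f"subtyping_{cell}", t0)

    # align every cell's subtype names to the reference cell
    ref_labels = solutions[REFERENCE_CELL].labels
    aligned: dict[str, dict[str, int]] = {}
    for cell, sol in solutions.items():
        aligned[cell] = (dict(ref_labels) if cell == REFERENCE_CELL
                         else _align_cell_labels(ref_labels, sol.labels))

    # --- subtype characterization -----------------------------------------
    t0 = time.perf_counter()
    diagnosis_tables: dict[str, dict] = {}
    clinical_cmp: dict[str, list] = {}
    roi_cmp: dict[str, dict] = {}
    cell_masks: dict[str, dict[int, set[str]]] = {}
    for cell, (feats, recs) in cell_inputs.items():
        labels = aligned[cell]
        rec_by_id = {r.subject_id: r for r in recs}
        subtype_names = sorted(set(labels.values()))
        table = [[sum(1 for s, l in labels.items()
                      if l == j and rec_by_id[s].primary_diagnosis == dx)
                  for dx in ("ASD", "ADHD")] for j in subtype_names]
        entry: dict = {"table": table, "subtypes": subtype_names}
        if len(subtype_names) == 2 and all(sum(row) for row in table) \
                and all(c for c in np.array(table).sum(axis=0)):
            chi2, p = chi_square_diagnosis(table)
            entry.update(chi2=chi2, p=p)
        diagnosis_tables[cell] = entry

        meta = records_to_frame(recs)[["age", "handedness", "iq"]]
        rows = []
        for a in range(len(subtype_names)):
            for b in range(a + 1, len(subtype_names)):
                ja, jb = subtype_names[a], subtype_names[b]
                ids_a = [s for s, l in labels.items() if l == ja]
                ids_b = [s for s, l in labels.items() if l == jb]
                if min(len(ids_a), len(ids_b)) < 2:
                    continue      # degenerate subtype: skip the contrast
                res = two_sample_tests(
                    meta, ids_a, ids_b,
                    contrast=f"subtype{ja}_vs_subtype{jb}", alpha=config.alpha)
                rows += [[r.variable_id, r.contrast, r.statistic, r.raw_p,
                          r.q_value, r.significant] for r in res]
        clinical_cmp[cell] = rows

        masks = _subtype_masks(feats, recs, labels, config.alpha)
        cell_masks[cell] = masks
        roi_cmp[cell] = {f"subtype{j}": len(m) for j, m in masks.items()}
    tick("characterization", t0)

    # --- conjunction across cells on the reference atlas ------------------
    t0 = time.perf_counter()
    conjunction: dict[str, dict] = {}
    ref_subtypes = sorted(cell_masks[REFERENCE_CELL])
    for j in ref_subtypes:
        projected = []
        cell_ids = []
        for cell in cell_masks:
            if j not in cell_masks[cell]:
                continue
            mask = cell_masks[cell][j]
            if cell.startswith("anatomical"):
                mask = project_mask(mask, cw_an_to_fn, threshold=0.5)
            projected.append(mask)
            cell_ids.append(cell)
        if len(projected) >= 2:
            res = conjunction_mask(projected, cell_ids)
            res.per_network_percentages = network_percentages(
                res.intersection_mask, mapping_fn)
            conjunction[f"subtype{j}"] = {
                "cells": cell_ids,
                "n_rois": len(res.intersection_mask),
                "mask": sorted(res.intersection_mask),
                "network_percentages": res.per_network_percentages,
            }
    tick("conjunction", t0)

    # --- dice membership consistency --------------------------------------
    t0 = time.perf_counter()
    dice: dict[str, dict] = {}
    for cell, sol in solutions.items():
        if cell == REFERENCE_CELL:
            continue
        try:
            per, overall = dice_membership(ref_labels, sol.labels)
        except ValueError as exc:
            dice[cell] = {"error": str(exc)}
            continue
        dice[cell] = {"per_subtype": {str(k): v for k, v in per.items()},
                      "overall": overall}
    tick("dice", t0)

    # --- conventional three-group comparison ------------------------------
    t0 = time.perf_counter()
    conventional: dict[str, dict] = {}
    rec_by_id = {r.subject_id: r for r in records}
    dx_of = {s: ("NTC" if rec_by_id[s].group == "control"
                 else rec_by_id[s].primary_diagnosis)
             for s in features_fn.subject_ids}
    groups3 = np.array([dx_of[s] for s in features_fn.subject_ids])
    if len(set(groups3.tolist())) >= 3:
        meta_all = records_to_frame(records)[["age", "handedness", "iq"]]
        demo = {}
        for var in meta_all.columns:
            v = meta_all[var].to_numpy(float)
            g = np.array([dx_of[s] for s in meta_all.index])
            ok = np.isfinite(v)
            F, p, pairs = anova_posthoc(v[ok], g[ok], alpha=config.alpha)
            demo[var] = {"F": F, "p": p,
                         "tukey": None if pairs is None else
                         [[t.group_a, t.group_b, t.p_value, t.significant]
                          for t in pairs]}
        conventional["demographics"] = demo
        Fp = [anova_posthoc(features_fn.values[:, i], groups3,
                            alpha=0.0)[:2]    # alpha=0: skip post-hoc here
              for i in range(features_fn.n_rois)]
        ps = np.array([p for _, p in Fp])
        q = fdr_bh(ps)
        conventional["roi_anova"] = {
            "n_rois": int(features_fn.n_rois),
            "n_significant_fdr": int(np.sum(q < config.alpha)),
        }
    tick("conventional", t0)

    report = RunReport(
        config=_config_dict(config), version=__version__, seed=config.seed,
        stability=stability,
        solutions={cell: {"labels": aligned[cell],
                          "k": int(stability[cell]["selected_k"]),
                          "counts": {str(j): int(sum(1 for l in aligned[cell].values()
                                                     if l == j))
                                     for j in sorted(set(aligned[cell].values()))},
                          "converged": bool(sol.converged)}
                   for cell, sol in solutions.items()},
        diagnosis_tables=diagnosis_tables,
        clinical_comparisons=clinical_cmp,
        roi_comparisons=roi_cmp,
        conjunction=conjunction,
        dice=dice,
        conventional=conventional,
        elapsed_s={},  # excluded from determinism-sensitive content
    )
    if config.out_dir:
        out = Path(config.out_dir)
        write_report(report, out)
        _write_file(out / "solutions.json", lambda p: p.write_text(json.dumps(
            {cell: solution_to_dict(sol) for cell, sol in solutions.items()},
            indent=2, sort_keys=True) + "\n"))
        if truth is not None:
            _write_file(out / "ground_truth.json", lambda p: p.write_text(
                json.dumps({"subtype_label": truth.subtype_label,
                            "affected_roi_sets": [sorted(s) for s in
                                                  truth.affected_roi_sets]},
                           indent=2, sort_keys=True) + "\n"))
    logger.info("pipeline finished in %.1fs", time.perf_counter() - t_all)
    return report


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d
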