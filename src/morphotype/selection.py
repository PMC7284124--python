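"""Choosing the number of subtypes and assessing its significance.

The number of clusters k is swept over a range; for each k the clinical
group is split into cross-validation folds, the polytope is refit with
each fold held out, and the adjusted Rand index (ARI) between every pair
of fold solutions — evaluated on the clinical subjects common to both
training sets — measures the stability of the k-cluster solution. The k
with the highest mean ARI is selected (ties to the smaller k). Hamming
distance (label-aligned mismatch fraction) and the plain Rand index are
reported as secondary dissimilarity/similarity metrics.

Significance of the selected k is assessed by a permutation test: the
clinical/control group labels are shuffled (group sizes preserved), the
cross-validated ARI is recomputed on each shuffled dataset to form the
null distribution, and the observed ARI is compared against it with
add-one smoothing, ``p = (1 + #{null >= observed}) / (1 + n_perm)``.

The partition indices are computed from integer pair/contingency counts,
so they agree bit-exactly with brute-force pair-counting oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import comb

from .datatypes import FeatureTable, SubjectRecord
from .hydra import HydraConfig, adjust_covariates, fit_hydra

__all__ = [
    "StabilityReport", "adjusted_rand_index", "rand_index",
    "hamming_distance", "cv_stability_sweep", "permutation_test",
    "permutation_pvalue",
]


@dataclass
class StabilityReport:
    """Per-k cross-validated stability metrics and the selection outcome."""

    k_values: list[int]
    ari_mean: dict[int, float]
    ari_sd: dict[int, float]
    hamming_mean: dict[int, float]
    hamming_sd: dict[int, float]
    rand_mean: dict[int, float]
    rand_sd: dict[int, float]
    selected_k: int
    observed_ari: float = float("nan")
    permutation_p: float = float("nan")
    n_permutations: int = 0

    def to_dict(self) -> dict:
        return {
            "k_values": list(self.k_values),
            "ari_mean": {str(k): v for k, v in self.ari_mean.items()},
            "ari_sd": {str(k): v for k, v in self.ari_sd.items()},
            "hamming_mean": {str(k): v for k, v in self.hamming_mean.items()},
            "hamming_sd": {str(k): v for k, v in self.hamming_sd.items()},
            "rand_mean": {str(k): v for k, v in self.rand_mean.items()},
            "rand_sd": {str(k): v for k, v in self.rand_sd.items()},
            "selected_k": self.selected_k,
            "observed_ari": self.observed_ari,
            "permutation_p": self.permutation_p,
            "n_permutations": self.n_permutations,
        }


# ---------------------------------------------------------------------------
# partition agreement indices

def _check_pair(labels_a: Sequence, labels_b: Sequence) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("label vectors must be non-empty")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return a, b


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    ``(index - expected) / (max - expected)`` over subject pairs; 1 for
    identical partitions, symmetric, invariant to label renaming, and
    around 0 for independent labelings.
    """
    a, b = _check_pair(labels_a, labels_b)
    t = _contingency(a, b)
    n = int(a.size)
    sum_ij = int(comb(t, 2, exact=False).sum())        # entries <= n, exact in float
    sum_a = int(comb(t.sum(axis=1), 2, exact=False).sum())
    sum_b = int(comb(t.sum(axis=0), 2, exact=False).sum())
    total = n * (n - 1) // 2
    if total == 0:
        return 1.0
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:                          # both partitions trivial
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Fraction of subject pairs on which the partitions agree."""
    a, b = _check_pair(labels_a, labels_b)
    t = _contingency(a, b)
    n = int(a.size)
    total = n * (n - 1) // 2
    if total == 0:
        return 1.0
    sum_ij = int(comb(t, 2, exact=False).sum())
    sum_a = int(comb(t.sum(axis=1), 2, exact=False).sum())
    sum_b = int(comb(t.sum(axis=0), 2, exact=False).sum())
    agree_together = sum_ij
    agree_apart = total - sum_a - sum_b + sum_ij
    return (agree_together + agree_apart) / total


def hamming_distance(labels_a: Sequence, labels_b: Sequence) -> float:
    """Label-aligned mismatch fraction between two labelings.

    Minimum over all label-name bijections of the fraction of subjects
    whose labels disagree; 0 iff the partitions are identical, at most 1.
    The optimal bijection is found by Hungarian assignment on the (padded)
    contingency table, which is exact.
    """
    a, b = _check_pair(labels_a, labels_b)
    t = _contingency(a, b)
    size = max(t.shape)
    padded = np.zeros((size, size), dtype=np.int64)
    padded[: t.shape[0], : t.shape[1]] = t
    rows, cols = linear_sum_assignment(padded, maximize=True)
    matched = int(padded[rows, cols].sum())
    return (int(a.size) - matched) / int(a.size)


# ---------------------------------------------------------------------------
# cross-validated stability

def _clinical_folds(clinical_ids: list[str], n_folds: int,
                    rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(len(clinical_ids))
    return np.array_split(order, n_folds)


def _cv_solutions(features: FeatureTable, records: Sequence[SubjectRecord],
                  k: int, n_folds: int, config: HydraConfig,
                  fold_seed: int):
    """One clustering solution per held-out fold; returns solutions + held-out sets."""
    rec_by_id = {r.subject_id: r for r in records}
    clinical_ids = [s for s in features.subject_ids
                    if rec_by_id[s].group == "clinical"]
    control_ids = [s for s in features.subject_ids
                   if rec_by_id[s].group == "control"]
    rng = np.random.default_rng(fold_seed)
    folds = _clinical_folds(clinical_ids, n_folds, rng)
    solutions = []
    held_out = []
    for f, fold in enumerate(folds):
        out = {clinical_ids[i] for i in fold}
        train_ids = control_ids + [s for s in clinical_ids if s not in out]
        if len(train_ids) - len(control_ids) < k:
            raise ValueError(f"fold {f} leaves fewer than k={k} clinical subjects")
        sub = features.subset_subjects(train_ids)
        sol = fit_hydra(sub, records, k=k, config=config, preadjusted=True)
        solutions.append(sol)
        held_out.append(out)
    return solutions, held_out


def _pairwise_stats(solutions, held_out: list[set[str]],
                    clinical_ids: list[str], features: FeatureTable
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ARI / Hamming / Rand for every fold-solution pair.

    Pairs are compared on the clinical subjects common to both training
    sets. With 2 folds the training sets share no clinical subjects; the
    pair is then compared by relabeling all clinical subjects under each
    fold's polytope decision rule (same contract as :func:`assign_new`).
    """
    clinical = features.subset_subjects(clinical_ids)
    aris, hams, rands = [], [], []
    n = len(solutions)
    for i in range(n):
        for j in range(i + 1, n):
            shared = [s for s in clinical_ids
                      if s not in held_out[i] and s not in held_out[j]]
            if shared:
                la = [solutions[i].labels[s] for s in shared]
                lb = [solutions[j].labels[s] for s in shared]
            else:
                pa = solutions[i].predict(clinical)
                pb = solutions[j].predict(clinical)
                la = [pa[s] for s in clinical_ids]
                lb = [pb[s] for s in clinical_ids]
            aris.append(adjusted_rand_index(la, lb))
            hams.append(hamming_distance(la, lb))
            rands.append(rand_index(la, lb))
    return np.array(aris), np.array(hams), np.array(rands)


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def cv_stability_sweep(features: FeatureTable, records: Sequence[SubjectRecord],
                       k_range: Sequence[int] = range(2, 11), n_folds: int = 10,
                       config: Optional[HydraConfig] = None,
                       preadjusted: bool = False) -> StabilityReport:
    """Sweep k, scoring each solution's cross-validated stability.

    For each k the clinical subjects are split into ``n_folds`` seeded
    folds; the polytope is refit on all controls plus the clinical
    subjects outside each fold, and ARI / Hamming / Rand are computed for
    every pair of fold solutions on their shared training subjects.
    ``selected_k`` maximizes mean ARI, ties to the smaller k.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    config = config or HydraConfig()
    if not preadjusted:
        features = adjust_covariates(features, records,
                                     sample=config.covariate_sample)
    rec_by_id = {r.subject_id: r for r in records}
    clinical_ids = [s for s in features.subject_ids
                    if rec_by_id[s].group == "clinical"]

    k_values = sorted(int(k) for k in k_range)
    ari_mean, ari_sd = {}, {}
    ham_mean, ham_sd = {}, {}
    rnd_mean, rnd_sd = {}, {}
    fold_seed = int(np.random.SeedSequence([config.seed, 0xF01D]).generate_state(1)[0] % 2**31)
    for k in k_values:
        sols, outs = _cv_solutions(features, records, k, n_folds, config, fold_seed)
        aris, hams, rands = _pairwise_stats(sols, outs, clinical_ids, features)
        ari_mean[k] = float(np.mean(aris))
        ari_sd[k] = _sd(aris)
        ham_mean[k] = float(np.mean(hams))
        ham_sd[k] = _sd(hams)
        rnd_mean[k] = float(np.mean(rands))
        rnd_sd[k] = _sd(rands)
    selected = min(k_values, key=lambda k: (-ari_mean[k], k))
    return StabilityReport(k_values, ari_mean, ari_sd, ham_mean, ham_sd,
                           rnd_mean, rnd_sd, selected_k=selected,
                           observed_ari=ari_mean[selected])


def _mean_cv_ari(features: FeatureTable, records: Sequence[SubjectRecord],
                 k: int, n_folds: int, config: HydraConfig) -> float:
    rec_by_id = {r.subject_id: r for r in records}
    clinical_ids = [s for s in features.subject_ids
                    if rec_by_id[s].group == "clinical"]
    fold_seed = int(np.random.SeedSequence([config.seed, 0xF01D]).generate_state(1)[0] % 2**31)
    sols, outs = _cv_solutions(features, records, k, n_folds, config, fold_seed)
    aris, _, _ = _pairwise_stats(sols, outs, clinical_ids, features)
    return float(np.mean(aris))


def permutation_test(features: FeatureTable, records: Sequence[SubjectRecord],
                     k_selected: int, n_permutations: int = 5000,
                     config: Optional[HydraConfig] = None, n_folds: int = 10,
                     preadjusted: bool = False) -> tuple[float, np.ndarray]:
    """Permutation significance of the selected clustering solution.

    The observed statistic is the mean cross-validated ARI at
    ``k_selected``. Each iteration shuffles the clinical/control group
    labels across all subjects (group sizes preserved) and recomputes the
    statistic with the identical procedure and internal seeds, so under
    the null the observed value is exchangeable with the permuted ones.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    config = config or HydraConfig()
    if not preadjusted:
        features = adjust_covariates(features, records,
                                     sample=config.covariate_sample)
    observed = _mean_cv_ari(features, records, k_selected, n_folds, config)

    groups = [r.group for r in records]
    rec_list = list(records)
    shuffler = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x5EED]).generate_state(1)[0])
    null = np.empty(n_permutations)
    for it in range(n_permutations):
        perm = shuffler.permutation(len(groups))
        shuffled = [replace(rec_list[i], group=groups[perm[i]],
                            primary_diagnosis=(rec_list[i].primary_diagnosis
                                               if groups[perm[i]] == "clinical" else "none"),
                            dual_diagnosis=(rec_list[i].dual_diagnosis
                                            and groups[perm[i]] == "clinical"))
                    for i in range(len(rec_list))]
        null[it] = _mean_cv_ari(features, shuffled, k_selected, n_folds, config)
    return permutation_pvalue(observed, null), null


def permutation_pvalue(observed: float, null: Sequence[float]) -> float:
    """Add-one permutation p: ``(1 + #{null >= observed}) / (1 + n)``.

    Ties count against the observed statistic; p is never 0.
    """
    null = np.asarray(null, dtype=float)
    if null.size < 1:
        raise ValueError("empty null distribution")
    return (1.0 + float(np.sum(null >= observed))) / (1.0 + null.size)
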