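#!/usr/bin/env python
"""Select the number of subtypes by cross-validated ARI and test it.

Sweeps k = 2..6 with 10-fold cross-validated ARI (Hamming and Rand as
secondary stability metrics), then runs the group-label permutation test
at the selected k. Expected on the simulated cohort: k = 2 wins with mean
CV ARI near 1 and permutation p at the resolution floor.
"""

import json
from pathlib import Path

from morphotype import HydraConfig, cv_stability_sweep, permutation_test, read_cohort

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 2026
N_PERMUTATIONS = 99


def main() -> None:
    features, records = read_cohort(BASE / "cohort" / "features_functional.tsv",
                                    BASE / "cohort" / "metadata.tsv",
                                    atlas_id="functional")
    config = HydraConfig(n_restarts=8, seed=SEED)
    report = cv_stability_sweep(features, records, range(2, 7), n_folds=10,
                                config=config)
    print("k   ARI (mean+-sd)    Hamming        Rand")
    for k in report.k_values:
        print(f"{k}   {report.ari_mean[k]:.3f}+-{report.ari_sd[k]:.3f}    "
              f"{report.hamming_mean[k]:.3f}+-{report.hamming_sd[k]:.3f}    "
              f"{report.rand_mean[k]:.3f}+-{report.rand_sd[k]:.3f}")
    p, null = permutation_test(features, records, report.selected_k,
                               N_PERMUTATIONS, config, n_folds=10)
    report.permutation_p = p
    report.n_permutations = N_PERMUTATIONS
    print(f"\nselected k = {report.selected_k} "
          f"(mean CV ARI {report.ari_mean[report.selected_k]:.3f}); "
          f"permutation p = {p:.4f} over {N_PERMUTATIONS} shuffles "
          f"(null max {null.max():.3f})")
    out = BASE / "stability.json"
    out.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
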