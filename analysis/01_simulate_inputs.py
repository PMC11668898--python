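#!/usr/bin/env python
"""Generate every synthetic input for the downstream analyses.

Writes caller variant tables, a signature matrix and mixture catalogue,
per-cell-line count matrices, a scored survival cohort, and assay tables
(colonies, foci, intensities) under results/inputs/, each alongside its
machine-readable ground truth. All downstream scripts read these files
through the package's own readers.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from radres import signatures as SIG
from radres import ssgsea as SS
from radres import survival as SV
from radres import synth
from radres import variants as VAR
from radres.diffexpr import write_counts

SEED = 20240901
OUT = Path("results/inputs")


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    # multi-caller variant tables: 3 callers x 3 replicates, planted truth
    tables, truth = synth.sim_caller_calls(
        n_true=120, sens_per_caller={c: 0.9 for c in ("mutect2", "strelka2", "lancet")},
        fp_per_caller={c: 10 for c in ("mutect2", "strelka2", "lancet")},
        n_replicates=3, seed=SEED,
    )
    all_calls = [c for calls in tables.values() for c in calls]
    VAR.write_variant_table(all_calls, OUT / "caller_calls.tsv")
    synth.write_truth_variants(truth, OUT / "truth_variants.tsv")
    print(f"caller tables: {len(tables)} (caller, replicate) pairs, "
          f"{len(all_calls)} calls, {len(truth)} true somatic SNVs")

    # signature matrix + 0.6/0.4 mixture catalogue
    sigs = synth.sim_signature_matrix(n_signatures=10, seed=SEED + 1)
    SIG.write_signature_matrix(sigs, OUT / "signature_matrix.tsv")
    mixture = {"S01": 0.6, "S05": 0.4}
    catalogue = synth.sim_catalogue(mixture, 2000, sigs, seed=SEED + 2)
    VAR.write_catalogue(catalogue, OUT / "mixture_catalogue.tsv")
    (OUT / "mixture_truth.json").write_text(json.dumps(mixture))
    print(f"catalogue: {int(catalogue.sum())} mutations from mixture {mixture}")

    # counts: 4 cell lines, 18 shared planted genes (5 up, 13 down)
    rng = np.random.default_rng(SEED + 3)
    genes = [f"G{i + 1:05d}" for i in range(5000)]
    idx = rng.choice(5000, size=18, replace=False)
    planted = [synth.PlantedGene(genes[i], 2.0, True) for i in idx[:5]] + [
        synth.PlantedGene(genes[i], -2.0, True) for i in idx[5:]
    ]
    mats, deg_truth = synth.sim_counts(
        n_genes=5000, n_per_group=3, n_cell_lines=4,
        planted=planted, dispersion=0.05, seed=SEED + 4,
    )
    for cl, cm in mats.items():
        write_counts(cm, OUT / f"counts_{cl}.tsv", OUT / f"meta_{cl}.tsv")
    deg_truth.to_csv(OUT / "truth_degs.tsv", sep="\t", index=False)
    print(f"counts: {len(mats)} cell lines x 5000 genes, "
          f"{len(deg_truth)} planted shared DEGs")

    # survival cohort whose hazard doubles above the 60th score percentile
    expr, clinical, cohort_truth = synth.sim_cohort(n_patients=400, seed=SEED + 5)
    SS.write_expression(expr, OUT / "cohort_expression.tsv")
    SV.write_clinical(clinical, OUT / "cohort_clinical.tsv")
    (OUT / "cohort_truth.json").write_text(json.dumps(
        {k: (v.tolist() if isinstance(v, np.ndarray) else v)
         for k, v in cohort_truth.items()}
    ))
    print(f"cohort: {len(clinical)} patients, "
          f"{int(clinical['event'].sum())} events, "
          f"true threshold at q={cohort_truth['true_threshold_quantile']}")

    # assays; RR cells carry a heavier high-intensity component than WT
    synth.sim_clonogenic(seed=SEED + 6).to_csv(OUT / "colonies.csv", index=False)
    foci, _ = synth.sim_cell_measurements(n_cells=50, seed=SEED + 7)
    _, int_rr = synth.sim_cell_measurements(
        n_cells=300, foci_mean_per_condition={"RR": 2.40},
        intensity_mixture=[(0.6, 25.0, 8.0), (0.4, 50.0, 10.0)], seed=SEED + 8,
    )
    _, int_wt = synth.sim_cell_measurements(
        n_cells=300, foci_mean_per_condition={"WT": 0.28},
        intensity_mixture=[(0.85, 22.0, 7.0), (0.15, 45.0, 9.0)], seed=SEED + 9,
    )
    foci.to_csv(OUT / "foci.csv", index=False)
    pd.concat([int_rr, int_wt], ignore_index=True).to_csv(
        OUT / "intensities.csv", index=False
    )
    print("assays: colonies.csv, foci.csv, intensities.csv written")


if __name__ == "__main__":
    main()
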