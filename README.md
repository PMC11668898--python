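# radres

Statistical toolkit and analysis pipeline for comparative radioresistance
studies of cancer cell-line models, written for computational biologists
who need the full chain from somatic-variant consensus to patient-outcome
stratification as tested, seeded, reproducible code.

The scientific setting: radioresistant (RR) derivatives of prostate and
head-and-neck cancer cell lines are generated by fractionated irradiation
and compared with their wild-type (WT) parentals. The analysis chain is:

- **Consensus SNV calling** — variants reported by ≥ 2 of 3 independent
  callers in ≥ 2 of 3 replicates are accepted; accepted SNVs are binned
  into the 96 pyrimidine-centred trinucleotide contexts.
- **SBS signature refitting** — the catalogue spectrum p is decomposed as
  p ≈ S·w with w ≥ 0, Σw ≤ 1, by greedy forward selection with a 0.06
  weight cutoff and an NNLS re-optimization; sparse catalogues are guarded
  against overfitting by collapsing to the dominant signature.
- **Differential expression** — per cell line, a negative-binomial Wald
  test (median-of-ratios size factors, trend-moderated dispersions);
  DEGs at BH-adjusted P < 0.05 are intersected across cell lines requiring
  the same direction of dysregulation; over-representation by the
  hypergeometric upper tail with rich factors.
- **ssGSEA** — per-patient heterochromatin-pathway enrichment
  ES = Σᵢ [P_in^w(i) − P_out(i)] with rank weight r^0.25.
- **Survival** — Kaplan–Meier, reverse-KM follow-up, log-rank, Cox PH
  (Efron ties), and a stepwise quantile cutoff scan
  (median/tertile/quartile/quintile) selecting the split with minimal
  log-rank P.
- **Assay statistics** — clonogenic surviving fractions with the
  linear-quadratic fit SF(d) = exp(−(B1·d + B2·d²)); paired t-tests on
  per-replicate mean foci counts; Gaussian-KDE tail mass P(MGV ≥ 40);
  ΔΔCt fold changes.

Real sequencing inputs are large and access-controlled, so the package
ships a first-class synthetic-data module (`radres.synth`) that generates
every pipeline input with known ground truth and explicit seeds — caller
tables with per-caller sensitivity/false-positive structure, catalogues
from signature mixtures, NB counts with planted shared-direction DEGs,
cohorts whose hazard depends on the pathway score through a threshold,
Poisson colony counts under the LQ model, and mixture-distributed per-cell
measurements. All recovery claims in the test suite are made against that
planted truth; see `docs/methods.md` for what the generators do and do not
emulate.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data; each writes its tables under `results/` and prints what it found:

```
$ python analysis/01_simulate_inputs.py
$ python analysis/02_variant_consensus.py
1051 calls read (0 non-SNV rows skipped)
consensus: 120 variants (120/120 true recovered, 0 false kept)
effects: {'synonymous': 75, 'non_synonymous': 40, 'other': 5, 'total': 120}
$ python analysis/03_fit_signatures.py
fitted weights: {'S01': 0.6089, 'S05': 0.3878}
true mixture:   {'S01': 0.6, 'S05': 0.4}
11-mutation catalogue: retained ['S02'], removed ['S01'] (overfit flag: True)
$ python analysis/04_differential_expression.py
common DEGs across 4 lines: 18 (5 up, 13 down); planted recovery 18/18
ORA top term: TERM_SPIKED (k=18/K=48, rich factor 0.375, FDR 1.39e-37)
$ python analysis/05_score_and_survival.py
cutoff scan: selected quintile q=0.60 (threshold 0.245, unadjusted log-rank P 2.81e-05)
Cox high vs low: HR 1.70 (95% CI 1.32-2.18); true HR 2.00
reverse-KM median follow-up: 41.6 months
$ python analysis/06_assay_statistics.py
LQ fit: B1 0.261/Gy (true 0.300), B2 0.0436/Gy^2 (true 0.0300); SF(2 Gy) = 0.504
foci/cell: RR 2.48+-0.27 vs WT 0.28+-0.04; paired t P = 0.0061
RR: P(MGV >= 40) = 0.387 ... WT: P(MGV >= 40) = 0.097
```

Reading the output: the consensus rule recovered all 120 planted somatic
SNVs while rejecting every caller-specific false positive; the signature
refit returned the 0.6/0.4 mixture to within ~0.01; the four-line
intersection found exactly the 18 planted shared-direction genes (5 up,
13 down); the cutoff scan put the optimal survival split at the 60th score
percentile, where the generator doubled the hazard; and the assay
statistics recovered the planted LQ parameters and group contrasts within
sampling noise of their Poisson/mixture designs.

The same stages can be run from one config:

```
radres run --config my_run.yaml        # or: radres run  (bundled demo)
```

A run writes every output with a SHA-256 manifest into a JSON + text
report; identical configs reproduce identical outputs.

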