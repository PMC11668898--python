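# Methods

`radres` re-implements, as a tested pipeline over synthetic data with known
ground truth, the statistical backbone of a comparative radioresistance
study: matched radioresistant (RR) and parental wild-type (WT) cancer cell
lines are compared at the genomic and transcriptomic level, a
heterochromatin-formation expression signature is scored in radiotherapy
cohorts and related to outcome, and the supporting radiobiology assays
(clonogenic survival, immunofluorescence foci and intensity, qPCR) are
summarized. This note documents the models, the defaults and the reasoning
behind the open design choices. Everything quantitative claimed here is
computed by the test suite or by `scripts/acceptance.py`.

## Consensus somatic SNV calling (`radres.variants`)

Somatic variants are assumed to be called per sequencing replicate by
several independent callers. A variant key is the exact tuple
(chrom, pos, ref, alt), 1-based, single-nucleotide only; indel and
multi-nucleotide rows are counted and skipped at read time, never silently
dropped. The consensus rule retains a key iff at least `min_callers`
(default 2) distinct callers report it within a replicate, in at least
`min_replicates` (default 2) replicates. The phrase "agreement in at least
duplicates" admits a second reading — each of ≥ 2 callers reproducible in
≥ 2 replicates without ever co-occurring — which is available as
`mode="per_caller"`; the per-replicate reading is the default because caller
agreement within a library is the stronger evidence against artifacts.
Effect annotations that disagree across callers are resolved by majority,
ties falling to `other`.

Consensus SNVs are binned into the standard 96 trinucleotide-context classes
(pyrimidine-strand convention: purine-reference variants are
reverse-complemented before binning), in COSMIC order (substitution-major,
flanks alphabetical). The catalogue total always equals the consensus count.

## Signature refitting (`radres.signatures`)

A catalogue **m** (96 counts, normalized to a spectrum **p**) is explained
as a non-negative mixture of known signature spectra S (96 × k, columns
summing to 1): minimize ‖p − S w‖² with w ≥ 0 and Σw ≤ 1. Following the
established refitting scheme, signatures enter by greedy forward selection:
at each step every candidate's single weight is optimized by golden-section
search on [0, 1 − Σw] with the others fixed, and the candidate with the
largest SSE reduction joins; iteration stops when the relative SSE
improvement falls below `tol` (1e-3). Ties break to the lexicographically
smallest signature id, making the fit invariant to column order. Weights
below `weight_cutoff` (0.06, the referenced method's documented default)
are then discarded and the surviving support re-optimized by non-negative
least squares, iterating until all survivors clear the cutoff. When
sampling noise pushes the unconstrained NNLS total past 1 the solution is
projected onto {w ≥ 0, Σw = 1} via a penalty-row NNLS; for realistic
spectra the overshoot is ≲ 0.01, so the projection rarely moves any weight
noticeably.

**Overfit guard.** With very few mutations the forward selection can
scatter weight across signatures a larger catalogue would not support. The
study this emulates reported a single signature for its least-mutated cell
line (11 SNVs), without stating the criterion; as a declared proxy — not a
claim about the original procedure — exposures with fewer than
`min_mutations` (50) mutations are collapsed to the single largest-weight
signature, flagged, and the removed signatures recorded.

## Differential expression and intersection (`radres.diffexpr`)

Each cell line is tested independently, RR vs WT, with a deliberately
simple negative-binomial Wald test (the original study used DESeq2, whose
internals are out of scope here; externally produced DE tables can be
ingested via `read_de_table` so the downstream intersection is engine-
agnostic):

- size factors by median-of-ratios against the geometric-mean
  pseudo-reference;
- gene-wise NB dispersion α (var = μ + αμ²) by method of moments, pooled
  over the two groups;
- **dispersion moderation**: with 3 + 3 samples the raw gene-wise estimate
  has 4 residual df and is far too noisy to test with — it simultaneously
  inflates false positives (underestimated α) and false negatives
  (overestimated α). A parametric trend α(μ) = a₁ + a₀/μ is fitted across
  genes and the gene-wise estimate shrunk toward it with prior weight
  `dispersion_prior_df` (8, i.e. twice the residual df); this is a
  light-weight analogue of the moderation every production RNA-seq engine
  applies, and both the null behaviour and the planted-gene recovery of the
  test depend on it;
- Wald z = log2FC / SE with a delta-method SE, SE²(log μ̂) ≈ (1/μ + α)/n per
  group, pseudo-count 0.5 guarding empty means; two-sided normal p;
  Benjamini–Hochberg across genes.

DEGs are genes with adjusted P strictly below α = 0.05. The cross-model
intersection keeps genes significant in **every** scope cell line with the
**same direction** of dysregulation, and additionally reports the fraction
exceeding a fold-change threshold everywhere; ">1 fold-change" is read as
|log2FC| > 1 (`fc_threshold`, configurable, since linear-fold > 2 is the
other defensible reading).

Over-representation uses the hypergeometric upper tail P(X ≥ k) for each
gene set with at least `min_size` (20) universe genes, BH across tested
terms, significance at FDR < 0.1. The universe is all genes tested for DE.
The rich factor is k divided by the term's full listed size (not its
universe-restricted size). GO-graph semantic simplification of overlapping
terms requires the ontology DAG and is out of scope; overlapping terms are
reported as-is.

## ssGSEA scoring (`radres.ssgsea`)

For one sample with N genes and a set G, genes are ranked by expression
(average ranks on ties, rank 1 = lowest) and walked in decreasing order;
the score is

  ES = Σᵢ [ P_in^w(i) − P_out(i) ],  P_in^w(i) = Σ_{j≤i, j∈G} r_j^α / Σ_{j∈G} r_j^α,

with P_out the uniform ECDF over out-of-set genes and α = 0.25 (the
reference implementation's default). Scores are divided by (max − min)
across samples by default, again matching that implementation's default
normalization. The statistic depends only on within-sample ranks, so any
per-sample monotone transform leaves it unchanged — but scores are only
comparable among samples scored together on one expression scale, so
cohorts must be scored separately. The bundled
`data/heterochromatin_synthetic.gmt` is a synthetic 91-gene stand-in for
the heterochromatin-formation pathway (gene-set membership is
ontology-version-dependent); real analyses must supply their own GMT.

## Survival analysis (`radres.survival`)

Kaplan–Meier product-limit estimation (subjects censored at an event time
count as at risk there), the k-group log-rank test (hypergeometric
variance, χ² with k − 1 df), and a single-covariate Cox proportional-
hazards fit by damped Newton–Raphson on the Efron-corrected partial
likelihood (Efron being the widely used default for ties). Monotone
likelihood/separation is detected (estimate drifting to the bound or
iteration budget) and reported via `converged=False` rather than a
misleading finite estimate. The covariate is standardized internally for
numerical stability and the estimate back-transformed. Median follow-up
uses the reverse-KM convention (censoring treated as the event); a curve
never reaching 0.5 reports "not reached" as NaN. These primitives are
hand-implemented — the cutoff scan below evaluates thousands of log-rank
tests, and the scan's internal consistency check needs the Cox score test
at β = 0 — and are cross-checked against lifelines in the test suite.

**Cutoff scan.** Candidate thresholds are every interior quantile of the
median/tertile/quartile/quintile schemes ({.5}, {⅓, ⅔}, {.25, .5, .75},
{.2, .4, .6, .8}), linear-interpolation quantiles, deduplicated by value;
"high" is score strictly above the threshold. This superset representation
covers "uppermost-k-groups" splits (a cutoff at the 40th percentile is
"top three quintiles high"). Candidates leaving either arm below
`min_group_frac` (10%) of the cohort are invalid. The selected split
minimizes the log-rank P, ties breaking toward the threshold nearest the
median. Minimum-P selection over multiple looks is an optimistic procedure;
all candidate P-values are reported and labelled unadjusted.

## Assay statistics (`radres.assays`)

*Clonogenic.* PE = colonies/cells plated per replicate;
SF(d) = mean PE(d) / mean PE(0 Gy), so SF at the control dose is exactly 1.
The linear-quadratic model SF(d) = exp(−(B1·d + B2·d²)) is fitted by
default in log space — −ln SF regressed on (d, d²) through the origin —
which is exact on noiseless LQ data and keeps the fit a linear-algebra
identity; curve-fitting software typically fits in linear SF space, so
`space="linear"` is offered and the two agree closely on clean data. A
non-negativity clamp is reported when active. B1 is in Gy⁻¹, B2 in Gy⁻².

*Foci.* The pairing unit for the paired two-tailed t-test is the replicate:
per-replicate mean foci/cell are paired across conditions (per-cell pairing
across conditions is meaningless). Samples under `min_cells` (50) cells are
flagged, not dropped. Zero-variance paired differences make t undefined and
raise.

*Intensity.* Per-cell mean gray values (MGV, non-negative) are summarized
by a Gaussian KDE with Silverman's bandwidth on a 512-point grid spanning
[min − 3bw, max + 3bw]; the reported statistic is the trapezoidal mass on
[threshold, end] with threshold 40 MGV (comparison ≥ 40), clipped to [0,1]
after renormalizing the gridded density. Fewer than 80 cells at/above the
threshold triggers a data-sufficiency warning (a scoring convention of the
emulated protocol), not an error.

*qPCR.* ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts the mean
control-condition ΔCt; fold change = 2^(−ΔΔCt). The control-condition mean
therefore always maps to fold change 1.

## Synthetic data (`radres.synth`)

Every generator is a pure function of (parameters, seed) — same call, same
bytes — and returns machine-readable ground truth beside the data. Defaults
are the study conditions the emulated designs state, or a realistic choice
made once:

- **Caller tables**: 3 callers × 3 replicates; per-caller sensitivity 0.9;
  10 unique false sites per (caller, replicate) — unique so false calls can
  never reach consensus, modelling caller-specific artifacts.
- **Signature spectra**: each column is 0.6 × Dirichlet(0.15) spikes +
  0.4 × Dirichlet(5) background. Real SBS spectra put part of their mass in
  a few dominant peaks over a broad background; all-spike columns would
  make refitting artificially ill-conditioned, all-flat ones
  unidentifiable. Catalogues are multinomial draws from the mixture
  spectrum.
- **Counts**: NB via gamma–Poisson; baselines lognormal(μ=5, σ=1) (natural
  log; median ≈ 148 counts), gene-wise dispersion 0.05 (typical for
  genetically identical cell-line replicates), 10% lognormal library-size
  jitter; 3 RR vs 3 WT per line. Planted genes get |log2FC| = 2, same sign
  in every line when shared; their baselines are floored at the
  distribution median because a fold change on a gene at the detection
  floor is not identifiable at n = 3 by any method — the validated common
  DEGs this emulates are well-expressed genes.
- **Cohorts**: a latent N(0,1) per-patient pathway activity shifts the set
  genes (effect 1.5 on a σ=1 expression scale), so the ssGSEA score orders
  patients by activity; event times are exponential (baseline median 24
  months) with hazard × exp(log HR) above the planted score quantile
  (defaults HR 2 at the 60th percentile); censoring is independent
  exponential, calibrated per subject so the expected censored fraction is
  exact (default 30%).
- **Clonogenic**: colonies ~ Poisson(cells × PE₀ × exp(−(B1 d + B2 d²)))
  with B1 = 0.3/Gy, B2 = 0.03/Gy², PE₀ = 0.4, 1000 cells plated, doses
  0/1/2/4 Gy, 3 replicates (the emulated assay's dose ladder and replicate
  count); `poisson_noise=False` returns exact expectations for exactness
  tests.
- **Cell measurements**: foci Poisson with per-condition means 2.40 vs 0.28
  (the scale of the emulated RR-vs-WT contrast); intensities from a normal
  mixture truncated at 0 by resampling, default 0.6·N(25,8) + 0.4·N(50,10)
  (a low/high-MGV mixture with ≈ 0.355 of its mass ≥ 40).

What the generators deliberately do **not** emulate: read-level error
profiles and alignment artifacts (calls are drawn at the site level),
signature spectra of any real catalogue version, expression correlation
structure between genes, batch effects, non-proportional hazards or
informative censoring, and optical segmentation errors. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated models, not robustness to every failure mode of real data.

## Problem sizes

The test suite and acceptance script run the recovery simulations at the
sizes the analyses are specified at: 100 random call sets for the consensus
oracle, 20 two-signature catalogues of 2000 mutations, 20 four-line count
simulations of 5000 genes, 2000 null cohorts for log-rank calibration, 200
cohorts of 400 patients each for Cox recovery and the cutoff scan, 100
Poisson clonogenic experiments, and 5000-cell intensity samples. The full
suite and the acceptance script each complete in about half a minute on one
CPU.

## Known limitations

- The DE test is a two-group Wald test: no covariates, no interaction
  terms, no outlier handling (Cook's-distance-style) — by design.
- The Cox fit is single-covariate; multivariable adjustment, competing
  risks and PH diagnostics are out of scope.
- The signature refit assumes the supplied matrix contains the generating
  signatures; it does not extract signatures de novo.
- The cutoff scan's selected P-value is unadjusted for the scan itself and
  must be interpreted as exploratory, exactly as reported.
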