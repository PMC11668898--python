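"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a seed: the same
call reproduces byte-identical tables. Ground truth (planted variants,
signature weights, DEG directions, hazard structure, LQ parameters) is
always returned alongside the data so downstream stages can be scored
against it. The generators emulate the *statistical* structure of the real
inputs — per-caller sensitivity and false-positive behaviour over
triplicates, multinomial context spectra from signature mixtures,
overdispersed negative-binomial counts, score-dependent hazards, Poisson
colony counts under the linear-quadratic model, and mixture-distributed
per-cell measurements — not raw reads or images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import CountsMatrix
from .signatures import SignatureMatrix
from .ssgsea import GeneSet, SsgseaParams, ssgsea_scores
from .variants import BASES, CONTEXTS_96, VariantCall, revcomp

_CALLERS = ("mutect2", "strelka2", "lancet")


def _rng(seed: int) -> np.random.Generator:
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValueError("seed must be a non-negative integer")
    return np.random.default_rng(int(seed))


# ------------------------------------------------------------ variant calls

@dataclass(frozen=True)
class VariantTruth:
    chrom: str
    pos: int
    ref: str
    alt: str
    is_true_somatic: bool
    context: str  # 3-mer centred on pos
    effect: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def _random_variant(rng, chrom: str, pos: int, effect_probs=(0.6, 0.35, 0.05)) -> VariantTruth:
    ref = rng.choice(BASES)
    alt = rng.choice([b for b in BASES if b != ref])
    flank5, flank3 = rng.choice(BASES), rng.choice(BASES)
    effect = rng.choice(["synonymous", "non_synonymous", "other"], p=list(effect_probs))
    return VariantTruth(
        chrom=chrom, pos=pos, ref=str(ref), alt=str(alt),
        is_true_somatic=True, context=f"{flank5}{ref}{flank3}", effect=str(effect),
    )


def sim_caller_calls(
    n_true: int,
    sens_per_caller: dict[str, float] | None = None,
    fp_per_caller: dict[str, int] | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    sample_id: str = "SIM-RR",
) -> tuple[dict[tuple[str, str], list[VariantCall]], list[VariantTruth]]:
    """Per-(caller, replicate) variant tables with planted true somatic SNVs.

    Each true variant is reported by caller ``c`` in each replicate
    independently with probability ``sens_per_caller[c]``; each (caller,
    replicate) additionally reports ``fp_per_caller[c]`` unique false
    sites (never shared between tables, so they cannot reach consensus).
    """
    if n_true <= 0:
        raise ValueError("n_true must be positive")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    sens = sens_per_caller or {c: 0.9 for c in _CALLERS}
    fps = fp_per_caller or {c: 10 for c in _CALLERS}
    for c, s in sens.items():
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"sensitivity for {c} outside [0,1]")
    rng = _rng(seed)

    positions = rng.choice(np.arange(1, 10_000_001), size=n_true, replace=False)
    truth = [_random_variant(rng, "chr1", int(p)) for p in np.sort(positions)]

    fp_pos = iter(
        rng.choice(np.arange(20_000_001, 40_000_001),
                   size=sum(fps.values()) * n_replicates, replace=False)
    )
    tables: dict[tuple[str, str], list[VariantCall]] = {}
    for caller in sorted(sens):
        for rep_i in range(1, n_replicates + 1):
            rep = f"rep{rep_i}"
            calls: list[VariantCall] = []
            detected = rng.random(n_true) < sens[caller]
            for v, hit in zip(truth, detected):
                if hit:
                    calls.append(
                        VariantCall(
                            sample_id=sample_id, replicate_id=rep, caller_id=caller,
                            chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                            effect=v.effect, context=v.context,
                        )
                    )
            for _ in range(fps.get(caller, 0)):
                fv = _random_variant(rng, "chr2", int(next(fp_pos)))
                calls.append(
                    VariantCall(
                        sample_id=sample_id, replicate_id=rep, caller_id=caller,
                        chrom=fv.chrom, pos=fv.pos, ref=fv.ref, alt=fv.alt,
                        effect=fv.effect, context=fv.context,
                    )
                )
            tables[(caller, rep)] = calls
    return tables, truth


def write_truth_variants(truth: list[VariantTruth], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
             "is_true_somatic": int(v.is_true_somatic), "context": v.context,
             "effect": v.effect}
            for v in truth
        ]
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------- signature matrices

def sim_signature_matrix(
    n_signatures: int = 10,
    seed: int = 0,
    spike_fraction: float = 0.6,
    spike_concentration: float = 0.15,
    background_concentration: float = 5.0,
) -> SignatureMatrix:
    """Random signature spectra over the 96 contexts.

    Real SBS spectra concentrate part of their mass in a few dominant
    context peaks on top of a broad background across many contexts; each
    synthetic column is accordingly a ``spike_fraction`` mixture of a
    sparse Dirichlet draw (the peaks) and a near-uniform Dirichlet draw
    (the background). Purely spiky columns (3-4 nonzero bins) would be an
    unrealistically ill-conditioned refitting problem; purely flat ones
    would be unidentifiable.
    """
    rng = _rng(seed)
    spikes = rng.dirichlet(np.full(96, spike_concentration), size=n_signatures).T
    background = rng.dirichlet(np.full(96, background_concentration), size=n_signatures).T
    mat = spike_fraction * spikes + (1.0 - spike_fraction) * background
    names = [f"S{i + 1:02d}" for i in range(n_signatures)]
    return SignatureMatrix(names=names, matrix=mat)


def sim_catalogue(
    weights: dict[str, float],
    n_mutations: int,
    sig_matrix: SignatureMatrix,
    seed: int = 0,
) -> pd.Series:
    """Multinomial 96-context catalogue from a signature mixture."""
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    total_w = sum(weights.values())
    if abs(total_w - 1.0) > 1e-9:
        raise ValueError(f"mixture weights must sum to 1, got {total_w}")
    missing = set(weights) - set(sig_matrix.names)
    if missing:
        raise ValueError(f"signatures not in matrix: {sorted(missing)}")
    spectrum = np.zeros(96)
    for name, w in weights.items():
        spectrum += w * sig_matrix.column(name)
    rng = _rng(seed)
    counts = rng.multinomial(n_mutations, spectrum / spectrum.sum())
    return pd.Series(counts, index=list(CONTEXTS_96), name="count")


# ------------------------------------------------------------------- counts

@dataclass
class PlantedGene:
    gene: str
    log2fc: float
    shared: bool  # same-direction effect in every cell line vs one line only


def sim_counts(
    n_genes: int = 5000,
    n_per_group: int = 3,
    n_cell_lines: int = 4,
    planted: list[PlantedGene] | None = None,
    dispersion: float = 0.05,
    seed: int = 0,
    baseline_log_mean: float = 5.0,
    baseline_log_sd: float = 1.0,
    planted_min_baseline: float | None = None,
) -> tuple[dict[str, CountsMatrix], pd.DataFrame]:
    """Negative-binomial RR-vs-WT count matrices, one per cell line.

    Baselines are lognormal(``baseline_log_mean``, ``baseline_log_sd``)
    per gene and cell line; counts are gamma-Poisson with the given
    dispersion. Planted genes with ``shared=True`` receive their log2 fold
    change (same sign) in every cell line; non-shared planted genes in one
    cell line only (assigned round-robin). Planted genes are placed on
    adequately expressed genes: their baselines are floored at
    ``planted_min_baseline`` (default the baseline distribution median,
    exp(baseline_log_mean)) — a fold change on a gene at the detection
    floor is not identifiable at small n by any test, and the validated
    common dysregulated genes this emulates are well-expressed. Returns the
    matrices and a truth table (gene, log2fc, shared, cell_line or 'all').
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (within-group variance needed)")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    planted = planted or []
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}
    for pg in planted:
        if pg.gene not in gene_index:
            raise ValueError(f"planted gene {pg.gene!r} outside the gene universe")
    rng = _rng(seed)
    cell_lines = [f"CL{i + 1}" for i in range(n_cell_lines)]

    truth_rows = []
    effects: dict[str, dict[str, float]] = {cl: {} for cl in cell_lines}
    unshared_i = 0
    for pg in planted:
        if pg.shared:
            for cl in cell_lines:
                effects[cl][pg.gene] = pg.log2fc
            truth_rows.append({"gene": pg.gene, "log2fc": pg.log2fc,
                               "shared": True, "cell_line": "all"})
        else:
            cl = cell_lines[unshared_i % n_cell_lines]
            unshared_i += 1
            effects[cl][pg.gene] = pg.log2fc
            truth_rows.append({"gene": pg.gene, "log2fc": pg.log2fc,
                               "shared": False, "cell_line": cl})

    if planted_min_baseline is None:
        planted_min_baseline = float(np.exp(baseline_log_mean))
    matrices: dict[str, CountsMatrix] = {}
    for cl in cell_lines:
        base = rng.lognormal(baseline_log_mean, baseline_log_sd, size=n_genes)
        for pg in planted:
            i = gene_index[pg.gene]
            base[i] = max(base[i], planted_min_baseline)
        mu = np.tile(base[:, None], (1, 2 * n_per_group))
        for gene, lfc in effects[cl].items():
            mu[gene_index[gene], :n_per_group] *= 2.0 ** lfc  # RR samples first
        # library-size variation across samples
        lib = rng.lognormal(0.0, 0.1, size=2 * n_per_group)
        mu = mu * lib
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        counts = rng.poisson(lam)
        samples = [f"{cl}-RR-{i + 1}" for i in range(n_per_group)] + [
            f"{cl}-WT-{i + 1}" for i in range(n_per_group)
        ]
        meta = pd.DataFrame(
            {
                "cell_line": cl,
                "phenotype": ["RR"] * n_per_group + ["WT"] * n_per_group,
            },
            index=pd.Index(samples, name="sample_id"),
        )
        matrices[cl] = CountsMatrix(
            counts=pd.DataFrame(counts, index=genes, columns=samples), meta=meta
        )
    truth = pd.DataFrame(truth_rows, columns=["gene", "log2fc", "shared", "cell_line"])
    return matrices, truth


# ------------------------------------------------------------------ cohorts

@dataclass
class CohortTruth:
    true_log_hazard_ratio: float = float(np.log(2.0))
    true_threshold_quantile: float = 0.6
    censoring_fraction: float = 0.3

    def __post_init__(self):
        if not 0.0 < self.true_threshold_quantile < 1.0:
            raise ValueError("true_threshold_quantile must be in (0,1)")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring_fraction must be in [0,1)")


def sim_cohort(
    n_patients: int = 400,
    gene_set: GeneSet | None = None,
    truth: CohortTruth | None = None,
    seed: int = 0,
    n_background_genes: int = 300,
    baseline_median_months: float = 24.0,
    activity_effect: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Expression + clinical tables whose hazard depends on a gene-set score.

    A latent per-patient pathway activity shifts the set genes' expression;
    the ssGSEA score of the set therefore orders patients by activity. Event
    times are exponential with the hazard multiplied by
    exp(true_log_hazard_ratio) for patients whose score exceeds the
    ``true_threshold_quantile`` of the score distribution. Censoring is
    independent and exponential, calibrated per subject so the expected
    censored fraction equals ``censoring_fraction``.
    """
    if n_patients < 20:
        raise ValueError("n_patients must be >= 20")
    truth = truth or CohortTruth()
    if gene_set is None:
        gene_set = GeneSet("HETEROCHROMATIN_SYN", frozenset(f"HET{i:03d}" for i in range(30)))
    if not gene_set.genes:
        raise ValueError("gene set must be non-empty")
    rng = _rng(seed)
    set_genes = sorted(gene_set.genes)
    bg_genes = [f"BG{i + 1:04d}" for i in range(n_background_genes)]
    patients = [f"P{i + 1:04d}" for i in range(n_patients)]

    activity = rng.normal(0.0, 1.0, size=n_patients)
    base_set = rng.normal(8.0, 1.0, size=len(set_genes))
    base_bg = rng.normal(8.0, 1.0, size=len(bg_genes))
    expr_set = base_set[:, None] + activity_effect * activity[None, :] + rng.normal(
        0.0, 1.0, size=(len(set_genes), n_patients)
    )
    expr_bg = base_bg[:, None] + rng.normal(0.0, 1.0, size=(len(bg_genes), n_patients))
    expr = pd.DataFrame(
        np.vstack([expr_set, expr_bg]), index=set_genes + bg_genes, columns=patients
    )

    scores = ssgsea_scores(expr, gene_set, SsgseaParams())
    threshold = float(np.quantile(scores, truth.true_threshold_quantile))
    high = scores.to_numpy() > threshold

    lam0 = np.log(2.0) / baseline_median_months
    lam = lam0 * np.exp(truth.true_log_hazard_ratio * high)
    event_time = rng.exponential(1.0 / lam)
    c = truth.censoring_fraction
    if c > 0:
        cens_rate = lam * c / (1.0 - c)
        cens_time = rng.exponential(1.0 / cens_rate)
    else:
        cens_time = np.full(n_patients, np.inf)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)

    clinical = pd.DataFrame(
        {
            "patient_id": patients,
            "time_months": time,
            "event": event,
            "score": scores.to_numpy(),
        }
    )
    truth_out = {
        "true_log_hazard_ratio": truth.true_log_hazard_ratio,
        "true_threshold_quantile": truth.true_threshold_quantile,
        "true_threshold_value": threshold,
        "censoring_fraction": truth.censoring_fraction,
        "high_mask": high,
    }
    return expr, clinical, truth_out


# --------------------------------------------------------------- clonogenic

def sim_clonogenic(
    b1: float = 0.3,
    b2: float = 0.03,
    pe0: float = 0.4,
    doses: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0),
    cells_plated: int = 1000,
    n_replicates: int = 3,
    seed: int = 0,
    arm: str = "RR",
    poisson_noise: bool = True,
) -> pd.DataFrame:
    """Colony counts under the linear-quadratic survival model.

    Expected colonies at dose d: cells_plated * pe0 * exp(-(b1 d + b2 d^2));
    observed counts are Poisson unless ``poisson_noise=False``, which
    returns the exact expectations (variance-free mode for exactness tests).
    """
    if not 0.0 < pe0 <= 1.0:
        raise ValueError("pe0 must be in (0,1]")
    if any(d < 0 for d in doses):
        raise ValueError("doses must be >= 0")
    rng = _rng(seed)
    rows = []
    for d in doses:
        expected = cells_plated * pe0 * np.exp(-(b1 * d + b2 * d * d))
        for rep in range(1, n_replicates + 1):
            colonies = rng.poisson(expected) if poisson_noise else expected
            rows.append(
                {"arm": arm, "dose": float(d), "cells_plated": cells_plated,
                 "colonies": colonies, "replicate": f"rep{rep}"}
            )
    return pd.DataFrame(rows)


# -------------------------------------------------------- cell measurements

def _truncated_mixture(rng, n, mixture):
    weights = np.array([w for w, _, _ in mixture], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    if any(sd <= 0 for _, _, sd in mixture):
        raise ValueError("mixture sds must be > 0")
    out = np.empty(n)
    filled = 0
    while filled < n:
        comp = rng.choice(len(mixture), size=n - filled, p=weights)
        draw = np.array([rng.normal(mixture[c][1], mixture[c][2]) for c in comp])
        ok = draw >= 0  # MGV is a non-negative pixel mean; resample below 0
        take = draw[ok]
        out[filled:filled + take.size] = take
        filled += take.size
    return out


def sim_cell_measurements(
    n_cells: int = 50,
    foci_mean_per_condition: dict[str, float] | None = None,
    intensity_mixture: list[tuple[float, float, float]] | None = None,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell foci counts and intensity measurements.

    Foci counts are Poisson with a per-condition mean (defaults 2.40 vs
    0.28, the scale of H3K27me3 foci in RR vs WT cells); intensities are
    drawn from a normal mixture truncated at 0 (default
    0.6 N(25,8) + 0.4 N(50,10), a low/high-MGV mixture with roughly a third
    of its mass at or above 40).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    foci_means = foci_mean_per_condition or {"RR": 2.40, "WT": 0.28}
    mixture = intensity_mixture or [(0.6, 25.0, 8.0), (0.4, 50.0, 10.0)]
    rng = _rng(seed)
    foci_rows = []
    intensity_rows = []
    for cond in sorted(foci_means):
        for rep in range(1, n_replicates + 1):
            counts = rng.poisson(foci_means[cond], size=n_cells)
            intens = _truncated_mixture(rng, n_cells, mixture)
            for i in range(n_cells):
                cell = f"{cond}-rep{rep}-c{i + 1:03d}"
                foci_rows.append(
                    {"cell_id": cell, "condition": cond, "replicate": f"rep{rep}",
                     "foci": int(counts[i])}
                )
                intensity_rows.append(
                    {"cell_id": cell, "condition": cond, "replicate": f"rep{rep}",
                     "intensity": float(intens[i])}
                )
    return pd.DataFrame(foci_rows), pd.DataFrame(intensity_rows)
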