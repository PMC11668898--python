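"""End-to-end orchestration of the radioresistance analysis stages.

A run is described by a single plain-text (YAML) config: a global seed, an
output directory, the stages to execute, and per-stage parameters (all
defaulting to the values documented on the stage functions). Stages run in
dependency order:

    variants    simulate caller tables -> consensus -> effect counts -> catalogue
    signatures  simulate catalogue from a mixture -> refit -> overfit guard
    de          simulate counts -> per-line NB Wald -> intersection -> ORA
    survival    simulate cohort -> ssGSEA scores -> cutoff scan -> KM/Cox
    assays      simulate colonies/foci/intensities/qPCR -> LQ, t-test, KDE-AUC

Every output file is listed in the run report with its SHA-256 checksum;
rerunning the same config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assays as A
from . import diffexpr as DE
from . import signatures as SIG
from . import ssgsea as SS
from . import survival as SURV
from . import synth as SYN
from . import variants as VAR

STAGE_ORDER = ("variants", "signatures", "de", "survival", "assays")

_DEFAULTS: dict[str, dict] = {
    "variants": {
        "n_true": 120, "n_replicates": 3, "min_callers": 2, "min_replicates": 2,
        "sensitivity": 0.9, "false_positives": 10,
    },
    "signatures": {
        "n_signatures": 8, "mixture": {"S01": 0.6, "S03": 0.4}, "n_mutations": 2000,
        "weight_cutoff": 0.06, "overfit_min_mutations": 50,
    },
    "de": {
        "n_genes": 1200, "n_cell_lines": 4, "n_per_group": 3,
        "n_shared_up": 5, "n_shared_down": 13, "n_private": 20,
        "log2fc": 2.0, "dispersion": 0.05, "alpha": 0.05,
        "ora_min_size": 20, "ora_fdr_cutoff": 0.1,
    },
    "survival": {
        "n_patients": 200, "hazard_ratio": 2.0, "threshold_quantile": 0.6,
        "censoring_fraction": 0.3, "min_group_frac": 0.1,
    },
    "assays": {
        "b1": 0.3, "b2": 0.03, "pe0": 0.4, "doses": [0.0, 1.0, 2.0, 4.0],
        "cells_plated": 1000, "n_replicates": 3, "n_cells": 50,
        "n_cells_intensity": 120, "kde_threshold": 40.0,
    },
}

# fixed per-stage seed offsets so stages are independently reproducible
_SEED_OFFSET = {name: 1000 + i for i, name in enumerate(STAGE_ORDER)}


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "results/run"
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    params: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known_top = {"seed", "outdir", "stages"} | set(STAGE_ORDER)
        unknown = set(raw) - known_top
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        stages = raw.get("stages", list(STAGE_ORDER))
        bad = set(stages) - set(STAGE_ORDER)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        params = {}
        for stage in STAGE_ORDER:
            given = raw.get(stage, {}) or {}
            unknown = set(given) - set(_DEFAULTS[stage])
            if unknown:
                raise ValueError(
                    f"unknown key(s) in stage '{stage}': {sorted(unknown)}"
                )
            params[stage] = {**_DEFAULTS[stage], **given}
        return cls(
            seed=int(raw.get("seed", 1)),
            outdir=str(raw.get("outdir", "results/run")),
            stages=[s for s in STAGE_ORDER if s in stages],
            params=params,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return {"seed": self.seed, "outdir": self.outdir, "stages": list(self.stages),
                **{s: self.params.get(s, {}) for s in self.stages}}


@dataclass
class RunReport:
    seed: int
    config: dict
    versions: dict[str, str]
    stages: dict[str, dict] = field(default_factory=dict)
    manifest: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "config": self.config, "versions": self.versions,
            "stages": self.stages, "manifest": self.manifest, "warnings": self.warnings,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _register(report: RunReport, path: Path) -> None:
    report.manifest.append({"path": str(path), "sha256": _sha256(path)})


def _stage_variants(cfg: RunConfig, out: Path, report: RunReport) -> dict:
    p = cfg.params["variants"]
    seed = cfg.seed + _SEED_OFFSET["variants"]
    sens = {c: p["sensitivity"] for c in ("mutect2", "strelka2", "lancet")}
    fps = {c: p["false_positives"] for c in sens}
    tables, truth = SYN.sim_caller_calls(
        n_true=p["n_true"], sens_per_caller=sens, fp_per_caller=fps,
        n_replicates=p["n_replicates"], seed=seed,
    )
    all_calls = [c for calls in tables.values() for c in calls]
    VAR.write_variant_table(all_calls, out / "caller_calls.tsv")
    SYN.write_truth_variants(truth, out / "truth_variants.tsv")
    consensus = VAR.consensus_filter(
        all_calls, min_callers=p["min_callers"], min_replicates=p["min_replicates"]
    )
    effects = VAR.count_by_effect(consensus, all_calls)
    contexts = {v.key: v.context for v in truth}
    contexts.update({c.key: c.context for c in all_calls if c.context})
    catalogue = VAR.build_96_catalogue(consensus, contexts)
    VAR.write_catalogue(catalogue, out / "consensus_catalogue.tsv")
    truth_keys = {v.key for v in truth}
    recovered = sum(1 for v in consensus if v.key in truth_keys)
    for f in ("caller_calls.tsv", "truth_variants.tsv", "consensus_catalogue.tsv"):
        _register(report, out / f)
    return {
        "n_true": p["n_true"], "n_consensus": len(consensus),
        "n_true_recovered": recovered, "effect_counts": effects,
        "catalogue_total": int(catalogue.sum()),
    }


def _stage_signatures(cfg: RunConfig, out: Path, report: RunReport) -> dict:
    p = cfg.params["signatures"]
    seed = cfg.seed + _SEED_OFFSET["signatures"]
    sigs = SYN.sim_signature_matrix(n_signatures=p["n_signatures"], seed=seed)
    SIG.write_signature_matrix(sigs, out / "signature_matrix.tsv")
    catalogue = SYN.sim_catalogue(p["mixture"], p["n_mutations"], sigs, seed=seed + 1)
    VAR.write_catalogue(catalogue, out / "mixture_catalogue.tsv")
    exposure = SIG.refit_signatures(catalogue, sigs, weight_cutoff=p["weight_cutoff"])
    exposure = SIG.apply_overfit_guard(exposure, min_mutations=p["overfit_min_mutations"])
    (out / "exposure.json").write_text(json.dumps(exposure.to_dict(), indent=2))
    errors = {
        name: abs(exposure.weights.get(name, 0.0) - w) for name, w in p["mixture"].items()
    }
    for f in ("signature_matrix.tsv", "mixture_catalogue.tsv", "exposure.json"):
        _register(report, out / f)
    return {
        "true_mixture": p["mixture"], "fitted_weights": exposure.weights,
        "residual_sse": exposure.residual_sse,
        "mean_abs_weight_error": float(np.mean(list(errors.values()))),
        "flagged_overfit": exposure.flagged_overfit,
    }


def _stage_de(cfg: RunConfig, out: Path, report: RunReport) -> dict:
    p = cfg.params["de"]
    seed = cfg.seed + _SEED_OFFSET["de"]
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(p["n_genes"])]
    chosen = rng.choice(p["n_genes"], size=p["n_shared_up"] + p["n_shared_down"] + p["n_private"],
                        replace=False)
    planted = []
    i = 0
    for _ in range(p["n_shared_up"]):
        planted.append(SYN.PlantedGene(genes[chosen[i]], p["log2fc"], True)); i += 1
    for _ in range(p["n_shared_down"]):
        planted.append(SYN.PlantedGene(genes[chosen[i]], -p["log2fc"], True)); i += 1
    for j in range(p["n_private"]):
        sign = 1.0 if j % 2 == 0 else -1.0
        planted.append(SYN.PlantedGene(genes[chosen[i]], sign * p["log2fc"], False)); i += 1
    matrices, truth = SYN.sim_counts(
        n_genes=p["n_genes"], n_per_group=p["n_per_group"],
        n_cell_lines=p["n_cell_lines"], planted=planted,
        dispersion=p["dispersion"], seed=seed,
    )
    truth.to_csv(out / "truth_degs.tsv", sep="\t", index=False)
    deg_sets, de_tables = {}, {}
    for cl, cm in matrices.items():
        de = DE.nb_wald_de(cm)
        de_tables[cl] = de
        DE.write_de_table(de, out / f"de_{cl}.tsv")
        deg_sets[cl] = DE.select_degs(de, alpha=p["alpha"])
    common = DE.intersect_common_degs(deg_sets, de_tables=de_tables)
    pd.DataFrame(
        sorted(common.genes.items()), columns=["gene", "direction"]
    ).to_csv(out / "common_degs.tsv", sep="\t", index=False)

    shared_truth = truth[truth["shared"]]
    truth_dirs = {r.gene: ("up" if r.log2fc > 0 else "down")
                  for r in shared_truth.itertuples()}
    recovered = sum(1 for g, d in truth_dirs.items() if common.genes.get(g) == d)

    # ORA against synthetic GO-like sets: one term spiked with the planted
    # shared genes, the rest random
    universe = set(de_tables[list(de_tables)[0]].index)
    spiked = set(truth_dirs) | set(rng.choice(sorted(universe), size=30, replace=False))
    gene_sets = {"TERM_SPIKED": spiked}
    for t in range(10):
        gene_sets[f"TERM_RAND{t:02d}"] = set(
            rng.choice(sorted(universe), size=40, replace=False)
        )
    ora = DE.ora_enrich(set(common.genes), universe, gene_sets,
                        min_size=p["ora_min_size"], fdr_cutoff=p["ora_fdr_cutoff"])
    ora.to_csv(out / "ora_results.tsv", sep="\t")
    for f in ("truth_degs.tsv", "common_degs.tsv", "ora_results.tsv"):
        _register(report, out / f)
    return {
        "n_shared_planted": len(truth_dirs),
        "n_common": len(common.genes), "n_up": common.n_up, "n_down": common.n_down,
        "n_planted_recovered": recovered,
        "recovery_fraction": recovered / max(len(truth_dirs), 1),
        "ora_top_term": str(ora.index[0]) if len(ora) else None,
        "ora_top_fdr": float(ora["fdr"].iloc[0]) if len(ora) else None,
    }


def _stage_survival(cfg: RunConfig, out: Path, report: RunReport) -> dict:
    p = cfg.params["survival"]
    seed = cfg.seed + _SEED_OFFSET["survival"]
    truth = SYN.CohortTruth(
        true_log_hazard_ratio=float(np.log(p["hazard_ratio"])),
        true_threshold_quantile=p["threshold_quantile"],
        censoring_fraction=p["censoring_fraction"],
    )
    expr, clinical, truth_out = SYN.sim_cohort(
        n_patients=p["n_patients"], truth=truth, seed=seed
    )
    SS.write_expression(expr, out / "cohort_expression.tsv")
    SURV.write_clinical(clinical, out / "cohort_clinical.tsv")
    t = clinical["time_months"].to_numpy()
    e = clinical["event"].to_numpy()
    s = clinical["score"].to_numpy()
    scan = SURV.scan_cutoffs(t, e, s, min_group_frac=p["min_group_frac"])
    scan.candidates.to_csv(out / "cutoff_scan.tsv", sep="\t", index=False)
    sel = scan.selected_row
    high = s > sel["threshold"]
    cox = SURV.cox_fit(t, e, high.astype(float))
    followup = SURV.reverse_km_followup(t, e)
    for f in ("cohort_expression.tsv", "cohort_clinical.tsv", "cutoff_scan.tsv"):
        _register(report, out / f)
    return {
        "n_patients": p["n_patients"],
        "true_threshold_quantile": p["threshold_quantile"],
        "selected_scheme": str(sel["scheme"]),
        "selected_quantile": float(sel["quantile_level"]),
        "selected_threshold": float(sel["threshold"]),
        "selected_logrank_p": float(sel["logrank_p"]),
        "hazard_ratio": cox.hr, "hr_ci95": list(cox.ci95),
        "median_followup_months": followup,
    }


def _stage_assays(cfg: RunConfig, out: Path, report: RunReport) -> dict:
    p = cfg.params["assays"]
    seed = cfg.seed + _SEED_OFFSET["assays"]
    colonies = SYN.sim_clonogenic(
        b1=p["b1"], b2=p["b2"], pe0=p["pe0"], doses=tuple(p["doses"]),
        cells_plated=p["cells_plated"], n_replicates=p["n_replicates"], seed=seed,
    )
    colonies.to_csv(out / "colonies.csv", index=False)
    clono = A.surviving_fractions(colonies)
    clono = A.fit_lq_result(clono, arm="RR")
    foci, _ = SYN.sim_cell_measurements(
        n_cells=p["n_cells"], n_replicates=p["n_replicates"], seed=seed + 1
    )
    _, intensities = SYN.sim_cell_measurements(
        n_cells=p["n_cells_intensity"], n_replicates=p["n_replicates"], seed=seed + 2
    )
    foci.to_csv(out / "foci.csv", index=False)
    intensities.to_csv(out / "intensities.csv", index=False)
    fs = A.foci_summary(foci, "RR", "WT")
    kde = A.intensity_kde_auc(
        intensities.loc[intensities["condition"] == "RR", "intensity"].to_numpy(),
        threshold=p["kde_threshold"],
    )
    qpcr = pd.DataFrame(
        [
            {"sample": f"ctrl{r}", "gene": g, "ct": ct, "is_control_condition": True}
            for r in (1, 2, 3) for g, ct in (("BAHD1", 25.0), ("GAPDH", 20.0))
        ]
        + [
            {"sample": f"rr{r}", "gene": g, "ct": ct, "is_control_condition": False}
            for r in (1, 2, 3) for g, ct in (("BAHD1", 24.0), ("GAPDH", 20.0))
        ]
    )
    fold = A.ddct_fold_change(qpcr, "BAHD1", "GAPDH")
    for f in ("colonies.csv", "foci.csv", "intensities.csv"):
        _register(report, out / f)
    return {
        "lq_b1": clono.b1, "lq_b2": clono.b2,
        "true_b1": p["b1"], "true_b2": p["b2"],
        "sf_2gy": clono.sf_at("RR", 2.0) if 2.0 in p["doses"] else None,
        "foci_mean_rr": fs.mean_a, "foci_mean_wt": fs.mean_b, "foci_p": fs.p,
        "kde_auc_above": kde.auc_above,
        "qpcr_fold_change_rr": float(fold[[s for s in fold.index if s.startswith("rr")]].mean()),
    }


_STAGE_FUNCS = {
    "variants": _stage_variants,
    "signatures": _stage_signatures,
    "de": _stage_de,
    "survival": _stage_survival,
    "assays": _stage_assays,
}


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages in dependency order and report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        seed=config.seed,
        config=config.to_dict(),
        versions={
            "radres": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    )
    for stage in config.stages:
        t0 = _time.perf_counter()
        try:
            summary = _STAGE_FUNCS[stage](config, out, report)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        summary["elapsed_s"] = round(_time.perf_counter() - t0, 3)
        report.stages[stage] = summary
    return report


def write_report(report: RunReport, path: str | Path) -> None:
    """Write the machine-readable JSON report and a text summary twin."""
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=2, default=str))
    lines = [f"radres run report (seed={report.seed})", ""]
    for stage, summary in report.stages.items():
        lines.append(f"[{stage}]")
        for k, v in summary.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
    lines.append("outputs:")
    for entry in report.manifest:
        lines.append(f"  {entry['path']}  sha256={entry['sha256'][:12]}")
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")


def demo_config(outdir: str = "results/demo", seed: int = 1) -> RunConfig:
    """The bundled all-synthetic demo configuration."""
    return RunConfig.from_dict({"seed": seed, "outdir": outdir})
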