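"""Radiobiology assay statistics.

Clonogenic survival: plating efficiency PE = colonies / cells plated per
replicate; surviving fraction SF(d) = mean PE(d) / mean PE(0 Gy); the
linear-quadratic model SF(d) = exp(-(B1 d + B2 d^2)) is fitted as a linear
least-squares problem for (B1, B2) on -ln SF against (d, d^2) through the
origin (the model itself forces SF(0)=1), optionally in linear SF space.

Immunofluorescence: per-condition foci counts are summarized as replicate
means and compared with a paired two-tailed t-test across replicates;
per-cell mean-gray-value (MGV) intensities are summarized by a Gaussian KDE
(Silverman bandwidth) and the probability mass at or above a threshold
(default 40 MGV) reported as the area under the density curve.

qPCR: relative expression by the delta-delta-Ct method,
fold change = 2^-((Ct_target - Ct_ref)_sample - mean (Ct_target - Ct_ref)_control).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit, nnls

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- clonogenic

@dataclass
class ClonogenicResult:
    """Per-replicate PE, per-dose SF, and (optionally) LQ parameters."""

    pe: pd.DataFrame  # columns: arm, dose, replicate, pe
    sf: pd.DataFrame  # columns: arm, dose, sf
    b1: float | None = None
    b2: float | None = None
    clamped: bool = False

    def sf_at(self, arm: str, dose: float) -> float:
        m = self.sf[(self.sf["arm"] == arm) & (self.sf["dose"] == dose)]
        if m.empty:
            raise ValueError(f"no SF for arm {arm!r} at dose {dose}")
        return float(m["sf"].iloc[0])


def surviving_fractions(colonies: pd.DataFrame, control_dose: float = 0.0) -> ClonogenicResult:
    """PE and SF per arm from a colony-count table.

    ``colonies`` needs columns arm, dose, cells_plated, colonies, replicate.
    SF(d) = mean PE(d) / mean PE(control_dose), so SF(control) is exactly 1.
    """
    for col in ("arm", "dose", "cells_plated", "colonies", "replicate"):
        if col not in colonies.columns:
            raise ValueError(f"colony table is missing column '{col}'")
    df = colonies.copy()
    df["pe"] = df["colonies"] / df["cells_plated"]
    if (df["pe"] > 1).any():
        warnings.warn("plating efficiency > 1 for some replicates", stacklevel=2)
    sf_rows = []
    for arm, sub in df.groupby("arm", sort=True):
        mean_pe = sub.groupby("dose")["pe"].mean()
        if control_dose not in mean_pe.index:
            raise ValueError(f"arm {arm!r} has no control dose {control_dose}")
        pe0 = mean_pe[control_dose]
        if pe0 == 0:
            raise ValueError(f"arm {arm!r}: control plating efficiency is 0")
        for dose, pe_d in mean_pe.items():
            sf_rows.append({"arm": arm, "dose": dose, "sf": pe_d / pe0})
    return ClonogenicResult(
        pe=df[["arm", "dose", "replicate", "pe"]],
        sf=pd.DataFrame(sf_rows),
    )


def fit_lq(
    doses, sf, space: str = "log", clamp_nonnegative: bool = True
) -> tuple[float, float, bool]:
    """Fit the linear-quadratic model SF = exp(-(B1 d + B2 d^2)).

    ``space="log"`` (default) solves the linear system -ln SF = B1 d + B2 d^2
    through the origin by least squares; ``space="linear"`` performs
    non-linear least squares on SF directly (the convention of common
    curve-fitting software). Returns ``(b1, b2, clamped)`` where ``clamped``
    reports whether the non-negativity clamp was active.
    """
    doses = np.asarray(doses, dtype=float)
    sf = np.asarray(sf, dtype=float)
    mask = doses > 0
    if np.unique(doses[mask]).size < 2:
        raise ValueError("need >= 2 distinct nonzero doses")
    if np.any(sf[mask] <= 0) or np.any(sf[mask] > 1 + 1e-9):
        raise ValueError("surviving fractions must lie in (0, 1]")
    d, y = doses[mask], -np.log(sf[mask])
    X = np.column_stack([d, d * d])
    if space == "log":
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        clamped = False
        if clamp_nonnegative and np.any(beta < 0):
            beta, _ = nnls(X, y)
            clamped = True
        return float(beta[0]), float(beta[1]), clamped
    if space == "linear":
        def model(dd, b1, b2):
            return np.exp(-(b1 * dd + b2 * dd * dd))
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        popt, _ = curve_fit(model, d, sf[mask], p0=np.clip(beta0, 0, None))
        clamped = False
        if clamp_nonnegative and np.any(popt < 0):
            bounds = ([0, 0], [np.inf, np.inf])
            popt, _ = curve_fit(model, d, sf[mask], p0=[0.1, 0.01], bounds=bounds)
            clamped = True
        return float(popt[0]), float(popt[1]), clamped
    raise ValueError(f"unknown fitting space {space!r}")


def fit_lq_result(result: ClonogenicResult, arm: str, space: str = "log") -> ClonogenicResult:
    """Attach LQ parameters fitted to one arm's SF curve."""
    sub = result.sf[result.sf["arm"] == arm]
    b1, b2, clamped = fit_lq(sub["dose"].to_numpy(), sub["sf"].to_numpy(), space=space)
    return ClonogenicResult(pe=result.pe, sf=result.sf, b1=b1, b2=b2, clamped=clamped)


def sf_ratio(result_a: ClonogenicResult, result_b: ClonogenicResult,
             arm_a: str, arm_b: str, dose: float) -> float:
    """Ratio SF_a(dose) / SF_b(dose) between two arms."""
    sf_b = result_b.sf_at(arm_b, dose)
    if sf_b == 0:
        raise ValueError("denominator surviving fraction is 0")
    return result_a.sf_at(arm_a, dose) / sf_b


# --------------------------------------------------------------------- foci

@dataclass
class FociSummary:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    replicate_means_a: np.ndarray
    replicate_means_b: np.ndarray
    t_statistic: float
    p: float
    flagged_low_n: list[str] = field(default_factory=list)


def foci_summary(
    foci: pd.DataFrame, group_a: str, group_b: str, min_cells: int = 50
) -> FociSummary:
    """Mean foci per cell per condition with a paired two-tailed t-test.

    ``foci`` needs columns condition, replicate, foci (one row per cell).
    The pairing unit is the replicate: per-replicate mean counts are paired
    across the two conditions (replicates matched by id). Samples with fewer
    than ``min_cells`` cells are flagged, not dropped. Zero-variance paired
    differences make the t statistic undefined and raise.
    """
    for col in ("condition", "replicate", "foci"):
        if col not in foci.columns:
            raise ValueError(f"foci table is missing column '{col}'")
    flagged = []
    means = {}
    for cond in (group_a, group_b):
        sub = foci[foci["condition"] == cond]
        if sub.empty:
            raise ValueError(f"no cells for condition {cond!r}")
        per_rep = sub.groupby("replicate")["foci"]
        for rep, cnt in per_rep.size().items():
            if cnt < min_cells:
                flagged.append(f"{cond}/{rep}: {cnt} cells < {min_cells}")
        means[cond] = per_rep.mean()
    a, b = means[group_a].align(means[group_b], join="inner")
    if len(a) < 2:
        raise ValueError("need >= 2 paired replicates")
    diffs = a.to_numpy() - b.to_numpy()
    if np.allclose(diffs, diffs[0]):
        raise ValueError("paired differences have zero variance; t-test undefined")
    t_stat, p = stats.ttest_rel(a.to_numpy(), b.to_numpy())
    if flagged:
        logger.warning("foci_summary: low cell counts: %s", "; ".join(flagged))
    return FociSummary(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        replicate_means_a=a.to_numpy(), replicate_means_b=b.to_numpy(),
        t_statistic=float(t_stat), p=float(p), flagged_low_n=flagged,
    )


# ---------------------------------------------------------------- intensity

@dataclass
class KdeAucResult:
    grid: np.ndarray
    density: np.ndarray
    threshold: float
    auc_above: float
    auc_below: float
    n_cells: int
    n_above_threshold: int


def intensity_kde_auc(
    intensities, threshold: float = 40.0, grid_size: int = 512,
    min_cells_above: int = 80,
) -> KdeAucResult:
    """Gaussian-KDE tail mass of per-cell intensities at/above a threshold.

    Silverman's rule sets the bandwidth; the density is evaluated on a
    ``grid_size``-point grid spanning [min - 3bw, max + 3bw] and the mass on
    [threshold, end] integrated by the trapezoidal rule (clipped to [0,1]).
    Fewer than ``min_cells_above`` cells at/above the threshold triggers a
    data-sufficiency warning.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("need >= 2 distinct intensity values")
    kde = stats.gaussian_kde(x, bw_method="silverman")
    bw = float(kde.factor * x.std(ddof=1))
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_size)
    density = kde(grid)
    total = np.trapezoid(density, grid)
    density = density / total  # renormalize the truncated tail mass away
    above_grid = np.concatenate([[threshold], grid[grid > threshold]])
    if above_grid.size > 1 and threshold <= grid[-1]:
        dens_above = np.concatenate([kde([threshold]) / total, density[grid > threshold]])
        auc_above = float(np.clip(np.trapezoid(dens_above, above_grid), 0.0, 1.0))
    else:
        auc_above = 0.0 if threshold > grid[-1] else 1.0
    n_above = int((x >= threshold).sum())
    if n_above < min_cells_above:
        logger.warning(
            "intensity_kde_auc: only %d cells >= %g (minimum %d recommended)",
            n_above, threshold, min_cells_above,
        )
    return KdeAucResult(
        grid=grid, density=density, threshold=threshold,
        auc_above=auc_above, auc_below=1.0 - auc_above,
        n_cells=x.size, n_above_threshold=n_above,
    )


# --------------------------------------------------------------------- qPCR

def ddct_fold_change(
    qpcr: pd.DataFrame, target_gene: str, reference_gene: str
) -> pd.Series:
    """Per-sample fold change by the delta-delta-Ct method.

    ``qpcr`` needs columns sample, gene, ct, is_control_condition. For each
    sample, dCt = Ct(target) - Ct(reference); ddCt subtracts the mean dCt of
    the control-condition samples; fold change = 2^-ddCt.
    """
    for col in ("sample", "gene", "ct", "is_control_condition"):
        if col not in qpcr.columns:
            raise ValueError(f"qPCR table is missing column '{col}'")
    ct = qpcr.pivot_table(index="sample", columns="gene", values="ct")
    for gene in (target_gene, reference_gene):
        if gene not in ct.columns or ct[gene].isna().any():
            raise ValueError(f"missing Ct values for gene {gene!r}")
    dct = ct[target_gene] - ct[reference_gene]
    control_samples = qpcr.loc[qpcr["is_control_condition"].astype(bool), "sample"].unique()
    if len(control_samples) == 0:
        raise ValueError("no control-condition samples")
    ddct = dct - dct.loc[control_samples].mean()
    return np.power(2.0, -ddct).rename("fold_change")
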