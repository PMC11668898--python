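"""Per-cell-line differential expression and cross-model intersection.

Radioresistant (RR) vs parental wild-type (WT) expression is compared
independently within each cell line with a negative-binomial Wald test
(median-of-ratios size factors, method-of-moments gene-wise dispersion, no
shrinkage), genes are selected at an adjusted-P threshold, and the selected
sets are intersected across cell lines requiring a consistent direction of
dysregulation. Selected gene lists are tested for Gene Ontology term
over-representation with the hypergeometric upper tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

PHENOTYPES = ("RR", "WT")


@dataclass
class CountsMatrix:
    """Gene × sample integer counts with sample metadata.

    ``meta`` is indexed by sample id and carries ``cell_line`` and
    ``phenotype`` (RR or WT) columns.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in counts matrix")
        if not set(self.counts.columns) == set(self.meta.index):
            raise ValueError("counts columns and metadata index must match")
        bad = set(self.meta["phenotype"]) - set(PHENOTYPES)
        if bad:
            raise ValueError(f"unknown phenotypes {sorted(bad)}")

    def subset_cell_line(self, cell_line: str) -> "CountsMatrix":
        meta = self.meta[self.meta["cell_line"] == cell_line]
        if meta.empty:
            raise ValueError(f"no samples for cell line {cell_line!r}")
        return CountsMatrix(self.counts[meta.index], meta)


def write_counts(cm: CountsMatrix, counts_path: str | Path, meta_path: str | Path) -> None:
    cm.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
    cm.meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


def read_counts(counts_path: str | Path, meta_path: str | Path) -> CountsMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountsMatrix(counts, meta)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors.

    The pseudo-reference is the per-gene geometric mean over samples; each
    sample's factor is the median ratio to that reference over genes with a
    positive reference.
    """
    log_counts = np.log(counts.where(counts > 0))
    log_ref = log_counts.mean(axis=1)  # NaN where any sample has a zero
    usable = log_ref.notna()
    if usable.sum() == 0:
        raise ValueError("no gene has positive counts in all samples")
    ratios = log_counts.loc[usable].sub(log_ref[usable], axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def nb_wald_de(
    cm: CountsMatrix, cell_line: str | None = None, dispersion_prior_df: float = 8.0
) -> pd.DataFrame:
    """Negative-binomial Wald test of RR vs WT for one cell line.

    Returns a DataFrame indexed by gene with ``log2fc`` (RR vs WT), ``p``
    and BH-adjusted ``p_adj``. Counts are normalized by median-of-ratios
    size factors; the gene-wise NB dispersion alpha (var = mu + alpha mu^2)
    is a pooled method-of-moments estimate shrunk toward a fitted
    mean-dispersion trend alpha(mu) = a1 + a0/mu (a light-weight analogue of
    the dispersion moderation RNA-seq engines use — with 2+2 residual
    degrees of freedom the raw gene-wise estimate is far too noisy to test
    with, inflating both false positives and false negatives);
    ``dispersion_prior_df`` sets the strength of that shrinkage. The final
    alpha is floored at 1e-8. The Wald statistic is the log2 fold change
    over its delta-method standard error. All-zero genes are excluded
    (logged).
    """
    if cell_line is not None:
        cm = cm.subset_cell_line(cell_line)
    groups = {ph: cm.meta.index[cm.meta["phenotype"] == ph] for ph in PHENOTYPES}
    for ph, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"need >=2 {ph} samples, got {len(idx)}")

    counts = cm.counts.astype(float)
    nonzero = counts.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("nb_wald_de: excluded %d all-zero genes", n_dropped)
    counts = counts.loc[nonzero]

    sf = size_factors(counts)
    norm = counts / sf

    rr, wt = norm[groups["RR"]].to_numpy(), norm[groups["WT"]].to_numpy()
    n_rr, n_wt = rr.shape[1], wt.shape[1]
    mu_rr, mu_wt = rr.mean(axis=1), wt.mean(axis=1)
    var_rr = rr.var(axis=1, ddof=1)
    var_wt = wt.var(axis=1, ddof=1)

    # pooled MoM dispersion: average excess variance over both groups
    mu_bar = (mu_rr + mu_wt) / 2
    excess = ((var_rr - mu_rr) + (var_wt - mu_wt)) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_gene = np.where(mu_bar > 0, excess / np.square(mu_bar), 0.0)
    alpha_gene = np.clip(alpha_gene, 0.0, None)

    # parametric mean-dispersion trend alpha(mu) = a1 + a0/mu, then shrink
    # the noisy gene-wise estimate toward it weighted by residual df
    ok = mu_bar > 0
    design = np.column_stack([np.ones(int(ok.sum())), 1.0 / mu_bar[ok]])
    coef, *_ = np.linalg.lstsq(design, alpha_gene[ok], rcond=None)
    coef = np.clip(coef, 0.0, None)
    alpha_trend = np.clip(
        coef[0] + coef[1] / np.clip(mu_bar, 1e-8, None), 1e-8, None
    )
    df_resid = (n_rr - 1) + (n_wt - 1)
    alpha = (df_resid * alpha_gene + dispersion_prior_df * alpha_trend) / (
        df_resid + dispersion_prior_df
    )
    alpha = np.clip(alpha, 1e-8, None)

    pseudo = 0.5
    log2fc = np.log2(mu_rr + pseudo) - np.log2(mu_wt + pseudo)
    # delta method: var(log mu_hat) ~ (1/mu + alpha) / n per group
    v_rr = (1.0 / (mu_rr + pseudo) + alpha) / n_rr
    v_wt = (1.0 / (mu_wt + pseudo) + alpha) / n_wt
    se_log2 = np.sqrt(v_rr + v_wt) / np.log(2)
    z = log2fc / se_log2
    p = 2 * stats.norm.sf(np.abs(z))
    p_adj = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "p_adj": p_adj}, index=counts.index
    ).rename_axis("gene")


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Ingest an externally produced DE table (gene, log2fc, p, p_adj)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("log2fc", "p", "p_adj"):
        if col not in df.columns:
            raise ValueError(f"DE table {path} is missing column '{col}'")
    return df


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.rename_axis("gene").to_csv(path, sep="\t")


def select_degs(de: pd.DataFrame, alpha: float = 0.05) -> dict[str, str]:
    """Genes with adjusted P strictly below ``alpha``, with direction.

    Returns ``{gene: "up"|"down"}``; genes with log2fc exactly 0 are
    excluded (no direction).
    """
    sig = de[(de["p_adj"] < alpha) & (de["log2fc"] != 0)]
    return {g: ("up" if lfc > 0 else "down") for g, lfc in sig["log2fc"].items()}


@dataclass
class CommonDEGSet:
    """Direction-consistent DEG intersection over a set of cell lines."""

    genes: dict[str, str]  # gene -> direction
    scope: tuple[str, ...]
    n_up: int
    n_down: int
    log2fc: pd.DataFrame | None = None  # per-cell-line log2fc of members
    frac_above_fc: float | None = None  # fraction with |log2fc| > threshold everywhere


def intersect_common_degs(
    deg_sets: dict[str, dict[str, str]],
    scope: set[str] | list[str] | None = None,
    de_tables: dict[str, pd.DataFrame] | None = None,
    fc_threshold: float = 1.0,
) -> CommonDEGSet:
    """Genes significant in every scope cell line with identical direction."""
    if scope is None:
        scope = sorted(deg_sets)
    scope = sorted(scope)
    if not scope:
        raise ValueError("scope must be non-empty")
    missing = set(scope) - set(deg_sets)
    if missing:
        raise ValueError(f"no DEG sets for cell lines {sorted(missing)}")

    common: dict[str, str] = {}
    first, *rest = scope
    for gene, direction in deg_sets[first].items():
        if all(deg_sets[cl].get(gene) == direction for cl in rest):
            common[gene] = direction

    lfc_frame = None
    frac = None
    if de_tables is not None and common:
        lfc_frame = pd.DataFrame(
            {cl: de_tables[cl].loc[list(common), "log2fc"] for cl in scope}
        ).rename_axis("gene")
        frac = float((lfc_frame.abs() > fc_threshold).all(axis=1).mean())

    n_up = sum(1 for d in common.values() if d == "up")
    return CommonDEGSet(
        genes=common,
        scope=tuple(scope),
        n_up=n_up,
        n_down=len(common) - n_up,
        log2fc=lfc_frame,
        frac_above_fc=frac,
    )


def ora_enrich(
    selected: set[str],
    universe: set[str],
    gene_sets: dict[str, set[str]],
    min_size: int = 20,
    fdr_cutoff: float = 0.1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` within gene sets.

    Terms are restricted to the universe; terms with fewer than ``min_size``
    universe genes are not tested. ``rich_factor`` is k over the term's full
    listed size. P-values are upper-tail P(X >= k), BH-adjusted across the
    tested terms.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    N, n = len(universe), len(selected)
    rows = []
    for term, members in gene_sets.items():
        in_universe = members & universe
        K = len(in_universe)
        if K < min_size:
            continue
        k = len(in_universe & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "K_listed": len(members),
                "p": p,
                "rich_factor": k / len(members),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "k", "K", "n", "N", "K_listed", "p", "fdr",
                     "rich_factor", "significant"]
        ).set_index("term")
    df = pd.DataFrame(rows).set_index("term")
    df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = df["fdr"] < fdr_cutoff
    return df.sort_values("p")
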