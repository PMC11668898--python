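"""Single-sample gene-set enrichment (ssGSEA) scoring.

Each sample is scored for one gene set (here the heterochromatin-formation
pathway) from its within-sample expression ranks alone: walking the genes in
decreasing expression order, the score accumulates the gap between the
rank-weighted ECDF of the in-set genes and the uniform ECDF of the out-of-set
genes. Scores are optionally rescaled by the (max - min) over samples,
matching the reference implementation's default. Because the statistic is
rank-based, any per-sample monotone transform of expression leaves it
unchanged — but scores are only comparable between samples processed on the
same expression scale, so cohorts must be scored separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self):
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class SsgseaParams:
    """alpha: rank-weight exponent; normalize: divide by score range."""

    alpha: float = 0.25
    normalize_across_samples: bool = True

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


def load_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file (name, description, genes...), one set per line."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            sets.append(GeneSet(name=fields[0], genes=frozenset(fields[2:])))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description] + sorted(gs.genes)) + "\n")


def _sample_score(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Unnormalized ssGSEA running-sum score for one sample.

    ``values`` are the expression values, ``in_set`` a boolean mask. Genes
    are ranked (average ties, rank 1 = lowest expression) and walked in
    decreasing-expression order; the score is
    sum_i [ P_in^w(i) - P_out(i) ] with in-set genes weighted by rank^alpha.
    """
    n = values.size
    ranks = rankdata(values)  # average ties, 1..n ascending
    order = np.argsort(-ranks, kind="stable")  # decreasing expression
    in_ordered = in_set[order]
    r_ordered = ranks[order]
    w = np.where(in_ordered, np.abs(r_ordered) ** alpha, 0.0)
    total_in = w.sum()
    n_out = n - int(in_set.sum())
    if total_in == 0 or n_out == 0:
        raise ValueError("gene set must be a proper non-empty subset of the genes")
    p_in = np.cumsum(w) / total_in
    p_out = np.cumsum(~in_ordered) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    expr: pd.DataFrame,
    gene_set: GeneSet,
    params: SsgseaParams | None = None,
) -> pd.Series:
    """Per-sample ssGSEA scores for one gene set.

    ``expr`` is gene × sample. Set genes absent from the matrix are dropped
    with a warning; an empty intersection is an error.
    """
    params = params or SsgseaParams()
    if expr.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    present = gene_set.genes & set(expr.index)
    if not present:
        raise ValueError(f"no gene of set {gene_set.name!r} is in the matrix")
    dropped = len(gene_set.genes) - len(present)
    if dropped:
        logger.warning(
            "ssgsea: %d/%d genes of %s absent from the matrix",
            dropped, len(gene_set.genes), gene_set.name,
        )
    in_set = expr.index.isin(present)
    values = expr.to_numpy(dtype=float)
    scores = np.array(
        [_sample_score(values[:, j], in_set, params.alpha) for j in range(values.shape[1])]
    )
    if params.normalize_across_samples:
        span = scores.max() - scores.min()
        if span > 0:
            scores = scores / span
    return pd.Series(scores, index=expr.columns, name="score")


def write_scores(scores: pd.Series, path: str | Path) -> None:
    scores.rename_axis("patient_id").to_csv(path, sep="\t")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.rename_axis("gene").to_csv(path, sep="\t")
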