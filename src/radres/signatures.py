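"""SBS mutational-signature refitting by iterative forward selection.

A mutation catalogue (96 trinucleotide-context counts) is explained as a
non-negative mixture of known signature spectra. Following the established
refitting scheme, signatures are added greedily — at each step the candidate
whose optimal single weight most reduces the squared reconstruction error
joins the model — until the relative improvement falls below ``tol``.
Weights below ``weight_cutoff`` are then discarded and the surviving support
is re-optimized by non-negative least squares. Sparse catalogues (few SNVs)
are prone to overfitting many small signatures; :func:`apply_overfit_guard`
collapses such fits to the single dominant signature and flags them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .variants import CONTEXTS_96

logger = logging.getLogger(__name__)

_GOLDEN = (np.sqrt(5) - 1) / 2


@dataclass
class SignatureMatrix:
    """96 × S matrix of signature spectra; each column sums to 1."""

    names: list[str]
    matrix: np.ndarray  # shape (96, S)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise ValueError(
                f"signature matrix shape {self.matrix.shape} != (96, {len(self.names)})"
            )
        if np.any(self.matrix < 0):
            raise ValueError("signature spectra must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each signature column must sum to 1 (±1e-6)")

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(CONTEXTS_96), columns=self.names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureMatrix":
        if list(df.index) != list(CONTEXTS_96):
            raise ValueError("signature table must be indexed by the 96 COSMIC contexts")
        return cls(names=list(df.columns), matrix=df.to_numpy(dtype=float))


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    return SignatureMatrix.from_frame(pd.read_csv(path, sep="\t", index_col=0))


def write_signature_matrix(sigs: SignatureMatrix, path: str | Path) -> None:
    sigs.to_frame().rename_axis("context").to_csv(path, sep="\t")


@dataclass
class SignatureExposure:
    """Fitted signature weights for one catalogue."""

    weights: dict[str, float]
    residual_sse: float
    n_mutations: int
    flagged_overfit: bool = False
    removed_by_guard: list[str] = field(default_factory=list)
    sse_path: list[float] = field(default_factory=list)  # SSE after each forward step

    def to_dict(self) -> dict:
        return {
            "weights": dict(self.weights),
            "residual_sse": self.residual_sse,
            "n_mutations": self.n_mutations,
            "flagged_overfit": self.flagged_overfit,
            "removed_by_guard": list(self.removed_by_guard),
        }


def _sse(p: np.ndarray, recon: np.ndarray) -> float:
    d = p - recon
    return float(d @ d)


def _golden_section(f, lo: float, hi: float, tol: float = 1e-7) -> float:
    """Minimize a unimodal scalar function on [lo, hi]."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    return (a + b) / 2


def refit_signatures(
    catalogue: pd.Series | np.ndarray,
    sigs: SignatureMatrix,
    weight_cutoff: float = 0.06,
    tol: float = 1e-3,
) -> SignatureExposure:
    """Fit non-negative signature weights to a catalogue.

    The catalogue is normalized to a probability spectrum p; the fit
    minimizes ``||p - S w||^2`` with w ≥ 0 and Σw ≤ 1. Greedy forward
    selection (candidate weight by golden-section search, others fixed) is
    followed by discarding weights < ``weight_cutoff`` and an NNLS
    re-optimization on the retained support, iterated until all surviving
    weights clear the cutoff. Ties between candidates break to the
    lexicographically smallest signature id.
    """
    counts = np.asarray(
        catalogue.to_numpy() if isinstance(catalogue, pd.Series) else catalogue,
        dtype=float,
    )
    if counts.shape != (96,):
        raise ValueError("catalogue must have 96 entries")
    total = counts.sum()
    if total <= 0:
        raise ValueError("catalogue total must be > 0")
    p = counts / total
    S = sigs.matrix
    order = np.argsort(np.array(sigs.names))  # deterministic candidate order

    w = np.zeros(S.shape[1])
    sse = _sse(p, np.zeros(96))
    sse_path = [sse]
    while True:
        budget = 1.0 - w.sum()
        if budget <= 1e-12:
            break
        base = S @ w
        best = None  # (sse, name_for_tiebreak, idx, weight)
        for j in order:
            col = S[:, j]
            # candidate already in model: re-optimize its own weight too
            lo = 0.0
            hi = min(1.0, w[j] + budget)
            a_star = _golden_section(lambda a: _sse(p, base + (a - w[j]) * col), lo, hi)
            cand_sse = _sse(p, base + (a_star - w[j]) * col)
            key = (cand_sse, sigs.names[j])
            if best is None or key < best[0]:
                best = (key, j, a_star)
        (cand_sse, _), j, a_star = best
        if sse > 0 and (sse - cand_sse) / sse < tol:
            break
        w[j] = a_star
        sse = cand_sse
        sse_path.append(sse)

    # cutoff + NNLS re-optimization on the surviving support, iterated
    while True:
        support = np.flatnonzero(w >= weight_cutoff)
        if support.size == 0:
            # keep the single best signature rather than return an empty fit
            support = np.array([int(np.argmax(w))]) if w.max() > 0 else np.array([], dtype=int)
        if support.size == 0:
            w_final = np.zeros_like(w)
            break
        sol, _ = nnls(S[:, support], p)
        if sol.sum() > 1.0:
            # project onto {w >= 0, sum w = 1} via a penalty row (sampling
            # noise can push the unconstrained optimum slightly past 1)
            rho = 1e4
            A = np.vstack([S[:, support], rho * np.ones(support.size)])
            b = np.concatenate([p, [rho]])
            sol, _ = nnls(A, b)
            if sol.sum() > 1.0:  # penalty leaves O(rho^-2) slack
                sol = sol / sol.sum()
        w_final = np.zeros_like(w)
        w_final[support] = sol
        if np.all(sol >= weight_cutoff) or support.size == 1:
            break
        w = w_final

    residual = _sse(p, S @ w_final)
    weights = {
        sigs.names[j]: float(w_final[j]) for j in np.flatnonzero(w_final > 0)
    }
    return SignatureExposure(
        weights=weights,
        residual_sse=residual,
        n_mutations=int(round(total)),
        sse_path=sse_path,
    )


def reconstruct_error(
    exposure: SignatureExposure,
    sigs: SignatureMatrix,
    catalogue: pd.Series | np.ndarray,
) -> float:
    """SSE between the normalized catalogue and the exposure's reconstruction."""
    counts = np.asarray(
        catalogue.to_numpy() if isinstance(catalogue, pd.Series) else catalogue,
        dtype=float,
    )
    p = counts / counts.sum()
    recon = np.zeros(96)
    for name, weight in exposure.weights.items():
        recon += weight * sigs.column(name)
    return _sse(p, recon)


def apply_overfit_guard(
    exposure: SignatureExposure, min_mutations: int = 50
) -> SignatureExposure:
    """Collapse sparse-catalogue fits to the single dominant signature.

    With very few mutations the forward selection can scatter weight over
    several signatures that a larger catalogue would not support; below
    ``min_mutations`` only the largest-weight signature is retained and the
    exposure is flagged.
    """
    if exposure.n_mutations >= min_mutations:
        return exposure
    if not exposure.weights:
        return exposure
    top = max(exposure.weights.items(), key=lambda kv: (kv[1], kv[0]))[0]
    removed = sorted(set(exposure.weights) - {top})
    logger.info(
        "overfit guard: %d mutations < %d, keeping %s, removing %s",
        exposure.n_mutations, min_mutations, top, removed,
    )
    return SignatureExposure(
        weights={top: exposure.weights[top]},
        residual_sse=exposure.residual_sse,
        n_mutations=exposure.n_mutations,
        flagged_overfit=True,
        removed_by_guard=removed,
        sse_path=exposure.sse_path,
    )
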