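"""Survival analysis: Kaplan-Meier, log-rank, Cox PH, and cutoff scanning.

Cohorts are tables with one row per patient (``time_months`` > 0, ``event``
in {0,1}, optionally a per-patient ``score``). The module provides the
product-limit estimator, the reverse-KM median follow-up, the k-group
log-rank test, a single-covariate Cox proportional-hazards fit (Efron tie
correction, Newton-Raphson), and the stepwise quantile cutoff scan that
dichotomizes a continuous score at median/tertile/quartile/quintile
boundaries and picks the split with the smallest log-rank P. The scan is a
multiple-look procedure; reported P-values are deliberately unadjusted and
labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

SCHEMES: dict[str, tuple[float, ...]] = {
    "median": (0.5,),
    "tertile": (1 / 3, 2 / 3),
    "quartile": (0.25, 0.5, 0.75),
    "quintile": (0.2, 0.4, 0.6, 0.8),
}


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("patient_id", "time_months", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical table {path} is missing column '{col}'")
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _validate(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("no records")
    if np.any(time <= 0):
        raise ValueError("times must be > 0")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event must be 0/1")
    return time, event


@dataclass
class KMCurve:
    times: np.ndarray  # distinct event times, increasing
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float:
        """Smallest event time with S <= 0.5; NaN when never reached."""
        below = np.flatnonzero(self.survival <= 0.5)
        return float(self.times[below[0]]) if below.size else float("nan")


def km_estimate(time, event) -> KMCurve:
    """Product-limit survival estimator.

    Subjects censored exactly at an event time are counted at risk at that
    time (the standard convention).
    """
    time, event = _validate(time, event)
    event_times = np.unique(time[event == 1])
    surv, s = [], 1.0
    at_risk = []
    for t in event_times:
        n_t = int((time >= t).sum())
        d_t = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d_t / n_t
        surv.append(s)
        at_risk.append(n_t)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv, dtype=float),
        at_risk=np.asarray(at_risk, dtype=int),
    )


def reverse_km_followup(time, event) -> float:
    """Median follow-up by the reverse Kaplan-Meier method.

    Censoring is treated as the event of interest; returns the median of
    that curve, NaN when the curve never reaches 0.5 (not reached).
    """
    time, event = _validate(time, event)
    return km_estimate(time, 1 - event).median


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


def logrank_test(groups: list[tuple[np.ndarray, np.ndarray]]) -> LogRankResult:
    """k-group log-rank test; ``groups`` is a list of (time, event) pairs."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    parsed = [_validate(t, e) for t, e in groups]
    time = np.concatenate([t for t, _ in parsed])
    event = np.concatenate([e for _, e in parsed])
    label = np.concatenate([np.full(t.size, g) for g, (t, _) in enumerate(parsed)])

    k = len(groups)
    event_times = np.unique(time[event == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k - 1, k - 1))
    for t in event_times:
        at_risk = time >= t
        n = int(at_risk.sum())
        dying = (time == t) & (event == 1)
        d = int(dying.sum())
        n_g = np.array([(at_risk & (label == g)).sum() for g in range(k)], dtype=float)
        d_g = np.array([(dying & (label == g)).sum() for g in range(k)], dtype=float)
        O += d_g
        E += d * n_g / n
        if n > 1:
            f = d * (n - d) / (n - 1)
            p_g = n_g / n
            for a in range(k - 1):
                for b in range(k - 1):
                    V[a, b] += f * (p_g[a] * (1.0 if a == b else 0.0) - p_g[a] * p_g[b])
    diff = (O - E)[: k - 1]
    if k == 2:
        stat = 0.0 if V[0, 0] == 0 else float(diff[0] ** 2 / V[0, 0])
    else:
        stat = float(diff @ np.linalg.pinv(V) @ diff)
    df = k - 1
    return LogRankResult(statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)))


def _efron_quantities(beta, time, event, x):
    """Log partial likelihood, score, and information at beta (Efron ties)."""
    order = np.argsort(-time, kind="stable")  # decreasing time
    t_s, e_s, x_s = time[order], event[order], x[order]
    ebx = np.exp(beta * x_s)
    # cumulative risk-set sums walking times downward
    cs = np.cumsum(ebx)
    csx = np.cumsum(x_s * ebx)
    csxx = np.cumsum(x_s * x_s * ebx)
    ll = 0.0
    U = 0.0
    I = 0.0
    i = 0
    n = t_s.size
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        # block [i, j) shares the time t_s[i]; risk set = indices [0, j)
        dying = np.flatnonzero(e_s[i:j] == 1) + i
        d = dying.size
        if d:
            s_R, sx_R, sxx_R = cs[j - 1], csx[j - 1], csxx[j - 1]
            eD = ebx[dying]
            s_D, sx_D, sxx_D = eD.sum(), (x_s[dying] * eD).sum(), (x_s[dying] ** 2 * eD).sum()
            ll += beta * x_s[dying].sum()
            U += x_s[dying].sum()
            for l in range(d):
                frac = l / d
                phi = s_R - frac * s_D
                phix = sx_R - frac * sx_D
                phixx = sxx_R - frac * sxx_D
                ll -= np.log(phi)
                U -= phix / phi
                I += phixx / phi - (phix / phi) ** 2
        i = j
    return ll, U, I


@dataclass
class CoxFit:
    beta: float
    hr: float
    se: float
    ci95: tuple[float, float]
    converged: bool
    n_iter: int


def cox_fit(
    time, event, covariate, max_iter: int = 50, tol: float = 1e-9,
    beta_bound: float = 20.0,
) -> CoxFit:
    """Single-covariate Cox PH fit by Newton-Raphson with Efron ties.

    Monotone likelihood (separation) is reported via ``converged=False``
    with the estimate clamped at ``beta_bound``.
    """
    time, event = _validate(time, event)
    x = np.asarray(covariate, dtype=float)
    if x.size != time.size:
        raise ValueError("covariate length mismatch")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    if event.sum() == 0:
        raise ValueError("no events")
    # scale for numerical stability, back-transform at the end
    scale = np.std(x)
    xs = (x - x.mean()) / scale

    beta = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, U, I = _efron_quantities(beta, time, event, xs)
        if I <= 0:
            break
        step = U / I
        step = float(np.clip(step, -2.0, 2.0))  # damped
        beta += step
        if abs(beta) > beta_bound:
            beta = float(np.sign(beta) * beta_bound)
            break
        if abs(step) < tol:
            converged = True
            break
    _, _, I = _efron_quantities(beta, time, event, xs)
    se_s = float(1.0 / np.sqrt(I)) if I > 0 else float("inf")
    b = beta / scale
    se = se_s / scale
    lo, hi = np.exp(b - 1.96 * se), np.exp(b + 1.96 * se)
    return CoxFit(
        beta=float(b), hr=float(np.exp(b)), se=float(se),
        ci95=(float(lo), float(hi)), converged=converged, n_iter=it,
    )


def cox_score_test(time, event, covariate) -> LogRankResult:
    """Cox score (Rao) test of beta = 0; equals the log-rank test when
    event times are untied and the covariate is a group indicator."""
    time, event = _validate(time, event)
    x = np.asarray(covariate, dtype=float)
    _, U, I = _efron_quantities(0.0, time, event, x)
    stat = 0.0 if I <= 0 else float(U * U / I)
    return LogRankResult(statistic=stat, df=1, p=float(stats.chi2.sf(stat, 1)))


@dataclass
class CutoffScanResult:
    candidates: pd.DataFrame  # scheme, quantile_level, threshold, logrank_p, n_high, n_low, valid
    selected: int  # index into candidates

    @property
    def selected_row(self) -> pd.Series:
        return self.candidates.loc[self.selected]


def scan_cutoffs(
    time, event, score,
    schemes: dict[str, tuple[float, ...]] | None = None,
    min_group_frac: float = 0.1,
) -> CutoffScanResult:
    """Stepwise quantile cutoff scan for score stratification.

    Every interior quantile of every scheme is a candidate threshold
    (duplicated threshold values are scanned once); high = score strictly
    above the threshold. Candidates leaving either arm below
    ``min_group_frac`` of the cohort are invalid. The selected candidate
    minimizes the log-rank P; ties break toward the threshold nearest the
    median score. P-values are not adjusted for the multiple looks.
    """
    time, event = _validate(time, event)
    score = np.asarray(score, dtype=float)
    if score.size != time.size:
        raise ValueError("score length mismatch")
    if np.ptp(score) == 0:
        raise ValueError("scores are constant; no split possible")
    schemes = schemes or SCHEMES
    n = time.size
    median_score = float(np.quantile(score, 0.5))

    rows = []
    seen: dict[float, int] = {}
    for scheme, levels in schemes.items():
        for q in levels:
            thr = float(np.quantile(score, q))  # linear interpolation
            if thr in seen:
                continue
            seen[thr] = len(rows)
            high = score > thr
            n_high, n_low = int(high.sum()), int((~high).sum())
            valid = min(n_high, n_low) >= min_group_frac * n
            if valid:
                lr = logrank_test(
                    [(time[high], event[high]), (time[~high], event[~high])]
                )
                p = lr.p
            else:
                p = float("nan")
            rows.append(
                {
                    "scheme": scheme,
                    "quantile_level": q,
                    "threshold": thr,
                    "logrank_p": p,
                    "n_high": n_high,
                    "n_low": n_low,
                    "valid": valid,
                }
            )
    cand = pd.DataFrame(rows)
    valid = cand[cand["valid"]]
    if valid.empty:
        raise ValueError("no valid split under the group-size constraint")
    best_p = valid["logrank_p"].min()
    ties = valid[valid["logrank_p"] == best_p]
    selected = int((ties["threshold"] - median_score).abs().idxmin())
    return CutoffScanResult(candidates=cand, selected=selected)
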