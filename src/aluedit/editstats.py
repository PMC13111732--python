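"""Donor-paired statistics for differential editing.

Two routes are provided. The one-sided Wilcoxon signed-rank test compares
editing indices (or normalised event counts) between conditions within
donors, exact for small n; the a-priori alternative is that deaminase
knockdown *reduces* editing. Per-gene normalised event counts are fitted
with a linear model with treatment as a fixed effect and donor as a
blocking factor — for balanced complete designs this yields the same
treatment estimates as a donor-random-effect mixed model, deterministically
and without an optimiser. P-values across genes are Benjamini–Hochberg
adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError

__all__ = [
    "PairedSample",
    "DifferentialEditingResult",
    "wilcoxon_signed_rank",
    "paired_condition_model",
    "bh_adjust",
]


@dataclass(frozen=True)
class PairedSample:
    """One donor's per-condition values (AEI or normalised event counts)."""

    donor: str
    values_by_condition: Mapping[str, float]


@dataclass(frozen=True)
class DifferentialEditingResult:
    """One unit's (gene or 'AEI') contrast between two conditions."""

    unit: str
    contrast: tuple[str, str]
    estimate: float
    statistic: float
    p_value: float
    q_value: float | None = None


def _exact_signed_rank_counts(n: int) -> np.ndarray:
    """Null distribution of the positive-rank sum W for n distinct ranks:
    counts[w] = number of the 2^n sign assignments with rank-sum w.

    Computed by the generating-polynomial product Π(1 + x^k), k = 1..n —
    identical to enumerating every sign assignment.
    """
    counts = np.zeros(n * (n + 1) // 2 + 1, dtype=np.float64)
    counts[0] = 1.0
    for k in range(1, n + 1):
        counts[k:] = counts[k:] + counts[:-k]
    return counts


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    alternative: str = "less",
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired data (or on differences if ``y``
    is None).

    Zero differences are dropped (Wilcoxon's original treatment); ties among
    nonzero |differences| receive midranks. The exact null distribution is
    used when n <= 25 and the |differences| are distinct; otherwise the
    normal approximation with continuity and tie correction applies.
    ``alternative='less'`` tests whether x tends to be smaller than y.

    Returns (W, p) where W is the positive-rank sum.
    """
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if d.shape != y.shape:
            raise ValueError("paired vectors must have equal length")
        d = d - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")

    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    w = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n

    if n <= 25 and not has_ties:
        counts = _exact_signed_rank_counts(n)
        total = 2.0**n
        wi = int(round(w))
        p_less = counts[: wi + 1].sum() / total
        p_greater = counts[wi:].sum() / total
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(absd, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        sd = np.sqrt(var)
        p_less = stats.norm.cdf((w - mu + 0.5) / sd)
        p_greater = stats.norm.sf((w - mu - 0.5) / sd)

    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    return w, float(min(p, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Order-preserving, capped at 1; q >= p always. Input values outside
    [0, 1] are rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _fit_blocked(
    values: np.ndarray, cond_codes: np.ndarray, donor_codes: np.ndarray, n_cond: int, n_donor: int
) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """OLS fit of value ~ condition + donor (treatment-coded dummies) for
    one or many units sharing the same design.

    ``values`` has shape (n_units, n_obs). Returns condition-effect
    estimates relative to the first condition (n_units, n_cond-1), their
    covariance scale (X'X)^-1 restricted to condition columns, and the
    residual degrees of freedom; residual variances are computed by the
    caller. Implemented with numpy least squares — closed-form, no
    optimiser."""
    n_obs = values.shape[1]
    X = np.ones((n_obs, 1 + (n_cond - 1) + (n_donor - 1)))
    for c in range(1, n_cond):
        X[:, c] = cond_codes == c
    for dnr in range(1, n_donor):
        X[:, n_cond - 1 + dnr] = donor_codes == dnr
    rank = np.linalg.matrix_rank(X)
    df = n_obs - rank
    if df <= 0:
        raise InsufficientDataError("no residual degrees of freedom in the blocked design")
    beta, *_ = np.linalg.lstsq(X, values.T, rcond=None)
    xtx_inv = np.linalg.pinv(X.T @ X)
    resid = values.T - X @ beta
    s2 = (resid**2).sum(axis=0) / df
    return beta, xtx_inv, df, s2


def paired_condition_model(
    values: pd.DataFrame,
    samples: pd.DataFrame,
    contrasts: Sequence[tuple[str, str]] | None = None,
) -> list[DifferentialEditingResult]:
    """Fit value = μ + condition + donor + ε per unit (gene or AEI row) with
    donor as a blocking factor, and report condition contrasts.

    ``values`` is a units × samples frame; ``samples`` is indexed by
    sample_id with columns ``condition`` and ``donor``. Each contrast
    (a, b) reports the estimated a − b effect (for balanced two-condition
    designs: the mean paired difference), its t-statistic, two-sided
    p-value, and BH q-value across units.
    """
    missing = [s for s in values.columns if s not in samples.index]
    if missing:
        raise ValueError(f"samples sheet lacks entries for {missing}")
    sheet = samples.loc[list(values.columns)]
    conditions = sorted(sheet["condition"].unique())
    donors = sorted(sheet["donor"].unique())
    if len(conditions) < 2:
        raise InsufficientDataError("need at least 2 conditions")
    complete_donors = (
        sheet.groupby("donor")["condition"].nunique().ge(2).sum()
    )
    if complete_donors < 2:
        raise InsufficientDataError("need at least 2 donors observed in 2 or more conditions")
    if contrasts is None:
        contrasts = [
            (a, b) for i, a in enumerate(conditions) for b in conditions[i + 1 :]
        ]
    for a, b in contrasts:
        if a not in conditions or b not in conditions:
            raise ValueError(f"contrast ({a}, {b}) references an unknown condition")

    cond_codes = np.array([conditions.index(c) for c in sheet["condition"]])
    donor_codes = np.array([donors.index(d) for d in sheet["donor"]])
    vals = values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("values matrix contains NaN; drop incomplete units first")

    beta, xtx_inv, df, s2 = _fit_blocked(
        vals, cond_codes, donor_codes, len(conditions), len(donors)
    )

    results: list[DifferentialEditingResult] = []
    p_by_contrast: dict[tuple[str, str], list[float]] = {c: [] for c in contrasts}
    rows_by_contrast: dict[tuple[str, str], list[DifferentialEditingResult]] = {
        c: [] for c in contrasts
    }
    n_params = xtx_inv.shape[0]
    for a, b in contrasts:
        cvec = np.zeros(n_params)
        ia, ib = conditions.index(a), conditions.index(b)
        if ia > 0:
            cvec[ia] = 1.0
        if ib > 0:
            cvec[ib] = -1.0
        est = cvec @ beta  # per unit
        var_scale = float(cvec @ xtx_inv @ cvec)
        se = np.sqrt(var_scale * s2)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, est / se, 0.0)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
        for u, unit in enumerate(values.index):
            row = DifferentialEditingResult(
                unit=str(unit),
                contrast=(a, b),
                estimate=float(est[u]),
                statistic=float(tstat[u]),
                p_value=float(min(pvals[u], 1.0)),
            )
            rows_by_contrast[(a, b)].append(row)
            p_by_contrast[(a, b)].append(row.p_value)

    for contrast, rows in rows_by_contrast.items():
        qvals = bh_adjust(p_by_contrast[contrast])
        for row, q in zip(rows, qvals):
            results.append(
                DifferentialEditingResult(
                    unit=row.unit,
                    contrast=row.contrast,
                    estimate=row.estimate,
                    statistic=row.statistic,
                    p_value=row.p_value,
                    q_value=float(q),
                )
            )
    return results


def results_to_frame(results: Sequence[DifferentialEditingResult]) -> pd.DataFrame:
    """Tabulate results as a tidy frame (one row per unit × contrast)."""
    return pd.DataFrame(
        {
            "unit": [r.unit for r in results],
            "condition_a": [r.contrast[0] for r in results],
            "condition_b": [r.contrast[1] for r in results],
            "estimate": [r.estimate for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
        }
    )
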