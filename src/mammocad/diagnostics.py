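"""Multicollinearity diagnostics for extracted deep features.

Quantifies the pairwise linear dependence that motivates PCA reduction:
Pearson correlations over feature pairs with the corresponding two-sided
p-values (t transform with n-2 degrees of freedom), a 10-bin p-value
histogram over [0, 1], and the fraction of significantly correlated pairs.
On real deep features the p-value mass concentrates in the [0, 0.1] bin —
the signature of the multicollinearity problem.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("mammocad")

DEFAULT_MAX_FEATURES = 200


@dataclass(frozen=True)
class CorrelationReport:
    pairs: tuple[tuple[int, int], ...]       # (i, j) with i < j, evaluated pairs
    correlations: np.ndarray                  # r per pair
    p_values: np.ndarray                      # two-sided p per pair
    histogram: np.ndarray                     # 10 equal-width bins over [0, 1]
    frac_significant: float                   # fraction of pairs with p < 0.1
    n_constant_excluded: int
    corr_matrix: np.ndarray                   # full evaluated-subset matrix

    def __post_init__(self) -> None:
        if np.any(np.abs(self.correlations) > 1 + 1e-12):
            raise ValueError("|r| must be <= 1")
        if int(self.histogram.sum()) != len(self.pairs):
            raise ValueError("histogram counts must sum to evaluated pairs")


def pairwise_correlation(
    X, max_features: int = DEFAULT_MAX_FEATURES
) -> CorrelationReport:
    """Pearson r and p-value for every pair of the first ``max_features``
    columns.

    p-values come from t = r * sqrt((n-2) / (1-r^2)) against a t distribution
    with n-2 degrees of freedom (two-sided), with p clamped to 0 for |r| = 1.
    Constant columns have undefined r; their pairs are excluded from the
    report with a logged count.
    """
    vals = getattr(X, "values", X)
    vals = np.asarray(vals, dtype=float)
    if vals.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    n, p = vals.shape
    if n < 3:
        raise ValueError("need at least 3 samples for correlation p-values")
    m = min(p, max_features)
    sub = vals[:, :m]

    sd = sub.std(axis=0, ddof=1)
    ok = sd > 0
    n_const = int(np.sum(~ok))
    if n_const:
        logger.info("excluding %d constant feature columns from correlation", n_const)

    with np.errstate(invalid="ignore"):
        R = np.corrcoef(sub, rowvar=False).reshape(m, m)

    pairs, rs, ps = [], [], []
    df = n - 2
    for i in range(m):
        for j in range(i + 1, m):
            if not (ok[i] and ok[j]):
                continue
            r = float(np.clip(R[i, j], -1.0, 1.0))
            if abs(r) >= 1.0:
                pv = 0.0
            else:
                t = r * np.sqrt(df / (1.0 - r * r))
                pv = float(2 * stats.t.sf(abs(t), df))
            pairs.append((i, j))
            rs.append(r)
            ps.append(pv)

    p_arr = np.asarray(ps)
    hist = pvalue_histogram(p_arr) if p_arr.size else np.zeros(10, dtype=int)
    frac = float(np.mean(p_arr < 0.1)) if p_arr.size else 0.0
    return CorrelationReport(
        pairs=tuple(pairs),
        correlations=np.asarray(rs),
        p_values=p_arr,
        histogram=hist,
        frac_significant=frac,
        n_constant_excluded=n_const,
        corr_matrix=R,
    )


def pvalue_histogram(p_values, bins: int = 10) -> np.ndarray:
    """Counts over equal-width bins on [0, 1]; the last bin is right-closed."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    counts, _ = np.histogram(p, bins=np.linspace(0.0, 1.0, bins + 1))
    return counts


def report_to_json(report: CorrelationReport, path: str | os.PathLike) -> None:
    doc = {
        "n_pairs": len(report.pairs),
        "n_constant_excluded": report.n_constant_excluded,
        "frac_pairs_p_below_0.1": report.frac_significant,
        "pvalue_histogram": report.histogram.tolist(),
        "mean_abs_correlation": float(np.mean(np.abs(report.correlations)))
        if len(report.pairs)
        else None,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def write_corr_matrix(report: CorrelationReport, path: str | os.PathLike) -> None:
    np.savetxt(path, report.corr_matrix, delimiter="\t", fmt="%.6g")
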