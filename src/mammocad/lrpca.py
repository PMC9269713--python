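"""LR-PCA: eigendecomposition feature reduction + Wald-significance PC selection.

Deep features extracted from frozen CNNs are massively multicollinear, which
destabilizes downstream classifiers.  The LR-PCA procedure addresses this in
two stages:

1.  **PCA on the feature covariance.**  The sample covariance matrix of the
    training features is eigendecomposed; components are ranked by
    eigenvalue magnitude and the top ``K`` (default 50) retained.  PCA can be
    fit pooled over all training rows, or — the variant that performs best —
    per class, taking ``ceil(K / n_classes)`` components from each class's own
    covariance (with that class's own mean) and concatenating the blocks, so
    class-specific variance directions survive the reduction.

2.  **Wald selection via binomial logistic regression.**  A logistic
    regression with intercept is fit on the K PC scores by IRLS; each
    coefficient's Wald statistic t = beta / SE (SE from the inverse observed
    information) yields a two-sided normal p-value, and only components with
    p < alpha (default 0.05) are kept for classification.  This replaces the
    arbitrary retained-variance thresholds (80%, 90%, ...) of conventional PC
    truncation with a supervised significance criterion.

Both stages are fit on training rows only; held-out data is projected and
filtered with the frozen training-time transform.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
from scipy import stats

POOLED_TAG = "pooled"

#: IRLS convergence tolerance on the coefficient update (inf-norm).
LR_TOL = 1e-8
#: IRLS iteration cap (the Firth fallback gets twice as many).
LR_MAX_ITER = 100
#: Default retained-component count and significance level.
DEFAULT_K = 50
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class Component:
    """One principal direction with its fitting context."""

    direction: np.ndarray  # unit vector in feature space
    eigenvalue: float
    fit_mean: np.ndarray   # mean subtracted before projection
    class_tag: Hashable    # POOLED_TAG or the class label


@dataclass(frozen=True)
class PCABasis:
    """Affine PCA projection with per-class bookkeeping.

    ``components`` holds the retained directions in projection order;
    ``spectra`` keeps each fitting group's full |eigenvalue| spectrum
    (descending) so retained-energy curves are computable after truncation.
    """

    components: tuple[Component, ...]
    mode: str  # "pooled" | "per_class"
    K: int
    spectra: dict[Hashable, np.ndarray]

    def __post_init__(self) -> None:
        if self.mode not in ("pooled", "per_class"):
            raise ValueError(f"unknown PCA mode {self.mode!r}")
        if not 0 < self.K <= len(self.components):
            raise ValueError("K must be in [1, number of stored components]")

    @property
    def n_features(self) -> int:
        return self.components[0].direction.size

    def column_meta(self) -> list[tuple[Hashable, int]]:
        """(class_tag, within-group rank) per projected column."""
        rank: dict[Hashable, int] = {}
        meta = []
        for comp in self.components[: self.K]:
            rank[comp.class_tag] = rank.get(comp.class_tag, 0) + 1
            meta.append((comp.class_tag, rank[comp.class_tag]))
        return meta


@dataclass(frozen=True)
class PCScores:
    values: np.ndarray  # n_samples x K
    column_meta: tuple[tuple[Hashable, int], ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[1] != len(self.column_meta):
            raise ValueError("score column count must match column_meta")
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("scores contain non-finite entries")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class CoefficientRecord:
    index: int | str  # column index, or "intercept"
    estimate: float
    standard_error: float
    t_statistic: float
    p_value: float


@dataclass(frozen=True)
class LRFit:
    """Binomial logistic fit with per-coefficient Wald statistics."""

    coefficients: tuple[CoefficientRecord, ...]  # one per score column
    intercept: CoefficientRecord
    converged: bool
    iterations: int
    firth_used: bool = False  # separation fallback engaged

    def p_values(self) -> np.ndarray:
        return np.array([c.p_value for c in self.coefficients])


@dataclass(frozen=True)
class PCSelection:
    selected: tuple[int, ...]
    alpha: float


# --------------------------------------------------------------------------
# PCA fitting
# --------------------------------------------------------------------------

def _eig_sorted(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose a symmetric matrix; order by |eigenvalue| descending.

    Ties in |eigenvalue| keep the original (ascending-eigenvalue) eigh index
    order; each eigenvector's sign is fixed so its largest-magnitude entry is
    positive.
    """
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(-np.abs(lam), kind="stable")
    lam, vec = lam[order], vec[:, order]
    for j in range(vec.shape[1]):
        k = np.argmax(np.abs(vec[:, j]))
        if vec[k, j] < 0:
            vec[:, j] = -vec[:, j]
    return lam, vec


def fit_pca(X: np.ndarray, class_tag: Hashable = POOLED_TAG) -> PCABasis:
    """Covariance PCA on all rows of ``X`` (mean-centered, unscaled).

    Components are eigenvectors of the n-1-divisor sample covariance, ranked
    by eigenvalue magnitude.  All ``min(n-1, p)``-relevant directions are
    stored (K = full rank of the decomposition); truncation happens at
    projection/selection time.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
    lam, vec = _eig_sorted(cov)
    comps = tuple(
        Component(direction=vec[:, j].copy(), eigenvalue=float(lam[j]),
                  fit_mean=mu, class_tag=class_tag)
        for j in range(p)
    )
    return PCABasis(
        components=comps,
        mode="pooled" if class_tag == POOLED_TAG else "per_class",
        K=p,
        spectra={class_tag: np.abs(lam)},
    )


def fit_classwise_pca(
    X: np.ndarray, y: Sequence[Hashable], k_per_class: int
) -> PCABasis:
    """Per-class covariance PCA, blocks concatenated in label-sorted order.

    Each class's rows get their own mean and eigenbasis; the top
    ``k_per_class`` components (by |eigenvalue|) per class are kept, so a
    binary problem with ``k_per_class = 25`` yields the 50-component combined
    basis.  Each component carries its class's fitting mean, making the
    combined projection a fixed affine map.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k_per_class < 1:
        raise ValueError("k_per_class must be >= 1")
    classes = sorted(set(y.tolist()))
    comps: list[Component] = []
    spectra: dict[Hashable, np.ndarray] = {}
    for c in classes:
        rows = X[y == c]
        if rows.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        sub = fit_pca(rows, class_tag=c)
        if k_per_class > len(sub.components):
            raise ValueError(
                f"k_per_class={k_per_class} exceeds feature count "
                f"{len(sub.components)} for class {c!r}"
            )
        comps.extend(sub.components[:k_per_class])
        spectra[c] = sub.spectra[c]
    return PCABasis(
        components=tuple(comps),
        mode="per_class",
        K=k_per_class * len(classes),
        spectra=spectra,
    )


def project(X: np.ndarray, basis: PCABasis, k: int | None = None) -> PCScores:
    """Project rows onto the basis: score_j = v_j . (x - mu_j).

    Each component subtracts its own fitting mean (the pooled mean in pooled
    mode, the component's class mean in per-class mode).  Only the first
    ``k`` (default ``basis.K``) components are used.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != basis.n_features:
        raise ValueError(
            f"feature count {X.shape[1] if X.ndim == 2 else '?'} does not "
            f"match basis dimensionality {basis.n_features}"
        )
    k = basis.K if k is None else k
    comps = basis.components[:k]
    V = np.stack([c.direction for c in comps], axis=1)        # p x k
    M = np.stack([c.fit_mean for c in comps], axis=1)         # p x k
    scores = X @ V - np.einsum("pk,pk->k", M, V)
    return PCScores(values=scores, column_meta=tuple(basis.column_meta()[:k]))


def retained_energy(basis: PCABasis, k: int) -> float | dict[Hashable, float]:
    """Cumulative |eigenvalue| fraction captured by the top-k components.

    Denominator is the full spectrum of the source fit.  Pooled mode returns
    one fraction; per-class mode returns one fraction per class tag.
    """
    out: dict[Hashable, float] = {}
    for tag, spec in basis.spectra.items():
        if not 1 <= k <= spec.size:
            raise ValueError(f"k={k} out of range [1, {spec.size}] for {tag!r}")
        total = spec.sum()
        out[tag] = float(spec[:k].sum() / total) if total > 0 else 1.0
    if basis.mode == "pooled":
        return out[POOLED_TAG]
    return out


# --------------------------------------------------------------------------
# Binomial logistic regression with Wald statistics (IRLS)
# --------------------------------------------------------------------------

def _irls(Xd: np.ndarray, y01: np.ndarray) -> tuple[np.ndarray, int, bool]:
    """Plain Newton/IRLS for the unpenalized binomial log-likelihood."""
    n, d = Xd.shape
    beta = np.zeros(d)
    converged = False
    it = 0
    for it in range(1, LR_MAX_ITER + 1):
        eta = np.clip(Xd @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        grad = Xd.T @ (y01 - p)
        hess = (Xd * w[:, None]).T @ Xd
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, it, False
        beta = beta + step
        if np.max(np.abs(step)) < LR_TOL:
            converged = True
            break
    return beta, it, converged


def _irls_firth(
    Xd: np.ndarray, y01: np.ndarray
) -> tuple[np.ndarray, int, bool]:
    """Firth bias-reduced IRLS (Jeffreys-prior penalized likelihood).

    The modified score U*(beta) = X'(y - p + h (1/2 - p)) with h the
    leverages of the weighted design keeps the estimate finite under
    complete or quasi-complete separation, which is exactly when this
    fallback is invoked.  Steps are damped to at most 5 in inf-norm.
    """
    n, d = Xd.shape
    beta = np.zeros(d)
    for it in range(1, 2 * LR_MAX_ITER + 1):
        eta = np.clip(Xd @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        XW = Xd * w[:, None]
        info = XW.T @ Xd
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, info_inv, Xd)
        score = Xd.T @ (y01 - p + h * (0.5 - p))
        step = info_inv @ score
        m = np.max(np.abs(step))
        if m > 5.0:
            step *= 5.0 / m
        beta = beta + step
        if m < LR_TOL:
            return beta, it, True
    return beta, it, False


def fit_binomial_lr(scores: PCScores | np.ndarray, y: Sequence) -> LRFit:
    """Maximum-likelihood binomial logistic regression on PC scores.

    Fits with intercept by iteratively reweighted least squares (tolerance
    1e-8, at most 100 iterations).  Standard errors come from the inverse of
    the observed information at the optimum; t = beta/SE with two-sided
    p-values from the standard normal.  If the fit fails to converge —
    the IRLS signature of complete or quasi-complete separation, where the
    unpenalized MLE diverges and Wald statistics degenerate — the model is
    refit with Firth's bias-reduced likelihood (Jeffreys prior), which
    keeps estimates finite and Wald inference usable, and the fit is
    flagged.
    """
    vals = scores.values if isinstance(scores, PCScores) else np.asarray(scores, float)
    if vals.ndim != 2:
        raise ValueError("scores must be 2-D")
    n, K = vals.shape
    y01, _ = _binarize(y)
    if len(y01) != n:
        raise ValueError("label count does not match score rows")
    if len(np.unique(y01)) < 2:
        raise ValueError("labels are constant; logistic regression undefined")
    if n <= K + 1:
        raise ValueError(f"need n > K+1 samples, got n={n}, K={K}")

    Xd = np.hstack([np.ones((n, 1)), vals])
    beta, it, converged = _irls(Xd, y01)

    firth_used = False
    if not converged:
        beta, it, converged = _irls_firth(Xd, y01)
        firth_used = True

    eta = np.clip(Xd @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    info = (Xd * w[:, None]).T @ Xd
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))

    def record(idx, j):
        b = float(beta[j])
        s = float(se[j])
        if s > 0:
            t = b / s
            pv = float(2 * stats.norm.sf(abs(t)))
        else:
            t, pv = math.inf if b else 0.0, 0.0 if b else 1.0
        return CoefficientRecord(idx, b, s, float(t), pv)

    return LRFit(
        coefficients=tuple(record(j - 1, j) for j in range(1, K + 1)),
        intercept=record("intercept", 0),
        converged=converged,
        iterations=it,
        firth_used=firth_used,
    )


def _binarize(y: Sequence) -> tuple[np.ndarray, list]:
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    if len(classes) > 2:
        raise ValueError(f"binomial LR needs binary labels, got {classes}")
    return (y == classes[-1]).astype(float), classes


def select_significant(fit: LRFit, alpha: float = DEFAULT_ALPHA) -> PCSelection:
    """Keep score columns whose Wald p-value falls below ``alpha``.

    The intercept is never selected; an empty selection is legal (the caller
    may then fall back to all K components).
    """
    sel = tuple(c.index for c in fit.coefficients if c.p_value < alpha)
    return PCSelection(selected=sel, alpha=alpha)


# --------------------------------------------------------------------------
# Full reduction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LRPCAResult:
    train_scores: np.ndarray    # n_train x |selected|
    other_scores: np.ndarray    # n_other x |selected|
    basis: PCABasis
    lr_fit: LRFit
    selection: PCSelection
    full_train_scores: PCScores
    full_other_scores: PCScores


def lr_pca_reduce(
    X_train: np.ndarray,
    y_train: Sequence,
    X_other: np.ndarray | None = None,
    mode: str = "pooled",
    K: int = DEFAULT_K,
    alpha: float = DEFAULT_ALPHA,
) -> LRPCAResult:
    """Run the full LR-PCA reduction, fit on training rows only.

    Steps: covariance PCA (pooled, or per-class with ceil(K / n_classes)
    components per class), projection of training rows, binomial logistic
    fit on the K scores, Wald selection at ``alpha``, and projection +
    column filtering of ``X_other`` with the frozen training transform.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_arr = np.asarray(y_train)
    if mode == "pooled":
        basis = fit_pca(X_train)
        k = min(K, len(basis.components))
        basis = PCABasis(basis.components, "pooled", k, basis.spectra)
    elif mode == "per_class":
        n_classes = len(set(y_arr.tolist()))
        k_per_class = math.ceil(K / n_classes)
        basis = fit_classwise_pca(X_train, y_arr, k_per_class)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    train_scores = project(X_train, basis)
    lr_fit = fit_binomial_lr(train_scores, y_arr)
    selection = select_significant(lr_fit, alpha)
    cols = list(selection.selected)

    if X_other is None:
        X_other = np.empty((0, X_train.shape[1]))
    other_scores = project(np.asarray(X_other, dtype=float), basis)
    return LRPCAResult(
        train_scores=train_scores.values[:, cols],
        other_scores=other_scores.values[:, cols],
        basis=basis,
        lr_fit=lr_fit,
        selection=selection,
        full_train_scores=train_scores,
        full_other_scores=other_scores,
    )


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def basis_to_json(basis: PCABasis, path: str | os.PathLike) -> None:
    doc = {
        "mode": basis.mode,
        "K": basis.K,
        "components": [
            {
                "class_tag": str(c.class_tag),
                "eigenvalue": c.eigenvalue,
                "direction": c.direction.tolist(),
                "fit_mean": c.fit_mean.tolist(),
            }
            for c in basis.components
        ],
        "spectra": {str(k): v.tolist() for k, v in basis.spectra.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def lr_fit_to_json(fit: LRFit, selection: PCSelection | None, path) -> None:
    """Coefficient table mirroring the (index, SE, t, p) report layout."""
    rows = [
        {
            "predictor": f"PC{c.index + 1}",
            "estimate": c.estimate,
            "SE": c.standard_error,
            "t": c.t_statistic,
            "p": c.p_value,
        }
        for c in fit.coefficients
    ]
    doc = {
        "intercept": {
            "estimate": fit.intercept.estimate,
            "SE": fit.intercept.standard_error,
            "t": fit.intercept.t_statistic,
            "p": fit.intercept.p_value,
        },
        "coefficients": rows,
        "converged": fit.converged,
        "iterations": fit.iterations,
        "firth_used": fit.firth_used,
    }
    if selection is not None:
        doc["selected"] = [f"PC{j + 1}" for j in selection.selected]
        doc["alpha"] = selection.alpha
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def write_scores(scores: PCScores, sample_ids: Sequence[str], path) -> None:
    cols = [f"{tag}:rank{r}" for tag, r in scores.column_meta]
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(cols) + "\n")
        for sid, row in zip(sample_ids, scores.values):
            fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
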