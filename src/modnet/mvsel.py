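"""Sparse PLS-DA, recursive feature elimination, and the
univariate/multivariate DEG intersection.

With three replicates per subject a per-gene test alone is fragile, so
the pipeline pairs it with a multivariate selector: a sparse partial
least squares discriminant analysis (sPLS-DA) whose first latent
component maximizes covariance between expression scores and the class
indicator, with sparsity imposed by soft-thresholding the loading
vector.  Recursive feature elimination (RFE) repeatedly refits the model
and drops the genes with the smallest absolute component-1 loadings
until 10% of the genes remain.  The final DEG list is the intersection
of the univariate (BH-adjusted p < alpha) and multivariate selections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SplsdaFit", "RfeResult", "splsda_fit", "rfe_select",
           "intersect_selections"]


@dataclass
class SplsdaFit:
    n_components: int
    genes: list[str]
    loadings: np.ndarray          # genes x components, unit-norm columns
    scores: np.ndarray            # samples x components (X-variates)
    variance_explained: list[float]
    sparsity: list[int]           # nonzero loadings per component


@dataclass
class RfeResult:
    trace: list[list[str]] = field(default_factory=list)
    final_genes: list[str] = field(default_factory=list)
    retain_fraction: float = 0.1


def _encode_response(groups: list[str]) -> np.ndarray:
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    y = np.array([1.0 if g == labels[1] else 0.0 for g in groups])
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("one group is empty")
    return y - y.mean()


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and unit-scale columns; returns (X_std, keep_mask).

    Constant genes carry no discriminative signal and are dropped.
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    return Xs, keep


def _soft_threshold(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold ``w`` to its ``keep`` largest-magnitude entries."""
    if keep >= len(w):
        return w
    mags = np.abs(w)
    # threshold at the (keep+1)-th largest magnitude; ties resolved by
    # stable order so exactly `keep` survive
    order = np.argsort(-mags, kind="stable")
    lam = mags[order[keep]]
    out = np.sign(w) * np.maximum(mags - lam, 0.0)
    # ties at lam would zero out extra entries; re-add in stable order
    nz = np.flatnonzero(out)
    if len(nz) < keep:
        for i in order:
            if out[i] == 0.0 and mags[i] > 0 and len(np.flatnonzero(out)) < keep:
                out[i] = np.sign(w[i]) * 1e-12
    return out


def splsda_fit(
    log2cpm: pd.DataFrame,
    groups: dict[str, str],
    n_components: int = 1,
    keep: int | None = None,
) -> SplsdaFit:
    """Fit a sparse PLS-DA on a genes x samples log2CPM matrix.

    The class membership is encoded as a centered indicator; each
    component's loading vector maximizes covariance between predictor
    scores and the response, soft-thresholded to the ``keep``
    largest-magnitude entries and renormalized; the predictor matrix is
    deflated between components.  ``keep=None`` disables sparsity.
    """
    samples = list(log2cpm.columns)
    y = _encode_response([groups[s] for s in samples])
    X_full = log2cpm.to_numpy(dtype=float).T  # samples x genes
    Xs, keep_mask = _standardize(X_full)
    genes = [g for g, k in zip(log2cpm.index, keep_mask) if k]
    n, p = Xs.shape
    if keep is not None and keep > p:
        raise ValueError(f"keep={keep} exceeds {p} usable genes")
    k_eff = p if keep is None else keep

    total_var = (Xs**2).sum()
    X = Xs.copy()
    yd = y.copy()
    loadings = np.zeros((p, n_components))
    scores = np.zeros((n, n_components))
    var_explained: list[float] = []
    sparsity: list[int] = []

    for comp in range(n_components):
        w = X.T @ yd
        if np.allclose(w, 0):
            break
        w = _soft_threshold(w, k_eff)
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w = w / nw
        t = X @ w
        tt = float(t @ t)
        if tt == 0:
            break
        pvec = X.T @ t / tt
        var_explained.append(float(tt * (pvec @ pvec) / total_var))
        loadings[:, comp] = w
        scores[:, comp] = t
        sparsity.append(int(np.count_nonzero(w)))
        X = X - np.outer(t, pvec)
        yd = yd - t * (t @ yd) / tt

    return SplsdaFit(
        n_components=n_components,
        genes=genes,
        loadings=loadings,
        scores=scores,
        variance_explained=var_explained,
        sparsity=sparsity,
    )


def rfe_select(
    log2cpm: pd.DataFrame,
    groups: dict[str, str],
    retain_fraction: float = 0.10,
    step_fraction: float = 0.2,
) -> RfeResult:
    """Recursive feature elimination driven by sPLS-DA loadings.

    Iterates: fit the model on the current genes, rank by absolute
    component-1 loading (ties lexicographic on gene symbol), drop the
    bottom ``step_fraction``; the last step truncates to exactly
    floor(retain_fraction * initial gene count).  Deterministic for
    fixed inputs and invariant to gene input order.
    """
    if not (0.0 < retain_fraction < 1.0):
        raise ValueError("retain_fraction must be in (0, 1)")
    n_init = len(log2cpm.index)
    target = int(np.floor(retain_fraction * n_init))
    if target < 1:
        raise ValueError("retain_fraction leaves no genes")

    current = sorted(str(g) for g in log2cpm.index)
    result = RfeResult(retain_fraction=retain_fraction)
    while len(current) > target:
        fit = splsda_fit(log2cpm.loc[current], groups, n_components=1)
        mags = dict(zip(fit.genes, np.abs(fit.loadings[:, 0])))
        ranked = sorted(current, key=lambda g: (-mags.get(g, 0.0), g))
        step = max(1, int(step_fraction * len(current)))
        n_next = max(target, len(current) - step)
        current = sorted(ranked[:n_next])
        result.trace.append(list(current))
    result.final_genes = list(current)
    return result


def intersect_selections(univariate: pd.DataFrame, multivariate: RfeResult,
                         alpha: float = 0.05) -> dict[str, str]:
    """Intersect the univariate DEGs with the RFE-retained genes.

    ``univariate`` is an ``nb_wald_test`` result table; the returned dict
    maps each gene in the intersection to its direction (up/down) carried
    from the univariate result.
    """
    sig = univariate[
        univariate["padj"].notna() & (univariate["padj"] < alpha)
    ]
    chosen = set(map(str, sig.index)) & set(multivariate.final_genes)
    return {g: str(sig.loc[g, "direction"]) for g in sorted(chosen)}
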