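"""Normalisation, covariate residualisation and PCA diagnostics.

Counts are put on a log2 counts-per-million scale with spike-adjusted
library sizes; nuisance covariates are removed for visualisation by
ordinary least squares residualisation per region (the linear surrogate
for the adjustment the count model applies during testing); PCA and
PC-covariate association matrices summarise what drives the variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CountMatrix, SampleRecord


@dataclass
class NormalizedMatrix:
    """log2-CPM values (regions x samples) with the library sizes used."""

    values: np.ndarray
    region_ids: list
    samples: list
    library_sizes: np.ndarray
    spike_adjusted: bool


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # regions x components
    variance_fraction: np.ndarray


def logcpm(
    matrix: CountMatrix,
    samples: Optional[Sequence[SampleRecord]] = None,
    use_spike: bool = True,
    pseudocount: float = 0.5,
    library_sizes: Optional[np.ndarray] = None,
) -> NormalizedMatrix:
    """log2((count + pseudocount) / (library_size * spike_ratio) * 1e6).

    Library sizes default to column sums of the methyl counts; the
    per-sample spike enrichment ratio multiplies the effective size when
    ``use_spike`` and sample records are supplied.
    """
    lib = matrix.library_sizes() if library_sizes is None else np.asarray(library_sizes, float)
    if (lib <= 0).any():
        raise ValueError("zero or negative library size")
    spike = np.ones(len(matrix.samples))
    if use_spike and samples is not None:
        by_id = {s.sample_id: s.spike_enrichment_ratio for s in samples}
        spike = np.array([by_id.get(sid, 1.0) for sid in matrix.samples])
    eff = lib * spike
    vals = np.log2((matrix.methyl_counts + pseudocount) / eff[None, :] * 1e6)
    return NormalizedMatrix(
        values=vals,
        region_ids=list(matrix.region_ids),
        samples=list(matrix.samples),
        library_sizes=eff,
        spike_adjusted=use_spike,
    )


def _design_from_covariates(covariates: pd.DataFrame) -> np.ndarray:
    """Numeric design from a mixed covariate table: numerics standardised
    where non-constant, categoricals one-hot (first level dropped).
    Aliased columns are dropped via QR pivoting."""
    cols = []
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype.kind in "biufc":
            x = col.to_numpy(dtype=float)
            x = np.where(np.isnan(x), np.nanmedian(x) if np.isfinite(np.nanmedian(x)) else 0.0, x)
            cols.append(x)
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
    X = np.column_stack([np.ones(len(covariates))] + cols) if cols else np.ones((len(covariates), 1))
    # drop aliased columns deterministically (keep earliest independent set)
    keep = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
    return X[:, keep]


def residualize(
    norm: NormalizedMatrix, covariates: pd.DataFrame, keep: Sequence[str] = ()
) -> NormalizedMatrix:
    """Remove nuisance covariates per region by OLS; idempotent.

    ``covariates`` is row-aligned to ``norm.samples``; all columns except
    those in ``keep`` are regressed out; residuals plus each region's grand
    mean are returned.
    """
    if len(covariates) != len(norm.samples):
        raise ValueError("covariate table not aligned to samples")
    nuisance = covariates[[c for c in covariates.columns if c not in set(keep)]]
    if nuisance.shape[1] == 0:
        return NormalizedMatrix(
            norm.values.copy(), norm.region_ids, norm.samples, norm.library_sizes, norm.spike_adjusted
        )
    X = _design_from_covariates(nuisance)
    # hat matrix applied to all regions at once: residual = Y - Y X (X'X)^-1 X'
    Y = norm.values.T  # samples x regions
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = resid.T + norm.values.mean(axis=1, keepdims=True)
    return NormalizedMatrix(
        out, norm.region_ids, norm.samples, norm.library_sizes, norm.spike_adjusted
    )


def pca(norm: NormalizedMatrix, n_components: int = 6, scale: bool = True) -> PCAResult:
    """Region-centred (optionally unit-scaled) SVD with a fixed sign
    convention: each component's largest-magnitude loading is positive."""
    X = norm.values.T  # samples x regions
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs >= 2 samples")
    n_components = min(n_components, n - 1, p)
    Xc = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = (S**2).sum()
    for k in range(min(len(S), n_components)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    scores = (U * S)[:, :n_components]
    loadings = Vt[:n_components].T
    var_frac = (S[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    return PCAResult(scores=scores, loadings=loadings, variance_fraction=var_frac)


def pc_covariate_correlation(
    pca_result: PCAResult, covariates: pd.DataFrame, n_pcs: int = 6
) -> pd.DataFrame:
    """Association in [0, 1] between each of the top PCs and each covariate.

    Numeric covariates: absolute Pearson r with the PC score.  Categorical:
    correlation ratio (square root of the between-group variance fraction).
    Constant covariates get 0.
    """
    n_pcs = min(n_pcs, pca_result.scores.shape[1])
    out = {}
    for name in covariates.columns:
        col = covariates[name]
        assoc = []
        for k in range(n_pcs):
            pc = pca_result.scores[:, k]
            if col.dtype.kind in "biufc" and col.nunique(dropna=True) > 2:
                x = col.to_numpy(dtype=float)
                ok = np.isfinite(x)
                if ok.sum() < 3 or np.std(x[ok]) == 0:
                    assoc.append(0.0)
                    continue
                r = np.corrcoef(x[ok], pc[ok])[0, 1]
                assoc.append(abs(float(r)))
            else:
                groups = col.astype(str).to_numpy()
                levels = np.unique(groups)
                if len(levels) < 2:
                    assoc.append(0.0)
                    continue
                grand = pc.mean()
                ss_between = sum(
                    (groups == g).sum() * (pc[groups == g].mean() - grand) ** 2 for g in levels
                )
                ss_total = ((pc - grand) ** 2).sum()
                assoc.append(float(np.sqrt(ss_between / ss_total)) if ss_total > 0 else 0.0)
        out[name] = assoc
    return pd.DataFrame(out, index=[f"PC{k + 1}" for k in range(n_pcs)]).T
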