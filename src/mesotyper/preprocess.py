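"""Cross-batch harmonisation and variance-based gene filtering.

Batch effects are removed with the parametric empirical-Bayes
location/scale adjustment (ComBat): per-gene standardisation, method-of-
moments normal / inverse-gamma priors on the per-(gene, batch) location and
scale, iterative EB shrinkage, adjustment, and back-transformation.  No
covariate design matrix is used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix


@dataclass
class BatchModel:
    """Fitted ComBat parameters, exposed for inspection."""

    grand_mean: pd.Series              # per-gene alpha-hat
    pooled_var: pd.Series              # per-gene sigma-hat^2
    gamma_star: pd.DataFrame           # genes x batches shrunk location
    delta_star: pd.DataFrame           # genes x batches shrunk scale (var)
    hyper: pd.DataFrame                # per-batch EB hyperparameters


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m ** 2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _it_sol(Z: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
            g_bar: float, t2: float, a: float, b: float,
            conv: float = 1e-4, max_iter: int = 500
            ) -> tuple[np.ndarray, np.ndarray]:
    """Iterative EB solution for one batch (parametric priors)."""
    n = Z.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        ss = ((Z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * ss + b) / (n / 2 + a - 1)
        change = max(np.abs((g_new - g_old) / g_old).max(initial=0.0),
                     np.abs((d_new - d_old) / d_old).max(initial=0.0))
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def fit_batch_model(X: ExpressionMatrix) -> BatchModel:
    """Fit the parametric EB batch model (requires >=2 samples per batch)."""
    if X.batch is None:
        raise ValueError("batch labels required for batch adjustment")
    batches = list(pd.unique(X.batch))
    counts = X.batch.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"batches with <2 samples: {list(small.index)}")

    V = X.values.to_numpy(dtype=float)
    genes = X.values.index
    n_total = V.shape[1]
    masks = {b: (X.batch == b).to_numpy() for b in batches}

    batch_means = np.column_stack([V[:, masks[b]].mean(axis=1) for b in batches])
    weights = np.array([masks[b].sum() / n_total for b in batches])
    grand = batch_means @ weights
    resid = V - batch_means[:, [batches.index(b) for b in X.batch]]
    pooled = (resid ** 2).mean(axis=1)  # N denominator, canonical choice
    zero = pooled <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance genes dropped from "
                      "batch model")
    keep = ~zero
    Z = (V[keep] - grand[keep, None]) / np.sqrt(pooled[keep])[:, None]

    gamma = np.empty((keep.sum(), len(batches)))
    delta = np.empty_like(gamma)
    hyper_rows = []
    for j, b in enumerate(batches):
        Zb = Z[:, masks[b]]
        g_hat = Zb.mean(axis=1)
        d_hat = Zb.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        a, bp = _aprior(d_hat), _bprior(d_hat)
        gamma[:, j], delta[:, j] = _it_sol(Zb, g_hat, d_hat, g_bar, t2, a, bp)
        hyper_rows.append({"batch": b, "gamma_bar": g_bar, "tau2": t2,
                           "a_prior": a, "b_prior": bp})

    gidx = genes[keep]
    return BatchModel(
        grand_mean=pd.Series(grand[keep], index=gidx),
        pooled_var=pd.Series(pooled[keep], index=gidx),
        gamma_star=pd.DataFrame(gamma, index=gidx, columns=batches),
        delta_star=pd.DataFrame(delta, index=gidx, columns=batches),
        hyper=pd.DataFrame(hyper_rows).set_index("batch"))


def combat_adjust(X: ExpressionMatrix) -> ExpressionMatrix:
    """Remove batch location/scale effects; ids and dims are unchanged
    (zero-variance genes are dropped with a warning).

    A single-batch matrix is returned unchanged.
    """
    if X.batch is None:
        raise ValueError("batch labels required for combat_adjust")
    if X.batch.nunique() == 1:
        return ExpressionMatrix(X.values.copy(), batch=X.batch.copy(),
                                scale_tag=X.scale_tag)
    model = fit_batch_model(X)
    genes = model.grand_mean.index
    V = X.values.loc[genes].to_numpy(dtype=float)
    sd = np.sqrt(model.pooled_var.to_numpy())
    Z = (V - model.grand_mean.to_numpy()[:, None]) / sd[:, None]
    out = np.empty_like(Z)
    for b in model.gamma_star.columns:
        m = (X.batch == b).to_numpy()
        g = model.gamma_star[b].to_numpy()
        d = model.delta_star[b].to_numpy()
        out[:, m] = (Z[:, m] - g[:, None]) / np.sqrt(d)[:, None]
    adjusted = out * sd[:, None] + model.grand_mean.to_numpy()[:, None]
    return ExpressionMatrix(
        pd.DataFrame(adjusted, index=genes, columns=X.values.columns),
        batch=X.batch.copy(), scale_tag=X.scale_tag)


def variance_filter(X: ExpressionMatrix, fraction: float = 0.5
                    ) -> ExpressionMatrix:
    """Keep the ceil(fraction * G) highest-variance genes.

    Variance uses the n-1 denominator on the log2 values; ties are broken
    by gene id lexicographic order so the filter is deterministic and
    idempotent.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_keep = math.ceil(fraction * X.n_genes)
    var = X.values.var(axis=1, ddof=1)
    order = sorted(X.values.index, key=lambda g: (-var[g], g))
    sel = set(order[:n_keep])
    keep = [g for g in X.values.index if g in sel]
    return ExpressionMatrix(X.values.loc[keep].copy(),
                            batch=None if X.batch is None else X.batch.copy(),
                            scale_tag=X.scale_tag)
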