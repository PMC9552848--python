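"""Multi-run NMF, cophenetic rank selection, and immune-module annotation.

This is stage 1 of the subtyping system: the expression matrix is factorised
into nonnegative gene modules (basis W) and sample loadings (H) with the
Brunet multiplicative updates under Kullback-Leibler divergence, the rank is
chosen from the drop of the cophenetic coefficient of the multi-run consensus
matrix, and the module whose samples carry the highest composite immune
enrichment score is annotated as the immune module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix

_EPS = np.finfo(float).tiny


@dataclass
class NMFModel:
    """Best-run factors plus the consensus summaries of a multi-run NMF."""

    rank: int
    W: pd.DataFrame                      # genes x rank, nonnegative
    H: pd.DataFrame                      # rank x samples, nonnegative
    consensus: pd.DataFrame              # samples x samples co-assignment rate
    divergence: float
    n_runs: int
    cophenetic: dict[int, float] = field(default_factory=dict)
    chosen_k: int | None = None
    module_annotation: dict[int, str] = field(default_factory=dict)
    annotation_ambiguous: bool = False

    @property
    def module_assignment(self) -> pd.Series:
        """Gene -> module index (argmax basis row)."""
        return pd.Series(self.W.to_numpy().argmax(axis=1), index=self.W.index)

    @property
    def sample_module(self) -> pd.Series:
        """Sample -> module index (argmax coefficient column)."""
        return pd.Series(self.H.to_numpy().argmax(axis=0), index=self.H.columns)


def kl_divergence(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalised KL divergence D(V || WH), with 0*log(0) = 0."""
    WH = W @ H
    mask = V > 0
    term = np.zeros_like(V)
    term[mask] = V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS))
    return float(term.sum() - V.sum() + WH.sum())


def multiplicative_update(V: np.ndarray, W: np.ndarray, H: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """One Brunet KL update of (W, H): H first, then W with the new H."""
    WH = np.maximum(W @ H, _EPS)
    H = H * (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
    WH = np.maximum(W @ H, _EPS)
    W = W * ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
    return W, H


def _single_run(V: np.ndarray, k: int, rng: np.random.Generator,
                max_iter: int, tol: float, stop_conv: int = 40
                ) -> tuple[np.ndarray, np.ndarray, float]:
    """One random restart of the Brunet KL NMF.

    Stops when the sample connectivity (argmax H) has been unchanged for
    ``stop_conv`` consecutive checks (every 10 iterations) -- the stopping
    rule of the original consensus-NMF procedure, which preserves restart
    diversity -- or when the relative objective change falls below ``tol``,
    or at ``max_iter``.
    """
    scale = max(V.mean(), _EPS)
    W = rng.uniform(size=(V.shape[0], k)) * scale
    H = rng.uniform(size=(k, V.shape[1])) * scale
    prev = kl_divergence(V, W, H)
    check_every = 10
    assign = H.argmax(axis=0)
    stable = 0
    for it in range(1, max_iter + 1):
        W, H = multiplicative_update(V, W, H)
        if it % check_every == 0 or it == max_iter:
            new_assign = H.argmax(axis=0)
            if np.array_equal(new_assign, assign):
                stable += 1
                if stop_conv and stable >= stop_conv:
                    break
            else:
                stable = 0
                assign = new_assign
            obj = kl_divergence(V, W, H)
            if prev - obj < tol * max(prev, _EPS):
                prev = obj
                break
            prev = obj
    return W, H, kl_divergence(V, W, H)


def nmf_factorize(X: ExpressionMatrix, k: int, n_runs: int = 20,
                  seed: int = 0, max_iter: int = 2000,
                  tol: float = 1e-6, stop_conv: int = 40) -> NMFModel:
    """Multi-run KL-divergence NMF with best-objective selection.

    Each restart draws W, H from U(0,1) scaled by mean(X) and iterates the
    Brunet multiplicative updates until the relative objective change falls
    below ``tol`` or ``max_iter`` is reached.  Per-run sample assignments
    (argmax over H columns) are pooled into the consensus matrix: the
    fraction of runs co-assigning each sample pair.

    Input values must be nonnegative; matrices with negatives (e.g. after
    batch adjustment) should be shifted first (:func:`shift_nonnegative`).
    """
    V = X.values.to_numpy(dtype=float)
    if k >= min(V.shape):
        raise ValueError(f"rank {k} must be < min(G, N) = {min(V.shape)}")
    if (V < 0).any():
        raise ValueError("NMF input must be nonnegative; shift the matrix "
                         "first (see shift_nonnegative)")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    master = np.random.SeedSequence(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    n = V.shape[1]
    co = np.zeros((n, n))
    for child in master.spawn(n_runs):
        rng = np.random.default_rng(child)
        W, H, div = _single_run(V, k, rng, max_iter, tol, stop_conv)
        assign = H.argmax(axis=0)
        co += (assign[:, None] == assign[None, :])
        if best is None or div < best[2]:
            best = (W, H, div)
    consensus = co / n_runs
    np.fill_diagonal(consensus, 1.0)
    W, H, div = best
    return NMFModel(
        rank=k,
        W=pd.DataFrame(W, index=X.values.index,
                       columns=[f"module_{j}" for j in range(k)]),
        H=pd.DataFrame(H, index=[f"module_{j}" for j in range(k)],
                       columns=X.values.columns),
        consensus=pd.DataFrame(consensus, index=X.values.columns,
                               columns=X.values.columns),
        divergence=div, n_runs=n_runs)


def shift_nonnegative(X: ExpressionMatrix) -> tuple[ExpressionMatrix, float]:
    """Shift a matrix by its global minimum so all entries are >= 0."""
    lo = float(X.values.min().min())
    if lo >= 0:
        return X, 0.0
    shifted = ExpressionMatrix(X.values - lo, batch=X.batch,
                               scale_tag=X.scale_tag)
    return shifted, -lo


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Correlation between consensus dissimilarity (1 - C) and the cophenetic
    distances of its average-linkage dendrogram."""
    D = 1.0 - consensus
    np.fill_diagonal(D, 0.0)
    condensed = squareform(np.clip(D, 0.0, None), checks=False)
    if condensed.std() == 0:
        raise ValueError("degenerate consensus matrix: all samples identical")
    Z = average(condensed)
    rho, _ = cophenet(Z, condensed)
    return float(rho)


def select_rank(X: ExpressionMatrix, k_range: range | list[int] = range(2, 11),
                n_runs: int = 20, seed: int = 0, max_iter: int = 2000,
                tol: float = 1e-6, stop_conv: int = 40
                ) -> tuple[dict[int, float], int, dict[int, NMFModel]]:
    """Cophenetic rank-selection sweep.

    Runs the multi-run NMF at each candidate rank, computes the cophenetic
    coefficient of each consensus matrix, and picks the rank *before* the
    largest drop: chosen_k = argmax_k [rho(k) - rho(k+1)].
    """
    ks = sorted(k_range)
    if len(ks) < 2:
        raise ValueError("k_range must contain at least two candidate ranks")
    rho: dict[int, float] = {}
    models: dict[int, NMFModel] = {}
    for i, k in enumerate(ks):
        model = nmf_factorize(X, k, n_runs=n_runs, seed=seed + 1000 * i,
                              max_iter=max_iter, tol=tol, stop_conv=stop_conv)
        rho[k] = cophenetic_coefficient(model.consensus.to_numpy())
        models[k] = model
    chosen = choose_rank_from_curve(rho)
    models[chosen].cophenetic = rho
    models[chosen].chosen_k = chosen
    return rho, chosen, models


def choose_rank_from_curve(rho: dict[int, float]) -> int:
    """The rank before the largest cophenetic drop (ties -> smaller k)."""
    ks = sorted(rho)
    drops = {ks[i]: round(rho[ks[i]] - rho[ks[i + 1]], 9)
             for i in range(len(ks) - 1)}
    return max(drops, key=lambda k: (drops[k], -k))


def kim_park_scores(W: pd.DataFrame) -> pd.Series:
    """Kim-Park basis feature score: 1 minus the normalised entropy of the
    row-normalised basis weights.  1 = fully module-specific gene."""
    k = W.shape[1]
    P = W.to_numpy(dtype=float)
    P = P / np.maximum(P.sum(axis=1, keepdims=True), _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(P > 0, P * np.log2(P), 0.0).sum(axis=1)
    score = 1.0 + ent / np.log2(k)
    return pd.Series(score, index=W.index)


def extract_exemplars(model: NMFModel, module: int, n: int = 200) -> list[str]:
    """Top-n exemplar genes of a module.

    Genes assigned to the module (argmax basis row) are ranked by the
    Kim-Park feature score; if fewer than ``n`` genes are assigned, all are
    returned with a warning.
    """
    if module not in range(model.rank):
        raise ValueError(f"module {module} out of range 0..{model.rank - 1}")
    assigned = model.module_assignment
    genes = assigned.index[assigned == module]
    scores = kim_park_scores(model.W.loc[genes]) if len(genes) else pd.Series(dtype=float)
    ranked = sorted(genes, key=lambda g: (-scores[g], g))
    if len(ranked) < n:
        warnings.warn(f"module {module} has only {len(ranked)} genes "
                      f"(requested {n}); returning all")
        return ranked
    return ranked[:n]


def annotate_modules(model: NMFModel, scores: "pd.DataFrame",
                     immune_signatures: list[str]) -> dict[int, str]:
    """Name each module from a z-normalised signature x sample score matrix.

    The module whose samples have the highest mean composite immune score
    (mean over ``immune_signatures`` rows) is named ``"immune"``; each other
    module is named after its highest-scoring non-immune signature.  Exact
    ties set ``annotation_ambiguous`` and break deterministically by module
    index.
    """
    missing = [s for s in immune_signatures if s not in scores.index]
    if missing:
        raise KeyError(f"immune signatures absent from score matrix: {missing}")
    sample_mod = model.sample_module
    composite = scores.loc[immune_signatures].mean(axis=0)
    means = {m: composite[sample_mod.index[sample_mod == m]].mean()
             for m in range(model.rank)}
    vals = np.array([means[m] for m in range(model.rank)])
    model.annotation_ambiguous = bool(len(np.unique(np.round(vals, 12)))
                                      < len(vals))
    immune_module = min(means, key=lambda m: (-means[m], m))
    other_sigs = [s for s in scores.index if s not in immune_signatures]
    annotation: dict[int, str] = {}
    for m in range(model.rank):
        if m == immune_module:
            annotation[m] = "immune"
            continue
        cols = sample_mod.index[sample_mod == m]
        if other_sigs and len(cols):
            sig_means = scores.loc[other_sigs, cols].mean(axis=1)
            annotation[m] = str(sig_means.idxmax())
        else:
            annotation[m] = f"module_{m}"
    model.module_annotation = annotation
    return annotation
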