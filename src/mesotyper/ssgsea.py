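"""Single-sample gene-set enrichment (ssGSEA) scoring.

Per sample, genes are ranked by expression and each set's enrichment score
is the sum over the ranked list of the difference between the rank-weighted
in-set ECDF (weights |rank|^alpha) and the uniform out-of-set ECDF.  Scores
depend only on each sample's gene ranking, so any strictly increasing
per-sample transform leaves them unchanged.  No cross-sample rescaling is
applied beyond the optional per-signature z-normalisation used for heatmaps
and template matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, GeneSetCollection


@dataclass
class SignatureScores:
    """Signature x sample score matrix with its normalisation provenance."""

    scores: pd.DataFrame
    normalisation: str = "raw"   # "raw" | "z"
    alpha: float = 0.25

    def __post_init__(self) -> None:
        if self.normalisation not in ("raw", "z"):
            raise ValueError(f"unknown normalisation {self.normalisation!r}")
        if self.normalisation == "z":
            nontrivial = self.scores.std(axis=1, ddof=0) > 0
            if nontrivial.any():
                means = self.scores.loc[nontrivial].mean(axis=1)
                if means.abs().max() > 1e-9:
                    raise ValueError("z-normalised rows must have mean ~0")

    @property
    def signatures(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


def _sample_scores(values: np.ndarray, gene_index: pd.Index,
                   sets: GeneSetCollection, alpha: float,
                   set_masks: dict[str, np.ndarray]) -> dict[str, float]:
    ranks = rankdata(values)                      # ascending, average ties
    order = np.argsort(-values, kind="stable")    # descending expression walk
    weights = np.abs(ranks) ** alpha
    out: dict[str, float] = {}
    n = len(values)
    for name, mask in set_masks.items():
        in_walk = mask[order]
        n_in = int(mask.sum())
        w = weights[order] * in_walk
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~in_walk) / (n - n_in)
        out[name] = float((p_in - p_out).sum())
    return out


def ssgsea_score(X: ExpressionMatrix, sets: GeneSetCollection,
                 alpha: float = 0.25) -> SignatureScores:
    """Score every gene set in every sample.

    Sets intersecting fewer than 2 matrix genes are dropped with a warning;
    a set covering the whole gene universe has no out-set ECDF and is an
    error.
    """
    gene_index = X.values.index
    set_masks: dict[str, np.ndarray] = {}
    for name in sets.names:
        mask = gene_index.isin(sets[name])
        n_in = int(mask.sum())
        if n_in == len(gene_index):
            raise ValueError(f"gene set {name!r} equals the full gene "
                             "universe; enrichment undefined")
        if n_in < 2:
            warnings.warn(f"gene set {name!r} has {n_in} genes in the "
                          "matrix; scored as missing")
            continue
        set_masks[name] = mask
    V = X.values.to_numpy(dtype=float)
    cols = {}
    for j, sample in enumerate(X.values.columns):
        cols[sample] = _sample_scores(V[:, j], gene_index, sets, alpha,
                                      set_masks)
    scores = pd.DataFrame(cols).reindex(list(set_masks))
    scores.index.name = "signature"
    return SignatureScores(scores, normalisation="raw", alpha=alpha)


def z_normalize(scores: SignatureScores) -> SignatureScores:
    """Per-signature (row) z-score; constant rows become 0 with a warning."""
    if scores.scores.shape[1] < 2:
        raise ValueError("z-normalisation needs >= 2 samples")
    mat = scores.scores
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant signature rows set to 0")
        sd = sd.mask(flat, 1.0)
    z = mat.sub(mean, axis=0).div(sd, axis=0)
    z[flat] = 0.0
    return SignatureScores(z, normalisation="z", alpha=scores.alpha)
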