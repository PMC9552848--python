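"""Immune / non-immune dichotomisation and activated / suppressed NTP split.

Stage 2: Monti-style consensus clustering of the exemplar-gene matrix
(k = 2) followed by random-forest out-of-bag label refinement (the
"MDS-RF" step: flip any sample whose OOB probability for the other class
exceeds a threshold, with a classical-MDS embedding of the forest proximity
matrix for inspection).  Stage 3: nearest-template prediction on z-normalised
signature scores assigns each immune sample to the activated or suppressed
template by cosine distance, with permutation p-values and BH FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .containers import CohortLabels, ExpressionMatrix, GeneSetCollection
from .nmf import annotate_modules, extract_exemplars, nmf_factorize, \
    select_rank, shift_nonnegative
from .preprocess import combat_adjust, variance_filter
from .ssgsea import SignatureScores, ssgsea_score, z_normalize


@dataclass
class ConsensusResult:
    consensus: pd.DataFrame       # samples x samples, symmetric, diag 1
    k: int
    p_item: float
    n_resamples: int
    labels: pd.Series             # sample -> 1..k


@dataclass
class TemplateDefinition:
    """Class -> marker signature sets, implying binary template vectors.

    The template vector of a class over the full signature panel is 1 on its
    own markers and 0 elsewhere.
    """

    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        if len(self.markers) < 2:
            raise ValueError("need at least two template classes")
        seen: set[str] = set()
        for cls, sigs in self.markers.items():
            if not sigs:
                raise ValueError(f"template class {cls!r} has no markers")
            overlap = seen & set(sigs)
            if overlap:
                raise ValueError(f"marker signatures shared between classes: "
                                 f"{sorted(overlap)}")
            seen |= set(sigs)

    @property
    def classes(self) -> list[str]:
        return list(self.markers)

    @property
    def panel(self) -> list[str]:
        return [s for sigs in self.markers.values() for s in sigs]

    def vectors(self, signatures: list[str]) -> pd.DataFrame:
        """Binary class templates over an ordered signature panel."""
        out = pd.DataFrame(0.0, index=self.classes, columns=signatures)
        for cls, sigs in self.markers.items():
            out.loc[cls, [s for s in sigs if s in signatures]] = 1.0
        return out


def default_templates() -> TemplateDefinition:
    """Templates over the planted synthetic marker signatures."""
    return TemplateDefinition({
        "immune_activated": ["activated_markers"],
        "immune_suppressed": ["suppressed_markers"],
    })


@dataclass
class NTPResult:
    predictions: pd.DataFrame     # class, distance per class, p, fdr, ambiguous

    @property
    def labels(self) -> pd.Series:
        return self.predictions["class"]


def consensus_cluster(X_exemplar: ExpressionMatrix, k: int = 2,
                      n_resamples: int = 1000, p_item: float = 0.8,
                      seed: int = 0) -> ConsensusResult:
    """Monti resampling consensus with an inner k-means.

    Each iteration subsamples ``p_item`` of the samples, runs k-means (fixed
    k, Euclidean, on row-z-scored genes), and co-assignment is accumulated
    among co-sampled pairs.  Final labels cut the average-linkage tree of
    (1 - consensus) at k.
    """
    n = X_exemplar.n_samples
    if k < 2 or k > n:
        raise ValueError(f"k={k} invalid for {n} samples")
    V = X_exemplar.values.to_numpy(dtype=float)
    mu = V.mean(axis=1, keepdims=True)
    sd = V.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = ((V - mu) / sd).T                     # samples x genes
    rng = np.random.default_rng(seed)
    n_sub = max(k, int(round(p_item * n)))
    co = np.zeros((n, n))
    together = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = rng.choice(n, size=n_sub, replace=False)
        km = KMeans(n_clusters=k, n_init=1,
                    random_state=int(rng.integers(2 ** 31)))
        lab = km.fit_predict(Z[idx])
        same = lab[:, None] == lab[None, :]
        co[np.ix_(idx, idx)] += same
        together[np.ix_(idx, idx)] += 1
    with np.errstate(invalid="ignore"):
        consensus = np.where(together > 0, co / np.maximum(together, 1), 0.0)
    consensus = (consensus + consensus.T) / 2
    np.fill_diagonal(consensus, 1.0)
    D = squareform(np.clip(1.0 - consensus, 0.0, None), checks=False)
    labels = fcluster(average(D), t=k, criterion="maxclust")
    samples = X_exemplar.values.columns
    return ConsensusResult(
        consensus=pd.DataFrame(consensus, index=samples, columns=samples),
        k=k, p_item=p_item, n_resamples=n_resamples,
        labels=pd.Series(labels, index=samples))


def mds_rf_refine(X_exemplar: ExpressionMatrix, labels: pd.Series,
                  max_iter: int = 10, flip_threshold: float = 0.5,
                  seed: int = 0, n_estimators: int = 500
                  ) -> tuple[pd.Series, pd.DataFrame]:
    """Random-forest out-of-bag label refinement with an MDS embedding.

    Iterates: fit a random forest on the current labels, compute per-sample
    out-of-bag class probabilities, and flip any sample whose OOB probability
    for a different class exceeds ``flip_threshold``; stops when no sample
    flips or after ``max_iter`` rounds.  If a flip would empty a class the
    last stable labelling is returned with a warning.  Also returns the 2-D
    classical-MDS embedding of the final forest's proximity matrix.
    """
    y = labels.reindex(X_exemplar.sample_ids).astype(str)
    if y.nunique() < 2:
        raise ValueError("refinement needs >= 2 classes present")
    Xmat = X_exemplar.values.to_numpy(dtype=float).T
    rf = None
    for _ in range(max_iter):
        rf = RandomForestClassifier(n_estimators=n_estimators,
                                    oob_score=True, random_state=seed,
                                    n_jobs=1)
        rf.fit(Xmat, y.to_numpy())
        proba = pd.DataFrame(rf.oob_decision_function_,
                             index=y.index, columns=rf.classes_)
        best = proba.idxmax(axis=1)
        best_p = proba.max(axis=1)
        flips = (best != y) & (best_p > flip_threshold)
        if not flips.any():
            break
        candidate = y.copy()
        candidate[flips] = best[flips]
        if candidate.nunique() < y.nunique():
            warnings.warn("refinement would empty a class; keeping last "
                          "stable labelling")
            break
        y = candidate
    prox = _forest_proximity(rf, Xmat)
    embedding = _classical_mds(1.0 - prox, 2)
    emb = pd.DataFrame(embedding, index=y.index, columns=["MDS1", "MDS2"])
    return y, emb


def _forest_proximity(rf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    leaves = rf.apply(X)                         # samples x trees
    n = X.shape[0]
    prox = np.zeros((n, n))
    for t in range(leaves.shape[1]):
        same = leaves[:, t][:, None] == leaves[:, t][None, :]
        prox += same
    return prox / leaves.shape[1]


def _classical_mds(D: np.ndarray, n_components: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_components]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def ntp_classify(scores: SignatureScores, templates: TemplateDefinition,
                 n_perm: int = 1000, seed: int = 0) -> NTPResult:
    """Nearest-template prediction on z-normalised signature scores.

    Each sample is assigned to the class whose binary template has the
    smallest cosine distance over the signature panel.  Significance comes
    from a per-sample null of random templates with the same marker counts:
    p = (1 + #null distances <= observed) / (n_perm + 1), then BH FDR across
    samples.  Exact distance ties set the ambiguity flag and break to the
    first class in definition order.
    """
    if scores.normalisation != "z":
        raise ValueError("NTP expects z-normalised signature scores")
    panel = list(scores.scores.index)
    missing = [s for s in templates.panel if s not in panel]
    if missing:
        raise KeyError(f"template markers absent from scores: {missing}")
    T = templates.vectors(panel).to_numpy()           # classes x signatures
    S = scores.scores.to_numpy().T                    # samples x signatures
    classes = templates.classes
    dist = _cosine_distance(S, T)                     # samples x classes
    order = np.argsort(dist, axis=1, kind="stable")
    pred_idx = order[:, 0]
    ambiguous = np.isclose(dist[np.arange(len(S)), order[:, 0]],
                           dist[np.arange(len(S)), order[:, 1]])
    observed = dist[np.arange(len(S)), pred_idx]

    rng = np.random.default_rng(seed)
    counts = {cls: len(templates.markers[cls]) for cls in classes}
    n_sig = len(panel)
    exceed = np.zeros(len(S))
    for _ in range(n_perm):
        null_t = np.zeros((len(classes), n_sig))
        for i, cls in enumerate(classes):
            pick = rng.choice(n_sig, size=counts[cls], replace=False)
            null_t[i, pick] = 1.0
        # the null statistic mirrors the selection step: the minimum
        # distance over one random template per class
        null_d = _cosine_distance(S, null_t).min(axis=1)
        exceed += null_d <= observed
    p = (1.0 + exceed) / (n_perm + 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    pred = pd.DataFrame(
        {"class": [classes[i] for i in pred_idx],
         "p": p, "fdr": fdr, "ambiguous": ambiguous},
        index=scores.scores.columns)
    for i, cls in enumerate(classes):
        pred[f"dist_{cls}"] = dist[:, i]
    return NTPResult(pred)


def _cosine_distance(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine distance between rows of A and rows of B, in [0, 2]."""
    na = np.linalg.norm(A, axis=1, keepdims=True)
    nb = np.linalg.norm(B, axis=1, keepdims=True)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return 1.0 - (A / na) @ (B / nb).T


@dataclass
class ClassifyConfig:
    """Knobs of the three-stage chain (defaults follow the reference run)."""

    variance_fraction: float = 0.5
    use_combat: bool = True
    k: int | None = 4                 # None -> cophenetic rank selection
    k_range: tuple[int, int] = (2, 6)
    nmf_runs: int = 10
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-7
    exemplar_n: int = 200
    n_resamples: int = 1000
    p_item: float = 0.8
    flip_threshold: float = 0.5
    n_perm: int = 1000
    seed: int = 0
    #: signatures averaged into the composite immune score; None -> the
    #: union of all template marker signatures
    immune_signatures: tuple[str, ...] | None = None


def classify_cohort(X: ExpressionMatrix, sets: GeneSetCollection,
                    templates: TemplateDefinition,
                    config: ClassifyConfig | None = None) -> CohortLabels:
    """Full three-stage chain producing the three-way subtype labels.

    variance filter -> (optional ComBat) -> NMF at rank k -> immune-module
    exemplars -> consensus clustering (k=2) -> immune-arm annotation by mean
    composite immune score -> MDS-RF refinement -> NTP sub-classification of
    the immune arm.
    """
    cfg = config or ClassifyConfig()
    work = X
    if cfg.use_combat and work.batch is not None and work.batch.nunique() > 1:
        work = combat_adjust(work)
    work = variance_filter(work, cfg.variance_fraction)
    nonneg, _ = shift_nonnegative(work)

    if cfg.k is None:
        _, k, models = select_rank(nonneg, range(cfg.k_range[0],
                                                 cfg.k_range[1] + 1),
                                   n_runs=cfg.nmf_runs, seed=cfg.seed,
                                   max_iter=cfg.nmf_max_iter, tol=cfg.nmf_tol)
        model = models[k]
    else:
        model = nmf_factorize(nonneg, cfg.k, n_runs=cfg.nmf_runs,
                              seed=cfg.seed, max_iter=cfg.nmf_max_iter,
                              tol=cfg.nmf_tol)

    raw_scores = ssgsea_score(X, sets)
    zscores = z_normalize(raw_scores)
    wanted = list(cfg.immune_signatures) if cfg.immune_signatures \
        else templates.panel
    immune_sigs = [s for s in wanted if s in zscores.scores.index]
    annotate_modules(model, zscores.scores, immune_sigs)
    immune_module = next(m for m, name in model.module_annotation.items()
                         if name == "immune")
    exemplars = extract_exemplars(model, immune_module, cfg.exemplar_n)

    X_ex = work.subset_genes([g for g in exemplars])
    cons = consensus_cluster(X_ex, k=2, n_resamples=cfg.n_resamples,
                             p_item=cfg.p_item, seed=cfg.seed + 1)
    refined, _ = mds_rf_refine(X_ex, cons.labels.astype(str),
                               flip_threshold=cfg.flip_threshold,
                               seed=cfg.seed + 2)

    composite = zscores.scores.loc[immune_sigs].mean(axis=0)
    arm_means = {arm: composite[refined.index[refined == arm]].mean()
                 for arm in refined.unique()}
    immune_arm = max(arm_means, key=lambda a: (arm_means[a], a))
    immune_samples = list(refined.index[refined == immune_arm])

    labels = pd.Series("non_immune", index=X.values.columns, dtype=object)
    ambiguous = pd.Series(False, index=X.values.columns)
    if immune_samples:
        sub_scores = SignatureScores(zscores.scores[immune_samples],
                                     normalisation="raw", alpha=zscores.alpha)
        # re-normalise within the immune arm so templates contrast act vs sup
        sub_z = z_normalize(sub_scores)
        ntp = ntp_classify(sub_z, templates, n_perm=cfg.n_perm,
                           seed=cfg.seed + 3)
        labels[immune_samples] = ntp.labels
        ambiguous[immune_samples] = ntp.predictions["ambiguous"].to_numpy()
    return CohortLabels(labels, stage_tag="ntp", ambiguous=ambiguous)
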