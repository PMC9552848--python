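"""Gene-panel classifier construction.

The builder mirrors a multi-stage marker-discovery recipe: six feature
selectors (chi-square, information gain, FCBF, random-forest permutation
importance, gradient-boosting gain, Boruta) vote on candidate genes; genes
nominated by at least four algorithms form the candidate panel; highly
correlated features are pruned; panel size is chosen by stepwise (one gene
at a time) cross-validated accuracy and by recursive feature elimination on
the two binary contrasts (immune vs non-immune, activated vs suppressed);
and four model families (LDA, naive Bayes, bagged trees, random forest)
compete on a stratified 70/30 split to produce the final multiclass
gene-panel classifier.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.inspection import permutation_importance
from sklearn.metrics import accuracy_score, confusion_matrix, roc_auc_score
from sklearn.model_selection import (LeaveOneOut, StratifiedKFold,
                                     cross_val_score, train_test_split)
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .containers import CohortLabels, ExpressionMatrix

FILTER_METHODS = ("chi2", "info_gain", "fcbf")
MODEL_METHODS = ("rf_mda", "gboost", "boruta")
ALL_METHODS = FILTER_METHODS + MODEL_METHODS
FAMILIES = ("lda", "naive_bayes", "bagged_trees", "random_forest")

#: sample-count boundary between leave-one-out and 10-fold cross-validation
LOOCV_MAX_N = 200


def _xy(X: ExpressionMatrix, y: pd.Series) -> tuple[np.ndarray, np.ndarray, list[str]]:
    y = y.reindex(X.sample_ids)
    if y.isna().any():
        raise ValueError("labels missing for some samples")
    if y.nunique() < 2:
        raise ValueError("need >= 2 classes")
    return X.values.to_numpy(dtype=float).T, y.to_numpy(dtype=object), X.gene_ids


def discretize(values: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Equal-frequency binning of one gene's values (constant genes -> one bin)."""
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, values, side="right")


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _mutual_info(x_binned: np.ndarray, y: np.ndarray) -> float:
    hy = _entropy(y)
    h_cond = 0.0
    n = len(y)
    for v in np.unique(x_binned):
        mask = x_binned == v
        h_cond += mask.sum() / n * _entropy(y[mask])
    return hy - h_cond


def _symmetric_uncertainty(x_binned: np.ndarray, y: np.ndarray) -> float:
    hx, hy = _entropy(x_binned), _entropy(y)
    if hx + hy == 0:
        return 0.0
    return 2.0 * _mutual_info(x_binned, y) / (hx + hy)


def _chi2_stat(x_binned: np.ndarray, y: np.ndarray) -> float:
    table = pd.crosstab(x_binned, y).to_numpy()
    if min(table.shape) < 2:
        return 0.0
    return float(stats.chi2_contingency(table, correction=False).statistic)


def rank_features(X: ExpressionMatrix, y: pd.Series, method: str,
                  n_bins: int = 3) -> pd.DataFrame:
    """Filter-method gene ranking on equal-frequency binned expression.

    Returns a DataFrame indexed by gene with ``score`` (descending order)
    and, for FCBF, a boolean ``selected`` column from the predominance-based
    redundancy removal.
    """
    if method not in FILTER_METHODS:
        raise ValueError(f"unknown filter method {method!r}")
    mat, labels, genes = _xy(X, y)
    binned = np.column_stack([discretize(mat[:, j], n_bins)
                              for j in range(mat.shape[1])])
    if method == "chi2":
        score = np.array([_chi2_stat(binned[:, j], labels)
                          for j in range(binned.shape[1])])
        out = pd.DataFrame({"score": score}, index=genes)
    elif method == "info_gain":
        score = np.array([_mutual_info(binned[:, j], labels)
                          for j in range(binned.shape[1])])
        out = pd.DataFrame({"score": score}, index=genes)
    else:  # fcbf
        su = np.array([_symmetric_uncertainty(binned[:, j], labels)
                       for j in range(binned.shape[1])])
        order = sorted(range(len(genes)), key=lambda j: (-su[j], genes[j]))
        kept: list[int] = []
        for j in order:
            if su[j] <= 0:
                continue
            redundant = any(
                _symmetric_uncertainty(binned[:, i], binned[:, j]) >= su[j]
                for i in kept)
            if not redundant:
                kept.append(j)
        selected = np.zeros(len(genes), dtype=bool)
        selected[kept] = True
        out = pd.DataFrame({"score": su, "selected": selected}, index=genes)
    return out.sort_values("score", ascending=False, kind="stable")


def model_importance(X: ExpressionMatrix, y: pd.Series, method: str,
                     seed: int = 0) -> pd.DataFrame:
    """Model-based gene importance ranking.

    ``rf_mda``: random-forest permutation importance (mean decrease in
    accuracy on a held-out stratified split); ``gboost``: gradient-boosted
    tree total split gain; ``boruta``: shadow-feature hit counts with
    binomial confirm/reject decisions (``confirmed`` column).
    """
    if method not in MODEL_METHODS:
        raise ValueError(f"unknown model method {method!r}")
    mat, labels, genes = _xy(X, y)
    if method == "rf_mda":
        idx_tr, idx_te = next(StratifiedKFold(
            n_splits=3, shuffle=True, random_state=seed).split(mat, labels))
        rf = RandomForestClassifier(n_estimators=300, random_state=seed,
                                    n_jobs=1)
        rf.fit(mat[idx_tr], labels[idx_tr])
        imp = permutation_importance(rf, mat[idx_te], labels[idx_te],
                                     n_repeats=5, random_state=seed,
                                     scoring="accuracy", n_jobs=1)
        out = pd.DataFrame({"score": imp.importances_mean}, index=genes)
    elif method == "gboost":
        codes, _ = pd.factorize(pd.Series(labels), sort=True)
        model = XGBClassifier(n_estimators=200, max_depth=3,
                              learning_rate=0.2, tree_method="hist",
                              importance_type="gain", random_state=seed,
                              verbosity=0, n_jobs=1)
        model.fit(mat, codes)
        out = pd.DataFrame({"score": model.feature_importances_}, index=genes)
    else:
        out = _boruta(mat, labels, genes, seed)
    return out.sort_values("score", ascending=False, kind="stable")


def _boruta(mat: np.ndarray, labels: np.ndarray, genes: list[str],
            seed: int, n_iter: int = 30, alpha: float = 0.01) -> pd.DataFrame:
    """Boruta: real features must beat the best permuted shadow feature."""
    rng = np.random.default_rng(seed)
    hits = np.zeros(mat.shape[1], dtype=int)
    for it in range(n_iter):
        shadow = mat.copy()
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        both = np.hstack([mat, shadow])
        rf = RandomForestClassifier(n_estimators=200, max_features="sqrt",
                                    random_state=seed + it, n_jobs=1)
        rf.fit(both, labels)
        imp = rf.feature_importances_
        threshold = imp[mat.shape[1]:].max()
        hits += imp[: mat.shape[1]] > threshold
    p_hi = stats.binom.sf(hits - 1, n_iter, 0.5)
    p_lo = stats.binom.cdf(hits, n_iter, 0.5)
    confirmed = p_hi < alpha
    rejected = p_lo < alpha
    return pd.DataFrame({"score": hits / n_iter, "confirmed": confirmed,
                         "rejected": rejected}, index=genes)


@dataclass
class FeatureVote:
    """Per-gene selection flags of the six algorithms plus vote summaries."""

    table: pd.DataFrame  # columns: six bool flags, vote, mean_rank

    @property
    def votes(self) -> pd.Series:
        return self.table["vote"]


def feature_vote(X: ExpressionMatrix, y: pd.Series, seed: int = 0,
                 n_top: int = 100) -> FeatureVote:
    """Run all six selectors and tabulate per-gene votes.

    Ranking methods nominate their top ``n_top`` positive-score genes; FCBF
    nominates its predominance-selected subset and Boruta its confirmed set.
    """
    flags = {}
    ranks = {}
    for method in FILTER_METHODS:
        res = rank_features(X, y, method)
        ranks[method] = pd.Series(np.arange(1, len(res) + 1), index=res.index)
        if method == "fcbf":
            flags[method] = res["selected"]
        else:
            top = res.index[: n_top][res["score"].iloc[: n_top] > 0]
            flags[method] = pd.Series(res.index.isin(top), index=res.index)
    for method in MODEL_METHODS:
        res = model_importance(X, y, method, seed=seed)
        ranks[method] = pd.Series(np.arange(1, len(res) + 1), index=res.index)
        if method == "boruta":
            flags[method] = res["confirmed"]
        else:
            top = res.index[: n_top][res["score"].iloc[: n_top] > 0]
            flags[method] = pd.Series(res.index.isin(top), index=res.index)
    genes = X.gene_ids
    table = pd.DataFrame({m: flags[m].reindex(genes) for m in ALL_METHODS})
    table["vote"] = table[list(ALL_METHODS)].sum(axis=1)
    table["mean_rank"] = pd.DataFrame(
        {m: ranks[m].reindex(genes) for m in ALL_METHODS}).mean(axis=1)
    return FeatureVote(table)


def ensemble_vote(votes: FeatureVote, min_votes: int = 4) -> list[str]:
    """Genes selected by at least ``min_votes`` algorithms, ordered by
    (vote desc, mean importance rank asc, gene id)."""
    t = votes.table
    chosen = t[t["vote"] >= min_votes]
    if chosen.empty:
        warnings.warn(f"no gene reached {min_votes} votes; consider a lower "
                      "threshold")
    order = sorted(chosen.index,
                   key=lambda g: (-chosen.at[g, "vote"],
                                  chosen.at[g, "mean_rank"], g))
    return order


def prune_correlated(X: ExpressionMatrix, panel: list[str],
                     cutoff: float = 0.8) -> list[str]:
    """Iterative pairwise-correlation pruning (findCorrelation heuristic).

    While any pair exceeds ``cutoff`` in absolute Pearson correlation, the
    member of the worst pair with the larger mean absolute correlation
    against all remaining features is dropped.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0,1)")
    keep = list(panel)
    if len(keep) < 2:
        return keep
    corr = X.subset_genes(keep).values.T.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    idx = list(range(len(keep)))
    while True:
        sub = corr[np.ix_(idx, idx)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= cutoff:
            break
        mean_i = sub[i].sum() / (len(idx) - 1)
        mean_j = sub[j].sum() / (len(idx) - 1)
        drop = i if mean_i >= mean_j else j
        idx.pop(drop)
    return [keep[i] for i in idx]


def _cv_splitter(n: int, scheme: str, seed: int, n_splits: int = 10):
    if scheme == "loocv" or (scheme == "auto" and n <= LOOCV_MAX_N):
        return LeaveOneOut(), "loocv"
    return (StratifiedKFold(n_splits=n_splits, shuffle=True,
                            random_state=seed), "kfold")


def _default_model(seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)


@dataclass
class PanelEvaluation:
    genes: list[str]
    accuracy: list[float]      # accuracy(m) for nested panels of size m=1..M
    cv_scheme: str
    chosen_size: int

    @property
    def chosen_panel(self) -> list[str]:
        return self.genes[: self.chosen_size]


def stepwise_panel(X: ExpressionMatrix, y: pd.Series, ranked_genes: list[str],
                   model=None, cv: str = "auto", seed: int = 0,
                   max_size: int | None = None) -> PanelEvaluation:
    """Incremental (one gene at a time) panel-size evaluation.

    The chosen size is the smallest panel whose cross-validated accuracy is
    within half a binomial standard error of the curve maximum.
    """
    if not ranked_genes:
        raise ValueError("ranked_genes must be non-empty")
    mat, labels, _ = _xy(X.subset_genes(ranked_genes), y)
    M = len(ranked_genes) if max_size is None else min(max_size,
                                                       len(ranked_genes))
    splitter, scheme = _cv_splitter(len(labels), cv, seed)
    model = model if model is not None else _default_model(seed)
    cols = {g: i for i, g in enumerate(X.subset_genes(ranked_genes).gene_ids)}
    order = [cols[g] for g in ranked_genes]
    acc = []
    for m in range(1, M + 1):
        sub = mat[:, order[:m]]
        acc.append(float(cross_val_score(clone(model), sub, labels,
                                         cv=splitter,
                                         scoring="accuracy").mean()))
    best = max(acc)
    se = np.sqrt(best * (1 - best) / len(labels))
    chosen = next(m for m, a in enumerate(acc, start=1) if a >= best - 0.5 * se)
    return PanelEvaluation(list(ranked_genes[:M]), acc, scheme, chosen)


def rfe_select(X: ExpressionMatrix, y_binary: pd.Series, model=None,
               cv: str = "auto", seed: int = 0, min_size: int = 1,
               drop_fraction: float = 0.25, cv_splits: int = 10
               ) -> tuple[list[str], pd.DataFrame]:
    """Recursive feature elimination for a binary contrast.

    Each round fits the model, ranks genes by importance, records the
    cross-validated accuracy of the current subset, and drops the weakest
    ``drop_fraction`` (at least one gene), stopping at ``min_size``.  The
    best-accuracy subset is returned (ties -> the smaller subset), along
    with the elimination trace.
    """
    mat, labels, genes = _xy(X, y_binary)
    if len(np.unique(labels)) != 2:
        raise ValueError("rfe_select expects a binary contrast")
    splitter, scheme = _cv_splitter(len(labels), cv, seed, cv_splits)
    model = model if model is not None else _default_model(seed)
    current = list(range(len(genes)))
    trace = []
    best_subset, best_acc = None, -1.0
    while True:
        sub = mat[:, current]
        acc = float(cross_val_score(clone(model), sub, labels, cv=splitter,
                                    scoring="accuracy").mean())
        trace.append({"size": len(current), "accuracy": acc})
        # ties prefer the smaller panel, i.e. a later (smaller) subset wins
        if acc >= best_acc:
            best_acc = acc
            best_subset = list(current)
        if len(current) <= min_size:
            break
        fitted = clone(model).fit(sub, labels)
        importance = _model_feature_importance(fitted, sub, labels)
        n_drop = max(1, int(len(current) * drop_fraction))
        n_drop = min(n_drop, len(current) - min_size)
        order = np.argsort(importance, kind="stable")
        drop = set(order[:n_drop])
        current = [c for i, c in enumerate(current) if i not in drop]
    chosen = [genes[i] for i in best_subset]
    return chosen, pd.DataFrame(trace)


def _model_feature_importance(model, mat: np.ndarray,
                              labels: np.ndarray) -> np.ndarray:
    if hasattr(model, "feature_importances_"):
        return np.asarray(model.feature_importances_, dtype=float)
    if hasattr(model, "coef_"):
        return np.abs(np.atleast_2d(model.coef_)).sum(axis=0)
    if hasattr(model, "estimators_"):
        imps = [est.feature_importances_ for est in model.estimators_
                if hasattr(est, "feature_importances_")]
        if imps:
            return np.mean(imps, axis=0)
    # model-agnostic fallback: univariate ANOVA F statistic
    f, _ = f_classif(mat, labels)
    return np.nan_to_num(f)


def _make_family(family: str, seed: int):
    if family == "lda":
        return LinearDiscriminantAnalysis()
    if family == "naive_bayes":
        return GaussianNB()
    if family == "bagged_trees":
        return BaggingClassifier(DecisionTreeClassifier(random_state=seed),
                                 n_estimators=100, random_state=seed, n_jobs=1)
    if family == "random_forest":
        return RandomForestClassifier(n_estimators=300, random_state=seed,
                                      n_jobs=1)
    raise ValueError(f"unknown model family {family!r}")


@dataclass
class ClassifierBundle:
    """Final gene panel, trained model, and evaluation metrics."""

    panel: list[str]
    family: str
    model: object
    classes: list[str]
    train_cv_accuracy: float
    test_accuracy: float
    auc_per_class: dict[str, float]
    confusion: pd.DataFrame
    split_seed: int
    family_report: pd.DataFrame = field(default_factory=pd.DataFrame)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.Series(self.panel, name="gene").to_csv(
            directory / "panel.tsv", sep="\t", index=False)
        metrics = {
            "family": self.family, "classes": self.classes,
            "train_cv_accuracy": self.train_cv_accuracy,
            "test_accuracy": self.test_accuracy,
            "auc_per_class": self.auc_per_class,
            "split_seed": self.split_seed,
            "confusion": self.confusion.to_dict(),
        }
        (directory / "metrics.json").write_text(json.dumps(metrics, indent=2))
        joblib.dump(self.model, directory / "model.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "ClassifierBundle":
        directory = Path(directory)
        metrics = json.loads((directory / "metrics.json").read_text())
        panel = pd.read_csv(directory / "panel.tsv", sep="\t")["gene"].tolist()
        model = joblib.load(directory / "model.joblib")
        return cls(panel=panel, family=metrics["family"], model=model,
                   classes=metrics["classes"],
                   train_cv_accuracy=metrics["train_cv_accuracy"],
                   test_accuracy=metrics["test_accuracy"],
                   auc_per_class=metrics["auc_per_class"],
                   confusion=pd.DataFrame(metrics["confusion"]),
                   split_seed=metrics["split_seed"])


def _family_rfe(model_proto, mat: np.ndarray, labels: np.ndarray,
                genes: list[str], splitter) -> tuple[list[int], float]:
    """Drop-one-at-a-time RFE over a small panel for one model family."""
    current = list(range(len(genes)))
    best_cols, best_acc = None, -1.0
    while True:
        sub = mat[:, current]
        acc = float(cross_val_score(clone(model_proto), sub, labels,
                                    cv=splitter, scoring="accuracy").mean())
        if acc >= best_acc:
            best_acc, best_cols = acc, list(current)
        if len(current) == 1:
            break
        fitted = clone(model_proto).fit(sub, labels)
        imp = _model_feature_importance(fitted, sub, labels)
        current.pop(int(np.argmin(imp)))
    return best_cols, best_acc


def train_final(X: ExpressionMatrix, y: pd.Series, panel: list[str],
                split: float = 0.7, families: tuple[str, ...] = FAMILIES,
                seed: int = 0, max_retries: int = 5,
                cv_splits: int = 10) -> ClassifierBundle:
    """Train and select the final multiclass gene-panel classifier.

    Stratified ``split``/(1-split) train/test partition; each model family
    is refined by per-family RFE over the input panel with cross-validation
    on the training set; the family with the best CV accuracy wins and is
    evaluated on the held-out split (accuracy, per-class one-vs-rest AUC,
    confusion matrix).
    """
    Xp = X.subset_genes(panel)
    mat, labels, genes = _xy(Xp, y)
    class_counts = pd.Series(labels).value_counts()
    if (class_counts < 5).any():
        raise ValueError("every class needs >= 5 samples")
    for attempt in range(max_retries):
        rs = seed + attempt
        idx_tr, idx_te = train_test_split(
            np.arange(len(labels)), test_size=1 - split, stratify=labels,
            random_state=rs)
        if (len(np.unique(labels[idx_tr])) == class_counts.size
                and len(np.unique(labels[idx_te])) == class_counts.size):
            break
        warnings.warn("a class was absent from a split; re-drawing")
    # family comparison uses stratified k-fold regardless of cohort size:
    # per-family RFE multiplies the CV cost by the panel size, which makes
    # leave-one-out prohibitive for the tree ensembles
    splitter = StratifiedKFold(n_splits=cv_splits, shuffle=True,
                               random_state=seed)

    report = []
    for family in families:
        proto = _make_family(family, seed)
        cols, acc = _family_rfe(proto, mat[idx_tr], labels[idx_tr], genes,
                                splitter)
        report.append({"family": family, "cv_accuracy": acc,
                       "panel_size": len(cols), "cols": cols})
    report_df = pd.DataFrame(report)
    best = report_df.sort_values(["cv_accuracy", "panel_size"],
                                 ascending=[False, True],
                                 kind="stable").iloc[0]
    final_cols = list(best["cols"])
    final_genes = [genes[i] for i in final_cols]
    model = _make_family(best["family"], seed)
    model.fit(mat[np.ix_(idx_tr, final_cols)], labels[idx_tr])

    te_X = mat[np.ix_(idx_te, final_cols)]
    pred = model.predict(te_X)
    proba = model.predict_proba(te_X)
    classes = list(model.classes_)
    auc = {}
    for i, cls in enumerate(classes):
        auc[cls] = float(roc_auc_score((labels[idx_te] == cls).astype(int),
                                       proba[:, i]))
    conf = pd.DataFrame(
        confusion_matrix(labels[idx_te], pred, labels=classes),
        index=[f"true_{c}" for c in classes],
        columns=[f"pred_{c}" for c in classes])
    return ClassifierBundle(
        panel=final_genes, family=str(best["family"]), model=model,
        classes=classes,
        train_cv_accuracy=float(best["cv_accuracy"]),
        test_accuracy=float(accuracy_score(labels[idx_te], pred)),
        auc_per_class=auc, confusion=conf, split_seed=seed,
        family_report=report_df.drop(columns=["cols"]))


def predict_subtype(bundle: ClassifierBundle, X_new: ExpressionMatrix
                    ) -> tuple[CohortLabels, pd.DataFrame]:
    """Apply a trained bundle to new samples.

    Raises if any panel gene is missing from ``X_new`` (naming the genes);
    returns predicted labels (stage tag ``predicted``) and the per-sample
    class-probability table.
    """
    missing = [g for g in bundle.panel if g not in X_new.values.index]
    if missing:
        raise KeyError(f"panel genes missing from input: {missing}")
    mat = X_new.subset_genes(bundle.panel).values.to_numpy(dtype=float).T
    proba = bundle.model.predict_proba(mat)
    proba_df = pd.DataFrame(proba, index=X_new.sample_ids,
                            columns=bundle.classes)
    labels = pd.Series(np.asarray(bundle.classes, dtype=object)[
        proba.argmax(axis=1)], index=X_new.sample_ids)
    return CohortLabels(labels, stage_tag="predicted"), proba_df
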