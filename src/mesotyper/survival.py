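"""Survival analysis and subtype-stratified somatic-mutation association.

Kaplan-Meier estimation and Cox proportional-hazards regression are done
with lifelines (Efron tie handling); the k-group unweighted log-rank test
is computed directly in numpy so that large null-calibration sweeps stay
cheap, and is cross-checked against lifelines in the test suite.  Mutation
enrichment per gene uses two-sided Fisher exact tests (group vs rest or all
pairs) with Benjamini-Hochberg correction across genes.  All tests are
two-sided at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CohortLabels, MutationTable, SurvivalTable


@dataclass
class KMEstimate:
    """Per-group product-limit curves (event times, survival, at-risk)."""

    curves: dict[str, pd.DataFrame]   # columns: time, at_risk, events,
                                      # censored, survival

    def median_survival(self) -> dict[str, float]:
        out = {}
        for g, df in self.curves.items():
            below = df[df["survival"] <= 0.5]
            out[g] = float(below["time"].iloc[0]) if len(below) else float("inf")
        return out


def _align(surv: SurvivalTable, groups: CohortLabels | pd.Series
           ) -> pd.DataFrame:
    labels = groups.labels if isinstance(groups, CohortLabels) else groups
    common = surv.data.index.intersection(labels.index)
    if not len(common):
        raise ValueError("no overlap between survival samples and group labels")
    df = surv.data.loc[common, ["time", "event"]].copy()
    df["group"] = labels.loc[common]
    return df


def km_estimate(surv: SurvivalTable, groups: CohortLabels | pd.Series
                ) -> KMEstimate:
    """Product-limit survival curve per group with right censoring."""
    df = _align(surv, groups)
    curves = {}
    for g, block in df.groupby("group", sort=True):
        if block.empty:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(block["time"], block["event"])
        table = kmf.event_table.iloc[1:] if 0.0 not in block["time"].values \
            else kmf.event_table
        sf = kmf.survival_function_["KM_estimate"]
        curve = pd.DataFrame({
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(),
            "events": table["observed"].to_numpy(),
            "censored": table["censored"].to_numpy(),
            "survival": sf.reindex(table.index).to_numpy(),
        }).reset_index(drop=True)
        curves[str(g)] = curve
    return KMEstimate(curves)


def logrank_test(surv: SurvivalTable, groups: CohortLabels | pd.Series
                 ) -> tuple[float, float]:
    """Unweighted k-group log-rank test; returns (chi-square, p), df = k-1."""
    df = _align(surv, groups)
    group_names = sorted(df["group"].unique())
    k = len(group_names)
    if k < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    codes = df["group"].map({g: i for i, g in enumerate(group_names)}).to_numpy()
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)

    order = np.argsort(time, kind="stable")
    time, event, codes = time[order], event[order], codes[order]
    event_times = np.unique(time[event == 1])

    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        nj = np.bincount(codes[at_risk], minlength=k).astype(float)
        dying = at_risk & (time == t) & (event == 1)
        d = dying.sum()
        dj = np.bincount(codes[dying], minlength=k).astype(float)
        O += dj
        E += d * nj / n
        if n > 1:
            frac = nj / n
            V += d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, p


def cox_multivariate(surv: SurvivalTable, covariates: list[str] | None = None
                     ) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit (Efron ties).

    Categorical covariates are dummy-coded against their first sorted level.
    Returns a forest-plot-ready table: HR, 95% CI, and p per coefficient.
    """
    covariates = covariates if covariates is not None else surv.covariates
    data = surv.data[["time", "event"] + list(covariates)].copy()
    for c in covariates:
        if data[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    data = pd.get_dummies(data, columns=[c for c in covariates
                                         if data[c].dtype == object],
                          drop_first=True, dtype=float)
    n_events = int(data["event"].sum())
    n_coef = data.shape[1] - 2
    if n_events < 5 * n_coef:
        warnings.warn(f"only {n_events} events for {n_coef} coefficients; "
                      "estimates may be unstable")
    cph = CoxPHFitter()
    cph.fit(data, duration_col="time", event_col="event")
    summary = cph.summary
    return pd.DataFrame({
        "HR": summary["exp(coef)"],
        "HR_lower95": summary["exp(coef) lower 95%"],
        "HR_upper95": summary["exp(coef) upper 95%"],
        "p": summary["p"],
    })


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 count table."""
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass
class EnrichmentReport:
    """Per-gene, per-comparison mutation enrichment table."""

    table: pd.DataFrame   # gene, comparison, counts, odds_ratio, p, fdr,
                          # direction

    def significant(self, threshold: float = 0.05,
                    use_fdr: bool = False) -> pd.DataFrame:
        col = "fdr" if use_fdr else "p"
        return self.table[self.table[col] < threshold]


def mutation_enrichment(maf: MutationTable, groups: CohortLabels | pd.Series,
                        mode: str = "vs_rest", include_silent: bool = False,
                        min_mutated: int = 1) -> EnrichmentReport:
    """Per-gene subtype mutation enrichment via two-sided Fisher exact tests.

    ``vs_rest`` compares each group against all other samples; ``pairwise``
    compares every group pair.  BH FDR is applied across all gene x
    comparison tests.
    """
    if mode not in ("vs_rest", "pairwise"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = groups.labels if isinstance(groups, CohortLabels) else groups
    samples = labels.index
    group_names = sorted(labels.unique())
    if len(group_names) < 2:
        raise ValueError("enrichment needs >= 2 groups")
    rows = []
    for gene in maf.genes(include_silent=include_silent):
        mutated = maf.mutated_samples(gene, include_silent=include_silent)
        mutated &= set(samples)
        if len(mutated) < min_mutated:
            continue
        is_mut = pd.Series(samples.isin(mutated), index=samples)
        if mode == "vs_rest":
            comparisons = [(g, None) for g in group_names]
        else:
            comparisons = [(a, b) for i, a in enumerate(group_names)
                           for b in group_names[i + 1:]]
        for a, b in comparisons:
            in_a = labels == a
            in_b = (labels != a) if b is None else (labels == b)
            t = np.array([[int((is_mut & in_a).sum()),
                           int((~is_mut & in_a).sum())],
                          [int((is_mut & in_b).sum()),
                           int((~is_mut & in_b).sum())]])
            if t[0].sum() == 0 or t[1].sum() == 0:
                continue
            odds = stats.contingency.odds_ratio(t, kind="sample").statistic \
                if t.min() >= 0 else np.nan
            p = fisher_exact_2x2(t)
            rate_a = t[0, 0] / t[0].sum()
            rate_b = t[1, 0] / t[1].sum()
            rows.append({
                "gene": gene, "group": a,
                "versus": "rest" if b is None else b,
                "mutated_in_group": int(t[0, 0]), "group_size": int(t[0].sum()),
                "mutated_in_other": int(t[1, 0]), "other_size": int(t[1].sum()),
                "odds_ratio": float(odds),
                "direction": "enriched" if rate_a > rate_b else
                             ("depleted" if rate_a < rate_b else "equal"),
                "p": p,
            })
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["fdr"] = []
    return EnrichmentReport(table)


def group_compare(values: pd.Series, groups: pd.Series, paired: bool = False
                  ) -> tuple[str, float, float]:
    """Two-group comparison with a Shapiro-Wilk normality gate.

    Both groups normal at alpha = 0.05 -> Student t-test; otherwise
    Mann-Whitney U.  Groups smaller than 3 skip the gate and fall back to
    Mann-Whitney with a warning.  Returns (test name, statistic, p).
    """
    common = values.index.intersection(groups.index)
    v, g = values.loc[common], groups.loc[common]
    names = sorted(g.unique())
    if len(names) != 2:
        raise ValueError("group_compare expects exactly two groups")
    a = v[g == names[0]].to_numpy(dtype=float)
    b = v[g == names[1]].to_numpy(dtype=float)
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs >= 2 values")
    if min(len(a), len(b)) < 3:
        warnings.warn("group too small for Shapiro test; using Mann-Whitney")
        normal = False
    else:
        normal = (stats.shapiro(a).pvalue > 0.05
                  and stats.shapiro(b).pvalue > 0.05)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal group sizes")
        if normal:
            res = stats.ttest_rel(a, b)
            return "paired_t", float(res.statistic), float(res.pvalue)
        res = stats.wilcoxon(a, b)
        return "wilcoxon", float(res.statistic), float(res.pvalue)
    if normal:
        res = stats.ttest_ind(a, b)
        return "t", float(res.statistic), float(res.pvalue)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return "mannwhitney", float(res.statistic), float(res.pvalue)


def chi_square_association(x: pd.Series, y: pd.Series) -> tuple[float, float]:
    """Chi-square test of independence between two categorical labellings."""
    common = x.index.intersection(y.index)
    table = pd.crosstab(x.loc[common], y.loc[common])
    res = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(res.statistic), float(res.pvalue)
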