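"""Truth-known synthetic MPM-like cohorts.

The generator emulates the statistical structure the subtyping analysis
assumes: multi-batch log2 expression with additive batch location/scale
effects, a low-rank gene-module structure (a shared immune module, activated
and suppressed marker modules, and cell-cycle / IFN-epithelial / ECM modules
that partition the non-immune samples), three latent immune subtypes,
subtype-dependent exponential survival with independent censoring, and
subtype-enriched somatic mutations.  Every downstream stage is tested
against the planted truth, so no external cohort download is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (CohortLabels, ExpressionMatrix, GeneSetCollection,
                         MutationTable, SurvivalTable, SUBTYPES)

#: module target kinds: which samples get the module's expression boost
TARGETS = ("immune", "activated", "suppressed", "subgroup", "covers",
           "random", "all")


@dataclass(frozen=True)
class ModuleSpec:
    """A planted gene module of marker-like genes.

    ``target`` selects the samples in which the module is up-regulated:
    ``immune`` = both immune subtypes, ``activated`` / ``suppressed`` = one
    fine subtype, ``subgroup`` = a dedicated random subgroup of non-immune
    samples (this is what gives the cohort its multi-module non-immune arm).

    Module genes sit at ``off_level`` (near the log2 noise floor) outside
    their target samples and at ``off_level + effect_size`` within them --
    the bimodal on/off behaviour of real lineage marker genes, and the
    separability structure that makes NMF module recovery well posed.
    """

    name: str
    n_genes: int
    effect_size: float
    target: str = "subgroup"
    off_level: float = 3.5
    #: for target="covers": names of subgroup modules whose samples also
    #: express this module (nested / hierarchical structure)
    covers: tuple[str, ...] = ()
    #: for target="random": fraction of samples (drawn at random, crossing
    #: subtype boundaries) expressing this module -- minor co-expression
    #: programs below the main subtype structure
    subset_fraction: float = 0.25
    #: (subgroup module name, fraction) pairs: samples of those subgroups
    #: also express this module at fraction * effect_size.  Cross-expression
    #: correlates subgroup centroids (a nested similarity hierarchy) without
    #: introducing any additional gene module
    secondary: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"unknown module target {self.target!r}")
        if self.covers and self.target != "covers":
            raise ValueError("covers requires target='covers'")


@dataclass(frozen=True)
class MutationSpec:
    """A planted mutable gene with per-subtype mutation probabilities."""

    gene: str
    rates: dict[str, float]
    variant_classification: str = "Missense_Mutation"
    variant_type: str = "SNP"


def default_modules() -> list[ModuleSpec]:
    """Default planted modules.

    The shared immune module and the three non-immune modules carry strong
    marker-like contrasts (4.5 sigma on/off, e.g. 3.5 -> 8 on the log2
    scale) and define the cohort's four-module sample structure; the
    activated / suppressed marker modules carry a weaker 3 sigma contrast
    that the signature-level NTP stage resolves without dominating the
    module-level NMF structure.
    """
    return [
        ModuleSpec("immune", 80, 4.5, "immune"),
        ModuleSpec("lymphoid_ifn", 30, 3.0, "activated"),
        ModuleSpec("tam_mdsc_stroma", 30, 3.0, "suppressed"),
        ModuleSpec("cell_cycle", 60, 4.5, "subgroup"),
        ModuleSpec("ifn_epithelial", 60, 4.5, "subgroup"),
        ModuleSpec("ecm", 60, 4.5, "subgroup"),
        ModuleSpec("stromal_axis", 40, 3.5, "covers",
                   covers=("ifn_epithelial", "ecm")),
    ]


def default_mutations() -> list[MutationSpec]:
    return [
        MutationSpec("BAP1", {"non_immune": 0.28, "immune_suppressed": 0.25,
                              "immune_activated": 0.45}),
        MutationSpec("NF2", {"non_immune": 0.28, "immune_suppressed": 0.45,
                             "immune_activated": 0.25}),
        MutationSpec("SETDB1", {"non_immune": 0.02, "immune_suppressed": 0.18,
                                "immune_activated": 0.02}),
        MutationSpec("LATS2", {"non_immune": 0.12, "immune_suppressed": 0.12,
                               "immune_activated": 0.12}),
        MutationSpec("TP53", {"non_immune": 0.15, "immune_suppressed": 0.15,
                              "immune_activated": 0.15}),
        MutationSpec("TTN", {"non_immune": 0.35, "immune_suppressed": 0.35,
                             "immune_activated": 0.35}),
    ]


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full description of a synthetic cohort.

    Defaults follow the cohort the subtyping system was developed on: 333
    samples split 62.5% / 21.0% / 16.5% into non-immune / immune-suppressed /
    immune-activated, expression generated directly on the log2 scale with
    unit noise, two batches with a location/scale offset, exponential
    survival ordered suppressed < non-immune < activated, and
    subtype-enriched mutations (BAP1-like in activated, NF2/SETDB1-like in
    suppressed).
    """

    n_samples: int = 333
    n_genes: int = 2000
    module_specs: tuple[ModuleSpec, ...] = field(
        default_factory=lambda: tuple(default_modules()))
    subtype_proportions: tuple[float, float, float] = (0.625, 0.210, 0.165)
    n_batches: int = 2
    batch_shift: float = 1.0
    batch_scale: float = 1.25
    noise_sd: float = 1.0
    #: correlated (co-regulation) noise: number of latent expression factors
    #: shared across genes, and the per-factor standard deviation in log2
    #: units; set n_noise_factors=0 for purely independent noise
    n_noise_factors: int = 6
    noise_factor_sd: float = 0.4
    baseline_mean: float = 7.0
    #: monthly exponential hazards, ordered (non_immune, suppressed, activated)
    hazard_per_subtype: tuple[float, float, float] = (0.035, 0.058, 0.023)
    censor_rate: float = 0.3
    mutation_specs: tuple[MutationSpec, ...] = field(
        default_factory=lambda: tuple(default_mutations()))
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        if any(h <= 0 for h in self.hazard_per_subtype):
            raise ValueError("hazards must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0,1)")
        total = sum(m.n_genes for m in self.module_specs)
        if total > self.n_genes:
            raise ValueError(f"module genes ({total}) exceed n_genes")
        for p, name in zip(self.subtype_proportions, SUBTYPES):
            if 0 < p * self.n_samples < 1:
                raise ValueError(f"subtype {name} expects <1 sample at n="
                                 f"{self.n_samples}; infeasible config")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated cohort."""

    true_labels: CohortLabels
    module_membership: pd.Series  # gene -> module name ('background' if none)
    subgroup: pd.Series           # non-immune samples -> non-immune module
    config: SyntheticCohortConfig

    def module_genes(self, module: str) -> list[str]:
        return list(self.module_membership.index[self.module_membership == module])


def _draw_subtypes(rng: np.random.Generator, cfg: SyntheticCohortConfig) -> np.ndarray:
    labels = rng.choice(len(SUBTYPES), size=cfg.n_samples,
                        p=np.asarray(cfg.subtype_proportions))
    return np.asarray(SUBTYPES, dtype=object)[labels]


def generate_cohort(config: SyntheticCohortConfig
                    ) -> tuple[ExpressionMatrix, SyntheticTruth, SurvivalTable,
                               MutationTable, GeneSetCollection]:
    """Generate a full truth-known cohort.

    Expression = baseline + planted module effects (per latent subtype) +
    per-gene batch location shift + batch-scaled Gaussian noise, clipped at 0
    so the matrix is directly usable by NMF.  Survival is exponential with
    the subtype hazard and independently censored; mutations are Bernoulli
    per (gene, subtype).  The returned gene-set collection contains one set
    per planted module plus activated / suppressed marker alias sets.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]

    subtype = _draw_subtypes(rng, cfg)
    is_immune = subtype != "non_immune"

    # assign module gene blocks front-to-back, remainder is background
    membership = pd.Series("background", index=pd.Index(genes, name="gene"),
                           dtype=object)
    cursor = 0
    module_rows: dict[str, np.ndarray] = {}
    for mod in cfg.module_specs:
        rows = np.arange(cursor, cursor + mod.n_genes)
        module_rows[mod.name] = rows
        membership.iloc[rows] = mod.name
        cursor += mod.n_genes

    # non-immune subgroup assignment for 'subgroup'-targeted modules
    subgroup_mods = [m.name for m in cfg.module_specs if m.target == "subgroup"]
    subgroup = pd.Series(index=pd.Index(samples, name="sample_id"), dtype=object)
    ni_idx = np.flatnonzero(~is_immune)
    if subgroup_mods and len(ni_idx):
        picks = rng.integers(0, len(subgroup_mods), size=len(ni_idx))
        subgroup.iloc[ni_idx] = np.asarray(subgroup_mods, dtype=object)[picks]

    signal = np.full((cfg.n_genes, cfg.n_samples), cfg.baseline_mean)
    for mod in cfg.module_specs:
        signal[module_rows[mod.name], :] = mod.off_level
        if mod.effect_size == 0:
            continue
        if mod.target == "all":
            cols = np.ones(cfg.n_samples, dtype=bool)
        elif mod.target == "immune":
            cols = is_immune
        elif mod.target == "activated":
            cols = subtype == "immune_activated"
        elif mod.target == "suppressed":
            cols = subtype == "immune_suppressed"
        elif mod.target == "covers":
            cols = subgroup.isin(mod.covers).to_numpy()
        elif mod.target == "random":
            cols = rng.random(cfg.n_samples) < mod.subset_fraction
        else:  # subgroup
            cols = (subgroup == mod.name).to_numpy()
        signal[np.ix_(module_rows[mod.name], np.flatnonzero(cols))] += mod.effect_size
        for other, frac in mod.secondary:
            sec = (subgroup == other).to_numpy()
            signal[np.ix_(module_rows[mod.name],
                          np.flatnonzero(sec))] += frac * mod.effect_size

    # batch structure: round-robin assignment, per-gene location shift around
    # a centred batch offset, and a batch-specific noise scale
    batch_idx = np.arange(cfg.n_samples) % cfg.n_batches
    offsets = (np.arange(cfg.n_batches) - (cfg.n_batches - 1) / 2)
    shifts = offsets * cfg.batch_shift
    scales = cfg.batch_scale ** offsets
    gene_shift = np.empty((cfg.n_genes, cfg.n_batches))
    for b in range(cfg.n_batches):
        gene_shift[:, b] = rng.normal(shifts[b], 0.25 * abs(cfg.batch_shift) + 1e-12,
                                      size=cfg.n_genes)
    noise = rng.normal(0.0, cfg.noise_sd, size=signal.shape)
    if cfg.n_noise_factors > 0 and cfg.noise_factor_sd > 0:
        # co-regulation: latent expression factors shared across genes make
        # the noise correlated, as in real transcriptomes
        loadings = rng.normal(0.0, 1.0, size=(cfg.n_genes, cfg.n_noise_factors))
        factors = rng.normal(0.0, cfg.noise_factor_sd,
                             size=(cfg.n_noise_factors, cfg.n_samples))
        noise = noise + loadings @ factors
    X = signal + gene_shift[:, batch_idx] + noise * scales[batch_idx]
    np.clip(X, 0.0, None, out=X)

    expr = ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=samples),
        batch=pd.Series([f"batch{b}" for b in batch_idx], index=samples,
                        name="batch"))

    labels = CohortLabels(pd.Series(subtype, index=samples, name="subtype"),
                          stage_tag="truth")

    # survival: exponential event time at the subtype hazard; a Bernoulli
    # censoring flag with uniform-on-(0, T) censoring time keeps censoring
    # independent of group under equal hazards
    hazard_map = dict(zip(SUBTYPES, cfg.hazard_per_subtype))
    lam = np.array([hazard_map[s] for s in subtype])
    event_time = rng.exponential(1.0 / lam)
    censored = rng.random(cfg.n_samples) < cfg.censor_rate
    obs_time = np.where(censored, event_time * rng.random(cfg.n_samples),
                        event_time)
    obs_time = np.maximum(obs_time, 1e-6)
    surv = SurvivalTable(pd.DataFrame(
        {"time": obs_time, "event": (~censored).astype(int),
         "subtype": subtype},
        index=pd.Index(samples, name="sample_id")))

    # mutations
    rows = []
    for spec in cfg.mutation_specs:
        p = np.array([spec.rates.get(s, 0.0) for s in subtype])
        hit = rng.random(cfg.n_samples) < p
        for s_id in np.asarray(samples, dtype=object)[hit]:
            rows.append((s_id, spec.gene, spec.variant_classification,
                         spec.variant_type))
    maf = MutationTable(pd.DataFrame(
        rows, columns=["sample_id", "gene", "variant_classification",
                       "variant_type"]))

    sets = {m.name: set(membership.index[membership == m.name])
            for m in cfg.module_specs}
    for mod in cfg.module_specs:
        if mod.target == "activated":
            sets.setdefault("activated_markers", set()).update(sets[mod.name])
        elif mod.target == "suppressed":
            sets.setdefault("suppressed_markers", set()).update(sets[mod.name])
    gmt = GeneSetCollection(sets)

    truth = SyntheticTruth(labels, membership, subgroup, cfg)
    return expr, truth, surv, maf, gmt


def generate_null_cohort(config: SyntheticCohortConfig
                         ) -> tuple[ExpressionMatrix, SyntheticTruth,
                                    SurvivalTable, MutationTable,
                                    GeneSetCollection]:
    """Same tuple as :func:`generate_cohort` with all planted effects zeroed.

    Module effect sizes are set to 0, every subtype gets the non-immune
    hazard, and each gene's mutation rate is the proportion-weighted mean of
    its subtype rates, so no downstream stage should find structure.
    """
    props = dict(zip(SUBTYPES, config.subtype_proportions))
    null_mods = tuple(replace(m, effect_size=0.0) for m in config.module_specs)
    null_muts = tuple(
        replace(spec, rates={s: sum(spec.rates.get(t, 0.0) * props[t]
                                    for t in SUBTYPES) for s in SUBTYPES})
        for spec in config.mutation_specs)
    base_hazard = config.hazard_per_subtype[0]
    null_cfg = replace(config, module_specs=null_mods,
                       mutation_specs=null_muts,
                       hazard_per_subtype=(base_hazard,) * 3)
    return generate_cohort(null_cfg)


def rank_benchmark_config(seed: int = 0, n_samples: int = 100,
                          n_genes: int = 600) -> SyntheticCohortConfig:
    """A compact four-module cohort used for NMF rank-recovery benchmarks.

    The activated / suppressed marker contrast is omitted so the cohort
    carries exactly four sample-level structures: the immune arm plus three
    non-immune modules with graded strength and a shared stromal axis over
    the IFN-epithelial and ECM subgroups (an unambiguous merge hierarchy,
    as in real cohorts where subtype similarity is nested).  Correlated
    latent-factor noise supplies the minor co-expression structure that
    makes above-rank components restart-unstable.  Gene and sample counts
    are scaled down so repeated multi-rank NMF sweeps stay cheap.
    """
    modules = (
        ModuleSpec("immune", 80, 4.5, "immune"),
        ModuleSpec("cell_cycle", 50, 4.5, "subgroup"),
        ModuleSpec("ifn_epithelial", 40, 4.5, "subgroup"),
        ModuleSpec("ecm", 30, 4.5, "subgroup"),
        ModuleSpec("stromal_axis", 40, 3.5, "covers",
                   covers=("ifn_epithelial", "ecm")),
    )
    return SyntheticCohortConfig(n_samples=n_samples, n_genes=n_genes,
                                 module_specs=modules,
                                 n_noise_factors=10, noise_factor_sd=0.35,
                                 seed=seed)


def panel_benchmark_config(seed: int = 0, n_samples: int = 240,
                           n_genes: int = 500) -> SyntheticCohortConfig:
    """A compact cohort for gene-panel selection benchmarks.

    Forty informative genes (20 shared immune, 10 activated markers, 10
    suppressed markers) among ``n_genes`` total, so feature-selection recall
    and RFE behaviour can be measured against an exactly known panel via
    ``SyntheticTruth.module_membership``.
    """
    modules = (
        ModuleSpec("immune", 20, 4.5, "immune"),
        ModuleSpec("lymphoid_ifn", 10, 3.0, "activated"),
        ModuleSpec("tam_mdsc_stroma", 10, 3.0, "suppressed"),
    )
    return SyntheticCohortConfig(n_samples=n_samples, n_genes=n_genes,
                                 module_specs=modules, seed=seed)
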