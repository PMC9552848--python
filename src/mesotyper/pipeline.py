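"""End-to-end orchestration with a single master seed and a run manifest.

A run is configured by one structured (YAML) document with per-stage
sections.  The master seed fans out to per-stage seeds through a fixed
counter scheme (``numpy.random.SeedSequence``), so any stage can be re-run
in isolation and reproduce its in-pipeline behaviour.  Every artefact
written by a run is referenced in the manifest with its content hash; the
manifest itself is deterministic for a given configuration and seed
(wall-clock timing goes to the run log, not the manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (ClassifyConfig, TemplateDefinition, classify_cohort,
                       default_templates)
from .containers import CohortLabels, ExpressionMatrix
from .io import (read_expression, read_gene_sets, read_maf, read_survival,
                 write_expression, write_gene_sets, write_labels, write_maf,
                 write_survival)
from .panel import (ClassifierBundle, ensemble_vote, feature_vote,
                    prune_correlated, rfe_select, train_final)
from .preprocess import variance_filter
from .simulate import (ModuleSpec, MutationSpec, SyntheticCohortConfig,
                       generate_cohort)
from .ssgsea import ssgsea_score, z_normalize
from .survival import km_estimate, logrank_test, mutation_enrichment

log = logging.getLogger("mesotyper")

#: fixed stage order used by the counter-based seed fan-out
STAGES = ("simulate", "classify", "panel", "survival")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    idx = STAGES.index(stage)
    state = np.random.SeedSequence(master_seed).generate_state(len(STAGES))
    return int(state[idx] & 0x7FFFFFFF)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _cohort_config_from_dict(block: dict[str, Any], seed: int
                             ) -> SyntheticCohortConfig:
    block = dict(block)
    if "module_specs" in block:
        block["module_specs"] = tuple(ModuleSpec(**m)
                                      for m in block["module_specs"])
    if "mutation_specs" in block:
        block["mutation_specs"] = tuple(MutationSpec(**m)
                                        for m in block["mutation_specs"])
    for key in ("subtype_proportions", "hazard_per_subtype"):
        if key in block:
            block[key] = tuple(block[key])
    block.setdefault("seed", seed)
    return SyntheticCohortConfig(**block)


def _load_inputs(config: dict[str, Any], master_seed: int):
    if "simulate" in config:
        cfg = _cohort_config_from_dict(config.get("simulate") or {},
                                       stage_seed(master_seed, "simulate"))
        expr, truth, surv, maf, gmt = generate_cohort(cfg)
        return expr, surv, maf, gmt, truth
    block = config.get("input")
    if not block or "expression" not in block:
        raise ValueError("config needs either a 'simulate' block or an "
                         "'input' block with an expression path")
    batch = None
    if block.get("batch"):
        batch = pd.read_csv(block["batch"], sep="\t",
                            index_col="sample_id")["batch"]
    expr = read_expression(block["expression"],
                           format=block.get("format", "tsv"), batch=batch)
    surv = read_survival(block["survival"]) if block.get("survival") else None
    maf = read_maf(block["maf"]) if block.get("maf") else None
    gmt = read_gene_sets(block["gmt"]) if block.get("gmt") else None
    return expr, surv, maf, gmt, None


def _templates_from_config(config: dict[str, Any]) -> TemplateDefinition:
    block = config.get("templates")
    if block:
        return TemplateDefinition({cls: list(sigs)
                                   for cls, sigs in block.items()})
    return default_templates()


def run_full_pipeline(config: dict[str, Any], output_dir: str | Path
                      ) -> dict[str, Any]:
    """Execute every stage and write artefacts plus a run manifest.

    Stages: input/simulate -> signature scoring -> three-stage subtype
    classification -> gene-panel classifier construction -> survival and
    mutation-enrichment reports.  Returns the manifest dict.
    """
    t0 = time.time()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0))
    artefacts: dict[str, Path] = {}

    expr, surv, maf, gmt, truth = _load_inputs(config, master_seed)
    if gmt is None:
        raise ValueError("a gene-set collection is required (input.gmt or "
                         "simulate block)")
    write_expression(expr, out / "expression.tsv")
    artefacts["expression"] = out / "expression.tsv"
    if truth is not None:
        write_labels(truth.true_labels, out / "true_labels.tsv")
        artefacts["true_labels"] = out / "true_labels.tsv"
    write_gene_sets(gmt, out / "gene_sets.gmt")
    artefacts["gene_sets"] = out / "gene_sets.gmt"

    log.info("scoring %d signatures on %d samples", len(gmt), expr.n_samples)
    scores = z_normalize(ssgsea_score(expr, gmt))
    scores.scores.to_csv(out / "signature_scores.tsv", sep="\t",
                         lineterminator="\n")
    artefacts["signature_scores"] = out / "signature_scores.tsv"

    templates = _templates_from_config(config)
    cls_block = dict(config.get("classify") or {})
    cls_block.setdefault("seed", stage_seed(master_seed, "classify"))
    cls_cfg = ClassifyConfig(**cls_block)
    log.info("classifying cohort (k=%s)", cls_cfg.k)
    labels = classify_cohort(expr, gmt, templates, cls_cfg)
    write_labels(labels, out / "subtype_labels.tsv")
    artefacts["subtype_labels"] = out / "subtype_labels.tsv"

    panel_block = dict(config.get("classifier") or {})
    bundle = None
    if panel_block.get("enabled", True):
        bundle = build_classifier(expr, labels, panel_block,
                                  seed=stage_seed(master_seed, "panel"))
        bundle.save(out / "classifier")
        artefacts["classifier_panel"] = out / "classifier" / "panel.tsv"
        artefacts["classifier_metrics"] = out / "classifier" / "metrics.json"

    reports: dict[str, Any] = {}
    if surv is not None:
        write_survival(surv, out / "survival.tsv")
        artefacts["survival"] = out / "survival.tsv"
        km = km_estimate(surv, labels)
        chi2, p = logrank_test(surv, labels)
        reports["logrank"] = {"chi2": chi2, "p": p}
        reports["median_survival"] = km.median_survival()
    if maf is not None:
        write_maf(maf, out / "mutations.maf")
        artefacts["mutations"] = out / "mutations.maf"
        enr = mutation_enrichment(maf, labels, mode="vs_rest")
        enr.table.to_csv(out / "mutation_enrichment.tsv", sep="\t",
                         index=False, lineterminator="\n")
        artefacts["mutation_enrichment"] = out / "mutation_enrichment.tsv"
    (out / "reports.json").write_text(json.dumps(reports, indent=2,
                                                 sort_keys=True))
    artefacts["reports"] = out / "reports.json"

    manifest = {
        "package_version": __version__,
        "master_seed": master_seed,
        "config": config,
        "stage_seeds": {s: stage_seed(master_seed, s) for s in STAGES},
        "artefacts": {name: {"path": p.name, "sha256": _sha256(p)}
                      for name, p in sorted(artefacts.items())},
        "subtype_counts": labels.counts(),
    }
    if bundle is not None:
        manifest["classifier"] = {
            "family": bundle.family, "panel": bundle.panel,
            "train_cv_accuracy": bundle.train_cv_accuracy,
            "test_accuracy": bundle.test_accuracy,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    (out / "run.log").write_text(
        f"completed in {time.time() - t0:.1f}s\n")
    return manifest


def build_classifier(expr: ExpressionMatrix, labels: CohortLabels,
                     block: dict[str, Any], seed: int = 0) -> ClassifierBundle:
    """The full panel-construction chain on a labelled cohort.

    Six-algorithm vote on the top-variance genes, correlation pruning, RFE
    on the two binary contrasts (immune vs non-immune, activated vs
    suppressed), union of the two subsets, and final model-family selection
    on a stratified 70/30 split.
    """
    y = labels.labels
    vote_fraction = float(block.get("vote_gene_fraction", 0.25))
    n_top = int(block.get("n_top", 100))
    min_votes = int(block.get("min_votes", 4))
    cutoff = float(block.get("correlation_cutoff", 0.8))

    Xv = variance_filter(expr, vote_fraction)
    votes = feature_vote(Xv, y, seed=seed, n_top=n_top)
    candidates = ensemble_vote(votes, min_votes=min_votes)
    if not candidates:
        candidates = ensemble_vote(votes, min_votes=max(1, min_votes - 1))
    pruned = prune_correlated(Xv, candidates, cutoff=cutoff)
    log.info("vote panel %d genes -> %d after correlation pruning",
             len(candidates), len(pruned))

    coarse = labels.coarse
    sub = y[y != "non_immune"]
    panel_a, _ = rfe_select(Xv.subset_genes(pruned), coarse, cv="kfold",
                            seed=seed)
    if sub.nunique() == 2:
        X_sub = Xv.subset_genes(pruned).subset_samples(list(sub.index))
        panel_b, _ = rfe_select(X_sub, sub, cv="kfold", seed=seed + 1)
    else:
        panel_b = []
    merged = sorted(set(panel_a) | set(panel_b))
    log.info("RFE panels %d + %d -> %d-gene merged panel",
             len(panel_a), len(panel_b), len(merged))
    return train_final(expr, y, merged, seed=seed)


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
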