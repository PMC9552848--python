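"""Core in-memory containers shared by every pipeline stage.

All expression data is held as a genes x samples :class:`pandas.DataFrame`
on the log2 scale.  Containers validate their invariants on construction so
that downstream stages can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SUBTYPES = ("non_immune", "immune_suppressed", "immune_activated")
COARSE = ("non_immune", "immune")
STAGE_TAGS = ("nmf", "consensus", "mds_rf", "ntp", "predicted", "truth")


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Log-scale gene x sample expression with optional per-sample batch labels.

    Parameters
    ----------
    values
        genes x samples DataFrame; index = gene ids, columns = sample ids.
    batch
        Optional per-sample batch label, indexed by sample id.
    scale_tag
        ``"log2"`` (default) or ``"linear"``.
    """

    values: pd.DataFrame
    batch: pd.Series | None = None
    scale_tag: str = "log2"

    def __post_init__(self) -> None:
        if self.scale_tag not in ("log2", "linear"):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        _check_unique(list(self.values.index), "gene ids")
        _check_unique(list(self.values.columns), "sample ids")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.batch is not None:
            self.batch = self.batch.reindex(self.values.columns)
            if self.batch.isna().any():
                missing = self.batch.index[self.batch.isna()].tolist()
                raise ValueError(f"samples without batch label: {missing[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)].copy(),
                                batch=None if self.batch is None else self.batch.copy(),
                                scale_tag=self.scale_tag)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        batch = None if self.batch is None else self.batch.loc[list(samples)].copy()
        return ExpressionMatrix(self.values[list(samples)].copy(), batch=batch,
                                scale_tag=self.scale_tag)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> set of gene ids."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets


@dataclass
class MutationTable:
    """Long-format somatic mutation calls, one row per call.

    ``records`` columns: sample_id, gene, variant_classification, variant_type,
    silent (bool flag; silent calls are retained but excluded from enrichment
    by default).
    """

    records: pd.DataFrame

    SILENT_CLASSES = frozenset({"Silent", "Intron", "3'UTR", "5'UTR", "3'Flank",
                                "5'Flank", "IGR", "RNA"})

    def __post_init__(self) -> None:
        required = {"sample_id", "gene", "variant_classification", "variant_type"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"mutation table missing columns: {sorted(missing)}")
        if (self.records["gene"].astype(str).str.len() == 0).any():
            raise ValueError("mutation table contains empty gene fields")
        if "silent" not in self.records.columns:
            self.records = self.records.assign(
                silent=self.records["variant_classification"].isin(self.SILENT_CLASSES))

    @property
    def sample_ids(self) -> set[str]:
        return set(self.records["sample_id"])

    def mutated_samples(self, gene: str, include_silent: bool = False) -> set[str]:
        rec = self.records
        if not include_silent:
            rec = rec[~rec["silent"]]
        return set(rec.loc[rec["gene"] == gene, "sample_id"])

    def genes(self, include_silent: bool = False) -> list[str]:
        rec = self.records if include_silent else self.records[~self.records["silent"]]
        return sorted(rec["gene"].unique())


@dataclass
class SurvivalTable:
    """Right-censored survival data with optional covariates.

    ``data`` columns: sample_id (index), time (months, > 0), event (0/1),
    plus any covariate columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "time" not in self.data.columns or "event" not in self.data.columns:
            raise ValueError("survival table needs 'time' and 'event' columns")
        if (self.data["time"] <= 0).any():
            raise ValueError("survival times must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event must be 0/1")
        _check_unique(list(self.data.index), "survival sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event")]


@dataclass
class CohortLabels:
    """Per-sample subtype call with provenance stage.

    ``labels`` is a Series of fine subtype labels indexed by sample id; the
    coarse immune / non_immune label is derived unless supplied.  Fine and
    coarse labels must be consistent: both immune_* fine labels map to the
    coarse "immune" arm.
    """

    labels: pd.Series
    stage_tag: str = "predicted"
    coarse: pd.Series | None = None
    ambiguous: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.stage_tag not in STAGE_TAGS:
            raise ValueError(f"unknown stage_tag {self.stage_tag!r}")
        bad = set(self.labels.unique()) - set(SUBTYPES) - set(COARSE)
        if bad:
            raise ValueError(f"unknown subtype labels: {sorted(bad)}")
        derived = self.labels.map(
            lambda s: "non_immune" if s == "non_immune" else "immune")
        if self.coarse is None:
            self.coarse = derived
        else:
            self.coarse = self.coarse.reindex(self.labels.index)
            fine_known = self.labels.isin(SUBTYPES) & (self.labels != "non_immune")
            if (self.coarse[fine_known] != "immune").any():
                raise ValueError("coarse labels inconsistent with fine labels")
            if ((self.labels == "non_immune") & (self.coarse != "non_immune")).any():
                raise ValueError("coarse labels inconsistent with fine labels")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"subtype": self.labels, "coarse": self.coarse})
        out["stage"] = self.stage_tag
        if self.ambiguous is not None:
            out["ambiguous"] = self.ambiguous.reindex(self.labels.index).fillna(False)
        out.index.name = "sample_id"
        return out

    def counts(self) -> dict[str, int]:
        return {str(k): int(v) for k, v in
                self.labels.value_counts().items()}


def labels_from_mapping(mapping: Mapping[str, str], stage_tag: str) -> CohortLabels:
    return CohortLabels(pd.Series(dict(mapping), dtype=object), stage_tag=stage_tag)
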