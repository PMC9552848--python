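"""Bundled signature defaults for real-data runs.

The package ships a 26-signature immune / TME panel whose *names* follow the
standard tumour-microenvironment vocabulary (TAM, MDSC, TLS, CYT, pDCs,
Pan_F_TBRs, Treg, TGF-beta, ECM, Wnt/beta-catenin, stroma, lymphocyte
lineages, IFN, checkpoint, ...).  The bundled member genes are compact
canonical markers and are intentionally user-replaceable: pass your own GMT
for any serious real-data analysis.  Synthetic-cohort runs use the
generator-matched gene sets instead.
"""

from __future__ import annotations

from importlib import resources

from .classify import TemplateDefinition
from .containers import GeneSetCollection
from .io import read_gene_sets

#: the visual grouping of the 26 signatures into the two immune templates
ACTIVATED_SIGNATURES = ["T_cells", "CD8_T_cells", "CD4_T_cells", "B_cells",
                        "NK_cells", "CYT", "IFN_gamma", "IFN_type_I", "TLS",
                        "Checkpoint", "pDCs", "Antigen_presentation"]
SUPPRESSED_SIGNATURES = ["TAM", "MDSC", "Treg", "TGF_beta", "Pan_F_TBRs",
                         "ECM", "Wnt_beta_catenin", "Stroma", "CAF",
                         "Neutrophils", "Monocytes"]


def default_signature_collection() -> GeneSetCollection:
    """Load the bundled 26-signature GMT."""
    ref = resources.files("mesotyper") / "data" / "immune_signatures_26.gmt"
    with resources.as_file(ref) as path:
        return read_gene_sets(path)


def default_immune_templates() -> TemplateDefinition:
    """Activated / suppressed templates over the bundled 26-signature panel."""
    return TemplateDefinition({
        "immune_activated": list(ACTIVATED_SIGNATURES),
        "immune_suppressed": list(SUPPRESSED_SIGNATURES),
    })
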