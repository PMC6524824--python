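"""End-to-end convenience: raw matrices -> signature calls.

Chains the standard stages: cell detection filter, shortening orientation,
log2(TPM+1), ssGSEA on both channels, and the joint correlation /
odds-ratio signature model.  Gene-level runs skip ssGSEA (a gene's own
score is its "enrichment") and apply the gene detection filter instead.
"""
from __future__ import annotations

from .data import (
    APAMatrix,
    CellAnnotation,
    EnrichmentMatrix,
    ExpressionMatrix,
    GeneSetCollection,
)
from .enrichment import log_transform_expression, orient_shortening, ssgsea_scores
from .selection import filter_cells, filter_genes
from .signatures import SignatureModel, SignatureResults

__all__ = ["enrich_both_channels", "signature_pipeline"]


def enrich_both_channels(
    apa: APAMatrix,
    expression: ExpressionMatrix,
    gene_sets: GeneSetCollection,
    tau: float = 0.25,
    min_overlap: int = 3,
    normalize: bool = True,
    min_cell_fraction: float = 0.10,
) -> tuple[EnrichmentMatrix, EnrichmentMatrix]:
    """Filter cells, orient the APA channel, and ssGSEA both channels."""
    apa = filter_cells(apa, min_fraction=min_cell_fraction)
    short = orient_shortening(apa)
    logexpr = log_transform_expression(
        ExpressionMatrix(expression.data.loc[:, apa.cells])
    )
    apa_es = ssgsea_scores(short, gene_sets, tau=tau, min_overlap=min_overlap,
                           normalize=normalize, channel="apa")
    expr_es = ssgsea_scores(logexpr, gene_sets, tau=tau, min_overlap=min_overlap,
                            normalize=normalize, channel="expression")
    return apa_es, expr_es


def signature_pipeline(
    apa: APAMatrix,
    expression: ExpressionMatrix,
    annotation: CellAnnotation,
    gene_sets: GeneSetCollection | None = None,
    gene_level: bool = False,
    tau: float = 0.25,
    min_overlap: int = 3,
    min_cell_fraction: float = 0.10,
    min_gene_detect: float = 0.30,
    alpha_pcc: float = 0.05,
    alpha_or: float = 0.01,
    or_min: float = 2.0,
    pcc_scope: str = "within",
) -> SignatureResults:
    """Run the full signature analysis on raw inputs.

    With ``gene_level`` the matrices are passed through as their own
    scores after the 30%-detection gene filter; otherwise ``gene_sets``
    drive ssGSEA on both channels.
    """
    if gene_level:
        apa = filter_cells(apa, min_fraction=min_cell_fraction)
        apa = filter_genes(apa, min_detect_fraction=min_gene_detect)
        apa_es = EnrichmentMatrix(orient_shortening(apa), channel="apa")
        expr_es = EnrichmentMatrix(
            log_transform_expression(
                ExpressionMatrix(expression.data.loc[:, apa.cells])
            ),
            channel="expression",
        )
    else:
        if gene_sets is None:
            raise ValueError("gene_sets are required unless gene_level=True")
        apa_es, expr_es = enrich_both_channels(
            apa, expression, gene_sets, tau=tau, min_overlap=min_overlap,
            min_cell_fraction=min_cell_fraction,
        )
    model = SignatureModel(apa_es, expr_es,
                           annotation.subset(apa_es.cells),
                           pcc_scope=pcc_scope)
    return model.fit(alpha_pcc=alpha_pcc, alpha_or=alpha_or, or_min=or_min)
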