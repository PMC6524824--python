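"""Tumor-type contrasts on gene-set APA enrichment.

Only cells annotated as tumor cells enter the contrast.  For each
(gene set, tumor type) pair the delta is the mean enrichment score of that
type's cells minus the mean of all other tumor cells, with a two-sided
Welch t-test p-value (a pooled-variance Student t is available behind a
flag).  The per-type top-k report ranks significant sets by delta in the
shortening direction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import CellAnnotation, EnrichmentMatrix

logger = logging.getLogger(__name__)

__all__ = ["contrast_tumor_types", "top_k", "TumorContrastModel", "TumorContrastResults"]


def contrast_tumor_types(
    apa_es: EnrichmentMatrix,
    annotation: CellAnnotation,
    alpha: float = 0.01,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-(gene set, tumor type) delta and two-sided t-test.

    Returns a DataFrame with columns gene_set, tumor_type, n_in, n_out,
    delta, t_stat, p_value, significant.  Pairs where either group has
    fewer than two observed scores, or where the test is degenerate (zero
    variance at n = 2), carry missing statistics and are never significant.
    """
    tbl = annotation.table
    tumor_cells = tbl.index[(tbl["cell_type"] == "tumor") & tbl["tumor_type"].notna()]
    tumor_cells = apa_es.cells.intersection(tumor_cells)
    types = sorted(tbl.loc[tumor_cells, "tumor_type"].unique().tolist())
    if len(types) < 2:
        raise ValueError("need at least two tumor types to contrast")
    scores = apa_es.data.loc[:, tumor_cells]
    labels = tbl.loc[tumor_cells, "tumor_type"].to_numpy()
    rows = []
    for t in types:
        in_mask = labels == t
        in_scores = scores.to_numpy(float)[:, in_mask]
        out_scores = scores.to_numpy(float)[:, ~in_mask]
        n_in = np.isfinite(in_scores).sum(axis=1)
        n_out = np.isfinite(out_scores).sum(axis=1)
        with np.errstate(all="ignore"):
            delta = np.nanmean(np.where(np.isfinite(in_scores), in_scores, np.nan), axis=1) \
                - np.nanmean(np.where(np.isfinite(out_scores), out_scores, np.nan), axis=1)
            tstat, pval = stats.ttest_ind(
                in_scores, out_scores, axis=1,
                equal_var=equal_var, nan_policy="omit",
            )
        # degenerate designs (zero pooled variance) yield +-inf statistics;
        # those pairs carry missing statistics rather than spurious zeros
        ok = (n_in >= 2) & (n_out >= 2) & np.isfinite(np.asarray(tstat, float))
        tstat = np.where(ok, tstat, np.nan)
        pval = np.where(ok, pval, np.nan)
        delta = np.where((n_in >= 1) & (n_out >= 1), delta, np.nan)
        for i, gs in enumerate(apa_es.components):
            rows.append({
                "gene_set": gs, "tumor_type": t,
                "n_in": int(n_in[i]), "n_out": int(n_out[i]),
                "delta": float(delta[i]) if np.isfinite(delta[i]) else np.nan,
                "t_stat": float(tstat[i]) if np.isfinite(tstat[i]) else np.nan,
                "p_value": float(pval[i]) if np.isfinite(pval[i]) else np.nan,
            })
    out = pd.DataFrame(rows)
    out["significant"] = (out["p_value"] < alpha).fillna(False)
    return out


def top_k(
    contrasts: pd.DataFrame,
    tumor_type: str,
    k: int = 10,
) -> list[str]:
    """The k most shortening-shifted significant gene sets of one type.

    Larger delta (toward shortening on the oriented score) ranks first;
    ties break by smaller p-value, then by gene-set id.  If fewer than k
    contrasts are significant, all of them are returned with a notice.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = contrasts[(contrasts["tumor_type"] == tumor_type) & contrasts["significant"]]
    sub = sub.sort_values(
        ["delta", "p_value", "gene_set"], ascending=[False, True, True],
        kind="mergesort",
    )
    if len(sub) < k:
        logger.info(
            "top_k: only %d significant gene set(s) for %s (k=%d)",
            len(sub), tumor_type, k,
        )
    return sub["gene_set"].head(k).tolist()


class TumorContrastModel:
    """Model-style wrapper: ``TumorContrastModel(es, annot).fit()``."""

    def __init__(self, apa_es: EnrichmentMatrix, annotation: CellAnnotation) -> None:
        self.apa_es = apa_es
        self.annotation = annotation

    def fit(self, alpha: float = 0.01, equal_var: bool = False) -> "TumorContrastResults":
        contrasts = contrast_tumor_types(
            self.apa_es, self.annotation, alpha=alpha, equal_var=equal_var
        )
        return TumorContrastResults(contrasts=contrasts, alpha=alpha)


@dataclass
class TumorContrastResults:
    contrasts: pd.DataFrame
    alpha: float

    def top_k(self, tumor_type: str, k: int = 10) -> list[str]:
        return top_k(self.contrasts, tumor_type, k=k)

    def summary(self) -> str:
        lines = [f"Tumor-type contrasts (alpha = {self.alpha})"]
        for t, grp in self.contrasts.groupby("tumor_type"):
            lines.append(
                f"  {t}: {int(grp['significant'].sum())}/{len(grp)} "
                "significantly switched gene sets"
            )
        return "\n".join(lines)
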