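"""Cell-type-specific "3'UTR shortening + over-expression" signatures.

A component (gene set or gene) is a signature of a cell type when two
statistics agree:

* the Pearson correlation between its shortening score and its expression
  score across the cells of that type is positive and significant under
  the Fisher-Z normal approximation, and
* cells exceeding the global medians of both scores are enriched in the
  type: a 2x2 median-split table (in-type/out-of-type x flagged/unflagged)
  gives an odds ratio above a cutoff with a significant two-sided Fisher
  exact p.

The default cutoffs are PCC > 0 with p < 0.05 and OR > 2 with p < 0.01,
applied jointly with no multiple-testing correction (a Benjamini-Hochberg
option is available but off by default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import CellAnnotation, EnrichmentMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "shortening_overexpression_flags",
    "contingency",
    "odds_ratio",
    "within_type_pcc",
    "select_signatures",
    "SignatureModel",
    "SignatureResults",
]


def shortening_overexpression_flags(
    apa_es: EnrichmentMatrix, expr_es: EnrichmentMatrix, component: str
) -> pd.Series:
    """Flag cells whose shortening AND expression scores both exceed the
    component's global medians.

    Medians are taken over cells in which both scores are observed; cells
    missing either score are excluded from the result entirely, and a cell
    sitting exactly at a median is not flagged.
    """
    s = apa_es.data.loc[component]
    e = expr_es.data.loc[component].reindex(s.index)
    obs = s.notna() & e.notna()
    if int(obs.sum()) < 4:
        raise ValueError(
            f"component {component!r}: fewer than 4 cells with both scores"
        )
    s_obs, e_obs = s[obs], e[obs]
    med_s, med_e = s_obs.median(), e_obs.median()
    return (s_obs > med_s) & (e_obs > med_e)


def contingency(
    flags: pd.Series, annotation: CellAnnotation, cell_type: str
) -> tuple[int, int, int, int]:
    """Median-split 2x2 table (A, B, C, D) for one cell type.

    A: in-type cells flagged; B: other cells flagged; C: in-type cells not
    flagged; D: other cells not flagged.  Only cells present in ``flags``
    (i.e. with both scores observed) are counted.
    """
    types = annotation.table["cell_type"]
    if cell_type not in set(types):
        raise ValueError(f"cell type {cell_type!r} absent from annotation")
    in_type = types.reindex(flags.index) == cell_type
    a = int((flags & in_type).sum())
    b = int((flags & ~in_type).sum())
    c = int((~flags & in_type).sum())
    d = int((~flags & ~in_type).sum())
    return a, b, c, d


def odds_ratio(table: tuple[int, int, int, int]) -> tuple[float, float]:
    """Odds ratio AD/BC and two-sided Fisher exact p for a 2x2 table.

    The Haldane-Anscombe correction (0.5 added to every cell) is applied to
    the odds ratio only when some cell is zero; the Fisher p is always
    computed on the uncorrected counts (minimum-likelihood two-sided
    convention: sum of hypergeometric probabilities no larger than that of
    the observed table, at fixed margins).
    """
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if a + b + c + d == 0:
        raise ValueError("empty 2x2 table")
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    or_value = (aa * dd) / (bb * cc)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(or_value), float(p)


def _pearson_fisher_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = x.size
    if n < 4:
        raise ValueError("Fisher-Z p-value requires at least 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        logger.warning("collinear scores: |r| = 1, reporting p = 0")
        return float(np.sign(r)), 0.0
    z = np.arctanh(r)
    p = 2.0 * stats.norm.sf(abs(z) * np.sqrt(n - 3))
    return r, float(p)


def within_type_pcc(
    apa_es: EnrichmentMatrix,
    expr_es: EnrichmentMatrix,
    component: str,
    annotation: CellAnnotation,
    cell_type: str,
) -> tuple[float, float]:
    """Pearson correlation of shortening vs expression scores across the
    cells of one type, with a two-sided Fisher-Z p-value."""
    s = apa_es.data.loc[component]
    e = expr_es.data.loc[component].reindex(s.index)
    in_type = annotation.table["cell_type"].reindex(s.index) == cell_type
    obs = s.notna() & e.notna() & in_type
    return _pearson_fisher_z(s[obs].to_numpy(), e[obs].to_numpy())


_STAT_COLUMNS = [
    "component", "cell_type", "n_cells_in_type", "pcc", "pcc_p",
    "A", "B", "C", "D", "odds_ratio", "or_p", "hit",
]


class SignatureModel:
    """Joint correlation / odds-ratio model for cell-type signatures.

    Parameters
    ----------
    apa_es, expr_es : EnrichmentMatrix
        Component x cell shortening and expression scores on a shared cell
        axis (cells are intersected; components are intersected too).
    annotation : CellAnnotation
        Must cover every shared cell.
    cell_types : sequence of str, optional
        Types to evaluate; all annotated types by default.
    pcc_scope : {"within", "all"}
        Whether the correlation is taken over the candidate type's cells
        (default) or over all cells.
    """

    def __init__(
        self,
        apa_es: EnrichmentMatrix,
        expr_es: EnrichmentMatrix,
        annotation: CellAnnotation,
        cell_types=None,
        pcc_scope: str = "within",
    ) -> None:
        if pcc_scope not in ("within", "all"):
            raise ValueError("pcc_scope must be 'within' or 'all'")
        cells = apa_es.cells.intersection(expr_es.cells)
        missing = cells.difference(annotation.cells)
        if len(missing):
            raise ValueError(f"cells without annotation: {list(missing[:5])}")
        comps = apa_es.components.intersection(expr_es.components)
        if len(cells) == 0 or len(comps) == 0:
            raise ValueError("no shared cells/components between the matrices")
        self.apa = apa_es.data.loc[comps, cells]
        self.expr = expr_es.data.loc[comps, cells]
        self.annotation = annotation
        self.types = list(cell_types) if cell_types is not None else (
            annotation.table["cell_type"].reindex(cells).dropna().unique().tolist()
        )
        self.pcc_scope = pcc_scope

    def fit(
        self,
        alpha_pcc: float = 0.05,
        alpha_or: float = 0.01,
        or_min: float = 2.0,
        fdr: bool = False,
    ) -> "SignatureResults":
        """Evaluate every (component, cell type) pair and flag hits.

        A hit requires pcc > 0 with pcc_p < alpha_pcc AND odds_ratio >
        or_min with or_p < alpha_or (strict inequalities).  With ``fdr``
        the two p-value families are Benjamini-Hochberg adjusted first.
        """
        if not (0 < alpha_pcc <= 1 and 0 < alpha_or <= 1):
            raise ValueError("significance cutoffs must be in (0, 1]")
        apa, expr = self.apa.to_numpy(float), self.expr.to_numpy(float)
        comps = self.apa.index
        cells = self.apa.columns
        obs = np.isfinite(apa) & np.isfinite(expr)
        n_obs = obs.sum(axis=1)
        sm = np.where(obs, apa, np.nan)
        em = np.where(obs, expr, np.nan)
        with np.errstate(all="ignore"):
            med_s = np.nanmedian(sm, axis=1, keepdims=True)
            med_e = np.nanmedian(em, axis=1, keepdims=True)
            flags = (sm > med_s) & (em > med_e)  # NaN comparisons are False
        type_labels = self.annotation.table["cell_type"].reindex(cells).to_numpy()

        rows = []
        for t in self.types:
            in_type = type_labels == t
            a_vec = (flags & in_type).sum(axis=1)
            c_vec = (obs & in_type).sum(axis=1) - a_vec
            b_vec = (flags & ~in_type).sum(axis=1)
            d_vec = (obs & ~in_type).sum(axis=1) - b_vec
            for i, comp in enumerate(comps):
                row = dict.fromkeys(_STAT_COLUMNS)
                row.update(component=comp, cell_type=t,
                           n_cells_in_type=int(a_vec[i] + c_vec[i]), hit=False)
                if n_obs[i] < 4:
                    rows.append(row)
                    continue
                table = (int(a_vec[i]), int(b_vec[i]), int(c_vec[i]), int(d_vec[i]))
                row.update(A=table[0], B=table[1], C=table[2], D=table[3])
                orv, orp = odds_ratio(table)
                row.update(odds_ratio=orv, or_p=orp)
                if self.pcc_scope == "within":
                    sel = obs[i] & in_type
                else:
                    sel = obs[i]
                try:
                    r, p = _pearson_fisher_z(apa[i, sel], expr[i, sel])
                    row.update(pcc=r, pcc_p=p)
                except ValueError:
                    pass  # ineligible pair: stats stay missing, hit False
                rows.append(row)

        stats_df = pd.DataFrame(rows, columns=_STAT_COLUMNS)
        pcc_p = stats_df["pcc_p"].astype(float)
        or_p = stats_df["or_p"].astype(float)
        if fdr:
            pcc_p = _bh_adjust(pcc_p)
            or_p = _bh_adjust(or_p)
        stats_df["hit"] = (
            (stats_df["pcc"].astype(float) > 0)
            & (pcc_p < alpha_pcc)
            & (stats_df["odds_ratio"].astype(float) > or_min)
            & (or_p < alpha_or)
        ).fillna(False)
        stats_df = stats_df.sort_values(
            ["cell_type", "odds_ratio"], ascending=[True, False],
            na_position="last", kind="mergesort",
        ).reset_index(drop=True)
        return SignatureResults(
            stats=stats_df,
            alpha_pcc=alpha_pcc, alpha_or=alpha_or, or_min=or_min,
            pcc_scope=self.pcc_scope,
        )


def _bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment, NaNs passed through."""
    mask = p.notna().to_numpy()
    out = p.astype(float).copy()
    vals = out.to_numpy()[mask]
    m = vals.size
    if m:
        order = np.argsort(vals)
        ranked = vals[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        res = np.empty(m)
        res[order] = np.minimum(adj, 1.0)
        out.iloc[np.flatnonzero(mask)] = res
    return out


@dataclass
class SignatureResults:
    """Per-(component, cell type) statistics and the hit calls they imply."""

    stats: pd.DataFrame
    alpha_pcc: float
    alpha_or: float
    or_min: float
    pcc_scope: str

    @property
    def hits(self) -> pd.DataFrame:
        return self.stats[self.stats["hit"]].reset_index(drop=True)

    def hit_pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.hits["component"], self.hits["cell_type"]))

    def summary(self) -> str:
        lines = [
            "Cell-type signature selection",
            f"  cutoffs: PCC > 0 (p < {self.alpha_pcc}), "
            f"OR > {self.or_min} (p < {self.alpha_or}); "
            f"PCC scope: {self.pcc_scope}",
            f"  pairs tested: {len(self.stats)}   hits: {int(self.stats['hit'].sum())}",
        ]
        for t, grp in self.hits.groupby("cell_type"):
            lines.append(f"  {t}: {len(grp)} hit(s): "
                         + ", ".join(grp['component'].head(8)))
        return "\n".join(lines)


def select_signatures(
    apa_es: EnrichmentMatrix,
    expr_es: EnrichmentMatrix,
    annotation: CellAnnotation,
    cell_types=None,
    alpha_pcc: float = 0.05,
    alpha_or: float = 0.01,
    or_min: float = 2.0,
    pcc_scope: str = "within",
) -> pd.DataFrame:
    """Functional shorthand for ``SignatureModel(...).fit(...)``; returns
    the per-pair statistics table sorted by cell type then odds ratio."""
    model = SignatureModel(apa_es, expr_es, annotation,
                           cell_types=cell_types, pcc_scope=pcc_scope)
    return model.fit(alpha_pcc=alpha_pcc, alpha_or=alpha_or, or_min=or_min).stats
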