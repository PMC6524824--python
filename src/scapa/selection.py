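"""Detection filters and variance-baseline selection of variable components.

Cells are kept when enough of their genes carry an APA estimate; genes (for
gene-level analyses) are kept when estimated in enough cells.  A component
(gene or gene set) is "variable" when its standard deviation across cells
exceeds a baseline formed from the distribution of all components' standard
deviations: mean + multiplier x s.d. (multiplier 1 by default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import APAMatrix

logger = logging.getLogger(__name__)

__all__ = ["filter_cells", "filter_genes", "select_variable", "VariationReport"]

_EPS = 1e-9  # guards float round-off at fraction x count thresholds


def filter_cells(apa: APAMatrix, min_fraction: float = 0.10) -> APAMatrix:
    """Keep cells whose non-missing gene count is >= min_fraction of genes.

    The boundary is inclusive: with 100 genes and min_fraction 0.10, a cell
    with exactly 10 detected genes survives.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    counts = apa.data.notna().sum(axis=0)
    keep = counts >= min_fraction * apa.data.shape[0] - _EPS
    if not keep.any():
        raise ValueError("cell filter removed every cell")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_cells: dropped %d/%d cells", n_drop, len(keep))
    return APAMatrix(apa.data.loc[:, keep].copy(), dialect=apa.dialect)


def filter_genes(apa: APAMatrix, min_detect_fraction: float = 0.30) -> APAMatrix:
    """Keep genes detected (non-missing) in >= min_detect_fraction of cells;
    boundary inclusive.  Used for gene-level analyses only."""
    if not 0 <= min_detect_fraction <= 1:
        raise ValueError("min_detect_fraction must be in [0, 1]")
    counts = apa.data.notna().sum(axis=1)
    keep = counts >= min_detect_fraction * apa.data.shape[1] - _EPS
    if not keep.any():
        logger.warning("filter_genes: every gene fell below the detection threshold")
    return APAMatrix(apa.data.loc[keep].copy(), dialect=apa.dialect)


@dataclass
class VariationReport:
    """Per-component variation levels and the selection they imply.

    ``levels`` is the sample s.d. of each component across cells (NaN when
    fewer than two cells are observed); ``baseline`` is
    mean(levels) + multiplier x s.d.(levels); ``selected`` flags components
    strictly above the baseline.
    """

    levels: pd.Series
    baseline: float
    selected: pd.Series
    multiplier: float = 1.0

    @property
    def selected_components(self) -> list[str]:
        return self.selected.index[self.selected].tolist()


def select_variable(matrix: pd.DataFrame, multiplier: float = 1.0) -> VariationReport:
    """Score components by cross-cell s.d. and select those above baseline.

    ``matrix`` is component x cell (an enrichment or gene-score matrix);
    missing entries are excluded pairwise.  Sample (n-1) standard deviations
    are used throughout; a component observed in fewer than two cells has a
    missing variation level and is never selected.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two cells to measure variation")
    vals = matrix.to_numpy(dtype=float)
    nobs = np.isfinite(vals).sum(axis=1)
    with np.errstate(invalid="ignore"):
        levels = np.array([
            np.nanstd(row[np.isfinite(row)], ddof=1) if k >= 2 else np.nan
            for row, k in zip(vals, nobs)
        ])
    levels = pd.Series(levels, index=matrix.index, name="variation_level")
    defined = levels.dropna().to_numpy()
    if defined.size == 0:
        raise ValueError("no component has a defined variation level")
    spread = float(np.std(defined, ddof=1)) if defined.size >= 2 else 0.0
    baseline = float(np.mean(defined)) + multiplier * spread
    selected = (levels > baseline).fillna(False)
    return VariationReport(levels=levels, baseline=baseline,
                           selected=selected, multiplier=multiplier)
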