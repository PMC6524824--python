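"""In-memory containers shared across the pipeline.

Matrices are thin, validated wrappers around a pandas DataFrame with genes
(or gene-set components) on the rows and cells on the columns.  APA score
matrices may contain missing entries (a gene whose 3'UTR usage could not be
estimated in that cell); expression matrices may not.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

#: APA quantification dialects understood by the pipeline.  ``dapars``
#: carries a change in Percentage of Distal polyA-site Usage Index (dPDUI,
#: values in [-1, 1], shortening negative); ``roar`` carries a ratio-of-
#: ratios statistic (positive, shortening > 1).
APA_DIALECTS = ("dapars", "roar")

#: Canonical cell-type labels for tumor-microenvironment annotation.
CELL_TYPES = ("tumor", "B", "T", "myeloid", "stromal", "other")


def _check_unique(labels, what: str) -> None:
    if len(set(labels)) != len(labels):
        dupes = pd.Index(labels)[pd.Index(labels).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} ids: {dupes[:5]}")


@dataclass
class APAMatrix:
    """Gene x cell matrix of per-cell APA scores.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are gene ids, columns cell ids, ``NaN`` marks a gene whose
        3'UTR usage was not estimated in that cell.
    dialect : {"dapars", "roar"}
        Which quantifier produced the scores; decides the valid range and
        the orientation applied by :func:`scapa.enrichment.orient_shortening`.
    """

    data: pd.DataFrame
    dialect: str

    def __post_init__(self) -> None:
        if self.dialect not in APA_DIALECTS:
            raise ValueError(f"unknown APA dialect {self.dialect!r}")
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "cell")
        vals = self.data.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if self.dialect == "dapars":
            if finite.size and (finite.min() < -1 or finite.max() > 1):
                bad = np.argwhere(np.abs(np.nan_to_num(vals)) > 1)
                g, c = bad[0]
                raise ValueError(
                    f"dapars value out of [-1, 1] at gene "
                    f"{self.data.index[g]!r}, cell {self.data.columns[c]!r}"
                )
        else:
            if finite.size and finite.min() <= 0:
                bad = np.argwhere(np.nan_to_num(vals, nan=1.0) <= 0)
                g, c = bad[0]
                raise ValueError(
                    f"roar value must be > 0; offending gene "
                    f"{self.data.index[g]!r}, cell {self.data.columns[c]!r}"
                )

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def cells(self) -> pd.Index:
        return self.data.columns


@dataclass
class ExpressionMatrix:
    """Gene x cell matrix of TPM values (non-negative, complete)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "cell")
        vals = self.data.to_numpy(dtype=float)
        if np.isnan(vals).any():
            g, c = np.argwhere(np.isnan(vals))[0]
            raise ValueError(
                f"expression matrix has a missing value at gene "
                f"{self.data.index[g]!r}, cell {self.data.columns[c]!r}"
            )
        if (vals < 0).any():
            g, c = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative TPM at gene {self.data.index[g]!r}, "
                f"cell {self.data.columns[c]!r}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def cells(self) -> pd.Index:
        return self.data.columns


@dataclass
class CellAnnotation:
    """Per-cell labels: patient of origin, cell type, optional tumor type.

    ``table`` is indexed by cell id with columns ``patient``, ``cell_type``
    and ``tumor_type`` (the last may be all-NA for single-cancer cohorts).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "cell")
        for col in ("patient", "cell_type"):
            if col not in self.table.columns:
                raise ValueError(f"annotation table lacks column {col!r}")
        if "tumor_type" not in self.table.columns:
            self.table = self.table.assign(tumor_type=pd.NA)

    @property
    def cells(self) -> pd.Index:
        return self.table.index

    def cell_types(self) -> list[str]:
        return sorted(self.table["cell_type"].dropna().unique().tolist())

    def subset(self, cells) -> "CellAnnotation":
        return CellAnnotation(self.table.loc[list(cells)].copy())


class GeneSetCollection(Mapping):
    """Ordered mapping of gene-set id -> member gene ids.

    Duplicate members within a set are collapsed (GMT files in the wild
    occasionally repeat genes); set order is preserved from the source.
    """

    def __init__(
        self,
        sets: Mapping[str, list[str]] | None = None,
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self._sets: dict[str, list[str]] = {}
        self._desc: dict[str, str] = {}
        sets = sets or {}
        for name, members in sets.items():
            self.add(name, members, (descriptions or {}).get(name, ""))

    def add(self, name: str, members, description: str = "") -> None:
        if name in self._sets:
            raise ValueError(f"duplicate gene-set id {name!r}")
        seen: dict[str, None] = dict.fromkeys(members)
        if not seen:
            raise ValueError(f"gene set {name!r} is empty")
        self._sets[name] = list(seen)
        self._desc[name] = description

    def __getitem__(self, name: str) -> list[str]:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def description(self, name: str) -> str:
        return self._desc[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def membership_matrix(self, genes: pd.Index) -> np.ndarray:
        """Boolean (n_sets x n_genes) indicator of membership, rows in
        collection order and columns in the order of ``genes``."""
        gene_pos = {g: i for i, g in enumerate(genes)}
        out = np.zeros((len(self._sets), len(genes)), dtype=bool)
        for row, members in enumerate(self._sets.values()):
            for g in members:
                j = gene_pos.get(g)
                if j is not None:
                    out[row, j] = True
        return out


@dataclass
class EnrichmentMatrix:
    """Component x cell enrichment scores.

    ``components`` are gene-set ids after ssGSEA, or gene ids for the
    gene-level passthrough; ``channel`` records whether the scores derive
    from APA shortening or expression.
    """

    data: pd.DataFrame
    channel: str = "apa"

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "component")
        _check_unique(self.data.columns, "cell")
        if self.channel not in ("apa", "expression"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def components(self) -> pd.Index:
        return self.data.index

    @property
    def cells(self) -> pd.Index:
        return self.data.columns
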