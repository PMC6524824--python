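"""Synthetic cohorts with planted cell-type-specific APA signatures.

The generator emulates the statistical structure the downstream analysis
assumes: a gene x cell APA score matrix (dapars- or roar-dialect, with
dropout), a paired TPM expression matrix, a cell annotation table, gene
sets with a toy parent-term hierarchy, and patient survival tables with a
group-dependent hazard.

One latent per-entry shortening variable (a dPDUI-style score) serves both
APA dialects: the dapars file carries the dPDUI itself (truncated Gaussian
in [-1, 1], shortening negative) and the roar file carries 2^(-dPDUI)
(positive, shortening > 1).  For each cell type a few gene sets are
"planted": in cells of that type their member genes are shifted toward
shortening AND toward higher expression, with both shifts scaled by a
shared per-cell activity factor so that shortening and over-expression
co-vary within the type — the coupling the signature statistic is built
to detect.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    APAMatrix,
    CellAnnotation,
    EnrichmentMatrix,
    ExpressionMatrix,
    GeneSetCollection,
)

__all__ = [
    "SimConfig",
    "SurvivalSimConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_go_hierarchy",
    "simulate_survival",
    "simulate_tumor_scores",
]

#: s.d. of the per-patient random intercept on log2 expression.
_PATIENT_SD = 0.2
#: per-cell activity factor: truncated normal around 1.
_ACTIVITY_SD = 0.3
_ACTIVITY_MIN = 0.1
#: log2 expression baselines are drawn uniformly from this range.
_BASELINE_RANGE = (1.0, 8.0)

_TYPE_NAMES = ("tumor", "B", "T", "myeloid", "stromal")


def _type_names(n: int) -> list[str]:
    names = list(_TYPE_NAMES[:n])
    names += [f"type{i}" for i in range(len(names), n)]
    return names


@dataclass
class SimConfig:
    """Cohort-simulation parameters.

    Defaults describe a cohort of 5 cell types x 40 cells over 2,000 genes
    and 300 gene sets, with 3 planted signature sets per type and planted
    shifts of three noise standard deviations on both channels.
    """

    n_cell_types: int = 5
    cells_per_type: int = 40
    n_patients: int = 10
    n_genes: int = 2000
    n_gene_sets: int = 300
    genes_per_set: tuple[int, int] = (15, 25)
    planted_sets_per_type: int = 3
    shortening_effect: float = 0.45
    expression_effect: float = 0.45
    dropout_rate_apa: float = 0.3
    noise_sd: float = 0.15
    apa_dialect: str = "dapars"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_cell_types=self.n_cell_types, cells_per_type=self.cells_per_type,
            n_patients=self.n_patients, n_genes=self.n_genes,
            n_gene_sets=self.n_gene_sets,
        )
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.planted_sets_per_type < 0:
            raise ValueError("planted_sets_per_type must be >= 0")
        lo, hi = self.genes_per_set
        if not (1 <= lo <= hi):
            raise ValueError("genes_per_set must be an increasing range >= 1")
        if not 0 <= self.dropout_rate_apa <= 1:
            raise ValueError("dropout_rate_apa must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for eff in (self.shortening_effect, self.expression_effect):
            if not np.isfinite(eff):
                raise ValueError("effects must be finite")
        if self.apa_dialect not in ("dapars", "roar"):
            raise ValueError(f"unknown apa_dialect {self.apa_dialect!r}")
        if self.planted_sets_per_type * self.n_cell_types > self.n_gene_sets:
            raise ValueError("more planted sets than gene sets available")
        pool = self.genes_per_set[1] * self.planted_sets_per_type * self.n_cell_types
        if pool + self.genes_per_set[1] > self.n_genes:
            raise ValueError("n_genes too small for the planted gene pools")


@dataclass
class SurvivalSimConfig:
    """Two-group survival simulation: exponential event times with hazard
    baseline_hazard * exp(log_hazard_ratio * group), independent
    exponential censoring and administrative censoring at max_followup."""

    n_patients: int = 200
    baseline_hazard: float = 0.1      # events per year
    log_hazard_ratio: float = 0.0     # per unit of the group indicator
    censor_rate: float = 0.05         # censorings per year
    max_followup: float = 15.0        # years
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.baseline_hazard <= 0 or self.censor_rate <= 0:
            raise ValueError("rates must be positive")
        if self.max_followup <= 0:
            raise ValueError("max_followup must be positive")
        if not np.isfinite(self.log_hazard_ratio):
            raise ValueError("log_hazard_ratio must be finite")


@dataclass
class SimulatedCohort:
    apa: APAMatrix
    expression: ExpressionMatrix
    annotation: CellAnnotation
    gene_sets: GeneSetCollection
    parent_table: dict[str, set[str]]
    truth: dict[str, dict[str, list[str]]]  # type -> {gene_sets, genes}


def _streams(seed: int, n: int = 8) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _make_gene_sets(config: SimConfig, rng_sets: np.random.Generator):
    """Gene sets, parent table and the planted-set truth map.

    Planted sets of a cell type draw their members from a reserved gene
    pool of that type (mirroring the largely disjoint marker programs of
    real cell types) and share an identical parent pool, so same-type
    planted sets sit at Jaccard 1 in the parent network.  Background sets
    draw members from the remaining genes and 1-3 parents from a global
    parent pool.
    """
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    types = _type_names(config.n_cell_types)
    lo, hi = config.genes_per_set
    pool_size = hi * config.planted_sets_per_type
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    truth: dict[str, dict[str, list[str]]] = {}
    global_parents = [f"GO_P{i:02d}" for i in range(12)]
    cursor = 0
    set_idx = 0
    for t in types:
        pool = genes[cursor:cursor + pool_size]
        cursor += pool_size
        planted_ids, planted_genes = [], set()
        for _ in range(config.planted_sets_per_type):
            size = int(rng_sets.integers(lo, hi + 1))
            members = list(rng_sets.choice(pool, size=size, replace=False))
            name = f"GS{set_idx:04d}_{t}"
            sets[name] = members
            desc[name] = f"planted signature set for {t}"
            parents[name] = {f"GO_{t}_parent{i}" for i in range(3)}
            planted_ids.append(name)
            planted_genes.update(members)
            set_idx += 1
        truth[t] = {"gene_sets": planted_ids,
                    "genes": sorted(planted_genes)}
    background_genes = genes[cursor:]
    while set_idx < config.n_gene_sets:
        size = int(rng_sets.integers(lo, hi + 1))
        members = list(rng_sets.choice(background_genes, size=size, replace=False))
        name = f"GS{set_idx:04d}"
        sets[name] = members
        desc[name] = "background set"
        n_par = int(rng_sets.integers(1, 4))
        parents[name] = set(rng_sets.choice(global_parents, size=n_par,
                                            replace=False))
        set_idx += 1
    return genes, GeneSetCollection(sets, desc), parents, truth


def simulate_go_hierarchy(config: SimConfig):
    """Gene sets plus a term -> parent-terms table (standalone view of the
    collection embedded in :func:`simulate_cohort`; same seed, same GMT)."""
    rngs = _streams(config.seed)
    _, coll, parents, _ = _make_gene_sets(config, rngs[1])
    return coll, parents


def _truncnorm(rng, loc, scale, low, high):
    a = (low - loc) / scale
    b = (high - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale,
                               size=np.shape(loc), random_state=rng)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Draw a full synthetic cohort with planted signatures.

    Background dPDUI is a truncated Gaussian in [-1, 1] around 0 with
    ``noise_sd``; planted entries shift the mean by
    ``-shortening_effect * a_c`` (toward shortening) where ``a_c`` is the
    cell's activity factor.  Log2 expression is a per-gene baseline plus a
    per-patient random intercept plus noise, with
    ``+expression_effect * a_c`` on planted entries; TPM is the
    exponentiated matrix with columns rescaled to sum to 10^6.  APA entries
    are then dropped out independently at ``dropout_rate_apa``.
    """
    rngs = _streams(config.seed)
    rng_cells, rng_sets, rng_apa, rng_drop, rng_expr, rng_act, rng_base, _ = rngs

    genes, coll, parents, truth = _make_gene_sets(config, rng_sets)
    types = _type_names(config.n_cell_types)
    n_cells = config.n_cell_types * config.cells_per_type
    cells = [f"c{i:04d}" for i in range(n_cells)]
    cell_type = np.repeat(types, config.cells_per_type)
    patients = rng_cells.integers(0, config.n_patients, size=n_cells)
    annotation = CellAnnotation(pd.DataFrame({
        "patient": [f"p{int(i):03d}" for i in patients],
        "cell_type": cell_type,
        "tumor_type": pd.NA,
    }, index=pd.Index(cells, name="cell")))

    gene_pos = {g: i for i, g in enumerate(genes)}
    planted = np.zeros((config.n_genes, n_cells), dtype=bool)
    for t in types:
        cell_mask = cell_type == t
        rows = [gene_pos[g] for g in truth[t]["genes"]]
        planted[np.ix_(rows, np.flatnonzero(cell_mask))] = True

    activity = _truncnorm(rng_act, np.ones(n_cells), _ACTIVITY_SD,
                          _ACTIVITY_MIN, np.inf)

    # latent dPDUI (shortening negative)
    loc = np.where(planted, -config.shortening_effect * activity[None, :], 0.0)
    dpdui = _truncnorm(rng_apa, loc, config.noise_sd, -1.0, 1.0)
    apa_vals = dpdui if config.apa_dialect == "dapars" else 2.0 ** (-dpdui)
    drop = rng_drop.random(apa_vals.shape) < config.dropout_rate_apa
    apa_vals = np.where(drop, np.nan, apa_vals)
    apa = APAMatrix(pd.DataFrame(apa_vals, index=pd.Index(genes, name="gene"),
                                 columns=cells), dialect=config.apa_dialect)

    baseline = rng_base.uniform(*_BASELINE_RANGE, size=config.n_genes)
    pat_intercept = rng_expr.normal(0.0, _PATIENT_SD, size=config.n_patients)
    log2e = (
        baseline[:, None]
        + pat_intercept[patients][None, :]
        + rng_expr.normal(0.0, config.noise_sd, size=(config.n_genes, n_cells))
        + np.where(planted, config.expression_effect * activity[None, :], 0.0)
    )
    tpm = 2.0 ** log2e
    tpm = tpm / tpm.sum(axis=0, keepdims=True) * 1e6
    expression = ExpressionMatrix(pd.DataFrame(
        tpm, index=pd.Index(genes, name="gene"), columns=cells))

    return SimulatedCohort(apa=apa, expression=expression, annotation=annotation,
                           gene_sets=coll, parent_table=parents, truth=truth)


def simulate_survival(config: SurvivalSimConfig, group) -> pd.DataFrame:
    """Simulate (time, event, group, age) records for a binary group.

    Event times are exponential with hazard
    ``baseline_hazard * exp(log_hazard_ratio * group)``; censoring is the
    minimum of an independent exponential (``censor_rate``) and the
    administrative cutoff at ``max_followup``.
    """
    group = np.asarray(group)
    if group.shape != (config.n_patients,):
        raise ValueError("group indicator length must equal n_patients")
    rng_event, rng_cens, rng_cov = _streams(config.seed, 3)
    hazard = config.baseline_hazard * np.exp(config.log_hazard_ratio * group)
    t_event = rng_event.exponential(1.0 / hazard)
    t_cens = np.minimum(rng_cens.exponential(1.0 / config.censor_rate,
                                             size=config.n_patients),
                        config.max_followup)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    age = rng_cov.normal(60.0, 10.0, size=config.n_patients)
    return pd.DataFrame({
        "time": time, "event": event,
        "group": group.astype(int), "age": age,
    }, index=pd.Index([f"p{i:04d}" for i in range(config.n_patients)],
                      name="patient"))


def simulate_tumor_scores(
    n_tumor_types: int = 3,
    n_gene_sets: int = 200,
    planted_sets_per_type: int = 5,
    cells_per_type: int = 30,
    effect: float = 0.45,
    noise_sd: float = 0.15,
    seed: int = 0,
):
    """Gene-set x tumor-cell enrichment scores with planted per-type shifts.

    Used to exercise the tumor-type contrast directly at the gene-set
    score level: background scores are N(0, noise_sd); the planted sets of
    each tumor type are shifted by ``+effect`` (toward shortening) in that
    type's cells only.  Returns (EnrichmentMatrix, CellAnnotation, truth).
    """
    if planted_sets_per_type * n_tumor_types > n_gene_sets:
        raise ValueError("more planted sets than gene sets available")
    rng = np.random.default_rng(seed)
    n_cells = n_tumor_types * cells_per_type
    sets = [f"GS{i:04d}" for i in range(n_gene_sets)]
    cells = [f"c{i:04d}" for i in range(n_cells)]
    tumor_type = np.repeat([f"T{i}" for i in range(n_tumor_types)],
                           cells_per_type)
    scores = rng.normal(0.0, noise_sd, size=(n_gene_sets, n_cells))
    truth: dict[str, list[str]] = {}
    for k in range(n_tumor_types):
        ids = list(range(k * planted_sets_per_type, (k + 1) * planted_sets_per_type))
        scores[np.ix_(ids, np.flatnonzero(tumor_type == f"T{k}"))] += effect
        truth[f"T{k}"] = [sets[i] for i in ids]
    es = EnrichmentMatrix(pd.DataFrame(
        scores, index=pd.Index(sets, name="component"), columns=cells),
        channel="apa")
    annotation = CellAnnotation(pd.DataFrame({
        "patient": [f"p{t}" for t in tumor_type],
        "cell_type": "tumor",
        "tumor_type": tumor_type,
    }, index=pd.Index(cells, name="cell")))
    return es, annotation, truth
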