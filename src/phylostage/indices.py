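"""Transcriptome age and divergence indices over staged expression data.

The Transcriptome Age Index (TAI) of a sample is the expression-weighted mean
phylostratum of its genes,

    TAI = sum_i s_i * e_i / sum_i e_i,

where ``s_i`` is gene *i*'s phylostratum (PAI) and ``e_i`` its expression in
the sample.  A low TAI means the transcriptome's expression mass sits on
evolutionarily ancient genes.  The Transcriptome Divergence Index (TDI) is the
same weighted mean computed with divergence strata (dN/dS deciles) as weights.

Because the index is a ratio it is invariant to rescaling a sample's column;
library-size normalization still matters whenever columns are averaged before
the index is taken (the ``mean-expression`` stage aggregation), so the
pipeline normalizes to counts-per-million by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agemap import AgeMap, DivergenceStrata, _StratumMap
from .exceptions import ValidationError
from .stages import ordered_stages

__all__ = [
    "StagedExpression",
    "IndexProfile",
    "normalize_library",
    "compute_index_sample",
    "compute_profile",
    "AGGREGATIONS",
]

#: Stage-aggregation modes for :func:`compute_profile`.
AGGREGATIONS = ("mean-expression", "mean-of-sample-indices")


@dataclass
class StagedExpression:
    """Nonnegative genes x samples expression matrix with per-sample stage labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample.  Counts or any
        nonnegative normalized unit.
    stages
        Series mapping sample id -> stage label in {I, II, III, IV, NAT};
        must cover exactly the matrix columns.
    """

    values: pd.DataFrame
    stages: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.stages = self.stages.astype(str)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression matrix contains negative values")
        missing = set(self.values.columns) - set(self.stages.index)
        if missing:
            raise ValidationError(
                f"samples without a stage label: {sorted(missing)}"
            )
        # keep exactly the matrix columns, in matrix order
        self.stages = self.stages.loc[self.values.columns]
        ordered_stages(self.stages)  # validates the label set

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

    def stages_present(self) -> list[str]:
        return ordered_stages(self.stages)

    def samples_of_stage(self, stage: str) -> list[str]:
        return list(self.stages.index[self.stages == stage])

    def subset_stages(self, keep) -> "StagedExpression":
        keep = set(keep)
        cols = [s for s in self.values.columns if self.stages[s] in keep]
        if not cols:
            raise ValidationError(f"no samples left after restricting to stages {sorted(keep)}")
        return StagedExpression(self.values[cols], self.stages.loc[cols])

    def log2_transform(self) -> "StagedExpression":
        """Return a copy with values replaced by log2(1 + x)."""
        return StagedExpression(np.log2(1.0 + self.values), self.stages.copy())


def normalize_library(data: StagedExpression, scale: float = 1e6) -> StagedExpression:
    """Scale each sample column so its total equals ``scale`` (counts-per-scale).

    Stage labels are unchanged.  An all-zero column cannot be normalized and
    raises an error naming the sample.
    """
    if not scale > 0:
        raise ValidationError(f"scale must be positive, got {scale}")
    totals = data.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValidationError(
            f"cannot normalize all-zero sample column {zero.index[0]!r}"
        )
    return StagedExpression(data.values / totals * scale, data.stages.copy())


def compute_index_sample(expr_column, strata: _StratumMap, gene_ids=None) -> float:
    """Expression-weighted mean stratum of one sample.

    Parameters
    ----------
    expr_column
        Nonnegative expression values: a pandas Series indexed by gene id, or
        an array accompanied by ``gene_ids``.
    strata
        An :class:`~phylostage.agemap.AgeMap` (TAI) or
        :class:`~phylostage.agemap.DivergenceStrata` (TDI).

    Genes without a stratum annotation are excluded.  Raises
    :class:`ValidationError` if no annotated gene has positive expression.
    """
    if isinstance(expr_column, pd.Series):
        series = expr_column
    else:
        if gene_ids is None:
            raise ValidationError(
                "compute_index_sample: pass a pandas Series or provide gene_ids"
            )
        series = pd.Series(np.asarray(expr_column, dtype=float), index=list(gene_ids))
    e = series.to_numpy(dtype=float)
    if (e < 0).any():
        raise ValidationError("negative expression value")
    s = strata.stratum_vector(series.index)
    annotated = ~np.isnan(s)
    mass = e[annotated].sum()
    if not (e[annotated] > 0).any():
        raise ValidationError(
            "no annotated gene with positive expression in this sample"
        )
    return float((s[annotated] * e[annotated]).sum() / mass)


@dataclass
class IndexProfile:
    """Per-sample and per-stage index values.

    ``per_stage`` keys are a subset of (I, II, III, IV, NAT) in that fixed
    order.  ``n_genes_dropped`` counts matrix genes lacking a stratum
    annotation; they never contribute to any index value.
    """

    per_sample: pd.Series
    per_stage: pd.Series
    index_kind: str
    aggregation: str
    n_genes_used: int
    n_genes_dropped: int
    stages: pd.Series  # sample -> stage, for downstream grouping/plots

    def tumor_profile(self) -> pd.Series:
        """Per-stage values restricted to tumor stages I-IV."""
        keep = [s for s in self.per_stage.index if s != "NAT"]
        return self.per_stage.loc[keep]

    def to_dict(self) -> dict:
        return {
            "index_kind": self.index_kind,
            "aggregation": self.aggregation,
            "n_genes_used": self.n_genes_used,
            "n_genes_dropped": self.n_genes_dropped,
            "per_stage": {k: float(v) for k, v in self.per_stage.items()},
            "per_sample": {k: float(v) for k, v in self.per_sample.items()},
        }


def _index_kind_of(strata: _StratumMap) -> str:
    if isinstance(strata, DivergenceStrata):
        return "TDI"
    if isinstance(strata, AgeMap):
        return "TAI"
    return "index"


def compute_profile(
    data: StagedExpression,
    strata: _StratumMap,
    aggregation: str = "mean-expression",
) -> IndexProfile:
    """Compute per-sample indices and one aggregated index per stage.

    Two stage aggregations are supported:

    ``mean-expression``
        The stage value is the index of the across-sample mean expression
        vector of that stage's columns (one pooled transcriptome per stage).
    ``mean-of-sample-indices``
        The stage value is the arithmetic mean of the stage's per-sample
        indices (matches boxplot-style per-stage summaries).

    The two agree for a single sample but differ in general.
    """
    if aggregation not in AGGREGATIONS:
        raise ValidationError(
            f"unknown aggregation {aggregation!r}; expected one of {AGGREGATIONS}"
        )
    stages = data.stages_present()
    if not stages:
        raise ValidationError("no stages present")

    s_all = strata.stratum_vector(data.gene_ids)
    annotated = ~np.isnan(s_all)
    n_used = int(annotated.sum())
    n_dropped = data.n_genes - n_used
    if n_used == 0:
        raise ValidationError("no gene in the matrix has a stratum annotation")
    X = data.values.to_numpy(dtype=float)[annotated, :]
    w = s_all[annotated]

    mass = X.sum(axis=0)
    dead = np.where(~(X > 0).any(axis=0))[0]
    if len(dead):
        raise ValidationError(
            "no annotated gene with positive expression in sample "
            f"{data.sample_ids[dead[0]]!r}"
        )
    per_sample = pd.Series(w @ X / mass, index=data.sample_ids, name="index")

    per_stage = {}
    for stage in stages:
        cols = [data.sample_ids.index(s) for s in data.samples_of_stage(stage)]
        if aggregation == "mean-expression":
            m = X[:, cols].mean(axis=1)
            per_stage[stage] = float((w * m).sum() / m.sum())
        else:
            per_stage[stage] = float(per_sample.iloc[cols].mean())
    per_stage = pd.Series(per_stage, name="index").loc[stages]

    return IndexProfile(
        per_sample=per_sample,
        per_stage=per_stage,
        index_kind=_index_kind_of(strata),
        aggregation=aggregation,
        n_genes_used=n_used,
        n_genes_dropped=n_dropped,
        stages=data.stages.copy(),
    )
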