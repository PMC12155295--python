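"""Model/Results front end over the functional modules.

`TranscriptomeIndex` is constructed from data (a staged expression matrix
plus a stratum annotation), `fit()` computes the index profile, and the
returned `TranscriptomeIndexResults` carries the estimates, exposes the
permutation tests, a text `summary()` and a profile plot — the familiar
model/results split.  `StratumEnrichment` does the same for DEG composition
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .agemap import AgeMap, DivergenceStrata, _StratumMap
from .enrichment import StratumEnrichmentResult, chi2_bootstrap
from .exceptions import ValidationError
from .indices import (
    AGGREGATIONS,
    IndexProfile,
    StagedExpression,
    compute_profile,
    normalize_library,
)
from .pattern_tests import PatternTestResult, StageModules, permutation_test

__all__ = ["TranscriptomeIndex", "TranscriptomeIndexResults", "StratumEnrichment", "StratumEnrichmentResults"]


class TranscriptomeIndex:
    """Transcriptome age/divergence index model for staged expression data.

    Parameters
    ----------
    data
        Staged expression matrix (counts or normalized units).
    strata
        :class:`AgeMap` for TAI, :class:`DivergenceStrata` for TDI.
    aggregation
        How per-stage values are formed; see :func:`phylostage.indices.compute_profile`.
    normalize, scale
        Apply counts-per-``scale`` library normalization before fitting
        (default counts-per-million).
    log_transform
        Replace values by ``log2(1 + x)`` after normalization.

    Examples
    --------
    >>> model = TranscriptomeIndex(data, ages)
    >>> res = model.fit()
    >>> res.per_stage
    >>> res.flat_line_test(B=1000, seed=1).p_value
    """

    def __init__(
        self,
        data: StagedExpression,
        strata: _StratumMap,
        aggregation: str = "mean-expression",
        normalize: bool = True,
        scale: float = 1e6,
        log_transform: bool = False,
    ) -> None:
        if aggregation not in AGGREGATIONS:
            raise ValidationError(f"unknown aggregation {aggregation!r}")
        if not isinstance(strata, (AgeMap, DivergenceStrata)):
            raise ValidationError("strata must be an AgeMap or DivergenceStrata")
        self.raw_data = data
        self.strata = strata
        self.aggregation = aggregation
        self.normalize = normalize
        self.scale = scale
        self.log_transform = log_transform
        work = normalize_library(data, scale) if normalize else data
        if log_transform:
            work = work.log2_transform()
        self.data = work

    @classmethod
    def from_files(cls, expr_path, meta_path, ages_path=None, dnds_path=None, **kwargs):
        """Build the model from TSV files (TAI from ages, TDI from dN/dS)."""
        from .agemap import load_age_map, load_divergence_map, rank_deciles
        from .io import load_staged_expression

        data = load_staged_expression(expr_path, meta_path)
        if (ages_path is None) == (dnds_path is None):
            raise ValidationError("provide exactly one of ages_path (TAI) or dnds_path (TDI)")
        if ages_path is not None:
            strata: _StratumMap = load_age_map(ages_path)
        else:
            strata = rank_deciles(load_divergence_map(dnds_path))
        return cls(data, strata, **kwargs)

    def fit(self) -> "TranscriptomeIndexResults":
        profile = compute_profile(self.data, self.strata, self.aggregation)
        return TranscriptomeIndexResults(self, profile)


class TranscriptomeIndexResults:
    """Fitted index profile with pattern tests, summary and plotting."""

    def __init__(self, model: TranscriptomeIndex, profile: IndexProfile) -> None:
        self.model = model
        self.profile = profile

    @property
    def per_stage(self) -> pd.Series:
        return self.profile.per_stage

    @property
    def per_sample(self) -> pd.Series:
        return self.profile.per_sample

    def _test(self, test_kind, modules, B, seed) -> PatternTestResult:
        return permutation_test(
            self.model.data,
            self.model.strata,
            modules=modules,
            test_kind=test_kind,
            B=B,
            seed=seed,
            aggregation=self.model.aggregation,
        )

    def flat_line_test(self, B: int = 1000, seed: int = 0) -> PatternTestResult:
        return self._test("flat_line", None, B, seed)

    def hourglass_test(
        self,
        direction: str = "reductive",
        modules: StageModules | None = None,
        B: int = 1000,
        seed: int = 0,
    ) -> PatternTestResult:
        if direction not in ("reductive", "reverse"):
            raise ValidationError(f"unknown direction {direction!r}")
        kind = "reductive_hourglass" if direction == "reductive" else "reverse_hourglass"
        return self._test(kind, modules, B, seed)

    def test_patterns(
        self,
        modules: StageModules | None = None,
        B: int = 1000,
        seed: int = 0,
        alpha: float = 0.05,
        gated: bool = True,
    ) -> dict:
        """Run the flat-line test and, when it rejects (or ``gated=False``),
        both hourglass tests.  Returns a dict of results / not-run markers."""
        flat = self.flat_line_test(B=B, seed=seed)
        out: dict = {"flat_line": flat}
        if gated and flat.p_value > alpha:
            reason = f"flat-line p={flat.p_value:.4g} > alpha={alpha}"
            out["reductive_hourglass"] = {"status": "not_run", "reason": reason}
            out["reverse_hourglass"] = {"status": "not_run", "reason": reason}
            return out
        out["reductive_hourglass"] = self.hourglass_test("reductive", modules, B=B, seed=seed)
        out["reverse_hourglass"] = self.hourglass_test("reverse", modules, B=B, seed=seed)
        return out

    def summary(self) -> str:
        p = self.profile
        lines = [
            f"{'Transcriptome Age Index (TAI)' if p.index_kind == 'TAI' else 'Transcriptome Divergence Index (TDI)' if p.index_kind == 'TDI' else p.index_kind}",
            "=" * 58,
            f"Aggregation:      {p.aggregation}",
            f"Genes used:       {p.n_genes_used}   (dropped, no annotation: {p.n_genes_dropped})",
            f"Samples:          {len(p.per_sample)}",
            "",
            f"{'stage':<8}{'n_samples':>10}{'index':>12}",
            "-" * 30,
        ]
        counts = p.stages.value_counts()
        for stage, value in p.per_stage.items():
            lines.append(f"{stage:<8}{int(counts.get(stage, 0)):>10}{value:>12.4f}")
        return "\n".join(lines)

    def plot(self, ax=None, show_samples: bool = True):
        """Stage profile line with optional per-sample scatter."""
        from .plotting import plot_profile

        return plot_profile(self.profile, ax=ax, show_samples=show_samples)


@dataclass
class StratumEnrichment:
    """Phylostratum enrichment model for a DEG list against a background."""

    deg: set
    background: AgeMap

    def fit(self, n_bootstrap: int = 10_000, seed: int = 0) -> "StratumEnrichmentResults":
        result = chi2_bootstrap(self.deg, self.background, n_bootstrap=n_bootstrap, seed=seed)
        return StratumEnrichmentResults(self, result)


class StratumEnrichmentResults:
    """Per-stratum Fisher tests plus the bootstrap chi-square, with summary()."""

    def __init__(self, model: StratumEnrichment, result: StratumEnrichmentResult) -> None:
        self.model = model
        self.result = result

    @property
    def per_stratum(self) -> pd.DataFrame:
        return self.result.per_stratum

    @property
    def bootstrap_p(self) -> float:
        return self.result.bootstrap_p

    def summary(self) -> str:
        r = self.result
        lines = [
            "Phylostratum enrichment of DEG list",
            "=" * 64,
            f"DEG genes: {r.n_deg}   background: {int(r.per_stratum['count_background'].sum())}",
            f"chi2 = {r.chi2:.3f} (df {r.chi2_df}),  bootstrap p = {r.bootstrap_p:.4g} "
            f"({r.n_bootstrap} resamples, seed {r.seed})",
            "",
            f"{'stratum':<8}{'deg':>6}{'bg':>8}{'OR':>10}{'fisher_p':>12}{'q':>12}",
            "-" * 56,
        ]
        for stratum, row in r.per_stratum.iterrows():
            lines.append(
                f"{stratum:<8}{int(row['count_deg']):>6}{int(row['count_background']):>8}"
                f"{row['odds_ratio']:>10.3f}{row['fisher_p']:>12.3g}{row['fisher_q']:>12.3g}"
            )
        return "\n".join(lines)
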