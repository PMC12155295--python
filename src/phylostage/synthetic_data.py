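"""Synthetic staged tumor expression data with known planted structure.

The generator emulates the statistical shape of staged bulk RNA-seq inputs so
that every downstream step — indices, pattern tests, enrichment — can be
exercised and calibrated without external data:

* a gene universe with phylostrata drawn from a configurable distribution
  over 14 strata and log-normal dN/dS values;
* negative-binomial counts with gene-specific log-normal baseline means and a
  common dispersion, per-sample columns for stages I-IV plus NAT controls;
* an optional planted index pattern: under ``hourglass``, genes in the
  youngest age tertile have their mean counts multiplied by ``2**(delta*w)``
  in stages I and IV while the most ancient tertile is boosted in stages II
  and III; ``reverse_hourglass`` swaps the stage sets; ``flat`` plants
  nothing.  The scaling ``w`` is solved numerically at generation time so the
  expected early/late-vs-mid TAI separation equals the requested effect size
  ``delta`` (in index units);
* a DEG table with planted phylostratum enrichment: membership probability is
  multiplied by ``enrichment_fold`` for genes in the enriched strata, and
  log2 fold changes are drawn from stratum-dependent Gaussians (ancient
  strata trending up, mid strata down, young strata large-magnitude).

Everything is deterministic under a fixed seed; the three generators use
disjoint seed streams derived from ``config.seed``, so each can be called
independently and still reproduce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .agemap import AgeMap, DivergenceMap
from .exceptions import ValidationError
from .indices import StagedExpression
from .stages import STAGE_ORDER, TUMOR_STAGES

__all__ = ["SimulationConfig", "generate_universe", "generate_expression", "generate_deg_table"]

PATTERNS = ("flat", "hourglass", "reverse_hourglass")


def _default_samples() -> dict[str, int]:
    return {"I": 10, "II": 10, "III": 10, "IV": 10, "NAT": 10}


def _default_log2fc_medians(n_strata: int) -> dict[int, float]:
    """Stratum -> mean of the log2FC Gaussian (ancient up, mid down, young big)."""
    medians = {}
    for s in range(1, n_strata + 1):
        if s <= 2:
            medians[s] = 1.0
        elif s <= 7:
            medians[s] = -0.8
        else:
            medians[s] = 0.0  # young strata: mixed sign, large spread
    return medians


def _default_log2fc_sds(n_strata: int) -> dict[int, float]:
    return {s: (2.5 if s >= 8 else 0.5) for s in range(1, n_strata + 1)}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults describe a desk-scale cohort: 2,000 genes uniformly spread over
    14 phylostrata, 10 samples per tumor stage plus 10 NAT controls,
    negative-binomial counts with mean-100 log-normal baselines and shape 5
    (variance ``mu + mu^2/5``, i.e. clearly overdispersed), planted effect
    size two index units, and tenfold DEG enrichment of strata 6, 7 and 9.
    """

    n_genes: int = 2000
    n_strata: int = 14
    stratum_probs: tuple[float, ...] | None = None  # None -> uniform
    samples_per_stage: dict[str, int] = field(default_factory=_default_samples)
    pattern: str = "flat"
    effect_size: float = 2.0
    baseline_mean: float = 100.0
    baseline_sigma: float = 1.0
    dispersion: float | None = 5.0  # NB shape; None or inf -> Poisson
    dnds_median: float = 0.2
    dnds_sigma: float = 0.8
    dnds_stratum_slope: float = 0.0  # optional log-scale coupling of dN/dS to age
    enriched_strata: tuple[int, ...] = (6, 7, 9)
    enrichment_fold: float = 10.0
    deg_rate: float = 0.05
    log2fc_medians: dict[int, float] | None = None
    log2fc_sds: dict[int, float] | None = None
    cancer_type: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.n_strata < 1:
            raise ValidationError("n_strata must be >= 1")
        if self.stratum_probs is None:
            self.stratum_probs = tuple([1.0 / self.n_strata] * self.n_strata)
        probs = np.asarray(self.stratum_probs, dtype=float)
        if probs.size != self.n_strata:
            raise ValidationError(
                f"stratum_probs has {probs.size} entries for {self.n_strata} strata"
            )
        if (probs < 0).any():
            raise ValidationError("stratum_probs must be nonnegative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError(f"stratum_probs sum to {probs.sum()}, not 1")
        if self.pattern not in PATTERNS:
            raise ValidationError(f"unknown pattern {self.pattern!r}")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if not self.baseline_mean > 0:
            raise ValidationError("baseline_mean must be positive")
        if self.dispersion is not None and not self.dispersion > 0:
            raise ValidationError("dispersion must be positive (or None for Poisson)")
        bad = [s for s in self.enriched_strata if not 1 <= s <= self.n_strata]
        if bad:
            raise ValidationError(
                f"enriched strata {bad} outside 1..{self.n_strata}"
            )
        if not 0 < self.deg_rate <= 1:
            raise ValidationError("deg_rate must lie in (0, 1]")
        if self.enrichment_fold < 1:
            raise ValidationError("enrichment_fold must be >= 1")
        unknown = set(self.samples_per_stage) - set(STAGE_ORDER)
        if unknown:
            raise ValidationError(f"unknown stages in samples_per_stage: {sorted(unknown)}")
        if any(n < 0 for n in self.samples_per_stage.values()):
            raise ValidationError("sample counts must be >= 0")

    def to_dict(self) -> dict:
        out = asdict(self)
        out["stratum_probs"] = [float(p) for p in self.stratum_probs]
        out["enriched_strata"] = [int(s) for s in self.enriched_strata]
        return out


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # disjoint deterministic streams per generator
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def generate_universe(config: SimulationConfig) -> tuple[AgeMap, DivergenceMap]:
    """Draw the gene universe: phylostrata and dN/dS values.

    Strata are iid from ``stratum_probs``; dN/dS is log-normal with median
    ``dnds_median`` and log-sd ``dnds_sigma``, independent of the stratum
    unless ``dnds_stratum_slope`` couples the log-median to (stratum - mean
    stratum).
    """
    rng = _rng(config, 1)
    genes = _gene_ids(config.n_genes)
    strata = rng.choice(
        np.arange(1, config.n_strata + 1), size=config.n_genes, p=config.stratum_probs
    )
    mu = math.log(config.dnds_median)
    if config.dnds_stratum_slope != 0.0:
        centered = strata - strata.mean()
        loc = mu + config.dnds_stratum_slope * centered
    else:
        loc = np.full(config.n_genes, mu)
    dnds = np.exp(rng.normal(loc, config.dnds_sigma))
    ages = AgeMap(dict(zip(genes, (int(s) for s in strata))))
    divergence = DivergenceMap(dict(zip(genes, dnds)))
    return ages, divergence


def _age_tertiles(ages: AgeMap) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Boolean masks (ancient, young) over genes sorted into stable order.

    Genes are sorted by (stratum, gene id) and cut into three contiguous
    groups of near-equal size; the first third is the "ancient" tertile and
    the last third the "young" tertile.
    """
    ordered = sorted(ages.entries.items(), key=lambda kv: (kv[1], kv[0]))
    genes = [g for g, _ in ordered]
    n = len(genes)
    third = n // 3
    ancient = np.zeros(n, dtype=bool)
    young = np.zeros(n, dtype=bool)
    ancient[:third] = True
    young[n - third :] = True
    return ancient, young, genes


def _expected_tai(strata: np.ndarray, mass: np.ndarray) -> float:
    return float((strata * mass).sum() / mass.sum())


def _solve_effect_factor(
    delta: float, strata: np.ndarray, mu: np.ndarray, ancient: np.ndarray, young: np.ndarray
) -> float:
    """Fold factor f so the expected TAI gap (young-boosted minus
    ancient-boosted transcriptome) equals ``delta``."""
    if delta == 0:
        return 1.0

    def gap(f: float) -> float:
        mass_young = np.where(young, mu * f, mu)
        mass_ancient = np.where(ancient, mu * f, mu)
        return _expected_tai(strata, mass_young) - _expected_tai(strata, mass_ancient) - delta

    max_gap = gap(1e9)  # gap saturates as f grows
    if max_gap < 0:
        raise ValidationError(
            f"effect_size {delta} exceeds the maximum expected index separation "
            f"achievable for this universe ({max_gap + delta:.3f})"
        )
    hi = 2.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - guarded by max_gap check
            break
    return float(brentq(gap, 1.0, hi, xtol=1e-12, rtol=1e-12))


def generate_expression(config: SimulationConfig, ages: AgeMap) -> StagedExpression:
    """Draw staged negative-binomial counts with the configured planted pattern.

    Baseline means are log-normal across genes (mean ``baseline_mean``); the
    planted pattern multiplies means by the solved fold factor in the stage
    sets described in the module docstring.  NAT columns always use baseline
    means.
    """
    rng = _rng(config, 2)
    ancient, young, genes = _age_tertiles(ages)
    strata = np.array([ages.entries[g] for g in genes], dtype=float)
    n = len(genes)

    sigma = config.baseline_sigma
    mu = rng.lognormal(
        mean=math.log(config.baseline_mean) - sigma**2 / 2.0, sigma=sigma, size=n
    )

    if config.pattern == "flat" or config.effect_size == 0:
        f = 1.0
    else:
        f = _solve_effect_factor(config.effect_size, strata, mu, ancient, young)
    boost_young = np.where(young, f, 1.0)
    boost_ancient = np.where(ancient, f, 1.0)
    if config.pattern == "hourglass":
        stage_mean = {
            "I": mu * boost_young,
            "II": mu * boost_ancient,
            "III": mu * boost_ancient,
            "IV": mu * boost_young,
        }
    elif config.pattern == "reverse_hourglass":
        stage_mean = {
            "I": mu * boost_ancient,
            "II": mu * boost_young,
            "III": mu * boost_young,
            "IV": mu * boost_ancient,
        }
    else:
        stage_mean = {s: mu for s in TUMOR_STAGES}
    stage_mean["NAT"] = mu

    columns: dict[str, np.ndarray] = {}
    stage_labels: dict[str, str] = {}
    for stage in STAGE_ORDER:
        n_samples = int(config.samples_per_stage.get(stage, 0))
        means = stage_mean[stage]
        for k in range(1, n_samples + 1):
            sample_id = f"{stage}_{k:02d}"
            if config.dispersion is None or math.isinf(config.dispersion):
                counts = rng.poisson(means)
            else:
                shape = config.dispersion
                counts = rng.negative_binomial(shape, shape / (shape + means))
            columns[sample_id] = counts
            stage_labels[sample_id] = stage
    if not columns:
        raise ValidationError("samples_per_stage produced no samples")

    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"), dtype=float)
    # restore a stable gene order independent of the tertile sort
    values = values.loc[sorted(genes)]
    return StagedExpression(values, pd.Series(stage_labels))


def generate_deg_table(config: SimulationConfig, ages: AgeMap):
    """Draw a DEG table with planted phylostratum enrichment.

    Per tumor stage, gene *g* enters the DEG list with probability
    ``deg_rate * enrichment_fold`` if its stratum is enriched and
    ``deg_rate`` otherwise (capped at 1).  log2FC values come from
    stratum-dependent Gaussians; adjusted p-values are drawn below 0.05 on a
    log scale (they are bookkeeping, not inference).
    """
    from .enrichment import DegTable

    rng = _rng(config, 3)
    genes = sorted(ages.entries)
    strata = np.array([ages.entries[g] for g in genes])
    medians = config.log2fc_medians or _default_log2fc_medians(config.n_strata)
    sds = config.log2fc_sds or _default_log2fc_sds(config.n_strata)
    enriched = np.isin(strata, np.asarray(config.enriched_strata, dtype=int))
    p_member = np.where(
        enriched, min(1.0, config.deg_rate * config.enrichment_fold), config.deg_rate
    )

    rows = []
    for stage in TUMOR_STAGES:
        member = rng.random(len(genes)) < p_member
        idx = np.where(member)[0]
        loc = np.array([medians[int(s)] for s in strata[idx]])
        scale = np.array([sds[int(s)] for s in strata[idx]])
        log2fc = rng.normal(loc, scale)
        padj = 10.0 ** (-rng.uniform(1.31, 8.0, size=idx.size))
        for j, g_idx in enumerate(idx):
            rows.append(
                {
                    "gene_id": genes[g_idx],
                    "log2fc": float(log2fc[j]),
                    "padj": float(padj[j]),
                    "stage": stage,
                    "cancer_type": config.cancer_type,
                }
            )
    frame = pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj", "stage", "cancer_type"])
    return DegTable(frame)
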