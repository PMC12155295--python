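"""Phylostratum composition analysis of differentially expressed gene lists.

Given a DEG list and the background gene universe with phylostratum (PAI)
annotations, this module asks whether the DEG list's age composition deviates
from the background:

* per stratum, a 2x2 contingency table (DEG vs non-DEG background, in vs out
  of the stratum) with Fisher's exact test and Benjamini-Hochberg q-values
  across strata;
* globally, a chi-square goodness-of-fit statistic of the observed DEG
  stratum counts against expected counts ``|DEG| x background proportions``,
  calibrated by a bootstrap null: resampled gene sets of size |DEG| are drawn
  from the background without replacement, the same chi-square is computed
  for each, and the empirical p-value is the (add-one corrected) fraction of
  resamples whose statistic reaches the observed one;
* descriptively, the median log2 fold change of DEGs per (stratum, stage).

Strata with expected count zero (absent from the background) are dropped from
the chi-square with the degrees of freedom reduced accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .agemap import AgeMap
from .exceptions import ValidationError
from .stages import TUMOR_STAGES

__all__ = [
    "DegTable",
    "StratumEnrichmentResult",
    "stratum_contingency",
    "fisher_exact",
    "chi2_bootstrap",
    "median_log2fc_by_stratum",
    "naive_log2fc",
]

DEG_COLUMNS = ("gene_id", "log2fc", "padj", "stage", "cancer_type")


@dataclass
class DegTable:
    """Differentially-expressed-gene table: one row per (gene, stage, cancer)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(DEG_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValidationError(f"DEG table lacks columns {sorted(missing)}")
        df = self.frame.loc[:, list(DEG_COLUMNS)].copy()
        df["log2fc"] = df["log2fc"].astype(float)
        df["padj"] = df["padj"].astype(float)
        if ((df["padj"] < 0) | (df["padj"] > 1)).any():
            raise ValidationError("padj values must lie in [0, 1]")
        bad_stage = set(df["stage"]) - set(TUMOR_STAGES)
        if bad_stage:
            raise ValidationError(f"DEG table has non-tumor stages {sorted(bad_stage)}")
        dup = df.duplicated(subset=["cancer_type", "stage", "gene_id"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValidationError(
                f"duplicate DEG entry for gene {row['gene_id']!r} in "
                f"({row['cancer_type']}, stage {row['stage']})"
            )
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def gene_sets(self) -> dict[tuple[str, str], set[str]]:
        """(cancer_type, stage) -> set of DEG gene ids."""
        return {
            key: set(group["gene_id"])
            for key, group in self.frame.groupby(["cancer_type", "stage"], sort=True)
        }

    def all_genes(self) -> set[str]:
        return set(self.frame["gene_id"])


def _check_deg_in_background(deg, background: AgeMap) -> list[str]:
    deg = sorted(set(deg))
    for gene in deg:
        if gene not in background:
            raise ValidationError(
                f"DEG gene {gene!r} is absent from the background age map"
            )
    return deg


def stratum_contingency(deg, background: AgeMap, stratum: int) -> np.ndarray:
    """2x2 table (DEG vs non-DEG background) x (in vs out of ``stratum``).

    Cells: ``[[deg_in, deg_out], [bg_in, bg_out]]`` where the background row
    counts non-DEG genes only.
    """
    deg = _check_deg_in_background(deg, background)
    deg_set = set(deg)
    a = sum(1 for g in deg if background.entries[g] == stratum)
    b = len(deg) - a
    bg_in = sum(
        1 for g, s in background.entries.items() if s == stratum and g not in deg_set
    )
    bg_out = (len(background) - len(deg)) - bg_in
    return np.array([[a, b], [bg_in, bg_out]], dtype=int)


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns ``(odds_ratio, p)``.  The p-value sums hypergeometric
    probabilities of all tables (at the observed margins) no more probable
    than the observed one.  The odds ratio is the cross-product
    ``(a*d)/(b*c)``, reported as ``inf`` when ``b*c = 0`` with ``a*d > 0``
    and as ``nan`` when both products vanish.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.all(t == np.floor(t)):
            raise ValidationError("table cells must be integers")
        t = t.astype(int)
    if (t < 0).any():
        raise ValidationError("table cells must be nonnegative")
    (a, b), (c, d) = t
    _, p = sps.fisher_exact(t, alternative="two-sided")
    ad, bc = a * d, b * c
    if bc == 0:
        odds = float("inf") if ad > 0 else float("nan")
    else:
        odds = ad / bc
    return float(odds), float(p)


@dataclass
class StratumEnrichmentResult:
    """Per-stratum Fisher results plus the global chi-square bootstrap test."""

    per_stratum: pd.DataFrame  # index: stratum; columns: counts, OR, p, q
    chi2: float
    chi2_df: int
    bootstrap_p: float
    n_bootstrap: int
    seed: int
    n_deg: int

    def to_dict(self) -> dict:
        per = {
            int(stratum): {
                "count_deg": int(row["count_deg"]),
                "count_background": int(row["count_background"]),
                "odds_ratio": float(row["odds_ratio"]),
                "fisher_p": float(row["fisher_p"]),
                "fisher_q": float(row["fisher_q"]),
            }
            for stratum, row in self.per_stratum.iterrows()
        }
        return {
            "per_stratum": per,
            "chi2": float(self.chi2),
            "chi2_df": int(self.chi2_df),
            "bootstrap_p": float(self.bootstrap_p),
            "n_bootstrap": int(self.n_bootstrap),
            "seed": int(self.seed),
            "n_deg": int(self.n_deg),
        }


def chi2_bootstrap(
    deg,
    background: AgeMap,
    n_bootstrap: int = 10_000,
    seed: int = 0,
) -> StratumEnrichmentResult:
    """Chi-square test of DEG stratum composition with a bootstrap null.

    Expected stratum counts are ``|DEG|`` times the background stratum
    proportions; the statistic is ``sum (O - E)^2 / E`` over strata with
    ``E > 0``.  The null is built by drawing ``n_bootstrap`` gene sets of
    size |DEG| from the background without replacement and recomputing the
    statistic; ``bootstrap_p = (1 + #{chi2_b >= chi2_obs}) / (n_bootstrap + 1)``.
    Per-stratum Fisher's exact tests with Benjamini-Hochberg q-values are
    filled alongside.
    """
    deg = _check_deg_in_background(deg, background)
    if len(deg) < 1:
        raise ValidationError("DEG list is empty")
    if n_bootstrap < 100:
        raise ValidationError(f"n_bootstrap must be >= 100, got {n_bootstrap}")
    if len(background) < len(deg):
        raise ValidationError(
            f"background ({len(background)}) smaller than DEG list ({len(deg)})"
        )

    n_strata = background.n_strata
    bg_strata = np.fromiter(background.entries.values(), dtype=int, count=len(background))
    bg_counts = np.bincount(bg_strata, minlength=n_strata + 1)[1:]
    deg_strata = np.array([background.entries[g] for g in deg], dtype=int)
    deg_counts = np.bincount(deg_strata, minlength=n_strata + 1)[1:]

    n_deg = len(deg)
    expected = n_deg * bg_counts / len(background)
    live = expected > 0
    chi2_obs = float(((deg_counts - expected)[live] ** 2 / expected[live]).sum())
    df = int(live.sum()) - 1

    rng = np.random.default_rng(seed)
    resampled = rng.multivariate_hypergeometric(bg_counts, n_deg, size=n_bootstrap)
    null = ((resampled - expected)[:, live] ** 2 / expected[live]).sum(axis=1)
    bootstrap_p = float((1 + np.count_nonzero(null >= chi2_obs)) / (n_bootstrap + 1))

    strata_present = [s for s in range(1, n_strata + 1) if bg_counts[s - 1] > 0]
    rows = []
    for stratum in strata_present:
        a = int(deg_counts[stratum - 1])
        b = n_deg - a
        c = int(bg_counts[stratum - 1]) - a
        d = (len(background) - n_deg) - c
        odds, p = fisher_exact([[a, b], [c, d]])
        rows.append(
            {
                "count_deg": a,
                "count_background": int(bg_counts[stratum - 1]),
                "odds_ratio": odds,
                "fisher_p": p,
            }
        )
    per_stratum = pd.DataFrame(rows, index=pd.Index(strata_present, name="stratum"))
    per_stratum["fisher_q"] = multipletests(
        per_stratum["fisher_p"].to_numpy(), method="fdr_bh"
    )[1]

    return StratumEnrichmentResult(
        per_stratum=per_stratum,
        chi2=chi2_obs,
        chi2_df=df,
        bootstrap_p=bootstrap_p,
        n_bootstrap=n_bootstrap,
        seed=seed,
        n_deg=n_deg,
    )


def median_log2fc_by_stratum(deg: DegTable, ages: AgeMap) -> pd.DataFrame:
    """Median log2FC of DEGs per (phylostratum, stage).

    Returns a strata x stages DataFrame (all background strata 1..n, tumor
    stages I-IV); cells with no member genes are NaN, never zero.
    """
    df = deg.frame
    missing = [g for g in df["gene_id"] if g not in ages]
    if missing:
        raise ValidationError(
            f"DEG gene {missing[0]!r} lacks an age annotation"
        )
    work = df.assign(stratum=[ages.entries[g] for g in df["gene_id"]])
    table = work.pivot_table(
        index="stratum", columns="stage", values="log2fc", aggfunc="median"
    )
    table = table.reindex(
        index=range(1, ages.n_strata + 1),
        columns=[s for s in TUMOR_STAGES],
    )
    table.index.name = "stratum"
    table.columns.name = "stage"
    return table


def naive_log2fc(tumor_means, normal_means, pseudocount: float = 1.0) -> np.ndarray:
    """Elementwise ``log2((t + pc) / (n + pc))``.

    A fixture-grade fold-change helper for synthetic data; it is not a
    differential-expression method (no dispersion modelling, no shrinkage).
    """
    t = np.asarray(tumor_means, dtype=float)
    n = np.asarray(normal_means, dtype=float)
    if t.shape != n.shape:
        raise ValidationError(
            f"length mismatch: tumor {t.shape} vs normal {n.shape}"
        )
    if not pseudocount > 0:
        raise ValidationError(f"pseudocount must be > 0, got {pseudocount}")
    return np.log2((t + pseudocount) / (n + pseudocount))
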