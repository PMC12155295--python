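"""Permutation tests for flat, hourglass and reverse-hourglass index profiles.

A transcriptome index profile over ordered tumor stages can be (a) flat, (b)
hourglass-shaped — high in the early and late stages, dipping in the middle —
or (c) reverse-hourglass-shaped.  Three one-sided permutation tests cover
these alternatives:

* flat-line test: statistic = population variance of the per-stage profile
  (monotone-equivalent to its standard deviation); rejects for large variance,
  i.e. any deviation from constancy;
* reductive hourglass test: with ``e``, ``m``, ``l`` the mean index of the
  early, mid and late stage modules, statistic = min(e - m, l - m); positive
  only when the mid module sits strictly below both flanks;
* reverse hourglass test: statistic = min(m - e, m - l), the mirror image.

The null model permutes the gene -> stratum assignment uniformly at random
while holding expression fixed, recomputes the stage profile and statistic,
and reports the empirical upper-tail p-value with add-one correction,
``p = (1 + #{null >= observed}) / (B + 1)``, so p is never zero and never
below ``1/(B+1)``.  Permuting strata rather than expression keeps the full
correlation structure of the expression data intact under the null.

NAT control samples never enter the test statistic: the hourglass claim
concerns the tumor stages I-IV only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .agemap import _StratumMap
from .exceptions import ValidationError
from .indices import AGGREGATIONS, StagedExpression
from .stages import TUMOR_STAGES

__all__ = [
    "StageModules",
    "PatternTestResult",
    "profile_statistic_flat",
    "hourglass_score",
    "permutation_test",
    "TEST_KINDS",
]

TEST_KINDS = ("flat_line", "reductive_hourglass", "reverse_hourglass")


@dataclass(frozen=True)
class StageModules:
    """Partition of tumor stages into early / mid / late modules."""

    early: frozenset = field(default_factory=lambda: frozenset({"I"}))
    mid: frozenset = field(default_factory=lambda: frozenset({"II", "III"}))
    late: frozenset = field(default_factory=lambda: frozenset({"IV"}))

    def __post_init__(self) -> None:
        object.__setattr__(self, "early", frozenset(self.early))
        object.__setattr__(self, "mid", frozenset(self.mid))
        object.__setattr__(self, "late", frozenset(self.late))
        for name, module in (("early", self.early), ("mid", self.mid), ("late", self.late)):
            if not module:
                raise ValidationError(f"stage module {name!r} is empty")
        if (self.early & self.mid) or (self.early & self.late) or (self.mid & self.late):
            raise ValidationError("stage modules must be disjoint")
        if "NAT" in (self.early | self.mid | self.late):
            raise ValidationError("NAT cannot be part of a stage module")

    @classmethod
    def from_spec(cls, spec: str) -> "StageModules":
        """Parse ``"I:II,III:IV"`` into early / mid / late stage sets."""
        parts = spec.split(":")
        if len(parts) != 3:
            raise ValidationError(
                f"module spec {spec!r} must have three ':'-separated groups"
            )
        groups = [frozenset(p.split(",")) - {""} for p in parts]
        return cls(*groups)

    def validate_for(self, stages) -> None:
        """Check the modules are disjoint, non-empty and cover ``stages``."""
        present = set(stages) - {"NAT"}
        covered = self.early | self.mid | self.late
        uncovered = present - covered
        if uncovered:
            raise ValidationError(
                f"stages {sorted(uncovered)} are not assigned to any module"
            )
        absent = covered - present
        if absent:
            raise ValidationError(
                f"module stages {sorted(absent)} not present in the profile"
            )

    def to_spec(self) -> str:
        def fmt(module):
            return ",".join(s for s in TUMOR_STAGES if s in module)

        return ":".join(fmt(m) for m in (self.early, self.mid, self.late))


@dataclass
class PatternTestResult:
    """Observed statistic, permutation null summary and empirical p-value."""

    test_kind: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    null_mean: float
    null_sd: float
    parametric_p: float | None
    aggregation: str
    modules: str | None
    profile: dict
    null_values: np.ndarray | None = None

    def to_dict(self, include_null: bool = False) -> dict:
        out = {
            "test_kind": self.test_kind,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n_permutations": int(self.n_permutations),
            "seed": int(self.seed),
            "null_mean": float(self.null_mean),
            "null_sd": float(self.null_sd),
            "parametric_p": None if self.parametric_p is None else float(self.parametric_p),
            "aggregation": self.aggregation,
            "modules": self.modules,
            "profile": self.profile,
        }
        if include_null and self.null_values is not None:
            out["null_values"] = [float(v) for v in self.null_values]
        return out


def profile_statistic_flat(per_stage) -> float:
    """Population variance of the per-stage index values.

    The flat-line statistic; the quoted standard deviation is its square
    root, so the two induce identical permutation p-values.  Requires at
    least three stages.
    """
    values = np.asarray(pd.Series(per_stage), dtype=float)
    if values.size < 3:
        raise ValidationError(
            f"flat-line statistic needs >= 3 stages, got {values.size}"
        )
    return float(np.var(values))


def hourglass_score(per_stage, modules: StageModules, direction: str) -> float:
    """Module-contrast score for the (reverse) hourglass alternative.

    With ``e``, ``m``, ``l`` the arithmetic means of the early, mid and late
    module values: reductive score = min(e - m, l - m); reverse score =
    min(m - e, m - l).  Either score is positive only when the profile bends
    in the corresponding direction on *both* sides.
    """
    if direction not in ("reductive", "reverse"):
        raise ValidationError(f"unknown direction {direction!r}")
    series = pd.Series(per_stage, dtype=float)
    modules.validate_for(series.index)

    def module_mean(module) -> float:
        members = [s for s in series.index if s in module]
        if not members:
            raise ValidationError(f"empty stage module {sorted(module)}")
        return float(series.loc[members].mean())

    e, m, l = map(module_mean, (modules.early, modules.mid, modules.late))
    if direction == "reductive":
        return float(min(e - m, l - m))
    return float(min(m - e, m - l))


def _stage_groups(data: StagedExpression) -> tuple[list[str], list[np.ndarray]]:
    """Tumor stages present (canonical order) and their column-index arrays."""
    stages = [s for s in data.stages_present() if s != "NAT"]
    sample_pos = {s: i for i, s in enumerate(data.sample_ids)}
    groups = [
        np.array([sample_pos[smp] for smp in data.samples_of_stage(st)], dtype=int)
        for st in stages
    ]
    return stages, groups


def _profiles_from_strata(S: np.ndarray, X: np.ndarray, groups, aggregation: str) -> np.ndarray:
    """Stage profiles for each row of stratum assignments ``S`` (B x genes)."""
    if aggregation == "mean-expression":
        M = np.column_stack([X[:, g].mean(axis=1) for g in groups])
        return (S @ M) / M.sum(axis=0)
    per_sample = (S @ X) / X.sum(axis=0)
    return np.column_stack([per_sample[:, g].mean(axis=1) for g in groups])


def _statistics(profiles: np.ndarray, stages, modules: StageModules | None, test_kind: str) -> np.ndarray:
    if test_kind == "flat_line":
        return np.var(profiles, axis=1)
    assert modules is not None
    e = profiles[:, [i for i, s in enumerate(stages) if s in modules.early]].mean(axis=1)
    m = profiles[:, [i for i, s in enumerate(stages) if s in modules.mid]].mean(axis=1)
    l = profiles[:, [i for i, s in enumerate(stages) if s in modules.late]].mean(axis=1)
    if test_kind == "reductive_hourglass":
        return np.minimum(e - m, l - m)
    return np.minimum(m - e, m - l)


def permutation_test(
    data: StagedExpression,
    strata: _StratumMap,
    modules: StageModules | None = None,
    test_kind: str = "flat_line",
    B: int = 1000,
    seed: int = 0,
    aggregation: str = "mean-expression",
    keep_null: bool = False,
) -> PatternTestResult:
    """One-sided permutation test of a stage profile against the flat null.

    The observed statistic is computed on the true gene -> stratum map; each
    of the ``B`` replicates permutes that map uniformly at random (expression
    held fixed), recomputes the stage profile under the same aggregation, and
    records the statistic.  All three tests reject in their own upper tail.

    Identical ``seed`` and inputs give a bit-identical result.
    """
    if test_kind not in TEST_KINDS:
        raise ValidationError(f"unknown test kind {test_kind!r}")
    if aggregation not in AGGREGATIONS:
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    if B < 100:
        raise ValidationError(f"B must be >= 100, got {B}")

    tumor = data.subset_stages(TUMOR_STAGES)
    stages, groups = _stage_groups(tumor)
    if test_kind == "flat_line":
        if len(stages) < 3:
            raise ValidationError(
                f"flat-line test needs >= 3 tumor stages, got {len(stages)}"
            )
        modules = None
    else:
        if modules is None:
            modules = StageModules()
        modules.validate_for(stages)

    s_all = strata.stratum_vector(tumor.gene_ids)
    annotated = ~np.isnan(s_all)
    if not annotated.any():
        raise ValidationError("no gene in the matrix has a stratum annotation")
    X = tumor.values.to_numpy(dtype=float)[annotated, :]
    w = s_all[annotated]
    if not (X.sum(axis=0) > 0).all():
        dead = int(np.where(~(X.sum(axis=0) > 0))[0][0])
        raise ValidationError(
            f"no annotated expression in sample {tumor.sample_ids[dead]!r}"
        )

    observed_profile = _profiles_from_strata(w[None, :], X, groups, aggregation)
    observed = float(
        _statistics(observed_profile, stages, modules, test_kind)[0]
    )
    if not np.isfinite(observed):
        raise ValidationError("non-finite observed statistic")
    # snap float-summation noise (degenerate inputs, e.g. a single stratum,
    # would otherwise yield statistics of order eps^2 instead of exactly 0)
    _SNAP = 1e-9
    if abs(observed) < _SNAP:
        observed = 0.0

    rng = np.random.default_rng(seed)
    S = rng.permuted(np.broadcast_to(w, (B, w.size)).copy(), axis=1)
    null_profiles = _profiles_from_strata(S, X, groups, aggregation)
    null = _statistics(null_profiles, stages, modules, test_kind)

    p_value = float((1 + np.count_nonzero(null >= observed - _SNAP)) / (B + 1))
    null_mean = float(null.mean())
    null_sd = float(null.std())
    parametric_p = (
        float(sps.norm.sf((observed - null_mean) / null_sd)) if null_sd > 0 else None
    )
    return PatternTestResult(
        test_kind=test_kind,
        statistic=observed,
        p_value=p_value,
        n_permutations=B,
        seed=seed,
        null_mean=null_mean,
        null_sd=null_sd,
        parametric_p=parametric_p,
        aggregation=aggregation,
        modules=None if modules is None else modules.to_spec(),
        profile={s: float(v) for s, v in zip(stages, observed_profile[0])},
        null_values=null if keep_null else None,
    )
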