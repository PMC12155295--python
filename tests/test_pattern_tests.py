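"""Flat-line, hourglass and reverse-hourglass permutation tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phylostage import (
    AgeMap,
    SimulationConfig,
    StagedExpression,
    StageModules,
    ValidationError,
    generate_expression,
    generate_universe,
    hourglass_score,
    normalize_library,
    permutation_test,
    profile_statistic_flat,
)

class TestFlatStatistic:
    def test_constant_profile_is_zero(self):
        assert profile_statistic_flat([2.0, 2.0, 2.0, 2.0]) == 0.0

    def test_population_variance(self):
        assert profile_statistic_flat([1.0, 2.0, 3.0, 4.0]) == pytest.approx(1.25)

    def test_two_stages_rejected(self):
        with pytest.raises(ValidationError):
            profile_statistic_flat([1.0, 3.0])


class TestHourglassScore:
    def test_reductive_dip(self):
        profile = pd.Series({"I": 3.0, "II": 1.0, "III": 1.0, "IV": 3.0})
        assert hourglass_score(profile, StageModules(), "reductive") == pytest.approx(2.0)

    def test_flat_profile_scores_zero(self):
        profile = pd.Series({"I": 1.0, "II": 1.0, "III": 1.0, "IV": 1.0})
        assert hourglass_score(profile, StageModules(), "reductive") == 0.0
        assert hourglass_score(profile, StageModules(), "reverse") == 0.0

    def test_reverse_bump(self):
        profile = pd.Series({"I": 1.0, "II": 3.0, "III": 3.0, "IV": 1.0})
        assert hourglass_score(profile, StageModules(), "reverse") == pytest.approx(2.0)

    @given(st.lists(st.floats(min_value=-10, max_value=10), min_size=4, max_size=4))
    def test_direction_identity(self, values):
        """reductive + reverse = min(x,y) - max(x,y) <= 0, equality iff x = y."""
        profile = pd.Series(dict(zip(["I", "II", "III", "IV"], values)))
        modules = StageModules()
        red = hourglass_score(profile, modules, "reductive")
        rev = hourglass_score(profile, modules, "reverse")
        e, m, l = values[0], (values[1] + values[2]) / 2, values[3]
        x, y = e - m, l - m
        assert red + rev == pytest.approx(min(x, y) - max(x, y), abs=1e-9)
        assert red + rev <= 1e-9
        if abs(x - y) > 1e-9:
            assert red + rev < 0


class TestStageModules:
    def test_from_spec_roundtrip(self):
        modules = StageModules.from_spec("I:II,III:IV")
        assert modules.early == {"I"} and modules.mid == {"II", "III"} and modules.late == {"IV"}
        assert modules.to_spec() == "I:II,III:IV"

    def test_overlap_rejected(self):
        with pytest.raises(ValidationError):
            StageModules(frozenset({"I"}), frozenset({"I", "II"}), frozenset({"IV"}))

    def test_empty_module_rejected(self):
        with pytest.raises(ValidationError):
            StageModules.from_spec("I::IV")

    def test_uncovered_stage_rejected(self):
        modules = StageModules.from_spec("I:II:IV")
        with pytest.raises(ValidationError):
            modules.validate_for(["I", "II", "III", "IV"])


def _degenerate_data(n_genes=40, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    samples = {f"{st}_{k}": st for st in ("I", "II", "III", "IV") for k in range(3)}
    values = pd.DataFrame(
        rng.uniform(1, 10, (n_genes, len(samples))), index=genes, columns=list(samples)
    )
    return StagedExpression(values, pd.Series(samples)), genes


class TestPermutationTest:
    def test_single_stratum_gives_p_one(self):
        data, genes = _degenerate_data()
        strata = AgeMap({g: 5 for g in genes})
        result = permutation_test(data, strata, test_kind="flat_line", B=200, seed=1)
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_p_value_bounds(self):
        data, genes = _degenerate_data(seed=5)
        rng = np.random.default_rng(2)
        strata = AgeMap({g: int(s) for g, s in zip(genes, rng.integers(1, 15, len(genes)))})
        for kind in ("flat_line", "reductive_hourglass", "reverse_hourglass"):
            result = permutation_test(data, strata, test_kind=kind, B=199, seed=3)
            assert 1.0 / 200 <= result.p_value <= 1.0

    def test_seed_reproducibility(self):
        data, genes = _degenerate_data(seed=9)
        rng = np.random.default_rng(4)
        strata = AgeMap({g: int(s) for g, s in zip(genes, rng.integers(1, 15, len(genes)))})
        a = permutation_test(data, strata, test_kind="flat_line", B=250, seed=42)
        b = permutation_test(data, strata, test_kind="flat_line", B=250, seed=42)
        assert a.statistic == b.statistic
        assert a.p_value == b.p_value
        assert a.null_mean == b.null_mean and a.null_sd == b.null_sd

    def test_nat_excluded_from_statistic(self, small_ages, small_expression):
        """Adding NAT columns must not change the tumor-stage statistic."""
        tumor_only = small_expression.subset_stages(["I", "II", "III", "IV"])
        with_nat = small_expression
        a = permutation_test(tumor_only, small_ages, test_kind="flat_line", B=100, seed=0)
        b = permutation_test(with_nat, small_ages, test_kind="flat_line", B=100, seed=0)
        assert a.statistic == pytest.approx(b.statistic)

    def test_small_b_rejected(self, small_ages, small_expression):
        with pytest.raises(ValidationError):
            permutation_test(small_expression, small_ages, B=50, seed=0)

    def test_planted_hourglass_regression(self):
        """Generator defaults, delta=2, seed 7, B=1000: frozen seed-fixed result."""
        cfg = SimulationConfig(pattern="hourglass", effect_size=2.0, seed=7)
        ages, _ = generate_universe(cfg)
        data = normalize_library(generate_expression(cfg, ages))
        result = permutation_test(
            data, ages, test_kind="reductive_hourglass", B=1000, seed=7
        )
        assert result.p_value < 0.05
        assert result.p_value == pytest.approx(0.000999000999000999)
        assert result.statistic == pytest.approx(2.0020856481288067, abs=1e-9)

    def test_null_permutes_strata_not_expression(self):
        """The null keeps expression fixed: per-sample totals of the data used in
        every permutation equal the observed totals (permutation only relabels
        strata, whose multiset is preserved by construction)."""
        data, genes = _degenerate_data(seed=12)
        rng = np.random.default_rng(8)
        strata = AgeMap({g: int(s) for g, s in zip(genes, rng.integers(1, 15, len(genes)))})
        result = permutation_test(
            data, strata, test_kind="flat_line", B=300, seed=1, keep_null=True
        )
        # every null statistic is the variance of a profile whose values are
        # bounded by the stratum range, as for the observed profile
        lo, hi = 1, 14
        max_var = ((hi - lo) / 2.0) ** 2
        assert np.all(result.null_values >= 0)
        assert np.all(result.null_values <= max_var)
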