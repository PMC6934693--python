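"""Single-generation update rules: examples, identities, and invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drivegates import (
    DegeneratePopulationError,
    DriveParams,
    EffectiveParams,
    InductionSettings,
    ModelVariant,
    effective_params,
    het_fitness,
    mean_fitness,
    step,
    step_inducible_efficiency,
    step_inducible_fitness,
    step_self_cleaving,
    step_standard,
)

Q_GRID = [0.0, 0.001, 0.01, 0.1, 0.25, 0.5, 0.75, 0.9, 0.99, 1.0]

unit = st.floats(min_value=0.0, max_value=1.0)


@pytest.mark.parametrize(
    "f,h,expected",
    [
        (1.0, 0.5, 1.0),   # heterozygote of two unit-fitness alleles
        (0.0, 0.5, 0.5),   # codominant midpoint
        (0.7, 0.5, 0.85),  # (1-h) + f*h by hand
        (0.3, 0.0, 1.0),   # fully recessive cost
        (0.3, 1.0, 0.3),   # fully dominant cost
    ],
)
def test_het_fitness_formula(f, h, expected):
    assert het_fitness(f, h) == pytest.approx(expected, abs=1e-15)


@given(f=unit, h=unit)
@settings(max_examples=100, derandomize=True)
def test_het_fitness_between_f_and_one(f, h):
    w = het_fitness(f, h)
    assert min(f, 1.0) - 1e-12 <= w <= max(f, 1.0) + 1e-12


@pytest.mark.parametrize("bad", [(-0.1, 0.5), (1.1, 0.5), (0.5, -0.01), (0.5, 2.0)])
def test_het_fitness_rejects_out_of_range(bad):
    with pytest.raises(ValueError):
        het_fitness(*bad)


def test_params_reject_out_of_range():
    with pytest.raises(ValueError):
        DriveParams(e_W=1.5, f=0.7)
    with pytest.raises(ValueError):
        DriveParams(e_W=0.5, f=-0.2)
    with pytest.raises(ValueError):
        InductionSettings(alpha=1.2, start_generation=0)
    with pytest.raises(ValueError):
        InductionSettings(alpha=0.5, start_generation=-1)


class TestEffectiveParams:
    PARAMS = DriveParams(
        e_W=0.8, f=0.7, e_W_induced=0.1, f_induced=0.4, e_D=0.05, e_D_induced=0.9
    )

    def test_identity_before_signal(self):
        ind = InductionSettings(alpha=0.9, start_generation=10, enabled=True)
        eff = effective_params(self.PARAMS, ind, generation=9)
        assert (eff.e_eff, eff.f_eff, eff.E) == (0.8, 0.7, 0.05)

    def test_identity_when_disabled(self):
        ind = InductionSettings(alpha=0.9, start_generation=0, enabled=False)
        eff = effective_params(self.PARAMS, ind, generation=100)
        assert (eff.e_eff, eff.f_eff, eff.E) == (0.8, 0.7, 0.05)

    def test_full_response(self):
        ind = InductionSettings(alpha=1.0, start_generation=0, enabled=True)
        eff = effective_params(self.PARAMS, ind, generation=0)
        assert eff.e_eff == pytest.approx(0.1)
        assert eff.f_eff == pytest.approx(0.4)
        assert eff.E == pytest.approx(0.9)

    def test_convex_combination(self):
        ind = InductionSettings(alpha=0.9, start_generation=10, enabled=True)
        eff = effective_params(self.PARAMS, ind, generation=10)
        assert eff.e_eff == pytest.approx(0.9 * 0.1 + 0.1 * 0.8)  # 0.17
        assert eff.f_eff == pytest.approx(0.9 * 0.4 + 0.1 * 0.7)  # 0.43
        assert eff.E == pytest.approx(0.1 * 0.05 + 0.9 * 0.9)

    def test_signal_persists_after_start(self):
        ind = InductionSettings(alpha=0.6, start_generation=5, enabled=True)
        for g in (5, 6, 50, 999):
            assert effective_params(self.PARAMS, ind, g).e_eff == pytest.approx(
                0.6 * 0.1 + 0.4 * 0.8
            )


class TestStepStandard:
    def test_absent_allele_stays_absent(self, sample_params):
        assert step_standard(0.0, sample_params) == 0.0

    def test_full_conversion_no_cost(self):
        # e_W=1, f=1: all heterozygotes convert, no selection differential
        assert step_standard(0.5, DriveParams(e_W=1, f=1)) == pytest.approx(0.75)

    def test_sample_point_one_step(self, sample_params):
        # frozen from the genotype-enumeration oracle at q_D=0.001
        assert step_standard(0.001, sample_params) == pytest.approx(
            0.0012901063478022896, abs=1e-15
        )

    def test_fixed_allele_stays_fixed(self, sample_params):
        assert step_standard(1.0, sample_params) == pytest.approx(1.0)

    def test_neutral_hardy_weinberg_fixed_point(self):
        p = DriveParams(e_W=0.0, f=1.0)
        for q in Q_GRID:
            assert step_standard(q, p) == pytest.approx(q, abs=1e-15)

    def test_closed_form_limit_perfect_drive(self):
        # e_W=1, f=1: 1 - q' = (1 - q)^2 exactly
        p = DriveParams(e_W=1.0, f=1.0)
        q = 0.001
        for _ in range(20):
            q_next = step_standard(q, p)
            assert 1.0 - q_next == pytest.approx((1.0 - q) ** 2, abs=1e-15)
            q = q_next

    def test_monotone_in_e_W_at_unit_fitness(self):
        # at f=1, d q'/d e_W = q_W q_D >= 0
        for q in (0.1, 0.5, 0.9):
            values = [step_standard(q, DriveParams(e_W=e, f=1.0)) for e in
                      [i / 20 for i in range(21)]]
            assert values == sorted(values)


class TestReductionIdentities:
    @pytest.mark.parametrize("q", Q_GRID)
    def test_inducible_efficiency_collapses(self, q, sample_params):
        assert step_inducible_efficiency(q, sample_params, sample_params.e_W) == \
            step_standard(q, sample_params)

    @pytest.mark.parametrize("q", Q_GRID)
    def test_inducible_fitness_collapses(self, q, sample_params):
        assert step_inducible_fitness(q, sample_params, sample_params.f) == \
            step_standard(q, sample_params)

    @pytest.mark.parametrize("q", Q_GRID)
    def test_self_cleaving_collapses_at_zero_cleavage(self, q, sample_params):
        assert step_self_cleaving(q, sample_params, 0.0) == \
            step_standard(q, sample_params)

    @pytest.mark.parametrize("q", Q_GRID)
    def test_alpha_zero_is_standard(self, q):
        p = DriveParams(e_W=0.8, f=0.7, e_W_induced=0.1, f_induced=0.2,
                        e_D=0.0, e_D_induced=0.9)
        ind = InductionSettings(alpha=0.9, start_generation=10, enabled=True)
        eff = effective_params(p, ind, generation=0)  # pre-signal
        for variant in ModelVariant:
            assert step(q, p, variant, eff) == step_standard(q, p)


class TestStepInducible:
    def test_post_induction_decline(self, sample_params):
        # effective efficiency 0.17 makes the rare drive shrink
        p = DriveParams(e_W=0.8, f=0.7, e_W_induced=0.1)
        assert step_inducible_efficiency(0.013, p, 0.17) < 0.013

    def test_zero_efficiency_unit_fitness_is_neutral(self):
        p = DriveParams(e_W=0.8, f=1.0)
        for q in Q_GRID:
            assert step_inducible_efficiency(q, p, 0.0) == pytest.approx(q, abs=1e-15)

    def test_unit_effective_fitness_no_drive_is_neutral(self):
        p = DriveParams(e_W=0.0, f=0.7)
        for q in Q_GRID:
            assert step_inducible_fitness(q, p, 1.0) == pytest.approx(q, abs=1e-15)


class TestStepSelfCleaving:
    def test_all_lethal_corner_raises(self, sample_params):
        with pytest.raises(DegeneratePopulationError):
            step_self_cleaving(1.0, sample_params, 1.0)

    def test_known_value(self, sample_params):
        # frozen from the genotype-enumeration oracle
        assert step_self_cleaving(0.5, sample_params, 0.6) == pytest.approx(
            0.4242957746478873, abs=1e-15
        )

    def test_cleavage_reduces_drive_frequency(self, sample_params):
        base = step_self_cleaving(0.5, sample_params, 0.0)
        for E in (0.2, 0.5, 0.9):
            assert step_self_cleaving(0.5, sample_params, E) < base


class TestMeanFitness:
    def test_unity_when_no_cost_no_lethality(self):
        p = DriveParams(e_W=0.8, f=1.0)
        for q in Q_GRID:
            assert mean_fitness(q, p, ModelVariant.STANDARD) == pytest.approx(1.0)

    def test_sample_point(self, sample_params):
        assert mean_fitness(0.001, sample_params, ModelVariant.STANDARD) == \
            pytest.approx(0.99946024, abs=1e-12)

    def test_all_lethal_corner_is_zero(self, sample_params):
        eff = EffectiveParams(e_eff=0.8, f_eff=0.7, E=1.0)
        assert mean_fitness(1.0, sample_params, ModelVariant.SELF_CLEAVING, eff) == \
            pytest.approx(0.0, abs=1e-15)

    def test_matches_step_denominator(self, sample_params):
        # q' * wbar must equal the numerator implied by the surviving pools
        q = 0.3
        eff = EffectiveParams(e_eff=0.8, f_eff=0.7, E=0.4)
        wbar = mean_fitness(q, sample_params, ModelVariant.SELF_CLEAVING, eff)
        q_next = step_self_cleaving(q, sample_params, 0.4)
        assert 0.0 < wbar <= 1.0
        assert 0.0 <= q_next <= 1.0


@given(
    q=st.floats(min_value=0.0, max_value=1.0),
    e=unit,
    f=unit,
    h=unit,
    E=unit,
)
@settings(max_examples=300, derandomize=True)
def test_steps_map_unit_interval_into_itself(q, e, f, h, E):
    """Closure: every update maps [0,1] -> [0,1] whenever mean fitness > 0."""
    p = DriveParams(e_W=e, f=f, h=h)
    for fn in (
        lambda: step_standard(q, p),
        lambda: step_inducible_efficiency(q, p, e),
        lambda: step_inducible_fitness(q, p, f),
        lambda: step_self_cleaving(q, p, E),
    ):
        try:
            out = fn()
        except DegeneratePopulationError:
            continue
        assert 0.0 <= out <= 1.0
        assert math.isfinite(out)
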