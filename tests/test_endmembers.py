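"""Dietary (Model-style concentration-weighted) and microbial end members."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutaa.endmembers import (
    DEFAULT_CASEIN_PROFILE,
    DEFAULT_CORNMEAL_PROFILE,
    DEFAULT_DIETS,
    AAProfile,
    DietComposition,
    FractionationTable,
    build_endmember_set,
    carbohydrate_pool_delta,
    dietary_aa_delta,
    microbial_endmember_delta,
    protein_source_fractions,
)


def low_protein_diet(**overrides) -> DietComposition:
    kwargs = dict(
        treatment_label="9P:75C",
        mass_fraction_casein=0.051,
        mass_fraction_sucrose=0.36,
        mass_fraction_cornmeal=0.39,
        mass_fraction_other=0.199,
    )
    kwargs.update(overrides)
    return DietComposition(**kwargs)


class TestDietComposition:
    def test_mass_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to"):
            low_protein_diet(mass_fraction_other=0.10)

    def test_default_diets_match_labels(self):
        # casein + 10% of cornmeal mass reproduces the labelled protein %
        for diet, protein in zip(DEFAULT_DIETS, (0.40, 0.21, 0.12, 0.09)):
            assert diet.total_protein_fraction == pytest.approx(protein)
        assert all(d.mass_fraction_sucrose == 0.36 for d in DEFAULT_DIETS)


class TestProteinSourceFractions:
    def test_low_protein_diet_split(self):
        # 0.039 g corn protein / 0.090 g total protein
        f_cas, f_corn = protein_source_fractions(low_protein_diet())
        assert f_corn == pytest.approx(0.039 / 0.090, abs=1e-9)
        assert f_cas + f_corn == pytest.approx(1.0)

    @pytest.mark.parametrize("overrides", [
        {"mass_fraction_cornmeal": 0.0, "mass_fraction_other": 0.589},
        {"cornmeal_protein_fraction": 0.0},
    ])
    def test_no_corn_protein_collapses_to_casein(self, overrides):
        f_cas, f_corn = protein_source_fractions(low_protein_diet(**overrides))
        assert f_cas == 1.0 and f_corn == 0.0

    def test_protein_free_diet_rejected(self):
        diet = low_protein_diet(
            mass_fraction_casein=0.0, cornmeal_protein_fraction=0.0, mass_fraction_other=0.25
        )
        with pytest.raises(ValueError, match="no protein"):
            protein_source_fractions(diet)


class TestDietaryAADelta:
    def test_equal_concentrations_reduce_to_fraction_weighting(self):
        """With equal AA concentrations the concentration-weighted model
        collapses to simple protein-mass weighting (oracle equivalence)."""
        prof = AAProfile("x", {"Val": 0.05})
        delta = dietary_aa_delta(low_protein_diet(), prof, prof, ["Val"])["Val"]
        f_corn = 0.039 / 0.090
        expected = (1 - f_corn) * -26.5 + f_corn * -12.0
        assert delta == pytest.approx(expected, abs=1e-9)
        assert delta == pytest.approx(-20.22, abs=0.06)

    def test_single_source_collapse(self):
        casein = AAProfile("casein", {"Val": 0.066})
        corn_free = AAProfile("cornmeal", {"Val": 0.0})
        delta = dietary_aa_delta(low_protein_diet(), casein, corn_free, ["Val"])["Val"]
        assert delta == pytest.approx(-26.5)

    def test_scale_invariance_of_concentrations(self):
        doubled_cas = AAProfile("casein", {k: 2 * v for k, v in DEFAULT_CASEIN_PROFILE.concentration.items()})
        doubled_corn = AAProfile("cornmeal", {k: 2 * v for k, v in DEFAULT_CORNMEAL_PROFILE.concentration.items()})
        base = dietary_aa_delta(low_protein_diet(), DEFAULT_CASEIN_PROFILE, DEFAULT_CORNMEAL_PROFILE)
        scaled = dietary_aa_delta(low_protein_diet(), doubled_cas, doubled_corn)
        for aa in base:
            assert scaled[aa] == pytest.approx(base[aa], abs=1e-12)

    def test_zero_in_both_sources_reported_per_aa(self):
        prof = AAProfile("x", {"Val": 0.0})
        with pytest.raises(ValueError, match="Val"):
            dietary_aa_delta(low_protein_diet(), prof, prof, ["Val"])

    @given(c_cas=st.floats(0.001, 0.2), c_corn=st.floats(0.001, 0.2))
    @settings(max_examples=100, deadline=None)
    def test_mixing_boundedness(self, c_cas, c_corn):
        """Output δ lies within [min, max] of the two source δ values."""
        delta = dietary_aa_delta(
            low_protein_diet(), AAProfile("c", {"Val": c_cas}), AAProfile("m", {"Val": c_corn}), ["Val"]
        )["Val"]
        assert -26.5 - 1e-9 <= delta <= -12.0 + 1e-9


class TestCarbohydratePool:
    def test_weighted_mean_of_sucrose_and_cornmeal(self):
        # cornmeal carb mass specified directly as 0.39
        diet = low_protein_diet(cornmeal_carb_fraction=1.0)
        assert carbohydrate_pool_delta(diet) == pytest.approx(
            (0.36 * -12.2 + 0.39 * -12.0) / 0.75, abs=1e-9
        )

    def test_no_cornmeal_gives_sucrose_delta(self):
        diet = low_protein_diet(mass_fraction_cornmeal=0.0, mass_fraction_other=0.589)
        assert carbohydrate_pool_delta(diet) == pytest.approx(-12.2)

    def test_equal_source_deltas_are_proportion_free(self):
        diet = low_protein_diet(delta_sucrose=-12.0, delta_cornmeal=-12.0)
        assert carbohydrate_pool_delta(diet) == pytest.approx(-12.0)

    def test_carbohydrate_free_diet_rejected(self):
        diet = low_protein_diet(
            mass_fraction_sucrose=0.0, mass_fraction_cornmeal=0.0, mass_fraction_other=0.949
        )
        with pytest.raises(ValueError, match="no carbohydrate"):
            carbohydrate_pool_delta(diet)


class TestMicrobialEndmember:
    def test_offset_addition(self):
        table = FractionationTable(offset={"Val": -3.0})
        assert microbial_endmember_delta(-12.1, table, ["Val"])["Val"] == pytest.approx(-15.1)

    def test_zero_offsets_equal_carb_pool(self):
        table = FractionationTable(offset={"Val": 0.0, "Ile": 0.0})
        out = microbial_endmember_delta(-12.1, table, ["Val", "Ile"])
        assert all(v == pytest.approx(-12.1) for v in out.values())

    def test_translation_equivariance(self):
        table = FractionationTable(offset={"Val": -3.0, "Thr": 1.5})
        base = microbial_endmember_delta(-12.1, table, ["Val", "Thr"])
        shifted = microbial_endmember_delta(-11.1, table, ["Val", "Thr"])
        for aa in base:
            assert shifted[aa] - base[aa] == pytest.approx(1.0)

    def test_missing_aa_named_in_error(self):
        table = FractionationTable(offset={"Val": 0.0})
        with pytest.raises(KeyError, match="Thr"):
            microbial_endmember_delta(-12.1, table, ["Val", "Thr"])


def test_endmember_set_total_over_grid(default_endmembers):
    labels = [d.treatment_label for d in DEFAULT_DIETS]
    for t in labels:
        for aa in ("Thr", "Lys", "Phe", "Val", "Ile", "Leu"):
            d_diet, d_micro = default_endmembers.require(t, aa)
            assert -27.0 < d_diet < -11.0
            assert -13.0 < d_micro < -11.0
    frame = default_endmembers.to_frame()
    assert len(frame) == 2 * len(labels) * 6
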