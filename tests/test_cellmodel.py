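"""Lysosomal ion-trapping cell model: speciation, fluxes, steady states."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

from fiasma.cellmodel import (
    CellModel,
    CellModelParams,
    SpeciationProfile,
    clys_descriptor,
    fraction_speciation,
    required_incubation,
    simulate_accumulation,
)
from fiasma.errors import ConfigurationError


def neutral_only_params(**overrides) -> CellModelParams:
    """Neutral-species-dominated limit: zero potentials, negligible ionic
    permeability, no lipid sorption -- the regime with a closed-form
    steady state."""
    p = CellModelParams(**overrides)
    for name in ("external", "cytosol", "lysosome", "mitochondrion"):
        setattr(p, name, replace(getattr(p, name), potential_mv=0.0, lipid_fraction=0.0))
    p.ionic_log_offset = -300.0
    return p


def henderson_hasselbalch_ratio(profile: SpeciationProfile, ph_in: float, ph_out: float) -> float:
    """Independent closed-form ion-trap ratio: total(in)/total(out) when only
    the neutral species equilibrates across the membrane."""

    def total_over_neutral(ph: float) -> float:
        if profile.variant == "monobase":
            return 1.0 + 10.0 ** (profile.pka_base1 - ph)
        if profile.variant == "monoacid":
            return 1.0 + 10.0 ** (ph - profile.pka_acid)
        if profile.variant == "bibase":
            return (
                1.0
                + 10.0 ** (profile.pka_base1 - ph)
                + 10.0 ** (profile.pka_base1 + profile.pka_base2 - 2.0 * ph)
            )
        return (1.0 + 10.0 ** (profile.pka_base1 - ph)) * (
            1.0 + 10.0 ** (ph - profile.pka_acid)
        )

    return total_over_neutral(ph_in) / total_over_neutral(ph_out)


class TestSpeciation:
    def test_monobase_at_its_pka_is_half_protonated(self):
        f = fraction_speciation(SpeciationProfile("monobase", pka_base1=9.0), 9.0)
        assert f["neutral"] == pytest.approx(0.5) and f["cation1"] == pytest.approx(0.5)

    def test_monobase_strongly_protonated_in_acid(self):
        f = fraction_speciation(SpeciationProfile("monobase", pka_base1=9.0), 5.0)
        assert f["neutral"] == pytest.approx(1.0 / (1.0 + 1e4), rel=1e-9)

    def test_no_relevant_group_convention_is_neutral(self):
        f = fraction_speciation(SpeciationProfile("monoacid", pka_acid=15.0), 7.4)
        assert f["neutral"] == pytest.approx(1.0, abs=1e-7)

    @pytest.mark.parametrize(
        "profile",
        [
            SpeciationProfile("monobase", pka_base1=8.0),
            SpeciationProfile("monoacid", pka_acid=4.0),
            SpeciationProfile("bibase", pka_base1=9.5, pka_base2=7.0),
            SpeciationProfile("zwitter", pka_base1=8.0, pka_acid=4.0),
        ],
    )
    @pytest.mark.parametrize("ph", [1.0, 5.0, 7.4, 10.0, 13.0])
    def test_fractions_sum_to_one(self, profile, ph):
        assert sum(fraction_speciation(profile, ph).values()) == pytest.approx(1.0, abs=1e-12)

    def test_variant_pka_mismatch_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            SpeciationProfile("bibase", pka_base1=9.0)
        with pytest.raises(ConfigurationError):
            SpeciationProfile("bibase", pka_base1=5.0, pka_base2=9.0)


class TestSteadyState:
    def test_monobase_ion_trap_closed_form(self):
        params = neutral_only_params()
        model = CellModel(SpeciationProfile("monobase", pka_base1=9.0), params, 3.0)
        expected = (1 + 10 ** (9 - 5.0)) / (1 + 10 ** (9 - 7.4))
        assert model.lysosome_ratio() == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(245.06, abs=0.01)

    def test_oracle_equivalence_all_variants_random_configs(self):
        rng = np.random.default_rng(42)
        params = neutral_only_params()
        checked = 0
        for _ in range(120):
            variant = rng.choice(["monoacid", "monobase", "bibase", "zwitter"])
            pkas = np.sort(rng.uniform(2.0, 12.0, size=2))[::-1]
            if variant == "monoacid":
                profile = SpeciationProfile("monoacid", pka_acid=pkas[0])
            elif variant == "monobase":
                profile = SpeciationProfile("monobase", pka_base1=pkas[0])
            elif variant == "bibase":
                profile = SpeciationProfile("bibase", pka_base1=pkas[0], pka_base2=pkas[1])
            else:
                profile = SpeciationProfile("zwitter", pka_base1=pkas[0], pka_acid=pkas[1])
            p = replace(params)
            p.lysosome = replace(p.lysosome, ph=float(rng.uniform(3.5, 6.5)))
            p.external = replace(p.external, ph=float(rng.uniform(6.8, 8.0)))
            model = CellModel(profile, p, float(rng.uniform(-1, 6)))
            expected = henderson_hasselbalch_ratio(profile, p.lysosome.ph, p.external.ph)
            assert model.lysosome_ratio() == pytest.approx(expected, rel=1e-4)
            checked += 1
        assert checked >= 100

    def test_non_ionizable_compound_equilibrates_to_external(self):
        params = neutral_only_params()
        profile = SpeciationProfile("monoacid", pka_acid=15.0)
        assert clys_descriptor(profile, params, 2.0) == pytest.approx(
            params.external_conc_um, rel=1e-6
        )

    def test_monobase_clys_neutral_limit(self):
        params = neutral_only_params()
        profile = SpeciationProfile("monobase", pka_base1=9.0)
        assert clys_descriptor(profile, params, 3.0) == pytest.approx(2450.6, rel=1e-3)

    def test_acid_excluded_from_acidic_lysosome(self):
        params = CellModelParams()
        profile = SpeciationProfile("monoacid", pka_acid=4.0)
        assert clys_descriptor(profile, params, 2.0) < params.external_conc_um

    def test_base_trapped_at_default_preset(self):
        params = CellModelParams()
        for pka in (4.0, 7.0, 9.0, 11.0):
            profile = SpeciationProfile("monobase", pka_base1=pka)
            assert CellModel(profile, params, 3.0).lysosome_ratio() >= 1.0

    def test_monotone_in_pka_up_to_plateau_in_neutral_regime(self):
        params = neutral_only_params()
        ratios = [
            CellModel(SpeciationProfile("monobase", pka_base1=pka), params, 3.0).lysosome_ratio()
            for pka in np.arange(3.0, 11.4, 0.5)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(ratios, ratios[1:]))


class TestKinetics:
    def test_initial_concentrations_are_zero(self):
        res = simulate_accumulation(
            SpeciationProfile("monobase", pka_base1=9.0), CellModelParams(), 3.0, 60.0
        )
        for name in ("cytosol", "lysosome", "mitochondrion"):
            assert res.concentrations[name][0] == 0.0
            assert (res.concentrations[name] >= -1e-9).all()

    def test_mass_conserved_in_closed_system(self):
        params = CellModelParams(closed_system=True)
        res = simulate_accumulation(
            SpeciationProfile("monobase", pka_base1=9.0), params, 3.0, 500.0
        )
        vols = {n: getattr(params, n).volume
                for n in ("external", "cytosol", "lysosome", "mitochondrion")}
        mass = sum(res.concentrations[n] * vols[n] for n in vols)
        assert np.ptp(mass) / mass[0] < 1e-6

    def test_output_invariant_to_tolerance_refinement(self):
        profile = SpeciationProfile("monobase", pka_base1=9.0)
        coarse = simulate_accumulation(profile, CellModelParams(), 3.0, 60.0, rtol=1e-6)
        fine = simulate_accumulation(profile, CellModelParams(), 3.0, 60.0, rtol=1e-10)
        ratio = fine.concentrations["lysosome"][-1] / coarse.concentrations["lysosome"][-1]
        assert ratio == pytest.approx(1.0, rel=1e-4)

    def test_moderate_monobase_fills_within_screening_window(self):
        t = required_incubation(
            SpeciationProfile("monobase", pka_base1=9.0), CellModelParams(), 3.0
        )
        assert t <= 30.0

    def test_extreme_lipophilicity_slows_accumulation(self):
        profile = SpeciationProfile("monobase", pka_base1=9.0)
        t3 = required_incubation(profile, CellModelParams(), 3.0)
        t8 = required_incubation(profile, CellModelParams(), 8.0, cap_min=1e6)
        assert t8 > t3

    def test_second_basic_centre_slows_accumulation(self):
        params = CellModelParams()
        t_bi = required_incubation(
            SpeciationProfile("bibase", pka_base1=10.0, pka_base2=9.0), params, 3.0
        )
        t_mono = required_incubation(
            SpeciationProfile("monobase", pka_base1=10.0), params, 3.0
        )
        assert t_bi >= t_mono

    def test_cap_exceeded_reported_as_infinite(self):
        t = required_incubation(
            SpeciationProfile("bibase", pka_base1=11.0, pka_base2=10.5),
            CellModelParams(), 8.0, cap_min=10.0,
        )
        assert math.isinf(t)

    def test_yaml_round_trip(self, tmp_path):
        params = CellModelParams.dmem()
        path = tmp_path / "preset.yaml"
        params.to_yaml(path)
        back = CellModelParams.from_yaml(path)
        assert back == params
        assert back.external.ph == 7.5
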