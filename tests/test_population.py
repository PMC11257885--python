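"""Virtual-population physiology: growth sampling, ontogeny, GFR, binding."""
import math

import numpy as np
import pytest

from dexpbpk.config import OntogenyParams
from dexpbpk.population import (
    DemographicSpec,
    bsa,
    cyp3a4_ontogeny,
    fu_pediatric,
    gfr_maturation,
    growth_table_median_weight,
    population_frame,
    sample_population,
)


@pytest.mark.parametrize(
    "weight,height,expected",
    [(36.0, 144.0, 1.2), (3.5, 50.0, math.sqrt(3.5 * 50 / 3600))],
)
def test_bsa_mosteller_closed_form(weight, height, expected):
    assert bsa(weight, height) == pytest.approx(expected, abs=1e-9)


def test_bsa_rejects_nonpositive_inputs():
    with pytest.raises(ValueError):
        bsa(0.0, 150.0)
    with pytest.raises(ValueError):
        bsa(10.0, -1.0)


class TestOntogeny:
    def test_adult_normalization(self, pop_config):
        # the asymptote is exactly 1; at 30 y the default sigmoid has
        # essentially converged
        assert cyp3a4_ontogeny(1e4, pop_config.ontogeny) == pytest.approx(1.0, abs=1e-6)
        assert cyp3a4_ontogeny(30.0, pop_config.ontogeny) == pytest.approx(1.0, abs=1e-2)

    def test_rises_steeply_over_first_year(self, pop_config):
        f = lambda a: cyp3a4_ontogeny(a, pop_config.ontogeny)
        assert f(1 / 365.25) < f(1.0)
        assert f(1 / 365.25) < 0.25 * f(1.0)

    def test_overshoot_gives_single_interior_maximum(self, pop_config):
        ages = np.linspace(0.0, 18.0, 2000)
        f = cyp3a4_ontogeny(ages, pop_config.ontogeny)
        i_peak = int(np.argmax(f))
        assert 0 < i_peak < len(ages) - 1
        assert 1.0 < ages[i_peak] < 6.0  # per-kg clearance peak region
        assert f[i_peak] > 1.0
        # monotone up to the peak, monotone down after
        assert np.all(np.diff(f[: i_peak + 1]) >= -1e-12)
        assert np.all(np.diff(f[i_peak:]) <= 1e-12)

    def test_zero_overshoot_is_monotone(self, pop_config):
        params = pop_config.ontogeny.model_copy(update={"overshoot_amplitude": 0.0})
        f = cyp3a4_ontogeny(np.linspace(0.0, 18.0, 500), params)
        assert np.all(np.diff(f) >= 0)
        assert np.all(f > 0)

    def test_pure_function(self, pop_config):
        assert cyp3a4_ontogeny(0.5, pop_config.ontogeny) == cyp3a4_ontogeny(
            0.5, pop_config.ontogeny
        )

    def test_negative_age_rejected(self, pop_config):
        with pytest.raises(ValueError):
            cyp3a4_ontogeny(-0.1, pop_config.ontogeny)


class TestGfr:
    def test_adult_asymptote(self, pop_config):
        assert gfr_maturation(30.0, 70.0, pop_config.gfr) == pytest.approx(
            pop_config.gfr.adult_gfr_ml_min, rel=0.01
        )

    def test_neonatal_size_normalized_fraction_below_adult(self, pop_config):
        neonate = gfr_maturation(0.0, 3.5, pop_config.gfr) / 3.5
        adult = gfr_maturation(30.0, 70.0, pop_config.gfr) / 70.0
        assert neonate < adult

    def test_monotone_in_age_at_fixed_weight(self, pop_config):
        ages = np.linspace(0.0, 18.0, 200)
        vals = [gfr_maturation(a, 20.0, pop_config.gfr) for a in ages]
        assert np.all(np.diff(vals) >= 0)


class TestFuPediatric:
    def test_identity_at_adult_protein_level(self):
        assert fu_pediatric(0.3, 1.0) == pytest.approx(0.3, abs=1e-12)

    def test_closed_form(self):
        assert fu_pediatric(0.5, 0.5) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_strictly_decreasing_in_albumin_ratio(self):
        ratios = np.linspace(0.3, 1.5, 50)
        vals = [fu_pediatric(0.3, r) for r in ratios]
        assert np.all(np.diff(vals) < 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fu_pediatric(0.0, 1.0)
        with pytest.raises(ValueError):
            fu_pediatric(0.3, 0.0)


class TestSampling:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            DemographicSpec(2.0, 6.0, 0)
        with pytest.raises(ValueError):
            DemographicSpec(6.0, 2.0, 10)
        with pytest.raises(ValueError):
            DemographicSpec(2.0, 6.0, 10, proportion_female=1.5)

    def test_seed_determinism(self, pop_config):
        a = sample_population(DemographicSpec(1.0, 2.0, 50, seed=123), pop_config)
        b = sample_population(DemographicSpec(1.0, 2.0, 50, seed=123), pop_config)
        assert [s.weight_kg for s in a] == [s.weight_kg for s in b]
        assert [s.cyp3a4_abundance_multiplier for s in a] == [
            s.cyp3a4_abundance_multiplier for s in b
        ]

    def test_median_weight_matches_growth_table(self, pop_config):
        subjects = sample_population(
            DemographicSpec(2.0, 6.0, 1000, seed=7), pop_config
        )
        med = float(np.median([s.weight_kg for s in subjects]))
        table = 0.5 * (
            growth_table_median_weight(pop_config, 4.0, "M")
            + growth_table_median_weight(pop_config, 4.0, "F")
        )
        assert med == pytest.approx(table, rel=0.05)

    def test_age_outside_growth_support_rejected(self, pop_config):
        with pytest.raises(ValueError):
            sample_population(DemographicSpec(17.0, 25.0, 5), pop_config)

    def test_physiology_internally_consistent(self, pop_config):
        subjects = sample_population(
            DemographicSpec(1e-9, 18.0, 200, seed=5), pop_config
        )
        for s in subjects:
            assert s.bsa_m2 == pytest.approx(bsa(s.weight_kg, s.height_cm), abs=1e-9)
            assert 0 < s.albumin_ratio <= 1.0
            flows = s.hepatic_blood_flow_L_h + s.renal_blood_flow_L_h
            assert flows < s.cardiac_output_L_h

    def test_export_frame(self, pop_config):
        subjects = sample_population(DemographicSpec(2.0, 6.0, 5, seed=1), pop_config)
        frame = population_frame(subjects)
        assert len(frame) == 5
        assert {"age_years", "weight_kg", "gfr_ml_min"} <= set(frame.columns)
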