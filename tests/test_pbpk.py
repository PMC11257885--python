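"""PBPK core: clearance scaling, ODE integration, linearity, caps."""
import numpy as np
import pytest

from dexpbpk.pbpk import (
    DoseEvent,
    Regimen,
    apply_caps,
    build_model,
    default_grid,
    hepatic_clearance,
    regimen_from_mg_per_kg,
    scale_clint,
    simulate_profile,
)

from conftest import make_subject


class TestHepaticClearance:
    def test_well_stirred_closed_form(self):
        assert hepatic_clearance(90.0, 0.3, 30.0) == pytest.approx(
            90 * 0.3 * 30 / (90 + 0.3 * 30), abs=1e-9
        )

    def test_zero_intrinsic_clearance(self):
        assert hepatic_clearance(90.0, 0.3, 0.0) == 0.0

    def test_bounded_by_hepatic_flow(self):
        prev = 0.0
        for clint in (1.0, 10.0, 100.0, 1e4, 1e8):
            cl = hepatic_clearance(90.0, 0.3, clint)
            assert prev < cl < 90.0
            prev = cl

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            hepatic_clearance(-1.0, 0.3, 30.0)


class TestScaleClint:
    def test_adult_normalization(self, compound):
        s = make_subject()
        c = compound.model_copy(update={"fm_cyp3a4": 1.0})
        expected = (
            c.clint_u_adult_ul_min_mg * s.mppgl_mg_g * s.liver_weight_g * 60e-6
        )
        assert scale_clint(s, c) == pytest.approx(expected, rel=1e-12)

    def test_independent_of_ontogeny_when_fm_zero(self, compound):
        c = compound.model_copy(update={"fm_cyp3a4": 0.0})
        lo = scale_clint(make_subject(cyp3a4_ontogeny_fraction=0.1), c)
        hi = scale_clint(make_subject(cyp3a4_ontogeny_fraction=1.6), c)
        assert lo == pytest.approx(hi, rel=1e-12)

    def test_ontogeny_halving_ratio(self, compound):
        c = compound.model_copy(update={"fm_cyp3a4": 0.85})
        half = scale_clint(make_subject(cyp3a4_ontogeny_fraction=0.5), c)
        full = scale_clint(make_subject(cyp3a4_ontogeny_fraction=1.0), c)
        assert half / full == pytest.approx(0.575, rel=1e-12)

    def test_clearance_monotone_in_ontogeny(self, compound):
        cls = [
            build_model(make_subject(cyp3a4_ontogeny_fraction=f), compound)
            .total_cl_plasma_L_h
            for f in (0.1, 0.5, 1.0, 1.5)
        ]
        assert np.all(np.diff(cls) > 0)


class TestModelConstruction:
    def test_flow_conservation(self, pop_config, compound, subject):
        model = build_model(subject, compound)
        co = subject.cardiac_output_L_h
        assert abs(sum(model.flows_L_h.values()) - co) < 1e-3 * co

    def test_no_elimination_flags_divergent_auc(self, compound):
        c = compound.model_copy(
            update={"clint_u_adult_ul_min_mg": 0.0, "renal_fraction": 0.0}
        )
        model = build_model(make_subject(), c)
        assert model.total_cl_plasma_L_h == 0.0
        assert model.auc_diverges
        prof = simulate_profile(
            model, Regimen((DoseEvent(0.0, 10.0, 0.1),)), default_grid(24.0)
        )
        assert prof.auc_diverges


def _one_compartment_setup(cl_L_h=5.0, v_L=50.0, flow_scale=1e6):
    """Collapse the model to one compartment: Kp=1, B:P=1, huge flows."""
    from dexpbpk.config import CompoundConfig

    s = make_subject(
        weight_kg=v_L,
        height_cm=160.0,
        liver_volume_L=1.5,
        kidney_volume_L=0.3,
        blood_volume_L=4.0,
        cardiac_output_L_h=300.0 * flow_scale,
        hepatic_blood_flow_L_h=75.0 * flow_scale,
        renal_blood_flow_L_h=57.0 * flow_scale,
        albumin_ratio=1.0,
    )
    # fm=0 makes CLint independent of ontogeny; pick CLint so that with
    # near-infinite flow CLh -> fu_b * CLint = cl_L_h
    clint = cl_L_h / 1.0  # fu = 1
    per_mg = clint / (s.mppgl_mg_g * s.liver_weight_g * 60e-6)
    c = CompoundConfig(
        molecular_weight=392.46,
        fu_adult=1.0,
        blood_plasma_ratio=1.0,
        clint_u_adult_ul_min_mg=per_mg,
        fm_cyp3a4=0.0,
        renal_fraction=0.0,
        kp_liver=1.0,
        kp_kidney=1.0,
        kp_rest=1.0,
    )
    return build_model(s, c)


class TestSimulation:
    def test_one_compartment_limit_matches_analytic_bolus(self):
        model = _one_compartment_setup(cl_L_h=5.0, v_L=50.0)
        reg = Regimen((DoseEvent(0.0, 10.0, 0.0),))  # true bolus
        grid = default_grid(48.0)
        prof = simulate_profile(model, reg, grid)
        t = prof.times_h
        analytic = (10.0 / 50.0) * np.exp(-0.1 * t)
        mask = t > 0.5  # allow instantaneous mixing across compartments
        rel = np.abs(prof.plasma_conc_mg_L[mask] - analytic[mask]) / analytic[mask]
        assert rel.max() < 1e-4

    def test_mass_balance(self, compound, subject):
        model = build_model(subject, compound)
        reg = regimen_from_mg_per_kg(0.5, 3, 6.0, subject, max_per_day_mg=None)
        prof = simulate_profile(model, reg, default_grid(48.0))
        assert prof.mass_balance_residual < 1e-6

    def test_dose_linearity_r2(self, compound, subject):
        model = build_model(subject, compound)
        doses = np.array([1.0, 2.0, 4.0])
        aucs = []
        for d in doses:
            reg = Regimen((DoseEvent(0.0, float(d), 0.1),))
            prof = simulate_profile(model, reg, default_grid(48.0))
            aucs.append(np.trapezoid(prof.plasma_conc_mg_L, prof.times_h))
        aucs = np.asarray(aucs)
        slope = (doses @ aucs) / (doses @ doses)
        ss_res = float(((aucs - slope * doses) ** 2).sum())
        ss_tot = float(((aucs - aucs.mean()) ** 2).sum())
        assert 1.0 - ss_res / ss_tot > 1.0 - 1e-9

    def test_superposition_of_shifted_single_doses(self, compound, subject):
        model = build_model(subject, compound)
        grid = default_grid(48.0)
        multi = simulate_profile(
            model,
            Regimen(tuple(DoseEvent(t, 5.0, 0.1) for t in (0.0, 6.0, 12.0))),
            grid,
        )
        total = np.zeros_like(grid)
        single = simulate_profile(
            model, Regimen((DoseEvent(0.0, 5.0, 0.1),)), grid
        )
        conc = np.interp(grid, single.times_h, single.plasma_conc_mg_L)
        for shift in (0.0, 6.0, 12.0):
            total += np.interp(
                grid - shift, grid, conc, left=0.0
            )
        multi_on_grid = np.interp(grid, multi.times_h, multi.plasma_conc_mg_L)
        rel = np.abs(multi_on_grid - total).max() / conc.max()
        assert rel < 1e-6

    def test_doubling_dose_doubles_concentrations(self, compound, subject):
        model = build_model(subject, compound)
        grid = default_grid(24.0)
        p1 = simulate_profile(model, Regimen((DoseEvent(0.0, 5.0, 0.1),)), grid)
        p2 = simulate_profile(model, Regimen((DoseEvent(0.0, 10.0, 0.1),)), grid)
        np.testing.assert_allclose(
            p2.plasma_conc_mg_L, 2.0 * p1.plasma_conc_mg_L, rtol=1e-9
        )

    def test_zero_doses_zero_profile(self, compound, subject):
        model = build_model(subject, compound)
        prof = simulate_profile(model, Regimen(()), default_grid(24.0))
        assert np.all(prof.plasma_conc_mg_L == 0.0)

    def test_expm_agrees_with_stiff_integrator(self, compound, subject):
        model = build_model(subject, compound)
        reg = regimen_from_mg_per_kg(0.5, 3, 6.0, subject, max_per_day_mg=None)
        grid = default_grid(48.0, 0.5)
        a = simulate_profile(model, reg, grid, backend="expm")
        b = simulate_profile(model, reg, grid, backend="ivp")
        scale = a.plasma_conc_mg_L.max()
        assert np.abs(a.plasma_conc_mg_L - b.plasma_conc_mg_L).max() / scale < 1e-6


class TestCaps:
    def test_no_cap_when_under_limit(self):
        reg = apply_caps(0.5, 3, 6.0, 10.0, max_per_day_mg=40.0)
        assert [e.amount_mg for e in reg.dose_events] == [5.0, 5.0, 5.0]
        assert not reg.capped

    def test_daily_cap_scales_window_proportionally(self):
        reg = apply_caps(0.5, 3, 6.0, 90.0, max_per_day_mg=40.0)
        amounts = [e.amount_mg for e in reg.dose_events]
        assert reg.capped
        assert sum(amounts) == pytest.approx(40.0, abs=1e-9)
        # proportional: equal doses stay equal
        assert amounts[0] == pytest.approx(amounts[1]) == pytest.approx(amounts[2])

    def test_rolling_window_spanning_more_than_a_day(self):
        # q12h x 4 at 15 mg: windows [0,24) and [12,36) and [24,48) hold
        # two doses each, so no window may exceed 25 mg
        reg = apply_caps(15.0, 4, 12.0, 1.0, max_per_day_mg=25.0)
        starts = [e.start_h for e in reg.dose_events]
        amounts = np.array([e.amount_mg for e in reg.dose_events])
        for i, t0 in enumerate(starts):
            window = [
                j for j, t in enumerate(starts) if t0 <= t < t0 + 24.0
            ]
            assert amounts[window].sum() <= 25.0 + 1e-9

    def test_cap_disabled_is_identity(self):
        reg = apply_caps(0.5, 3, 6.0, 90.0, max_per_day_mg=None)
        assert [e.amount_mg for e in reg.dose_events] == [45.0, 45.0, 45.0]
        assert not reg.capped

    def test_per_dose_cap(self):
        reg = apply_caps(0.5, 3, 6.0, 30.0, max_per_dose_mg=10.0, max_per_day_mg=40.0)
        assert [e.amount_mg for e in reg.dose_events] == [10.0, 10.0, 10.0]
        assert reg.capped
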