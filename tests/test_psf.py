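"""Elementary and systemic psfs, hyperbolic fitting, transmission strength,
and elementary-parameter adjustment."""

import numpy as np
import pytest

import psfkit as pk
from psfkit.fixtures import binding_equilibrium_complex, covalent_cycle_steady_state
from psfkit.model import RateConstants, build_scheme
from psfkit.psf import HyperbolicFit, LinearFit
from conftest import TIGHT


class TestElementaryBindingPsf:
    def test_matches_quadratic_closed_form(self):
        grid = pk.make_grid(10.0, 2000.0, 8)
        curve = pk.elementary_binding_psf(grid, b_total=100.0, kon=0.01,
                                          koff=1.0, criterion=TIGHT)
        kd = 1.0 / 0.01
        oracle = np.array(
            [binding_equilibrium_complex(a, 100.0, kd) for a in grid])
        assert np.allclose(curve.values, oracle, rtol=1e-6)

    def test_saturates_at_partner_total_and_is_monotone(self):
        grid = pk.make_grid(100.0, 1e6, 8)
        curve = pk.elementary_binding_psf(grid, b_total=50.0, kon=0.01, koff=1.0)
        assert np.all(np.diff(curve.values) >= -1e-9)
        assert curve.values[-1] == pytest.approx(50.0, rel=1e-2)

    def test_requires_positive_koff(self):
        with pytest.raises(ValueError):
            pk.elementary_binding_psf([1, 2, 3], 10.0, kon=1.0, koff=0.0)


class TestElementaryEnzymaticPsf:
    FWD = RateConstants(kon=0.01, koff=1.0, kcat=0.5)
    REV = RateConstants(kon=0.01, koff=1.0, kcat=0.5)

    def test_no_catalysis_means_no_product(self):
        curve = pk.elementary_enzymatic_psf(
            [10.0, 50.0, 200.0], substrate_total=500.0,
            forward_rates=RateConstants(kon=0.01, koff=1.0, kcat=0.0),
            reverse_rates=self.REV, criterion=TIGHT)
        assert np.allclose(curve.values, 0.0, atol=1e-8)

    def test_overwhelming_forward_capacity_converts_everything(self):
        curve = pk.elementary_enzymatic_psf(
            [1e5], substrate_total=500.0,
            forward_rates=RateConstants(kon=0.1, koff=0.1, kcat=5.0),
            reverse_rates=RateConstants(kon=1e-4, koff=1.0, kcat=1e-3),
            phosphatase_total=1.0)
        assert curve.values[-1] == pytest.approx(500.0, rel=1e-2)

    def test_missing_reverse_arm_rejected(self):
        with pytest.raises(ValueError, match="reverse"):
            pk.elementary_enzymatic_psf(
                [10.0], 100.0, forward_rates=self.FWD,
                reverse_rates=RateConstants(kon=0.01, koff=1.0, kcat=0.0))

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_flux_balance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        fwd = RateConstants(kon=float(rng.uniform(1e-3, 0.05)),
                            koff=float(rng.uniform(0.2, 3.0)),
                            kcat=float(rng.uniform(0.1, 1.0)))
        rev = RateConstants(kon=float(rng.uniform(1e-3, 0.05)),
                            koff=float(rng.uniform(0.2, 3.0)),
                            kcat=float(rng.uniform(0.1, 1.0)))
        st, pt = float(rng.uniform(300, 1500)), float(rng.uniform(30, 150))
        e_grid = [float(rng.uniform(10, 300))]
        curve = pk.elementary_enzymatic_psf(
            e_grid, st, fwd, rev, phosphatase_total=pt, criterion=TIGHT)
        oracle = covalent_cycle_steady_state(
            st, e_grid[0], pt, fwd.kon, fwd.koff, fwd.kcat,
            rev.kon, rev.koff, rev.kcat)
        assert curve.values[0] == pytest.approx(oracle["Sp"], rel=1e-6)


class TestFitPsf:
    def test_noiseless_recovery_to_a_tenth_of_percent(self):
        x = pk.make_grid(10.0, 10000.0, 20)
        truth = dict(Y=100.0, C=500.0, n=1.0, y0=0.0)
        y = truth["y0"] + truth["Y"] * x / (truth["C"] + x)
        fit = pk.fit_psf(pk.PsfCurve("A", "B", x, y))
        assert isinstance(fit, HyperbolicFit)
        assert fit.Y == pytest.approx(100.0, rel=1e-3)
        assert fit.C == pytest.approx(500.0, rel=1e-3)
        assert fit.n == pytest.approx(1.0, rel=1e-3)
        assert abs(fit.y0) < 0.1

    def test_steep_curve_recovery(self):
        x = pk.make_grid(50.0, 5000.0, 20)
        y = 10.0 + 80.0 * x ** 2.5 / (700.0 ** 2.5 + x ** 2.5)
        fit = pk.fit_psf(pk.PsfCurve("A", "B", x, y))
        assert isinstance(fit, HyperbolicFit)
        assert fit.n == pytest.approx(2.5, rel=1e-3)
        assert fit.C == pytest.approx(700.0, rel=1e-3)

    def test_noisy_recovery_within_estimator_noise(self):
        rng = np.random.default_rng(42)
        x = pk.make_grid(10.0, 10000.0, 20)
        y = 100.0 * x / (500.0 + x) * (1 + 0.01 * rng.standard_normal(len(x)))
        fit = pk.fit_psf(pk.PsfCurve("A", "B", x, y))
        assert isinstance(fit, HyperbolicFit)
        assert fit.Y == pytest.approx(100.0, rel=0.05)
        assert fit.C == pytest.approx(500.0, rel=0.05)

    def test_linear_data_selects_linear_fit(self):
        x = pk.make_grid(10.0, 1000.0, 10)
        y = 0.05 * x + 3.0
        fit = pk.fit_psf(pk.PsfCurve("A", "B", x, y))
        assert isinstance(fit, LinearFit)
        assert fit.slope_ == pytest.approx(0.05)

    def test_decreasing_curve_gets_negative_amplitude(self):
        x = pk.make_grid(10.0, 10000.0, 15)
        y = 200.0 - 150.0 * x / (300.0 + x)
        fit = pk.fit_psf(pk.PsfCurve("A", "B", x, y))
        assert isinstance(fit, HyperbolicFit)
        assert fit.Y < 0
        assert fit.Y == pytest.approx(-150.0, rel=1e-3)

    def test_constant_curve_yields_flat_fit(self):
        x = pk.make_grid(1.0, 100.0, 5)
        fit = pk.fit_psf(pk.PsfCurve("A", "B", x, np.full(5, 7.0)))
        assert isinstance(fit, LinearFit)
        assert fit.slope_ == 0.0 and fit.intercept == 7.0

    def test_selection_never_worse_than_both_candidates(self):
        rng = np.random.default_rng(7)
        x = pk.make_grid(5.0, 5000.0, 12)
        for _ in range(5):
            y = np.abs(rng.uniform(1, 100) * x / (rng.uniform(10, 2000) + x)
                       + rng.normal(0, 1, len(x)))
            curve = pk.PsfCurve("A", "B", x, y)
            fit = pk.fit_psf(curve)
            slope, intercept = np.polyfit(x, y, 1)
            lin_sse = float(np.sum((y - slope * x - intercept) ** 2))
            assert fit.sse <= lin_sse + 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pk.fit_psf(pk.PsfCurve("A", "B", [1, 2, 3], [1, 2, 3]))


class TestTransmissionStrength:
    HYP = HyperbolicFit(Y=100.0, C=500.0, n=1.0, y0=0.0, sse=0.0)

    def test_halfway_point_gain_is_one_third(self):
        out = pk.transmission_strength(self.HYP, 500.0, factor=2.0)
        assert out["relative_gain"] == pytest.approx(1.0 / 3.0)

    def test_near_saturation_gain_is_one_thirtyninth(self):
        out = pk.transmission_strength(self.HYP, 19 * 500.0, factor=2.0)
        assert out["relative_gain"] == pytest.approx(1.0 / 39.0)

    def test_low_end_slope_is_Y_over_C(self):
        out = pk.transmission_strength(self.HYP, 0.0)
        assert out["slope"] == pytest.approx(100.0 / 500.0)

    def test_gain_decreases_with_input(self):
        xs = np.geomspace(1.0, 1e5, 30)
        gains = [pk.transmission_strength(self.HYP, float(x))["relative_gain"]
                 for x in xs]
        assert np.all(np.diff(gains) < 0)

    def test_zero_output_gain_is_undefined(self):
        out = pk.transmission_strength(self.HYP, 0.0, factor=2.0)
        assert out["relative_gain"] is None
        assert out["slope"] == pytest.approx(100.0 / 500.0)


class TestSystemicPsf:
    def test_single_scheme_system_equals_elementary_curve(self):
        grid = pk.make_grid(20.0, 2000.0, 6)
        system = pk.make_fixture("toy_binding",
                                 {"b_total": 100.0, "kon": 0.01, "koff": 1.0})
        curves = pk.systemic_psf(system, "A", (20.0, 2000.0), n=6,
                                 criterion=TIGHT)
        elem = pk.elementary_binding_psf(grid, 100.0, 0.01, 1.0, criterion=TIGHT)
        assert np.allclose(curves["AB"].values, elem.values, rtol=1e-6)

    def test_requires_declared_input(self, toy_binding_system):
        with pytest.raises(ValueError, match="not declared as an input"):
            pk.systemic_psf(toy_binding_system, "B", (1.0, 10.0), n=4)

    def test_values_bounded_by_moiety_totals(self, striatal, da_sweep):
        for name in ("DaD1R", "pThr34", "PKAc", "AC5GoaGTP", "cAMP"):
            curve = da_sweep[name]
            m = striatal.moiety_containing(name)
            assert m is not None
            total = m.total(striatal.with_initial(
                {"Ca": 8000.0}).initial_concentrations())
            assert curve.values.max() <= total * (1 + 1e-6)


class TestPsfMatrix:
    def _two_pathway_system(self):
        """Two disjoint binding reactions driven by separate inputs."""
        schemes = [
            build_scheme("binding", {"a": "A1", "b": "B1", "complex": "C1"},
                         {"kon": 0.01, "koff": 1.0}, scheme_id=1),
            build_scheme("binding", {"a": "A2", "b": "B2", "complex": "C2"},
                         {"kon": 0.01, "koff": 1.0}, scheme_id=2),
        ]
        species = [
            pk.SpeciesDecl("A1", 100.0, is_input=True),
            pk.SpeciesDecl("B1", 100.0),
            pk.SpeciesDecl("C1", 0.0),
            pk.SpeciesDecl("A2", 100.0, is_input=True),
            pk.SpeciesDecl("B2", 100.0),
            pk.SpeciesDecl("C2", 0.0),
        ]
        return pk.ReactionSystem(species, schemes)

    def test_disjoint_subsystems_depend_on_one_axis_each(self):
        system = self._two_pathway_system()
        grids = (pk.make_grid(10, 1000, 4), pk.make_grid(10, 1000, 4))
        mats = pk.psf_matrices(system, ("A1", "A2"), grids, ["C1", "C2"])
        s1 = mats["C1"].dependence_shares()
        s2 = mats["C2"].dependence_shares()
        assert s1["A1"] > 0.99 and s1["A2"] < 1e-6
        assert s2["A2"] > 0.99 and s2["A1"] < 1e-6

    def test_identical_inputs_rejected(self, striatal):
        with pytest.raises(ValueError):
            pk.psf_matrix(striatal, ("Da", "Da"), ([1, 2], [1, 2]), "cAMP")


class TestAdjustElementary:
    GRID = pk.make_grid(20.0, 2000.0, 5)

    def test_fixed_point_leaves_parameters_unchanged(self):
        system = pk.make_fixture("toy_binding",
                                 {"b_total": 100.0, "kon": 0.01, "koff": 1.0})
        target = pk.systemic_psf(system, "A", (20.0, 2000.0), n=5)["AB"]
        res = pk.adjust_elementary_to_match(
            system, 1, target, ["kon", "koff"], "A", "AB", self.GRID,
            tolerance=1e-3, maxiter=40)
        assert res.converged
        assert res.rates.kon == pytest.approx(0.01, rel=0.02)
        assert res.rates.koff == pytest.approx(1.0, rel=0.02)

    def test_recovers_perturbed_affinity(self):
        system = pk.make_fixture("toy_binding",
                                 {"b_total": 100.0, "kon": 0.01, "koff": 1.0})
        target = pk.systemic_psf(system, "A", (20.0, 2000.0), n=5)["AB"]
        perturbed = system.with_scheme_rates(
            1, RateConstants(kon=0.02, koff=0.5))
        res = pk.adjust_elementary_to_match(
            perturbed, 1, target, ["kon", "koff"], "A", "AB", self.GRID,
            tolerance=5e-3, maxiter=120)
        # the psf identifies the affinity (koff/kon ratio) to within 5%
        assert res.converged
        assert res.rates.koff / res.rates.kon == pytest.approx(100.0, rel=0.05)
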