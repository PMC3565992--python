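"""Reaction-system construction, expansion, and the built-in striatal model."""

import numpy as np
import pytest

import psfkit as pk
from psfkit.model import RateConstants, SchemeKind, build_scheme, mass_action_rates
from psfkit.steady import moiety_drift


@pytest.mark.parametrize("kind,participants,rates,n_steps", [
    ("binding", {"a": "Da", "b": "D1R", "complex": "DaD1R"},
     {"kon": 0.00111, "koff": 10}, 2),
    ("irreversible_binding", {"a": "GoaGDP", "b": "Gbc", "complex": "Gabc"},
     {"kon": 100}, 1),
    ("enzymatic", {"substrate": "ATP", "enzyme": "AC5GoaGTP",
                   "complex": "AC5GoaGTP_ATP", "products": ("cAMP", "AC5GoaGTP")},
     {"kon": 0.000128, "koff": 0.261, "kcat": 28.46}, 3),
    ("conversion", {"a": "GoaGTP", "b": "GoaGDP"}, {"kcat": 10}, 1),
    ("decomposition", {"complex": "DaD1RGabc",
                       "products": ("DaD1R", "GoaGTP", "Gbc")}, {"kcat": 20}, 1),
])
def test_scheme_expansion_sizes_and_balance(kind, participants, rates, n_steps):
    scheme = build_scheme(kind, participants, rates, scheme_id=1)
    steps = scheme.expand()
    assert len(steps) == n_steps
    # every declared species appears in the expansion
    seen = {n for st in steps for n, _ in (*st.reactants, *st.products)}
    assert seen == scheme.species_names()


def test_binding_scheme_rate_constants_propagate():
    scheme = build_scheme("binding", {"a": "A", "b": "B", "complex": "AB"},
                          {"kon": 0.5, "koff": 2.0})
    fwd, rev = scheme.expand()
    assert fwd.rate_constant == 0.5 and rev.rate_constant == 2.0
    assert fwd.reactants == (("A", 1), ("B", 1)) and fwd.products == (("AB", 1),)
    assert rev.reactants == (("AB", 1),)


@pytest.mark.parametrize("bad", [
    # missing required rate for the kind
    lambda: build_scheme("binding", {"a": "A", "b": "B", "complex": "AB"},
                         {"kon": 1.0}),
    # unknown role
    lambda: build_scheme("conversion", {"a": "A", "b": "B", "enzyme": "E"},
                         {"kcat": 1.0}),
    # negative rate
    lambda: build_scheme("conversion", {"a": "A", "b": "B"}, {"kcat": -1.0}),
])
def test_build_scheme_rejects_invalid(bad):
    with pytest.raises(ValueError):
        bad()


def test_expand_system_empty_and_order():
    assert pk.expand_system([]) == []
    s1 = build_scheme("binding", {"a": "A", "b": "B", "complex": "AB"},
                      {"kon": 1, "koff": 1}, scheme_id=1)
    s2 = build_scheme("conversion", {"a": "AB", "b": "C"}, {"kcat": 1}, scheme_id=2)
    labels = [st.label for st in pk.expand_system([s1, s2])]
    assert labels == ["1:forward", "1:reverse", "2:forward"]


def test_mass_action_rates_simple_product():
    step = build_scheme("irreversible_binding",
                        {"a": "Da", "b": "D1R", "complex": "DaD1R"},
                        {"kon": 0.00111}).expand()
    rates = mass_action_rates(step, {"Da": 5000.0, "D1R": 500.0, "DaD1R": 0.0})
    assert rates["DaD1R"] == pytest.approx(0.00111 * 5000 * 500)  # 2775 nM/s
    assert rates["Da"] == pytest.approx(-2775.0)
    # zero-concentration reactant stalls the step
    rates0 = mass_action_rates(step, {"Da": 0.0, "D1R": 500.0, "DaD1R": 0.0})
    assert rates0["DaD1R"] == 0.0


def test_mass_action_rates_fourth_order_step(striatal):
    # PP2A + 4 Ca association: rate = k [PP2A] [Ca]^4
    scheme = striatal.scheme(38)
    fwd = scheme.expand()[0]
    assert fwd.order == 5
    conc = {"PP2A": 2000.0, "Ca": 10.0, "PP2Ac": 0.0}
    rates = mass_action_rates([fwd], conc)
    assert rates["PP2Ac"] == pytest.approx(7.72e-12 * 2000.0 * 10.0 ** 4)
    assert rates["Ca"] == pytest.approx(-4 * rates["PP2Ac"])


def test_mass_action_rates_rejects_unknown_species():
    step = build_scheme("conversion", {"a": "A", "b": "B"}, {"kcat": 1}).expand()
    with pytest.raises(KeyError):
        mass_action_rates(step, {"A": 1.0})


class TestWeakReversibility:
    def test_builtin_passes(self, striatal):
        assert pk.check_weak_reversibility(striatal).passed

    def test_reversible_binding_passes_irreversible_fails(self):
        rev = pk.make_fixture("toy_binding")
        assert pk.check_weak_reversibility(rev).passed
        irr = pk.ReactionSystem(
            [pk.SpeciesDecl("A", 1.0), pk.SpeciesDecl("B", 1.0),
             pk.SpeciesDecl("AB", 0.0)],
            [build_scheme("irreversible_binding",
                          {"a": "A", "b": "B", "complex": "AB"}, {"kon": 1.0})],
        )
        rep = pk.check_weak_reversibility(irr)
        assert not rep.passed
        assert any("AB" in f for f in rep.failures())

    def test_removing_nucleotide_regeneration_breaks_it(self, striatal):
        # without the AMP -> ATP closing step, AMP is never consumed
        schemes = [s for s in striatal.schemes if s.id != 40]
        broken = pk.ReactionSystem(striatal.species, schemes, striatal.moieties)
        rep = pk.check_weak_reversibility(broken)
        assert not rep.passed
        assert not rep.consumed["AMP"]


class TestBuiltinModel:
    def test_counts(self, striatal):
        assert len(striatal.schemes) == 40
        # 21 bindings x2 + 12 enzymatic x3 + 5 conversions + 1 decomposition
        # + 1 irreversible binding
        kinds = [s.kind for s in striatal.schemes]
        expected = (2 * kinds.count(SchemeKind.BINDING)
                    + 3 * kinds.count(SchemeKind.ENZYMATIC)
                    + kinds.count(SchemeKind.CONVERSION)
                    + kinds.count(SchemeKind.DECOMPOSITION)
                    + kinds.count(SchemeKind.IRREVERSIBLE_BINDING))
        assert len(striatal.steps) == expected == 85

    def test_initial_totals(self, striatal):
        init = striatal.initial_concentrations()
        assert init["D1R"] == 500.0
        assert init["DARPP32"] == 50000.0
        assert init["ATP"] == 2e6
        assert init["CaM"] == 10000.0
        assert init["DaD1R"] == 0.0

    def test_inputs(self, striatal):
        assert set(striatal.inputs) == {"Da", "Ca"}

    def test_spot_rate_constants(self, striatal):
        assert striatal.scheme(1).rates == RateConstants(kon=0.00111, koff=10)
        assert striatal.scheme(9).rates == RateConstants(
            kon=0.000128, koff=0.261, kcat=28.46)
        assert striatal.scheme(38).rates.kon == 7.72e-12
        assert striatal.scheme(38).stoich.get("b") == 4
        assert striatal.scheme(31).kind is SchemeKind.CONVERSION

    def test_moiety_conservation_along_trajectory(self, striatal):
        traj = pk.integrate(striatal.with_initial({"Da": 500.0}),
                            striatal.with_initial({"Da": 500.0}).initial_concentrations(),
                            duration=300.0,
                            t_eval=np.linspace(0, 300, 31))
        drift = moiety_drift(striatal, traj)
        assert max(drift.values()) < 1e-6
        # D1R moiety total stays at the declared 500 nM
        d1r = striatal.moiety("D1R")
        totals = [d1r.total(traj.state_at(i)) for i in range(len(traj.times))]
        assert np.allclose(totals, 500.0, rtol=1e-9)


class TestFixtures:
    def test_toy_binding_closed_form_special_point(self):
        # At = Bt = Kd gives [AB] = Kd (3 - sqrt 5)/2
        from psfkit.fixtures import binding_equilibrium_complex
        kd = 100.0
        ab = binding_equilibrium_complex(kd, kd, kd)
        assert ab == pytest.approx(kd * (3 - np.sqrt(5)) / 2)

    def test_random_fixture_deterministic_and_reversible(self):
        a = pk.make_fixture("random_weakly_reversible", seed=7)
        b = pk.make_fixture("random_weakly_reversible", seed=7)
        from psfkit.io import systems_equal
        assert systems_equal(a, b)
        for seed in (1, 7, 23):
            sys_r = pk.make_fixture("random_weakly_reversible", seed=seed)
            assert pk.check_weak_reversibility(sys_r).passed

    def test_random_fixture_requires_seed(self):
        with pytest.raises(ValueError):
            pk.make_fixture("random_weakly_reversible")

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            pk.make_fixture("toy_binding", {"a_total": -1.0})
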