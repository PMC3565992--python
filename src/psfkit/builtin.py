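"""Built-in striatal dopamine/calcium signaling model.

A 40-scheme mass-action model of DARPP-32 regulation in striatal medium spiny
neurons: dopamine binds the D1 receptor, activates Golf/AC5/cAMP/PKA, while
calcium acts through calmodulin on PP2B (calcineurin), CaMKII and PDE1; both
pathways converge on the phosphorylation state of DARPP-32 (Thr34 / Thr75).
Inputs are extracellular dopamine (Da) and calcium (Ca).

The protein phosphatase-1 branch of the original published model is not
included (its release reaction dissolves a ternary complex in one step, which
falls outside the two reaction shapes used here); an AMP -> ATP regeneration
step closes the adenine-nucleotide loop so that every species is both produced
and consumed.

Naming: species identifiers are opaque strings; a name like ``Ca2CaM`` binds
*one* Ca per elementary binding event as written in the scheme list, except
where an explicit stoichiometry is given (four Ca in the PP2A–Ca association).
"""

from __future__ import annotations

from .model import (
    Moiety,
    RateConstants,
    ReactionScheme,
    ReactionSystem,
    SchemeKind,
    SpeciesDecl,
    build_scheme,
)

__all__ = ["builtin_striatal_model", "INITIAL_TOTALS", "TABLE5_SPECIES"]

# Initial total concentrations, nM.  PP1 belongs to the excluded branch and is
# listed for completeness of the published totals but not declared as a species.
INITIAL_TOTALS: dict[str, float] = {
    "D1R": 500.0,
    "Gabc": 3000.0,
    "AC5": 2500.0,
    "ATP": 2e6,
    "CaMKII": 20000.0,
    "DARPP32": 50000.0,
    "PP2A": 2000.0,
    "PP2B": 4000.0,
    "PDE1": 4000.0,
    "PDE4": 2000.0,
    "PKA": 1200.0,
    "CaM": 10000.0,
    "Cdk5": 1800.0,
    "Ca": 1000.0,
    "Da": 5000.0,
}

_PP1_TOTAL_UNUSED = 5000.0  # published total for the excluded PP1 branch

# Species whose step-response delays are tabulated in the delay analysis.
TABLE5_SPECIES = (
    "DaD1R", "AC5GoaGTP", "AC5CaGoaGTP", "cAMP", "PKAc",
    "pThr34", "PP2Ap", "PP2Ac", "pThr75",
)


def _binding(i, a, b, cx, kon, koff, stoich=None):
    return build_scheme(
        SchemeKind.BINDING, {"a": a, "b": b, "complex": cx},
        RateConstants(kon=kon, koff=koff), scheme_id=i, stoich=stoich,
    )


def _irr_binding(i, a, b, cx, kon):
    return build_scheme(
        SchemeKind.IRREVERSIBLE_BINDING, {"a": a, "b": b, "complex": cx},
        RateConstants(kon=kon), scheme_id=i,
    )


def _enzymatic(i, s, e, cx, products, kon, koff, kcat):
    return build_scheme(
        SchemeKind.ENZYMATIC,
        {"substrate": s, "enzyme": e, "complex": cx, "products": tuple(products)},
        RateConstants(kon=kon, koff=koff, kcat=kcat), scheme_id=i,
    )


def _conversion(i, a, b, kcat):
    return build_scheme(
        SchemeKind.CONVERSION, {"a": a, "b": b}, RateConstants(kcat=kcat),
        scheme_id=i,
    )


def _decomposition(i, cx, products, kcat):
    return build_scheme(
        SchemeKind.DECOMPOSITION, {"complex": cx, "products": tuple(products)},
        RateConstants(kcat=kcat), scheme_id=i,
    )


def _schemes() -> list[ReactionScheme]:
    return [
        # --- cAMP pathway: receptor, G protein, adenylyl cyclase, PKA -------
        _binding(1, "Da", "D1R", "DaD1R", 0.00111, 10),
        _binding(2, "DaD1R", "Gabc", "DaD1RGabc", 0.0006, 0.001),
        _binding(3, "Gabc", "D1R", "GabcD1R", 6e-5, 0.0003),
        _binding(4, "GabcD1R", "Da", "DaD1RGabc", 0.00333, 10),
        _decomposition(5, "DaD1RGabc", ("DaD1R", "GoaGTP", "Gbc"), 20),
        _conversion(6, "GoaGTP", "GoaGDP", 10),
        _irr_binding(7, "GoaGDP", "Gbc", "Gabc", 100),
        _binding(8, "GoaGTP", "AC5", "AC5GoaGTP", 0.0385, 50),
        _enzymatic(9, "ATP", "AC5GoaGTP", "AC5GoaGTP_ATP",
                   ("cAMP", "AC5GoaGTP"), 0.000128, 0.261, 28.46),
        _binding(10, "AC5", "Ca", "AC5Ca", 0.001, 0.9),
        _binding(11, "AC5Ca", "GoaGTP", "AC5CaGoaGTP", 0.0192, 25),
        _enzymatic(12, "ATP", "AC5CaGoaGTP", "AC5CaGoaGTP_ATP",
                   ("cAMP", "AC5CaGoaGTP"), 6e-5, 0.131, 14.23),
        _binding(13, "PDE1", "Ca4CaM", "PDE1CaM", 0.1, 1),
        _enzymatic(14, "cAMP", "PDE1CaM", "PDE1CaM_cAMP",
                   ("AMP", "PDE1CaM"), 0.0046, 44, 11),
        _enzymatic(15, "cAMP", "PDE4", "PDE4_cAMP",
                   ("AMP", "PDE4"), 0.02, 72, 18),
        _binding(16, "PKA", "cAMP", "PKAcAMP2", 2.6e-5, 0.006),
        _binding(17, "PKAcAMP2", "cAMP", "PKAcAMP4", 3.46e-5, 0.06),
        _binding(18, "PKAr", "PKAc", "PKAcAMP4", 0.00102, 0.0048),
        # --- Ca pathway: calmodulin, calcineurin, CaMKII --------------------
        _binding(19, "Ca4CaM", "PP2B", "PP2BCa4CaM", 1, 0.3),
        _binding(20, "PP2BCa2CaM", "Ca", "PP2BCa4CaM", 0.1, 10),
        _binding(21, "CaM", "PP2B", "PP2BCaM", 1, 3),
        _binding(22, "Ca2CaM", "PP2B", "PP2BCa2CaM", 1, 0.3),
        _binding(23, "PP2BCaM", "Ca", "PP2BCa2CaM", 0.006, 0.91),
        _binding(24, "CaM", "Ca", "Ca2CaM", 0.006, 9.1),
        _binding(25, "Ca2CaM", "Ca", "Ca4CaM", 0.1, 1000),
        _binding(26, "Ca4CaM", "CaMKII", "CaMKIICa4CaM", 0.00075, 0.1),
        _conversion(27, "CaMKIICa4CaM", "CaMKIIpCa4CaM", 0.005),
        _conversion(28, "CaMKIIpCa4CaM", "CaMKIICa4CaM", 0.015),
        # --- DARPP-32 phosphorylation cycles --------------------------------
        _enzymatic(29, "DARPP32", "PKAc", "DARPP32PKAc",
                   ("pThr34", "PKAc"), 0.0027, 8, 2),
        _enzymatic(30, "PP2A", "PKAc", "PKAcPP2A",
                   ("PP2Ap", "PKAc"), 0.0025, 0.3, 0.1),
        # written as an unassisted decay of the phosphorylated form; the only
        # mass-conserving reading of the published row
        _conversion(31, "PP2Ap", "PP2A", 0.004),
        _enzymatic(32, "pThr34", "PP2BCa4CaM", "pThr34PP2B",
                   ("DARPP32", "PP2BCa4CaM"), 0.001, 2, 0.5),
        _enzymatic(33, "pThr34", "PP2A", "pThr34PP2A",
                   ("DARPP32", "PP2A"), 0.0001, 2, 0.5),
        _enzymatic(34, "DARPP32", "Cdk5", "DARPP32Cdk5",
                   ("pThr75", "Cdk5"), 0.00045, 2, 0.5),
        _binding(35, "pThr75", "PKAc", "pThr75PKAc", 0.00037, 1),
        _enzymatic(36, "pThr75", "PP2Ap", "pThr75PP2Ap",
                   ("DARPP32", "PP2Ap"), 0.0004, 12, 3),
        _enzymatic(37, "pThr75", "PP2A", "pThr75PP2A",
                   ("DARPP32", "PP2A"), 0.0001, 6.4, 1.6),
        _binding(38, "PP2A", "Ca", "PP2Ac", 7.72e-12, 0.01, stoich={"b": 4}),
        _enzymatic(39, "pThr75", "PP2Ac", "pThr75PP2Ac",
                   ("DARPP32", "PP2Ac"), 0.0004, 12, 3),
        _conversion(40, "AMP", "ATP", 10),
    ]


def _moieties() -> list[Moiety]:
    def m(name, *members):
        return Moiety(name, tuple(
            (x, 1) if isinstance(x, str) else x for x in members))

    return [
        m("D1R", "D1R", "DaD1R", "GabcD1R", "DaD1RGabc"),
        m("Da", "Da", "DaD1R", "DaD1RGabc"),
        m("Galpha", "Gabc", "GabcD1R", "DaD1RGabc", "GoaGTP", "GoaGDP",
          "AC5GoaGTP", "AC5GoaGTP_ATP", "AC5CaGoaGTP", "AC5CaGoaGTP_ATP"),
        m("Gbetagamma", "Gabc", "GabcD1R", "DaD1RGabc", "Gbc"),
        m("AC5", "AC5", "AC5GoaGTP", "AC5GoaGTP_ATP", "AC5Ca",
          "AC5CaGoaGTP", "AC5CaGoaGTP_ATP"),
        m("PDE1", "PDE1", "PDE1CaM", "PDE1CaM_cAMP"),
        m("PDE4", "PDE4", "PDE4_cAMP"),
        # regulatory and catalytic halves of the PKA holoenzyme pool
        m("PKA_regulatory", "PKA", "PKAcAMP2", "PKAcAMP4", "PKAr"),
        m("PKA_catalytic", "PKA", "PKAcAMP2", "PKAcAMP4", "PKAc",
          "DARPP32PKAc", "PKAcPP2A", "pThr75PKAc"),
        m("CaM", "CaM", "Ca2CaM", "Ca4CaM", "PDE1CaM", "PDE1CaM_cAMP",
          "PP2BCaM", "PP2BCa2CaM", "PP2BCa4CaM", "CaMKIICa4CaM",
          "CaMKIIpCa4CaM", "pThr34PP2B"),
        m("CaMKII", "CaMKII", "CaMKIICa4CaM", "CaMKIIpCa4CaM"),
        m("PP2B", "PP2B", "PP2BCaM", "PP2BCa2CaM", "PP2BCa4CaM", "pThr34PP2B"),
        m("PP2A", "PP2A", "PKAcPP2A", "PP2Ap", "pThr34PP2A", "pThr75PP2Ap",
          "pThr75PP2A", "PP2Ac", "pThr75PP2Ac"),
        m("DARPP32", "DARPP32", "DARPP32PKAc", "pThr34", "pThr34PP2B",
          "pThr34PP2A", "DARPP32Cdk5", "pThr75", "pThr75PKAc",
          "pThr75PP2Ap", "pThr75PP2A", "pThr75PP2Ac"),
        m("Cdk5", "Cdk5", "DARPP32Cdk5"),
        # adenine nucleotides; PKAcAMP4 carries two cAMP and the regulatory
        # subunit inherits them on holoenzyme dissociation, so both count 2
        m("adenine", "ATP", "cAMP", "AMP", "AC5GoaGTP_ATP",
          "AC5CaGoaGTP_ATP", "PDE1CaM_cAMP", "PDE4_cAMP",
          "PKAcAMP2", ("PKAcAMP4", 2), ("PKAr", 2)),
    ]


def builtin_striatal_model() -> ReactionSystem:
    """The bundled 40-scheme striatal model with Da and Ca as inputs."""
    schemes = _schemes()
    names: list[str] = []
    seen: set[str] = set()
    for sch in schemes:
        for n in _scheme_species_in_order(sch):
            if n not in seen:
                seen.add(n)
                names.append(n)
    species = [
        SpeciesDecl(n, INITIAL_TOTALS.get(n, 0.0), is_input=n in ("Da", "Ca"))
        for n in names
    ]
    return ReactionSystem(species, schemes, _moieties(), name="striatal")


def _scheme_species_in_order(sch: ReactionScheme) -> list[str]:
    out: list[str] = []
    for role in ("a", "b", "substrate", "enzyme", "complex", "products"):
        v = sch.participants.get(role)
        if v is None:
            continue
        out.extend([v] if isinstance(v, str) else list(v))
    return out
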