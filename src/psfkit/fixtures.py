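"""Small reaction systems with known behavior, used as oracles in tests.

These are first-class generators, not stored data: the closed forms they admit
(quadratic binding equilibrium, flux-balance covalent cycle) are what the
numerical machinery is checked against.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .model import (
    Moiety,
    RateConstants,
    ReactionSystem,
    SchemeKind,
    SpeciesDecl,
    build_scheme,
)

__all__ = [
    "make_fixture",
    "toy_binding",
    "toy_covalent_cycle",
    "random_weakly_reversible",
    "binding_equilibrium_complex",
    "covalent_cycle_steady_state",
]


def make_fixture(kind: str, params: dict | None = None, seed: int | None = None) -> ReactionSystem:
    """Dispatcher: ``toy_binding`` | ``toy_covalent_cycle`` | ``random_weakly_reversible``."""
    params = dict(params or {})
    if kind == "toy_binding":
        return toy_binding(**params)
    if kind == "toy_covalent_cycle":
        return toy_covalent_cycle(**params)
    if kind == "random_weakly_reversible":
        if seed is None:
            raise ValueError("random_weakly_reversible requires a seed")
        return random_weakly_reversible(seed, **params)
    raise ValueError(f"unknown fixture kind {kind!r}")


def toy_binding(
    a_total: float = 100.0,
    b_total: float = 100.0,
    kon: float = 0.01,
    koff: float = 1.0,
) -> ReactionSystem:
    """Single reversible association A + B <-> AB."""
    if min(a_total, b_total) < 0 or min(kon, koff) < 0:
        raise ValueError("totals and rates must be >= 0")
    scheme = build_scheme(
        SchemeKind.BINDING, {"a": "A", "b": "B", "complex": "AB"},
        RateConstants(kon=kon, koff=koff), scheme_id=1,
    )
    species = [
        SpeciesDecl("A", a_total, is_input=True),
        SpeciesDecl("B", b_total),
        SpeciesDecl("AB", 0.0),
    ]
    moieties = [
        Moiety("A", (("A", 1), ("AB", 1))),
        Moiety("B", (("B", 1), ("AB", 1))),
    ]
    return ReactionSystem(species, [scheme], moieties, name="toy_binding")


def toy_covalent_cycle(
    substrate_total: float = 1000.0,
    kinase_total: float = 100.0,
    phosphatase_total: float = 100.0,
    kon_k: float = 0.01,
    koff_k: float = 1.0,
    kcat_k: float = 0.5,
    kon_p: float = 0.01,
    koff_p: float = 1.0,
    kcat_p: float = 0.5,
) -> ReactionSystem:
    """Covalent modification cycle: kinase E1 phosphorylates S, phosphatase E2 reverses.

    S + E1 <-> SE1 -> Sp + E1 ; Sp + E2 <-> SpE2 -> S + E2.
    """
    vals = (substrate_total, kinase_total, phosphatase_total,
            kon_k, koff_k, kcat_k, kon_p, koff_p, kcat_p)
    if any(v < 0 for v in vals):
        raise ValueError("totals and rates must be >= 0")
    forward = build_scheme(
        SchemeKind.ENZYMATIC,
        {"substrate": "S", "enzyme": "E1", "complex": "SE1", "products": ("Sp", "E1")},
        RateConstants(kon=kon_k, koff=koff_k, kcat=kcat_k), scheme_id=1,
    )
    reverse = build_scheme(
        SchemeKind.ENZYMATIC,
        {"substrate": "Sp", "enzyme": "E2", "complex": "SpE2", "products": ("S", "E2")},
        RateConstants(kon=kon_p, koff=koff_p, kcat=kcat_p), scheme_id=2,
    )
    species = [
        SpeciesDecl("S", substrate_total),
        SpeciesDecl("E1", kinase_total, is_input=True),
        SpeciesDecl("E2", phosphatase_total),
        SpeciesDecl("SE1", 0.0),
        SpeciesDecl("Sp", 0.0),
        SpeciesDecl("SpE2", 0.0),
    ]
    moieties = [
        Moiety("S", (("S", 1), ("SE1", 1), ("Sp", 1), ("SpE2", 1))),
        Moiety("E1", (("E1", 1), ("SE1", 1))),
        Moiety("E2", (("E2", 1), ("SpE2", 1))),
    ]
    return ReactionSystem(species, [forward, reverse], moieties, name="toy_covalent_cycle")


def random_weakly_reversible(
    seed: int,
    n_species: int = 6,
    n_schemes: int = 5,
) -> ReactionSystem:
    """Random system built only from reversible schemes, hence weakly reversible.

    Deterministic per seed.  Bindings create fresh complex species; conversion
    pairs connect existing species in both directions.
    """
    rng = np.random.default_rng(seed)
    if n_species < 2 or n_schemes < 1:
        raise ValueError("need at least 2 species and 1 scheme")
    base = [f"X{i}" for i in range(n_species)]
    species = {n: float(rng.uniform(10, 1000)) for n in base}
    schemes = []
    moieties: list[Moiety] = []
    sid = 0
    used: set[str] = set()
    for _ in range(n_schemes):
        sid += 1
        if rng.random() < 0.5 and len(base) >= 2:
            i, j = rng.choice(len(base), size=2, replace=False)
            a, b = base[i], base[j]
            cx = f"{a}_{b}"
            if cx in species:
                cx = f"{a}_{b}_{sid}"
            species[cx] = 0.0
            schemes.append(build_scheme(
                SchemeKind.BINDING, {"a": a, "b": b, "complex": cx},
                RateConstants(kon=float(rng.uniform(1e-3, 1e-1)),
                              koff=float(rng.uniform(0.1, 10.0))),
                scheme_id=sid,
            ))
            used |= {a, b, cx}
        else:
            i, j = rng.choice(len(base), size=2, replace=False)
            a, b = base[i], base[j]
            schemes.append(build_scheme(
                SchemeKind.CONVERSION, {"a": a, "b": b},
                RateConstants(kcat=float(rng.uniform(0.01, 1.0))), scheme_id=sid,
            ))
            sid += 1
            schemes.append(build_scheme(
                SchemeKind.CONVERSION, {"a": b, "b": a},
                RateConstants(kcat=float(rng.uniform(0.01, 1.0))), scheme_id=sid,
            ))
            used |= {a, b}
    decls = [
        SpeciesDecl(n, t, is_input=(n == base[0]))
        for n, t in species.items() if n in used
    ]
    return ReactionSystem(decls, schemes, moieties, name=f"random_{seed}")


# ---------------------------------------------------------------------------
# closed-form / root-finding oracles
# ---------------------------------------------------------------------------

def binding_equilibrium_complex(a_total: float, b_total: float, kd: float) -> float:
    """Equilibrium [AB] for A + B <-> AB: the smaller root of the quadratic

    AB^2 - (At + Bt + Kd) AB + At Bt = 0.
    """
    s = a_total + b_total + kd
    disc = s * s - 4.0 * a_total * b_total
    return (s - np.sqrt(max(disc, 0.0))) / 2.0


def covalent_cycle_steady_state(
    substrate_total: float,
    kinase_total: float,
    phosphatase_total: float,
    kon_k: float, koff_k: float, kcat_k: float,
    kon_p: float, koff_p: float, kcat_p: float,
) -> dict[str, float]:
    """Exact steady state of the covalent cycle by flux balance + bisection.

    At steady state each complex satisfies kon*S*E = (koff+kcat)*C, i.e.
    C = Etot*S/(Km+S) with Km = (koff+kcat)/kon, and the catalytic fluxes
    through the two arms balance.  The free-substrate level S is the unique
    root of the conservation equation, found by bracketing.
    """
    if kon_k == 0 or kcat_k == 0 or kinase_total == 0:
        # no forward flux at all: everything stays unphosphorylated
        return {"S": substrate_total, "Sp": 0.0, "SE1": 0.0, "SpE2": 0.0,
                "E1": kinase_total, "E2": phosphatase_total}
    km_k = (koff_k + kcat_k) / kon_k
    km_p = (koff_p + kcat_p) / kon_p

    def sp_of_s(s: float) -> float:
        # flux balance: kcat_k*E1t*s/(km_k+s) = kcat_p*E2t*sp/(km_p+sp)
        jf = kcat_k * kinase_total * s / (km_k + s)
        denom = kcat_p * phosphatase_total - jf
        if denom <= 0:
            return np.inf  # forward flux exceeds phosphatase capacity
        return km_p * jf / denom

    def residual(s: float) -> float:
        sp = sp_of_s(s)
        if not np.isfinite(sp):
            return np.inf
        se1 = kinase_total * s / (km_k + s)
        spe2 = phosphatase_total * sp / (km_p + sp)
        return s + sp + se1 + spe2 - substrate_total

    # the flux balance is only feasible while the forward flux stays below the
    # phosphatase capacity; the residual is monotone in s and diverges at the
    # feasibility edge, so bracket against that edge when it lies inside [0, St]
    q = kcat_p * phosphatase_total / (kcat_k * kinase_total)
    s_crit = km_k * q / (1.0 - q) if q < 1 else np.inf
    hi = substrate_total if s_crit >= substrate_total else s_crit
    eps = 1e-9
    while residual(hi * (1.0 - eps) if hi == s_crit else hi) < 0:
        if hi != s_crit:
            raise RuntimeError("could not bracket the steady state")
        eps *= 1e-2
        if eps < 1e-15:
            raise RuntimeError("could not bracket the steady state")
    hi = hi * (1.0 - eps) if hi == s_crit else hi
    s = brentq(residual, 0.0, hi, xtol=1e-12, rtol=1e-14)
    sp = sp_of_s(s)
    se1 = kinase_total * s / (km_k + s)
    spe2 = phosphatase_total * sp / (km_p + sp)
    return {
        "S": s, "Sp": sp, "SE1": se1, "SpE2": spe2,
        "E1": kinase_total - se1, "E2": phosphatase_total - spe2,
    }
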