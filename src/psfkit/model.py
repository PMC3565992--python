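"""Mass-action reaction systems.

A reaction system is described by a list of *reaction schemes* — the rows a
modeler writes down (a reversible binding, a Michaelis–Menten style enzymatic
conversion, ...) — which are expanded into *elementary steps*, the single
arrows that carry one mass-action rate constant each.  Concentrations are in
nM throughout, time in seconds; a step of total reactant order m has a rate
constant in nM^-(m-1) s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SchemeKind",
    "SpeciesDecl",
    "RateConstants",
    "ElementaryStep",
    "ReactionScheme",
    "Moiety",
    "ReactionSystem",
    "ReversibilityReport",
    "build_scheme",
    "expand_scheme",
    "expand_system",
    "mass_action_rates",
    "check_weak_reversibility",
    "RateEvaluator",
]


class SchemeKind(str, Enum):
    """The reaction-row shapes a system may contain."""

    BINDING = "binding"                          # A + B <-> AB
    IRREVERSIBLE_BINDING = "irreversible_binding"  # A + B -> AB
    ENZYMATIC = "enzymatic"                      # S + E <-> SE -> P... + E
    CONVERSION = "conversion"                    # A -> B
    DECOMPOSITION = "decomposition"              # AB -> C + D + ...


@dataclass(frozen=True)
class SpeciesDecl:
    """A chemical species with its initial total concentration (nM)."""

    name: str
    initial_total: float = 0.0
    is_input: bool = False

    def __post_init__(self) -> None:
        if self.initial_total < 0:
            raise ValueError(
                f"species {self.name!r}: initial_total must be >= 0, "
                f"got {self.initial_total}"
            )


@dataclass(frozen=True)
class RateConstants:
    """kon / koff / kcat for a scheme; which fields apply depends on the kind.

    kon is in nM^-(m-1) s^-1 where m is the number of binding partners
    counted with stoichiometry; koff and kcat are first-order (s^-1).
    """

    kon: float | None = None
    koff: float | None = None
    kcat: float | None = None

    def __post_init__(self) -> None:
        for label in ("kon", "koff", "kcat"):
            v = getattr(self, label)
            if v is not None and v < 0:
                raise ValueError(f"rate constant {label} must be >= 0, got {v}")


@dataclass(frozen=True)
class ElementaryStep:
    """One mass-action arrow: reactants -> products at a single rate constant.

    ``reactants`` and ``products`` are tuples of (species name, stoichiometry).
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_constant: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.reactants and not self.products:
            raise ValueError("elementary step needs at least one participant")
        if self.rate_constant < 0:
            raise ValueError("rate_constant must be >= 0")
        for name, stoich in (*self.reactants, *self.products):
            if stoich < 1:
                raise ValueError(f"stoichiometry for {name!r} must be >= 1")

    @property
    def order(self) -> int:
        return sum(s for _, s in self.reactants)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        def side(parts: tuple[tuple[str, int], ...]) -> str:
            return " + ".join(
                name if s == 1 else f"{s}*{name}" for name, s in parts
            ) or "0"

        return f"{side(self.reactants)} -> {side(self.products)} @ {self.rate_constant}"


# role sets required per kind
_ROLE_REQUIREMENTS: dict[SchemeKind, tuple[set[str], set[str]]] = {
    # kind: (required roles, required rate fields)
    SchemeKind.BINDING: ({"a", "b", "complex"}, {"kon", "koff"}),
    SchemeKind.IRREVERSIBLE_BINDING: ({"a", "b", "complex"}, {"kon"}),
    SchemeKind.ENZYMATIC: ({"substrate", "enzyme", "complex", "products"},
                           {"kon", "koff", "kcat"}),
    SchemeKind.CONVERSION: ({"a", "b"}, {"kcat"}),
    SchemeKind.DECOMPOSITION: ({"complex", "products"}, {"kcat"}),
}


@dataclass(frozen=True)
class ReactionScheme:
    """A modeler-level reaction row, expandable to elementary steps.

    ``participants`` maps role names to species.  Roles by kind:

    - binding / irreversible_binding: ``a``, ``b``, ``complex``
      (``a`` may carry stoichiometry via ``stoich`` mapping, e.g. 4 Ca)
    - enzymatic: ``substrate``, ``enzyme``, ``complex``, ``products`` (tuple)
    - conversion: ``a``, ``b``
    - decomposition: ``complex``, ``products`` (tuple)
    """

    id: int
    kind: SchemeKind
    participants: Mapping[str, str | tuple[str, ...]]
    rates: RateConstants
    stoich: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required, rate_fields = _ROLE_REQUIREMENTS[self.kind]
        missing = required - set(self.participants)
        if missing:
            raise ValueError(
                f"scheme {self.id} ({self.kind.value}): missing roles {sorted(missing)}"
            )
        unknown = set(self.participants) - required
        if unknown:
            raise ValueError(
                f"scheme {self.id} ({self.kind.value}): unknown roles {sorted(unknown)}"
            )
        for f_name in rate_fields:
            if getattr(self.rates, f_name) is None:
                raise ValueError(
                    f"scheme {self.id} ({self.kind.value}): rate {f_name!r} is required"
                )

    # -- species bookkeeping ------------------------------------------------
    def species_names(self) -> set[str]:
        out: set[str] = set()
        for v in self.participants.values():
            if isinstance(v, str):
                out.add(v)
            else:
                out.update(v)
        return out

    def _mult(self, role: str) -> int:
        return int(self.stoich.get(role, 1))

    def expand(self) -> list[ElementaryStep]:
        """Elementary steps in deterministic order: forward, reverse, catalytic."""
        p = self.participants
        r = self.rates
        sid = self.id
        if self.kind in (SchemeKind.BINDING, SchemeKind.IRREVERSIBLE_BINDING):
            a, b, cx = p["a"], p["b"], p["complex"]
            lhs = ((a, self._mult("a")), (b, self._mult("b")))
            rhs = ((cx, self._mult("complex")),)
            steps = [ElementaryStep(lhs, rhs, r.kon, label=f"{sid}:forward")]
            if self.kind is SchemeKind.BINDING:
                steps.append(
                    ElementaryStep(rhs, lhs, r.koff, label=f"{sid}:reverse")
                )
            return steps
        if self.kind is SchemeKind.ENZYMATIC:
            s, e, cx = p["substrate"], p["enzyme"], p["complex"]
            prods = tuple((q, 1) for q in p["products"])
            lhs = ((s, 1), (e, 1))
            mid = ((cx, 1),)
            return [
                ElementaryStep(lhs, mid, r.kon, label=f"{sid}:forward"),
                ElementaryStep(mid, lhs, r.koff, label=f"{sid}:reverse"),
                ElementaryStep(mid, prods, r.kcat, label=f"{sid}:catalytic"),
            ]
        if self.kind is SchemeKind.CONVERSION:
            return [
                ElementaryStep(
                    ((p["a"], 1),), ((p["b"], 1),), r.kcat, label=f"{sid}:forward"
                )
            ]
        # decomposition
        prods = tuple((q, 1) for q in p["products"])
        return [
            ElementaryStep(
                ((p["complex"], 1),), prods, r.kcat, label=f"{sid}:forward"
            )
        ]


@dataclass(frozen=True)
class Moiety:
    """A conserved group: the multiplicity-weighted sum of members is constant."""

    name: str
    members: tuple[tuple[str, int], ...]

    def total(self, conc: Mapping[str, float]) -> float:
        return float(sum(conc.get(n, 0.0) * m for n, m in self.members))

    def member_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.members)


@dataclass(frozen=True)
class ReversibilityReport:
    """Per-species produced/consumed flags; pass iff every species has both."""

    produced: Mapping[str, bool]
    consumed: Mapping[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.produced.values()) and all(self.consumed.values())

    def failures(self) -> list[str]:
        out = []
        for name in self.produced:
            problems = []
            if not self.produced[name]:
                problems.append("never produced")
            if not self.consumed[name]:
                problems.append("never consumed")
            if problems:
                out.append(f"{name}: {', '.join(problems)}")
        return out


@dataclass
class ReactionSystem:
    """Species, schemes, and the derived elementary steps of a kinetic model."""

    species: list[SpeciesDecl]
    schemes: list[ReactionScheme]
    moieties: list[Moiety] = field(default_factory=list)
    name: str = "unnamed"

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate species declarations: {dupes}")
        declared = set(names)
        referenced: set[str] = set()
        for sch in self.schemes:
            referenced |= sch.species_names()
        undeclared = referenced - declared
        if undeclared:
            raise ValueError(f"schemes reference undeclared species: {sorted(undeclared)}")
        self.steps: list[ElementaryStep] = expand_system(self.schemes)

    # -- convenience --------------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def inputs(self) -> list[str]:
        return [s.name for s in self.species if s.is_input]

    def species_index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}

    def initial_concentrations(self) -> dict[str, float]:
        return {s.name: s.initial_total for s in self.species}

    def moiety(self, name: str) -> Moiety:
        for m in self.moieties:
            if m.name == name:
                return m
        raise KeyError(f"no moiety named {name!r}")

    def moiety_containing(self, species: str) -> Moiety | None:
        """The first declared moiety that contains ``species``, if any."""
        for m in self.moieties:
            if species in m.member_names():
                return m
        return None

    def scheme(self, scheme_id: int) -> ReactionScheme:
        for sch in self.schemes:
            if sch.id == scheme_id:
                return sch
        raise KeyError(f"no scheme with id {scheme_id}")

    def with_initial(self, overrides: Mapping[str, float]) -> "ReactionSystem":
        """Copy of the system with some initial totals replaced."""
        unknown = set(overrides) - set(self.species_names)
        if unknown:
            raise KeyError(f"unknown species in overrides: {sorted(unknown)}")
        new_species = [
            replace(s, initial_total=float(overrides.get(s.name, s.initial_total)))
            for s in self.species
        ]
        return ReactionSystem(new_species, self.schemes, self.moieties, self.name)

    def with_scheme_rates(self, scheme_id: int, rates: RateConstants) -> "ReactionSystem":
        """Copy of the system with one scheme's rate constants replaced."""
        new_schemes = [
            replace(sch, rates=rates) if sch.id == scheme_id else sch
            for sch in self.schemes
        ]
        return ReactionSystem(self.species, new_schemes, self.moieties, self.name)


def build_scheme(
    kind: SchemeKind | str,
    participants: Mapping[str, str | Sequence[str]],
    rates: RateConstants | Mapping[str, float],
    scheme_id: int = 0,
    stoich: Mapping[str, int] | None = None,
) -> ReactionScheme:
    """Validate and construct a reaction scheme.

    ``participants`` uses the role names documented on :class:`ReactionScheme`;
    ``products`` may be given as any sequence of species names.
    """
    kind = SchemeKind(kind)
    if not isinstance(rates, RateConstants):
        rates = RateConstants(**dict(rates))
    norm: dict[str, str | tuple[str, ...]] = {}
    for role, v in participants.items():
        norm[role] = v if isinstance(v, str) else tuple(v)
    return ReactionScheme(
        id=scheme_id, kind=kind, participants=norm, rates=rates,
        stoich=dict(stoich or {}),
    )


def expand_scheme(scheme: ReactionScheme) -> list[ElementaryStep]:
    return scheme.expand()


def expand_system(schemes: Iterable[ReactionScheme]) -> list[ElementaryStep]:
    """Concatenated expansions, ordered by scheme then forward/reverse/catalytic."""
    out: list[ElementaryStep] = []
    for sch in schemes:
        out.extend(sch.expand())
    return out


class RateEvaluator:
    """Vectorized mass-action right-hand side for a fixed species ordering.

    Precomputes the reactant-order matrix R (n_steps x n_species) and the net
    stoichiometry matrix N so that ``dc/dt = N^T (k * prod c^R)``.  Negative
    concentrations handed in by an ODE solver are clipped to zero before the
    rate evaluation.
    """

    def __init__(self, steps: Sequence[ElementaryStep], species_order: Sequence[str]):
        self.species_order = list(species_order)
        index = {n: i for i, n in enumerate(self.species_order)}
        n_steps, n_sp = len(steps), len(self.species_order)
        self.R = np.zeros((n_steps, n_sp))
        self.N = np.zeros((n_steps, n_sp))
        self.k = np.zeros(n_steps)
        for j, step in enumerate(steps):
            self.k[j] = step.rate_constant
            for name, s in step.reactants:
                if name not in index:
                    raise KeyError(f"unknown species in step: {name!r}")
                self.R[j, index[name]] += s
                self.N[j, index[name]] -= s
            for name, s in step.products:
                if name not in index:
                    raise KeyError(f"unknown species in step: {name!r}")
                self.N[j, index[name]] += s
        self.NT = self.N.T.copy()
        # columns that actually enter some rate law (order > 0 somewhere)
        self._active = np.flatnonzero(self.R.any(axis=0))

    def step_rates(self, c: np.ndarray) -> np.ndarray:
        cpos = np.maximum(c, 0.0)
        # prod over species of c^R ; 0**0 == 1 in numpy so zeros are safe
        with np.errstate(divide="ignore"):
            return self.k * np.prod(
                cpos[self._active] ** self.R[:, self._active], axis=1
            )

    def __call__(self, t: float, c: np.ndarray) -> np.ndarray:
        return self.NT @ self.step_rates(c)

    def jacobian(self, t: float, c: np.ndarray) -> np.ndarray:
        """d(dc/dt)/dc, exact for the clipped rate law away from clip boundaries."""
        cpos = np.maximum(c, 0.0)
        n_steps, n_sp = self.R.shape
        drdc = np.zeros((n_steps, n_sp))
        for i in self._active:
            Ri = self.R[:, i]
            mask = Ri > 0
            if not mask.any():
                continue
            # derivative of c_i^Ri term times the product over the others
            others = [j for j in self._active if j != i]
            prod_others = np.prod(
                cpos[others] ** self.R[np.ix_(np.flatnonzero(mask), others)], axis=1
            ) if others else np.ones(mask.sum())
            ci = cpos[i]
            expo = Ri[mask]
            dterm = np.where(expo == 1.0, 1.0, expo * ci ** (expo - 1.0))
            drdc[mask, i] = self.k[mask] * dterm * prod_others
        return self.NT @ drdc


def mass_action_rates(
    steps: Sequence[ElementaryStep], concentrations: Mapping[str, float]
) -> dict[str, float]:
    """Net rate of change (nM/s) per species under mass-action kinetics."""
    for name, c in concentrations.items():
        if c < 0:
            raise ValueError(f"concentration of {name!r} is negative ({c})")
    order = list(concentrations)
    ev = RateEvaluator(steps, order)
    dc = ev(0.0, np.array([concentrations[n] for n in order]))
    return dict(zip(order, dc.tolist()))


def check_weak_reversibility(system: ReactionSystem) -> ReversibilityReport:
    """Check that every species is both produced and consumed by some step.

    Weak reversibility in this operational sense (no pure sources or sinks)
    is what guarantees finite steady states under conservation of mass.
    """
    produced = {n: False for n in system.species_names}
    consumed = {n: False for n in system.species_names}
    for step in system.steps:
        if step.rate_constant == 0:
            continue
        for name, _ in step.reactants:
            consumed[name] = True
        for name, _ in step.products:
            produced[name] = True
    return ReversibilityReport(produced=produced, consumed=consumed)
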