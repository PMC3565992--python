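"""Input-dependent modularity: which species still transmit signal at a given
input level.

A species whose psf has saturated (risen past EC90 of its fitted range) or
depleted (fallen past EC10) is an *inactive link*: further input increases no
longer change it, so it transmits nothing downstream.  A species whose whole
sweep moves it by less than a span threshold is *nonresponsive* outright.
Modules are the connected components of the species graph restricted to
species that are still active.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .model import ReactionSystem
from .psf import HyperbolicFit, LinearFit, PsfCurve, fit_psf

__all__ = [
    "NodeActivity",
    "ModularityReport",
    "input_target_cutoffs",
    "classify_activity",
    "modules_at",
]

EC_LEVEL = 0.90  # saturation/depletion cutoff: EC90 rising, EC10 falling


@dataclass
class NodeActivity:
    species: str
    relative_span: float
    cutoff_input: float | None      # nM; None if never saturating in range
    direction: str                  # "rising" | "falling" | "flat"
    status: str                     # "nonresponsive" | "active" | "inactive"


@dataclass
class ModularityReport:
    input_level: float
    activities: dict[str, NodeActivity]
    modules: list[set[str]]
    inactive_links: list[str]

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def counts(self) -> dict[str, int]:
        out = {"nonresponsive": 0, "active": 0, "inactive": 0}
        for a in self.activities.values():
            out[a.status] += 1
        return out


def _cutoff_from_fit(
    fit: HyperbolicFit | LinearFit, grid: np.ndarray
) -> float | None:
    """Input level at which the fitted curve has covered EC90 of its full
    range (its y0 -> y0+Y excursion).  Linear fits never saturate."""
    if isinstance(fit, LinearFit):
        return None
    ratio = EC_LEVEL / (1.0 - EC_LEVEL)
    x = fit.C * ratio ** (1.0 / fit.n)
    if x > grid[-1]:
        return None   # not reached within the sampled range
    return float(x)


def _relative_span(curve: PsfCurve, floor: float = 1e-9) -> float:
    hi = float(np.max(np.abs(curve.values)))
    if hi <= floor:
        return 0.0
    return curve.span / hi


def input_target_cutoffs(
    curves: Mapping[str, PsfCurve],
    fits: Mapping[str, HyperbolicFit | LinearFit] | None = None,
) -> dict[str, float | None]:
    """Per-target input level beyond which the target no longer responds.

    Flat curves have no cutoff; targets whose fit is linear over the sampled
    range (no saturation visible) have none either.
    """
    fits = dict(fits or {})
    out: dict[str, float | None] = {}
    for name, curve in curves.items():
        if curve.span == 0 or _relative_span(curve) == 0.0:
            out[name] = None
            continue
        fit = fits.get(name)
        if fit is None:
            fit = fit_psf(curve)
        out[name] = _cutoff_from_fit(fit, curve.grid)
    return out


def classify_activity(
    curves: Mapping[str, PsfCurve],
    input_level: float,
    span_threshold: float = 0.10,
    fits: Mapping[str, HyperbolicFit | LinearFit] | None = None,
) -> dict[str, NodeActivity]:
    """Activity status of every species at one input level.

    nonresponsive: the sweep moves the species by less than ``span_threshold``
    of its level; inactive: the species has saturated/depleted (the queried
    level is at or beyond its EC90/EC10 cutoff); active otherwise.
    """
    cutoffs = input_target_cutoffs(curves, fits=fits)
    out: dict[str, NodeActivity] = {}
    for name, curve in curves.items():
        span = _relative_span(curve)
        if curve.span == 0:
            direction = "flat"
        else:
            direction = "rising" if curve.values[-1] >= curve.values[0] else "falling"
        cutoff = cutoffs[name]
        if span < span_threshold:
            status = "nonresponsive"
        elif cutoff is not None and input_level >= cutoff:
            status = "inactive"
        else:
            status = "active"
        out[name] = NodeActivity(name, span, cutoff, direction, status)
    return out


def modules_at(
    system: ReactionSystem,
    activities: Mapping[str, NodeActivity],
    input_level: float | None = None,
) -> ModularityReport:
    """Modules = connected components of the active-species graph.

    Reaction nodes act as conduits: two species are linked iff they are both
    active and participate in the same scheme.
    """
    level = input_level
    if level is None:
        level = float("nan")
    active = {n for n, a in activities.items() if a.status == "active"}
    g = nx.Graph()
    g.add_nodes_from(active)
    for scheme in system.schemes:
        members = [s for s in scheme.species_names() if s in active]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                g.add_edge(members[i], members[j])
    modules = [set(c) for c in nx.connected_components(g)]
    modules.sort(key=lambda c: (-len(c), min(c)))
    inactive = sorted(n for n, a in activities.items() if a.status == "inactive")
    return ModularityReport(
        input_level=level, activities=dict(activities),
        modules=modules, inactive_links=inactive,
    )
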