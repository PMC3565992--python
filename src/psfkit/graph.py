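"""The weighted dynamic graph: a bipartite species/reaction view of a system
annotated with steady-state concentration ranges and psf fit parameters.

Species nodes carry the [min, max] range attained over an input sweep;
reaction nodes carry the fitted transfer-function parameters — two fits for a
complex-formation scheme (complex build-up and partner depletion, left to
right) and one for an enzymatic scheme (enzyme -> modified substrate).
"""

from __future__ import annotations

import json
from typing import Mapping

import networkx as nx

from .model import ReactionScheme, ReactionSystem, SchemeKind
from .psf import HyperbolicFit, LinearFit, PsfCurve

__all__ = ["build_weighted_dynamic_graph", "export_graph", "reaction_node_id"]

# stable attribute schema; downstream tools diff these exports
SPECIES_ATTRS = ("range_min_nM", "range_max_nM")
FIT_ATTRS = ("fit_model", "Y", "C", "n", "y0", "slope", "intercept")

_KIND_COLOR = {
    SchemeKind.BINDING: "red",
    SchemeKind.IRREVERSIBLE_BINDING: "red",
    SchemeKind.ENZYMATIC: "blue",
    SchemeKind.CONVERSION: "blue",
    SchemeKind.DECOMPOSITION: "blue",
}


def reaction_node_id(scheme_id: int) -> str:
    return f"reaction:{scheme_id}"


def _fit_attrs(fit: HyperbolicFit | LinearFit, prefix: str) -> dict:
    out = {f"{prefix}fit_model": fit.model}
    for k, v in fit.params().items():
        out[f"{prefix}{k}"] = float(v)
    out[f"{prefix}sse"] = float(fit.sse)
    return out


def _fit_targets(scheme: ReactionScheme) -> list[str]:
    """Species whose psf fits label this reaction node, left to right."""
    p = scheme.participants
    if scheme.kind in (SchemeKind.BINDING, SchemeKind.IRREVERSIBLE_BINDING):
        return [p["complex"], p["b"]]          # complex formation, partner depletion
    if scheme.kind is SchemeKind.ENZYMATIC:
        prods = [q for q in p["products"] if q != p["enzyme"]]
        return [prods[0] if prods else p["products"][0]]
    if scheme.kind is SchemeKind.CONVERSION:
        return [p["b"]]
    return [p["products"][0]]                  # decomposition


def _edges(scheme: ReactionScheme) -> list[tuple[str, str]]:
    """(species, role) pairs for the bipartite edges of one scheme."""
    p = scheme.participants
    if scheme.kind in (SchemeKind.BINDING, SchemeKind.IRREVERSIBLE_BINDING):
        return [(p["a"], "source"), (p["b"], "source"), (p["complex"], "target")]
    if scheme.kind is SchemeKind.ENZYMATIC:
        out = [(p["substrate"], "source"), (p["enzyme"], "participant"),
               (p["complex"], "participant")]
        out += [(q, "target") for q in p["products"] if q != p["enzyme"]]
        return out
    if scheme.kind is SchemeKind.CONVERSION:
        return [(p["a"], "source"), (p["b"], "target")]
    return [(p["complex"], "source")] + [(q, "target") for q in p["products"]]


def build_weighted_dynamic_graph(
    system: ReactionSystem,
    curves: Mapping[str, PsfCurve],
    fits: Mapping[str, HyperbolicFit | LinearFit] | None = None,
) -> nx.Graph:
    """Assemble the annotated bipartite graph for one input condition.

    ``curves`` maps species to their systemic psfs from the sweep; ``fits``
    maps species to fitted transfer functions (missing entries leave the node
    labeled unknown).
    """
    fits = fits or {}
    g = nx.Graph()
    g.graph["input"] = next(iter(curves.values())).source if curves else ""
    for decl in system.species:
        attrs = {"node_type": "species", "bipartite": 0,
                 "is_input": decl.is_input, "color": "white"}
        curve = curves.get(decl.name)
        if curve is not None:
            lo, hi = curve.range
            attrs["range_min_nM"] = lo
            attrs["range_max_nM"] = hi
        else:
            attrs["range_unknown"] = True
        g.add_node(decl.name, **attrs)
    missing: list[str] = []
    for scheme in system.schemes:
        rid = reaction_node_id(scheme.id)
        attrs = {
            "node_type": "reaction", "bipartite": 1,
            "scheme_id": scheme.id, "scheme_kind": scheme.kind.value,
            "color": _KIND_COLOR[scheme.kind],
        }
        for slot, target in enumerate(_fit_targets(scheme), start=1):
            prefix = f"fit{slot}_"
            attrs[f"{prefix}target"] = target
            fit = fits.get(target)
            if fit is None:
                missing.append(target)
            else:
                attrs.update(_fit_attrs(fit, prefix))
        g.add_node(rid, **attrs)
        for species, role in _edges(scheme):
            g.add_edge(species, rid, role=role)
    if missing:
        g.graph["missing_fits"] = ",".join(sorted(set(missing)))
    return g


def export_graph(graph: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write the graph with all attributes as GraphML, DOT or JSON node-link."""
    if fmt == "graphml":
        nx.write_graphml(graph, path)
        return
    if fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(nx.node_link_data(graph, edges="links"), fh, indent=1)
        return
    if fmt == "dot":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(to_dot(graph))
        return
    raise ValueError(f"unknown graph format {fmt!r}")


def _dot_quote(s) -> str:
    return '"' + str(s).replace("\\", "\\\\").replace('"', '\\"') + '"'


def to_dot(graph: nx.Graph) -> str:
    """Plain DOT serialization with node/edge attributes."""
    lines = ["graph psf {"]
    for node, attrs in graph.nodes(data=True):
        body = ", ".join(
            f"{k}={_dot_quote(v)}" for k, v in sorted(attrs.items()))
        lines.append(f"  {_dot_quote(node)} [{body}];")
    for u, v, attrs in graph.edges(data=True):
        body = ", ".join(
            f"{k}={_dot_quote(w)}" for k, w in sorted(attrs.items()))
        suffix = f" [{body}]" if body else ""
        lines.append(f"  {_dot_quote(u)} -- {_dot_quote(v)}{suffix};")
    lines.append("}")
    return "\n".join(lines) + "\n"
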