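"""Reading and writing reaction systems as TSV or JSON text.

The TSV dialect has one row per declaration::

    # comment lines start with '#'
    species <TAB> name <TAB> initial_nM <TAB> input|-
    moiety  <TAB> name <TAB> member[*mult]+member...
    <id> <TAB> <kind> <TAB> lhs <TAB> mid <TAB> rhs <TAB> kon <TAB> koff <TAB> kcat

Scheme sides are '+'-separated species, with an optional 'n*' stoichiometry
prefix (e.g. ``PP2A+4*Ca``).  For binding rows lhs holds the two partners and
rhs the complex; enzymatic rows put the intermediate complex in the mid
column.  The JSON form mirrors the same fields.
"""

from __future__ import annotations

import json
from typing import Sequence

from .model import (
    Moiety,
    RateConstants,
    ReactionScheme,
    ReactionSystem,
    SchemeKind,
    SpeciesDecl,
    build_scheme,
)

__all__ = ["parse_model", "write_model", "read_model_file", "write_model_file",
           "ModelParseError", "systems_equal"]


class ModelParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


def _fmt_side(parts: Sequence[tuple[str, int]]) -> str:
    return "+".join(n if m == 1 else f"{m}*{n}" for n, m in parts)


def _parse_side(text: str, line: int) -> list[tuple[str, int]]:
    out = []
    for tok in filter(None, (t.strip() for t in text.split("+"))):
        if "*" in tok:
            mult_s, _, name = tok.partition("*")
            try:
                mult = int(mult_s)
            except ValueError:
                raise ModelParseError(f"bad stoichiometry {tok!r}", line)
            if mult < 1:
                raise ModelParseError(f"stoichiometry must be >= 1 in {tok!r}", line)
        else:
            name, mult = tok, 1
        if not name:
            raise ModelParseError(f"empty species name in {text!r}", line)
        out.append((name, mult))
    return out


def _scheme_row(sch: ReactionScheme) -> dict:
    p = sch.participants
    st = sch.stoich

    def one(role: str) -> list[tuple[str, int]]:
        return [(p[role], int(st.get(role, 1)))]

    if sch.kind in (SchemeKind.BINDING, SchemeKind.IRREVERSIBLE_BINDING):
        lhs, mid, rhs = one("a") + one("b"), [], one("complex")
    elif sch.kind is SchemeKind.ENZYMATIC:
        lhs = [(p["substrate"], 1), (p["enzyme"], 1)]
        mid = [(p["complex"], 1)]
        rhs = [(q, 1) for q in p["products"]]
    elif sch.kind is SchemeKind.CONVERSION:
        lhs, mid, rhs = [(p["a"], 1)], [], [(p["b"], 1)]
    else:  # decomposition
        lhs, mid, rhs = [(p["complex"], 1)], [], [(q, 1) for q in p["products"]]
    return {
        "id": sch.id,
        "kind": sch.kind.value,
        "lhs": _fmt_side(lhs),
        "mid": _fmt_side(mid),
        "rhs": _fmt_side(rhs),
        "kon": None if sch.rates.kon is None else float(sch.rates.kon),
        "koff": None if sch.rates.koff is None else float(sch.rates.koff),
        "kcat": None if sch.rates.kcat is None else float(sch.rates.kcat),
    }


def _build_from_row(row: dict, line: int) -> ReactionScheme:
    try:
        kind = SchemeKind(row["kind"])
    except ValueError:
        raise ModelParseError(f"unknown scheme kind {row['kind']!r}", line)
    lhs = _parse_side(row.get("lhs", ""), line)
    mid = _parse_side(row.get("mid", ""), line)
    rhs = _parse_side(row.get("rhs", ""), line)

    def rate(field: str) -> float:
        v = row.get(field)
        if v is None or v == "":
            raise ModelParseError(f"{kind.value} scheme requires {field}", line)
        return float(v)

    try:
        if kind in (SchemeKind.BINDING, SchemeKind.IRREVERSIBLE_BINDING):
            if len(lhs) != 2 or len(rhs) != 1 or mid:
                raise ModelParseError(
                    f"{kind.value} needs 'A+B' on lhs and one complex on rhs", line)
            (a, ma), (b, mb) = lhs
            (cx, mc) = rhs[0]
            rates = RateConstants(
                kon=rate("kon"),
                koff=rate("koff") if kind is SchemeKind.BINDING else None,
            )
            return build_scheme(
                kind, {"a": a, "b": b, "complex": cx}, rates,
                scheme_id=int(row["id"]),
                stoich={"a": ma, "b": mb, "complex": mc},
            )
        if kind is SchemeKind.ENZYMATIC:
            if len(lhs) != 2 or len(mid) != 1 or not rhs:
                raise ModelParseError(
                    "enzymatic needs 'S+E' lhs, complex mid, products rhs", line)
            return build_scheme(
                kind,
                {"substrate": lhs[0][0], "enzyme": lhs[1][0],
                 "complex": mid[0][0], "products": tuple(n for n, _ in rhs)},
                RateConstants(kon=rate("kon"), koff=rate("koff"), kcat=rate("kcat")),
                scheme_id=int(row["id"]),
            )
        if kind is SchemeKind.CONVERSION:
            if len(lhs) != 1 or len(rhs) != 1 or mid:
                raise ModelParseError("conversion needs one species per side", line)
            return build_scheme(
                kind, {"a": lhs[0][0], "b": rhs[0][0]},
                RateConstants(kcat=rate("kcat")), scheme_id=int(row["id"]),
            )
        # decomposition
        if len(lhs) != 1 or not rhs or mid:
            raise ModelParseError("decomposition needs one complex lhs and products rhs", line)
        return build_scheme(
            kind, {"complex": lhs[0][0], "products": tuple(n for n, _ in rhs)},
            RateConstants(kcat=rate("kcat")), scheme_id=int(row["id"]),
        )
    except ModelParseError:
        raise
    except (ValueError, KeyError) as exc:
        raise ModelParseError(str(exc), line)


# ---------------------------------------------------------------------------


def write_model(system: ReactionSystem, fmt: str = "tsv") -> str:
    if fmt == "json":
        doc = {
            "name": system.name,
            "species": [
                {"name": s.name, "initial_nM": float(s.initial_total),
                 "input": s.is_input}
                for s in system.species
            ],
            "moieties": [
                {"name": m.name, "members": [[n, mult] for n, mult in m.members]}
                for m in system.moieties
            ],
            "schemes": [_scheme_row(sch) for sch in system.schemes],
        }
        return json.dumps(doc, indent=2) + "\n"
    if fmt != "tsv":
        raise ValueError(f"unknown model format {fmt!r}")
    lines = [f"# psfkit model: {system.name}",
             "# species\tname\tinitial_nM\tinput",
             ]
    for s in system.species:
        lines.append(
            f"species\t{s.name}\t{float(s.initial_total)!r}"
            f"\t{'input' if s.is_input else '-'}")
    for m in system.moieties:
        lines.append(f"moiety\t{m.name}\t{_fmt_side(m.members)}")
    lines.append("# id\tkind\tlhs\tmid\trhs\tkon\tkoff\tkcat")
    for sch in system.schemes:
        row = _scheme_row(sch)
        def num(v):
            return "" if v is None else repr(float(v))
        lines.append("\t".join([
            str(row["id"]), row["kind"], row["lhs"], row["mid"], row["rhs"],
            num(row["kon"]), num(row["koff"]), num(row["kcat"]),
        ]))
    return "\n".join(lines) + "\n"


def parse_model(text: str) -> ReactionSystem:
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return _parse_json(stripped)
    return _parse_tsv(text)


def _parse_json(text: str) -> ReactionSystem:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"invalid JSON: {exc}")
    species = [
        SpeciesDecl(d["name"], float(d.get("initial_nM", 0.0)),
                    bool(d.get("input", False)))
        for d in doc.get("species", [])
    ]
    moieties = [
        Moiety(d["name"], tuple((n, int(m)) for n, m in d["members"]))
        for d in doc.get("moieties", [])
    ]
    schemes = [_build_from_row(row, i + 1) for i, row in enumerate(doc.get("schemes", []))]
    name = doc.get("name", "unnamed")
    try:
        return ReactionSystem(species, schemes, moieties, name=name)
    except ValueError as exc:
        raise ModelParseError(str(exc))


def _parse_tsv(text: str) -> ReactionSystem:
    species: list[SpeciesDecl] = []
    moieties: list[Moiety] = []
    schemes: list[ReactionScheme] = []
    name = "unnamed"
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            body = line.lstrip()[1:].strip()
            if body.startswith("psfkit model:"):
                name = body.partition(":")[2].strip()
            continue
        cells = line.split("\t")
        tag = cells[0].strip()
        if tag == "species":
            if len(cells) < 3:
                raise ModelParseError("species row needs name and initial_nM", lineno)
            try:
                initial = float(cells[2])
            except ValueError:
                raise ModelParseError(f"bad concentration {cells[2]!r}", lineno)
            flag = cells[3].strip() if len(cells) > 3 else "-"
            species.append(SpeciesDecl(cells[1].strip(), initial, flag == "input"))
        elif tag == "moiety":
            if len(cells) < 3:
                raise ModelParseError("moiety row needs name and members", lineno)
            members = tuple(_parse_side(cells[2], lineno))
            moieties.append(Moiety(cells[1].strip(), members))
        else:
            if len(cells) < 8:
                raise ModelParseError(
                    f"scheme row needs 8 columns, got {len(cells)}", lineno)
            try:
                sid = int(cells[0])
            except ValueError:
                raise ModelParseError(f"bad scheme id {cells[0]!r}", lineno)
            row = {
                "id": sid, "kind": cells[1].strip(),
                "lhs": cells[2], "mid": cells[3], "rhs": cells[4],
                "kon": cells[5].strip() or None,
                "koff": cells[6].strip() or None,
                "kcat": cells[7].strip() or None,
            }
            schemes.append(_build_from_row(row, lineno))
    try:
        return ReactionSystem(species, schemes, moieties, name=name)
    except ValueError as exc:
        raise ModelParseError(str(exc))


def read_model_file(path) -> ReactionSystem:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_model(fh.read())


def write_model_file(system: ReactionSystem, path, fmt: str | None = None) -> None:
    if fmt is None:
        fmt = "json" if str(path).endswith(".json") else "tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_model(system, fmt=fmt))


def systems_equal(a: ReactionSystem, b: ReactionSystem) -> bool:
    """Structural equality: species, moieties and expanded steps coincide."""
    if [(s.name, s.initial_total, s.is_input) for s in a.species] != \
       [(s.name, s.initial_total, s.is_input) for s in b.species]:
        return False
    if [(m.name, m.members) for m in a.moieties] != \
       [(m.name, m.members) for m in b.moieties]:
        return False
    return [(s.reactants, s.products, s.rate_constant) for s in a.steps] == \
           [(s.reactants, s.products, s.rate_constant) for s in b.steps]
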