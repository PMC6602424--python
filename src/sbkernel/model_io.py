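"""Model input/output.

Two on-disk model representations map onto the meta-model:

* an SBML Level-3-core **subset** (no packages): compartments, species,
  parameters, reactions with kinetic laws in content-MathML core, rules,
  events and constraints.  Unsupported constructs (extension packages,
  ``factorial``, MathML ``delay``) raise :class:`SbmlImportError` naming
  every offending element rather than being dropped silently.
* a bundled human-readable **text format** (reaction-and-equation language,
  documented in ``docs/format.md``), which additionally expresses modular
  models through ``module``/``end`` blocks and ``connect`` lines.

Both directions round-trip: reading back a written model yields an
element-wise identical model (same ids, same stoichiometries, equal
expression trees).  Time-course and steady-state observation tables are read
from delimited text via pandas.
"""

from __future__ import annotations

import io
import re
from fractions import Fraction
from typing import Union

import numpy as np
import pandas as pd
import sympy as sp
from lxml import etree

from . import expressions as ex
from .metamodel import (
    Constraint,
    Diagram,
    Event,
    MathModel,
    Parameter,
    Reaction,
    Rule,
    Variable,
    diagram_from_math,
    validate,
)
from .modular import Connection, ModularModel, compose

__all__ = [
    "SbmlImportError",
    "SbmlExportError",
    "TextSyntaxError",
    "read_sbml",
    "write_sbml",
    "read_text",
    "write_text",
    "read_timecourse",
]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_URI = "http://www.sbml.org/sbml/symbols/time"


class SbmlImportError(ValueError):
    pass


class SbmlExportError(ValueError):
    pass


class TextSyntaxError(ValueError):
    def __init__(self, message, line=None):
        where = f"line {line}: " if line is not None else ""
        super().__init__(f"{where}{message}")
        self.line = line


# --------------------------------------------------------------------------
# MathML core <-> sympy
# --------------------------------------------------------------------------

_MML_BINOPS = {
    "plus": lambda *a: sp.Add(*a),
    "times": lambda *a: sp.Mul(*a),
    "power": sp.Pow,
    "min": sp.Min,
    "max": sp.Max,
    "lt": sp.Lt,
    "leq": sp.Le,
    "gt": sp.Gt,
    "geq": sp.Ge,
    "eq": sp.Eq,
    "neq": sp.Ne,
    "and": sp.And,
    "or": sp.Or,
    "exp": sp.exp,
    "abs": sp.Abs,
    "not": sp.Not,
    "floor": sp.floor,
    "ceiling": sp.ceiling,
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
    "root": None,  # handled explicitly
}

_MML_UNSUPPORTED = {
    "factorial",
    "csymbol-delay",
    "partialdiff",
    "diff",
    "int",
    "sum",
    "product",
    "xor",
    "implies",
}


def _tag(el) -> str:
    return etree.QName(el).localname


def _mathml_to_sympy(math_el, time_symbol: str, problems: list):
    """Convert a <math> element's single child to a sympy expression."""
    children = [c for c in math_el if isinstance(c.tag, str)]
    if len(children) != 1:
        problems.append("math element must have exactly one child")
        return sp.Integer(0)
    return _mml_node(children[0], time_symbol, problems)


def _mml_node(el, time_symbol, problems):
    tag = _tag(el)
    if tag == "ci":
        return sp.Symbol(el.text.strip())
    if tag == "cn":
        return _mml_number(el)
    if tag == "csymbol":
        url = el.get("definitionURL", "")
        if url == TIME_URI:
            return sp.Symbol(time_symbol)
        problems.append(f"csymbol {url!r}")
        return sp.Integer(0)
    if tag == "true":
        return sp.true
    if tag == "false":
        return sp.false
    if tag == "pi":
        return sp.pi
    if tag == "exponentiale":
        return sp.E
    if tag == "piecewise":
        pairs = []
        for child in el:
            ctag = _tag(child)
            parts = [c for c in child if isinstance(c.tag, str)]
            if ctag == "piece":
                val = _mml_node(parts[0], time_symbol, problems)
                cond = _mml_node(parts[1], time_symbol, problems)
                pairs.append((val, cond))
            elif ctag == "otherwise":
                pairs.append((_mml_node(parts[0], time_symbol, problems), sp.true))
        return sp.Piecewise(*pairs)
    if tag == "apply":
        parts = [c for c in el if isinstance(c.tag, str)]
        op = _tag(parts[0])
        args = parts[1:]
        if op in _MML_UNSUPPORTED:
            problems.append(f"MathML operator <{op}>")
            return sp.Integer(0)
        if op == "csymbol":  # delay(...) and friends
            problems.append(f"csymbol apply {parts[0].get('definitionURL', '')!r}")
            return sp.Integer(0)
        sargs = [_mml_node(a, time_symbol, problems) for a in args]
        if op == "minus":
            return -sargs[0] if len(sargs) == 1 else sargs[0] - sargs[1]
        if op == "divide":
            return sargs[0] / sargs[1]
        if op == "ln":
            return sp.log(sargs[0])
        if op == "log":
            if _tag(args[0]) == "logbase":
                basel = [c for c in args[0] if isinstance(c.tag, str)][0]
                base = _mml_node(basel, time_symbol, problems)
                return sp.log(sargs[1] if len(sargs) > 1 else sargs[-1], base)
            return sp.log(sargs[0], 10)
        if op == "root":
            if args and _tag(args[0]) == "degree":
                degl = [c for c in args[0] if isinstance(c.tag, str)][0]
                deg = _mml_node(degl, time_symbol, problems)
                return sp.Pow(sargs[-1], 1 / deg)
            return sp.sqrt(sargs[0])
        fn = _MML_BINOPS.get(op)
        if fn is None:
            problems.append(f"MathML operator <{op}>")
            return sp.Integer(0)
        return fn(*sargs)
    if tag in ("logbase", "degree"):
        parts = [c for c in el if isinstance(c.tag, str)]
        return _mml_node(parts[0], time_symbol, problems)
    problems.append(f"MathML element <{tag}>")
    return sp.Integer(0)


def _mml_number(el):
    ntype = el.get("type", "real")
    if ntype == "integer":
        return sp.Integer(int(el.text.strip()))
    if ntype == "rational":
        parts = el.text.split() if el.text else []
        nums = [t for t in el.itertext()]
        joined = " ".join(nums).split()
        if len(joined) >= 2:
            return sp.Rational(int(joined[0]), int(joined[1]))
        return sp.Rational(int(parts[0]))
    if ntype == "e-notation":
        joined = " ".join(el.itertext()).split()
        return sp.Float(float(f"{joined[0]}e{joined[1]}"))
    value = float(el.text.strip())
    if value == int(value) and abs(value) < 1e15:
        return sp.Integer(int(value))
    return sp.Float(value)


def _E(tag, *children, text=None, **attrib):
    el = etree.Element(f"{{{MATHML_NS}}}{tag}", **{k: str(v) for k, v in attrib.items()})
    if text is not None:
        el.text = str(text)
    for c in children:
        el.append(c)
    return el


def _sympy_to_mml(expr, time_symbol: str):
    if isinstance(expr, sp.Symbol):
        if expr.name == time_symbol:
            return _E("csymbol", text=time_symbol, definitionURL=TIME_URI,
                      encoding="text")
        return _E("ci", text=expr.name)
    if expr is sp.true:
        return _E("true")
    if expr is sp.false:
        return _E("false")
    if expr is sp.pi:
        return _E("pi")
    if expr is sp.E:
        return _E("exponentiale")
    if isinstance(expr, sp.Integer):
        return _E("cn", text=int(expr), type="integer")
    if isinstance(expr, sp.Rational):
        el = _E("cn", text=str(expr.p), type="rational")
        sep = etree.SubElement(el, f"{{{MATHML_NS}}}sep")
        sep.tail = str(expr.q)
        return el
    if isinstance(expr, sp.Float):
        return _E("cn", text=repr(float(expr)))
    if expr.is_number:
        return _E("cn", text=repr(float(expr)))
    rec = lambda e: _sympy_to_mml(e, time_symbol)  # noqa: E731
    if isinstance(expr, sp.Add):
        return _E("apply", _E("plus"), *map(rec, expr.args))
    if isinstance(expr, sp.Mul):
        return _E("apply", _E("times"), *map(rec, expr.args))
    if isinstance(expr, sp.Pow):
        return _E("apply", _E("power"), rec(expr.base), rec(expr.exp))
    if isinstance(expr, sp.exp):
        return _E("apply", _E("exp"), rec(expr.args[0]))
    if isinstance(expr, sp.log):
        if len(expr.args) == 1:
            return _E("apply", _E("ln"), rec(expr.args[0]))
        return _E("apply", _E("log"), _E("logbase", rec(expr.args[1])), rec(expr.args[0]))
    if isinstance(expr, sp.Min):
        return _E("apply", _E("min"), *map(rec, expr.args))
    if isinstance(expr, sp.Max):
        return _E("apply", _E("max"), *map(rec, expr.args))
    if isinstance(expr, sp.Abs):
        return _E("apply", _E("abs"), rec(expr.args[0]))
    if isinstance(expr, sp.floor):
        return _E("apply", _E("floor"), rec(expr.args[0]))
    if isinstance(expr, sp.ceiling):
        return _E("apply", _E("ceiling"), rec(expr.args[0]))
    if isinstance(expr, (sp.sin, sp.cos, sp.tan)):
        return _E("apply", _E(type(expr).__name__), rec(expr.args[0]))
    if isinstance(expr, sp.Piecewise):
        pw = _E("piecewise")
        for value, cond in expr.args:
            if cond is sp.true:
                pw.append(_E("otherwise", rec(value)))
            else:
                pw.append(_E("piece", rec(value), rec(cond)))
        return pw
    relmap = {sp.Lt: "lt", sp.Le: "leq", sp.Gt: "gt", sp.Ge: "geq",
              sp.Eq: "eq", sp.Ne: "neq"}
    for cls, tag in relmap.items():
        if isinstance(expr, cls):
            return _E("apply", _E(tag), rec(expr.lhs), rec(expr.rhs))
    if isinstance(expr, sp.And):
        return _E("apply", _E("and"), *map(rec, expr.args))
    if isinstance(expr, sp.Or):
        return _E("apply", _E("or"), *map(rec, expr.args))
    if isinstance(expr, sp.Not):
        return _E("apply", _E("not"), rec(expr.args[0]))
    raise SbmlExportError(f"cannot serialize expression node {type(expr).__name__}")


def _math_element(expr, time_symbol):
    m = etree.Element(f"{{{MATHML_NS}}}math")
    m.append(_sympy_to_mml(expr, time_symbol))
    return m


# --------------------------------------------------------------------------
# SBML reading
# --------------------------------------------------------------------------

def read_sbml(source: Union[bytes, str, io.IOBase]) -> tuple:
    """Read an SBML L3-core-subset document into ``(Diagram, MathModel)``."""
    data = _as_bytes(source)
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise SbmlImportError(f"malformed XML: {exc}") from exc
    problems: list[str] = []
    for prefix, uri in (root.nsmap or {}).items():
        if uri and "sbml" in uri and "/core" not in uri and uri != SBML_NS:
            pkg = uri.rstrip("/").split("/")[-2] if "/version" in uri else uri
            problems.append(f"SBML package namespace {uri!r} ({prefix or pkg})")
    model_el = root.find(f"{{{SBML_NS}}}model")
    if model_el is None:
        # tolerate other level namespaces for the error message only
        raise SbmlImportError("document has no <model> in the SBML L3 core namespace")

    model = MathModel(name=model_el.get("id", model_el.get("name", "model")))
    seen_ids = set()

    def claim(sid, what):
        if sid in seen_ids:
            raise SbmlImportError(f"duplicate id {sid!r} ({what})")
        seen_ids.add(sid)

    comps = _list_of(model_el, "listOfCompartments", "compartment")
    # a sole unit compartment named "default" is the writer's implicit one
    implicit_default = (
        len(comps) == 1
        and comps[0].get("id") == "default"
        and float(comps[0].get("size", 1.0)) == 1.0
    )
    for comp in comps:
        cid = comp.get("id")
        claim(cid, "compartment")
        if not implicit_default:
            model.compartment_sizes[cid] = float(comp.get("size", 1.0))

    conc_species = []
    for spel in _list_of(model_el, "listOfSpecies", "species"):
        sid = spel.get("id")
        claim(sid, "species")
        boundary = spel.get("boundaryCondition") == "true" or spel.get("constant") == "true"
        init = spel.get("initialAmount")
        conc = spel.get("initialConcentration")
        value = 0.0
        if init is not None:
            value = float(init)
        elif conc is not None:
            value = float(conc)
            conc_species.append(sid)
        compartment = spel.get("compartment")
        if implicit_default and compartment == "default":
            compartment = None
        model.variables.append(
            Variable(
                id=sid,
                initial_value=value,
                units=spel.get("substanceUnits", ""),
                dynamics="constant-boundary" if boundary else "ode",
                compartment=compartment,
            )
        )

    for pel in _list_of(model_el, "listOfParameters", "parameter"):
        pid = pel.get("id")
        claim(pid, "parameter")
        model.parameters.append(
            Parameter(
                id=pid,
                value=float(pel.get("value", 0.0)),
                units=pel.get("units", ""),
                constant=pel.get("constant", "true") == "true",
            )
        )

    time_symbol = model.time_symbol
    for rel in _list_of(model_el, "listOfRules", None):
        tag = _tag(rel)
        math = rel.find(f"{{{MATHML_NS}}}math")
        expr = _mathml_to_sympy(math, time_symbol, problems)
        if tag == "rateRule":
            model.rules.append(Rule("rate", expr, target=rel.get("variable")))
        elif tag == "assignmentRule":
            model.rules.append(Rule("assignment", expr, target=rel.get("variable")))
            _set_dynamics(model, rel.get("variable"), "assigned")
        elif tag == "algebraicRule":
            model.rules.append(Rule("algebraic", expr))
        else:
            problems.append(f"rule element <{tag}>")

    for rxel in _list_of(model_el, "listOfReactions", "reaction"):
        rid = rxel.get("id")
        claim(rid, "reaction")
        rx = Reaction(
            id=rid,
            reversible=rxel.get("reversible", "false") == "true",
            fast=rxel.get("fast", "false") == "true",
        )
        for ref in _list_of(rxel, "listOfReactants", "speciesReference"):
            rx.reactants.append((ref.get("species"), _stoich(ref)))
        for ref in _list_of(rxel, "listOfProducts", "speciesReference"):
            rx.products.append((ref.get("species"), _stoich(ref)))
        for ref in _list_of(rxel, "listOfModifiers", "modifierSpeciesReference"):
            rx.modifiers.append(ref.get("species"))
        kl = rxel.find(f"{{{SBML_NS}}}kineticLaw")
        if kl is not None:
            for lp in _list_of(kl, "listOfLocalParameters", "localParameter"):
                problems.append(f"local parameter {lp.get('id')!r} in reaction {rid!r}")
            math = kl.find(f"{{{MATHML_NS}}}math")
            if math is not None:
                rx.kinetic_law = _mathml_to_sympy(math, time_symbol, problems)
        model.reactions.append(rx)

    for evel in _list_of(model_el, "listOfEvents", "event"):
        eid = evel.get("id") or f"event{len(model.events)}"
        trig_el = evel.find(f"{{{SBML_NS}}}trigger")
        trigger = sp.false
        if trig_el is not None:
            math = trig_el.find(f"{{{MATHML_NS}}}math")
            trigger = _mathml_to_sympy(math, time_symbol, problems)
        delay = 0.0
        delay_el = evel.find(f"{{{SBML_NS}}}delay")
        if delay_el is not None:
            delay = _mathml_to_sympy(
                delay_el.find(f"{{{MATHML_NS}}}math"), time_symbol, problems
            )
        ev = Event(
            id=eid,
            trigger=trigger,
            delay=delay,
            use_trigger_time_values=evel.get("useValuesFromTriggerTime", "false") == "true",
            halt=evel.get("sboTerm") == "SBO:0000354",
        )
        for ea in _list_of(evel, "listOfEventAssignments", "eventAssignment"):
            expr = _mathml_to_sympy(ea.find(f"{{{MATHML_NS}}}math"), time_symbol, problems)
            ev.assignments.append((ea.get("variable"), expr))
        model.events.append(ev)

    for cel in _list_of(model_el, "listOfConstraints", "constraint"):
        math = cel.find(f"{{{MATHML_NS}}}math")
        cond = _mathml_to_sympy(math, time_symbol, problems)
        msg_el = cel.find(f"{{{SBML_NS}}}message")
        message = " ".join("".join(msg_el.itertext()).split()) if msg_el is not None else ""
        model.constraints.append(
            Constraint(id=cel.get("id") or f"c{len(model.constraints)}", condition=cond,
                       message=message)
        )

    # fold initial assignments into initial values
    env = model.initial_env()
    for ia in _list_of(model_el, "listOfInitialAssignments", "initialAssignment"):
        sym = ia.get("symbol")
        expr = _mathml_to_sympy(ia.find(f"{{{MATHML_NS}}}math"), time_symbol, problems)
        value = ex.evaluate(expr, env)
        env[sym] = value
        _set_initial(model, sym, value)

    # concentration-initialized species: canonical state is amount
    for sid in conc_species:
        var = model.variable(sid)
        size = model.compartment_sizes.get(var.compartment, 1.0)
        var.initial_value = var.initial_value * size

    if problems:
        raise SbmlImportError(
            "unsupported SBML constructs: " + "; ".join(sorted(set(problems)))
        )
    diagram = diagram_from_math(model)
    return diagram, model


def _list_of(parent, list_tag, child_tag):
    holder = parent.find(f"{{{SBML_NS}}}{list_tag}") if list_tag else parent
    if list_tag and holder is None:
        return []
    if child_tag is None:
        return [c for c in holder if isinstance(c.tag, str)]
    return holder.findall(f"{{{SBML_NS}}}{child_tag}")


def _stoich(ref) -> Fraction:
    return Fraction(ref.get("stoichiometry", "1")).limit_denominator(10**6)


def _set_dynamics(model, vid, dynamics):
    for v in model.variables:
        if v.id == vid:
            v.dynamics = dynamics


def _set_initial(model, sym, value):
    for v in model.variables:
        if v.id == sym:
            v.initial_value = value
            return
    for p in model.parameters:
        if p.id == sym:
            p.value = value
            return
    if sym in model.compartment_sizes:
        model.compartment_sizes[sym] = value


def _as_bytes(source) -> bytes:
    if isinstance(source, bytes):
        return source
    if isinstance(source, str):
        if source.lstrip().startswith("<"):
            return source.encode()
        with open(source, "rb") as fh:
            return fh.read()
    data = source.read()
    return data.encode() if isinstance(data, str) else data


# --------------------------------------------------------------------------
# SBML writing
# --------------------------------------------------------------------------

def write_sbml(diagram: Diagram, model: MathModel) -> bytes:
    """Serialize a validated flat model to SBML L3V2-core-subset XML."""
    if isinstance(model, ModularModel) or isinstance(diagram, ModularModel):
        raise SbmlExportError("modular models cannot be exported to SBML; flatten first")
    if any(n.kind == "module" for n in diagram.nodes.values()):
        raise SbmlExportError("diagram contains module nodes; flatten first")
    diags = validate(diagram, model)
    if diags:
        raise SbmlExportError(
            "model fails validation: " + "; ".join(str(d) for d in diags)
        )
    nsmap = {None: SBML_NS}
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap, level="3", version="2")
    mel = etree.SubElement(root, f"{{{SBML_NS}}}model", id=model.name)
    ts = model.time_symbol

    def sub(parent, tag, **attrib):
        return etree.SubElement(parent, f"{{{SBML_NS}}}{tag}",
                                **{k: str(v) for k, v in attrib.items()})

    if model.compartment_sizes:
        lst = sub(mel, "listOfCompartments")
        for cid, size in model.compartment_sizes.items():
            sub(lst, "compartment", id=cid, size=_num(size), constant="true")
    if model.variables:
        species = [v for v in model.variables]
        lst = sub(mel, "listOfSpecies")
        for v in species:
            attrib = {
                "id": v.id,
                "initialAmount": _num(v.initial_value),
                "hasOnlySubstanceUnits": "true",
                "boundaryCondition": "true" if v.dynamics == "constant-boundary" else "false",
                "constant": "true" if v.dynamics == "constant-boundary" else "false",
            }
            if v.compartment:
                attrib["compartment"] = v.compartment
            elif model.compartment_sizes:
                attrib["compartment"] = next(iter(model.compartment_sizes))
            else:
                attrib["compartment"] = "default"
            if v.units:
                attrib["substanceUnits"] = v.units
            sub(lst, "species", **attrib)
        if not model.compartment_sizes:
            lst_c = etree.Element(f"{{{SBML_NS}}}listOfCompartments")
            c = etree.SubElement(lst_c, f"{{{SBML_NS}}}compartment",
                                 id="default", size="1", constant="true")
            c.tail = None
            mel.insert(0, lst_c)
    if model.parameters:
        lst = sub(mel, "listOfParameters")
        for p in model.parameters:
            attrib = {"id": p.id, "value": _num(p.value),
                      "constant": "true" if p.constant else "false"}
            if p.units:
                attrib["units"] = p.units
            sub(lst, "parameter", **attrib)
    if model.rules:
        lst = sub(mel, "listOfRules")
        for rule in model.rules:
            tag = {"rate": "rateRule", "assignment": "assignmentRule",
                   "algebraic": "algebraicRule"}[rule.kind]
            attrib = {"variable": rule.target} if rule.target else {}
            rel = sub(lst, tag, **attrib)
            rel.append(_math_element(rule.expression, ts))
    if model.constraints:
        lst = sub(mel, "listOfConstraints")
        for c in model.constraints:
            cel = sub(lst, "constraint", id=c.id)
            cel.append(_math_element(c.condition, ts))
            if c.message:
                msg = sub(cel, "message")
                p = etree.SubElement(msg, "{http://www.w3.org/1999/xhtml}p",
                                     nsmap={None: "http://www.w3.org/1999/xhtml"})
                p.text = c.message
    if model.reactions:
        lst = sub(mel, "listOfReactions")
        for r in model.reactions:
            attrib = {"id": r.id, "reversible": "true" if r.reversible else "false"}
            if r.fast:
                attrib["fast"] = "true"
            rel = sub(lst, "reaction", **attrib)
            if r.reactants:
                lr = sub(rel, "listOfReactants")
                for sid, st in r.reactants:
                    sub(lr, "speciesReference", species=sid,
                        stoichiometry=_num(st), constant="true")
            if r.products:
                lp = sub(rel, "listOfProducts")
                for sid, st in r.products:
                    sub(lp, "speciesReference", species=sid,
                        stoichiometry=_num(st), constant="true")
            if r.modifiers:
                lm = sub(rel, "listOfModifiers")
                for sid in r.modifiers:
                    sub(lm, "modifierSpeciesReference", species=sid)
            if r.kinetic_law is not None:
                kl = sub(rel, "kineticLaw")
                kl.append(_math_element(r.kinetic_law, ts))
    if model.events:
        lst = sub(mel, "listOfEvents")
        for e in model.events:
            evel = sub(lst, "event", id=e.id,
                       useValuesFromTriggerTime="true" if e.use_trigger_time_values else "false")
            if e.halt:
                evel.set("sboTerm", "SBO:0000354")  # marker carried through round-trip
            trig = sub(evel, "trigger", initialValue="false", persistent="true")
            trig.append(_math_element(e.trigger, ts))
            if _nonzero_delay(e.delay):
                dl = sub(evel, "delay")
                dexpr = e.delay if isinstance(e.delay, sp.Basic) else sp.Float(e.delay)
                dl.append(_math_element(dexpr, ts))
            if e.assignments:
                la = sub(evel, "listOfEventAssignments")
                for tgt, expr in e.assignments:
                    ea = sub(la, "eventAssignment", variable=tgt)
                    ea.append(_math_element(expr, ts))
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _nonzero_delay(delay) -> bool:
    if isinstance(delay, sp.Basic):
        return delay != sp.Integer(0) and delay != sp.Float(0.0)
    return float(delay) != 0.0


def _num(x) -> str:
    if isinstance(x, Fraction):
        return _num(float(x)) if x.denominator != 1 else str(x.numerator)
    x = float(x)
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


# --------------------------------------------------------------------------
# Text format
# --------------------------------------------------------------------------

_RE_REACTION = re.compile(r"^(fast\s+)?(?:([A-Za-z_]\w*)\s*:)?\s*(.*?)\s*(<->|->)\s*(.*?)\s*;\s*(.+)$")
_RE_EVENT = re.compile(r"^at\s*\((.+?)\)\s*(delay\s+\S+)?\s*(useTriggerValues)?\s*:\s*(.+)$")
_RE_CONSTRAINT = re.compile(r'^constraint\s*\((.+?)\)\s*(?::\s*"(.*)")?\s*$')
_RE_CONNECT = re.compile(
    r"^connect\s+(\w+)\.(\w+)\s*(=|->)\s*(\w+)\.(\w+)"
    r"(?:\s+master\s+(\w+)\.(\w+))?(?:\s+factor\s+(\S+))?\s*$"
)


def read_text(source: Union[str, io.IOBase]):
    """Parse the bundled text format.

    Returns ``(Diagram, MathModel)`` for a flat model and a
    :class:`ModularModel` when the source contains ``module`` blocks.
    """
    text = _as_text(source)
    lines = text.splitlines()
    blocks, connections, engines, name = _split_modules(lines)
    if blocks is None:  # flat model
        return _parse_flat(lines, name or "model")
    modules = {}
    for mod_name, mod_lines in blocks.items():
        modules[mod_name] = _parse_flat(mod_lines, mod_name)
    conns = []
    for lineno, m in connections:
        m1, s1, arrow, m2, s2, mm_, ms, factor = m.groups()
        kind = "directed" if arrow == "->" else "undirected"
        conn = Connection(
            kind=kind,
            endpoints=[(m1, s1), (m2, s2)],
            master=(mm_, ms) if mm_ else (None if kind == "directed" else (m1, s1)),
            factor=float(factor) if factor else 1.0,
        )
        conns.append(conn)
    mm = compose(modules, conns, name=name or "modular")
    for mod, engine in engines:
        mm.engines[mod] = engine
    return mm


def _as_text(source) -> str:
    if isinstance(source, str):
        if "\n" in source or (":" in source and ";" in source) or "=" in source:
            # heuristically treat as content unless it is an existing path
            import os

            if not ("\n" in source) and os.path.exists(source):
                with open(source) as fh:
                    return fh.read()
            return source
        with open(source) as fh:
            return fh.read()
    data = source.read()
    return data.decode() if isinstance(data, bytes) else data


def _strip_comment(line: str) -> str:
    for marker in ("#", "//"):
        # keep markers inside quotes
        depth = False
        out = []
        i = 0
        while i < len(line):
            ch = line[i]
            if ch == '"':
                depth = not depth
            if not depth and line[i:].startswith(marker):
                return "".join(out)
            out.append(ch)
            i += 1
        line = "".join(out)
    return line


def _split_modules(lines):
    blocks = {}
    connections = []
    engines = []
    name = None
    current = None
    has_modules = any(_strip_comment(l).strip().startswith("module ") for l in lines)
    if not has_modules:
        for l in lines:
            s = _strip_comment(l).strip()
            if s.startswith("model "):
                name = s.split(None, 1)[1].strip()
        return None, [], [], name
    for lineno, raw in enumerate(lines, 1):
        s = _strip_comment(raw).strip()
        if not s:
            continue
        if s.startswith("model "):
            name = s.split(None, 1)[1].strip()
        elif s.startswith("module "):
            current = s.split(None, 1)[1].strip()
            blocks[current] = []
        elif s == "end":
            current = None
        elif current is not None:
            blocks[current].append(raw)
        elif s.startswith("connect "):
            m = _RE_CONNECT.match(s)
            if not m:
                raise TextSyntaxError(f"bad connect statement: {s!r}", lineno)
            connections.append((lineno, m))
        elif s.startswith("engine "):
            parts = s.split()
            if len(parts) != 3:
                raise TextSyntaxError(f"bad engine statement: {s!r}", lineno)
            engines.append((parts[1], parts[2]))
        else:
            raise TextSyntaxError(f"statement outside module block: {s!r}", lineno)
    return blocks, connections, engines, name


def _parse_flat(lines, name):
    model = MathModel(name=name)
    declared_species = {}
    boundary = set()
    assignments = {}
    compartment_of = {}
    order = []  # declaration order of species

    def note_species(sid):
        if sid not in declared_species:
            declared_species[sid] = 0.0
            order.append(sid)

    for lineno, raw in enumerate(lines, 1):
        s = _strip_comment(raw).strip()
        if not s or s.startswith("model "):
            continue
        try:
            if s.startswith("compartment "):
                body = s[len("compartment "):]
                cid, _, value = body.partition("=")
                model.compartment_sizes[cid.strip()] = float(value.strip() or 1.0)
            elif s.startswith("species "):
                body = s[len("species "):]
                lhs, _, rhs = body.partition("=")
                sid = lhs.strip()
                comp = None
                rhs = rhs.strip()
                if " in " in f" {rhs} ":
                    rhs, _, comp = rhs.rpartition(" in ")
                    comp = comp.strip()
                if sid.startswith("$"):
                    sid = sid[1:]
                    boundary.add(sid)
                note_species(sid)
                declared_species[sid] = float(rhs.strip()) if rhs.strip() else 0.0
                if comp:
                    compartment_of[sid] = comp
            elif s.startswith(("const ", "param ")):
                body = s.split(None, 1)[1]
                pid, _, value = body.partition("=")
                assignments[pid.strip()] = float(value.strip())
            elif s.startswith("rate "):
                body = s[len("rate "):]
                tgt, _, expr = body.partition("=")
                model.rules.append(Rule("rate", ex.parse_expression(expr), target=tgt.strip()))
            elif s.startswith("assign "):
                body = s[len("assign "):]
                tgt, _, expr = body.partition("=")
                model.rules.append(
                    Rule("assignment", ex.parse_expression(expr), target=tgt.strip())
                )
            elif s.startswith("algebraic "):
                body = s[len("algebraic "):]
                lhs, _, expr = body.partition("=")
                model.rules.append(Rule("algebraic", ex.parse_expression(expr)))
            elif s.startswith("at "):
                m = _RE_EVENT.match(s)
                if not m:
                    raise TextSyntaxError(f"bad event statement: {s!r}", lineno)
                cond, delay_s, utv, actions = m.groups()
                ev = Event(
                    id=f"e{len(model.events) + 1}",
                    trigger=ex.parse_expression(cond),
                    use_trigger_time_values=bool(utv),
                )
                if delay_s:
                    ev.delay = ex.parse_expression(delay_s.split(None, 1)[1])
                for part in _split_top(actions, ","):
                    part = part.strip()
                    if part.startswith("halt"):
                        ev.halt = True
                        mmsg = re.search(r'"(.*)"', part)
                        ev.message = mmsg.group(1) if mmsg else ""
                        continue
                    tgt, _, expr = part.partition("=")
                    ev.assignments.append((tgt.strip(), ex.parse_expression(expr)))
                model.events.append(ev)
            elif s.startswith("constraint"):
                m = _RE_CONSTRAINT.match(s)
                if not m:
                    raise TextSyntaxError(f"bad constraint statement: {s!r}", lineno)
                cond, msg = m.groups()
                model.constraints.append(
                    Constraint(
                        id=f"c{len(model.constraints) + 1}",
                        condition=ex.parse_expression(cond),
                        message=msg or "",
                    )
                )
            elif _RE_REACTION.match(s):
                m = _RE_REACTION.match(s)
                fast, rid, lhs, arrow, rhs, law = m.groups()
                rid = rid or f"J{len(model.reactions) + 1}"
                rx = Reaction(id=rid, fast=bool(fast), reversible=arrow == "<->")
                rx.reactants = _parse_side(lhs, lineno)
                rx.products = _parse_side(rhs, lineno)
                for sid, _ in rx.reactants + rx.products:
                    note_species(sid)
                rx.kinetic_law = ex.parse_expression(law)
                model.reactions.append(rx)
            elif "=" in s:
                lhs, _, rhs = s.partition("=")
                assignments[lhs.strip()] = float(rhs.strip())
            else:
                raise TextSyntaxError(f"unrecognized statement: {s!r}", lineno)
        except TextSyntaxError:
            raise
        except Exception as exc:
            raise TextSyntaxError(f"{exc}", lineno) from exc

    # rule targets that are not parameters become variables
    rule_targets = {r.target for r in model.rules if r.target}
    species_ids = set(order)
    for tgt in rule_targets:
        if tgt not in species_ids and tgt not in assignments:
            note_species(tgt)
    for sid, value in assignments.items():
        if sid in declared_species:
            declared_species[sid] = value
    for sid in order:
        dynamics = "ode"
        if sid in boundary:
            dynamics = "constant-boundary"
        for r in model.rules:
            if r.target == sid and r.kind == "assignment":
                dynamics = "assigned"
        model.variables.append(
            Variable(
                id=sid,
                initial_value=declared_species[sid],
                dynamics=dynamics,
                compartment=compartment_of.get(sid),
            )
        )
    species_ids = {v.id for v in model.variables}
    for pid, value in assignments.items():
        if pid not in species_ids:
            model.parameters.append(Parameter(id=pid, value=value))
    # modifiers: species in the law that are neither reactants nor products
    for r in model.reactions:
        named = {sid for sid, _ in r.reactants} | {sid for sid, _ in r.products}
        if r.kinetic_law is not None:
            for sym in sorted(ex.free_symbols(r.kinetic_law)):
                if sym in species_ids and sym not in named:
                    r.modifiers.append(sym)
    diagram = diagram_from_math(model)
    return diagram, model


def _parse_side(side: str, lineno) -> list:
    side = side.strip()
    if not side:
        return []
    out = []
    for term in side.split("+"):
        term = term.strip()
        if not term:
            continue
        m = re.match(r"^(\d+(?:/\d+)?)\s*\*?\s*([A-Za-z_]\w*)$", term)
        if m:
            out.append((m.group(2), Fraction(m.group(1))))
        elif re.match(r"^[A-Za-z_]\w*$", term):
            out.append((term, Fraction(1)))
        else:
            raise TextSyntaxError(f"bad species term {term!r}", lineno)
    return out


def _split_top(text: str, sep: str) -> list:
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth -= 1
        if ch == sep and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return parts


def write_text(obj, model: MathModel = None) -> str:
    """Serialize a flat or modular model to the text format."""
    if isinstance(obj, ModularModel):
        out = [f"model {obj.name}", ""]
        for mod_name in obj.modules:
            _, math = obj.modules[mod_name]
            out.append(f"module {mod_name}")
            out.extend("  " + l for l in _flat_lines(math))
            out.append("end")
            out.append("")
        for conn in obj.connections:
            (m1, s1), (m2, s2) = conn.endpoints[0], conn.endpoints[1]
            if conn.kind == "directed":
                line = f"connect {m1}.{s1} -> {m2}.{s2}"
            else:
                line = f"connect {m1}.{s1} = {m2}.{s2}"
                if conn.master:
                    line += f" master {conn.master[0]}.{conn.master[1]}"
            if conn.factor != 1.0:
                line += f" factor {_num(conn.factor)}"
            out.append(line)
        for mod, engine in obj.engines.items():
            out.append(f"engine {mod} {engine}")
        return "\n".join(out) + "\n"
    diagram, math = (obj, model) if model is not None else (None, obj)
    return "\n".join([f"model {math.name}", ""] + _flat_lines(math)) + "\n"


def _flat_lines(model: MathModel) -> list:
    out = []
    for cid, size in model.compartment_sizes.items():
        out.append(f"compartment {cid} = {_num(size)}")
    for v in model.variables:
        prefix = "$" if v.dynamics == "constant-boundary" else ""
        line = f"species {prefix}{v.id} = {_num(v.initial_value)}"
        if v.compartment:
            line += f" in {v.compartment}"
        out.append(line)
    for p in model.parameters:
        out.append(f"const {p.id} = {_num(p.value)}")
    for r in model.reactions:
        arrow = "<->" if r.reversible else "->"
        lhs = " + ".join(_side_term(sid, st) for sid, st in r.reactants)
        rhs = " + ".join(_side_term(sid, st) for sid, st in r.products)
        law = ex.format_expression(r.kinetic_law) if r.kinetic_law is not None else "0"
        prefix = "fast " if r.fast else ""
        out.append(f"{prefix}{r.id}: {lhs} {arrow} {rhs}; {law}")
    for rule in model.rules:
        expr = ex.format_expression(rule.expression)
        if rule.kind == "rate":
            out.append(f"rate {rule.target} = {expr}")
        elif rule.kind == "assignment":
            out.append(f"assign {rule.target} = {expr}")
        else:
            out.append(f"algebraic 0 = {expr}")
    for e in model.events:
        head = f"at ({ex.format_expression(e.trigger)})"
        if _nonzero_delay(e.delay):
            dexpr = e.delay if isinstance(e.delay, sp.Basic) else sp.Float(e.delay)
            head += f" delay {ex.format_expression(dexpr)}"
        if e.use_trigger_time_values:
            head += " useTriggerValues"
        actions = [f"{tgt} = {ex.format_expression(expr)}" for tgt, expr in e.assignments]
        if e.halt:
            actions.append(f'halt "{e.message}"')
        out.append(f"{head}: {', '.join(actions)}")
    for c in model.constraints:
        out.append(f'constraint ({ex.format_expression(c.condition)}): "{c.message}"')
    return out


def _side_term(sid, st) -> str:
    st = Fraction(st)
    if st == 1:
        return sid
    if st.denominator == 1:
        return f"{st.numerator} {sid}"
    return f"{st} {sid}"


# --------------------------------------------------------------------------
# Observation tables
# --------------------------------------------------------------------------

def read_timecourse(source, steady_state: bool = False, name: str = "experiment"):
    """Read a delimited observation table into :class:`fitting.ExperimentData`.

    First column is time unless ``steady_state`` is set; remaining columns are
    observed symbols.  Comma-delimited, tab auto-detected; blank cells are
    retained and marked missing.  Raises on non-numeric cells and duplicate
    time points.
    """
    from .fitting import ExperimentData

    if hasattr(source, "read"):
        content = source.read()
        content = content.decode() if isinstance(content, bytes) else content
    else:
        with open(source) as fh:
            content = fh.read()
    sep = "\t" if "\t" in content.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(content), sep=sep)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise ValueError(
                f"non-numeric cell in column {col!r}: {bad.iloc[0]!r}"
                if len(bad)
                else f"non-numeric column {col!r}"
            )
    if steady_state:
        return ExperimentData.from_frame(df, kind="steady_state", name=name)
    times = df.iloc[:, 0].to_numpy(dtype=float)
    if len(np.unique(times)) != len(times):
        raise ValueError("duplicate time points in time-course table")
    return ExperimentData.from_frame(df, kind="time_course", name=name)
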