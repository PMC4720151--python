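"""Readers, writers and exporters.

Formats
-------
- BoolNet-style rule text (``targets, factors`` header; operators ``&``,
  ``|``, ``!``). Input nodes are declared with an empty factor or an
  explicit ``0``. Lossless round trip for any network.
- SBML-qual (Level 3 ``qual`` package, the qualitative-species +
  function-terms subset): import/export of Boolean models.
- Network exports: SIF and GraphML with a ``sign`` edge attribute, DOT.
- Result tables: attractor and mutant-scan CSV/JSON, trajectory CSV,
  fate-map GraphML/DOT.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import networkx as nx
import pandas as pd
from lxml import etree

from .expr import ExpressionError, parse_expression
from .network import (
    CORE_NODES,
    Interaction,
    LogicRule,
    NetworkError,
    NodeSpec,
    RegulatoryNetwork,
    Sign,
    extract_interactions,
)

if TYPE_CHECKING:  # pragma: no cover
    from .boolean import DiscreteAttractor
    from .continuous import ContinuousAttractor
    from .fate import FateMap, Trajectory

__all__ = [
    "ParseError",
    "parse_boolnet",
    "write_boolnet",
    "read_network",
    "write_network",
    "write_sif",
    "write_graphml",
    "write_dot",
    "read_sbml_qual",
    "write_sbml_qual",
    "attractor_table",
    "continuous_attractor_table",
    "write_fate_map_graphml",
    "write_fate_map_dot",
    "trajectory_table",
]


class ParseError(ValueError):
    """Syntax or validation error in a model file, with line information."""


# -- BoolNet-style text ------------------------------------------------------


def parse_boolnet(text: str, name: str = "network") -> RegulatoryNetwork:
    rules: dict[str, str] = {}
    inputs: list[str] = []
    targets_seen: dict[str, int] = {}
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not header_seen and line.lower().replace(" ", "") == "targets,factors":
            header_seen = True
            continue
        if "," not in line:
            raise ParseError(f"line {lineno}: expected 'target, factors', got {line!r}")
        target, factor = (part.strip() for part in line.split(",", 1))
        if not target:
            raise ParseError(f"line {lineno}: empty target name")
        if target in targets_seen:
            raise ParseError(
                f"line {lineno}: duplicate target {target!r} "
                f"(first declared on line {targets_seen[target]})"
            )
        targets_seen[target] = lineno
        if factor in ("", "0"):
            inputs.append(target)
        else:
            rules[target] = factor
    if not targets_seen:
        raise ParseError("no rules found")
    try:
        net = RegulatoryNetwork.from_rules(rules, inputs=inputs, name=name)
    except (ExpressionError, NetworkError) as exc:
        raise ParseError(str(exc)) from exc
    # reject rules that mention nodes never declared as a target
    undeclared = set(net.node_names) - set(targets_seen)
    if undeclared:
        raise ParseError(
            "rule(s) reference undeclared node(s): " + ", ".join(sorted(undeclared))
        )
    return net


def write_boolnet(net: RegulatoryNetwork) -> str:
    lines = ["targets, factors"]
    for node in net.nodes:
        if node.is_input:
            lines.append(f"{node.name}, 0")
        else:
            lines.append(f"{node.name}, {net.rules[node.name].expression.to_text()}")
    return "\n".join(lines) + "\n"


def read_network(path: str | Path, format: str = "boolnet_text") -> RegulatoryNetwork:
    path = Path(path)
    if format == "boolnet_text":
        return parse_boolnet(path.read_text("utf-8"), name=path.stem)
    if format == "sbml_qual":
        return read_sbml_qual(path)
    raise ValueError(f"unknown model format {format!r}")


def write_network(net: RegulatoryNetwork, path: str | Path, format: str = "boolnet_text") -> None:
    path = Path(path)
    if format == "boolnet_text":
        path.write_text(write_boolnet(net), "utf-8")
    elif format == "sbml_qual":
        write_sbml_qual(net, path)
    else:
        raise ValueError(f"unknown model format {format!r}")


# -- graph exports -----------------------------------------------------------


def _interaction_graph(net: RegulatoryNetwork) -> nx.DiGraph:
    g = nx.DiGraph(name=net.name)
    for node in net.nodes:
        g.add_node(node.name, is_input=node.is_input, category=node.category.value)
    for edge in extract_interactions(net):
        g.add_edge(edge.source, edge.target, sign=edge.sign.value)
    return g


def write_sif(net: RegulatoryNetwork, path: str | Path) -> None:
    lines = [
        f"{e.source}\t{'activates' if e.sign is Sign.POSITIVE else 'inhibits'}\t{e.target}"
        for e in extract_interactions(net)
    ]
    Path(path).write_text("\n".join(lines) + "\n", "utf-8")


def write_graphml(net: RegulatoryNetwork, path: str | Path) -> None:
    nx.write_graphml(_interaction_graph(net), str(path))


def write_dot(net: RegulatoryNetwork, path: str | Path) -> None:
    lines = [f'digraph "{net.name}" {{']
    for node in net.nodes:
        shape = "box" if node.is_input else "ellipse"
        lines.append(f'  "{node.name}" [shape={shape}];')
    for e in extract_interactions(net):
        style = "normal" if e.sign is Sign.POSITIVE else "tee"
        lines.append(f'  "{e.source}" -> "{e.target}" [arrowhead={style}, sign="{e.sign.symbol}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n", "utf-8")


# -- SBML-qual ---------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
_QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
_MATH_NS = "http://www.w3.org/1998/Math/MathML"


def _mathml(expr, parent) -> None:
    from .expr import And, Not, Or, Var

    if isinstance(expr, Var):
        apply = etree.SubElement(parent, f"{{{_MATH_NS}}}apply")
        etree.SubElement(apply, f"{{{_MATH_NS}}}eq")
        ci = etree.SubElement(apply, f"{{{_MATH_NS}}}ci")
        ci.text = f" {expr.name} "
        cn = etree.SubElement(apply, f"{{{_MATH_NS}}}cn")
        cn.set("type", "integer")
        cn.text = " 1 "
        return
    apply = etree.SubElement(parent, f"{{{_MATH_NS}}}apply")
    if isinstance(expr, Not):
        etree.SubElement(apply, f"{{{_MATH_NS}}}not")
        _mathml(expr.arg, apply)
    elif isinstance(expr, And):
        etree.SubElement(apply, f"{{{_MATH_NS}}}and")
        for a in expr.args:
            _mathml(a, apply)
    elif isinstance(expr, Or):
        etree.SubElement(apply, f"{{{_MATH_NS}}}or")
        for a in expr.args:
            _mathml(a, apply)
    else:  # pragma: no cover
        raise TypeError(expr)


def _parse_mathml(elem):
    from .expr import And, Not, Or, Var

    tag = etree.QName(elem).localname
    if tag == "math":
        children = [c for c in elem if isinstance(c.tag, str)]
        if len(children) != 1:
            raise ParseError("math element must contain one expression")
        return _parse_mathml(children[0])
    if tag != "apply":
        raise ParseError(f"unsupported MathML element <{tag}>")
    children = [c for c in elem if isinstance(c.tag, str)]
    op = etree.QName(children[0]).localname
    args = children[1:]
    if op == "eq":
        ci = next(c for c in args if etree.QName(c).localname == "ci")
        return Var(ci.text.strip())
    if op == "not":
        return Not(_parse_mathml(args[0]))
    if op == "and":
        parsed = [_parse_mathml(a) for a in args]
        return parsed[0] if len(parsed) == 1 else And(*parsed)
    if op == "or":
        parsed = [_parse_mathml(a) for a in args]
        return parsed[0] if len(parsed) == 1 else Or(*parsed)
    raise ParseError(f"unsupported MathML operator <{op}>")


def write_sbml_qual(net: RegulatoryNetwork, path: str | Path) -> None:
    """Export as SBML Level 3 with the qual package (Boolean subset)."""
    nsmap = {None: _SBML_NS, "qual": _QUAL_NS}
    sbml = etree.Element(f"{{{_SBML_NS}}}sbml", nsmap=nsmap)
    sbml.set("level", "3")
    sbml.set("version", "1")
    sbml.set(f"{{{_QUAL_NS}}}required", "true")
    model = etree.SubElement(sbml, f"{{{_SBML_NS}}}model")
    model.set("id", net.name)
    comps = etree.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    comp = etree.SubElement(comps, f"{{{_SBML_NS}}}compartment")
    comp.set("id", "default")
    comp.set("constant", "true")
    species = etree.SubElement(model, f"{{{_QUAL_NS}}}listOfQualitativeSpecies")
    for node in net.nodes:
        sp = etree.SubElement(species, f"{{{_QUAL_NS}}}qualitativeSpecies")
        sp.set(f"{{{_QUAL_NS}}}id", node.name)
        sp.set(f"{{{_QUAL_NS}}}compartment", "default")
        sp.set(f"{{{_QUAL_NS}}}constant", "false")
        sp.set(f"{{{_QUAL_NS}}}maxLevel", "1")
    transitions = etree.SubElement(model, f"{{{_QUAL_NS}}}listOfTransitions")
    for target in net.ruled_names:
        rule = net.rules[target]
        tr = etree.SubElement(transitions, f"{{{_QUAL_NS}}}transition")
        tr.set(f"{{{_QUAL_NS}}}id", f"tr_{target}")
        inputs = etree.SubElement(tr, f"{{{_QUAL_NS}}}listOfInputs")
        for i, src in enumerate(sorted(rule.expression.variables())):
            inp = etree.SubElement(inputs, f"{{{_QUAL_NS}}}input")
            inp.set(f"{{{_QUAL_NS}}}id", f"tr_{target}_in_{i}")
            inp.set(f"{{{_QUAL_NS}}}qualitativeSpecies", src)
            inp.set(f"{{{_QUAL_NS}}}transitionEffect", "none")
        outputs = etree.SubElement(tr, f"{{{_QUAL_NS}}}listOfOutputs")
        out = etree.SubElement(outputs, f"{{{_QUAL_NS}}}output")
        out.set(f"{{{_QUAL_NS}}}qualitativeSpecies", target)
        out.set(f"{{{_QUAL_NS}}}transitionEffect", "assignmentLevel")
        terms = etree.SubElement(tr, f"{{{_QUAL_NS}}}listOfFunctionTerms")
        default = etree.SubElement(terms, f"{{{_QUAL_NS}}}defaultTerm")
        default.set(f"{{{_QUAL_NS}}}resultLevel", "0")
        term = etree.SubElement(terms, f"{{{_QUAL_NS}}}functionTerm")
        term.set(f"{{{_QUAL_NS}}}resultLevel", "1")
        math = etree.SubElement(term, f"{{{_MATH_NS}}}math")
        _mathml(rule.expression, math)
    tree = etree.ElementTree(sbml)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def read_sbml_qual(path: str | Path) -> RegulatoryNetwork:
    """Import the Boolean subset of an SBML-qual file."""
    root = etree.parse(str(path)).getroot()
    model = root.find(f"{{{_SBML_NS}}}model")
    if model is None:
        raise ParseError("no <model> element found")
    names: list[str] = []
    for sp in model.iter(f"{{{_QUAL_NS}}}qualitativeSpecies"):
        names.append(sp.get(f"{{{_QUAL_NS}}}id"))
    rules: dict[str, LogicRule] = {}
    for tr in model.iter(f"{{{_QUAL_NS}}}transition"):
        out = tr.find(
            f"{{{_QUAL_NS}}}listOfOutputs/{{{_QUAL_NS}}}output"
        )
        target = out.get(f"{{{_QUAL_NS}}}qualitativeSpecies")
        term = tr.find(
            f"{{{_QUAL_NS}}}listOfFunctionTerms/{{{_QUAL_NS}}}functionTerm"
        )
        if term is None or term.get(f"{{{_QUAL_NS}}}resultLevel") != "1":
            raise ParseError(f"transition for {target} lacks a resultLevel-1 term")
        math = term.find(f"{{{_MATH_NS}}}math")
        rules[target] = LogicRule(target, _parse_mathml(math))
    inputs = [n for n in names if n not in rules]
    nodes = tuple(NodeSpec(n, is_input=n in inputs) for n in sorted(names, key=str.lower))
    return RegulatoryNetwork(
        nodes=nodes, rules=rules, name=model.get("id") or "network"
    )


# -- result tables -----------------------------------------------------------


def attractor_table(
    net: RegulatoryNetwork, attractors: Sequence["DiscreteAttractor"]
) -> pd.DataFrame:
    """Tidy per-attractor table: full pattern, core pattern, basin, label."""
    rows = []
    for k, att in enumerate(attractors):
        rows.append(
            {
                "attractor": k,
                "label": att.label or "",
                "period": att.period,
                "pattern": "".join(map(str, att.pattern(net))),
                "core_pattern": str(list(att.pattern(net, CORE_NODES))),
                "basin_count": att.basin_count,
                "basin_fraction": att.basin_fraction,
                **{f"state_{n}": v for n, v in zip(net.node_names, att.pattern(net))},
            }
        )
    return pd.DataFrame(rows)


def continuous_attractor_table(
    net: RegulatoryNetwork, attractors: Sequence["ContinuousAttractor"]
) -> pd.DataFrame:
    rows = []
    for k, att in enumerate(attractors):
        rows.append(
            {
                "attractor": k,
                "label": att.label or "",
                "support_count": att.support_count,
                "discovered_by": att.discovered_by,
                "residual": att.residual,
                "core_pattern": str([att.levels[n] for n in CORE_NODES if n in att.levels]),
                **{f"level_{n}": att.levels[n] for n in net.node_names},
            }
        )
    return pd.DataFrame(rows)


def trajectory_table(traj: "Trajectory") -> pd.DataFrame:
    """Long-format (time, node, level) table of a simulated trajectory."""
    rows = []
    for t, state in zip(traj.times, traj.states):
        for node, level in state.items():
            rows.append({"time": t, "node": node, "level": level})
    return pd.DataFrame(rows)


def write_fate_map_graphml(fmap: "FateMap", path: str | Path) -> None:
    nx.write_graphml(fmap.to_networkx(), str(path))


def write_fate_map_dot(fmap: "FateMap", path: str | Path) -> None:
    lines = ["digraph fatemap {"]
    for v in fmap.vertices:
        lines.append(f'  "{v}";')
    for e in fmap.edges:
        lines.append(
            f'  "{e.source}" -> "{e.destination}" [label="{e.perturbation}"];'
        )
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n", "utf-8")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", "utf-8")
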