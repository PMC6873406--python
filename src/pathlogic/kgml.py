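"""KGML parsing and compilation into logic circuits.

KEGG encodes a pathway as entries (genes, enzymes, compounds, groups, ...)
connected by typed relations.  Compilation turns that graph into a
feed-forward Boolean circuit by a fixed rule set:

* ortholog / brite / reaction / map entries are dropped — they carry no
  dynamic signalling information;
* relation subtypes that describe steady-state or purely chemical detail
  (compound, hidden compound, state change, missing interaction, and the
  post-translational modifications) are ignored;
* activation, expression and dissociation become BUF edges; inhibition and
  repression become NOT edges; indirect effects count as their direct
  counterparts;
* group entries (macromolecular complexes) and binding/association become
  AND gates over the members;
* several activating edges converging on one node combine through OR; when
  activators and inhibitors mix, the node computes
  ``OR(activators) AND NOT(i1) AND ... AND NOT(ik)``.

Entries with no incoming edges become circuit inputs.  Display names pass
through a user-supplied alias map (KEGG map labels are family names — e.g.
RAS for KRAS — and the mapping is deliberately explicit, not inferred).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from xml.etree import ElementTree

import yaml

from .circuit import Circuit

log = logging.getLogger(__name__)

__all__ = [
    "Entry",
    "Relation",
    "PathwayGraph",
    "CompileConfig",
    "CompileReport",
    "KGMLParseError",
    "parse_kgml",
    "compile_pathway",
]

DROPPED_ENTRY_TYPES = frozenset({"ortholog", "brite", "reaction", "map"})

ACTIVATING_SUBTYPES = frozenset({"activation", "expression", "indirect effect",
                                 "dissociation"})
INHIBITING_SUBTYPES = frozenset({"inhibition", "repression"})
BINDING_SUBTYPES = frozenset({"binding/association"})
IGNORED_SUBTYPES = frozenset({
    "compound", "hidden compound", "state change", "missing interaction",
    "phosphorylation", "dephosphorylation", "glycosylation", "ubiquitination",
    "methylation",
})


class KGMLParseError(ValueError):
    pass


@dataclass(frozen=True)
class Entry:
    id: str
    names: tuple[str, ...]
    type: str
    graphics_name: str = ""
    members: tuple[str, ...] = ()  # for group entries

    @property
    def display(self) -> str:
        if self.graphics_name:
            return self.graphics_name.split(",")[0].strip()
        return self.names[0] if self.names else self.id


@dataclass(frozen=True)
class Relation:
    entry1: str
    entry2: str
    subtypes: tuple[str, ...]


@dataclass
class PathwayGraph:
    name: str = ""
    entries: dict[str, Entry] = field(default_factory=dict)
    relations: list[Relation] = field(default_factory=list)

    def groups(self) -> dict[str, Entry]:
        return {eid: e for eid, e in self.entries.items() if e.type == "group"}


@dataclass
class CompileConfig:
    """Compilation options; loadable from a YAML document.

    ``aliases`` maps KEGG display names to canonical gene symbols.
    ``drop_edges`` lists ``[source_symbol, target_symbol]`` pairs to remove
    (user-curated feedback removal).  ``outputs`` fixes the output order;
    by default every sink net becomes an output, sorted by symbol.
    ``subtype_overrides`` reclassifies relation subtypes, mapping a subtype
    name to ``activation``, ``inhibition`` or ``ignore``.
    """

    aliases: dict[str, str] = field(default_factory=dict)
    drop_edges: list[tuple[str, str]] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    subtype_overrides: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, text: str) -> "CompileConfig":
        d = yaml.safe_load(text) or {}
        return cls(
            aliases=dict(d.get("aliases", {})),
            drop_edges=[tuple(e) for e in d.get("drop_edges", [])],
            outputs=list(d.get("outputs", [])),
            subtype_overrides=dict(d.get("subtype_overrides", {})),
        )

    def classify(self, subtype: str) -> str:
        """Resolve one relation subtype to act / inh / bind / ignore /
        unknown, honouring overrides."""
        override = self.subtype_overrides.get(subtype)
        if override == "ignore":
            return "ignore"
        if override == "activation":
            return "act"
        if override == "inhibition":
            return "inh"
        if subtype in IGNORED_SUBTYPES:
            return "ignore"
        if subtype in ACTIVATING_SUBTYPES:
            return "act"
        if subtype in INHIBITING_SUBTYPES:
            return "inh"
        if subtype in BINDING_SUBTYPES:
            return "bind"
        return "unknown"


@dataclass
class CompileReport:
    warnings: list[str] = field(default_factory=list)
    flagged_relations: list[Relation] = field(default_factory=list)

    def warn(self, msg: str) -> None:
        self.warnings.append(msg)
        log.warning(msg)


def parse_kgml(document: str) -> PathwayGraph:
    """Parse a KGML XML document into a raw pathway graph (no filtering)."""
    try:
        root = ElementTree.fromstring(document)
    except ElementTree.ParseError as exc:
        raise KGMLParseError(f"malformed KGML: {exc}") from exc
    if root.tag != "pathway":
        raise KGMLParseError(f"expected <pathway> root, got <{root.tag}>")

    graph = PathwayGraph(name=root.get("name", ""))
    for el in root:
        if el.tag == "entry":
            gfx = el.find("graphics")
            members = tuple(c.get("id") for c in el.findall("component"))
            entry = Entry(
                id=el.get("id"),
                names=tuple(el.get("name", "").split()),
                type=el.get("type", "other"),
                graphics_name=(gfx.get("name", "") if gfx is not None else ""),
                members=members,
            )
            graph.entries[entry.id] = entry
        elif el.tag == "relation":
            subtypes = tuple(s.get("name", "") for s in el.findall("subtype"))
            graph.relations.append(
                Relation(el.get("entry1"), el.get("entry2"), subtypes))
        elif el.tag == "reaction":
            continue  # stoichiometry is out of scope
        else:
            log.warning("unknown KGML element <%s> skipped", el.tag)

    for rel in graph.relations:
        for eid in (rel.entry1, rel.entry2):
            if eid not in graph.entries:
                raise KGMLParseError(f"relation references unknown entry {eid!r}")
    return graph


def _symbol(entry: Entry, aliases: dict[str, str]) -> str:
    name = entry.display
    return aliases.get(name, name)


def compile_pathway(graph: PathwayGraph, aliases: dict[str, str] | None = None,
                    config: CompileConfig | None = None,
                    report: CompileReport | None = None) -> Circuit:
    """Compile a parsed pathway graph into a Boolean circuit.

    Deterministic given (graph, aliases, config): entries are processed in
    sorted symbol order and the filter -> edges -> groups -> fan-in-combiner
    phases run in a fixed order, so gate ids are reproducible.
    """
    config = config or CompileConfig()
    if aliases:
        config.aliases = {**config.aliases, **aliases}
    report = report if report is not None else CompileReport()

    # phase 1: entry filtering and symbol resolution (duplicates merge)
    kept: dict[str, Entry] = {}
    symbol_of: dict[str, str] = {}
    for eid, entry in graph.entries.items():
        if entry.type in DROPPED_ENTRY_TYPES:
            continue
        kept[eid] = entry
        if entry.type != "group":
            symbol_of[eid] = _symbol(entry, config.aliases)

    # groups become AND complexes over their member symbols
    complex_members: dict[str, tuple[str, ...]] = {}
    for eid, entry in graph.groups().items():
        members = tuple(sorted(symbol_of[m] for m in entry.members
                               if m in symbol_of))
        if len(members) < 2:
            report.warn(f"group {eid} has fewer than 2 resolvable members; "
                        "skipped")
            kept.pop(eid, None)
            continue
        symbol_of[eid] = "[" + ":".join(members) + "]"
        complex_members[symbol_of[eid]] = members

    # phase 2: relation filtering and edge classification
    activators: dict[str, list[str]] = {}
    inhibitors: dict[str, list[str]] = {}

    def add_edge(kind: str, src: str, dst: str) -> None:
        if (src, dst) in {tuple(e) for e in config.drop_edges}:
            report.warn(f"edge {src} -> {dst} dropped by config")
            return
        bucket = activators if kind == "act" else inhibitors
        bucket.setdefault(dst, [])
        if src not in bucket[dst]:
            bucket[dst].append(src)

    for rel in graph.relations:
        if rel.entry1 not in kept or rel.entry2 not in kept:
            report.warn(f"relation {rel.entry1}->{rel.entry2} touches a "
                        "filtered entry; dropped")
            continue
        src, dst = symbol_of[rel.entry1], symbol_of[rel.entry2]
        classes = {s: config.classify(s) for s in rel.subtypes}
        for s, cls_ in classes.items():
            if cls_ == "unknown":
                report.warn(f"relation {src} -> {dst}: unknown subtype "
                            f"{s!r} skipped")
        effective = [s for s, c in classes.items()
                     if c in ("act", "inh", "bind")]
        if not effective:
            continue
        has_bind = any(classes[s] == "bind" for s in effective)
        has_act = any(classes[s] == "act" for s in effective)
        has_inh = any(classes[s] == "inh" for s in effective)
        if has_bind and (has_act or has_inh):
            # the rule set does not define this mix; flag rather than guess
            report.flagged_relations.append(rel)
            report.warn(f"relation {src} -> {dst} mixes binding with "
                        "activation/inhibition; flagged, binding ignored")
            has_bind = False
        if has_bind:
            # bare binding outside a declared group entry: flag and skip
            # (declared groups already produce the AND complex)
            report.flagged_relations.append(rel)
            report.warn(f"bare binding/association {src} -- {dst} outside a "
                        "group entry; flagged")
            continue
        if rel.subtypes and any(s == "dissociation" for s in effective):
            # dissociation from a complex releases (activates) the target;
            # the activating source is the complex minus the released member
            if src in complex_members and dst in complex_members[src]:
                others = [m for m in complex_members[src] if m != dst]
                for o in others:
                    add_edge("act", o, dst)
                continue
        if has_act:
            add_edge("act", src, dst)
        if has_inh:
            add_edge("inh", src, dst)

    # phase 3: build the circuit — groups first, then fan-in combiners
    circuit = Circuit()
    symbols = sorted(set(symbol_of.values())
                     | {s for v in activators.values() for s in v}
                     | {s for v in inhibitors.values() for s in v}
                     | set(activators) | set(inhibitors))
    driven = set(activators) | set(inhibitors) | set(complex_members)
    for sym in symbols:
        kind = "input" if sym not in driven else "internal"
        circuit.ensure_net(sym, kind)
        if kind == "input":
            circuit.input_order.append(sym)

    for sym in sorted(complex_members):
        circuit.add_gate("AND", complex_members[sym], sym)

    for sym in sorted(driven - set(complex_members)):
        acts = sorted(activators.get(sym, []))
        inhs = sorted(inhibitors.get(sym, []))
        if acts and not inhs:
            if len(acts) == 1:
                circuit.add_gate("BUF", acts, sym)
            else:
                circuit.add_gate("OR", acts, sym)
        elif inhs and not acts:
            if len(inhs) == 1:
                circuit.add_gate("NOT", inhs, sym)
            else:
                # repressed by several regulators: free only when all absent
                for i in inhs:
                    circuit.add_gate("NOT", [i], f"{sym}~no_{i}")
                circuit.add_gate("AND", [f"{sym}~no_{i}" for i in inhs], sym)
        else:
            # mixed regulation: OR(activators) AND NOT(each inhibitor)
            if len(acts) == 1:
                act_net = acts[0]
            else:
                act_net = f"{sym}~act"
                circuit.ensure_net(act_net)
                circuit.add_gate("OR", acts, act_net)
            inv_nets = []
            for i in inhs:
                inv = f"{sym}~no_{i}"
                circuit.ensure_net(inv)
                circuit.add_gate("NOT", [i], inv)
                inv_nets.append(inv)
            circuit.add_gate("AND", [act_net, *inv_nets], sym)

    if config.outputs:
        circuit.output_order = list(config.outputs)
    else:
        consumed = {i for g in circuit.gates for i in g.inputs}
        sinks = sorted(s for s in symbols
                       if s not in consumed and s in driven)
        circuit.output_order = sinks
    from .circuit import Net

    for sym in circuit.output_order:
        if sym in circuit.nets and circuit.nets[sym].kind == "internal":
            circuit.nets[sym] = Net(sym, circuit.nets[sym].label, "output")
    circuit.meta["source"] = {"pathway": graph.name, "compiler": "pathlogic"}
    return circuit
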