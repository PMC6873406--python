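"""Combinational Boolean circuits for signalling-pathway models.

A signalling pathway is modelled as a feed-forward digital circuit: every
gene/protein/complex is a single-bit net (1 = expressed/active, 0 = not
expressed) and every regulatory relation is a logic gate.  The circuit is
purely combinational — given one input assignment the value of every net is
uniquely determined, which is what makes exhaustive fault and intervention
analysis tractable.

Gate vocabulary
---------------
``BUF``   activation/expression (identity)
``NOT``   inhibition/repression
``OR``    combined activation by independent upstream regulators
``AND``   macromolecular complex / binding (all members required)
``MUX``   fault-injection switch: ``MUX(data, stuck, ctrl)`` routes ``data``
          when ``ctrl`` is 0 and the constant ``stuck`` value when ``ctrl``
          is 1 (the classic stuck-at fault model from digital testing).

Constant sources (e.g. stuck-at values, fault control bits) live in
:attr:`Circuit.constants` rather than in ``input_order`` so that the input
test vector keeps the biological arity of the pathway.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import networkx as nx
import yaml

__all__ = [
    "Gate",
    "Net",
    "Circuit",
    "Violation",
    "ValidationReport",
    "CircuitError",
    "StructuralError",
    "InputError",
    "TruthTableSizeError",
    "validate",
    "evaluate",
    "truth_table",
]

GATE_OPS = ("BUF", "NOT", "AND", "OR", "MUX")

#: default cap on the number of inputs truth_table() will enumerate
TRUTH_TABLE_CAP = 16


class CircuitError(Exception):
    """Base class for circuit-level errors."""


class StructuralError(CircuitError):
    """The circuit violates a structural invariant (cycle, bad arity, ...)."""


class InputError(CircuitError):
    """An input assignment does not cover the declared input nets."""


class TruthTableSizeError(CircuitError):
    """Truth-table enumeration was requested beyond the configured cap."""


@dataclass(frozen=True)
class Net:
    """A named single-bit signal.

    ``kind`` is one of ``input`` (driven by the test vector), ``internal``
    (driven by a gate or a constant source) or ``output`` (observed net).
    """

    id: str
    label: str = ""
    kind: str = "internal"

    def __post_init__(self):
        if self.kind not in ("input", "internal", "output"):
            raise ValueError(f"bad net kind {self.kind!r}")
        if not self.label:
            object.__setattr__(self, "label", self.id)


@dataclass(frozen=True)
class Gate:
    """A logic gate driving exactly one net.

    ``inputs`` is ordered; for ``MUX`` the fixed order is
    ``(data, stuck_value, control)``.
    """

    op: str
    inputs: tuple[str, ...]
    output: str

    def __post_init__(self):
        object.__setattr__(self, "inputs", tuple(self.inputs))
        if self.op not in GATE_OPS:
            raise ValueError(f"unknown gate op {self.op!r}")

    def arity_ok(self) -> bool:
        n = len(self.inputs)
        if self.op in ("BUF", "NOT"):
            return n == 1
        if self.op in ("AND", "OR"):
            return n >= 2
        return n == 3  # MUX

    def eval(self, bits: dict[str, int]) -> int:
        vals = [bits[i] for i in self.inputs]
        if self.op == "BUF":
            return vals[0]
        if self.op == "NOT":
            return 1 - vals[0]
        if self.op == "AND":
            return int(all(vals))
        if self.op == "OR":
            return int(any(vals))
        data, stuck, ctrl = vals
        return stuck if ctrl else data


@dataclass(frozen=True)
class Violation:
    kind: str
    detail: str

    def __str__(self):  # pragma: no cover - cosmetic
        return f"{self.kind}: {self.detail}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, kind: str, detail: str) -> None:
        self.violations.append(Violation(kind, detail))

    def kinds(self) -> set[str]:
        return {v.kind for v in self.violations}


@dataclass
class Circuit:
    """A net-list of Boolean gates with declared ordered inputs and outputs.

    ``constants`` maps net id -> fixed bit (constant sources such as MUX
    stuck values and perturbation control signals).  ``roles`` is a free-form
    gene -> role map carried through the interchange format.  ``meta`` holds
    provenance and the signatures of injected perturbations.
    """

    nets: dict[str, Net] = field(default_factory=dict)
    gates: list[Gate] = field(default_factory=list)
    input_order: list[str] = field(default_factory=list)
    output_order: list[str] = field(default_factory=list)
    constants: dict[str, int] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------

    def add_net(self, id: str, kind: str = "internal", label: str = "") -> Net:
        if id in self.nets:
            raise ValueError(f"duplicate net id {id!r}")
        net = Net(id, label or id, kind)
        self.nets[id] = net
        return net

    def ensure_net(self, id: str, kind: str = "internal") -> Net:
        if id not in self.nets:
            return self.add_net(id, kind)
        return self.nets[id]

    def add_gate(self, op: str, inputs, output: str) -> Gate:
        gate = Gate(op, tuple(inputs), output)
        for nid in (*gate.inputs, gate.output):
            self.ensure_net(nid)
        self.gates.append(gate)
        return gate

    def copy(self) -> "Circuit":
        return Circuit(
            nets=dict(self.nets),
            gates=list(self.gates),
            input_order=list(self.input_order),
            output_order=list(self.output_order),
            constants=dict(self.constants),
            roles=dict(self.roles),
            meta=json.loads(json.dumps(self.meta)),
        )

    def with_constant(self, net_id: str, bit: int) -> "Circuit":
        """Return a copy with one constant source re-pinned (e.g. a fault
        control signal toggled)."""
        if net_id not in self.constants:
            raise KeyError(f"{net_id!r} is not a constant source")
        c = self.copy()
        c.constants[net_id] = int(bit)
        return c

    # -- graph views ----------------------------------------------------------

    def driver_of(self) -> dict[str, Gate]:
        drv: dict[str, Gate] = {}
        for g in self.gates:
            drv.setdefault(g.output, g)
        return drv

    def consumers_of(self, net_id: str) -> list[Gate]:
        return [g for g in self.gates if net_id in g.inputs]

    def gate_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nets)
        for gate in self.gates:
            for src in gate.inputs:
                g.add_edge(src, gate.output)
        return g

    # -- interchange format ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nets": [
                {"id": n.id, "label": n.label, "kind": n.kind}
                for n in self.nets.values()
            ],
            "gates": [
                {"op": g.op, "inputs": list(g.inputs), "output": g.output}
                for g in self.gates
            ],
            "input_order": list(self.input_order),
            "output_order": list(self.output_order),
            "constants": dict(self.constants),
            "roles": dict(self.roles),
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Circuit":
        c = cls(
            input_order=list(d.get("input_order", [])),
            output_order=list(d.get("output_order", [])),
            constants={k: int(v) for k, v in d.get("constants", {}).items()},
            roles=dict(d.get("roles", {})),
            meta=dict(d.get("meta", {})),
        )
        for nd in d.get("nets", []):
            c.add_net(nd["id"], nd.get("kind", "internal"), nd.get("label", ""))
        for gd in d.get("gates", []):
            c.add_gate(gd["op"], gd["inputs"], gd["output"])
        return c

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=kw.pop("indent", 2), **kw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def loads(cls, text: str) -> "Circuit":
        # JSON is a YAML subset, so one loader covers both formats
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def load(cls, path) -> "Circuit":
        with open(path) as fh:
            return cls.loads(fh.read())

    def save(self, path) -> None:
        text = self.to_yaml() if str(path).endswith((".yml", ".yaml")) else self.to_json()
        with open(path, "w") as fh:
            fh.write(text)


# -- operations ---------------------------------------------------------------


def validate(circuit: Circuit) -> ValidationReport:
    """Check the structural invariants of a circuit.

    Reported violation kinds: ``bad_arity``, ``multiple_drivers``,
    ``driven_source`` (gate drives an input or constant), ``dangling_net``
    (net neither driven nor a source), ``unknown_net``, ``cycle``,
    ``unreachable_output``.
    """
    rep = ValidationReport()
    sources = set(circuit.input_order) | set(circuit.constants)

    for nid in list(circuit.input_order) + list(circuit.output_order):
        if nid not in circuit.nets:
            rep.add("unknown_net", f"declared net {nid!r} does not exist")

    seen_driver: dict[str, int] = {}
    for g in circuit.gates:
        if not g.arity_ok():
            rep.add("bad_arity", f"{g.op} gate driving {g.output!r} has "
                                 f"{len(g.inputs)} input(s)")
        for nid in (*g.inputs, g.output):
            if nid not in circuit.nets:
                rep.add("unknown_net", f"gate references undeclared net {nid!r}")
        if g.output in sources:
            rep.add("driven_source", f"gate drives source net {g.output!r}")
        seen_driver[g.output] = seen_driver.get(g.output, 0) + 1
    for nid, n in seen_driver.items():
        if n > 1:
            rep.add("multiple_drivers", f"net {nid!r} driven by {n} gates")

    driven = set(seen_driver)
    for nid in circuit.nets:
        if nid not in driven and nid not in sources:
            rep.add("dangling_net", f"net {nid!r} has no driver and is not an "
                                    "input or constant source")

    graph = circuit.gate_graph()
    if not nx.is_directed_acyclic_graph(graph):
        cyc = nx.find_cycle(graph)
        rep.add("cycle", " -> ".join(str(e[0]) for e in cyc))
    else:
        reachable = set(sources)
        for s in sources:
            if s in graph:
                reachable |= nx.descendants(graph, s)
        for nid in circuit.output_order:
            if nid not in reachable:
                rep.add("unreachable_output",
                        f"output {nid!r} not reachable from inputs/constants")
    return rep


def _eval_plan(circuit: Circuit):
    """Precompute the (driver, topological order) pair for repeated
    evaluation of one fixed circuit."""
    driver = circuit.driver_of()
    order = [n for n in nx.topological_sort(circuit.gate_graph())
             if n in driver]
    return driver, order


def _eval_fast(circuit: Circuit, inputs: dict[str, int], plan) -> dict[str, int]:
    driver, order = plan
    bits: dict[str, int] = {n: int(v) for n, v in circuit.constants.items()}
    for n in circuit.input_order:
        b = int(inputs[n])
        if b not in (0, 1):
            raise InputError(f"input {n!r} must be 0 or 1, got {inputs[n]!r}")
        bits[n] = b
    for nid in order:
        if nid not in bits:
            bits[nid] = driver[nid].eval(bits)
    return bits


def evaluate(circuit: Circuit, inputs: dict[str, int]) -> dict[str, int]:
    """Evaluate every net under one input assignment.

    ``inputs`` must assign a bit to every net in ``input_order``.  Returns a
    complete net-id -> bit assignment.  Evaluation is a pure function of the
    circuit and the inputs (gates are processed in topological order; the
    result is order-independent).
    """
    rep = validate(circuit)
    if not rep.ok:
        raise StructuralError("; ".join(map(str, rep.violations)))
    missing = [n for n in circuit.input_order if n not in inputs]
    if missing:
        raise InputError(f"missing input bit(s) for {missing}")
    return _eval_fast(circuit, inputs, _eval_plan(circuit))


def output_bits(circuit: Circuit, inputs: dict[str, int]) -> list[int]:
    """Convenience: the ordered output vector under one input assignment."""
    bits = evaluate(circuit, inputs)
    return [bits[n] for n in circuit.output_order]


def truth_table(circuit: Circuit, cap: int = TRUTH_TABLE_CAP):
    """Enumerate all ``2**n`` input assignments in lexicographic order.

    Returns a list of ``(input_bits, output_bits)`` tuple pairs.  This is the
    brute-force oracle against which fast evaluation and every perturbation
    invariant can be checked exhaustively on small circuits.
    """
    n = len(circuit.input_order)
    if n > cap:
        raise TruthTableSizeError(f"{n} inputs exceeds cap of {cap}")
    rep = validate(circuit)
    if not rep.ok:
        raise StructuralError("; ".join(map(str, rep.violations)))
    plan = _eval_plan(circuit)
    rows = []
    for k in range(2 ** n):
        vec = tuple((k >> (n - 1 - i)) & 1 for i in range(n))
        assign = dict(zip(circuit.input_order, vec))
        bits = _eval_fast(circuit, assign, plan)
        rows.append((vec, tuple(bits[o] for o in circuit.output_order)))
    return rows
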