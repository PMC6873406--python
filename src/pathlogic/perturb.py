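"""Fault and intervention injection.

Gene mutations are modelled as stuck-at faults behind a multiplexer: the
mutated net is switched between its normal driver (control = 0) and a
constant stuck value (control = 1).  Activating mutations of oncogenes are
stuck-at-1; loss-of-function mutations of tumor suppressors are stuck-at-0.

Drugs and miRNA mimics are inhibitors: each target net is routed through
``AND(target, NOT(active))`` so that an active intervention forces the
target to 0 while an inactive one is behaviour-preserving.  When a target
also carries a mutation the inhibitor sits downstream of the multiplexer —
the drug silences the gene product whether or not the gene is mutated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .circuit import Circuit, Gate

log = logging.getLogger(__name__)

# unmapped-target warnings are emitted once per (intervention, target)
_warned_unmapped: set[tuple[str, str]] = set()

__all__ = [
    "Mutation",
    "Intervention",
    "RoleError",
    "TargetError",
    "stuck_value_for",
    "inject_mutation",
    "inject_intervention",
]


class RoleError(ValueError):
    """A gene role does not determine a stuck-at polarity."""


class TargetError(KeyError):
    """A perturbation names a gene with no corresponding net."""


@dataclass(frozen=True)
class Mutation:
    """A (possibly compound) stuck-at fault.

    ``genes`` and ``stuck_values`` are parallel tuples so that one clinical
    event spanning several genes (e.g. an activating fusion plus a deletion
    of a suppressor) is a single record scored as one column.
    """

    label: str
    genes: tuple[str, ...]
    stuck_values: tuple[int, ...]
    control: int = 1
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "stuck_values",
                           tuple(int(v) for v in self.stuck_values))
        if len(self.genes) != len(self.stuck_values) or not self.genes:
            raise ValueError("genes and stuck_values must be parallel, non-empty")
        if any(v not in (0, 1) for v in self.stuck_values):
            raise ValueError("stuck values must be bits")

    @classmethod
    def single(cls, gene: str, stuck_value: int, label: str | None = None,
               control: int = 1, provenance: str = "") -> "Mutation":
        return cls(label or gene, (gene,), (int(stuck_value),), control, provenance)


@dataclass(frozen=True)
class Intervention:
    """A drug or miRNA mimic inhibiting one or more gene targets.

    One control bit governs all targets simultaneously.  ``unmapped`` holds
    declared targets that are not nets of the working circuit (e.g. a miRNA
    target outside the transcribed pathway); they are ignored at injection
    time with a warning.
    """

    name: str
    kind: str = "drug"  # drug | miRNA
    targets: tuple[str, ...] = ()
    active: int = 1
    unmapped: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "targets", tuple(self.targets))
        object.__setattr__(self, "unmapped", tuple(self.unmapped))
        if self.kind not in ("drug", "miRNA"):
            raise ValueError(f"bad intervention kind {self.kind!r}")

    def validate(self) -> None:
        if not self.targets and not self.unmapped:
            raise ValueError(f"intervention {self.name!r} has no targets")


def stuck_value_for(role: str) -> int:
    """Map a gene role to its stuck-at polarity.

    Oncogene mutations are activating (stuck-at-1); tumor-suppressor
    mutations are loss-of-function (stuck-at-0).  Any other role does not
    determine a polarity and the caller must supply an explicit stuck value.
    """
    if role in ("oncogene", "input_oncogene"):
        return 1
    if role == "tumor_suppressor":
        return 0
    raise RoleError(f"role {role!r} does not determine a stuck value")


def _signature(kind: str, payload) -> list:
    return [kind, payload]


def _fresh(circuit: Circuit, base: str) -> str:
    nid, k = base, 1
    while nid in circuit.nets:
        k += 1
        nid = f"{base}.{k}"
    return nid


def _splice_after(circuit: Circuit, gene: str, tag: str,
                  build) -> None:
    """Insert gates between ``gene``'s current source and its consumers.

    ``build(pre, out)`` must append gates driving net ``out`` from net
    ``pre`` (plus any constant sources it registers).  Two cases:

    * ``gene`` is gate-driven: the driving gate is re-targeted to a fresh
      ``pre`` net and the new gates drive ``gene`` itself, so consumers and
      the output order are untouched.
    * ``gene`` is an input or constant source: it cannot be re-driven, so a
      fresh effective net is driven from it and every consumer (and any
      output-order slot) is re-pointed at the effective net.
    """
    driver = circuit.driver_of().get(gene)
    if driver is not None:
        pre = _fresh(circuit, f"{gene}~pre:{tag}")
        circuit.add_net(pre)
        idx = circuit.gates.index(driver)
        circuit.gates[idx] = Gate(driver.op, driver.inputs, pre)
        build(pre, gene)
    else:
        eff = _fresh(circuit, f"{gene}~eff:{tag}")
        circuit.add_net(eff)
        for i, g in enumerate(list(circuit.gates)):
            if gene in g.inputs and g.output != eff:
                new_inputs = tuple(eff if x == gene else x for x in g.inputs)
                circuit.gates[i] = Gate(g.op, new_inputs, g.output)
        circuit.output_order = [eff if x == gene else x
                                for x in circuit.output_order]
        build(gene, eff)
        # downstream perturbations on this gene must attach to the new net
        circuit.meta.setdefault("gene_alias", {})[gene] = eff


def _resolve(circuit: Circuit, gene: str) -> str:
    alias = circuit.meta.get("gene_alias", {})
    seen = set()
    while gene in alias and gene not in seen:
        seen.add(gene)
        gene = alias[gene]
    return gene


def inject_mutation(circuit: Circuit, mutation: Mutation) -> Circuit:
    """Return a new circuit with ``mutation`` spliced in as MUX stage(s).

    With ``control = 0`` the result is bit-identical to the original circuit
    on every input; with ``control = 1`` downstream consumers read the stuck
    value.  Injection is idempotent per mutation identity.
    """
    sig = _signature("mutation", [mutation.label, list(mutation.genes),
                                  list(mutation.stuck_values)])
    c = circuit.copy()
    if sig in c.meta.get("perturbations", []):
        return c
    ctrl = f"mut:{mutation.label}:ctrl"
    for gene, stuck in zip(mutation.genes, mutation.stuck_values):
        target = _resolve(c, gene)
        if target not in c.nets:
            raise TargetError(f"mutation {mutation.label!r}: no net for gene "
                              f"{gene!r}")
        if ctrl not in c.nets:
            c.add_net(ctrl)
            c.constants[ctrl] = int(mutation.control)
        sv = f"mut:{mutation.label}:{gene}:sa{stuck}"
        c.add_net(sv)
        c.constants[sv] = stuck

        def build(pre, out, _sv=sv, _ctrl=ctrl):
            c.add_gate("MUX", (pre, _sv, _ctrl), out)

        _splice_after(c, target, f"mut:{mutation.label}", build)
    c.meta.setdefault("perturbations", []).append(sig)
    return c


def inject_intervention(circuit: Circuit, intervention: Intervention) -> Circuit:
    """Return a new circuit with an inhibitor stage on every mapped target.

    All of an intervention's targets share one control-bit constant source
    (``intv:<name>``).  With ``active = 0`` the circuit is behaviour
    preserving; with ``active = 1`` every target net reads 0 downstream.
    Unmapped targets are skipped with a warning.
    """
    sig = _signature("intervention", [intervention.name,
                                      sorted(intervention.targets)])
    c = circuit.copy()
    if sig in c.meta.get("perturbations", []):
        return c
    ctrl = f"intv:{intervention.name}"
    inv = f"intv:{intervention.name}:not"
    for t in intervention.unmapped:
        key = (intervention.name, t)
        if key not in _warned_unmapped:
            _warned_unmapped.add(key)
            log.warning("intervention %s: target %s is not in the circuit; "
                        "ignored", intervention.name, t)
    mapped = []
    for gene in intervention.targets:
        target = _resolve(c, gene)
        if target not in c.nets:
            raise TargetError(f"intervention {intervention.name!r}: no net for "
                              f"target {gene!r}")
        mapped.append(target)
    if mapped and ctrl not in c.nets:
        c.add_net(ctrl)
        c.constants[ctrl] = int(intervention.active)
        c.add_net(inv)
        c.add_gate("NOT", (ctrl,), inv)
    for target in mapped:
        def build(pre, out, _inv=inv):
            c.add_gate("AND", (pre, _inv), out)

        _splice_after(c, target, f"intv:{intervention.name}", build)
    c.meta.setdefault("perturbations", []).append(sig)
    return c
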