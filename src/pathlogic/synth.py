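"""Random role-annotated circuits and perturbation scenarios.

The generator produces acyclic BUF/NOT/AND/OR circuits with declared,
role-labelled inputs and outputs plus random mutation and intervention
sets, so every operation in the package can be exercised — and checked
against the brute-force truth-table oracle — without any bundled fixture.
Generation is a pure function of the parameters and seed.

Topology is deliberately generic (no scale-free structure): fan-in is
capped at 4 and depth at 10 so exhaustive 2^n analyses stay tractable.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import networkx as nx

from .circuit import Circuit, validate
from .fixtures import CaseStudy
from .perturb import Intervention, Mutation, stuck_value_for
from .scoring import PRO_APOPTOTIC, PROLIFERATIVE

__all__ = ["GeneratorParams", "ParameterError", "random_circuit", "random_case"]


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorParams:
    n_inputs: int = 5
    n_gates: int = 12
    op_weights: dict = field(default_factory=lambda: {
        "BUF": 2.0, "NOT": 1.0, "AND": 2.0, "OR": 2.0})
    n_proliferative_outputs: int = 2
    n_apoptotic_outputs: int = 1
    n_mutations: int = 2
    n_interventions: int = 3
    max_targets: int = 2
    max_fanin: int = 4
    max_depth: int = 10
    seed: int = 0

    def check(self) -> None:
        if self.n_inputs < 1:
            raise ParameterError("n_inputs must be >= 1")
        for name in ("n_gates", "n_proliferative_outputs",
                     "n_apoptotic_outputs", "n_mutations", "n_interventions"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.max_targets < 1 or self.max_fanin < 2:
            raise ParameterError("max_targets >= 1 and max_fanin >= 2 required")


def _rng(params: GeneratorParams) -> random.Random:
    return random.Random(params.seed)


def random_circuit(params: GeneratorParams) -> Circuit:
    """Generate a random valid acyclic circuit.

    Outputs are sampled only from nets reachable from the inputs, so no
    output is degenerate.  With ``n_gates=0`` the inputs themselves are the
    outputs (identity circuit).
    """
    params.check()
    rng = _rng(params)
    c = Circuit()
    depth: dict[str, int] = {}
    for i in range(params.n_inputs):
        nid = f"in{i}"
        c.add_net(nid, "input")
        c.input_order.append(nid)
        depth[nid] = 0

    ops, weights = zip(*sorted(params.op_weights.items()))
    for g in range(params.n_gates):
        op = rng.choices(ops, weights=weights)[0]
        pool = [n for n in c.nets if depth[n] < params.max_depth]
        if not pool:
            break
        fanin = 1 if op in ("BUF", "NOT") else rng.randint(
            2, min(params.max_fanin, max(2, len(pool))))
        srcs = rng.sample(sorted(pool), min(fanin, len(pool)))
        if op in ("AND", "OR") and len(srcs) < 2:
            op = "BUF"  # not enough distinct sources yet for a 2-ary gate
            srcs = srcs[:1]
        out = f"g{g}"
        c.add_net(out)
        c.add_gate(op, srcs, out)
        depth[out] = 1 + max(depth[s] for s in srcs)

    n_out = params.n_proliferative_outputs + params.n_apoptotic_outputs
    graph = c.gate_graph()
    reachable = set(c.input_order)
    for s in c.input_order:
        if s in graph:
            reachable |= nx.descendants(graph, s)
    gate_outs = sorted(n for n in reachable if not n.startswith("in"))
    candidates = gate_outs if gate_outs else sorted(reachable)
    if n_out > len(candidates):
        raise ParameterError(
            f"{n_out} outputs requested but only {len(candidates)} reachable "
            "nets available")
    c.output_order = rng.sample(candidates, n_out)
    rep = validate(c)
    assert rep.ok, rep.violations
    return c


def random_case(params: GeneratorParams) -> CaseStudy:
    """Wrap :func:`random_circuit` into a full synthetic case study.

    Input roles are drawn from {growth_factor, input_oncogene,
    tumor_suppressor}; outputs are split into proliferative and
    pro-apoptotic; mutations pick a role and take their stuck-at polarity
    from :func:`stuck_value_for`; interventions get 1..max_targets targets.
    """
    params.check()
    c = random_circuit(params)
    rng = random.Random(params.seed + 0x5EED)
    roles: dict[str, str] = {}
    for nid in c.input_order:
        roles[nid] = rng.choice(
            ["growth_factor", "input_oncogene", "tumor_suppressor"])
    n_pro = params.n_proliferative_outputs
    for i, nid in enumerate(c.output_order):
        roles[nid] = PROLIFERATIVE if i < n_pro else PRO_APOPTOTIC

    mutable = sorted(set(c.nets) - set(c.constants))
    mutations = []
    for k in range(min(params.n_mutations, len(mutable))):
        gene = rng.choice(mutable)
        mrole = rng.choice(["oncogene", "tumor_suppressor"])
        mutations.append(Mutation.single(
            gene, stuck_value_for(mrole), label=f"M{k}:{gene}",
            provenance=f"synthetic {mrole}"))

    interventions = []
    for k in range(params.n_interventions):
        n_t = rng.randint(1, params.max_targets)
        targets = rng.sample(mutable, min(n_t, len(mutable)))
        interventions.append(Intervention(
            name=f"I{k}", kind=rng.choice(["drug", "miRNA"]),
            targets=tuple(targets)))

    c.roles = roles
    return CaseStudy(name=f"synthetic-{params.seed}", circuit=c, roles=roles,
                     mutations=mutations, drugs=interventions, mirnas=[],
                     expected={})
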