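import itertools
import logging

import pytest

from pathlogic import load_fixture, simulate_case
from pathlogic.circuit import Circuit

logging.disable(logging.WARNING)  # fixture unmapped-target warnings are noisy


@pytest.fixture(scope="session")
def nsclc():
    return load_fixture("nsclc")


@pytest.fixture(scope="session")
def melanoma():
    return load_fixture("melanoma")


def recursive_eval(circuit: Circuit, inputs: dict[str, int]) -> dict[str, int]:
    """Independent pull-based (memoised recursive) evaluator.

    Deliberately shares no code with pathlogic's topological push
    evaluation; serves as the per-gate oracle in equivalence tests.
    """
    memo = {k: int(v) for k, v in circuit.constants.items()}
    memo.update({k: int(v) for k, v in inputs.items()})
    driver = {g.output: g for g in circuit.gates}

    def val(n):
        if n in memo:
            return memo[n]
        g = driver[n]
        vs = [val(i) for i in g.inputs]
        if g.op == "BUF":
            r = vs[0]
        elif g.op == "NOT":
            r = 1 - vs[0]
        elif g.op == "AND":
            r = min(vs)
        elif g.op == "OR":
            r = max(vs)
        elif g.op == "MUX":
            r = vs[1] if vs[2] else vs[0]
        else:  # pragma: no cover
            raise AssertionError(g.op)
        memo[n] = r
        return r

    for n in circuit.nets:
        if n in driver or n in memo:
            val(n)
    return memo


def recursive_outputs(circuit: Circuit, inputs) -> list[int]:
    memo = recursive_eval(circuit, inputs)
    return [memo[o] for o in circuit.output_order]


def all_input_vectors(circuit: Circuit):
    n = len(circuit.input_order)
    for bits in itertools.product((0, 1), repeat=n):
        yield dict(zip(circuit.input_order, bits))


def brute_force_ranking(circuit, mutations, candidates, max_combo, roles):
    """Independent exhaustive subset scan: re-enumerates every subset with
    itertools and recomputes each cumulative score, returning
    ``{frozenset(names): cumulative}``."""
    result = {}
    for k in range(1, max_combo + 1):
        for combo in itertools.combinations(candidates, k):
            profile = simulate_case(circuit, mutations, list(combo), roles)
            result[frozenset(i.name for i in combo)] = profile.cumulative
    return result
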