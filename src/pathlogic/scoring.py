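"""Pathogenic scoring and intervention ranking.

The healthy state of a cancer signalling pathway is probed with a fixed
input test vector: growth factors (and any oncogene inputs) at 0, tumor
suppressors at 1.  The observed output vector is summarised by the
pathogenic score

    S = P - A

where ``P`` counts active proliferative output genes and ``A`` counts
active pro-apoptotic output genes.  ``S = -A_max`` (no proliferation, full
apoptosis) is the healthy optimum; ``S = +P_max`` is the most dangerous
condition.  Each mutation is simulated one at a time; an intervention set
is judged by the sum of its with-intervention scores across all mutations
(the cumulative score) — the minimum cumulative score identifies the most
effective therapy.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import pandas as pd

from .circuit import Circuit, output_bits
from .perturb import Intervention, Mutation, inject_intervention, inject_mutation

__all__ = [
    "PROLIFERATIVE",
    "PRO_APOPTOTIC",
    "INPUT_ROLES",
    "GeneRoleError",
    "Score",
    "MutationRecord",
    "ScoreProfile",
    "RankingTable",
    "healthy_test_vector",
    "score",
    "simulate_case",
    "cumulative_score",
    "rank_interventions",
]

PROLIFERATIVE = "proliferative_output"
PRO_APOPTOTIC = "pro_apoptotic_output"
INPUT_ROLES = ("growth_factor", "input_oncogene", "tumor_suppressor")


class GeneRoleError(ValueError):
    """A net lacks the role annotation its position requires."""


@dataclass(frozen=True)
class Score:
    P: int
    A: int

    @property
    def S(self) -> int:
        return self.P - self.A

    def __int__(self) -> int:
        return self.S


@dataclass(frozen=True)
class MutationRecord:
    mutation: str
    output_without: tuple[int, ...]
    output_with: tuple[int, ...]
    s_without: int
    s_with: int


@dataclass
class ScoreProfile:
    """Per-mutation scores for one intervention set."""

    label: str
    interventions: tuple[str, ...]
    records: list[MutationRecord] = field(default_factory=list)

    @property
    def cumulative(self) -> int:
        return sum(r.s_with for r in self.records)

    def cells(self) -> list[str]:
        """Table cells in the paper-style "without -> with" convention."""
        return [f"{r.s_without} → {r.s_with}" for r in self.records]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "interventions": list(self.interventions),
            "mutations": [
                {
                    "mutation": r.mutation,
                    "output_without": list(r.output_without),
                    "output_with": list(r.output_with),
                    "s_without": r.s_without,
                    "s_with": r.s_with,
                }
                for r in self.records
            ],
            "cumulative": self.cumulative,
        }


@dataclass
class RankingTable:
    """Ranked intervention subsets plus the best single per mutation."""

    profiles: list[ScoreProfile]
    best_single_per_mutation: dict[str, list[str]]
    no_intervention_cumulative: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.profiles:
            row = {"set": p.label}
            row.update({r.mutation: f"{r.s_without} → {r.s_with}"
                        for r in p.records})
            row["cumulative"] = p.cumulative
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps({
            "profiles": [p.to_dict() for p in self.profiles],
            "best_single_per_mutation": self.best_single_per_mutation,
            "no_intervention_cumulative": self.no_intervention_cumulative,
        }, indent=2)


def _role(roles: dict[str, str], circuit: Circuit, net: str) -> str:
    label = circuit.nets[net].label if net in circuit.nets else net
    return roles.get(net) or roles.get(label, "none")


def healthy_test_vector(circuit: Circuit, roles: dict[str, str]) -> dict[str, int]:
    """Build the healthy input assignment from role labels.

    Growth factors and oncogene inputs are forced to 0, tumor suppressors
    to 1 — no proliferative stimulus, active suppression.
    """
    vec: dict[str, int] = {}
    for net in circuit.input_order:
        role = _role(roles, circuit, net)
        if role == "tumor_suppressor":
            vec[net] = 1
        elif role in ("growth_factor", "input_oncogene"):
            vec[net] = 0
        else:
            raise GeneRoleError(f"input net {net!r} has unusable role {role!r}")
    return vec


def score(output: list[int] | tuple[int, ...], roles: dict[str, str],
          circuit: Circuit) -> Score:
    """Score one output vector: S = (sum proliferative) - (sum pro-apoptotic)."""
    if len(output) != len(circuit.output_order):
        raise ValueError(
            f"output length {len(output)} != |output_order| "
            f"{len(circuit.output_order)}")
    P = A = 0
    for bit, net in zip(output, circuit.output_order):
        role = _role(roles, circuit, net)
        if role == PROLIFERATIVE:
            P += int(bit)
        elif role == PRO_APOPTOTIC:
            A += int(bit)
        else:
            raise GeneRoleError(f"output net {net!r} has unusable role {role!r}")
    return Score(P, A)


def _perturbed(circuit: Circuit, mutation: Mutation | None,
               interventions: list[Intervention], active: bool) -> Circuit:
    c = circuit
    if mutation is not None:
        c = inject_mutation(c, mutation)
    for itv in interventions:
        c = inject_intervention(
            c, Intervention(itv.name, itv.kind, itv.targets,
                            active=1 if active else 0, unmapped=itv.unmapped))
    return c


def simulate_case(circuit: Circuit, mutations: list[Mutation],
                  interventions: list[Intervention],
                  roles: dict[str, str] | None = None,
                  label: str | None = None,
                  simultaneous: bool = False) -> ScoreProfile:
    """Score an intervention set against each mutation.

    For every mutation independently (one active fault at a time, matching
    the per-column layout of the case-study tables) the circuit is evaluated
    under the healthy test vector twice: with the interventions inactive
    (``s_without``) and active (``s_with``).  With ``simultaneous=True`` a
    single record is produced with every fault active at once.
    """
    roles = roles if roles is not None else circuit.roles
    vec = healthy_test_vector(circuit, roles)
    names = tuple(sorted(i.name for i in interventions))
    profile = ScoreProfile(label or "/".join(names) or "(none)", names)

    groups: list[tuple[str, list[Mutation]]]
    if simultaneous and mutations:
        groups = [("+".join(m.label for m in mutations), list(mutations))]
    else:
        groups = [(m.label, [m]) for m in mutations]

    for glabel, muts in groups:
        base = circuit
        for m in muts:
            base = inject_mutation(base, m)
        off = _perturbed(base, None, interventions, active=False)
        on = _perturbed(base, None, interventions, active=True)
        out_without = tuple(output_bits(off, vec))
        out_with = tuple(output_bits(on, vec))
        profile.records.append(MutationRecord(
            glabel, out_without, out_with,
            score(out_without, roles, circuit).S,
            score(out_with, roles, circuit).S))
    return profile


def cumulative_score(profile: ScoreProfile) -> int:
    """Sum of the with-intervention scores over all mutations."""
    return profile.cumulative


def rank_interventions(circuit: Circuit, mutations: list[Mutation],
                       candidates: list[Intervention], max_combo: int = 2,
                       roles: dict[str, str] | None = None) -> RankingTable:
    """Exhaustively score every candidate subset of size 1..max_combo.

    Rows are sorted by cumulative score ascending (most effective first);
    ties break lexicographically on the sorted intervention names so equal
    minima are all reported, in a stable order.  The best single
    intervention per mutation is reported alongside (all minima).
    """
    if max_combo < 1:
        raise ValueError("max_combo must be >= 1")
    roles = roles if roles is not None else circuit.roles
    profiles: list[ScoreProfile] = []
    for k in range(1, max_combo + 1):
        for combo in itertools.combinations(
                sorted(candidates, key=lambda i: i.name), k):
            profiles.append(simulate_case(circuit, mutations, list(combo),
                                          roles))
    profiles.sort(key=lambda p: (p.cumulative, p.interventions))

    best_single: dict[str, list[str]] = {}
    singles = [p for p in profiles if len(p.interventions) == 1]
    for idx, m in enumerate(mutations):
        if not singles:
            break
        best = min(p.records[idx].s_with for p in singles)
        best_single[m.label] = sorted(p.interventions[0] for p in singles
                                      if p.records[idx].s_with == best)

    no_itv = simulate_case(circuit, mutations, [], roles).cumulative
    return RankingTable(profiles, best_single, no_itv)
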