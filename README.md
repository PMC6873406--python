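# pathlogic

Signalling pathways as Boolean logic circuits: in-silico screening of drugs
and miRNA mimics against cancer gene mutations.

`pathlogic` is for computational biologists who want a desk-scale,
fully-discrete model of how pathway-level interventions counteract driver
mutations. It compiles KEGG pathways (KGML) — or loads two bundled,
table-verified case studies, non-small cell lung cancer (NSCLC) and
melanoma — into combinational digital circuits in which every gene,
protein or complex is one Boolean net (1 = expressed) and every regulatory
relation is a logic gate:

| pathway relation | gate |
|---|---|
| activation / expression / dissociation | BUF |
| inhibition / repression | NOT |
| combined activation by independent regulators | OR |
| macromolecular complex / binding | AND |

On this substrate the model borrows two constructions from digital
testing and pharmacology:

* **Mutations are stuck-at faults.** A mutated gene net is routed through a
  multiplexer `MUX(driver, stuck, ctrl)`: with `ctrl = 1` the net is
  disconnected from its upstream gates and tied to a constant — stuck-at-1
  for activating oncogene mutations, stuck-at-0 for tumor-suppressor loss.
* **Drugs and miRNA mimics are inhibitor control signals.** Each target net
  is routed through `AND(target, NOT(active))`, placed downstream of the
  mutation multiplexer, so an active inhibitor silences the gene product
  whether or not the gene is mutated.

The circuit is probed with a fixed *healthy test vector* (growth factors
and oncogene inputs 0, tumor suppressors 1) and each output vector is
summarised by the pathogenic score

```
S = P − A
```

where `P` counts active proliferative output genes and `A` active
pro-apoptotic output genes. `S = −A_max` is the healthy optimum (no
proliferation, full apoptosis). Each mutation is simulated one at a time;
an intervention set is ranked by its **cumulative score** — the sum of its
with-intervention scores over all mutations — and the minimum identifies
the most effective (combination) therapy.

## Worked example

```python
from pathlogic import load_fixture, simulate_case, rank_interventions

case = load_fixture("nsclc")          # 5 inputs, 7 outputs, 10 mutations
profile = simulate_case(case.circuit, case.mutations,
                        case.by_name(["Everolimus", "Trametinib"]),
                        case.roles)
for r in profile.records:
    print(f"{r.mutation:>13}  {list(r.output_without)} -> "
          f"{list(r.output_with)}   {r.s_without} -> {r.s_with}")
print("cumulative:", profile.cumulative)
```

prints

```
         EGFR  [1, 0, 1, 0, 0, 0, 0] -> [0, 0, 1, 0, 1, 1, 1]   2 -> -2
        ERBB2  [1, 0, 0, 0, 0, 0, 0] -> [0, 0, 0, 0, 1, 1, 1]   1 -> -3
     EML4-ALK  [1, 0, 1, 1, 0, 0, 0] -> [0, 0, 1, 1, 1, 1, 1]   3 -> -1
         PTEN  [0, 0, 0, 0, 0, 0, 0] -> [0, 0, 0, 0, 1, 1, 1]   0 -> -3
         KRAS  [1, 0, 1, 0, 0, 0, 0] -> [0, 0, 1, 0, 1, 1, 1]   2 -> -2
         BRAF  [1, 0, 0, 0, 1, 1, 1] -> [0, 0, 0, 0, 1, 1, 1]   -2 -> -3
       PIK3CA  [1, 0, 0, 0, 0, 0, 0] -> [0, 0, 0, 0, 1, 1, 1]   1 -> -3
          AKT  [0, 0, 0, 0, 0, 0, 0] -> [0, 0, 0, 0, 1, 1, 1]   0 -> -3
          MEK  [1, 0, 0, 0, 1, 1, 1] -> [0, 0, 0, 0, 1, 1, 1]   -2 -> -3
 EML4-ALK+p16  [1, 1, 1, 1, 0, 0, 0] -> [0, 0, 1, 1, 1, 1, 1]   4 -> -1
cumulative: -24
```

Reading the first row: the EGFR stuck-at-1 fault alone turns on CCND1 and
MST1 (score +2); the Everolimus/Trametinib combination shuts the
AKT-mediated apoptosis block and the MEK→ERK→CCND1 axis, restoring the
three pro-apoptotic outputs (score −2). Six of the ten faults are fully
rectified to the healthy output `[0000111]`. Ranking all drug pairs
confirms Everolimus/Trametinib as the best two-drug combination:

```python
table = rank_interventions(case.circuit, case.mutations, case.drugs,
                           max_combo=2, roles=case.roles)
print(table.profiles[0].label, table.profiles[0].cumulative)
# Everolimus/Trametinib -24
```

The same calls from the shell:

```sh
pathlogic verify                                   # fixture regressions
pathlogic simulate --fixture nsclc --drugs Everolimus,Trametinib
pathlogic rank --fixture melanoma --set mirnas --max-combo 2
pathlogic import my_pathway.xml -o circuit.json    # KGML -> circuit
pathlogic synth --seed 7 -o synthetic.json         # random test fixture
```

## Layout

```
src/pathlogic/circuit.py    nets, gates, validation, evaluation, truth tables
src/pathlogic/kgml.py       KGML parsing and pathway-to-circuit compilation
src/pathlogic/perturb.py    stuck-at fault and inhibitor injection
src/pathlogic/scoring.py    test vectors, S = P − A, profiles, ranking
src/pathlogic/fixtures.py   bundled NSCLC + melanoma case studies (+ data/)
src/pathlogic/synth.py      seeded random circuits and scenarios
src/pathlogic/cli.py        command-line front end
docs/methods.md             model description, assumptions, limitations
```
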