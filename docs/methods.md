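# Methods

## The model

A signalling pathway is treated as a combinational digital circuit. Every
gene, enzyme, protein or macromolecular complex is a single Boolean net —
1 if the species is expressed/active, 0 otherwise — and every regulatory
relation is a logic gate: activation, expression and dissociation are
buffers; inhibition and repression are inverters; independent activators
converging on one node combine through OR; complexes and
binding/association require all members and combine through AND. The
circuit is feed-forward by construction: no state, no update schedule, no
attractors. Given one input assignment, every net has exactly one value,
so exhaustive analysis (truth tables, all single faults, all intervention
subsets) is cheap — the bundled case circuits have under 40 gates.

This discreteness is the central assumption and the central limitation:
expression is all-or-nothing, inhibition is complete, and kinetics, dose,
partial knock-down and feedback dynamics are all outside the model. What
the model buys in exchange is exactness — every reported number is an
integer function of the wiring, reproducible to the bit.

### Mutations: stuck-at faults behind a multiplexer

A driver mutation is modelled with the stuck-at fault abstraction from
digital testing. The mutated net is cut from its upstream gates and routed
through a 2-way multiplexer `MUX(driver, stuck, ctrl)`: with the control
bit at 0 the circuit is bit-identical to the unmutated one; at 1 the
constant stuck value replaces the physiological signal. Activating
oncogene mutations are stuck-at-1 (always expressed regardless of
upstream signalling); tumor-suppressor loss is stuck-at-0. Compound
clinical events (the NSCLC `EML4-ALK+p16` fusion-plus-deletion) are one
mutation record carrying several parallel faults under a single control
bit, scored as one column. Faults on input pins override the test vector
via the same mechanism applied to the pin's fan-out.

### Interventions: inhibitors as NOT+AND control stages

A drug or miRNA mimic with target set T inserts, for each t in T, the
stage `AND(t, NOT(active))` between t's source and all of t's consumers;
one `active` bit governs every target of the intervention. Inactive
interventions are behaviour-preserving; active ones force their targets
to 0 under every input and every fault configuration. When a target also
carries a mutation the inhibitor sits **downstream of the multiplexer**:
pharmacological inhibition silences the gene product whether or not the
gene is mutated. This placement is applied uniformly to drugs and miRNAs
(see "Known deviations" for the one table family this decision
contradicts). AntagomiR (miRNA-removal) semantics are deliberately not
modelled — the sources define no gate for them; miRNAs whose inhibition
*worsens* outcomes are simply visible as positive score changes.

### Test vector, score, ranking

The healthy input test vector sets growth factors to 0 and tumor
suppressors to 1; oncogene inputs (melanoma NRAS) are likewise set to 0,
extending the growth-factor rule — the published melanoma test vector
[0,0] forces the NRAS input low. Each output vector is summarised by the
pathogenic score `S = P − A` (active proliferative minus active
pro-apoptotic outputs). For the NSCLC outputs (4 proliferative, 3
pro-apoptotic) S ranges over [−3, 4]; both extremes are attained by
exactly one bit configuration, every other score by several.

Score tables are computed one-fault-at-a-time (each table column is a
single active mutation), matching the published layout; simultaneous
multi-fault simulation exists behind a flag but is not used for ranking.
An intervention set's cumulative score is the unweighted sum of its
with-intervention scores over all mutations (no prevalence weighting —
none is defined). `rank_interventions` scans **every** candidate subset of
size 1..`max_combo` (default 2, to keep combination toxicity plausible;
3 is supported), sorts ascending by cumulative score, and breaks ties
lexicographically on the sorted intervention names so that all minima are
reported in a stable order.

## KGML compilation

`parse_kgml` transcribes entries, groups and typed relations verbatim;
`compile_pathway` then applies, in a fixed order (entry filter → relation
filter → group AND-complexes → fan-in combiners): ortholog/brite/
reaction/map entries are dropped; compound, hidden-compound, state-change,
missing-interaction and post-translational-modification subtypes are
ignored; indirect effects count as direct; dissociation from a complex
releases (activates) the named member, driven by the remaining members.
Mixed regulation on one node compiles to
`OR(activators) AND NOT(i1) AND ... AND NOT(ik)`, composing the pure
rules the same way drug inhibition composes NOT with AND. Display names
pass through an explicit, fixture-versioned alias map (KEGG map labels
are family names — RAS for KRAS, RAF for BRAF — and guessing is worse
than declaring). Duplicate entries for one gene merge into one net (one
Boolean variable per gene); maplink relations are dropped; a relation
carrying both binding and activation/inhibition subtypes is flagged in
the compile report rather than silently resolved. Compilation is
deterministic given (graph, aliases, config).

## The bundled case studies

The NSCLC and melanoma circuits, role labels, mutation tables (with
ClinVar-style provenance strings) and drug/miRNA target maps ship as
package data. The published circuit schematics are raster figures, so the
wiring was transcribed with the published score tables as the arbiter:
transcription correctness is *defined* as reproducing the printed tables,
and every wiring choice not forced by the figures is annotated in the
circuit `meta`. Residual ambiguity remains possible in principle — two
distinct wirings matching all printed scores cannot be excluded — but the
bundled wirings reproduce, bit-exactly, all twenty faulted output vectors
of the NSCLC combination table and every self-consistent score cell of
all four published score tables (see below).

Two wiring points deserve explicit mention:

* **NSCLC PTEN.** The published fault data (PTEN stuck-at-0 silences
  every output; PI3K inhibition does not rescue it) force
  `AKT = OR(PI3K, NOT PTEN)`: suppressor loss alone activates AKT
  ("release" semantics) rather than merely permitting upstream signal
  (`AND NOT` semantics). The fixture therefore uses the OR form, while
  the KGML compiler keeps the AND-composition as its general default for
  mixed regulation — the fixture is explicit data, not compiler output.
* **Melanoma CDKN2A and CCND1.** The melanoma circuit has only two
  inputs, so the CDKN2A suppressor is a constant-1 source net (present in
  health) that the CDK4/6-column fault switches to 0. The published
  tables also require CCND1 to stay low under every stuck-at scenario
  while remaining reachable from the inputs; the fixture encodes this as
  `CCND1 = AND(ERK, MITF)` with MITF fed by the growth-factor receptor —
  the one annotated not-forced-by-figures choice in that circuit.

Targets outside the transcribed wiring (e.g. PDK1) carry an `unmapped`
flag and are ignored with a warning; one miRNA that appears only inside
published combination rows but not in the published target table is
carried with an empty target set, which exactly reproduces those rows.

### Known deviations of the published tables

The published tables contain a handful of cells that are arithmetically
inconsistent with the output vectors or with other rows printed beside
them. The fixture data records the self-consistent values and lists every
such cell under `printed_deviations`; nothing is silently patched. The
three consequential ones:

1. The NSCLC Everolimus/Trametinib EGFR cell is printed as −1 next to an
   output vector `[0010111]` that scores 1 − 3 = −2 (the identical vector
   is printed for KRAS with score −2). The simulated cumulative is
   therefore −24, not the printed −23.
2. The KRAS-mutation cells of the KRAS-targeting miRNAs behave as if the
   inhibitor sat upstream of the fault multiplexer, while the
   AKT-targeting miRNA rows (and every drug) require it downstream. With
   the downstream placement applied uniformly, let-7c/let-7g scores −28,
   not the printed −27.
3. The exhaustive pair scan finds miRNA pairs that jointly silence the
   AKT, CCND1, RASSF1→MST1 and STAT arms and restore the healthy output
   under *every* mutation (cumulative −30) — strictly better than the
   pair reported as best. Only 7 of the 190 pairs appear in the published
   table; the ranking here is instead verified against a brute-force
   subset oracle.

The acceptance tests assert the printed values and therefore fail on
exactly these three points; this is intentional.

## Synthetic data

The generator (`synth.py`) emits random acyclic BUF/NOT/AND/OR circuits
with role-labelled inputs and outputs plus random mutation/intervention
scenarios, as a pure function of the parameters and seed. Defaults: 5
inputs, 12 gates, fan-in ≤ 4, depth ≤ 10, outputs sampled only from nets
reachable from the inputs (no degenerate scoring), 2 proliferative + 1
pro-apoptotic outputs, 2 mutations with polarity from the oncogene/
suppressor rule, 3 interventions with 1–2 targets. These sizes keep the
exhaustive 2^n truth-table oracle instant while exercising every gate
type and both fault polarities. The topology is deliberately generic:
no scale-free degree structure, no biological motif statistics — so
passing property tests demonstrates correctness of the circuit machinery,
not realism of any biological conclusion drawn from random wirings.

## Numerical and degenerate-input choices

All signals are single bits; there is no multi-valued or probabilistic
logic. Cycles are rejected at validation (the modelled pathways are
feed-forward; a config hook lets users drop curated feedback edges before
compilation). Constant sources (stuck values, control bits) are ordinary
nets pinned in `Circuit.constants`, so the truth-table oracle needs no
special casing and control bits can be re-pinned without re-splicing.
Injection is idempotent per perturbation identity, and injection order of
distinct perturbations does not affect behaviour; repeated interventions
on one target chain ANDs in name order for reproducibility. The
truth-table enumerator refuses more than 16 inputs by default. Evaluation
validates structure first and then runs in topological order; the
contract is order-independence of the result.

## Problem sizes used in the checks

Everything is desk-scale: the case circuits have ≈25–30 nets; the
regression re-simulates ~60 published table rows per case in well under a
second; the property suites use 200 random circuits of 2–12 inputs for
oracle equivalence and exhaustive 2^n scans (n ≤ 6) for the
behaviour-preservation and forced-low invariants. The full test suite
runs in a few seconds on one CPU.
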