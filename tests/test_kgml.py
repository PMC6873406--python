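"""KGML parsing and pathway-to-circuit compilation rules."""

import pytest

from pathlogic.circuit import truth_table, validate
from pathlogic.kgml import (CompileConfig, CompileReport, KGMLParseError,
                            compile_pathway, parse_kgml)


def kgml(entries: str, relations: str = "") -> str:
    return (f'<?xml version="1.0"?>\n<pathway name="path:test">\n'
            f"{entries}\n{relations}\n</pathway>")


def gene(eid, name):
    return (f'<entry id="{eid}" name="hsa:{eid}" type="gene">'
            f'<graphics name="{name}"/></entry>')


def rel(e1, e2, *subtypes):
    subs = "".join(f'<subtype name="{s}" value="x"/>' for s in subtypes)
    return f'<relation entry1="{e1}" entry2="{e2}" type="PPrel">{subs}</relation>'


MINIMAL = kgml(gene(1, "GRB2") + gene(2, "SOS"), rel(1, 2, "activation"))


class TestParse:
    def test_minimal_two_entries_one_relation(self):
        g = parse_kgml(MINIMAL)
        assert len(g.entries) == 2
        assert len(g.relations) == 1
        assert g.relations[0].subtypes == ("activation",)

    def test_group_membership_recorded(self):
        doc = kgml(gene(1, "Rb") + gene(2, "E2F") +
                   '<entry id="3" name="undefined" type="group">'
                   '<component id="1"/><component id="2"/></entry>')
        g = parse_kgml(doc)
        assert g.entries["3"].members == ("1", "2")
        assert "3" in g.groups()

    def test_all_entry_types_survive_parsing(self):
        # parsing captures everything verbatim; filtering happens at compile
        parts = [gene(i, f"G{i}") for i in range(1, 9)]
        parts.append('<entry id="9" name="ko:K00001" type="ortholog"/>')
        parts.append('<entry id="10" name="path:hsa05200" type="map"/>')
        g = parse_kgml(kgml("".join(parts)))
        assert len(g.entries) == 10

    def test_malformed_xml_raises(self):
        with pytest.raises(KGMLParseError):
            parse_kgml("<pathway><entry id='1'")

    def test_unknown_relation_endpoint_raises(self):
        with pytest.raises(KGMLParseError):
            parse_kgml(kgml(gene(1, "A"), rel(1, 99, "activation")))


class TestCompileRules:
    def test_activation_becomes_buffer(self):
        c = compile_pathway(parse_kgml(MINIMAL))
        assert [(g.op, g.inputs, g.output) for g in c.gates] == [
            ("BUF", ("GRB2",), "SOS")]
        assert c.input_order == ["GRB2"]
        assert c.output_order == ["SOS"]

    def test_inhibition_becomes_not(self):
        doc = kgml(gene(1, "PTEN") + gene(2, "AKT"), rel(1, 2, "inhibition"))
        c = compile_pathway(parse_kgml(doc))
        assert [(g.op, g.output) for g in c.gates] == [("NOT", "AKT")]

    def test_two_activators_become_or_never_and(self):
        doc = kgml(gene(1, "SOS") + gene(2, "ALK") + gene(3, "KRAS"),
                   rel(1, 3, "activation") + rel(2, 3, "activation"))
        c = compile_pathway(parse_kgml(doc))
        (g,) = c.gates
        assert g.op == "OR" and set(g.inputs) == {"ALK", "SOS"}

    def test_group_becomes_and_over_members(self):
        doc = kgml(gene(1, "CCND1") + gene(2, "CDK4") + gene(3, "RB1") +
                   '<entry id="4" name="undefined" type="group">'
                   '<component id="1"/><component id="2"/></entry>',
                   rel(4, 3, "inhibition"))
        c = compile_pathway(parse_kgml(doc))
        ops = {g.output: g for g in c.gates}
        assert ops["[CCND1:CDK4]"].op == "AND"
        assert set(ops["[CCND1:CDK4]"].inputs) == {"CCND1", "CDK4"}
        assert ops["RB1"].op == "NOT"

    def test_dissociation_releases_member_as_buffer(self):
        # Rb:E2F complex dissociates and releases (activates) E2F
        doc = kgml(gene(1, "Rb") + gene(2, "E2F") +
                   '<entry id="3" name="undefined" type="group">'
                   '<component id="1"/><component id="2"/></entry>',
                   rel(3, 2, "dissociation"))
        c = compile_pathway(parse_kgml(doc))
        ops = {g.output: g for g in c.gates}
        assert ops["E2F"].op == "BUF" and ops["E2F"].inputs == ("Rb",)

    def test_indirect_effect_counts_as_activation(self):
        doc = kgml(gene(1, "MEK") + gene(2, "ERK"),
                   rel(1, 2, "indirect effect"))
        c = compile_pathway(parse_kgml(doc))
        assert [(g.op, g.output) for g in c.gates] == [("BUF", "ERK")]

    def test_mixed_regulation_is_or_of_activators_and_not_inhibitors(self):
        doc = kgml(gene(1, "A") + gene(2, "I") + gene(3, "X"),
                   rel(1, 3, "activation") + rel(2, 3, "inhibition"))
        c = compile_pathway(parse_kgml(doc))
        # brute-force: X = A AND NOT I
        got = dict(truth_table(c))
        want = {(a, i): (a & (1 - i),) for a in (0, 1) for i in (0, 1)}
        assert {k: got[k] for k in want} == want

    def test_dropped_entry_types_and_their_relations(self):
        doc = kgml(gene(1, "A") + gene(2, "B") +
                   '<entry id="3" name="ko:K1" type="ortholog"/>' +
                   '<entry id="4" name="path:x" type="map"/>',
                   rel(1, 2, "activation") + rel(3, 2, "activation") +
                   rel(1, 4, "activation"))
        report = CompileReport()
        c = compile_pathway(parse_kgml(doc), report=report)
        assert set(c.nets) == {"A", "B"}
        assert len(c.gates) == 1
        assert len(report.warnings) == 2

    def test_modification_subtypes_ignored(self):
        doc = kgml(gene(1, "A") + gene(2, "B") + gene(3, "C"),
                   rel(1, 2, "phosphorylation") + rel(1, 3, "activation",
                                                      "phosphorylation"))
        c = compile_pathway(parse_kgml(doc))
        # pure-modification edge vanishes; mixed one keeps its activation
        assert [(g.op, g.output) for g in c.gates] == [("BUF", "C")]
        assert "B" in c.input_order  # B left as an (unconnected) entry

    def test_alias_map_renames_family_labels(self):
        doc = kgml(gene(1, "RAS") + gene(2, "RAF"), rel(1, 2, "activation"))
        cfg = CompileConfig(aliases={"RAS": "KRAS", "RAF": "BRAF"})
        c = compile_pathway(parse_kgml(doc), config=cfg)
        assert set(c.nets) == {"KRAS", "BRAF"}

    def test_duplicate_entries_merge_to_one_net(self):
        doc = kgml(gene(1, "AKT") + gene(2, "AKT") + gene(3, "BAD"),
                   rel(1, 3, "inhibition") + rel(2, 3, "inhibition"))
        c = compile_pathway(parse_kgml(doc))
        assert sorted(c.nets) == ["AKT", "BAD"]
        (g,) = c.gates
        assert g.op == "NOT" and g.inputs == ("AKT",)

    def test_compilation_is_deterministic(self):
        doc = kgml("".join(gene(i, f"G{i}") for i in range(1, 7)),
                   rel(1, 3, "activation") + rel(2, 3, "activation") +
                   rel(3, 4, "inhibition") + rel(5, 4, "activation") +
                   rel(4, 6, "expression"))
        d1 = compile_pathway(parse_kgml(doc)).to_dict()
        d2 = compile_pathway(parse_kgml(doc)).to_dict()
        assert d1 == d2

    def test_subtype_override_reclassifies_edge(self):
        doc = kgml(gene(1, "A") + gene(2, "B"),
                   rel(1, 2, "phosphorylation"))
        cfg = CompileConfig(subtype_overrides={"phosphorylation":
                                               "activation"})
        c = compile_pathway(parse_kgml(doc), config=cfg)
        assert [(g.op, g.output) for g in c.gates] == [("BUF", "B")]

    def test_bare_binding_relation_is_flagged_not_guessed(self):
        doc = kgml(gene(1, "A") + gene(2, "B"),
                   rel(1, 2, "binding/association"))
        report = CompileReport()
        c = compile_pathway(parse_kgml(doc), report=report)
        assert report.flagged_relations
        assert not c.gates


class TestGrowthFactorCascade:
    """The receptor->adapter->GTPase cascade fragment: one adapter feeding
    SOS through a buffer and two convergent activators OR-ing into the
    GTPase, mirroring the published worked subcircuit."""

    DOC = kgml(
        gene(1, "GRB2") + gene(2, "SOS") + gene(3, "ALK") + gene(4, "RAS") +
        gene(5, "PKC") + gene(6, "RAF") + gene(7, "MEK") + gene(8, "ERK"),
        rel(1, 2, "activation") + rel(2, 4, "activation") +
        rel(3, 4, "activation") + rel(4, 6, "activation") +
        rel(5, 6, "activation") + rel(6, 7, "activation") +
        rel(7, 8, "activation"))

    def test_compiles_valid_and_gate_shapes(self):
        cfg = CompileConfig(aliases={"RAS": "KRAS", "RAF": "BRAF"})
        c = compile_pathway(parse_kgml(self.DOC), config=cfg)
        assert validate(c).ok
        ops = {g.output: (g.op, set(g.inputs)) for g in c.gates}
        assert ops["SOS"] == ("BUF", {"GRB2"})
        assert ops["KRAS"] == ("OR", {"SOS", "ALK"})
        assert ops["BRAF"] == ("OR", {"KRAS", "PKC"})
        assert ops["MEK"] == ("BUF", {"BRAF"})
        assert ops["ERK"] == ("BUF", {"MEK"})

    def test_truth_table_matches_hand_derived_function(self):
        cfg = CompileConfig(aliases={"RAS": "KRAS", "RAF": "BRAF"},
                            outputs=["ERK"])
        c = compile_pathway(parse_kgml(self.DOC), config=cfg)
        order = c.input_order
        for vec_bits, (erk,) in truth_table(c):
            v = dict(zip(order, vec_bits))
            kras = v["GRB2"] | v["ALK"]
            assert erk == (kras | v["PKC"])
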