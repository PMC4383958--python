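"""Parsers and writers: FASTA, gene table, Newick, OBO, GAF, OrthoXML."""

import logging

import pytest
from hypothesis import given, settings, strategies as st

from orthoforge import io as oio
from orthoforge.groups import build_hogs
from orthoforge.types import FormatError, SpeciesTree, clean_protein


# -- protein normalisation --------------------------------------------------

def test_clean_protein_uppercases_and_strips_stops(caplog):
    with caplog.at_level(logging.WARNING):
        assert clean_protein("mkv*") == "MKV"
    assert any("normalising" in r.message for r in caplog.records)


def test_clean_protein_rejects_garbage_and_empty():
    with pytest.raises(FormatError):
        clean_protein("MK1V")
    with pytest.raises(FormatError):
        clean_protein("***")


@settings(max_examples=50, derandomize=True)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX", min_size=1, max_size=50))
def test_clean_protein_is_idempotent_on_canonical_sequences(seq):
    assert clean_protein(seq) == seq


# -- FASTA ------------------------------------------------------------------

def test_fasta_variant_header_dialect(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">g1.1\nMKV\n>g2\nMAAL\n>g3.1\nMWW\n>g3.2\nMWWA\n")
    recs = oio.read_fasta(p)
    assert ("g1", 1, "MKV") in recs
    assert ("g2", 1, "MAAL") in recs  # missing suffix defaults to variant 1
    g3 = sorted(r for r in recs if r[0] == "g3")
    assert [(v, s) for _, v, s in g3] == [(1, "MWW"), (2, "MWWA")]


def test_fasta_duplicate_header_and_empty_sequence_are_errors(tmp_path):
    p = tmp_path / "dup.fa"
    p.write_text(">g1.1\nMKV\n>g1.1\nMKW\n")
    with pytest.raises(FormatError, match="duplicate"):
        oio.read_fasta(p)
    p2 = tmp_path / "empty.fa"
    p2.write_text(">g1\n*\n")
    with pytest.raises(FormatError):
        oio.read_fasta(p2)


def test_fasta_underscore_dialect(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">g1_2\nMKV\n")
    assert oio.read_fasta(p, variant_sep="_") == [("g1", 2, "MKV")]


# -- gene table -------------------------------------------------------------

def _write_table(tmp_path, rows, header="id\tgenome\tchromosome\tstart\tend"
                                        "\tstrand\tsubgenome\tchr_group"):
    p = tmp_path / "genes.tsv"
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    return p


def test_gene_table_full_row(tmp_path):
    p = _write_table(tmp_path, ["g1\tW\t3B\t100\t500\t+\tB\t3"])
    (gm,) = oio.read_gene_table(p)
    g = gm.genes[0]
    assert (g.subgenome, g.chromosome_group, g.strand) == ("B", 3, "+")


def test_gene_table_optional_columns_unset(tmp_path):
    p = tmp_path / "genes.tsv"
    p.write_text("id\tgenome\tchromosome\tstart\tend\tstrand\n"
                 "g1\tA\tchr1\t1\t90\t-\n")
    (gm,) = oio.read_gene_table(p)
    assert gm.genes[0].subgenome is None
    assert gm.genes[0].chromosome_group is None


def test_gene_table_groups_genomes_and_orders_by_position(tmp_path):
    rows = ["a2\tA\tchr1\t500\t600\t+\t\t", "a1\tA\tchr1\t10\t90\t+\t\t",
            "a3\tA\tchr2\t5\t50\t-\t\t", "b1\tB\tchr1\t1\t30\t+\t\t",
            "b2\tB\tchr1\t100\t130\t+\t\t", "b3\tB\tchr1\t50\t80\t-\t\t"]
    genomes = oio.read_gene_table(_write_table(tmp_path, rows))
    assert [g.id for g in genomes] == ["A", "B"]
    assert [g.id for g in genomes[0].genes] == ["a1", "a2", "a3"]
    assert [g.id for g in genomes[1].genes] == ["b1", "b3", "b2"]


def test_gene_table_row_errors_carry_line_numbers(tmp_path):
    p = _write_table(tmp_path, ["g1\tA\tchr1\t500\t100\t+\t\t"])
    with pytest.raises(FormatError, match="line 2"):
        oio.read_gene_table(p)
    p2 = _write_table(tmp_path, ["g1\tA\tchr1\t1\t10\t>\t\t"])
    with pytest.raises(FormatError, match="strand"):
        oio.read_gene_table(p2)


# -- Newick -----------------------------------------------------------------

def test_newick_basic_topology(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((A,B),C);\n")
    tree = oio.read_newick(p)
    assert sorted(l.name for l in tree.leaves()) == ["A", "B", "C"]
    assert sum(1 for n in tree.preorder() if not n.is_leaf) == 2


def test_newick_keeps_internal_names_and_polytomies(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((A,B)ab,C,D)root;\n")
    tree = oio.read_newick(p)
    assert tree.node("ab") is not None
    assert len(tree.root.children) == 3


def test_tree_validation_against_genomes(caplog):
    from conftest import make_genome

    tree = SpeciesTree.from_newick("((A,B),C);")
    with caplog.at_level(logging.WARNING):
        tree.validate_against([make_genome("A", {"a1": "MKV"}),
                               make_genome("B", {"b1": "MKV"})])
    assert any("C" in r.message for r in caplog.records)
    with pytest.raises(FormatError, match="Z"):
        tree.validate_against([make_genome("Z", {"z1": "MKV"})])


def test_explicitly_unrooted_tree_is_rejected():
    with pytest.raises(FormatError, match="rooted"):
        SpeciesTree.from_newick("[&U]((A,B),C);")


# -- OBO --------------------------------------------------------------------

OBO_TEXT = """format-version: 1.2

[Term]
id: T:1
name: root

[Term]
id: T:2
name: mid
is_a: T:1

[Term]
id: T:3
name: tip
alt_id: T:9
is_a: T:2
relationship: part_of T:1

[Term]
id: T:4
name: gone
is_obsolete: true
"""


def test_obo_chain_ancestors_and_alt_id(tmp_path):
    p = tmp_path / "o.obo"
    p.write_text(OBO_TEXT)
    onto = oio.read_obo(p)
    assert onto.ancestors("T:3") == {"T:3", "T:2", "T:1"}
    assert onto.resolve("T:9") == "T:3"
    assert "T:4" not in onto
    # part_of edges only enter the closure on request
    assert onto.parents("T:3") == {"T:2"}
    assert onto.parents("T:3", with_part_of=True) == {"T:2", "T:1"}


def test_obo_cycle_is_an_error(tmp_path):
    p = tmp_path / "cyc.obo"
    p.write_text("format-version: 1.2\n\n[Term]\nid: T:1\nname: a\n"
                 "is_a: T:2\n\n[Term]\nid: T:2\nname: b\nis_a: T:1\n")
    with pytest.raises(ValueError, match="cycle"):
        oio.read_obo(p)


# -- GAF --------------------------------------------------------------------

GAF_TEXT = (
    "!gaf-version: 2.1\n"
    "DB\tG1\tG1\t\tGO:0000001\tREF\tIMP\t\tP\t\t\tprotein\ttaxon:1\t"
    "20140101\tDB\n"
    "DB\tG2\tG2\t\tGO:0000002\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:1\t"
    "20140101\tDB\n"
    "DB\tG3\tG3\tNOT\tGO:0000001\tREF\tIMP\t\tP\t\t\tprotein\ttaxon:1\t"
    "20140101\tDB\n"
    "short\tline\n"
)


def test_gaf_evidence_codes_and_not_qualifier(tmp_path, caplog):
    p = tmp_path / "a.gaf"
    p.write_text(GAF_TEXT)
    with caplog.at_level(logging.WARNING):
        anns = oio.read_gaf(p)
    by_gene = {a.gene_id: a for a in anns}
    assert by_gene["G1"].is_experimental          # IMP is literature-based
    assert not by_gene["G2"].is_experimental      # IEA retained, not a source
    assert "G3" not in by_gene                    # NOT-qualified rows dropped
    assert any("line 5" in r.message for r in caplog.records)


def test_gaf_round_trip_preserves_records(tmp_path):
    p = tmp_path / "a.gaf"
    p.write_text(GAF_TEXT)
    anns = oio.read_gaf(p)
    out = tmp_path / "out.gaf"
    oio.write_gaf(out, anns)
    again = oio.read_gaf(out)
    assert {(a.gene_id, a.term_id, a.evidence) for a in again} == \
        {(a.gene_id, a.term_id, a.evidence) for a in anns}


# -- OrthoXML ---------------------------------------------------------------

def test_orthoxml_round_trip_on_simulated_hogs(tmp_path, small_world):
    hogs = build_hogs(small_world["orthologs"], small_world["tree"],
                      small_world["genomes"])
    path = tmp_path / "hogs.orthoxml"
    oio.write_orthoxml(hogs, small_world["genomes"], path)
    back = oio.read_orthoxml(path, small_world["tree"])
    assert sorted(h.structure() for h in hogs) == \
        sorted(h.structure() for h in back)


def test_orthoxml_duplication_becomes_paralog_group(tmp_path):
    from conftest import make_genome

    tree = SpeciesTree.from_newick("((A,B)ab,C)root;")
    genomes = [make_genome("A", {"a1": "MKVA", "a2": "MKVA"}),
               make_genome("B", {"b1": "MKVA", "b2": "MKVA"}),
               make_genome("C", {"c1": "MKVA"})]
    pairs = [("a1", "b1"), ("a2", "b2"), ("a1", "c1"), ("a2", "c1"),
             ("b1", "c1"), ("b2", "c1")]
    hogs = build_hogs(pairs, tree, genomes)
    path = tmp_path / "dup.orthoxml"
    oio.write_orthoxml(hogs, genomes, path)
    text = path.read_text()
    assert "<paralogGroup>" in text
    back = oio.read_orthoxml(path, tree)
    assert sorted(h.structure() for h in hogs) == \
        sorted(h.structure() for h in back)


def test_orthoxml_refuses_members_outside_gene_index(tmp_path):
    from conftest import make_genome
    from orthoforge.groups import HOG

    genomes = [make_genome("A", {"a1": "MKVA"})]
    ghost = HOG(root_level="A", gene="phantom")
    with pytest.raises(FormatError, match="phantom"):
        oio.write_orthoxml([ghost], genomes, tmp_path / "x.orthoxml")
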