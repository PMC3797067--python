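"""Haplogroup tree loading, cumulative motifs, classification, search."""

import pytest

from mitorho.haplogroups import (
    classify,
    classify_db,
    cumulative_motif,
    load_tree,
    search_motif,
)
from mitorho.haplotypes import HaplotypeDB
from mitorho.simulate import SimConfig, simulate_database
from mitorho.variants import VariantError

from conftest import hap, motif, var

HVS1 = ((16024, 16400),)
HVS12 = ((16024, 16400), (57, 372))

MINI = """ROOT
\tA\tT1000C
\t\tA1\tG2000A T3000C
\t\t\tA1a\t@T1000C
\tB\tC5000T
"""


def test_load_tree_structure_and_errors():
    t = load_tree(MINI.splitlines())
    assert set(t.by_name) == {"ROOT", "A", "A1", "A1a", "B"}
    assert t.node("A1a").depth == 3
    assert [c.name for c in t.root.children] == ["A", "B"]
    with pytest.raises(ValueError, match="duplicate"):
        load_tree(["ROOT", "\tA\tT1000C", "\tA\tT2000C"])
    with pytest.raises(ValueError, match="indentation"):
        load_tree(["ROOT", "\t\t\tdeep\tT1000C"])
    with pytest.raises(VariantError):
        load_tree(["ROOT", "\tA\tnot_a_token"])


def test_packaged_tree_node_count_matches_line_count(tree):
    from importlib import resources
    text = (resources.files("mitorho.data") / "mini_tree.txt").read_text()
    node_lines = [l for l in text.splitlines()
                  if l.strip() and not l.strip().startswith("#")]
    assert len(tree.by_name) == len(node_lines)
    assert tree.version == "mitorho-mini-1"
    assert tree.aliases == {"A16344G": "A16343G"}


def test_cumulative_motif_accumulates_and_back_mutation_removes():
    t = load_tree(MINI.splitlines())
    assert cumulative_motif(t, "ROOT") == set()
    assert cumulative_motif(t, "A1") == set(motif("T1000C-G2000A-T3000C"))
    # the @T1000C on A1a's branch removes the ancestral variant
    assert cumulative_motif(t, "A1a") == set(motif("G2000A-T3000C"))
    with pytest.raises(KeyError):
        cumulative_motif(t, "nope")


def test_paper_motifs_cumulate_along_packaged_tree(tree):
    m5 = cumulative_motif(tree, "M5a1b1a1")
    assert set(motif("C3954T-T9833C-T16298C")) <= m5
    assert {v for v in m5 if 16024 <= v.position <= 16400} == set(
        motif("G16129A-C16223T-C16291T-T16298C"))
    m35 = cumulative_motif(tree, "M35b2a1")
    assert {v for v in m35 if v.position >= 16024} == set(
        motif("G16129A-C16223T-A16230G-C16233T-T16304C-C16344T"))


@pytest.mark.parametrize("name,text,ranges,expect_candidate", [
    ("M5a1b1a1", "G16129A-C16223T-C16291T-T16298C", HVS1, True),
    ("M35b2a1", "G16129A-C16223T-A16230G-C16233T-T16304C-C16344T",
     HVS1, True),
    ("M18", "T246C-C16223T-A16318T", HVS12, True),
    ("U3", "A16343G", HVS1, True),
    ("H24", "A16293G-G16213A", HVS1, True),
])
def test_printed_motifs_classify_to_their_clades(tree, name, text, ranges,
                                                 expect_candidate):
    h = hap(name, text, ranges=ranges)
    a = classify(h, tree)
    assert a.haplogroup == name
    assert a.candidate is expect_candidate
    assert not a.missing_covered


def test_classify_trivial_and_candidate_semantics(tree):
    a = classify(hap("rcrs"), tree)
    assert a.haplogroup == "ROOT" and a.score == 0 and not a.candidate
    # M18 record without HVS-II coverage stays an M18 candidate
    no_hvs2 = hap("malaga", "C16223T-A16318T", ranges=HVS1)
    a = classify(no_hvs2, tree)
    assert a.haplogroup == "M18" and a.candidate
    assert any(v.position == 246 for v in a.missing_uncovered)


def test_score_is_matched_minus_missing_covered(tree):
    # full-range record missing one covered diagnostic of M5a1b1a1
    full = cumulative_motif(tree, "M5a1b1a1")
    partial = frozenset(v for v in full if v.position != 3954)
    a = classify(hap("x", partial), tree)
    assert a.score == len(a.matched) - len(a.missing_covered)
    assert not a.candidate


def test_private_variants_are_free(tree):
    base = cumulative_motif(tree, "U3b1c")
    extra = frozenset(base) | {var("T4703C")}
    a = classify(hap("x", extra), tree)
    assert a.haplogroup == "U3b1c"
    assert a.extras == [var("T4703C")]


def test_classify_cumulative_motifs_recover_every_node(tree):
    for node in tree:
        m = cumulative_motif(tree, node.name)
        a = classify(hap(node.name, frozenset(m)), tree)
        assert a.haplogroup == node.name
        assert a.score == len(m)


def test_adding_missing_diagnostics_never_decreases_best_score(tree):
    target = "M5a1b1a1"
    m = sorted(cumulative_motif(tree, target),
               key=lambda v: (v.position, v.derived))
    carried = set()
    prev = None
    for v in m:
        carried.add(v)
        a = classify(hap("x", frozenset(carried)), tree)
        if prev is not None:
            assert a.score >= prev
        prev = a.score
    assert classify(hap("x", frozenset(carried)), tree).haplogroup == target


def test_simulated_databases_classify_perfectly(tree):
    cfg = SimConfig(n=200, seed=3, private_rate=1.0,
                    composition={"M5": 0.4, "U3": 0.4, "L2c": 0.2})
    db, truth = simulate_database(cfg, tree)
    assignments = classify_db(db, tree)
    got = [assignments[r].haplogroup for r in truth["id"]]
    assert got == list(truth["haplogroup"])


def test_search_motif_planted_carriers(tree):
    m5 = "G16129A-C16223T-C16291T-T16298C"
    carriers = [hap(f"c{i}", m5, ranges=HVS1) for i in range(4)]
    distract = [hap("d1", "A16343G", ranges=HVS1),
                hap("d2", "C16223T-T16304C", ranges=HVS1)]
    short = [hap("s1", "C16223T", ranges=((16200, 16250),))]
    db = HaplotypeDB(carriers + distract + short)
    hits, not_ev = search_motif(db, motif(m5))
    assert sorted(h.id for h in hits) == [f"c{i}" for i in range(4)]
    assert [h.id for h in not_ev] == ["s1"]
    assert not (set(hits) & set(not_ev))
    with pytest.raises(ValueError):
        search_motif(db, [])
    assert search_motif(HaplotypeDB([]), motif(m5)) == ([], [])


def test_search_motif_haplogroup_exclusion(tree):
    h24 = "A16293G-G16213A"
    # an L1b record compatible with the H24 motif must be disregarded
    l1b = hap("l1b", cumulative_motif(tree, "L1b"))
    true_h24 = hap("h24", h24, ranges=HVS1)
    db = HaplotypeDB([l1b, true_h24])
    hits, _ = search_motif(db, motif(h24), exclude=["L1b", "A2"], tree=tree)
    assert [h.id for h in hits] == ["h24"]
    hits_all, _ = search_motif(db, motif(h24))
    assert len(hits_all) == 2
    with pytest.raises(KeyError, match="unknown haplogroup"):
        search_motif(db, motif(h24), exclude=["NOPE"], tree=tree)


def test_alias_resolves_u3_landmark(tree):
    t = load_tree(["#alias A16344G=A16343G", "ROOT", "\tU3\tA16344G"])
    assert cumulative_motif(t, "U3") == {var("A16343G")}
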