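"""Synthetic genealogies, mutation sprinkling and database generation."""

import numpy as np
import pytest

from mitorho.haplogroups import classify_db, cumulative_motif, search_motif
from mitorho.parsimony import build_tree, tree_length
from mitorho.simulate import (
    DEFAULT_SPECTRUM,
    MutationSpectrum,
    SimConfig,
    observable_spectrum,
    simulate_database,
    simulate_genealogy,
    sprinkle_mutations,
)


def test_spectrum_normalised_and_validated():
    w = np.asarray(DEFAULT_SPECTRUM.probabilities())
    assert w.sum() == pytest.approx(1.0)
    assert w[16182 - 1] > w[8000 - 1]  # hotspot outweighs baseline
    with pytest.raises(ValueError):
        MutationSpectrum(weights=(0.5, 0.5))
    with pytest.raises(ValueError):
        SimConfig(n=0)
    with pytest.raises(ValueError):
        SimConfig(composition={"M5": 0.7})


def test_single_tip_genealogy():
    g = simulate_genealogy(SimConfig(n=1, tmrca_years=500.0, seed=1))
    assert g.n == 1 and len(g.tips()) == 1


def test_star_genealogy_structure():
    g = simulate_genealogy(SimConfig(n=10, model="star",
                                     tmrca_years=1000.0, seed=1))
    assert len(g.root.children) == 10
    assert all(c.length_years == 1000.0 for c in g.root.children)
    assert g.tmrca_years == 1000.0


def test_coalescent_ultrametric_and_rescaled():
    g = simulate_genealogy(SimConfig(n=15, model="coalescent",
                                     tmrca_years=3000.0, seed=8))
    depths = g.tip_depths()
    assert len(depths) == 15
    assert max(depths.values()) == pytest.approx(min(depths.values()))
    assert g.tmrca_years == pytest.approx(3000.0)


def test_coalescent_total_length_matches_closed_form():
    # E[L] = 2 * (2 Ne g) * sum_{j<n} 1/j for the unrescaled coalescent
    n, ne, gy = 20, 500.0, 25.0
    expect = 2 * 2 * ne * gy * sum(1 / j for j in range(1, n))
    rng = np.random.default_rng(0)
    totals = []
    for _ in range(300):
        cfg = SimConfig(n=n, model="coalescent", tmrca_years=None,
                        ne_females=ne, generation_years=gy,
                        seed=int(rng.integers(2 ** 31)))
        totals.append(simulate_genealogy(cfg).total_branch_length())
    mean = np.mean(totals)
    se = np.std(totals, ddof=1) / np.sqrt(len(totals))
    assert abs(mean - expect) < 3 * se


def test_zero_rate_gives_root_haplotypes():
    g = simulate_genealogy(SimConfig(n=6, model="star",
                                     tmrca_years=1000.0, seed=3))
    haps, truth = sprinkle_mutations(g, rate=0.0, seed=4)
    assert all(not h.variants for h in haps)
    assert tree_length(truth) == 0


def test_poisson_mean_mutations_per_tip():
    g = simulate_genealogy(SimConfig(n=200, model="star",
                                     tmrca_years=2 * 3624.0, seed=5))
    haps, _ = sprinkle_mutations(g, spectrum=observable_spectrum(), seed=6)
    counts = [len(h.variants) for h in haps]
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(np.mean(counts) - 2.0) < 3 * se


def test_no_within_lineage_repeats_and_truth_tree_consistency():
    g = simulate_genealogy(SimConfig(n=30, model="coalescent",
                                     tmrca_years=30000.0, seed=9))
    haps, truth = sprinkle_mutations(g, rate=1 / 1000.0, seed=10)
    for h in haps:
        positions = [v.position for v in h.variants]
        assert len(positions) == len(set(positions))
    assert truth.n == 30
    truth.validate()


def test_force_perfect_phylogeny_option():
    g = simulate_genealogy(SimConfig(n=25, model="coalescent",
                                     tmrca_years=40000.0, seed=11))
    haps, truth = sprinkle_mutations(g, rate=1 / 900.0, seed=12,
                                     force_perfect=True)
    positions = [v.position for node in truth.nodes()
                 for v in node.mutations]
    assert len(positions) == len(set(positions))
    built = build_tree([h.masked() for h in haps], method="greedy")
    assert tree_length(built) == len({
        (v.position, v.derived) for h in haps
        for v in h.masked().variants})


def test_same_seed_bit_identical_different_seed_differs():
    def run(seed):
        g = simulate_genealogy(SimConfig(n=12, model="coalescent",
                                         tmrca_years=8000.0, seed=21))
        haps, _ = sprinkle_mutations(g, seed=seed, rate=1 / 500.0)
        return [(h.id, tuple(sorted(str(v) for v in h.variants)))
                for h in haps]

    assert run(7) == run(7)
    assert run(7) != run(8)


def test_database_composition_exact_and_truth_roundtrip(tree):
    cfg = SimConfig(n=400, seed=13, private_rate=0.0,
                    composition={"M(×M1)": 0.25, "N": 0.745, "L": 0.005})
    db, truth = simulate_database(cfg, tree)
    assert len(db) == 400
    assert truth["component"].value_counts().to_dict() == {
        "N": 298, "M(×M1)": 100, "L": 2}
    assignments = classify_db(db, tree)
    assert all(assignments[r].haplogroup == hg
               for r, hg in zip(truth["id"], truth["haplogroup"]))


def test_database_single_node_zero_private_identical_records(tree):
    cfg = SimConfig(n=20, seed=14, private_rate=0.0,
                    composition={"M5a1b1a1": 1.0})
    db, _ = simulate_database(cfg, tree)
    expected = frozenset(cumulative_motif(tree, "M5a1b1a1"))
    assert all(h.variants == expected for h in db)


def test_database_planted_motif_carriers_found_by_search(tree):
    cfg = SimConfig(n=120, seed=15, private_rate=0.5,
                    composition={"M5a1b1a1": 0.25, "U3": 0.5, "H24": 0.25})
    db, truth = simulate_database(cfg, tree)
    motif = sorted(cumulative_motif(tree, "M5a1b1a1"),
                   key=lambda v: v.position)
    hits, not_ev = search_motif(db, motif)
    planted = set(truth.loc[truth["haplogroup"] == "M5a1b1a1", "id"])
    assert {h.id for h in hits} == planted
    assert not not_ev


def test_database_hvs1_range_mode_respects_record_ranges(tree):
    cfg = SimConfig(n=30, seed=16, private_rate=1.0, range_mode="hvs1",
                    composition={"M5a1b1a1": 1.0})
    db, _ = simulate_database(cfg, tree)
    for h in db:
        assert not h.problems()
        assert all(16024 <= v.position <= 16400 for v in h.variants)


def test_database_unknown_component_raises(tree):
    cfg = SimConfig(n=10, seed=1, composition={"NOPE": 1.0})
    with pytest.raises(KeyError):
        simulate_database(cfg, tree)
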