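"""Parsimony tree construction, the exhaustive oracle and recurrence."""

import numpy as np
import pytest

from mitorho.parsimony import (
    annotate_recurrence,
    brute_force_min,
    build_tree,
    tree_length,
)
from mitorho.simulate import SimConfig, simulate_genealogy, sprinkle_mutations

from conftest import hap, motif, var


def random_instances(driver_seed, count, n_lo=3, n_hi=7, max_sites=12):
    """Coalescent-derived oracle-sized instances (hotspot-masked)."""
    rng = np.random.default_rng(driver_seed)
    made = 0
    while made < count:
        n = int(rng.integers(n_lo, n_hi + 1))
        cfg = SimConfig(n=n, model="coalescent", tmrca_years=4000.0,
                        seed=int(rng.integers(2 ** 31)))
        g = simulate_genealogy(cfg)
        haps, _truth = sprinkle_mutations(g, rate=1 / 800.0,
                                          seed=int(rng.integers(2 ** 31)))
        haps = [h.masked() for h in haps]
        sites = {(v.position, v.derived) for h in haps for v in h.variants}
        if not sites or len(sites) > max_sites:
            continue
        made += 1
        yield haps


def test_single_haplotype_gives_single_branch():
    h = hap("a", "T1000C-G2000A-T3000C")
    t = build_tree([h])
    assert tree_length(t) == 3
    assert t.n == 1
    table = t.branch_table()
    assert len(table) == 1 and table.loc[0, "m"] == 3


def test_star_configuration_five_identical_plus_one_step():
    root = frozenset(motif("A2833G-T7759C-T8895C-C11119T-T12783C-T15262C"))
    haps = [hap(f"r{i}", root) for i in range(5)]
    haps.append(hap("x", frozenset(root) | {var("T4703C")}))
    t = build_tree(haps, root_variants=root)
    assert tree_length(t) == 1
    tips = sorted(t.tips(), key=lambda n: n.multiplicity)
    assert [n.multiplicity for n in tips] == [1, 5]
    assert t.n == 6
    assert not annotate_recurrence(t)


def test_root_only_tree_has_length_zero():
    t = build_tree([hap(f"r{i}") for i in range(4)])
    assert tree_length(t) == 0 and t.n == 4


def test_star_with_private_mutations():
    haps = [hap(f"s{i}", frozenset({var(f"{1000 + i}T")}))
            for i in range(8)]
    t = build_tree(haps)
    assert tree_length(t) == 8
    assert all(n.multiplicity == 1 for n in t.tips())


def test_strict_mode_rejects_unmasked_hotspots():
    h = hap("a", "T16182C-T16298C")
    with pytest.raises(ValueError, match="hotspot"):
        build_tree([h])
    t = build_tree([h.masked()])
    assert tree_length(t) == 1


def test_brute_force_closed_forms():
    # perfect-phylogeny instance: length equals segregating sites
    a = hap("a", "T1000C-G2000A")
    b = hap("b", "T1000C-T3000C")
    assert brute_force_min([a, b]) == 3
    # disjoint private sets: j + k
    c = hap("c", "T1000C-G2000A-T3000C")
    d = hap("d", "C5000T-A6000G")
    assert brute_force_min([c, d]) == 5
    # one homoplasic site forces sites + 1
    e = hap("e", "T1000C-G2000A")
    f = hap("f", "T1000C")
    g = hap("g", "G2000A")
    assert brute_force_min([e, f, g]) == 3


def test_brute_force_guards_instance_size():
    haps = [hap(f"h{i}", frozenset({var(f"{1000 + i}T")}))
            for i in range(8)]
    with pytest.raises(ValueError, match="too large"):
        brute_force_min(haps)


def test_build_tree_matches_oracle_on_random_instances():
    for haps in random_instances(20250901, 200):
        t = build_tree(haps)
        assert tree_length(t) == brute_force_min(haps), \
            [sorted(map(str, h.variants)) for h in haps]


def test_path_reconstruction_invariant_on_random_instances():
    for haps in random_instances(77, 120, n_hi=12, max_sites=25):
        t = build_tree(haps)
        t.validate({h.id: frozenset(h.variants) for h in haps})


def test_collapsing_duplicates_preserves_length():
    for haps in random_instances(5150, 40):
        doubled = haps + [
            hap(h.id + "_dup", h.variants) for h in haps]
        t1 = build_tree(haps)
        t2 = build_tree(doubled)
        assert tree_length(t1) == tree_length(t2)
        assert t2.n == 2 * t1.n


def test_rooted_relative_to_basal_motif_gains_and_losses():
    root = frozenset(motif("T1000C-G2000A"))
    # one haplotype lost a root variant: that is a back-mutation event
    h = hap("a", frozenset({var("T1000C")}))
    t = build_tree([h], root_variants=root)
    assert tree_length(t) == 1
    (branch,) = list(t.branches())
    assert branch.mutations[0].back_mutation
    assert t.tip_variants(list(t.tips())[0]) == h.variants


def test_recurrence_annotation():
    # site 2000 conflicts with site 1000: one extra event, at 2000
    a = hap("a", "T1000C-G2000A")
    b = hap("b", "T1000C-T3000C")
    c = hap("c", "C4000T-G2000A")
    t = build_tree([a, b, c])
    assert tree_length(t) == 5  # 4 segregating sites + 1 recurrence
    assert annotate_recurrence(t) == [(2000, 2)]
    # perfect phylogenies carry no recurrence
    t2 = build_tree([hap("a", "T1000C"), hap("b", "G2000A")])
    assert annotate_recurrence(t2) == []


def test_forced_homoplasy_from_generator_is_annotated():
    from mitorho.simulate import MutationSpectrum
    w = np.full(16569, 1e-6)
    w[5000 - 1] = 1.0  # concentrate the spectrum on one site
    spec = MutationSpectrum(weights=tuple(w / w.sum()), ts_tv_ratio=1e9)
    cfg = SimConfig(n=12, model="star", tmrca_years=3624.0, seed=2)
    g = simulate_genealogy(cfg)
    haps, truth = sprinkle_mutations(g, rate=1 / 3624.0, spectrum=spec,
                                     seed=3)
    rec = dict(annotate_recurrence(truth))
    carriers = sum(1 for h in haps
                   if any(v.position == 5000 for v in h.variants))
    assert carriers >= 2        # star lineages hit the same site
    assert rec.get(5000) == carriers


def test_deterministic_output_and_newick_export():
    for haps in random_instances(99, 10):
        t1 = build_tree(haps)
        t2 = build_tree(list(reversed(haps)))
        assert t1.to_newick() == t2.to_newick()
        assert t1.branch_table().equals(t2.branch_table())
        assert t1.to_newick().endswith(";")


def test_greedy_matches_exact_on_compatible_sites():
    for haps in random_instances(123, 40):
        exact = tree_length(build_tree(haps, method="exact"))
        greedy = tree_length(build_tree(haps, method="greedy"))
        assert greedy >= exact
        if not annotate_recurrence(build_tree(haps, method="exact")):
            assert greedy == exact
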