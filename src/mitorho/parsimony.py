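"""Rooted maximum-parsimony trees for sets of closely related haplotypes.

Trees are rooted at a designated basal motif (the clade root haplotype),
identical haplotypes collapse into one tip with a multiplicity, and every
branch carries the list of mutations placed on it, so the structures feed
directly into rho/sigma founder dating.

Construction strategy
---------------------
Differences from the root (including losses of root variants, which become
back-mutation events) are treated as binary presence/absence characters.
For instances within the verification bounds (at most 7 distinct
haplotypes and 12 segregating characters) the search is exact: all rooted
binary topologies are scored and the best reconstruction is returned.
Beyond those bounds a documented greedy heuristic is used: haplotypes are
recursively partitioned on the character carried by most of them, ties
preferring the less mutable site, so recurrent events are pushed onto
hypermutable positions. :func:`brute_force_min` is an independently coded
exhaustive oracle used by the test-suite to guard the heuristic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .haplotypes import Haplotype, SeqRange
from .reference import MT_LENGTH, hotspot_weight
from .variants import (
    DEFAULT_HOTSPOT_POLICY,
    HotspotPolicy,
    Variant,
    format_variant,
)

EXACT_MAX_HAPLOTYPES = 7
EXACT_MAX_SITES = 12


class PhyloNode:
    """Tree node; ``mutations`` sit on the branch to the parent."""

    __slots__ = ("parent", "children", "mutations", "tip_ids", "multiplicity")

    def __init__(self, mutations=(), tip_ids=(), multiplicity=0):
        self.parent: PhyloNode | None = None
        self.children: list[PhyloNode] = []
        self.mutations: list[Variant] = list(mutations)
        self.tip_ids: tuple[str, ...] = tuple(tip_ids)
        self.multiplicity: int = multiplicity

    def add(self, child: "PhyloNode") -> "PhyloNode":
        child.parent = self
        self.children.append(child)
        return child

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    @property
    def n_tips_below(self) -> int:
        return sum(n.multiplicity for n in self.walk())


@dataclass
class Branch:
    """Flat view of one branch: mutation count and tips below it."""

    parent: str
    child: str
    mutations: list[Variant]
    n_tips_below: int

    @property
    def m(self) -> int:
        return len(self.mutations)


class PhyloTree:
    """Rooted parsimony tree over collapsed haplotypes."""

    def __init__(self, root: PhyloNode, root_variants=frozenset(),
                 scope: str = "whole_molecule"):
        self.root = root
        self.root_variants = frozenset(root_variants)
        self.scope = scope

    @property
    def n(self) -> int:
        """Number of sampled haplotypes, multiplicity-weighted."""
        return self.root.n_tips_below

    def nodes(self):
        return self.root.walk()

    def branches(self):
        """Every non-root node as a :class:`Branch` (named deterministically)."""
        names = self._node_names()
        for node in self.nodes():
            if node.parent is None:
                continue
            yield Branch(names[id(node.parent)], names[id(node)],
                         list(node.mutations), node.n_tips_below)

    def _node_names(self):
        names = {}
        counter = 0
        for node in self.nodes():
            if node.parent is None:
                names[id(node)] = "root"
            elif node.tip_ids and not node.children:
                names[id(node)] = node.tip_ids[0]
            else:
                counter += 1
                names[id(node)] = f"node{counter}"
        return names

    def tip_variants(self, node: PhyloNode) -> frozenset[Variant]:
        """Variant set implied by the root motif plus the path to ``node``."""
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        state = set(self.root_variants)
        for n in reversed(path):
            for v in n.mutations:
                if v.back_mutation:
                    state.discard(v.reverted())
                else:
                    # a re-gain undoes an earlier loss of a root variant
                    state.add(v)
            # normalise: a back-mutation variant never persists as state
        return frozenset(state)

    def tips(self):
        for node in self.nodes():
            if node.multiplicity:
                yield node

    def validate(self, haplotypes: dict[str, frozenset] | None = None):
        """Check the path-reconstruction invariant; raise on violation."""
        for node in self.tips():
            implied = self.tip_variants(node)
            if haplotypes is not None:
                for tid in node.tip_ids:
                    if frozenset(haplotypes[tid]) != implied:
                        raise AssertionError(
                            f"tip {tid}: path reconstruction mismatch")
        return True

    def to_newick(self) -> str:
        names = self._node_names()

        def fmt(node):
            label = names[id(node)]
            if node.multiplicity:
                label += f"_x{node.multiplicity}"
            muts = " ".join(format_variant(v) for v in node.mutations)
            comment = f"[&mutations={muts}]" if muts else ""
            if node.children:
                inner = ",".join(fmt(c) for c in node.children)
                return f"({inner}){label}:{len(node.mutations)}{comment}"
            return f"{label}:{len(node.mutations)}{comment}"

        return fmt(self.root) + ";"

    def branch_table(self) -> pd.DataFrame:
        rows = [{
            "parent": b.parent,
            "child": b.child,
            "mutations": " ".join(format_variant(v) for v in b.mutations),
            "m": b.m,
            "n_tips_below": b.n_tips_below,
        } for b in self.branches()]
        return pd.DataFrame(
            rows, columns=["parent", "child", "mutations", "m",
                           "n_tips_below"])


def tree_length(t: PhyloTree) -> int:
    """Parsimony score: total number of mutation events on the tree."""
    return sum(len(node.mutations) for node in t.nodes()
               if node.parent is not None)


def annotate_recurrence(t: PhyloTree) -> list[tuple[int, int]]:
    """Positions mutating more than once on the tree (events, not tips)."""
    counts: Counter[int] = Counter()
    for node in t.nodes():
        for v in node.mutations:
            counts[v.position] += 1
    return sorted((pos, k) for pos, k in counts.items() if k > 1)


# ---------------------------------------------------------------------------
# characters and collapsing

@dataclass(frozen=True)
class _Char:
    """Binary character: presence of one event relative to the root."""

    key: tuple
    var_on: Variant    # event taking root state -> derived state
    var_off: Variant   # the reverse event


def _characters(haps: list[Haplotype], root_variants: frozenset[Variant]):
    keys = {}
    incidence: list[set] = []
    for h in haps:
        hv = frozenset(h.variants)
        row = set()
        for v in hv - root_variants:
            key = ("gain", v.position, v.derived)
            if key not in keys:
                keys[key] = _Char(key, v, v.reverted())
            row.add(key)
        for v in root_variants - hv:
            key = ("loss", v.position, v.derived)
            if key not in keys:
                keys[key] = _Char(key, v.reverted(), v)
            row.add(key)
        incidence.append(row)
    return keys, incidence


def _collapse(haps: list[Haplotype], incidence):
    groups: dict[frozenset, list] = {}
    for h, row in zip(haps, incidence):
        groups.setdefault(frozenset(row), []).append(h.id)
    out = []
    for residue, ids in groups.items():
        out.append((residue, tuple(sorted(ids))))
    out.sort(key=lambda g: g[1])
    return out


# ---------------------------------------------------------------------------
# exact search (topology enumeration + per-character reconstruction)

def _topologies(n: int):
    """All rooted binary topologies over tip indices 0..n-1 (nested tuples)."""
    def insert_everywhere(tree, tip):
        yield (tip, tree)
        if isinstance(tree, tuple):
            a, b = tree
            for na in insert_everywhere(a, tip):
                yield (na, b)
            for nb in insert_everywhere(b, tip):
                yield (a, nb)

    def rec(k):
        if k == 1:
            yield 0
            return
        for t in rec(k - 1):
            yield from insert_everywhere(t, k - 1)

    yield from rec(n)


def _fitch_planes(topo, tipstates, full):
    """Bottom-up Fitch over bit-plane encoded binary characters.

    Returns (plane0, plane1, changes) where plane bits mark characters
    whose preliminary state set contains 0 (resp. 1).
    """
    if isinstance(topo, int):
        p0, p1 = tipstates[topo]
        return p0, p1, 0
    a0, a1, ca = _fitch_planes(topo[0], tipstates, full)
    b0, b1, cb = _fitch_planes(topo[1], tipstates, full)
    i0, i1 = a0 & b0, a1 & b1
    inter = i0 | i1
    disjoint = full & ~inter
    p0 = i0 | ((a0 | b0) & disjoint)
    p1 = i1 | ((a1 | b1) & disjoint)
    return p0, p1, ca + cb + bin(disjoint).count("1")


def _exact_tree(groups, chars, char_order):
    """Best rooted reconstruction over all topologies (deterministic)."""
    k = len(groups)
    nchars = len(char_order)
    full = (1 << nchars) - 1
    index = {key: i for i, key in enumerate(char_order)}
    tipstates = []
    for residue, _ids in groups:
        m1 = 0
        for key in residue:
            m1 |= 1 << index[key]
        tipstates.append((full & ~m1, m1))

    best = None
    best_topo = None
    for topo in _topologies(k):
        p0, p1, changes = _fitch_planes(topo, tipstates, full)
        changes += bin(full & ~p0).count("1")  # root forced ancestral
        if best is None or changes < best:
            best, best_topo = changes, topo

    # second pass on the winning topology: explicit state assignment
    def planes(t):
        if isinstance(t, int):
            p0, p1 = tipstates[t]
            return {"topo": t, "p0": p0, "p1": p1, "kids": []}
        left, right = planes(t[0]), planes(t[1])
        i0, i1 = left["p0"] & right["p0"], left["p1"] & right["p1"]
        inter = i0 | i1
        disjoint = full & ~inter
        return {"topo": t,
                "p0": i0 | ((left["p0"] | right["p0"]) & disjoint),
                "p1": i1 | ((left["p1"] | right["p1"]) & disjoint),
                "kids": [left, right]}

    annotated = planes(best_topo)

    root = PhyloNode()

    def assign(info, parent_state, parent_node):
        # prefer keeping the parent's state; flip only when forced
        state = 0
        for i in range(nchars):
            bit = 1 << i
            parent_bit = parent_state & bit
            if parent_bit:
                state |= bit if (info["p1"] & bit) else 0
            else:
                state |= 0 if (info["p0"] & bit) else bit
        flips = state ^ parent_state
        muts = []
        for i in range(nchars):
            if flips & (1 << i):
                char = chars[char_order[i]]
                muts.append(char.var_on if state & (1 << i) else char.var_off)
        muts.sort(key=lambda v: (v.position, v.derived))
        node = parent_node.add(PhyloNode(mutations=muts))
        if isinstance(info["topo"], int):
            _residue, ids = groups[info["topo"]]
            node.tip_ids = ids
            node.multiplicity = 0  # multiplicity filled in later
        for kid in info["kids"]:
            assign(kid, state, node)
        return node

    assign(annotated, 0, root)
    return root


# ---------------------------------------------------------------------------
# greedy recursive partition (used beyond the exact bounds)

def _greedy_tree(groups, chars, mutability):
    def weight(key):
        if mutability is not None:
            return mutability.get(key[1], 1.0)
        return hotspot_weight(key[1])

    root = PhyloNode()

    def rec(node, members):
        # members: list of (residue set, ids); attach finished ones here
        remaining = []
        for residue, ids in members:
            if residue:
                remaining.append((set(residue), ids))
            else:
                leaf = node.add(PhyloNode())
                leaf.tip_ids = ids
        while remaining:
            counts: Counter = Counter()
            for residue, _ids in remaining:
                counts.update(residue)
            # most carriers first; among ties the least mutable site, so
            # recurrent events land on hypermutable positions
            key = min(counts,
                      key=lambda k: (-counts[k], weight(k), k[1], k[2]))
            under = [(res - {key}, ids) for res, ids in remaining
                     if key in res]
            remaining = [(res, ids) for res, ids in remaining
                         if key not in res]
            child = node.add(PhyloNode(mutations=[chars[key].var_on]))
            rec(child, under)

    rec(root, list(groups))
    return root


def _tidy(root: PhyloNode) -> PhyloNode:
    """Collapse empty branches and unary chains; set multiplicities.

    Tip groups joined by mutation-free branches merge into one tip; a
    tip's multiplicity is the number of haplotype ids it carries.
    """

    def collapse(node):
        for child in list(node.children):
            collapse(child)
        # merge children connected by mutation-free branches into this node
        merged = True
        while merged:
            merged = False
            for child in list(node.children):
                if not child.mutations:
                    node.children.remove(child)
                    for gc in child.children:
                        node.add(gc)
                    node.tip_ids = tuple(sorted(node.tip_ids
                                                + child.tip_ids))
                    merged = True
        # splice unary pass-through nodes (no payload, single child)
        for child in list(node.children):
            while (len(child.children) == 1 and not child.tip_ids):
                only = child.children[0]
                child.mutations.extend(only.mutations)
                child.tip_ids = only.tip_ids
                child.children = only.children
                for gc in child.children:
                    gc.parent = child

    collapse(root)
    for node in root.walk():
        node.multiplicity = len(node.tip_ids)
        node.mutations.sort(key=lambda v: (v.position, v.derived))
    _order_children(root)
    return root


def _order_children(root: PhyloNode):
    def sort_key(node):
        first = (node.mutations[0].position if node.mutations
                 else MT_LENGTH + 1)
        tip = min(node.tip_ids) if node.tip_ids else ""
        below = min((t for n in node.walk() for t in n.tip_ids),
                    default="")
        return (first, below, tip)

    for node in root.walk():
        node.children.sort(key=sort_key)


CONTROL_REGION = (SeqRange(16024, MT_LENGTH), SeqRange(1, 576))


def _infer_scope(haps) -> str:
    def in_cr(r):
        return any(r.start >= c.start and r.end <= c.end
                   for c in CONTROL_REGION)

    if all(any((r.end - r.start + 1) >= 15000 for r in h.ranges)
           for h in haps):
        return "whole_molecule"
    if all(all(in_cr(r) for r in h.ranges) for h in haps):
        return "control_region"
    return "mixed"


def build_tree(haps: list[Haplotype],
               root_variants=frozenset(),
               method: str = "auto",
               mutability: dict[int, float] | None = None,
               policy: HotspotPolicy = DEFAULT_HOTSPOT_POLICY,
               strict: bool = True) -> PhyloTree:
    """Build a rooted maximum-parsimony tree for a clade.

    ``root_variants`` is the clade's basal motif (empty = the reference
    itself). ``method`` is ``"auto"`` (exact within the verification
    bounds, greedy beyond), ``"exact"`` or ``"greedy"``. In strict mode a
    haplotype still carrying hotspot variation is an error.
    """
    if method not in ("auto", "exact", "greedy"):
        raise ValueError(f"unknown method {method!r}")
    if not haps:
        raise ValueError("no haplotypes given")
    if strict:
        for h in haps:
            bad = [v for v in h.variants if policy.masks(v)]
            if bad:
                raise ValueError(
                    f"haplotype {h.id} carries unmasked hotspot variants: "
                    + " ".join(format_variant(v) for v in bad))
    root_variants = frozenset(root_variants)
    chars, incidence = _characters(haps, root_variants)
    groups = _collapse(haps, incidence)

    scope = _infer_scope(haps)
    nonempty = [(res, ids) for res, ids in groups if res]
    root = PhyloNode()
    for res, ids in groups:
        if not res:
            root.tip_ids = ids

    if nonempty:
        char_order = sorted({k for res, _ids in nonempty for k in res})
        small = (len(nonempty) <= EXACT_MAX_HAPLOTYPES
                 and len(char_order) <= EXACT_MAX_SITES)
        if method == "exact" and not small:
            raise ValueError(
                "instance too large for exact search: "
                f"{len(nonempty)} haplotypes, {len(char_order)} sites")
        use_exact = method == "exact" or (method == "auto" and small)
        if use_exact:
            built = _exact_tree(nonempty, chars, char_order)
        else:
            built = _greedy_tree(nonempty, chars, mutability)
        for child in built.children:
            root.add(child)
        if built.tip_ids:
            root.tip_ids = tuple(sorted(root.tip_ids + built.tip_ids))

    _tidy(root)
    tree = PhyloTree(root, root_variants=root_variants, scope=scope)
    tree.validate({h.id: frozenset(h.variants) for h in haps})
    return tree


# ---------------------------------------------------------------------------
# independent exhaustive oracle

def brute_force_min(haps: list[Haplotype], root_variants=frozenset()) -> int:
    """Exact minimum mutation count, by exhaustive enumeration.

    Independent of :func:`build_tree`: characters are raw symmetric
    differences from the root, every rooted binary topology over the
    distinct haplotypes is scored with set-based Fitch counting, and the
    root state is forced to the basal motif. Guarded to at most
    7 distinct haplotypes and 12 segregating sites.
    """
    root_variants = frozenset(root_variants)
    residues = sorted(
        {frozenset(h.variants) ^ root_variants for h in haps},
        key=lambda s: sorted((v.position, v.derived) for v in s))
    residues = [r for r in residues if r]
    if not residues:
        return 0
    sites = sorted({(v.position, v.derived) for r in residues for v in r})
    if len(residues) > EXACT_MAX_HAPLOTYPES or len(sites) > EXACT_MAX_SITES:
        raise ValueError(
            f"instance too large: {len(residues)} haplotypes, "
            f"{len(sites)} segregating sites")

    tip_sets = [frozenset((v.position, v.derived) for v in r)
                for r in residues]

    def fitch(topo):
        if isinstance(topo, int):
            return [frozenset([s in tip_sets[topo]]) for s in sites], 0
        left, lc = fitch(topo[0])
        right, rc = fitch(topo[1])
        states, changes = [], lc + rc
        for a, b in zip(left, right):
            inter = a & b
            if inter:
                states.append(inter)
            else:
                states.append(a | b)
                changes += 1
        return states, changes

    best = None
    for topo in _topologies(len(residues)):
        states, changes = fitch(topo)
        changes += sum(1 for s in states if False not in s)
        if best is None or changes < best:
            best = changes
    return best
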