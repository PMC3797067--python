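"""Synthetic genealogies, haplotypes and mixed databases with known truth.

The generator emulates the regimes a founder-effect analysis must handle:
star-like clades of near-identical haplotypes (recent expansion), deeper
Kingman-coalescent genealogies, Poisson mutation accumulation over a
hotspot-weighted site spectrum, and mixed databases with a known
haplogroup composition. Every draw comes from one seeded NumPy generator
stream, so a given seed reproduces outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplogroups import HaplogroupTree, cumulative_motif
from .haplotypes import (
    FULL_RANGE,
    HVS1_RANGE_DEFAULT,
    Haplotype,
    HaplotypeDB,
    SeqRange,
)
from .parsimony import PhyloNode, PhyloTree, _tidy
from .reference import (
    MT_LENGTH,
    TRANSITION_PARTNER,
    hotspot_weight,
    synthetic_reference,
)
from .variants import Variant, _classify


@dataclass(frozen=True)
class MutationSpectrum:
    """Per-site relative mutability and the transition:transversion ratio.

    The default weights every position 1 except known hypermutable sites
    (the 16182/16183/16519 hotspots and the 303-315 length-variable
    tract, plus a few fast control-region sites), and uses a strongly
    transition-biased ratio, as mtDNA control-region data show.
    """

    weights: tuple[float, ...] = ()
    ts_tv_ratio: float = 20.0

    def __post_init__(self):
        if not self.weights:
            w = np.array([hotspot_weight(p) for p in range(1, MT_LENGTH + 1)])
            object.__setattr__(self, "weights", tuple(w / w.sum()))
        else:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != MT_LENGTH:
                raise ValueError(
                    f"spectrum needs {MT_LENGTH} weights, got {len(w)}")
            if (w < 0).any():
                raise ValueError("negative mutability weight")
            object.__setattr__(self, "weights", tuple(w / w.sum()))
        if self.ts_tv_ratio < 0:
            raise ValueError("ts:tv ratio must be non-negative")

    def probabilities(self) -> np.ndarray:
        return np.asarray(self.weights)


DEFAULT_SPECTRUM = MutationSpectrum()


def observable_spectrum(ts_tv_ratio: float = 20.0) -> MutationSpectrum:
    """Uniform spectrum over the sites that survive hotspot masking.

    Parameter-recovery experiments use this so that every simulated
    mutation is countable by the estimator; with the default spectrum a
    small fraction of events lands on masked hotspots and is invisible
    downstream.
    """
    from .reference import HOTSPOT_POSITIONS, LENGTH_VARIATION_REGION

    w = np.ones(MT_LENGTH)
    for pos in HOTSPOT_POSITIONS:
        w[pos - 1] = 0.0
    lo, hi = LENGTH_VARIATION_REGION
    w[lo - 1:hi] = 0.0
    return MutationSpectrum(weights=tuple(w), ts_tv_ratio=ts_tv_ratio)


@dataclass
class SimConfig:
    """Parameters of one simulation run.

    Genealogy: ``n`` tips, ``model`` in {star, coalescent},
    ``tmrca_years`` (coalescent trees are rescaled to it when given,
    otherwise heights follow from ``ne_females`` and
    ``generation_years``), ``mu`` mutations per molecule per year.
    Databases: ``composition`` maps clade expressions to fractions,
    ``private_rate`` is the Poisson mean of extra private mutations per
    record.
    """

    n: int = 20
    model: str = "star"
    tmrca_years: float | None = 1000.0
    mu: float = 1.0 / 3624.0
    spectrum: MutationSpectrum = field(default_factory=MutationSpectrum)
    seed: int = 0
    ne_females: float = 1000.0
    generation_years: float = 25.0
    composition: dict[str, float] | None = None
    private_rate: float = 0.0
    range_mode: str = "full"     # "full" or "hvs1"
    group: str = "romani"
    population: str = "sim"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.model not in ("star", "coalescent"):
            raise ValueError(f"unknown genealogy model {self.model!r}")
        if self.mu < 0 or self.private_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.composition is not None:
            total = sum(self.composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("composition fractions must sum to 1")


class GenNode:
    """Genealogy node; ``length_years`` is the branch to the parent."""

    __slots__ = ("parent", "children", "length_years", "tip_id")

    def __init__(self, length_years=0.0, tip_id=None):
        self.parent = None
        self.children = []
        self.length_years = length_years
        self.tip_id = tip_id

    def add(self, child):
        child.parent = self
        self.children.append(child)
        return child

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class Genealogy:
    """Ultrametric rooted genealogy with branch lengths in years."""

    root: GenNode
    model: str
    tmrca_years: float
    n: int
    seed: int

    def tips(self):
        return [node for node in self.root.walk() if node.tip_id is not None]

    def total_branch_length(self) -> float:
        return sum(node.length_years for node in self.root.walk())

    def tip_depths(self) -> dict[str, float]:
        out = {}
        for tip in self.tips():
            depth, node = 0.0, tip
            while node.parent is not None:
                depth += node.length_years
                node = node.parent
            out[tip.tip_id] = depth
        return out


def simulate_genealogy(cfg: SimConfig) -> Genealogy:
    """Simulate a star or Kingman-coalescent genealogy.

    Star trees have ``n`` branches of exactly ``tmrca_years``. Coalescent
    trees draw exponential waiting times (rate k(k-1)/2 per 2*Ne_f
    generations) and are linearly rescaled to ``tmrca_years`` when that
    is set; the realised height is recorded either way.
    """
    rng = np.random.default_rng(cfg.seed)
    ids = [f"sim{i:04d}" for i in range(cfg.n)]
    if cfg.model == "star" or cfg.n == 1:
        t = float(cfg.tmrca_years if cfg.tmrca_years is not None else 0.0)
        root = GenNode()
        for tid in ids:
            root.add(GenNode(length_years=t, tip_id=tid))
        return Genealogy(root, cfg.model, t, cfg.n, cfg.seed)

    scale_years = 2.0 * cfg.ne_females * cfg.generation_years
    nodes = [GenNode(tip_id=tid) for tid in ids]
    heights = {id(node): 0.0 for node in nodes}
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(scale_years / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = GenNode()
        parent.add(a)
        parent.add(b)
        a.length_years = t - heights[id(a)]
        b.length_years = t - heights[id(b)]
        heights[id(parent)] = t
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    height = t
    if cfg.tmrca_years is not None and height > 0:
        factor = cfg.tmrca_years / height
        for node in root.walk():
            node.length_years *= factor
        height = cfg.tmrca_years
    return Genealogy(root, cfg.model, height, cfg.n, cfg.seed)


def _draw_variant(rng, position: int, ref: str, ts_tv: float) -> Variant:
    partner = TRANSITION_PARTNER[ref]
    if rng.random() < ts_tv / (ts_tv + 1.0):
        derived = partner
    else:
        derived = rng.choice([b for b in "ACGT" if b not in (ref, partner)])
    return Variant(position, ref, str(derived), _classify(ref, str(derived)))


def sprinkle_mutations(gen: Genealogy, rate: float | None = None,
                       spectrum: MutationSpectrum = DEFAULT_SPECTRUM,
                       seed: int = 0, force_perfect: bool = False,
                       ) -> tuple[list[Haplotype], PhyloTree]:
    """Drop Poisson mutations on a genealogy; return haplotypes + truth tree.

    Per-branch counts are Poisson(rate * branch_years); positions are
    drawn from the spectrum with no repeat along a root-to-tip lineage
    (no back mutations are simulated). With ``force_perfect`` a position
    is used at most once in the whole tree, guaranteeing a perfect
    phylogeny. The returned tree is the true mutation-labelled genealogy
    in parsimony-tree form (identical haplotypes collapsed).
    """
    if rate is None:
        rate = 1.0 / 3624.0
    if rate < 0:
        raise ValueError("mutation rate must be non-negative")
    rng = np.random.default_rng(seed)
    probs = spectrum.probabilities()
    ref = synthetic_reference()
    positions = np.arange(1, MT_LENGTH + 1)
    used_global: set[int] = set()

    branch_muts: dict[int, list[Variant]] = {}

    def place(node, path_positions):
        muts = []
        local = set()
        if node.parent is not None:
            k = rng.poisson(rate * node.length_years)
            for _ in range(k):
                for _attempt in range(1000):
                    pos = int(rng.choice(positions, p=probs))
                    if pos in path_positions or pos in local:
                        continue
                    if force_perfect and pos in used_global:
                        continue
                    break
                else:  # pragma: no cover - spectrum exhausted
                    raise RuntimeError("could not place mutation")
                used_global.add(pos)
                local.add(pos)
                muts.append(_draw_variant(rng, pos, ref[pos - 1],
                                          spectrum.ts_tv_ratio))
        branch_muts[id(node)] = muts
        child_path = path_positions | {v.position for v in muts}
        for c in node.children:
            place(c, child_path)

    place(gen.root, set())

    haps = []
    for tip in gen.tips():
        state: set[Variant] = set()
        node, chain = tip, []
        while node is not None:
            chain.append(node)
            node = node.parent
        for nd in reversed(chain):
            state.update(branch_muts[id(nd)])
        haps.append(Haplotype(id=tip.tip_id, population="sim",
                              group="unknown",
                              ranges=(SeqRange(*FULL_RANGE),),
                              variants=frozenset(state), source="simulated"))

    truth = _truth_tree(gen, branch_muts)
    return haps, truth


def _truth_tree(gen: Genealogy, branch_muts) -> PhyloTree:
    def convert(gnode):
        pnode = PhyloNode(mutations=branch_muts[id(gnode)])
        if gnode.tip_id is not None:
            pnode.tip_ids = (gnode.tip_id,)
        for c in gnode.children:
            pnode.add(convert(c))
        return pnode

    root = convert(gen.root)
    _tidy(root)  # zero-mutation branches collapse, identical tips merge
    return PhyloTree(root, root_variants=frozenset(),
                     scope="whole_molecule")


def simulate_database(cfg: SimConfig, tree: HaplogroupTree,
                      ) -> tuple[HaplotypeDB, pd.DataFrame]:
    """Draw a mixed database with known haplogroup composition.

    Record counts per component follow the composition exactly (largest
    remainder rounding); each record carries the cumulative motif of a
    node drawn uniformly from its component plus Poisson private
    mutations placed away from every diagnostic or hotspot position. The
    truth table maps each record to its haplogroup and private variants.
    """
    if cfg.composition is None:
        raise ValueError("cfg.composition is required")
    rng = np.random.default_rng(cfg.seed)
    components = sorted(cfg.composition.items())
    eligible = {expr: tree.resolve_expr(expr) for expr, _f in components}

    # exact counts by largest remainder
    raw = [(expr, frac * cfg.n) for expr, frac in components]
    counts = {expr: int(x) for expr, x in raw}
    short = cfg.n - sum(counts.values())
    for expr, _x in sorted(raw, key=lambda t: -(t[1] - int(t[1])))[:short]:
        counts[expr] += 1

    diagnostic_positions = {
        v.position for node in tree for v in node.diagnostic}
    probs = cfg.spectrum.probabilities().copy()
    for pos in diagnostic_positions:
        probs[pos - 1] = 0.0
    from .reference import HOTSPOT_POSITIONS, LENGTH_VARIATION_REGION
    for pos in HOTSPOT_POSITIONS:
        probs[pos - 1] = 0.0
    lo, hi = LENGTH_VARIATION_REGION
    probs[lo - 1:hi] = 0.0
    probs = probs / probs.sum()
    positions = np.arange(1, MT_LENGTH + 1)
    ref = synthetic_reference()

    ranges = ((SeqRange(*FULL_RANGE),) if cfg.range_mode == "full"
              else (SeqRange(*HVS1_RANGE_DEFAULT),))
    records, truth_rows = [], []
    i = 0
    for expr, _frac in components:
        for _ in range(counts[expr]):
            node_name = str(rng.choice(eligible[expr]))
            motif = cumulative_motif(tree, node_name)
            taken = {v.position for v in motif}
            privates = []
            for _k in range(rng.poisson(cfg.private_rate)):
                while True:
                    pos = int(rng.choice(positions, p=probs))
                    if pos not in taken:
                        break
                taken.add(pos)
                privates.append(_draw_variant(rng, pos, ref[pos - 1],
                                              cfg.spectrum.ts_tv_ratio))
            variants = frozenset(
                v for v in set(motif) | set(privates)
                if any(v.position in r for r in ranges))
            rec_id = f"db{i:05d}"
            i += 1
            records.append(Haplotype(
                id=rec_id, population=cfg.population, group=cfg.group,
                ranges=ranges, variants=variants, source="simulated"))
            truth_rows.append({
                "id": rec_id, "component": expr, "haplogroup": node_name,
                "n_private": len(privates),
                "private": " ".join(str(v) for v in sorted(
                    privates, key=lambda v: v.position)),
            })
    db = HaplotypeDB(records, provenance={
        "generator": "mitorho.simulate.simulate_database",
        "seed": cfg.seed, "n": cfg.n})
    truth = pd.DataFrame(
        truth_rows, columns=["id", "component", "haplogroup", "n_private",
                             "private"])
    return db, truth
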