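"""Diagnostic-variant haplogroup trees, classification and motif search.

Tree file format: one node per line, depth given by leading tabs, then the
clade name, then space-separated diagnostic variant tokens for the branch
leading to that clade (back mutations allowed). ``#`` starts a comment;
two directives are recognised in comments::

    #version: <tag>
    #alias OLDTOKEN=NEWTOKEN   # published synonym -> canonical token
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .haplotypes import Haplotype, HaplotypeDB
from .variants import Variant, VariantError, parse_variant


@dataclass
class HaplogroupNode:
    name: str
    diagnostic: list[Variant] = field(default_factory=list)
    children: list["HaplogroupNode"] = field(default_factory=list)
    parent: "HaplogroupNode | None" = None
    depth: int = 0


class HaplogroupTree:
    """Rooted tree of named clades carrying diagnostic variants."""

    def __init__(self, root: HaplogroupNode, version: str = "",
                 aliases: dict[str, str] | None = None):
        self.root = root
        self.version = version
        self.aliases = dict(aliases or {})
        self.by_name: dict[str, HaplogroupNode] = {}
        for node in self._walk(root):
            if node.name in self.by_name:
                raise ValueError(f"duplicate haplogroup name {node.name!r}")
            self.by_name[node.name] = node

    @staticmethod
    def _walk(node):
        yield node
        for child in node.children:
            yield from HaplogroupTree._walk(child)

    def __iter__(self):
        return self._walk(self.root)

    def __contains__(self, name: str) -> bool:
        return name in self.by_name

    def node(self, name: str) -> HaplogroupNode:
        try:
            return self.by_name[name]
        except KeyError:
            raise KeyError(f"unknown haplogroup {name!r}") from None

    def path(self, name: str) -> list[HaplogroupNode]:
        node = self.node(name)
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out[::-1]

    def is_under(self, name: str, ancestor: str) -> bool:
        """True when ``name`` equals or descends from ``ancestor``."""
        anc = self.node(ancestor)
        node = self.node(name)
        while node is not None:
            if node is anc:
                return True
            node = node.parent
        return False

    def resolve_expr(self, expr: str) -> list[str]:
        """Expand a clade expression to the names it covers.

        Grammar: ``NAME`` (the clade and everything below it) or
        ``NAME(×A,B)`` / ``NAME(xA,B)`` excluding the named subclades.
        """
        expr = expr.strip()
        excludes: list[str] = []
        if "(" in expr:
            base, _, rest = expr.partition("(")
            rest = rest.rstrip(")")
            for marker in ("×", "x"):
                if rest.startswith(marker):
                    rest = rest[len(marker):]
                    break
            else:
                raise ValueError(f"bad clade expression {expr!r}")
            excludes = [e.strip() for e in rest.split(",") if e.strip()]
            expr = base.strip()
        base_node = self.node(expr)
        for e in excludes:
            self.node(e)  # raise on unknown names
        return [n.name for n in self._walk(base_node)
                if not any(self.is_under(n.name, e) for e in excludes)]


def load_tree(source, ref_check: str = "strict") -> HaplogroupTree:
    """Load a haplogroup tree from an indented text file or line iterable."""
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source, encoding="utf-8") as fh:
            lines = fh.readlines()
    else:
        lines = list(source)

    version = ""
    aliases: dict[str, str] = {}
    stack: list[HaplogroupNode] = []
    root: HaplogroupNode | None = None
    for line_no, line in enumerate(lines, start=1):
        stripped = line.strip()
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.lower().startswith("version:"):
                version = body.split(":", 1)[1].strip()
            elif body.lower().startswith("alias "):
                old, _, new = body[6:].partition("=")
                aliases[old.strip()] = new.strip()
            continue
        if not stripped:
            continue
        depth = len(line) - len(line.lstrip("\t"))
        if line.lstrip("\t").startswith(" "):
            raise ValueError(
                f"line {line_no}: indentation must use tabs")
        fields = stripped.split()
        name, tokens = fields[0], fields[1:]
        diagnostics = []
        for tok in tokens:
            tok = aliases.get(tok, tok)
            try:
                diagnostics.append(parse_variant(tok, ref_check=ref_check))
            except VariantError as exc:
                raise VariantError(f"line {line_no} ({name}): {exc}") from exc
        node = HaplogroupNode(name, diagnostics, depth=depth)
        if depth == 0:
            if root is not None:
                raise ValueError(f"line {line_no}: multiple root nodes")
            root = node
        else:
            if depth > len(stack):
                raise ValueError(
                    f"line {line_no}: indentation jumps by more than one")
            parent = stack[depth - 1]
            node.parent = parent
            parent.children.append(node)
        del stack[depth:]
        stack.append(node)
    if root is None:
        raise ValueError("tree file contains no nodes")
    return HaplogroupTree(root, version=version, aliases=aliases)


def packaged_tree() -> HaplogroupTree:
    """The packaged mini haplogroup tree (see data/mini_tree.txt)."""
    text = (resources.files("mitorho.data") / "mini_tree.txt").read_text()
    return load_tree(text.splitlines())


def _motif_key(v: Variant):
    # back mutation at a position cancels the earlier variant there;
    # insertions live in their own keyspace
    if v.derived.startswith("+"):
        return (v.position, v.derived)
    return (v.position, None)


def cumulative_motif(tree: HaplogroupTree, name: str) -> set[Variant]:
    """Union of diagnostics from the root to ``name``.

    A back mutation on the path removes the earlier variant at the same
    position; a later different derived state overwrites an earlier one.
    """
    cache = tree.__dict__.setdefault("_motif_cache", {})
    if name in cache:
        return set(cache[name])
    state: dict = {}
    for node in tree.path(name):
        for v in node.diagnostic:
            key = _motif_key(v)
            if v.back_mutation:
                state.pop(key, None)
            else:
                state[key] = v
    cache[name] = frozenset(state.values())
    return set(state.values())


@dataclass
class Assignment:
    """Best-matching haplogroup for one record.

    ``score = |matched| - |missing_covered|``; private variants are free.
    ``candidate`` is set when diagnostics fall outside the record's
    sequenced range, i.e. the assignment cannot be confirmed from the
    available segment alone.
    """

    haplotype_id: str
    haplogroup: str
    matched: list[Variant]
    missing_covered: list[Variant]
    missing_uncovered: list[Variant]
    extras: list[Variant]
    score: int
    candidate: bool


def _score_node(h: Haplotype, motif: set[Variant]):
    hv = set(h.variants)
    matched, missing_cov, missing_uncov = [], [], []
    for v in sorted(motif, key=lambda v: (v.position, v.derived)):
        if v in hv:
            matched.append(v)
        elif h.covers(v.position):
            missing_cov.append(v)
        else:
            missing_uncov.append(v)
    return matched, missing_cov, missing_uncov


def classify(h: Haplotype, tree: HaplogroupTree,
             exclude_incomplete: bool = False) -> Assignment:
    """Assign a (hotspot-masked) record to its best haplogroup.

    Ties break by score, then fewer uncovered diagnostics (so partial
    records are not pulled into deep clades they carry no evidence
    for), then depth (deeper wins), then name. With
    ``exclude_incomplete`` nodes whose covered diagnostics are not all
    present are skipped (useful to sideline records with apparent
    documentation errors).
    """
    best = None
    for node in tree:
        motif = cumulative_motif(tree, node.name)
        matched, missing_cov, missing_uncov = _score_node(h, motif)
        if exclude_incomplete and missing_cov and node.parent is not None:
            continue
        score = len(matched) - len(missing_cov)
        key = (score, -len(missing_uncov), node.depth)
        if best is not None:
            b_node = best[0]
            b_key = (len(best[1]) - len(best[2]), -len(best[3]),
                     b_node.depth)
            if not (key > b_key
                    or (key == b_key and node.name < b_node.name)):
                continue
        best = (node, matched, missing_cov, missing_uncov)
    node, matched, missing_cov, missing_uncov = best
    motif = cumulative_motif(tree, node.name)
    extras = sorted(set(h.variants) - set(matched),
                    key=lambda v: (v.position, v.derived))
    return Assignment(
        haplotype_id=h.id,
        haplogroup=node.name,
        matched=matched,
        missing_covered=missing_cov,
        missing_uncovered=missing_uncov,
        extras=extras,
        score=len(matched) - len(missing_cov),
        candidate=bool(missing_uncov),
    )


def classify_db(db: HaplotypeDB, tree: HaplogroupTree,
                **kwargs) -> dict[str, Assignment]:
    return {h.id: classify(h, tree, **kwargs) for h in db}


def search_motif(db: HaplotypeDB, motif: list[Variant],
                 exclude: list[str] | None = None,
                 tree: HaplogroupTree | None = None,
                 ) -> tuple[list[Haplotype], list[Haplotype]]:
    """Range-aware motif search with haplogroup exclusions.

    Returns ``(hits, not_evaluable)``: hits cover and carry every motif
    variant and do not classify under an excluded clade; records lacking
    coverage of at least one motif position are not evaluable.
    """
    if not motif:
        raise ValueError("empty search motif")
    exclude = list(exclude or [])
    if exclude and tree is None:
        raise ValueError("haplogroup exclusions require a tree")
    for name in exclude:
        if tree is not None:
            tree.node(name)  # raise on unknown clade names
    hits, not_evaluable = [], []
    for h in db:
        if not all(h.covers(v.position) for v in motif):
            not_evaluable.append(h)
            continue
        if not all(v in h.variants for v in motif):
            continue
        if exclude:
            assignment = classify(h, tree)
            if any(tree.is_under(assignment.haplogroup, e) for e in exclude):
                continue
        hits.append(h)
    return hits, not_evaluable
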