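"""Haplogroup frequency tables, diversity counts and the phylogeographic
ancestry partition (admixture estimate) for classified databases.

Category schemes and partition rules are data, not code: both are lists of
clade expressions (``M``, ``M(×M1)``, ...) resolved against the haplogroup
tree, shipped as editable YAML files under ``mitorho/data/``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from .haplogroups import Assignment, HaplogroupTree
from .haplotypes import HaplotypeDB, SeqRange

_NORM_TOL = 1e-9


@dataclass
class CategoryScheme:
    """Ordered mapping of haplogroups to display categories.

    Each category lists the clade expressions it covers; the first
    matching category wins and ``other`` catches everything else,
    including records that could not be assigned below the root.
    """

    id: str
    categories: list[tuple[str, list[str]]]
    other_label: str = "other"

    @classmethod
    def from_yaml(cls, path_or_text) -> "CategoryScheme":
        if hasattr(path_or_text, "read"):
            doc = yaml.safe_load(path_or_text)
        else:
            text = str(path_or_text)
            if "\n" not in text and text.endswith((".yaml", ".yml")):
                with open(text, encoding="utf-8") as fh:
                    doc = yaml.safe_load(fh)
            else:
                doc = yaml.safe_load(text)
        cats = [(c["name"], list(c["clades"])) for c in doc["categories"]]
        return cls(id=doc.get("id", "scheme"), categories=cats,
                   other_label=doc.get("other_label", "other"))

    def category_of(self, haplogroup: str, tree: HaplogroupTree) -> str:
        for name, exprs in self.categories:
            for expr in exprs:
                if haplogroup in tree.resolve_expr(expr):
                    return name
        return self.other_label


def default_scheme() -> CategoryScheme:
    text = (resources.files("mitorho.data") / "categories.yaml").read_text()
    return CategoryScheme.from_yaml(text)


@dataclass
class PartitionRules:
    """Clade expressions defining the ancestry components.

    The default mirrors a simple phylogeographic reading of maternal
    lineages: South Asian = macro-haplogroup M excluding M1, sub-Saharan
    = the L clades outside M and N, West Eurasian = N-derived lineages
    plus M1, ``other`` = everything left over. The alternative reading
    that treats M1a1 as African is a different rules file, not code.
    """

    id: str
    components: list[tuple[str, list[str]]]
    other_label: str = "other"

    @classmethod
    def from_yaml(cls, path_or_text) -> "PartitionRules":
        text = str(path_or_text)
        if "\n" not in text and text.endswith((".yaml", ".yml")):
            with open(text, encoding="utf-8") as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(text)
        comps = [(c["name"], list(c["clades"])) for c in doc["components"]]
        return cls(id=doc.get("id", "rules"), components=comps,
                   other_label=doc.get("other_label", "other"))


def default_partition_rules() -> PartitionRules:
    text = (resources.files("mitorho.data") /
            "partition_rules.yaml").read_text()
    return PartitionRules.from_yaml(text)


@dataclass
class FrequencyTable:
    """Per-group haplogroup-category counts and fractions."""

    scheme_id: str
    counts: pd.DataFrame     # index: group label, columns: categories
    fractions: pd.DataFrame

    def __post_init__(self):
        sums = self.fractions.sum(axis=1)
        if not ((sums - 1.0).abs() < _NORM_TOL).all():
            raise AssertionError("per-group fractions do not sum to 1")

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        for col in self.fractions.columns:
            out[f"{col}_frac"] = self.fractions[col]
            out[f"{col}_pct"] = (self.fractions[col] * 100).round(1)
        out.to_csv(path, sep="\t", index_label="group")


def frequency_table(db: HaplotypeDB, assignments: dict[str, Assignment],
                    tree: HaplogroupTree,
                    scheme: CategoryScheme | None = None,
                    by: str = "population") -> FrequencyTable:
    """Tabulate haplogroup-category frequencies per group label.

    ``by`` selects the grouping field (``population`` or ``group``);
    every record must have an assignment.
    """
    scheme = scheme or default_scheme()
    missing = [h.id for h in db if h.id not in assignments]
    if missing:
        raise ValueError(
            f"records without assignment: {', '.join(missing[:5])}"
            + ("..." if len(missing) > 5 else ""))
    rows = []
    for h in db:
        hg = assignments[h.id].haplogroup
        rows.append({"group": getattr(h, by),
                     "category": scheme.category_of(hg, tree)})
    frame = pd.DataFrame(rows)
    counts = (frame.value_counts(["group", "category"]).unstack(fill_value=0)
              .sort_index())
    order = [name for name, _ in scheme.categories] + [scheme.other_label]
    counts = counts.reindex(
        columns=[c for c in order if c in counts.columns], fill_value=0)
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return FrequencyTable(scheme.id, counts, fractions)


@dataclass(frozen=True)
class AdmixtureEstimate:
    """Phylogeographically partitioned ancestry fractions."""

    fractions: dict[str, float]
    rule_set: str
    n: int

    def __post_init__(self):
        total = sum(self.fractions.values())
        if self.n and abs(total - 1.0) > _NORM_TOL:
            raise AssertionError("ancestry fractions do not sum to 1")
        if any(f < 0 for f in self.fractions.values()):
            raise AssertionError("negative ancestry fraction")

    def as_percent(self) -> dict[str, float]:
        return {k: round(100 * v, 1) for k, v in self.fractions.items()}

    def to_tsv(self, path) -> None:
        rows = [{"component": k, "fraction": v,
                 "percent": round(100 * v, 1)}
                for k, v in self.fractions.items()]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def ancestry_partition(assignments: dict[str, Assignment],
                       tree: HaplogroupTree,
                       rules: PartitionRules | None = None,
                       ) -> AdmixtureEstimate:
    """Partition classified records into ancestry components.

    Components are tested in rule order; a record joins the first
    component whose clade expressions contain its haplogroup. The result
    is invariant to record order and database duplication.
    """
    rules = rules or default_partition_rules()
    resolved = [(name, {hg for expr in exprs
                        for hg in tree.resolve_expr(expr)})
                for name, exprs in rules.components]
    counts = {name: 0 for name, _ in resolved}
    counts[rules.other_label] = counts.get(rules.other_label, 0)
    n = 0
    for assignment in assignments.values():
        n += 1
        for name, members in resolved:
            if assignment.haplogroup in members:
                counts[name] += 1
                break
        else:
            counts[rules.other_label] += 1
    fractions = {k: (v / n if n else 0.0) for k, v in counts.items()}
    return AdmixtureEstimate(fractions=fractions, rule_set=rules.id, n=n)


@dataclass(frozen=True)
class DiversitySummary:
    """Distinctness of haplotypes within a clade on a common range."""

    n_records: int
    n_distinct_haplotypes: int
    fraction_basal: float

    def __post_init__(self):
        if self.n_records >= 1 and not (
                1 <= self.n_distinct_haplotypes <= self.n_records):
            raise AssertionError("distinct-haplotype count out of bounds")


def diversity_summary(records, basal_motif,
                      common_range: SeqRange | None = None
                      ) -> DiversitySummary:
    """Count distinct haplotypes and the basal-motif fraction of a clade.

    Records are compared on ``common_range`` (default: the intersection
    of all declared ranges); ``fraction_basal`` is the share of records
    whose variants on that range equal the basal motif restricted to it.
    """
    records = list(records)
    if not records:
        raise ValueError("empty record set")
    if common_range is None:
        start = max(min(r.start for r in h.ranges) for h in records)
        end = min(max(r.end for r in h.ranges) for h in records)
        if start > end:
            raise ValueError("records share no common sequenced range")
        common_range = SeqRange(start, end)
    basal = frozenset(v for v in basal_motif
                      if v.position in common_range)
    seen = set()
    n_basal = 0
    for h in records:
        restricted = h.restricted([common_range])
        seen.add(restricted)
        if restricted == basal:
            n_basal += 1
    return DiversitySummary(
        n_records=len(records),
        n_distinct_haplotypes=len(seen),
        fraction_basal=n_basal / len(records),
    )
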