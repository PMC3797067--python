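"""Haplotype records, tab-separated database I/O, and alignment diffing.

Table dialect (tab-separated, header required)::

    id  population  group  ranges  variants  source

``ranges`` is ``start-end`` pairs joined by ``;`` (1-based, inclusive);
``variants`` is space-separated variant tokens, ``.`` for none; ``group``
is one of ``romani`` / ``non_romani`` / ``unknown``. Writers emit the same
dialect the readers accept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .reference import MT_LENGTH, check_position, synthetic_reference
from .variants import (
    DEFAULT_HOTSPOT_POLICY,
    DELETION,
    HotspotPolicy,
    Variant,
    VariantError,
    _classify,
    format_variant,
    parse_variant,
)

GROUPS = ("romani", "non_romani", "unknown")
REQUIRED_COLUMNS = ("id", "population", "group", "ranges", "variants")

#: Default HVS-I window; covers every control-region motif this package
#: ships. Some compilations stop at 16365 — pass your own range then.
HVS1_RANGE_DEFAULT = (16024, 16400)
HVS2_RANGE_DEFAULT = (57, 372)
FULL_RANGE = (1, MT_LENGTH)


@dataclass(frozen=True, order=True)
class SeqRange:
    """Inclusive 1-based rCRS interval covered by a record."""

    start: int
    end: int

    def __post_init__(self):
        check_position(self.start)
        check_position(self.end)
        if self.start > self.end:
            raise ValueError(f"range start {self.start} > end {self.end}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    def __str__(self):
        return f"{self.start}-{self.end}"


def parse_ranges(text: str) -> tuple[SeqRange, ...]:
    out = []
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            start, end = part.split("-")
            out.append(SeqRange(int(start), int(end)))
        except ValueError as exc:
            raise ValueError(f"bad range {part!r}: {exc}") from exc
    return tuple(out)


def format_ranges(ranges) -> str:
    return ";".join(str(r) for r in ranges)


@dataclass(frozen=True)
class Haplotype:
    """One mtDNA record: labels, sequenced range(s) and its variant set."""

    id: str
    population: str = ""
    group: str = "unknown"
    ranges: tuple[SeqRange, ...] = (SeqRange(*FULL_RANGE),)
    variants: frozenset[Variant] = frozenset()
    source: str = ""

    def covers(self, position: int) -> bool:
        return any(position in r for r in self.ranges)

    def restricted(self, ranges) -> frozenset[Variant]:
        """Variants whose position falls inside any of ``ranges``."""
        return frozenset(
            v for v in self.variants if any(v.position in r for r in ranges))

    def masked(self, policy: HotspotPolicy = DEFAULT_HOTSPOT_POLICY):
        return replace(self, variants=frozenset(
            v for v in self.variants if not policy.masks(v)))

    def problems(self) -> list[str]:
        """Invariant violations, empty when the record is well formed."""
        out = []
        if self.group not in GROUPS:
            out.append(f"unknown group label {self.group!r}")
        if not self.ranges:
            out.append("record declares no sequenced range")
        for v in self.variants:
            if not self.covers(v.position):
                out.append(
                    f"variant {format_variant(v)} outside declared ranges")
        seen: dict[int, Variant] = {}
        for v in sorted(self.variants, key=lambda v: (v.position, v.derived)):
            if v.derived.startswith("+"):
                continue  # insertions anchor next to a position
            if v.position in seen:
                out.append(f"position {v.position} appears more than once")
            seen[v.position] = v
        return out


@dataclass
class HaplotypeDB:
    """A collection of haplotype records with unique ids."""

    records: list[Haplotype] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [h.id for h in self.records]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {', '.join(dups)}")
        self._by_id = {h.id: h for h in self.records}

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, record_id: str) -> Haplotype:
        return self._by_id[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    def subset(self, ids) -> "HaplotypeDB":
        return HaplotypeDB([self._by_id[i] for i in ids],
                           dict(self.provenance))


@dataclass
class TableDiagnostics:
    """Row-level outcome of reading a haplotype table."""

    n_read: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str, str]] = field(default_factory=list)

    def summary(self) -> str:
        return (f"{self.n_accepted}/{self.n_read} rows accepted, "
                f"{len(self.rejected)} rejected")


def read_haplotype_table(path, ref_check: str = "strict"
                         ) -> tuple[HaplotypeDB, TableDiagnostics]:
    """Read a tab-separated haplotype table.

    Malformed rows are rejected with per-row diagnostics rather than
    aborting the read; missing required columns or duplicate ids raise.
    """
    diags = TableDiagnostics()
    records: list[Haplotype] = []
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty table")
        header = [c.strip() for c in header_line.rstrip("\n").split("\t")]
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ValueError(
                f"{path}: missing required columns: {', '.join(missing)}")
        idx = {c: header.index(c) for c in header}
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            diags.n_read += 1
            cells = line.split("\t")
            rec_id = cells[idx["id"]].strip() if len(cells) > idx["id"] else ""
            try:
                if len(cells) < len(REQUIRED_COLUMNS):
                    raise ValueError("too few columns")
                ranges = parse_ranges(cells[idx["ranges"]])
                var_field = cells[idx["variants"]].strip()
                variants = frozenset(
                    parse_variant(tok, ref_check=ref_check)
                    for tok in var_field.split()
                    if tok != ".")
                source = (cells[idx["source"]].strip()
                          if "source" in idx and len(cells) > idx["source"]
                          else "")
                hap = Haplotype(
                    id=rec_id,
                    population=cells[idx["population"]].strip(),
                    group=cells[idx["group"]].strip() or "unknown",
                    ranges=ranges,
                    variants=variants,
                    source=source,
                )
                probs = hap.problems()
                if probs:
                    raise ValueError("; ".join(probs))
                if not rec_id:
                    raise ValueError("empty record id")
            except (ValueError, VariantError) as exc:
                diags.rejected.append((line_no, rec_id, str(exc)))
                continue
            records.append(hap)
            diags.n_accepted += 1
    db = HaplotypeDB(records, provenance={"path": str(path),
                                          "read": diags.summary()})
    return db, diags


def write_haplotype_table(db: HaplotypeDB, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tpopulation\tgroup\tranges\tvariants\tsource\n")
        for h in db:
            toks = " ".join(format_variant(v) for v in sorted(
                h.variants, key=lambda v: (v.position, v.derived)))
            fh.write("\t".join([
                h.id, h.population, h.group, format_ranges(h.ranges),
                toks or ".", h.source]) + "\n")


def diff_aligned(seq: str, window: SeqRange, ref: str | None = None,
                 policy: HotspotPolicy = DEFAULT_HOTSPOT_POLICY,
                 ) -> set[Variant]:
    """Variants of an rCRS-aligned sequence slice against the reference.

    ``seq`` must have the same length as ``window``; ``ref`` is the
    full-length reference (defaults to the packaged synthetic stand-in).
    ``N`` sites are ignored. Gap columns are reported as deletions except
    inside the masked length-variation tract, where they are dropped.
    IUPAC-ambiguous sites become flagged heteroplasmies.
    """
    if ref is None:
        ref = synthetic_reference()
    width = window.end - window.start + 1
    if len(seq) != width:
        raise ValueError(
            f"sequence length {len(seq)} != window width {width}")
    lo, hi = policy.masked_region
    out: set[Variant] = set()
    for offset, raw in enumerate(seq):
        pos = window.start + offset
        state = raw.upper()
        r = ref[pos - 1].upper()
        if state in ("N", r):
            continue
        if state == "-":
            if lo <= pos <= hi:
                continue
            out.add(Variant(pos, r, "del", DELETION))
        elif state in "ACGT":
            out.add(Variant(pos, r, state, _classify(r, state)))
        else:
            out.add(Variant(pos, r, state, _classify(r, state),
                            heteroplasmy=True))
    return out


def read_fasta_haplotypes(path, window: SeqRange, ref: str | None = None,
                          policy: HotspotPolicy = DEFAULT_HOTSPOT_POLICY,
                          population: str = "", group: str = "unknown",
                          source: str = "") -> HaplotypeDB:
    """Diff pre-aligned FASTA sequences (one window) into haplotype records."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        variants = diff_aligned(str(rec.seq), window, ref=ref, policy=policy)
        records.append(Haplotype(id=rec.id, population=population,
                                 group=group, ranges=(window,),
                                 variants=frozenset(variants),
                                 source=source))
    return HaplotypeDB(records, provenance={"path": str(path),
                                            "format": "fasta"})
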