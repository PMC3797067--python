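"""Parsing, formatting and hotspot masking of rCRS-relative mtDNA variants.

Accepted token dialects
-----------------------
``T16298C``      substitution with explicit reference base
``16223T``       substitution, reference base implied by the rCRS
``A16318T``      transversion (suffix base differs from transition partner)
``@16129``       back mutation (reversion to the rCRS state)
``@G16129A``     back mutation written as the reverted forward mutation
``315+C``        insertion of one or more bases after a position
``16166d``       deletion (``del`` also accepted)
``16093Y``       point heteroplasmy (IUPAC code); parsed but flagged

Annotation suffixes used in figure notation — ``s`` (synonymous), ``-t``
(tRNA), ``-r`` (rRNA), ``-nc`` (non-coding), a parenthesised amino-acid
replacement, and a ``*`` prefix for gene-overlap positions — are carried in
:attr:`Variant.annotation` and never affect equality or computation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace

from .reference import (
    IUPAC_AMBIGUOUS,
    TRANSITION_PARTNER,
    HOTSPOT_POSITIONS,
    LENGTH_VARIATION_REGION,
    check_position,
    ref_base,
)

TRANSITION = "transition"
TRANSVERSION = "transversion"
INSERTION = "insertion"
DELETION = "deletion"


class VariantError(ValueError):
    """Raised for malformed or rCRS-inconsistent variant tokens."""


@dataclass(frozen=True)
class Variant:
    """One rCRS-relative mutation.

    ``derived`` holds the state after the event: a single base for
    substitutions, ``"+BASES"`` for insertions, ``"del"`` for deletions.
    Equality and hashing use ``(position, derived, back_mutation)`` so the
    same mutation written in different dialects compares equal and the
    annotation never separates otherwise identical variants.
    """

    position: int
    ref: str
    derived: str
    klass: str
    back_mutation: bool = False
    heteroplasmy: bool = False
    annotation: str = ""

    def __eq__(self, other):
        if not isinstance(other, Variant):
            return NotImplemented
        return (self.position, self.derived, self.back_mutation) == (
            other.position, other.derived, other.back_mutation)

    def __hash__(self):
        return hash((self.position, self.derived, self.back_mutation))

    def __str__(self):
        return format_variant(self)

    def __repr__(self):
        return f"Variant({format_variant(self)!r})"

    @property
    def is_indel(self) -> bool:
        return self.klass in (INSERTION, DELETION)

    def reverted(self) -> "Variant":
        """The event undoing this one (a back mutation, or the re-gain)."""
        if self.is_indel:
            raise VariantError(f"cannot revert indel {self}")
        return replace(self, ref=self.derived, derived=self.ref,
                       back_mutation=not self.back_mutation, annotation="")


_TOKEN_RE = re.compile(
    r"""^
    (?P<prefix>[@*]{0,2})
    (?:
        (?P<ref>[ACGT])?(?P<pos>\d+)(?P<der>[ACGTRYSWKMBDHVN])
      | (?P<ipos>\d+)\+(?P<ins>[ACGT]+)
      | (?P<dref>[ACGT])?(?P<dpos>\d+)(?:d|del)
      | (?P<bpos>\d+)
    )
    (?P<ann>s|-t|-r|-nc|\([^()]*\))?
    $""",
    re.VERBOSE,
)


def _classify(ref: str, derived: str) -> str:
    if ref in "ACGT" and TRANSITION_PARTNER[ref] == derived:
        return TRANSITION
    if ref in "ACGT" and derived in "ACGT":
        return TRANSVERSION
    # reference base unknown, or ambiguous derived state: call it a
    # transition when the derived state is compatible with one (the
    # dominant mutation class in mtDNA), a transversion otherwise
    if derived in IUPAC_AMBIGUOUS:
        if ref in "ACGT" and TRANSITION_PARTNER[ref] in IUPAC_AMBIGUOUS[derived]:
            return TRANSITION
        return TRANSVERSION
    return TRANSITION


def _check_pos(token: str, position: int) -> None:
    try:
        check_position(position)
    except ValueError as exc:
        raise VariantError(f"token {token!r}: {exc}") from exc


def _check_ref(token: str, position: int, ref: str, ref_check: str) -> None:
    known = ref_base(position)
    if known is not None and ref in "ACGT" and ref != known:
        msg = (f"token {token!r}: reference base {ref} conflicts with "
               f"rCRS base {known} at position {position}")
        if ref_check == "strict":
            raise VariantError(msg)
        if ref_check == "warn":
            warnings.warn(msg, stacklevel=3)


def parse_variant(token: str, ref_check: str = "strict") -> Variant:
    """Parse one variant token into a classified :class:`Variant`.

    ``ref_check`` controls validation of explicit reference bases against
    the attested rCRS table: ``"strict"`` (error), ``"warn"``, ``"off"``.
    """
    if ref_check not in ("strict", "warn", "off"):
        raise ValueError(f"unknown ref_check mode {ref_check!r}")
    raw = token
    token = token.strip()
    if not token:
        raise VariantError("empty variant token")
    m = _TOKEN_RE.match(token)
    if m is None:
        raise VariantError(f"malformed variant token {raw!r}")
    prefix = m.group("prefix")
    back = "@" in prefix
    annotation = ("*" if "*" in prefix else "") + (m.group("ann") or "")

    if m.group("ipos"):  # insertion
        position = int(m.group("ipos"))
        _check_pos(raw, position)
        ref = ref_base(position) or "N"
        return Variant(position, ref, "+" + m.group("ins"), INSERTION,
                       annotation=annotation)

    if m.group("dpos"):  # deletion
        position = int(m.group("dpos"))
        _check_pos(raw, position)
        given = m.group("dref")
        if given:
            _check_ref(raw, position, given, ref_check)
        ref = given or ref_base(position) or "N"
        return Variant(position, ref, "del", DELETION, annotation=annotation)

    if m.group("bpos"):  # bare position: only meaningful as a back mutation
        if not back:
            raise VariantError(
                f"token {raw!r} has no derived state and no '@' prefix")
        position = int(m.group("bpos"))
        _check_pos(raw, position)
        derived = ref_base(position) or "N"
        ref = TRANSITION_PARTNER.get(derived, "N")
        return Variant(position, ref, derived, _classify(ref, derived),
                       back_mutation=True, annotation=annotation)

    position = int(m.group("pos"))
    _check_pos(raw, position)
    given_ref = m.group("ref")
    der = m.group("der")

    if back:
        # "@G16129A" reads as the reversion of the forward mutation
        # G16129A: state A reverts to the rCRS base G.
        if given_ref is not None:
            _check_ref(raw, position, given_ref, ref_check)
        derived = given_ref or ref_base(position) or "N"
        ref = der
        if der in IUPAC_AMBIGUOUS:
            raise VariantError(f"heteroplasmic back mutation {raw!r}")
        return Variant(position, ref, derived, _classify(derived, ref),
                       back_mutation=True, annotation=annotation)

    if given_ref is not None:
        _check_ref(raw, position, given_ref, ref_check)
    ref = given_ref or ref_base(position) or "N"
    het = der in IUPAC_AMBIGUOUS
    if der == ref:
        raise VariantError(
            f"token {raw!r}: derived state equals the reference base")
    return Variant(position, ref, der, _classify(ref, der),
                   heteroplasmy=het, annotation=annotation)


def format_variant(v: Variant) -> str:
    """Canonical token for a variant; inverse of :func:`parse_variant`."""
    star = "*" if v.annotation.startswith("*") else ""
    ann = v.annotation[1:] if star else v.annotation
    if v.klass == INSERTION:
        core = f"{v.position}{v.derived}"  # derived already holds "+BASES"
    elif v.klass == DELETION:
        core = f"{v.position}d"
    elif v.back_mutation:
        if v.derived == "N":
            return f"@{star}{v.position}{ann}"
        return f"@{star}{v.derived}{v.position}{v.ref}{ann}"
    else:
        ref = "" if v.ref == "N" else v.ref
        core = f"{ref}{v.position}{v.derived}"
    return f"{star}{core}{ann}"


def parse_motif(text: str, ref_check: str = "strict") -> list[Variant]:
    """Parse a dash-separated variant motif, preserving token order."""
    tokens = [t.strip() for t in text.strip().split("-")]
    out: list[Variant] = []
    for i, tok in enumerate(tokens):
        if not tok:
            continue
        try:
            out.append(parse_variant(tok, ref_check=ref_check))
        except VariantError as exc:
            raise VariantError(f"motif token #{i + 1}: {exc}") from exc
    return out


def format_motif(variants) -> str:
    return "-".join(format_variant(v) for v in variants)


@dataclass(frozen=True)
class HotspotPolicy:
    """Which hypermutable variation is excluded from phylogeny and dating.

    Defaults: point hotspots 16182/16183/16519 are dropped, indels within
    the 303-315 length-variable tract are dropped, and point
    heteroplasmies are dropped everywhere.
    """

    masked_positions: frozenset[int] = HOTSPOT_POSITIONS
    masked_region: tuple[int, int] = LENGTH_VARIATION_REGION
    drop_indels_in_region: bool = True
    drop_heteroplasmies: bool = True

    def masks(self, v: Variant) -> bool:
        if v.position in self.masked_positions:
            return True
        lo, hi = self.masked_region
        if self.drop_indels_in_region and v.is_indel and lo <= v.position <= hi:
            return True
        if self.drop_heteroplasmies and v.heteroplasmy:
            return True
        return False


DEFAULT_HOTSPOT_POLICY = HotspotPolicy()


def mask_hotspots(variants, policy: HotspotPolicy = DEFAULT_HOTSPOT_POLICY):
    """Return a new set without hotspot/heteroplasmic variation."""
    return {v for v in variants if not policy.masks(v)}
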