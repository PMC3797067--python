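"""Reference coordinate system for human mtDNA (rCRS, 16,569 bp).

All variant notation in this package is relative to the revised Cambridge
Reference Sequence (rCRS). The package does not ship the full reference
sequence; instead it carries:

* :data:`ATTESTED_BASES` — rCRS bases at positions attested by published
  full-form variant tokens (a token like ``T16298C`` states that the rCRS
  base at 16298 is T) plus a small set of canonical control-region facts.
  Reference-base validation is strict at these positions and permissive
  elsewhere.
* :func:`synthetic_reference` — a deterministic full-length stand-in
  sequence that agrees with the attested table and is random elsewhere.
  It is *synthetic*: suitable as the default reference for alignment
  diffing in tests and simulations, not a substitute for the real rCRS
  when analysing real data (pass your own reference then).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

MT_LENGTH = 16569

#: Watson-Crick transition partners; everything else is a transversion.
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: IUPAC ambiguity codes accepted as (point-heteroplasmy) derived states.
IUPAC_AMBIGUOUS = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# rCRS bases at attested positions. Control region first, then coding.
ATTESTED_BASES: dict[int, str] = {
    # control region, HVS-I
    16126: "T", 16129: "G", 16186: "C", 16189: "T", 16213: "G",
    16223: "C", 16230: "A", 16233: "C", 16249: "T", 16290: "C",
    16291: "C", 16293: "A", 16298: "T", 16304: "T", 16311: "T",
    16318: "A", 16319: "G", 16320: "C", 16343: "A", 16344: "C",
    16362: "T", 16519: "T",
    # control region, HVS-II / HVS-III
    73: "A", 93: "A", 146: "T", 152: "T", 185: "G", 195: "T",
    198: "C", 246: "T", 263: "A", 310: "T", 315: "C", 325: "C",
    334: "T", 456: "C",
    # coding region
    1303: "G", 2833: "A", 3621: "T", 3954: "C", 5153: "A", 5301: "A",
    5426: "T", 5471: "G", 6045: "C", 6152: "G", 6446: "G", 6461: "A",
    6680: "T", 7645: "T", 7759: "T", 8701: "A", 8895: "T", 9006: "A",
    9064: "G", 9833: "T", 10400: "C", 10754: "A", 11016: "G",
    11047: "C", 11119: "C", 12308: "A", 12712: "A", 12783: "T",
    15262: "T",
}

#: Positions masked from phylogeny and dating by default: the HVS-I
#: hypervariable sites and the length-variable tract around position 310.
HOTSPOT_POSITIONS = frozenset({16182, 16183, 16519})
LENGTH_VARIATION_REGION = (303, 315)

# Relative mutability weights used both by the synthetic mutation spectrum
# and by the greedy homoplasy tie-break in parsimony reconstruction.
_HOTSPOT_WEIGHT = 50.0
_LENGTH_REGION_WEIGHT = 20.0
_FAST_SITES = {16189: 10.0, 16093: 10.0, 152: 5.0, 146: 5.0, 195: 5.0,
               16311: 5.0, 16362: 5.0}


def hotspot_weight(position: int) -> float:
    """Relative prior mutability of an rCRS position (1 = baseline)."""
    if position in HOTSPOT_POSITIONS:
        return _HOTSPOT_WEIGHT
    lo, hi = LENGTH_VARIATION_REGION
    if lo <= position <= hi:
        return _LENGTH_REGION_WEIGHT
    return _FAST_SITES.get(position, 1.0)


def ref_base(position: int) -> str | None:
    """rCRS base at ``position`` if attested, else ``None``."""
    return ATTESTED_BASES.get(position)


@lru_cache(maxsize=1)
def synthetic_reference() -> str:
    """Deterministic synthetic 16,569-bp stand-in for the rCRS.

    Bases at attested positions are exact; all other positions carry
    reproducible pseudo-random bases (fixed internal seed).
    """
    rng = np.random.default_rng(16569)
    bases = rng.choice(np.array(list("ACGT")), size=MT_LENGTH)
    seq = bases.tolist()
    for pos, base in ATTESTED_BASES.items():
        seq[pos - 1] = base
    return "".join(seq)


def check_position(position: int) -> None:
    if not 1 <= position <= MT_LENGTH:
        raise ValueError(
            f"position {position} outside rCRS coordinates 1..{MT_LENGTH}"
        )
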