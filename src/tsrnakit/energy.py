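"""Reduced nearest-neighbor energy model for intermolecular RNA duplexes.

The model scores a duplex between two strands as a sum of dinucleotide
stacking terms over consecutive base pairs, affine penalties for bulges and
internal loops between non-adjacent pairs, and a single duplex-initiation
penalty.  Watson-Crick and G·U wobble pairs are allowed; there is no
intramolecular structure and no pseudoknots.  Values are free energies at
37 degC in kcal/mol.  The table is deliberately compact — a self-contained
parameterization in the spirit of the Turner rules, not a reproduction of
them — and is plain data: any mapping with the same shape can be passed in
its place.

Sequences are handled in the DNA alphabet (T for U) like the rest of the
package; pairing semantics are RNA (A-T here means A-U).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

#: allowed base pairs (tsRNA base, target base): Watson-Crick + G-U wobble
CANONICAL_PAIRS = frozenset(
    [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")]
)

# Watson-Crick nearest-neighbor stack energies, keyed by the duplex read
# 5'->3' on the top strand: "XY" stacked on the complementary bottom strand.
# e.g. _WC_STACKS["GC"] is the 5'GC3'/3'CG5' stack.
_WC_STACKS: dict[str, float] = {
    "AA": -0.93,
    "AT": -1.10,
    "TA": -1.33,
    "CT": -2.08,
    "CA": -2.11,
    "GT": -2.24,
    "GA": -2.35,
    "CG": -2.36,
    "GG": -3.26,
    "GC": -3.42,
}

#: flat stacking term applied when either pair of the step is a G-U wobble
GU_STACK = -1.20

#: energy cost of bringing the two strands together, applied once per duplex;
#: kept below the strongest stack so even a lone GC/GC step is reportable
DUPLEX_INITIATION = 2.50

#: affine loop penalty: LOOP_OPEN + LOOP_EXTEND * unpaired nucleotides
LOOP_OPEN = 3.00
LOOP_EXTEND = 0.45


def _complement(base: str) -> str:
    return {"A": "T", "T": "A", "G": "C", "C": "G"}[base]


def _build_stack_table() -> dict[tuple[tuple[str, str], tuple[str, str]], float]:
    """Expand the compact WC table (plus the GU term) to all pair steps.

    A step is (pair_i, pair_{i+1}) where pair = (top-strand base, bottom-
    strand base) and the top strand runs 5'->3'.  Reading the same duplex
    from the other strand gives the symmetry
    stack((a,b),(c,d)) == stack((d,c),(b,a)), which the expansion honors.
    """
    table: dict[tuple[tuple[str, str], tuple[str, str]], float] = {}
    for p1 in CANONICAL_PAIRS:
        for p2 in CANONICAL_PAIRS:
            wobble = ("G", "T") in (p1, p2) or ("T", "G") in (p1, p2)
            if wobble:
                table[(p1, p2)] = GU_STACK
                continue
            # pure WC step: look up by the top-strand dinucleotide; the
            # compact table stores each duplex once, so fall back to the
            # symmetry-equivalent key.
            top = p1[0] + p2[0]
            if top in _WC_STACKS:
                table[(p1, p2)] = _WC_STACKS[top]
            else:
                flipped = p2[1] + p1[1]
                table[(p1, p2)] = _WC_STACKS[flipped]
    return table


@dataclass(frozen=True)
class EnergyParameters:
    """Parameter bundle for the duplex dynamic program."""

    stacks: Mapping[tuple[tuple[str, str], tuple[str, str]], float] = field(
        default_factory=_build_stack_table
    )
    initiation: float = DUPLEX_INITIATION
    loop_open: float = LOOP_OPEN
    loop_extend: float = LOOP_EXTEND
    max_loop: int = 15

    def __post_init__(self) -> None:
        if any(v >= 0 for v in self.stacks.values()):
            raise ValueError("all stack energies must be negative")
        if self.loop_open <= 0 or self.loop_extend <= 0:
            raise ValueError("loop penalties must be positive")

    def is_pair(self, a: str, b: str) -> bool:
        return (a, b) in CANONICAL_PAIRS

    def stack(self, p1: tuple[str, str], p2: tuple[str, str]) -> float:
        return self.stacks[(p1, p2)]

    def loop_penalty(self, unpaired: int) -> float:
        if unpaired <= 0:
            raise ValueError("loop penalty needs at least one unpaired nucleotide")
        return self.loop_open + self.loop_extend * unpaired


DEFAULT_ENERGY = EnergyParameters()
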