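"""Rule-based tsRNA typing from cleavage positions.

Fragments are labelled by where their ends fall on the parent mature tRNA:
5'-anchored pieces ending before the anticodon loop are tRF-5 (a/b/c by
length), 3'-anchored pieces starting after the loop are tRF-3 (a/b), halves
produced by cleavage inside the anticodon loop are tiRNA-5/tiRNA-3, trailer
pieces are tRF-1, and internal fragments spanning the anticodon are tRF-2.
The rules are evaluated in a fixed order so that exactly one label applies
to any placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .quantify import FragmentPlacement, TsRNARecord
    from .reference import MatureTRNA

#: every label the classifier can emit
TSRNA_TYPES = (
    "tRF-5a",
    "tRF-5b",
    "tRF-5c",
    "tRF-3a",
    "tRF-3b",
    "tRF-1",
    "tiRNA-5",
    "tiRNA-3",
    "tRF-2",
    "unclassified",
)


@dataclass(frozen=True)
class ClassificationRules:
    """Boundary parameters of the typing rule table.

    loop_halfwidth
        Number of nucleotides on each side of the anticodon triplet counted
        as the anticodon loop (default 3, giving a 9-nt window).
    trf5_max_a, trf5_max_b
        tRF-5 subtype length bins: 5a <= trf5_max_a, 5b in
        (trf5_max_a, trf5_max_b], 5c > trf5_max_b.
    trf3_max_a
        tRF-3a <= trf3_max_a nt; longer 3'-anchored fragments are tRF-3b.
    """

    loop_halfwidth: int = 3
    trf5_max_a: int = 16
    trf5_max_b: int = 24
    trf3_max_a: int = 19

    def loop(self, trna: "MatureTRNA") -> tuple[int, int]:
        """1-based inclusive anticodon-loop window on the parent."""
        return (
            trna.anticodon_start - self.loop_halfwidth,
            trna.anticodon_end + self.loop_halfwidth,
        )


DEFAULT_RULES = ClassificationRules()


def classify_interval(
    start: int,
    end: int,
    trna: "MatureTRNA",
    rules: ClassificationRules = DEFAULT_RULES,
    region: str = "mature",
) -> str:
    """Type the fragment occupying [start, end] (1-based) on ``trna``."""
    if region == "trailer":
        return "tRF-1"
    L = trna.length
    if not (1 <= start <= end <= L):
        raise ValueError(f"placement [{start},{end}] outside mature tRNA [1,{L}]")
    loop_lo, loop_hi = rules.loop(trna)
    length = end - start + 1
    if start == 1 and loop_lo <= end <= loop_hi:
        return "tiRNA-5"
    if start == 1 and end < loop_lo:
        if length <= rules.trf5_max_a:
            return "tRF-5a"
        if length <= rules.trf5_max_b:
            return "tRF-5b"
        return "tRF-5c"
    if end == L and loop_lo <= start <= loop_hi:
        return "tiRNA-3"
    if end == L and start > loop_hi:
        return "tRF-3a" if length <= rules.trf3_max_a else "tRF-3b"
    if (
        start > 1
        and end < L
        and start <= trna.anticodon_end
        and end >= trna.anticodon_start
    ):
        return "tRF-2"
    return "unclassified"


def classify_fragment(
    placement: "FragmentPlacement",
    trna: "MatureTRNA",
    rules: ClassificationRules = DEFAULT_RULES,
) -> str:
    """Type a FragmentPlacement against its parent tRNA."""
    return classify_interval(
        placement.start, placement.end, trna, rules, region=placement.region
    )


def _weights(records: Iterable["TsRNARecord"], weighting: str):
    recs = list(records)
    if not recs:
        raise ValueError("no records to summarize")
    if weighting == "abundance":
        w = [sum(r.counts.values()) for r in recs]
    elif weighting == "species":
        w = [1.0] * len(recs)
    else:
        raise ValueError("weighting must be 'abundance' or 'species'")
    total = float(sum(w))
    if total == 0:
        raise ValueError("all records have zero weight")
    return recs, [x / total for x in w]


def type_composition(
    records: Iterable["TsRNARecord"], weighting: str = "abundance"
) -> dict[str, float]:
    """Fraction of the catalog in each tsRNA type.

    ``abundance`` weights each tsRNA by its summed counts across samples;
    ``species`` counts each distinct tsRNA once.
    """
    recs, weights = _weights(records, weighting)
    out: dict[str, float] = {}
    for rec, w in zip(recs, weights):
        out[rec.type] = out.get(rec.type, 0.0) + w
    return out


def length_distribution(
    records: Iterable["TsRNARecord"], weighting: str = "abundance"
) -> dict[int, float]:
    """Fraction of the catalog at each fragment length (nt)."""
    recs, weights = _weights(records, weighting)
    out: dict[int, float] = {}
    for rec, w in zip(recs, weights):
        n = len(rec.sequence)
        out[n] = out.get(n, 0.0) + w
    return out


def composition_table(records: Iterable["TsRNARecord"]) -> pd.DataFrame:
    """Both weightings of the type composition as one tidy table."""
    recs = list(records)
    ab = type_composition(recs, "abundance")
    sp = type_composition(recs, "species")
    types = sorted(set(ab) | set(sp), key=TSRNA_TYPES.index)
    return pd.DataFrame(
        {
            "type": types,
            "abundance_fraction": [ab.get(t, 0.0) for t in types],
            "species_fraction": [sp.get(t, 0.0) for t in types],
        }
    )
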