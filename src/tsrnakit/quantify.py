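"""Read collapsing, placement on the tRNA reference, and the count matrix.

A tsRNA is identified with a distinct read sequence: identical reads collapse
to one row regardless of how many tRNA loci the sequence maps to, which is
how sequence-named tsRNA catalogs are built.  Placement is an exact (or
near-exact, configurable) search against mature-tRNA space rather than a
genome-wide alignment: the search space is a few hundred short references,
so direct matching is deterministic and complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .classify import ClassificationRules, DEFAULT_RULES, classify_fragment
from .express import ExpressionMatrix
from .reference import MatureTRNA

logger = logging.getLogger(__name__)

LENGTH_WINDOW = (14, 40)


@dataclass(frozen=True)
class FragmentPlacement:
    """One location of a fragment sequence on a reference tRNA.

    Coordinates are 1-based inclusive on the mature sequence (or, for
    ``region == "trailer"``, on the trailer).  ``cca_trimmed`` records how
    many trailing nucleotides were removed as non-templated CCA before the
    sequence matched.
    """

    sequence: str
    parent_id: str
    start: int
    end: int
    region: str = "mature"
    cca_trimmed: int = 0
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence) - self.cca_trimmed:
            raise ValueError("placement span inconsistent with sequence length")


@dataclass
class TsRNARecord:
    """A distinct fragment sequence with its placements, type and counts."""

    tsrna_id: str
    sequence: str
    type: str
    placements: list[FragmentPlacement]
    seed: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def primary_placement(self) -> FragmentPlacement:
        return self.placements[0]

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


def collapse_reads(
    fastq_path: str | Path,
    length_window: tuple[int, int] = LENGTH_WINDOW,
) -> tuple[dict[str, int], int]:
    """Collapse a FASTQ into sequence -> read count.

    Returns the counts of reads inside the length window and the number of
    out-of-window reads (counted, logged, excluded).
    """
    lo, hi = length_window
    counts: dict[str, int] = {}
    excluded = 0
    with open(fastq_path) as handle:
        iterator = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                item = next(iterator, None)
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record #{index + 1}: {exc}") from exc
            if item is None:
                break
            index += 1
            seq = item[1].upper().replace("U", "T")
            if lo <= len(seq) <= hi:
                counts[seq] = counts.get(seq, 0) + 1
            else:
                excluded += 1
    if excluded:
        logger.info("%s: excluded %d reads outside %d-%d nt", fastq_path, excluded, lo, hi)
    return counts, excluded


class ReferenceIndex:
    """Exact-substring index over a set of mature tRNAs (plus trailers)."""

    def __init__(
        self,
        reference: Sequence[MatureTRNA],
        length_window: tuple[int, int] = LENGTH_WINDOW,
    ):
        self.reference = list(reference)
        self.by_id = {t.id: t for t in self.reference}
        self.length_window = length_window
        lo, hi = length_window
        index: dict[str, list[tuple[str, int, str]]] = {}
        for trna in self.reference:
            for region, seq in (("mature", trna.sequence), ("trailer", trna.trailer)):
                if not seq:
                    continue
                for n in range(lo, min(hi, len(seq)) + 1):
                    for s in range(len(seq) - n + 1):
                        key = seq[s : s + n]
                        index.setdefault(key, []).append((trna.id, s + 1, region))
        self._index = index

    def exact(self, sequence: str) -> list[tuple[str, int, str]]:
        return self._index.get(sequence, [])


def _hamming_scan(
    sequence: str, reference: Sequence[MatureTRNA], max_mismatch: int
) -> list[tuple[str, int, str, int]]:
    """All placements of ``sequence`` with <= max_mismatch substitutions."""
    n = len(sequence)
    hits = []
    for trna in reference:
        for region, ref in (("mature", trna.sequence), ("trailer", trna.trailer)):
            if not ref:
                continue
            for s in range(len(ref) - n + 1):
                mm = 0
                window = ref[s : s + n]
                for a, b in zip(sequence, window):
                    if a != b:
                        mm += 1
                        if mm > max_mismatch:
                            break
                else:
                    hits.append((trna.id, s + 1, region, mm))
    return hits


def place_fragment(
    sequence: str,
    reference: Sequence[MatureTRNA] | ReferenceIndex,
    max_mismatch: int = 0,
    allow_cca_trim: bool = True,
) -> list[FragmentPlacement]:
    """Place a fragment on the reference at the minimal mismatch level found.

    If the untouched sequence is unplaceable and ``allow_cca_trim`` is set,
    1-3 trailing characters forming a prefix of "CCA" are removed and the
    search retried — fragments that run past the templated 3' end into the
    non-templated CCA otherwise escape placement.  Returns [] if unplaced.
    """
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)

    def _search(seq: str, trimmed: int) -> list[FragmentPlacement]:
        exact = index.exact(seq)
        if exact:
            return [
                FragmentPlacement(
                    sequence=sequence,
                    parent_id=pid,
                    start=start,
                    end=start + len(seq) - 1,
                    region=region,
                    cca_trimmed=trimmed,
                    mismatches=0,
                )
                for pid, start, region in exact
            ]
        if max_mismatch > 0:
            hits = _hamming_scan(seq, index.reference, max_mismatch)
            if hits:
                best = min(mm for *_, mm in hits)
                return [
                    FragmentPlacement(
                        sequence=sequence,
                        parent_id=pid,
                        start=start,
                        end=start + len(seq) - 1,
                        region=region,
                        cca_trimmed=trimmed,
                        mismatches=mm,
                    )
                    for pid, start, region, mm in hits
                    if mm == best
                ]
        return []

    placements = _search(sequence, 0)
    if not placements and allow_cca_trim:
        for k in (1, 2, 3):
            if len(sequence) - k >= index.length_window[0] and sequence[-k:] == "CCA"[:k]:
                placements = _search(sequence[:-k], k)
                if placements:
                    break
    return placements


def _primary(placements: list[FragmentPlacement]) -> FragmentPlacement:
    """Deterministic primary placement: fewest mismatches, 5'-most, smallest id."""
    return min(placements, key=lambda p: (p.mismatches, p.start, p.parent_id))


def build_matrix(
    samples: pd.DataFrame | str | Path,
    reference: Sequence[MatureTRNA],
    max_mismatch: int = 0,
    allow_cca_trim: bool = True,
    rules: ClassificationRules = DEFAULT_RULES,
    length_window: tuple[int, int] = LENGTH_WINDOW,
) -> tuple[ExpressionMatrix, list[TsRNARecord], pd.DataFrame]:
    """Quantify all samples into a tsRNA x sample count matrix.

    ``samples`` is a sample sheet (DataFrame or TSV path) with columns
    sample_id, group, fastq_path.  Returns the expression matrix, the tsRNA
    records (row order matches the matrix), and an unaligned-sequence report.
    """
    if not isinstance(samples, pd.DataFrame):
        samples = pd.read_csv(samples, sep="\t", dtype=str)
    for col in ("sample_id", "group", "fastq_path"):
        if col not in samples.columns:
            raise ValueError(f"sample sheet missing column {col!r}")

    per_sample: dict[str, dict[str, int]] = {}
    for _, row in samples.iterrows():
        counts, _ = collapse_reads(row["fastq_path"], length_window)
        per_sample[row["sample_id"]] = counts

    index = ReferenceIndex(reference, length_window)
    all_sequences = sorted(set().union(*per_sample.values()) if per_sample else set())

    placed: list[tuple[str, list[FragmentPlacement]]] = []
    unaligned_rows = []
    for seq in all_sequences:
        placements = place_fragment(seq, index, max_mismatch, allow_cca_trim)
        total = sum(c.get(seq, 0) for c in per_sample.values())
        if placements:
            placed.append((seq, placements))
        else:
            unaligned_rows.append({"sequence": seq, "total_count": total})
    unaligned = pd.DataFrame(unaligned_rows, columns=["sequence", "total_count"])

    # name serials in decreasing total count (ties lexicographic by sequence)
    def sort_key(item):
        seq, _ = item
        total = sum(c.get(seq, 0) for c in per_sample.values())
        return (-total, seq)

    placed.sort(key=sort_key)

    serial_counters: dict[tuple[str, str], int] = {}
    records: list[TsRNARecord] = []
    sample_ids = list(samples["sample_id"])
    for seq, placements in placed:
        placements = sorted(placements, key=lambda p: (p.mismatches, p.start, p.parent_id))
        primary = placements[0]
        parent = index.by_id[primary.parent_id]
        ts_type = classify_fragment(primary, parent, rules)
        prefix = "tiRNA" if ts_type.startswith("tiRNA") else "tRF"
        key = (parent.amino_acid, parent.anticodon)
        serial_counters[key] = serial_counters.get(key, 0) + 1
        tsrna_id = f"{prefix}-{parent.amino_acid}-{parent.anticodon}-{serial_counters[key]:03d}"
        records.append(
            TsRNARecord(
                tsrna_id=tsrna_id,
                sequence=seq,
                type=ts_type,
                placements=placements,
                seed=seq[1:8],
                counts={sid: per_sample[sid].get(seq, 0) for sid in sample_ids},
            )
        )

    counts_df = pd.DataFrame(
        {sid: [r.counts[sid] for r in records] for sid in sample_ids},
        index=[r.tsrna_id for r in records],
    )
    groups = pd.Series(list(samples["group"]), index=sample_ids)
    matrix = ExpressionMatrix(counts_df, groups)
    return matrix, records, unaligned


def records_table(records: Iterable[TsRNARecord]) -> pd.DataFrame:
    """Sidecar table: one row per tsRNA with its primary placement."""
    rows = []
    for r in records:
        p = r.primary_placement
        rows.append(
            {
                "tsrna_id": r.tsrna_id,
                "sequence": r.sequence,
                "type": r.type,
                "seed": r.seed,
                "parent_id": p.parent_id,
                "start": p.start,
                "end": p.end,
                "region": p.region,
                "cca_trimmed": p.cca_trimmed,
                "mismatches": p.mismatches,
                "n_placements": len(r.placements),
                "total_count": r.total_count,
            }
        )
    return pd.DataFrame(rows)
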