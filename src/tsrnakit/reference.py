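"""Mature tRNA reference handling.

A mature tRNA here is the processed molecule: introns removed, 5' leader and
3' trailer cleaved, and the universal 3'-terminal CCA present.  All fragment
classification downstream is expressed in 1-based inclusive coordinates on
this mature sequence, with the anticodon triplet as the central landmark.

Sequences are stored in the DNA alphabet (U normalized to T on load) so they
compare directly against FASTQ reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")

ANNOTATION_COLUMNS = (
    "id",
    "amino_acid",
    "anticodon",
    "anticodon_start",
    "anticodon_end",
    "origin",
    "trailer",
)


class ReferenceError(ValueError):
    """Raised for malformed or inconsistent tRNA reference input."""


@dataclass(frozen=True)
class MatureTRNA:
    """One mature, CCA-terminated tRNA with a located anticodon.

    Coordinates are 1-based inclusive on ``sequence``.  ``trailer`` holds the
    3' pre-tRNA trailer when known (the source of tRF-1 fragments); it is not
    part of ``sequence``.
    """

    id: str
    amino_acid: str
    anticodon: str
    sequence: str
    anticodon_start: int
    anticodon_end: int
    origin: str = "cytoplasmic"
    trailer: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence
        if not seq or set(seq) - _VALID_BASES:
            raise ReferenceError(f"{self.id}: sequence must be non-empty over ACGT")
        if not seq.endswith("CCA"):
            raise ReferenceError(f"{self.id}: mature tRNA must end in CCA")
        if len(self.anticodon) != 3 or set(self.anticodon) - _VALID_BASES:
            raise ReferenceError(f"{self.id}: anticodon must be a 3-mer over ACGT")
        if self.anticodon_end != self.anticodon_start + 2:
            raise ReferenceError(f"{self.id}: anticodon coordinates must span 3 nt")
        if not (1 <= self.anticodon_start < self.anticodon_end <= len(seq)):
            raise ReferenceError(f"{self.id}: anticodon coordinates out of range")
        observed = seq[self.anticodon_start - 1 : self.anticodon_end]
        if observed != self.anticodon:
            raise ReferenceError(
                f"{self.id}: annotated anticodon {self.anticodon} at "
                f"{self.anticodon_start}-{self.anticodon_end} but sequence has {observed}"
            )
        if self.origin not in ("cytoplasmic", "mitochondrial"):
            raise ReferenceError(f"{self.id}: origin must be cytoplasmic or mitochondrial")
        if set(self.trailer) - _VALID_BASES:
            raise ReferenceError(f"{self.id}: trailer must be over ACGT")

    @property
    def length(self) -> int:
        return len(self.sequence)


def normalize_sequence(raw: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return raw.strip().upper().replace("U", "T")


def append_cca(sequence: str, genomically_encoded_cca: bool = False) -> str:
    """Return the CCA-terminated form of a tRNA sequence.

    The 3' CCA of mature tRNA is usually added post-transcriptionally; genomic
    references therefore often lack it.  With ``genomically_encoded_cca`` the
    sequence is required to carry it already and is returned unchanged.
    """
    if not sequence or set(sequence) - _VALID_BASES:
        raise ReferenceError("sequence must be non-empty over ACGT")
    if genomically_encoded_cca:
        if not sequence.endswith("CCA"):
            raise ReferenceError("genomically_encoded_cca set but sequence does not end in CCA")
        return sequence
    return sequence + "CCA"


def locate_anticodon(sequence: str, anticodon: str) -> tuple[int, int]:
    """Locate an anticodon triplet, preferring the canonical central position.

    Among all occurrences the one whose start is nearest to
    ``round(L/2) - 4`` (the usual anticodon neighborhood of a cloverleaf) is
    chosen; ties break toward the 5'-most occurrence.  Returns 1-based
    inclusive (start, end).
    """
    starts = []
    pos = sequence.find(anticodon)
    while pos != -1:
        starts.append(pos + 1)
        pos = sequence.find(anticodon, pos + 1)
    if not starts:
        raise ReferenceError(
            f"anticodon {anticodon} not found in sequence; "
            "supply explicit coordinates via the annotation table"
        )
    center = round(len(sequence) / 2) - 4
    best = min(starts, key=lambda s: (abs(s - center), s))
    return best, best + 2


def _read_annotation_table(path: Path) -> dict[str, dict]:
    import csv

    rows: dict[str, dict] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(ANNOTATION_COLUMNS[:6]) - set(reader.fieldnames or ())
        if missing:
            raise ReferenceError(f"annotation table missing columns: {sorted(missing)}")
        for row in reader:
            rid = row["id"]
            if rid in rows:
                raise ReferenceError(f"duplicate annotation row for {rid}")
            rows[rid] = row
    return rows


def load_trna_reference(
    fasta_path: str | Path,
    annotation_path: str | Path | None = None,
) -> list[MatureTRNA]:
    """Load mature tRNA references from FASTA plus optional annotation table.

    Headers in GtRNAdb style (``tRNA-Gly-GCC-1-1``) are parsed for the amino
    acid and anticodon; an annotation table row, when present, always wins
    over header parsing and over the positional anticodon fallback.
    """
    fasta_path = Path(fasta_path)
    annotations = _read_annotation_table(Path(annotation_path)) if annotation_path else {}

    records: list[MatureTRNA] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise ReferenceError(f"duplicate reference id {rid}")
        seen.add(rid)
        seq = normalize_sequence(str(rec.seq))
        if set(seq) - _VALID_BASES:
            raise ReferenceError(f"{rid}: non-ACGTU characters in sequence")
        ann = annotations.get(rid)
        if ann is not None:
            amino_acid = ann["amino_acid"]
            anticodon = normalize_sequence(ann["anticodon"])
            ac_start = int(ann["anticodon_start"])
            ac_end = int(ann["anticodon_end"])
            origin = ann["origin"]
            trailer = normalize_sequence(ann.get("trailer") or "")
        else:
            amino_acid, anticodon = _parse_gtrnadb_id(rid)
            ac_start, ac_end = locate_anticodon(seq, anticodon)
            origin = "mitochondrial" if rid.lower().startswith(("mt-", "trna-mt")) else "cytoplasmic"
            trailer = ""
        records.append(
            MatureTRNA(
                id=rid,
                amino_acid=amino_acid,
                anticodon=anticodon,
                sequence=seq,
                anticodon_start=ac_start,
                anticodon_end=ac_end,
                origin=origin,
                trailer=trailer,
            )
        )
    if not records:
        logger.warning("no tRNA records found in %s", fasta_path)
    return records


def _parse_gtrnadb_id(rid: str) -> tuple[str, str]:
    """Extract (amino_acid, anticodon) from an id like tRNA-Gly-GCC-1-1."""
    parts = rid.split("-")
    if len(parts) >= 3 and parts[0].lower().endswith("trna"):
        anticodon = normalize_sequence(parts[2])
        if len(anticodon) == 3 and not set(anticodon) - _VALID_BASES:
            return parts[1], anticodon
    raise ReferenceError(
        f"cannot parse amino acid/anticodon from id {rid!r}; supply an annotation table"
    )


def write_trna_reference(
    records: Iterable[MatureTRNA],
    fasta_path: str | Path,
    annotation_path: str | Path,
) -> None:
    """Write records back to FASTA + annotation table (round-trip safe)."""
    records = list(records)
    with open(fasta_path, "w") as fa:
        for rec in records:
            fa.write(f">{rec.id}\n{rec.sequence}\n")
    with open(annotation_path, "w") as tab:
        tab.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for rec in records:
            tab.write(
                "\t".join(
                    [
                        rec.id,
                        rec.amino_acid,
                        rec.anticodon,
                        str(rec.anticodon_start),
                        str(rec.anticodon_end),
                        rec.origin,
                        rec.trailer,
                    ]
                )
                + "\n"
            )
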