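"""Seed extraction, UTR scanning, duplex MFE scoring and enrichment.

tsRNAs are assumed to act like miRNAs: nucleotides 2-8 of the molecule (the
seed) nucleate binding to a 3' UTR site that carries the seed's reverse
complement.  Candidate sites found by the seed scan are then scored by the
minimum free energy of the intermolecular RNA duplex between the full tsRNA
and the local UTR context, computed by dynamic programming under a reduced
nearest-neighbor model (see :mod:`tsrnakit.energy`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from .energy import DEFAULT_ENERGY, EnergyParameters
from .express import benjamini_hochberg

SEED_START, SEED_END = 2, 8  # 1-based inclusive positions defining the seed
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_seed(sequence: str) -> str:
    """Seed 7-mer: positions 2-8 of the molecule's 5' end."""
    if len(sequence) < SEED_END:
        raise ValueError(f"sequence shorter than {SEED_END} nt has no seed")
    return sequence[SEED_START - 1 : SEED_END]


@dataclass
class SeedGroup:
    seed: str
    member_ids: list[str]
    total_abundance: float = 0.0


def group_by_seed(records: Iterable) -> list[SeedGroup]:
    """Partition tsRNAs by their seed 7-mer.

    ``records`` are TsRNARecord-like objects (tsrna_id / sequence / counts).
    Groups come back sorted by summed member abundance, largest first.
    """
    groups: dict[str, SeedGroup] = {}
    for rec in records:
        seed = extract_seed(rec.sequence)
        grp = groups.setdefault(seed, SeedGroup(seed=seed, member_ids=[]))
        grp.member_ids.append(rec.tsrna_id)
        counts = getattr(rec, "counts", None)
        grp.total_abundance += float(sum(counts.values())) if counts else 0.0
    return sorted(groups.values(), key=lambda g: (-g.total_abundance, g.seed))


def position_frequency_matrix(
    sequences: Sequence[str], window: str = "seed", k: int = 7
) -> pd.DataFrame:
    """Per-position base counts and frequencies over a sequence window.

    ``window`` is ``"seed"`` (positions 2-8) or ``"three_prime"`` (the last
    ``k`` characters).  Returns a DataFrame indexed by base A/C/G/T whose
    columns are window positions; ``.attrs["frequencies"]`` holds the
    column-normalized version.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences for the frequency matrix")
    if window == "seed":
        parts = [extract_seed(s) for s in seqs]
    elif window == "three_prime":
        if any(len(s) < k for s in seqs):
            raise ValueError(f"all sequences must cover the 3' window of {k} nt")
        parts = [s[-k:] for s in seqs]
    else:
        raise ValueError("window must be 'seed' or 'three_prime'")
    width = len(parts[0])
    counts = pd.DataFrame(0, index=list("ACGT"), columns=range(1, width + 1))
    for p in parts:
        for pos, base in enumerate(p, start=1):
            counts.loc[base, pos] += 1
    freq = counts / counts.sum(axis=0)
    counts.attrs["frequencies"] = freq
    return counts


def scan_utr(seed: str, utr: str) -> list[int]:
    """All 1-based starts of the seed's reverse complement in a UTR.

    Overlapping occurrences are all reported.
    """
    site = reverse_complement(seed)
    hits = []
    pos = utr.find(site)
    while pos != -1:
        hits.append(pos + 1)
        pos = utr.find(site, pos + 1)
    return hits


@dataclass(frozen=True)
class Duplex:
    """Intermolecular duplex traceback: 1-based (tsrna_pos, utr_pos) pairs."""

    pairs: tuple[tuple[int, int], ...]

    def __bool__(self) -> bool:
        return bool(self.pairs)

    def render(self, tsrna_seq: str, utr_window: str) -> str:
        """Three-line alignment: tsRNA 5'->3' over pair marks over UTR 3'->5'."""
        if not self.pairs:
            return "(no duplex)"
        top, mid, bot = [], [], []
        (i0, j0) = self.pairs[0]
        i_prev, j_prev = i0, j0
        top.append(tsrna_seq[i0 - 1])
        mid.append("|")
        bot.append(utr_window[j0 - 1])
        for i, j in self.pairs[1:]:
            gap_x = tsrna_seq[i_prev : i - 1]
            gap_y = utr_window[j : j_prev - 1][::-1]
            width = max(len(gap_x), len(gap_y))
            top.append(gap_x.ljust(width, "-"))
            bot.append(gap_y.ljust(width, "-"))
            mid.append(" " * width)
            top.append(tsrna_seq[i - 1])
            mid.append("|")
            bot.append(utr_window[j - 1])
            i_prev, j_prev = i, j
        return (
            f"5' {''.join(top)} 3' (tsRNA)\n"
            f"   {''.join(mid)}\n"
            f"3' {''.join(bot)} 5' (UTR)"
        )


EMPTY_DUPLEX = Duplex(pairs=())

_MAX_HYBRID_LEN = 60


def hybrid_mfe(
    tsrna_seq: str,
    utr_window: str,
    params: EnergyParameters = DEFAULT_ENERGY,
) -> tuple[float, Duplex]:
    """Minimum free energy of the tsRNA / UTR-window intermolecular duplex.

    Dynamic program over base pairs (x_i, y_j): the tsRNA runs 5'->3', the
    UTR window pairs antiparallel, Watson-Crick and G-U pairs are allowed,
    consecutive pairs stack, and non-adjacent pairs are joined by affine
    bulge/internal-loop penalties bounded by ``params.max_loop`` unpaired
    nucleotides per strand.  One duplex-initiation penalty applies.  When no
    arrangement reaches a negative energy, (0.0, empty duplex) is returned.
    """
    x, y = tsrna_seq, utr_window
    if len(x) > _MAX_HYBRID_LEN or len(y) > _MAX_HYBRID_LEN:
        raise ValueError(
            f"sequences longer than {_MAX_HYBRID_LEN} nt: re-window the UTR context"
        )
    n, m = len(x), len(y)
    maxl = params.max_loop
    energy: dict[tuple[int, int], float] = {}
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    best_key: tuple[int, int] | None = None
    best_e = 0.0
    for i in range(1, n + 1):
        xi = x[i - 1]
        for j in range(m, 0, -1):
            if not params.is_pair(xi, y[j - 1]):
                continue
            pair = (xi, y[j - 1])
            e = params.initiation  # open the duplex at this pair
            par: tuple[int, int] | None = None
            for ip in range(max(1, i - 1 - maxl), i):
                for jp in range(j + 1, min(m, j + 1 + maxl) + 1):
                    prev = energy.get((ip, jp))
                    if prev is None:
                        continue
                    gap = (i - ip - 1) + (jp - j - 1)
                    if gap == 0:
                        step = params.stack((x[ip - 1], y[jp - 1]), pair)
                    else:
                        step = params.loop_penalty(gap)
                    if prev + step < e:
                        e = prev + step
                        par = (ip, jp)
            energy[(i, j)] = e
            parent[(i, j)] = par
            if e < best_e:
                best_e = e
                best_key = (i, j)
    if best_key is None:
        return 0.0, EMPTY_DUPLEX
    pairs: list[tuple[int, int]] = []
    key: tuple[int, int] | None = best_key
    while key is not None:
        pairs.append(key)
        key = parent[key]
    pairs.reverse()
    return best_e, Duplex(pairs=tuple(pairs))


def rescore_duplex(
    tsrna_seq: str,
    utr_window: str,
    duplex: Duplex,
    params: EnergyParameters = DEFAULT_ENERGY,
) -> float:
    """Recompute a duplex's energy from its pair list (traceback check)."""
    if not duplex:
        return 0.0
    x, y = tsrna_seq, utr_window
    e = params.initiation
    for (i1, j1), (i2, j2) in zip(duplex.pairs, duplex.pairs[1:]):
        if not (i2 > i1 and j2 < j1):
            raise ValueError("duplex pairs are not antiparallel-ordered")
        gap = (i2 - i1 - 1) + (j1 - j2 - 1)
        if gap == 0:
            e += params.stack((x[i1 - 1], y[j1 - 1]), (x[i2 - 1], y[j2 - 1]))
        else:
            e += params.loop_penalty(gap)
    return e


@dataclass(frozen=True)
class TargetHit:
    tsrna_id: str
    gene_id: str
    utr_position: int  # 1-based start of the seed-complementary site
    mfe: float
    duplex_text: str
    match_type: str = "seed7"


def _load_utrs(utr_fasta: str | Path | Mapping[str, str]) -> dict[str, str]:
    if isinstance(utr_fasta, Mapping):
        return {k: v.upper().replace("U", "T") for k, v in utr_fasta.items()}
    return {
        rec.id: str(rec.seq).upper().replace("U", "T")
        for rec in SeqIO.parse(str(utr_fasta), "fasta")
    }


def predict_targets(
    records: Iterable,
    utr_fasta: str | Path | Mapping[str, str],
    params: EnergyParameters = DEFAULT_ENERGY,
    mfe_cutoff: float = -15.0,
    context: int = 15,
) -> list[TargetHit]:
    """Seed-gated, MFE-filtered target prediction.

    For every (tsRNA, UTR) pair, each reverse-complement seed match is
    scored by :func:`hybrid_mfe` on the site plus ``context`` nt of flanking
    UTR; sites at or below ``mfe_cutoff`` kcal/mol become hits, returned
    sorted by MFE (most stable first).
    """
    utrs = _load_utrs(utr_fasta)
    hits: list[TargetHit] = []
    for rec in records:
        seq = rec.sequence
        seed = extract_seed(seq)
        for gene_id, utr in utrs.items():
            for pos in scan_utr(seed, utr):
                lo = max(0, pos - 1 - context)
                hi = min(len(utr), pos + 6 + context)
                window = utr[lo:hi]
                mfe, duplex = hybrid_mfe(seq, window, params)
                if mfe <= mfe_cutoff:
                    hits.append(
                        TargetHit(
                            tsrna_id=rec.tsrna_id,
                            gene_id=gene_id,
                            utr_position=pos,
                            mfe=mfe,
                            duplex_text=duplex.render(seq, window),
                        )
                    )
    return sorted(hits, key=lambda h: (h.mfe, h.tsrna_id, h.gene_id, h.utr_position))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p-value (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation is undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def hypergeometric_enrichment(
    target_genes: set[str],
    gene_sets: Mapping[str, Iterable[str]] | str | Path,
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of target genes in each gene set.

    Gene sets are intersected with the universe; the p-value per set is
    P(overlap >= observed) drawing |target_genes| genes from the universe.
    BH-FDR is applied across sets.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not target_genes <= universe:
        raise ValueError("target genes must be a subset of the universe")
    if not isinstance(gene_sets, Mapping):
        gene_sets = read_gmt(gene_sets)
    M, N = len(universe), len(target_genes)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        k = len(target_genes & members)
        p = float(stats.hypergeom.sf(k - 1, M, len(members), N))
        rows.append(
            {"gene_set": name, "set_size": len(members), "overlap": k, "p_value": min(p, 1.0)}
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = benjamini_hochberg(table["p_value"].values)
        table = table.sort_values("p_value", kind="stable").reset_index(drop=True)
    return table
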