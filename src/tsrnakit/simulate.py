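"""Synthetic study generator: reference tRNAs, planted fragment catalogs,
two-condition read sets, and 3'-UTR target sites.

The generator emulates the measured structure of a two-group (normal vs
IUGR) porcine skeletal-muscle tsRNA-seq experiment so every downstream
stage can be validated against planted truth: a catalog of distinct
fragments with a dominant tRF-5c class, ~80% of abundance at 31-32 nt, a
heavy-tailed abundance law whose top-ten fragments carry ~89% of normal
expression, group-exclusive subsets, spiked fold changes between two
3-replicate groups, and a controlled number of distinct seed 7-mers.

Key construction facts the defaults rely on:

* every 5'-anchored fragment of one parent shares that parent's positions
  2-8, so the number of seed groups equals (# parents carrying 5'-anchored
  fragments) + (# non-5' fragments, whose seeds are kept unique);
* the 31-32 nt abundance mass is carried entirely by tRF-5c fragments
  (other classes draw lengths outside 31-32), so the type-mixture and
  length-mass constraints can both be satisfied exactly by cell-wise
  rescaling.

The generator and the classifier share one rule table
(:mod:`tsrnakit.classify`), and every planted placement is re-checked
through it at build time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ClassificationRules, DEFAULT_RULES, classify_interval
from .reference import MatureTRNA
from .targets import extract_seed, reverse_complement

FIVE_PRIME_TYPES = ("tRF-5a", "tRF-5b", "tRF-5c", "tiRNA-5")
NON_FIVE_TYPES = ("tRF-3a", "tRF-3b", "tiRNA-3", "tRF-2")

GROUP_NORMAL = "normal"
GROUP_IUGR = "IUGR"

_BASES = np.array(list("ACGT"))

_AMINO_ACIDS = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile "
    "Leu Lys Met Phe Pro Ser Thr Trp Tyr Val"
).split()


class SimulationError(ValueError):
    """Raised when a simulation configuration is infeasible."""


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of the emulated experiment.

    Defaults reproduce the measured composition of the study the package
    targets: a 586-fragment catalog with 103 normal-only and 38 IUGR-only
    members and 221 distinct seeds, tRF-5c carrying 0.92 of abundance,
    0.80 of abundance at 31-32 nt, a normal-group top-ten share of 0.8916,
    19 down / 9 up spiked 8-fold changes, and 3 replicates per group at a
    depth of 2e6 reads.
    """

    catalog_size: int = 586
    n_seed_groups: int = 221
    group_specific: tuple[int, int] = (103, 38)  # (normal-only, IUGR-only)
    de_spikes: tuple[int, int, float] = (19, 9, 8.0)  # (n_down, n_up, fold change)
    type_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "tRF-5c": 0.92,
            "tRF-5a": 0.01,
            "tRF-5b": 0.01,
            "tiRNA-5": 0.02,
            "tRF-3a": 0.01,
            "tRF-3b": 0.01,
            "tiRNA-3": 0.01,
            "tRF-2": 0.01,
        }
    )
    length_mass_31_32: float = 0.80
    top10_share_normal: float = 0.8916
    replicates_per_group: int = 3
    depth: int = 2_000_000
    noise_sigma: float = 0.10  # sd of per-replicate log2 abundance
    error_rate: float = 0.0
    min_abundance: float = 3e-5
    zipf_exponent: float = 0.8
    n_nonfive_species: int = 100
    rng_seed: int = 1

    def __post_init__(self) -> None:
        total = sum(self.type_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"type_mixture sums to {total}, expected 1")
        if any(v < 0 or v > 1 for v in self.type_mixture.values()):
            raise SimulationError("type_mixture fractions must lie in [0, 1]")
        if self.catalog_size < sum(self.group_specific):
            raise SimulationError("catalog_size smaller than group-specific subsets")
        if self.depth <= 0:
            raise SimulationError("depth must be positive")
        if not (0.0 <= self.length_mass_31_32 <= self.type_mixture.get("tRF-5c", 0.0)):
            raise SimulationError(
                "length_mass_31_32 must fit inside the tRF-5c abundance share "
                "(31-32 nt mass is carried by tRF-5c fragments)"
            )
        if self.de_spikes[2] < 2.0:
            raise SimulationError("spiked fold change must be at least 2")
        if not (0 <= self.n_nonfive_species < self.n_seed_groups):
            raise SimulationError("n_nonfive_species must be in [0, n_seed_groups)")

    @property
    def n_parents(self) -> int:
        """Parents carrying 5'-anchored fragments (fixes the seed count)."""
        has_nonfive = any(self.type_mixture.get(t, 0.0) > 0 for t in NON_FIVE_TYPES)
        return self.n_seed_groups - (self.n_nonfive_species if has_nonfive else 0)

    @property
    def samples(self) -> pd.DataFrame:
        rows = []
        for group in (GROUP_NORMAL, GROUP_IUGR):
            for r in range(1, self.replicates_per_group + 1):
                rows.append({"sample_id": f"{group}_{r}", "group": group})
        return pd.DataFrame(rows)


@dataclass
class SimulationTruth:
    """Planted ground truth: one row per catalog fragment.

    ``fragments`` columns: sequence, parent_id, start, end, type, length,
    seed, baseline (global abundance, sums to 1), membership (shared /
    normal_only / iugr_only), log2fc (spiked IUGR-over-normal effect),
    top_rank (1-10 for the planted top fragments, 0 otherwise).
    """

    fragments: pd.DataFrame
    reference: list[MatureTRNA]
    config: SimulationConfig

    def profile(self, group: str) -> np.ndarray:
        """Expected relative abundance vector of one group (sums to 1)."""
        a = self.fragments["baseline"].to_numpy(dtype=float).copy()
        member = self.fragments["membership"].to_numpy()
        if group == GROUP_NORMAL:
            a[member == "iugr_only"] = 0.0
        elif group == GROUP_IUGR:
            a[member == "normal_only"] = 0.0
            a = a * np.power(2.0, self.fragments["log2fc"].to_numpy(dtype=float))
        else:
            raise ValueError(f"unknown group {group!r}")
        return a / a.sum()


# ---------------------------------------------------------------------------
# reference simulation


def simulate_reference(n_trnas: int, rng_seed: int = 1) -> list[MatureTRNA]:
    """Random mature tRNA references with canonical geometry.

    Sequences are 70-80 nt, CCA-terminated, with the anticodon at positions
    36-38 (inside the canonical 33-38 neighborhood) so that 25-34 nt
    tRF-5 and 33-40 nt half fragments are all constructible.  Positions 2-8
    are kept pairwise distinct across tRNAs, which also makes the 40-nt 5'
    prefixes distinct and fragment-to-parent assignment unambiguous.
    """
    if n_trnas < 1:
        raise SimulationError("n_trnas must be at least 1")
    rng = np.random.default_rng(rng_seed)
    records: list[MatureTRNA] = []
    seen_seeds: set[str] = set()
    for k in range(n_trnas):
        L = int(rng.integers(70, 81))
        ac_start = int(rng.integers(36, 39))
        for _ in range(1000):
            seq = "".join(_BASES[rng.integers(0, 4, size=L)])
            seq = seq[: L - 3] + "CCA"
            if seq[1:8] not in seen_seeds:
                break
        else:  # pragma: no cover - 4^7 space, effectively unreachable
            raise SimulationError("could not draw a distinct 5' seed region")
        seen_seeds.add(seq[1:8])
        anticodon = seq[ac_start - 1 : ac_start + 2]
        aa = _AMINO_ACIDS[k % len(_AMINO_ACIDS)]
        records.append(
            MatureTRNA(
                id=f"tRNA-{aa}-{anticodon}-{k + 1}-1",
                amino_acid=aa,
                anticodon=anticodon,
                sequence=seq,
                anticodon_start=ac_start,
                anticodon_end=ac_start + 2,
                origin="cytoplasmic",
            )
        )
    return records


# ---------------------------------------------------------------------------
# catalog construction


def _five_prime_lengths(trna: MatureTRNA, rules: ClassificationRules) -> dict[str, list[int]]:
    """Admissible 5'-anchored fragment lengths per type on one parent."""
    loop_lo, loop_hi = rules.loop(trna)
    out = {
        "tRF-5a": list(range(14, rules.trf5_max_a + 1)),
        "tRF-5b": list(range(rules.trf5_max_a + 1, rules.trf5_max_b + 1)),
        "tRF-5c": list(range(rules.trf5_max_b + 1, loop_lo)),
        "tiRNA-5": list(range(max(loop_lo, 14), min(loop_hi, 40, trna.length) + 1)),
    }
    return out


def _nonfive_candidates(
    trna: MatureTRNA, ts_type: str, rules: ClassificationRules
) -> list[tuple[int, int]]:
    """Candidate (start, end) placements for a non-5'-anchored type."""
    L = trna.length
    loop_lo, loop_hi = rules.loop(trna)
    cands: list[tuple[int, int]] = []
    if ts_type == "tRF-3a":
        for n in range(14, rules.trf3_max_a + 1):
            if L - n + 1 > loop_hi:
                cands.append((L - n + 1, L))
    elif ts_type == "tRF-3b":
        for n in range(rules.trf3_max_a + 1, 31):  # lengths 31-32 reserved for tRF-5c
            if L - n + 1 > loop_hi:
                cands.append((L - n + 1, L))
    elif ts_type == "tiRNA-3":
        for start in range(max(loop_lo, L - 39), min(loop_hi, L - 32) + 1):
            cands.append((start, L))
    elif ts_type == "tRF-2":
        for n in list(range(14, 31)):
            start = max(2, trna.anticodon_start - n // 2)
            end = start + n - 1
            if end < L and start <= trna.anticodon_end and end >= trna.anticodon_start:
                cands.append((start, end))
    else:
        raise SimulationError(f"unsupported non-5' type {ts_type}")
    return cands


def _top_profile(config: SimulationConfig) -> list[tuple[float, str]]:
    """Planted (share, cell) of the ten most expressed fragments.

    Mirrors the measured skew: the two most expressed fragments carry over
    75% of expression and the top four about 81.5%, with the top of the
    catalog dominated by 31-32 nt tRF-5c.
    """
    s = config.top10_share_normal
    if s >= 0.8146 + 6 * 2 * config.min_abundance:
        shares = [0.40, 0.36, 0.03, 0.0246] + [(s - 0.8146) / 6] * 6
        cells = ["5c_31_32", "5c_31_32", "5c_31_32"] + ["5c_other"] * 7
    else:
        # generic geometric fallback for non-default targets
        w = np.power(0.55, np.arange(10))
        shares = list(s * w / w.sum())
        cells = ["5c_31_32"] * 3 + ["5c_other"] * 7
    if sum(shares[:2]) >= config.length_mass_31_32:
        raise SimulationError("top-two share exceeds the 31-32 nt length mass")
    return list(zip(shares, cells))


def _cell_of(ts_type: str, length: int) -> str:
    if ts_type == "tRF-5c":
        return "5c_31_32" if length in (31, 32) else "5c_other"
    return ts_type


def simulate_catalog(
    config: SimulationConfig,
    reference: Sequence[MatureTRNA],
    rules: ClassificationRules = DEFAULT_RULES,
) -> SimulationTruth:
    """Plant a fragment catalog with the configured statistical structure.

    Raises :class:`SimulationError` when the reference cannot host the
    requested catalog (too few parents, colliding seed regions, ...).
    """
    reference = list(reference)
    if not reference:
        raise SimulationError("empty reference")
    rng = np.random.default_rng([config.rng_seed, 11])
    P = config.n_parents
    if len(reference) < P:
        raise SimulationError(
            f"need at least {P} reference tRNAs for {config.n_seed_groups} seed groups"
        )
    parents = reference[:P]
    parent_seeds = [t.sequence[1:8] for t in parents]
    if len(set(parent_seeds)) != P:
        raise SimulationError(
            "reference tRNAs must have pairwise distinct positions 2-8 "
            "(use simulate_reference or curate the reference)"
        )

    mixture = dict(config.type_mixture)
    nonfive_active = [t for t in NON_FIVE_TYPES if mixture.get(t, 0.0) > 0]
    five_active = [t for t in FIVE_PRIME_TYPES if mixture.get(t, 0.0) > 0]
    if "tRF-5c" not in five_active:
        raise SimulationError("the default construction requires a tRF-5c component")

    # ---- species plan ------------------------------------------------
    n_nonfive = config.n_nonfive_species if nonfive_active else 0
    if n_nonfive == 0:
        nonfive_active = []
    f5 = config.catalog_size - n_nonfive
    if f5 < P:
        raise SimulationError("catalog too small to cover every seed parent")
    counts_nonfive: dict[str, int] = {}
    if nonfive_active:
        counts_nonfive = {t: n_nonfive // len(nonfive_active) for t in nonfive_active}
        for t in nonfive_active[: n_nonfive % len(nonfive_active)]:
            counts_nonfive[t] += 1
    counts_five: dict[str, int] = {}
    for t in five_active:
        if t != "tRF-5c":
            counts_five[t] = max(1, round(0.06 * f5))
    counts_five["tRF-5c"] = f5 - sum(counts_five.values())
    if counts_five["tRF-5c"] < 10:
        raise SimulationError("too few tRF-5c species for the planted top fragments")
    n5c = counts_five["tRF-5c"]
    n_31_32 = min(2 * P, max(10, round(0.38 * n5c)))

    # ---- 5'-anchored placements --------------------------------------
    used_lengths: dict[str, set[int]] = {t.id: set() for t in parents}
    avail = {t.id: _five_prime_lengths(t, rules) for t in parents}
    rows: list[dict] = []
    used_seqs: set[str] = set()
    used_seeds: set[str] = set(parent_seeds)

    def assign_five(ts_type: str, count: int, allowed, top_ranks: list[int]):
        cursor = 0
        for idx in range(count):
            placed = False
            for attempt in range(P):
                parent = parents[(cursor + attempt) % P]
                options = [
                    l
                    for l in avail[parent.id][ts_type]
                    if l not in used_lengths[parent.id] and allowed(l)
                ]
                if not options:
                    continue
                length = options[0]
                used_lengths[parent.id].add(length)
                seq = parent.sequence[:length]
                if seq in used_seqs:  # pragma: no cover - distinct 2-8 regions
                    continue
                used_seqs.add(seq)
                got = classify_interval(1, length, parent, rules)
                if got != ts_type:
                    raise SimulationError(
                        f"generator/classifier disagree: planted {ts_type}, got {got}"
                    )
                rows.append(
                    {
                        "sequence": seq,
                        "parent_id": parent.id,
                        "start": 1,
                        "end": length,
                        "type": ts_type,
                        "length": length,
                        "seed": extract_seed(seq),
                        "top_rank": top_ranks[idx] if idx < len(top_ranks) else 0,
                    }
                )
                cursor = (cursor + attempt + 1) % P
                placed = True
                break
            if not placed:
                raise SimulationError(
                    f"cannot place {count} {ts_type} species on {P} parents"
                )

    # designated 31-32 nt tRF-5c first (ranks 1-3 are the catalog's head)
    assign_five("tRF-5c", n_31_32, lambda l: l in (31, 32), top_ranks=[1, 2, 3])
    assign_five("tRF-5c", n5c - n_31_32, lambda l: l not in (31, 32), top_ranks=[4, 5, 6, 7, 8, 9, 10])
    for t in five_active:
        if t != "tRF-5c":
            assign_five(t, counts_five[t], lambda l: l not in (31, 32), top_ranks=[])

    covered = {r["parent_id"] for r in rows}
    if len(covered) != P:
        raise SimulationError(
            "some seed parents received no 5'-anchored fragment; "
            "increase catalog_size or lower n_seed_groups"
        )

    # ---- non-5' placements (each with a catalog-unique seed) ---------
    order = rng.permutation(len(reference))
    for ts_type in nonfive_active:
        placed_count = 0
        cursor = 0
        while placed_count < counts_nonfive[ts_type]:
            placed = False
            for attempt in range(len(reference) * 4):
                trna = reference[order[(cursor + attempt) % len(reference)]]
                for start, end in _nonfive_candidates(trna, ts_type, rules):
                    seq = trna.sequence[start - 1 : end]
                    seed = extract_seed(seq)
                    if seq in used_seqs or seed in used_seeds:
                        continue
                    got = classify_interval(start, end, trna, rules)
                    if got != ts_type:
                        raise SimulationError(
                            f"generator/classifier disagree: planted {ts_type}, got {got}"
                        )
                    used_seqs.add(seq)
                    used_seeds.add(seed)
                    rows.append(
                        {
                            "sequence": seq,
                            "parent_id": trna.id,
                            "start": start,
                            "end": end,
                            "type": ts_type,
                            "length": end - start + 1,
                            "seed": seed,
                            "top_rank": 0,
                        }
                    )
                    placed_count += 1
                    placed = True
                    break
                if placed:
                    cursor = (cursor + attempt + 1) % len(reference)
                    break
            if not placed:
                raise SimulationError(
                    f"exhausted placements for {ts_type}; reference too small "
                    "or too repetitive"
                )

    df = pd.DataFrame(rows)
    if len(df) != config.catalog_size:
        raise SimulationError("internal error: catalog size mismatch")
    if df["seed"].nunique() != config.n_seed_groups:
        raise SimulationError("internal error: seed-group count mismatch")

    # ---- abundances ---------------------------------------------------
    df["cell"] = [_cell_of(t, l) for t, l in zip(df["type"], df["length"])]
    cell_mass = {t: mixture[t] for t in nonfive_active}
    for t in five_active:
        if t != "tRF-5c":
            cell_mass[t] = mixture[t]
    cell_mass["5c_31_32"] = config.length_mass_31_32
    cell_mass["5c_other"] = mixture["tRF-5c"] - config.length_mass_31_32

    top = _top_profile(config)
    baseline = np.zeros(len(df))
    top_mass_in = {"5c_31_32": 0.0, "5c_other": 0.0}
    for rank, (share, cell) in enumerate(top, start=1):
        idx = df.index[df["top_rank"] == rank]
        if len(idx) != 1:
            raise SimulationError("planted top fragment missing from the catalog")
        baseline[idx[0]] = share
        top_mass_in[cell] += share

    floor = config.min_abundance
    min_top = min(share for share, _ in top)
    for cell, mass in cell_mass.items():
        tail_idx = df.index[(df["cell"] == cell) & (df["top_rank"] == 0)].to_numpy()
        tail_mass = mass - top_mass_in.get(cell, 0.0)
        n = len(tail_idx)
        if n == 0:
            if tail_mass > 1e-12:
                raise SimulationError(f"cell {cell} has mass but no species")
            continue
        if tail_mass < n * floor:
            raise SimulationError(
                f"cell {cell}: mass {tail_mass:.4g} cannot give {n} species "
                f"the minimum abundance {floor:g}"
            )
        ranks = rng.permutation(n) + 1
        z = np.power(ranks, -config.zipf_exponent)
        a = floor + z / z.sum() * (tail_mass - n * floor)
        cap = 0.6 * min_top
        for _ in range(64):  # redistribute any tail mass above the head gap
            over = a > cap
            if not over.any():
                break
            excess = (a[over] - cap).sum()
            a[over] = cap
            room = ~over
            a[room] += excess * (a[room] / a[room].sum())
        baseline[tail_idx] = a

    baseline /= baseline.sum()
    df["baseline"] = baseline

    # ---- group membership and spikes ---------------------------------
    n_normal_only, n_iugr_only = config.group_specific
    membership = np.array(["shared"] * len(df), dtype=object)
    eligible = df.index[df["top_rank"] == 0].to_numpy()
    smallest = eligible[np.argsort(baseline[eligible], kind="stable")]
    if n_normal_only + n_iugr_only > len(smallest):
        raise SimulationError("not enough tail species for group-specific subsets")
    membership[smallest[:n_normal_only]] = "normal_only"
    membership[smallest[n_normal_only : n_normal_only + n_iugr_only]] = "iugr_only"
    df["membership"] = membership

    n_down, n_up, fc = config.de_spikes
    log2fc = np.zeros(len(df))
    if n_down + n_up:
        cand = df.index[(df["membership"] == "shared") & (df["top_rank"] == 0)].to_numpy()
        cand = cand[baseline[cand] > 0]
        if len(cand) < n_down + n_up:
            raise SimulationError("not enough shared species to spike")
        # Spike mid-abundance fragments: abundant enough that multinomial
        # counting noise is negligible next to the replicate jitter on both
        # sides of the fold change, light enough not to distort the planted
        # composition.  Down-spikes sit higher than up-spikes so the mass
        # they release in the IUGR profile roughly offsets the mass the
        # up-spikes gain, keeping that profile close to the baseline one.
        def nearest(pool: np.ndarray, anchor: float, k: int) -> np.ndarray:
            below = baseline[pool] < anchor
            order = np.lexsort((np.abs(np.log(baseline[pool] / anchor)), below))
            return pool[order[:k]]

        down_idx = nearest(cand, 1.2e-3, n_down)
        rest = np.setdiff1d(cand, down_idx)
        up_idx = nearest(rest, 3.5e-4, n_up)
        log2fc[down_idx] = -math.log2(fc)
        log2fc[up_idx] = math.log2(fc)
    df["log2fc"] = log2fc

    # ---- exact normal-group top-ten share ----------------------------
    df = _rescale_top_share(df, config)

    return SimulationTruth(fragments=df, reference=reference, config=config)


def _rescale_top_share(df: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Scale baselines cell-wise so the normal-group top-ten share is exact.

    The top fragments are scaled by a common factor and each cell's tail by
    a compensating factor that preserves the cell's normal-profile mass, so
    the type and length composition is left essentially untouched.
    """
    a = df["baseline"].to_numpy(dtype=float).copy()
    normal_mask = (df["membership"] != "iugr_only").to_numpy()
    p = a * normal_mask
    p /= p.sum()
    k = 10
    top_idx = np.argsort(-p, kind="stable")[:k]
    is_top = np.zeros(len(df), dtype=bool)
    is_top[top_idx] = True
    target = config.top10_share_normal
    T = p[is_top].sum()
    alpha = target / T
    scale = np.ones(len(df))
    scale[is_top] = alpha
    for cell in df.loc[is_top, "cell"].unique():
        in_cell = (df["cell"] == cell).to_numpy()
        cell_top = in_cell & is_top
        cell_rest = in_cell & ~is_top
        mass = p[in_cell].sum()
        rest_mass = p[cell_rest].sum()
        if rest_mass <= 0:
            raise SimulationError("top-share rescale needs tail mass in each head cell")
        beta = (mass - alpha * p[cell_top].sum()) / rest_mass
        if beta <= 0:
            raise SimulationError("top-share target infeasible for this catalog")
        scale[cell_rest] = beta
    a = a * scale
    df = df.copy()
    df["baseline"] = a / a.sum()
    return df


# ---------------------------------------------------------------------------
# read simulation


def simulate_sample_counts(
    truth: SimulationTruth,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Multinomial per-sample fragment counts with lognormal replicate jitter.

    Rows align with ``truth.fragments``; columns are sample ids.
    """
    config = config or truth.config
    rng = rng or np.random.default_rng([config.rng_seed, 23])
    out = {}
    for _, row in config.samples.iterrows():
        p = truth.profile(row["group"])
        if config.noise_sigma > 0:
            # noise_sigma is the sd of per-replicate log2 abundance, the same
            # scale the downstream Welch test operates on
            p = p * np.exp2(config.noise_sigma * rng.standard_normal(len(p)))
            p = p / p.sum()
        out[row["sample_id"]] = rng.multinomial(config.depth, p)
    return pd.DataFrame(out, index=truth.fragments.index)


def simulate_reads(
    truth: SimulationTruth,
    outdir: str | Path,
    config: SimulationConfig | None = None,
    rng_seed: int | None = None,
) -> pd.DataFrame:
    """Write one FASTQ per sample plus a sample sheet; returns the sheet.

    Reads are exact fragment sequences (constant quality "I"); a positive
    ``config.error_rate`` introduces uniform random substitutions.
    """
    config = config or truth.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng([seed, 23])
    counts = simulate_sample_counts(truth, config, rng)
    sequences = list(truth.fragments["sequence"])
    sheet_rows = []
    for _, row in config.samples.iterrows():
        sid = row["sample_id"]
        path = outdir / f"{sid}.fastq"
        with open(path, "w") as fq:
            read_no = 0
            for seq, c in zip(sequences, counts[sid]):
                if c == 0:
                    continue
                if config.error_rate > 0:
                    reads = [
                        _mutate(seq, rng, config.error_rate) for _ in range(int(c))
                    ]
                else:
                    reads = [seq] * int(c)
                qual = "I" * len(seq)
                block = "".join(
                    f"@{sid}.{read_no + i}\n{r}\n+\n{qual}\n"
                    for i, r in enumerate(reads)
                )
                read_no += int(c)
                fq.write(block)
        sheet_rows.append({"sample_id": sid, "group": row["group"], "fastq_path": str(path)})
    sheet = pd.DataFrame(sheet_rows)
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    return sheet


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    chars = list(seq)
    for i in np.nonzero(mask)[0]:
        chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


# ---------------------------------------------------------------------------
# UTR simulation


def simulate_utrs(
    tsrna_sequences: Sequence[str],
    n_genes: int,
    planted: Mapping[str, str],
    rng_seed: int = 1,
    utr_length: int = 300,
    site_prefix_len: int = 22,
    max_attempts: int = 500,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate 3' UTRs with planted tsRNA binding sites.

    ``planted`` maps a tsRNA sequence (which must appear in
    ``tsrna_sequences``) to the gene id that should carry its site.  A
    planted UTR contains the reverse complement of the tsRNA's 5' prefix
    (default 22 nt) and hence exactly one occurrence of the seed's reverse
    complement; all other listed seeds are excluded from every UTR, and
    background genes carry no listed seed complement at all.

    Returns (gene_id -> UTR sequence, truth table with the 1-based seed-site
    position per planted gene).
    """
    seqs = list(tsrna_sequences)
    for ts in planted:
        if ts not in seqs:
            raise SimulationError("planted tsRNA not in the provided list")
    gene_ids = [f"gene_{i + 1}" for i in range(n_genes)]
    unknown = set(planted.values()) - set(gene_ids)
    if unknown:
        raise SimulationError(f"planted gene ids outside gene_1..gene_{n_genes}: {unknown}")
    if len(set(planted.values())) != len(planted):
        raise SimulationError("each planted gene may carry only one site")
    rng = np.random.default_rng([rng_seed, 37])
    seed_rcs = {extract_seed(s): reverse_complement(extract_seed(s)) for s in seqs}
    gene_site = {g: ts for ts, g in planted.items()}

    utrs: dict[str, str] = {}
    rows = []
    for gene in gene_ids:
        ts = gene_site.get(gene)
        site = ""
        own_rc = None
        if ts is not None:
            own_rc = reverse_complement(extract_seed(ts))
            for plen in range(min(site_prefix_len, len(ts)), 7, -1):
                site = reverse_complement(ts[:plen])
                if site.count(own_rc) == 1:
                    break
            else:
                raise SimulationError(
                    f"cannot build a single-seed site for tsRNA {ts[:12]}..."
                )
        for _ in range(max_attempts):
            utr = "".join(_BASES[rng.integers(0, 4, size=utr_length)])
            if site:
                pos = int(rng.integers(0, utr_length - len(site) + 1))
                utr = utr[:pos] + site + utr[pos + len(site) :]
            bad = False
            for s_rc in seed_rcs.values():
                want = 1 if (site and s_rc == own_rc) else 0
                if utr.count(s_rc) != want:
                    bad = True
                    break
            if not bad:
                utrs[gene] = utr
                if site:
                    rows.append(
                        {
                            "gene_id": gene,
                            "tsrna_sequence": ts,
                            "seed_site_position": utr.index(own_rc) + 1,
                        }
                    )
                break
        else:
            raise SimulationError(
                f"rejection sampling failed for {gene} after {max_attempts} "
                "attempts; try longer UTRs or fewer listed seeds"
            )
    truth = pd.DataFrame(rows, columns=["gene_id", "tsrna_sequence", "seed_site_position"])
    return utrs, truth


def write_utr_fasta(utrs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fa:
        for gene, seq in utrs.items():
            fa.write(f">{gene}\n{seq}\n")
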