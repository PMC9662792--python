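"""Shared fixtures: a hand-built fixture tRNA, a small simulated study, and
an independent brute-force duplex enumerator used to check the MFE dynamic
program."""

from __future__ import annotations

import numpy as np
import pytest

from tsrnakit.energy import EnergyParameters
from tsrnakit.reference import MatureTRNA
from tsrnakit.simulate import SimulationConfig, simulate_catalog, simulate_reference


def make_fixture_trna(anticodon_start: int = 35, length: int = 76) -> MatureTRNA:
    """Deterministic 76-nt tRNA with the anticodon at 35-37 and no repeats
    of the anticodon triplet elsewhere."""
    rng = np.random.default_rng(20240301)
    bases = np.array(list("ACGT"))
    anticodon = "GCC"
    for _ in range(100):
        seq = "".join(bases[rng.integers(0, 4, size=length)])
        seq = seq[: length - 3] + "CCA"
        seq = seq[: anticodon_start - 1] + anticodon + seq[anticodon_start + 2 :]
        if seq.count(anticodon) == 1:
            break
    return MatureTRNA(
        id="tRNA-Gly-GCC-1-1",
        amino_acid="Gly",
        anticodon=anticodon,
        sequence=seq,
        anticodon_start=anticodon_start,
        anticodon_end=anticodon_start + 2,
    )


@pytest.fixture(scope="session")
def fixture_trna() -> MatureTRNA:
    return make_fixture_trna()


@pytest.fixture(scope="session")
def small_reference():
    return simulate_reference(8, rng_seed=5)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down study: 60 fragments, 30 seeds, light depth."""
    return SimulationConfig(
        catalog_size=60,
        n_seed_groups=30,
        group_specific=(6, 4),
        de_spikes=(3, 2, 8.0),
        n_nonfive_species=12,
        depth=100_000,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    reference = simulate_reference(small_config.n_parents + 2, rng_seed=7)
    return simulate_catalog(small_config, reference)


def brute_force_mfe(x: str, y: str, params: EnergyParameters) -> float:
    """Exhaustive enumeration of every loop-bounded intermolecular duplex.

    Builds each antiparallel pair set pair-by-pair (strictly increasing on x,
    strictly decreasing on y, per-step unpaired gaps bounded by
    ``params.max_loop`` on each strand) and scores it directly.  Independent
    of the dynamic program it validates.
    """
    n, m = len(x), len(y)
    valid = [
        (i, j)
        for i in range(1, n + 1)
        for j in range(1, m + 1)
        if params.is_pair(x[i - 1], y[j - 1])
    ]
    best = 0.0

    def extend(i: int, j: int, e: float) -> None:
        nonlocal best
        if e < best:
            best = e
        for i2 in range(i + 1, min(n, i + 1 + params.max_loop) + 1):
            for j2 in range(max(1, j - 1 - params.max_loop), j):
                if not params.is_pair(x[i2 - 1], y[j2 - 1]):
                    continue
                gap = (i2 - i - 1) + (j - j2 - 1)
                if gap == 0:
                    step = params.stack((x[i - 1], y[j - 1]), (x[i2 - 1], y[j2 - 1]))
                else:
                    step = params.loop_penalty(gap)
                extend(i2, j2, e + step)

    for i, j in valid:
        extend(i, j, params.initiation)
    return best
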