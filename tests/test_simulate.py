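"""Generator contracts: reference validity, planted catalog structure,
read determinism, and UTR planting."""

import numpy as np
import pandas as pd
import pytest

from tsrnakit.classify import classify_interval
from tsrnakit.reference import load_trna_reference, write_trna_reference
from tsrnakit.simulate import (
    SimulationConfig,
    SimulationError,
    simulate_catalog,
    simulate_reads,
    simulate_reference,
    simulate_sample_counts,
    simulate_utrs,
    write_utr_fasta,
)
from tsrnakit.targets import extract_seed, reverse_complement, scan_utr


class TestSimulateReference:
    def test_seeded_determinism(self):
        a = simulate_reference(5, rng_seed=1)
        b = simulate_reference(5, rng_seed=1)
        assert a == b

    def test_records_survive_their_own_loader(self, tmp_path, small_reference):
        fa, tab = tmp_path / "r.fa", tmp_path / "r.tsv"
        write_trna_reference(small_reference, fa, tab)
        assert load_trna_reference(fa, tab) == list(small_reference)

    def test_geometry_contract(self):
        (rec,) = simulate_reference(1, rng_seed=7)
        assert 33 <= rec.anticodon_start <= 38
        assert 70 <= rec.length <= 90
        assert rec.sequence.endswith("CCA")

    def test_distinct_five_prime_prefixes(self):
        ref = simulate_reference(40, rng_seed=3)
        prefixes = {t.sequence[:40] for t in ref}
        assert len(prefixes) == 40

    def test_rejects_empty_request(self):
        with pytest.raises(SimulationError):
            simulate_reference(0)


class TestSimulateCatalog:
    def test_planted_structure(self, small_truth, small_config):
        df = small_truth.fragments
        assert len(df) == small_config.catalog_size
        assert df["sequence"].nunique() == small_config.catalog_size
        assert df["seed"].nunique() == small_config.n_seed_groups
        counts = df["membership"].value_counts()
        assert counts.get("normal_only", 0) == small_config.group_specific[0]
        assert counts.get("iugr_only", 0) == small_config.group_specific[1]

    def test_spikes_are_exactly_the_configured_fold_changes(self, small_truth, small_config):
        n_down, n_up, fc = small_config.de_spikes
        lfc = small_truth.fragments["log2fc"]
        assert (lfc == -np.log2(fc)).sum() == n_down
        assert (lfc == np.log2(fc)).sum() == n_up
        assert (lfc != 0).sum() == n_down + n_up

    def test_truth_consistency_with_classifier(self, small_truth):
        """Planted labels agree with the classifier on truth coordinates."""
        by_id = {t.id: t for t in small_truth.reference}
        for row in small_truth.fragments.itertuples():
            got = classify_interval(row.start, row.end, by_id[row.parent_id])
            assert got == row.type
            assert by_id[row.parent_id].sequence[row.start - 1 : row.end] == row.sequence
            assert extract_seed(row.sequence) == row.seed

    def test_top_share_is_exact_in_the_normal_profile(self, small_truth, small_config):
        p = small_truth.profile("normal")
        assert np.sort(p)[-10:].sum() == pytest.approx(
            small_config.top10_share_normal, abs=1e-9
        )

    def test_abundance_mixture_without_top_rescale(self):
        """With the top-ten share left at its planted value the
        abundance-weighted type mixture is exact by construction."""
        cfg = SimulationConfig(
            catalog_size=60,
            n_seed_groups=30,
            group_specific=(0, 0),
            de_spikes=(0, 0, 8.0),
            n_nonfive_species=12,
            top10_share_normal=0.8916,
            rng_seed=3,
        )
        ref = simulate_reference(cfg.n_parents + 2, rng_seed=3)
        truth = simulate_catalog(cfg, ref)
        df = truth.fragments
        shares = df.groupby("type")["baseline"].sum()
        # group-specific and spike machinery disabled: only the top-share
        # rescale moves mass, and it preserves per-cell masses
        for t, frac in cfg.type_mixture.items():
            assert shares.get(t, 0.0) == pytest.approx(frac, abs=1e-6)
        mass_31_32 = df.loc[df["length"].isin([31, 32]), "baseline"].sum()
        assert mass_31_32 == pytest.approx(cfg.length_mass_31_32, abs=1e-6)

    def test_pure_trf5c_mixture(self):
        cfg = SimulationConfig(
            catalog_size=50,
            n_seed_groups=20,
            group_specific=(4, 3),
            de_spikes=(2, 1, 8.0),
            type_mixture={"tRF-5c": 1.0},
            length_mass_31_32=0.8,
            n_nonfive_species=0,
            rng_seed=11,
        )
        ref = simulate_reference(cfg.n_parents + 2, rng_seed=11)
        truth = simulate_catalog(cfg, ref)
        df = truth.fragments
        assert set(df["type"]) == {"tRF-5c"}
        assert (df["start"] == 1).all()
        by_id = {t.id: t for t in truth.reference}
        for row in df.itertuples():
            assert row.end < by_id[row.parent_id].anticodon_start - 3

    def test_infeasible_catalog_is_rejected(self):
        ref = simulate_reference(4, rng_seed=1)
        cfg = SimulationConfig(
            catalog_size=40, n_seed_groups=30, group_specific=(0, 0),
            n_nonfive_species=5, rng_seed=1,
        )
        with pytest.raises(SimulationError):
            simulate_catalog(cfg, ref)


class TestSimulateReads:
    def test_seeded_determinism_is_byte_identical(self, small_truth, small_config, tmp_path):
        sheet1 = simulate_reads(small_truth, tmp_path / "a", small_config)
        sheet2 = simulate_reads(small_truth, tmp_path / "b", small_config)
        for p1, p2 in zip(sheet1["fastq_path"], sheet2["fastq_path"]):
            assert open(p1, "rb").read() == open(p2, "rb").read()

    def test_counts_sum_to_depth_and_respect_membership(self, small_truth, small_config):
        counts = simulate_sample_counts(small_truth, small_config)
        assert (counts.sum(axis=0) == small_config.depth).all()
        member = small_truth.fragments["membership"]
        normal_cols = [s for s in counts if s.startswith("normal")]
        iugr_cols = [s for s in counts if s.startswith("IUGR")]
        assert counts.loc[member == "iugr_only", normal_cols].values.sum() == 0
        assert counts.loc[member == "normal_only", iugr_cols].values.sum() == 0

    def test_degenerate_profile_is_a_point_mass(self, small_truth, small_config):
        """sigma=0 and one dominant fragment: almost every read is it."""
        from dataclasses import replace

        truth = small_truth
        df = truth.fragments.copy()
        df["baseline"] = 0.0
        df.loc[df.index[0], "baseline"] = 1.0
        df["membership"] = "shared"
        df["log2fc"] = 0.0
        truth = type(truth)(fragments=df, reference=truth.reference, config=truth.config)
        cfg = replace(small_config, noise_sigma=0.0, group_specific=(0, 0))
        counts = simulate_sample_counts(truth, cfg)
        assert (counts.iloc[0] == cfg.depth).all()


class TestSimulateUTRs:
    def test_planted_seed_site_occurs_exactly_once(self):
        ts = "G" + "CATTGGT" + "ACGTACGTACGTACGTACGTACG"
        utrs, truth = simulate_utrs([ts], n_genes=4, planted={ts: "gene_2"}, rng_seed=1)
        assert set(utrs) == {"gene_1", "gene_2", "gene_3", "gene_4"}
        site_rc = reverse_complement("CATTGGT")
        assert site_rc == "ACCAATG"
        assert utrs["gene_2"].count(site_rc) == 1
        assert truth.loc[0, "seed_site_position"] == utrs["gene_2"].index(site_rc) + 1

    def test_background_genes_carry_no_listed_seed(self, small_truth):
        seqs = list(small_truth.fragments["sequence"][:5])
        utrs, _ = simulate_utrs(seqs, n_genes=6, planted={seqs[0]: "gene_1"}, rng_seed=2)
        for gene, utr in utrs.items():
            for i, s in enumerate(seqs):
                hits = scan_utr(extract_seed(s), utr)
                if gene == "gene_1" and extract_seed(s) == extract_seed(seqs[0]):
                    assert len(hits) == 1
                else:
                    assert hits == []

    def test_seeded_determinism(self):
        ts = "G" + "CATTGGT" + "ACGTACGTACGTACGTACGTACG"
        a, _ = simulate_utrs([ts], 3, {ts: "gene_1"}, rng_seed=9)
        b, _ = simulate_utrs([ts], 3, {ts: "gene_1"}, rng_seed=9)
        assert a == b

    def test_unknown_planted_tsrna_rejected(self):
        with pytest.raises(SimulationError):
            simulate_utrs(["A" * 20], 2, {"C" * 20: "gene_1"}, rng_seed=1)

    def test_fasta_round_trip(self, tmp_path):
        ts = "G" + "CATTGGT" + "ACGTACGTACGTACGTACGTACG"
        utrs, _ = simulate_utrs([ts], 2, {ts: "gene_1"}, rng_seed=4)
        path = tmp_path / "utrs.fa"
        write_utr_fasta(utrs, path)
        from Bio import SeqIO

        loaded = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        assert loaded == utrs
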