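"""CPM, expressed sets, top-share, BH-FDR and differential expression."""

import numpy as np
import pandas as pd
import pytest

from tsrnakit.express import (
    ExpressionMatrix,
    benjamini_hochberg,
    cpm_normalize,
    differential_expression,
    expressed_sets,
    top_share,
)
from tsrnakit.simulate import simulate_sample_counts


def matrix_from(rows, groups):
    counts = pd.DataFrame(rows).T
    counts.columns = list(groups)
    return ExpressionMatrix(counts, pd.Series(groups))


def two_group_matrix(data):
    """data: dict tsrna_id -> list of 6 counts (3 normal then 3 IUGR)."""
    counts = pd.DataFrame(data, index=["n1", "n2", "n3", "i1", "i2", "i3"]).T
    groups = pd.Series(
        ["normal"] * 3 + ["IUGR"] * 3, index=["n1", "n2", "n3", "i1", "i2", "i3"]
    )
    return ExpressionMatrix(counts, groups)


class TestCPM:
    def test_equal_counts_split_the_million(self):
        cpm = cpm_normalize(pd.DataFrame({"s": [1, 1]}))
        assert cpm["s"].tolist() == [5e5, 5e5]

    def test_single_row_column(self):
        assert cpm_normalize(pd.DataFrame({"s": [7]}))["s"].tolist() == [1e6]

    def test_columns_sum_to_a_million(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.integers(0, 500, size=(40, 4)) + 1)
        assert cpm_normalize(counts).sum(axis=0).values == pytest.approx([1e6] * 4)

    def test_zero_depth_sample_is_named(self):
        with pytest.raises(ValueError, match="empty"):
            cpm_normalize(pd.DataFrame({"ok": [1], "empty": [0]}))


class TestExpressedSets:
    def test_partition_and_membership(self):
        m = two_group_matrix(
            {
                "both": [5, 5, 5, 5, 5, 5],
                "norm": [2, 0, 1, 0, 0, 0],
                "iugr": [0, 0, 0, 3, 0, 0],
            }
        )
        sets = expressed_sets(m)
        assert sets["normal_only"] == {"norm"}
        assert sets["iugr_only"] == {"iugr"}
        assert sets["shared"] == {"both"}
        total = sum(len(v) for v in sets.values())
        assert total == 3


class TestTopShare:
    def test_totality(self):
        m = two_group_matrix({"a": [1] * 6, "b": [3] * 6})
        assert top_share(m, 2, "normal") == pytest.approx(1.0)

    def test_arithmetic(self):
        m = two_group_matrix({"a": [9, 9, 9, 1, 1, 1], "b": [1, 1, 1, 9, 9, 9]})
        assert top_share(m, 1, "normal") == pytest.approx(0.9)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(5)
        data = {f"t{i}": list(rng.integers(1, 100, 6)) for i in range(12)}
        m = two_group_matrix(data)
        shares = [top_share(m, k, "IUGR") for k in range(1, 13)]
        assert all(b >= a for a, b in zip(shares, shares[1:]))


class TestBenjaminiHochberg:
    def test_hand_oracle(self):
        # 0.01*3/1=0.03, 0.02*3/2=0.03, 0.03*3/3=0.03 -> step-up keeps 0.03
        assert benjamini_hochberg([0.01, 0.02, 0.03]) == pytest.approx([0.03] * 3)

    def test_equal_ps_are_a_fixed_point(self):
        assert benjamini_hochberg([0.5] * 4) == pytest.approx([0.5] * 4)

    def test_dominates_raw_p_and_preserves_order(self):
        rng = np.random.default_rng(8)
        p = rng.random(200)
        fdr = benjamini_hochberg(p)
        assert (fdr >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-15).all()

    def test_independent_stepup_oracle(self):
        """Direct implementation of the step-up definition."""
        rng = np.random.default_rng(21)
        p = rng.random(50)
        m = len(p)
        expected = np.empty(m)
        for i, pi in enumerate(p):
            expected[i] = min(
                min(pj * m / (np.sum(p <= pj)) for pj in p if pj >= pi), 1.0
            )
        assert benjamini_hochberg(p) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestDifferentialExpression:
    def test_identical_groups_are_ns(self):
        m = two_group_matrix({"a": [10, 20, 30, 10, 20, 30], "b": [5, 5, 5, 5, 5, 5]})
        table = differential_expression(m)
        assert (table["status"] == "ns").all()
        assert table["log2fc"].values == pytest.approx([0.0, 0.0])

    def test_planted_sixteen_fold_spike_with_zero_noise(self):
        """Exact 16-fold column ratio, zero within-group variance: the
        spiked row is called in the spiked direction."""
        m = two_group_matrix(
            {
                "spike": [100, 100, 100, 1600, 1600, 1600],
                "flat": [900, 900, 900, 900, 900, 900],
                "pad": [1000, 1000, 1000, 2500, 2500, 2500],
            }
        )
        table = differential_expression(m).set_index("tsrna_id")
        assert table.loc["spike", "status"] == "up"
        assert table.loc["spike", "log2fc"] > 1

    def test_label_swap_negates_log2fc_and_keeps_fdr(self):
        rng = np.random.default_rng(13)
        data = {f"t{i}": list(rng.integers(50, 5000, 6)) for i in range(30)}
        m = two_group_matrix(data)
        fwd = differential_expression(m)
        counts = m.counts.copy()
        swapped_groups = m.groups.map({"normal": "IUGR", "IUGR": "normal"})
        rev = differential_expression(ExpressionMatrix(counts, swapped_groups))
        assert rev["log2fc"].values == pytest.approx(-fwd["log2fc"].values)
        assert rev["fdr"].values == pytest.approx(fwd["fdr"].values)

    def test_small_group_rejected(self):
        counts = pd.DataFrame({"n1": [1], "i1": [2]})
        groups = pd.Series({"n1": "normal", "i1": "IUGR"})
        with pytest.raises(ValueError, match="2 samples"):
            differential_expression(ExpressionMatrix(counts, groups))


@pytest.fixture(scope="module")
def de_truth():
    from tsrnakit.simulate import SimulationConfig, simulate_catalog, simulate_reference

    cfg = SimulationConfig(group_specific=(0, 0), rng_seed=1)
    reference = simulate_reference(cfg.n_parents + 4, rng_seed=1)
    return simulate_catalog(cfg, reference), cfg


class TestSpikeRecovery:
    def test_spiked_fold_changes_are_recovered(self, de_truth):
        """Across 20 jitter seeds at study depth: every call is a true spike
        with the right sign, and recovery stays within the small-sample miss
        rate of the Welch test (at most two missed spikes per run, exact
        recovery in most runs)."""
        truth, cfg = de_truth
        spiked = truth.fragments["log2fc"]
        groups = pd.Series(
            list(cfg.samples["group"]), index=list(cfg.samples["sample_id"])
        )
        true_dir = {
            f"f{i}": ("down" if l < 0 else "up") for i, l in spiked.items() if l != 0
        }
        exact = 0
        for seed in range(20):
            counts = simulate_sample_counts(truth, cfg, np.random.default_rng([seed, 41]))
            counts.index = [f"f{i}" for i in counts.index]
            de = differential_expression(ExpressionMatrix(counts, groups))
            de.index = de["tsrna_id"]
            called = de[de["status"] != "ns"]
            # soundness: no false calls, correct signs
            for tsid, row in called.iterrows():
                assert tsid in true_dir and true_dir[tsid] == row["status"]
            assert len(called) >= len(true_dir) - 2
            exact += len(called) == len(true_dir)
        assert exact >= 13
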