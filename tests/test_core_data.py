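import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bacstab.core_data import (
    AbundanceTable,
    d_values,
    diversity,
    read_abundance_table,
    to_relative,
    top_n_with_remainder,
    write_abundance_table,
)

from conftest import make_design


class TestIO:
    def test_round_trip_exact(self, tiny_counts, full_design, tmp_path):
        rel = to_relative(tiny_counts)
        path = tmp_path / "rel.tsv"
        write_abundance_table(rel, path)
        back = read_abundance_table(path, full_design)
        assert back.mode == "relative"
        assert np.array_equal(back.data.to_numpy(), rel.data.to_numpy())

    def test_counts_mode_detected(self, tiny_counts, full_design, tmp_path):
        path = tmp_path / "counts.tsv"
        write_abundance_table(tiny_counts, path)
        assert read_abundance_table(path, full_design).mode == "counts"

    def test_unknown_sample_rejected(self, tiny_counts, full_design, tmp_path):
        df = tiny_counts.data.rename(columns={"A1R1": "Z9R9"})
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t")
        with pytest.raises(ValueError, match="Z9R9"):
            read_abundance_table(path, full_design)

    def test_negative_value_rejected(self):
        df = pd.DataFrame([[1.0, -2.0]], index=["t1"], columns=["A1R1", "A1R2"])
        with pytest.raises(ValueError, match="negative"):
            AbundanceTable(df, mode="counts")


class TestRelative:
    @pytest.mark.parametrize(
        "column, expected",
        [([2.0, 2.0], [0.5, 0.5]), ([1.0, 3.0], [0.25, 0.75])],
    )
    def test_forced_values(self, column, expected):
        df = pd.DataFrame({"s1": column}, index=["t1", "t2"])
        df.columns = ["A1R1"]
        rel = to_relative(AbundanceTable(df, mode="counts"))
        assert np.allclose(rel.data["A1R1"], expected)

    def test_idempotent(self, tiny_counts):
        once = to_relative(tiny_counts)
        twice = to_relative(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_all_zero_column_named(self):
        df = pd.DataFrame({"A1R1": [0.0, 0.0], "A1R2": [1.0, 1.0]}, index=["t1", "t2"])
        with pytest.raises(ValueError, match="A1R1"):
            to_relative(AbundanceTable(df, mode="counts"))


class TestTopN:
    def test_conservation_and_shape(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.integers(1, 50, size=(5, 3)).astype(float),
                          index=[f"t{i}" for i in range(5)],
                          columns=["A1R1", "A1R2", "A1R3"])
        t = AbundanceTable(df, mode="counts")
        out = top_n_with_remainder(t, 3)
        assert len(out.data) == 4
        assert "Other" in out.data.index
        assert np.allclose(out.data.sum(axis=0), df.sum(axis=0), atol=1e-12)

    def test_boundary_n_equal_taxa(self, tiny_counts):
        out = top_n_with_remainder(tiny_counts, 3)
        assert list(out.data.index) == list(tiny_counts.data.index)

    def test_tie_break_lexicographic(self):
        # all taxa share identical mean abundance: ranking must fall back to id
        df = pd.DataFrame(
            [[1.0, 1.0]] * 4,
            index=["zz", "aa", "mm", "bb"],
            columns=["A1R1", "A1R2"],
        )
        out = top_n_with_remainder(AbundanceTable(df, mode="counts"), 2)
        assert list(out.data.index[:2]) == ["aa", "bb"]

    def test_per_phylum_remainder(self):
        df = pd.DataFrame(
            np.array([[10, 10], [8, 8], [1, 1], [1, 1]], dtype=float),
            index=["t1", "t2", "t3", "t4"],
            columns=["A1R1", "A1R2"],
        )
        lineage = pd.Series(
            {
                "t1": "k__Bacteria;p__Proteobacteria",
                "t2": "k__Bacteria;p__Acidobacteria",
                "t3": "k__Bacteria;p__Proteobacteria",
                "t4": "k__Bacteria;p__Acidobacteria",
            }
        )
        t = AbundanceTable(df, mode="counts", lineage=lineage)
        out = top_n_with_remainder(t, 2)
        assert {"Other Proteobacteria", "Other Acidobacteria"} <= set(out.data.index)
        assert np.allclose(out.data.sum(axis=0), df.sum(axis=0))


class TestDValues:
    def test_pair_count_full_design(self, small_community):
        table, design, _ = small_community
        dt = d_values(to_relative(table), design)
        assert len(dt.labels) == 36
        assert dt.data.shape == (len(table.taxa), 36)

    def test_identical_sites_zero(self, full_design):
        samples = full_design.sample_ids
        df = pd.DataFrame(
            np.tile([[1.0], [2.0]], (1, len(samples))), index=["t1", "t2"], columns=samples
        )
        dt = d_values(AbundanceTable(df, mode="counts"), full_design)
        assert np.allclose(dt.data, 0.0)

    def test_single_pair_difference(self):
        design = make_design(stages=1, replicates=1)
        df = pd.DataFrame({"A1R1": [0.4], "B1R1": [0.1]}, index=["t1"])
        dt = d_values(AbundanceTable(df, mode="counts"), design)
        assert dt.data.loc["t1", "S1R1"] == pytest.approx(0.3)

    def test_site_swap_antisymmetry(self, small_community):
        table, design, _ = small_community
        rel = to_relative(table)
        dt = d_values(rel, design)
        swapped = design.frame.copy()
        swapped["site"] = swapped["site"].map({"A": "B", "B": "A"})
        from bacstab.core_data import SampleDesign

        dt2 = d_values(rel, SampleDesign(swapped))
        assert np.allclose(dt.data.to_numpy(), -dt2.data.to_numpy(), atol=1e-12)

    def test_unmatched_replicates_excluded(self):
        design = make_design(stages=1, replicates=2)
        frame = design.frame[design.frame["sample_id"] != "B1R2"]
        from bacstab.core_data import SampleDesign

        partial = SampleDesign(frame)
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0]], index=["t1"], columns=["A1R1", "A1R2", "B1R1"]
        )
        dt = d_values(AbundanceTable(df, mode="counts"), partial)
        assert dt.labels == ["S1R1"]


class TestDiversity:
    def test_uniform_shannon(self):
        df = pd.DataFrame({"A1R1": [10] * 10}, index=[f"t{i}" for i in range(10)]).astype(float)
        out = diversity(AbundanceTable(df, mode="counts"))
        assert out.loc["A1R1", "shannon"] == pytest.approx(np.log(10), abs=1e-9)

    def test_single_species_degenerate(self):
        df = pd.DataFrame({"A1R1": [50.0]}, index=["t1"])
        out = diversity(AbundanceTable(df, mode="counts"))
        assert out.loc["A1R1", "simpson_D"] == pytest.approx(1.0)
        assert out.loc["A1R1", "shannon"] == pytest.approx(0.0)

    def test_chao1_hand_value(self):
        # counts [5,3,1,1]: S=4, F1=2, F2=0 -> chao1 = 4 + 2*1/(2*1) = 5
        df = pd.DataFrame({"A1R1": [5.0, 3.0, 1.0, 1.0]}, index=list("abcd"))
        out = diversity(AbundanceTable(df, mode="counts"))
        assert out.loc["A1R1", "chao1"] == pytest.approx(5.0)
        assert out.loc["A1R1", "observed_richness"] == 4

    def test_richness_estimators_require_counts(self, tiny_counts):
        rel = to_relative(tiny_counts)
        with pytest.raises(ValueError, match="counts"):
            diversity(rel)
        out = diversity(rel, richness_estimators=False)
        assert {"shannon", "simpson_D"} <= set(out.columns)

    def test_invariant_under_taxon_reorder(self, tiny_counts):
        out = diversity(tiny_counts)
        shuffled = AbundanceTable(tiny_counts.data.iloc[::-1], mode="counts")
        out2 = diversity(shuffled)
        assert np.allclose(out[["shannon", "simpson_D"]], out2[["shannon", "simpson_D"]])

    def test_richness_not_above_chao1(self, small_community):
        table, _, _ = small_community
        out = diversity(table)
        assert (out["observed_richness"] <= out["chao1"] + 1e-9).all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.integers(min_value=2, max_value=6),
    st.integers(min_value=0, max_value=10_000),
)
def test_to_relative_columns_sum_to_one(n_taxa, seed):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.integers(1, 100, size=(n_taxa, 3)).astype(float),
        index=[f"t{i}" for i in range(n_taxa)],
        columns=["A1R1", "A1R2", "A1R3"],
    )
    rel = to_relative(AbundanceTable(df, mode="counts"))
    assert np.allclose(rel.data.sum(axis=0), 1.0, atol=1e-9)


class TestRarefy:
    def test_equal_depths_after_rarefaction(self, small_community):
        from bacstab.core_data import rarefy

        table, _, _ = small_community
        out = rarefy(table, seed=0)
        sums = out.data.sum(axis=0)
        assert (sums == sums.iloc[0]).all()
        assert (out.data.to_numpy() <= table.data.to_numpy()).all()

    def test_requires_counts(self, tiny_counts):
        from bacstab.core_data import rarefy

        with pytest.raises(ValueError, match="counts"):
            rarefy(to_relative(tiny_counts))

    def test_seeded_reproducible(self, tiny_counts):
        from bacstab.core_data import rarefy

        a = rarefy(tiny_counts, depth=5, seed=3)
        b = rarefy(tiny_counts, depth=5, seed=3)
        assert a.data.equals(b.data)
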