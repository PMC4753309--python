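"""Copy-number correction, Bray-Curtis clustering, succession analytics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ferromat.community import (
    AbundanceTable,
    MatState,
    bray_curtis,
    bray_curtis_matrix,
    classify_stage,
    cluster_dendrogram,
    decline_rate,
    extrapolate,
    primer_bias,
    relative_abundance,
)
from ferromat.config import StageThresholds
from ferromat.datasets import mature_mat_abundance_survey


def table(data: dict, mode="counts", copy_numbers=None):
    values = pd.DataFrame(data).T  # taxa as rows
    cn = pd.Series(copy_numbers) if copy_numbers else None
    return AbundanceTable(values=values, mode=mode, copy_numbers=cn)


class TestRelativeAbundance:
    def test_copy_number_correction(self):
        t = table({"A": {"s1": 100}, "B": {"s1": 50}}, copy_numbers={"A": 2.0, "B": 1.0})
        out = relative_abundance(t)
        assert out.values.at["A", "s1"] == pytest.approx(0.5)
        assert out.values.at["B", "s1"] == pytest.approx(0.5)
        assert out.mode == "proportions"

    def test_uniform_copies_equal_plain_normalization(self):
        counts = {"A": {"s1": 30, "s2": 5}, "B": {"s1": 70, "s2": 15}}
        plain = relative_abundance(table(counts))
        uniform = relative_abundance(table(counts, copy_numbers={"A": 1.0, "B": 1.0}))
        pd.testing.assert_frame_equal(plain.values, uniform.values)

    def test_single_taxon_sample(self):
        out = relative_abundance(table({"A": {"s1": 7}}))
        assert out.values.at["A", "s1"] == 1.0

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 100, (6, 4)),
                              index=list("ABCDEF"), columns=list("wxyz"))
        out = relative_abundance(AbundanceTable(values=counts.astype(float)))
        assert np.allclose(out.values.sum(axis=0), 1.0, atol=1e-12)

    def test_all_zero_sample_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            relative_abundance(table({"A": {"s1": 0}, "B": {"s1": 0}}))

    def test_duplicate_sample_ids_rejected(self):
        values = pd.DataFrame([[1.0, 2.0]], index=["A"], columns=["s1", "s1"])
        with pytest.raises(ValueError, match="duplicate"):
            AbundanceTable(values=values)


class TestBrayCurtis:
    def test_identical_vectors(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports(self):
        assert bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    def test_worked_example(self):
        assert bray_curtis([10, 0], [5, 5]) == pytest.approx(0.5)

    def test_both_zero_raises(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=10, max_size=10),
        st.lists(st.floats(0, 100, allow_nan=False), min_size=10, max_size=10),
    )
    def test_matches_elementwise_oracle(self, x, y):
        """Sum|x-y|/Sum(x+y) computed by explicit loop."""
        num = sum(abs(a - b) for a, b in zip(x, y))
        den = sum(a + b for a, b in zip(x, y))
        if den == 0:
            return
        assert bray_curtis(x, y) == pytest.approx(num / den, abs=1e-12)


class TestClusterDendrogram:
    def test_two_samples_join_at_their_distance(self):
        t = table({"A": {"s1": 1.0, "s2": 0.6}, "B": {"s1": 0.0, "s2": 0.4}},
                  mode="counts")
        dm = bray_curtis_matrix(t)
        dend = cluster_dendrogram(dm)
        assert dend.merge_heights()[-1] == pytest.approx(dm["s1", "s2"])

    def test_closest_pair_joins_first(self):
        data = np.array([[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]])
        from skbio import DistanceMatrix

        dend = cluster_dendrogram(DistanceMatrix(data, ids=["A", "B", "C"]))
        assert dend.merge_heights()[0] == pytest.approx(0.1)
        newick = dend.to_newick()
        assert "(A:" in newick.replace(" ", "") or "A:0.05" in newick

    def test_identical_samples_cluster_at_zero(self):
        t = table({"A": {"s1": 2.0, "s2": 2.0}, "B": {"s1": 1.0, "s2": 1.0}})
        dend = cluster_dendrogram(bray_curtis_matrix(t))
        assert dend.merge_heights()[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("linkage", ["complete", "average"])
    def test_merge_heights_are_monotone(self, linkage, osp):
        """Ultrametricity: heights never decrease along the merge sequence."""
        from ferromat.synthetic import gen_community_table
        from ferromat.config import NoiseSpec

        t = gen_community_table(osp, [4, 10, 15, 30, 40, 55, 70],
                                NoiseSpec("dirichlet", 50, 5))
        dend = cluster_dendrogram(bray_curtis_matrix(t), linkage=linkage)
        heights = dend.merge_heights()
        assert (np.diff(heights) >= -1e-12).all()

    def test_newick_is_parseable_with_branch_lengths(self):
        t = table({"A": {"s1": 1.0, "s2": 0.2, "s3": 0.5},
                   "B": {"s1": 0.0, "s2": 0.8, "s3": 0.5}})
        newick = cluster_dendrogram(bray_curtis_matrix(t)).to_newick()
        from skbio import TreeNode
        from io import StringIO

        tree = TreeNode.read(StringIO(newick))
        assert {n.name for n in tree.tips()} == {"s1", "s2", "s3"}


class TestDeclineAndExtrapolation:
    def test_two_point_decline(self):
        assert decline_rate([15, 70], [65, 10]) == pytest.approx(1.0)

    def test_constant_series(self):
        assert decline_rate([4, 30, 70], [15, 15, 15]) == pytest.approx(0.0, abs=1e-12)

    def test_extrapolation_with_floor(self):
        assert extrapolate(1.0, 70, 31, 100) == pytest.approx(1.0)
        assert extrapolate(1.0, 70, 10, 100) == 0.0  # floored

    def test_rod_taxon_default_trajectory_declines_one_percent_per_day(self, osp):
        from ferromat.synthetic import gen_community_table

        t = gen_community_table(osp, [10, 20, 30, 40, 50])
        rod = t.values.loc["Hydrogenobaculum"] * 100
        days = t.sample_meta["day"].to_numpy()
        assert decline_rate(days, rod.to_numpy()) == pytest.approx(1.0, rel=1e-9)


class TestPrimerBias:
    def test_published_survey_ratios(self):
        """Amplicon over/underestimation in the mature-mat comparison."""
        survey = mature_mat_abundance_survey()
        itag = AbundanceTable(values=survey[["osp_itag"]].dropna().rename(columns={"osp_itag": "osp"}))
        ref = AbundanceTable(values=survey[["osp_illumina"]].rename(columns={"osp_illumina": "osp"}))
        out = primer_bias(itag, ref).set_index("taxon")
        hydro = out.loc["Hydrogenobaculum"]
        assert hydro["ratio"] == pytest.approx(24.2 / 3, abs=0.01)  # 8.07
        assert hydro["flag"] == "over"
        myello = out.loc["M. yellowstonensis"]
        assert myello["ratio"] == pytest.approx(0.51 / 16, abs=0.001)  # 0.032
        assert myello["flag"] == "under"
        assert out.loc["Novel archaeal group 3", "flag"] == "absent"

    def test_identical_tables_are_unbiased(self):
        t = table({"A": {"s1": 0.6}, "B": {"s1": 0.4}})
        out = primer_bias(t, t)
        assert (out["ratio"] == 1.0).all()
        assert (out["flag"] == "unbiased").all()

    def test_no_shared_samples_raises(self):
        a = table({"A": {"s1": 1.0}})
        b = table({"A": {"s2": 1.0}})
        with pytest.raises(ValueError, match="share no samples"):
            primer_bias(a, b)


class TestClassifyStage:
    def test_primary_colonization(self):
        state = MatState(day=5, mat_depth_mm=0.0, visible_fe=False,
                         heterotroph_fraction=0.05)
        assert classify_stage(state) == "I"

    def test_visible_fe_accretion(self):
        state = MatState(day=20, mat_depth_mm=0.7, visible_fe=True,
                         heterotroph_fraction=0.1)
        assert classify_stage(state) == "II"

    def test_heterotroph_colonization(self):
        state = MatState(day=50, mat_depth_mm=3.0, visible_fe=True,
                         heterotroph_fraction=0.3, o2_gradient_present=True)
        assert classify_stage(state) == "III"

    def test_mature_mat(self):
        state = MatState(day=200, mat_depth_mm=15.0, visible_fe=True,
                         heterotroph_fraction=0.6)
        assert classify_stage(state) == "IV"

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            MatState(day=1, mat_depth_mm=-1, visible_fe=False, heterotroph_fraction=0)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        depth_a=st.floats(0, 20, allow_nan=False),
        extra=st.floats(0, 20, allow_nan=False),
        het=st.floats(0, 1, allow_nan=False),
        visible=st.booleans(),
    )
    def test_monotone_in_depth(self, depth_a, extra, het, visible):
        """Deeper mats never classify to an earlier stage."""
        order = {"I": 1, "II": 2, "III": 3, "IV": 4}
        a = MatState(day=30, mat_depth_mm=depth_a, visible_fe=visible,
                     heterotroph_fraction=het)
        b = MatState(day=30, mat_depth_mm=depth_a + extra, visible_fe=visible,
                     heterotroph_fraction=het)
        assert order[classify_stage(b)] >= order[classify_stage(a)]

    def test_thresholds_configurable(self):
        th = StageThresholds(mature_depth_mm=1.0)
        state = MatState(day=20, mat_depth_mm=1.5, visible_fe=True,
                         heterotroph_fraction=0.0)
        assert classify_stage(state, th) == "IV"
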