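import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri

import metaregulon as mr
from metaregulon import synthetic
from metaregulon.interactome import ValidationError


def activity_from(df):
    return mr.ActivityMatrix(
        nes=df,
        n_targets=pd.Series(50, index=df.index),
        source="test",
    )


class TestMutationAssociation:
    def test_top_three_mutated_samples_match_closed_form(self):
        """3 mutated samples holding the 3 largest activities among 200:
        NES = (q_198 + q_199 + q_200) / sqrt(3), directly computable."""
        n = 200
        samples = [f"s{j:03d}" for j in range(n)]
        activity = activity_from(
            pd.DataFrame([np.arange(n, dtype=float)], index=["P1"], columns=samples)
        )
        calls = np.zeros((1, n), dtype=int)
        calls[0, -3:] = 1  # the three largest activity samples
        mutations = mr.MutationMatrix(pd.DataFrame(calls, index=["P1"], columns=samples))
        curve = mr.mutation_association(activity, mutations, min_recurrence_list=[3])
        expected = ndtri(np.array([198, 199, 200]) / (n + 1)).sum() / np.sqrt(3)
        row = curve.per_protein.iloc[0]
        assert row["nes"] == pytest.approx(expected, abs=1e-10)
        assert row["p_two_sided"] < 0.01
        assert curve.fraction_significant == [1.0]

    def test_recurrence_below_threshold_excluded(self, rng):
        samples = [f"s{j}" for j in range(50)]
        activity = activity_from(
            pd.DataFrame(rng.normal(size=(2, 50)), index=["P1", "P2"], columns=samples)
        )
        calls = np.zeros((2, 50), dtype=int)
        calls[0, :2] = 1  # recurrence 2 < threshold 3
        calls[1, :5] = 1
        mutations = mr.MutationMatrix(pd.DataFrame(calls, index=["P1", "P2"], columns=samples))
        curve = mr.mutation_association(activity, mutations, min_recurrence_list=[3, 5])
        assert curve.per_protein["protein"].tolist() == ["P2"]
        assert curve.n_proteins_tested == [1, 1]

    def test_counts_non_increasing_in_threshold(self, rng):
        samples = [f"s{j}" for j in range(100)]
        activity = activity_from(
            pd.DataFrame(rng.normal(size=(20, 100)),
                         index=[f"P{i}" for i in range(20)], columns=samples)
        )
        calls = np.zeros((20, 100), dtype=int)
        for i in range(20):
            calls[i, rng.choice(100, size=3 + i, replace=False)] = 1
        mutations = mr.MutationMatrix(
            pd.DataFrame(calls, index=[f"P{i}" for i in range(20)], columns=samples)
        )
        curve = mr.mutation_association(activity, mutations, min_recurrence_list=[3, 8, 15])
        assert curve.n_proteins_tested == sorted(curve.n_proteins_tested, reverse=True)


class TestOrphanHoldout:
    def test_r_exactly_one_when_held_out_contributes_nothing(
        self, small_signature, small_master
    ):
        ghost = mr.Interactome(
            "ghost",
            {
                "R": mr.Regulon(
                    "R",
                    np.array([f"zz{i}" for i in range(30)], dtype=object),
                    np.ones(30),
                    np.ones(30),
                )
            },
        )
        res = mr.orphan_holdout(
            small_signature, [small_master, ghost], "ghost", method="NESScore"
        )
        assert (res.per_sample_r == 1.0).all()

    def test_half_fidelity_repertoire_keeps_high_correlation(self, small_truth, small_signature):
        ctxs = [
            synthetic.derive_context_interactome(
                small_truth.master, 0.5, seed=80 + i, name=f"ctx{i}", truth=small_truth
            )
            for i in range(4)
        ]
        res = mr.orphan_holdout(small_signature, ctxs, "ctx0", method="NESScore")
        assert res.median_r > 0.6  # generous floor for the small fixture
        assert res.per_sample_r.size == small_signature.data.shape[1]

    def test_disjoint_two_network_repertoire_drops_samples(self, small_signature, small_master):
        # the survivor network covers too few proteins -> all samples dropped
        few = mr.Interactome("few", {r: small_master[r] for r in small_master.regulators[:3]})
        ghost = mr.Interactome(
            "ghost",
            {
                "R": mr.Regulon(
                    "R",
                    np.array([f"zz{i}" for i in range(30)], dtype=object),
                    np.ones(30),
                    np.ones(30),
                )
            },
        )
        with pytest.warns(UserWarning, match="dropped"):
            res = mr.orphan_holdout(small_signature, [few, ghost], "ghost")
        assert res.per_sample_r.empty
        assert len(res.dropped_samples) == small_signature.data.shape[1]


class TestSyntheticBulk:
    def test_mean_of_identical_cells_equals_any_cell(self, rng):
        col = rng.normal(size=30)
        cells = mr.ExpressionMatrix(
            pd.DataFrame(
                np.tile(col[:, None], (1, 100)),
                index=[f"g{i}" for i in range(30)],
                columns=[f"c{j}" for j in range(100)],
            )
        )
        bulk, flagged = mr.synthetic_bulk(cells, ["A"] * 100, n_cells=100, n_replicates=2, seed=1)
        assert not flagged
        np.testing.assert_allclose(bulk.values, np.tile(col[:, None], (1, 2)), atol=1e-12)

    def test_seed_determinism_and_column_layout(self, rng):
        cells = mr.ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(10, 60)),
                         index=[f"g{i}" for i in range(10)],
                         columns=[f"c{j}" for j in range(60)])
        )
        labels = ["A"] * 20 + ["B"] * 20 + ["C"] * 20
        b1, _ = mr.synthetic_bulk(cells, labels, n_cells=10, n_replicates=5, seed=42)
        b2, _ = mr.synthetic_bulk(cells, labels, n_cells=10, n_replicates=5, seed=42)
        pd.testing.assert_frame_equal(b1.data, b2.data, atol=0, rtol=0)
        assert b1.data.shape[1] == 15  # 3 clusters x 5 replicates
        assert "B|rep3" in b1.data.columns

    def test_small_cluster_sampled_with_replacement_and_flagged(self, rng):
        cells = mr.ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(5, 8)),
                         index=[f"g{i}" for i in range(5)],
                         columns=[f"c{j}" for j in range(8)])
        )
        _, flagged = mr.synthetic_bulk(cells, ["A"] * 8, n_cells=20, n_replicates=1, seed=0)
        assert flagged == ["A"]

    def test_unknown_cluster_rejected(self, rng):
        cells = mr.ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(5, 8)),
                         index=[f"g{i}" for i in range(5)],
                         columns=[f"c{j}" for j in range(8)])
        )
        with pytest.raises(ValidationError):
            mr.synthetic_bulk(cells, ["A"] * 8, clusters=["B"], seed=0)


class TestDifferentialTopK:
    def make_profiles(self, rng, shift_features=10, shift=3.0):
        n_feat, n_per_group = 40, 8
        data = rng.normal(size=(n_feat, 2 * n_per_group))
        data[:shift_features, :n_per_group] += shift
        cols = [f"a{i}" for i in range(n_per_group)] + [f"b{i}" for i in range(n_per_group)]
        return (
            pd.DataFrame(data, index=[f"f{i}" for i in range(n_feat)], columns=cols),
            [f"a{i}" for i in range(n_per_group)],
            [f"b{i}" for i in range(n_per_group)],
        )

    def test_planted_shift_recovered_exactly(self, rng):
        profiles, ga, gb = self.make_profiles(rng)
        top = mr.differential_top_k(profiles, ga, gb, k=10)
        assert set(top.index) == {f"f{i}" for i in range(10)}
        assert (top["sign"] == 1).all()

    def test_flipping_groups_flips_signs(self, rng):
        profiles, ga, gb = self.make_profiles(rng)
        ab = mr.differential_top_k(profiles, ga, gb, k=10)
        ba = mr.differential_top_k(profiles, gb, ga, k=10)
        np.testing.assert_allclose(ba["z"].to_numpy(), -ab["z"].to_numpy(), atol=1e-12)

    def test_constant_feature_sorts_last(self, rng):
        profiles, ga, gb = self.make_profiles(rng)
        profiles.loc["f39"] = 5.0  # identical across groups
        top = mr.differential_top_k(profiles, ga, gb, k=39)
        assert "f39" not in top.index

    def test_oversized_k_truncates_with_warning(self, rng):
        profiles, ga, gb = self.make_profiles(rng)
        with pytest.warns(UserWarning, match="truncat"):
            top = mr.differential_top_k(profiles, ga, gb, k=1000)
        assert len(top) == 40


class TestRecapitulation:
    @pytest.fixture()
    def scenario(self, rng):
        """Cells of cluster A vs bulk of cluster B with 8 strongly shifted features."""
        n_feat = 40
        features = [f"f{i}" for i in range(n_feat)]
        shift = np.zeros(n_feat)
        shift[:8] = 4.0
        cells = pd.DataFrame(
            rng.normal(size=(n_feat, 25)) + shift[:, None],
            index=features, columns=[f"cell{j}" for j in range(25)],
        )
        bulk_b = pd.DataFrame(
            rng.normal(scale=0.2, size=(n_feat, 5)),
            index=features, columns=[f"b{j}" for j in range(5)],
        )
        top = pd.DataFrame({"z": 5.0, "sign": 1.0}, index=features[:8])
        return cells, bulk_b, top

    def test_well_separated_features_mostly_recapitulated(self, scenario):
        cells, bulk_b, top = scenario
        curve = mr.recapitulation_curve(cells, bulk_b, top, mode="single")
        assert curve.per_cell_fraction.median() > 0.9

    def test_pair_fraction_bounded_by_single_fraction(self, scenario):
        cells, bulk_b, top = scenario
        single = mr.recapitulation_curve(cells, bulk_b, top, mode="single")
        pair = mr.recapitulation_curve(cells, bulk_b, top, mode="pair")
        assert (pair.per_cell_fraction <= single.per_cell_fraction + 1e-12).all()

    def test_missing_feature_counts_as_not_recapitulated(self, scenario):
        cells, bulk_b, top = scenario
        dropped = cells.drop(index=["f0"])  # feature absent in the cells (dropout)
        full = mr.recapitulation_curve(cells, bulk_b, top, mode="single")
        partial = mr.recapitulation_curve(dropped, bulk_b, top, mode="single")
        assert partial.missing_features == ["f0"]
        assert (partial.per_cell_fraction <= full.per_cell_fraction + 1e-12).all()

    def test_one_minus_ecdf_is_non_increasing(self, scenario):
        cells, bulk_b, top = scenario
        curve = mr.recapitulation_curve(cells, bulk_b, top, mode="single")
        grid = np.linspace(0, 1, 11)
        summary = curve.one_minus_ecdf(grid)
        assert (np.diff(summary) <= 1e-12).all()


class TestVirtualFacs:
    @pytest.fixture()
    def matrix(self, rng):
        # planted X+/Y- population in the first 30 cells
        x = np.concatenate([rng.normal(3, 0.5, 30), rng.normal(-3, 0.5, 30)])
        y = np.concatenate([rng.normal(-3, 0.5, 30), rng.normal(3, 0.5, 30)])
        other = rng.normal(size=(3, 60))
        data = np.vstack([x, y, other])
        return pd.DataFrame(
            data, index=["CDX", "CDY", "m1", "m2", "m3"],
            columns=[f"cell{j}" for j in range(60)],
        )

    def test_planted_cluster_lands_in_its_gate(self, matrix):
        res = mr.virtual_facs(matrix, "CDX", "CDY", thresholds=(0.0, 0.0))
        assert res.gate_counts.loc["x+", "y-"] >= 29
        members = res.gate_members("x+y-")
        assert set(members) <= {f"cell{j}" for j in range(30)}

    def test_swapping_features_transposes_gate_table(self, matrix):
        ab = mr.virtual_facs(matrix, "CDX", "CDY")
        ba = mr.virtual_facs(matrix, "CDY", "CDX")
        assert ab.gate_counts.loc["x+", "y-"] == ba.gate_counts.loc["x-", "y+"]
        assert ab.gate_counts.loc["x+", "y+"] == ba.gate_counts.loc["x+", "y+"]

    def test_all_zero_markers_collapse_into_double_negative_gate(self, matrix):
        zeroed = matrix.copy()
        zeroed.loc[["CDX", "CDY"]] = 0.0
        res = mr.virtual_facs(zeroed, "CDX", "CDY", thresholds=(0.0, 0.0))
        assert res.gate_counts.loc["x-", "y-"] == zeroed.shape[1]

    def test_missing_feature_error_lists_available(self, matrix):
        with pytest.raises(ValidationError, match="CDX"):
            mr.virtual_facs(matrix, "NOPE", "CDY")
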