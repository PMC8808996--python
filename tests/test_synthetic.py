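import numpy as np
import pytest

from degas.synthetic import (
    GROUPS,
    PROPORTIONS,
    SimDesign,
    add_subtype_bias,
    build_patients,
    expected_association,
    four_type_labels,
    generate_dataset,
    largest_remainder,
    simulate_cells,
    split_cells,
)


class TestLargestRemainder:
    def test_sim1_disease_patient_counts(self):
        counts = largest_remainder(PROPORTIONS["sim1"]["disease"], 400)
        np.testing.assert_array_equal(counts, [200, 66, 67, 67, 0])

    def test_sim3_disease_patient_counts(self):
        counts = largest_remainder(PROPORTIONS["sim3"]["disease"], 400)
        assert counts.sum() == 400
        assert counts[3] == 120 and counts[4] == 80  # 30% / 20% of 400

    def test_normal_patients_equal_quarters(self):
        for scen in PROPORTIONS:
            counts = largest_remainder(PROPORTIONS[scen]["normal"], 400)
            np.testing.assert_array_equal(counts, [100, 100, 100, 100, 0])

    @pytest.mark.parametrize("total", [7, 400, 401])
    def test_always_sums_to_total(self, total):
        counts = largest_remainder([0.21, 0.33, 0.46], total)
        assert counts.sum() == total


class TestSimulateCells:
    def test_group_sizes_exact(self, small_design, small_data):
        X, y = simulate_cells(small_design)
        assert X.n_samples == 5 * small_design.cells_per_group
        names = y.labels()
        for g in GROUPS:
            assert (names == g).sum() == small_design.cells_per_group

    def test_counts_are_nonnegative_integers(self, small_data):
        v = small_data.cells.values
        assert v.min() >= 0
        np.testing.assert_array_equal(v, np.round(v))

    def test_no_de_means_no_group_separation(self):
        design = SimDesign(n_genes=100, cells_per_group=40, holdout_for_patients=100,
                           n_patients=10, cells_per_patient=20, de_strength=0.0,
                           de_scale=0.0, subtype_de_strength=0.0,
                           subtype_de_scale=0.0, seed=4)
        X, y = simulate_cells(design)
        # group centroids of log counts should be statistically identical
        logs = np.log2(X.values + 1)
        names = y.labels()
        cents = np.array([logs[names == g].mean(axis=0) for g in GROUPS])
        spread = cents.std(axis=0).mean()
        within = logs.std(axis=0).mean() / np.sqrt(design.cells_per_group)
        assert spread < 3 * within

    def test_four_type_labels_collapse(self, small_data):
        y4 = small_data.cell_types
        names5 = small_data.cell_groups.labels()
        names4 = y4.labels()
        assert set(names4[(names5 == "type4N") | (names5 == "type4D")]) == {"type4"}
        assert y4.onehot.shape[1] == 4

    def test_deterministic_under_seed(self, small_design):
        a, _ = simulate_cells(small_design)
        b, _ = simulate_cells(small_design)
        np.testing.assert_array_equal(a.values, b.values)


class TestSplitCells:
    def test_split_sizes_and_stratification(self, small_design):
        X, y = simulate_cells(small_design)
        (pool, pool_y), (rest, rest_y) = split_cells(X, y, 160, seed=0)
        assert pool.n_samples == 160 and rest.n_samples == X.n_samples - 160
        for g in GROUPS:
            assert (pool_y.labels() == g).sum() == 32
            assert (rest_y.labels() == g).sum() > 0

    def test_disjoint_and_exhaustive(self, small_design):
        X, y = simulate_cells(small_design)
        (pool, _), (rest, _) = split_cells(X, y, 160, seed=0)
        ids = set(pool.sample_ids) | set(rest.sample_ids)
        assert ids == set(X.sample_ids)
        assert not set(pool.sample_ids) & set(rest.sample_ids)

    def test_same_seed_same_split(self, small_design):
        X, y = simulate_cells(small_design)
        (a, _), _ = split_cells(X, y, 160, seed=9)
        (b, _), _ = split_cells(X, y, 160, seed=9)
        assert a.sample_ids == b.sample_ids

    def test_oversized_holdout_rejected(self, small_design):
        X, y = simulate_cells(small_design)
        with pytest.raises(ValueError, match="group"):
            split_cells(X, y, X.n_samples - 2, seed=0)


class TestBuildPatients:
    def test_patient_counts_conserve_pool_counts(self, small_data, small_design):
        X_pat, _, indices = build_patients(small_data.pool, small_data.pool_groups,
                                           small_design, return_indices=True)
        for i in (0, small_design.n_patients - 1):
            expected = small_data.pool.values[indices[i]].sum(axis=0)
            np.testing.assert_array_equal(X_pat.values[i], expected)

    def test_half_disease_half_normal(self, small_data, small_design):
        names = small_data.patient_labels.labels()
        assert (names == "disease").sum() == small_design.n_patients // 2

    def test_composition_follows_proportions(self, small_data, small_design):
        _, y, indices = build_patients(small_data.pool, small_data.pool_groups,
                                       small_design, return_indices=True)
        pool_names = small_data.pool_groups.labels()
        # first patient is disease; sim1 disease = 50% type 1
        comp = pool_names[indices[0]]
        frac = (comp == "type1").mean()
        assert frac == pytest.approx(0.5, abs=1e-9)
        assert (comp == "type4D").sum() == 0

    def test_missing_group_rejected(self, small_data, small_design):
        keep = small_data.pool_groups.labels() != "type4D"
        pool = small_data.pool.subset_samples(np.flatnonzero(keep))
        pool_y = small_data.pool_groups.subset(np.flatnonzero(keep))
        design = SimDesign(**{**vars(small_design), "scenario": "sim2"})
        with pytest.raises(ValueError, match="type4D"):
            build_patients(pool, pool_y, design)


class TestSubtypeBias:
    def test_zero_multiplier_is_identity(self, small_data):
        out = add_subtype_bias(small_data.patients, small_data.pool,
                               small_data.pool_groups, "type2", 50, multiplier=0.0)
        np.testing.assert_array_equal(out.values, small_data.patients.values)

    def test_bias_is_rank_one(self, small_data):
        out = add_subtype_bias(small_data.patients, small_data.pool,
                               small_data.pool_groups, "type2", 50, multiplier=10.0)
        delta = out.values - small_data.patients.values
        assert np.linalg.matrix_rank(delta) == 1
        np.testing.assert_array_equal(delta[0], delta[-1])

    def test_unknown_subtype_rejected(self, small_data):
        with pytest.raises(ValueError, match="nope"):
            add_subtype_bias(small_data.patients, small_data.pool,
                             small_data.pool_groups, "nope")


class TestExpectedAssociation:
    @pytest.mark.parametrize("scenario,positives", [
        ("sim1", {"type1"}),
        ("sim2", {"type4D"}),
        ("sim3", {"type4N", "type4D"}),
    ])
    def test_designed_groups_marked(self, scenario, positives):
        names = np.array(GROUPS, dtype=object)
        exp = expected_association(scenario, names)
        assert {g for g, e in zip(GROUPS, exp) if e == 1.0} == positives
        assert set(exp) <= {0.0, 1.0}


def test_full_pipeline_deterministic(small_design):
    a = generate_dataset(small_design)
    b = generate_dataset(small_design)
    np.testing.assert_array_equal(a.patients.values, b.patients.values)
    np.testing.assert_array_equal(a.expected, b.expected)
    assert a.cells.sample_ids == b.cells.sample_ids
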