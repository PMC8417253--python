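import itertools

import numpy as np
import pandas as pd
import pytest

import radstab as rs

from .oracles import similarity_bruteforce


def _make_table(values, flavor="a", n_timepoints=1, feature_names=None):
    """values: (n_patients, n_timepoints, n_features) array."""
    values = np.asarray(values, dtype=np.float64)
    n_p, n_t, n_f = values.shape
    names = feature_names or [f"f{j}" for j in range(n_f)]
    index = pd.MultiIndex.from_tuples(
        [(f"P{i:02d}", t) for i in range(n_p) for t in range(n_t)],
        names=["patient_id", "timepoint"])
    cols = [str(rs.FeatureId(flavor, "SIM", n)) for n in names]
    df = pd.DataFrame(values.reshape(n_p * n_t, n_f), index=index, columns=cols)
    return rs.FeatureTable(df)


def _assignment(labels):
    return rs.ClusterAssignment(groups={f"P{i:02d}": l for i, l in enumerate(labels)})


# ---------------------------------------------------------------------------
# similarity statistic


def test_similarity_identity_and_label_swap():
    ref = _assignment("AABB")
    assert rs.clustering_similarity(ref, ref) == 100.0
    swapped = _assignment("BBAA")
    assert rs.clustering_similarity(ref, swapped) == 100.0


def test_similarity_one_patient_moved_out_of_36():
    ref = _assignment("A" * 18 + "B" * 18)
    alt = _assignment("A" * 17 + "B" * 19)
    assert rs.clustering_similarity(ref, alt) == pytest.approx(3500.0 / 36.0)


def test_similarity_handles_single_group_partition():
    ref = _assignment("AAAA")
    alt = _assignment("AABB")
    assert rs.clustering_similarity(ref, alt) == 50.0


def test_similarity_mismatched_patient_sets_rejected():
    with pytest.raises(ValueError, match="different patient sets"):
        rs.clustering_similarity(_assignment("AA"), _assignment("AAB"))


def test_similarity_exhaustive_bruteforce_10_patients():
    """All 2^10 partitions against a fixed reference match the printed
    equation evaluated term by term, stay in [0, 100], and are symmetric."""
    ref_labels = "AABABBABBA"
    ref = _assignment(ref_labels)
    for bits in itertools.product("AB", repeat=10):
        alt = _assignment("".join(bits))
        sim = rs.clustering_similarity(ref, alt)
        expected = similarity_bruteforce(ref.groups, alt.groups)
        assert sim == pytest.approx(expected)
        assert 0.0 <= sim <= 100.0
        assert sim == pytest.approx(rs.clustering_similarity(alt, ref))
        identical_up_to_swap = all(b == r for b, r in zip(bits, ref_labels)) or \
            all(b != r for b, r in zip(bits, ref_labels))
        assert (sim == 100.0) == identical_up_to_swap


# ---------------------------------------------------------------------------
# signature assembly


def test_signature_dimensions_stacked():
    rng = np.random.default_rng(0)
    table = _make_table(rng.normal(size=(36, 8, 15)))
    features = [str(c) for c in table.data.columns]
    sig = rs.assemble_signature(table, table.patients, features, mode="stacked")
    assert sig.values.shape == (36, 120)


def test_signature_columns_standardized():
    rng = np.random.default_rng(1)
    table = _make_table(rng.normal(size=(12, 3, 4)) * 100 + 1000)
    sig = rs.assemble_signature(table, table.patients,
                                [str(c) for c in table.data.columns])
    assert np.abs(sig.values.mean(axis=0)).max() < 1e-9
    assert np.abs(sig.values.std(axis=0, ddof=0) - 1).max() < 1e-9


def test_delta_mode_zero_when_timepoints_identical():
    rng = np.random.default_rng(2)
    base = rng.normal(size=(6, 1, 3))
    values = np.repeat(base, 3, axis=1)  # all timepoints equal TP0
    table = _make_table(values)
    sig = rs.assemble_signature(table, table.patients,
                                [str(c) for c in table.data.columns], mode="delta")
    assert np.allclose(sig.values, 0.0)
    assert sig.values.shape == (6, 3 * 2)  # deltas for TP1, TP2 only


def test_non_finite_features_dropped_with_reason():
    rng = np.random.default_rng(3)
    values = rng.normal(size=(5, 2, 3))
    values[2, 1, 1] = np.inf
    table = _make_table(values)
    features = [str(c) for c in table.data.columns]
    sig = rs.assemble_signature(table, table.patients, features)
    assert sig.dropped_features == [features[1]]
    assert sig.values.shape == (5, 2 * 2)


def test_incomplete_patient_excluded_with_warning():
    rng = np.random.default_rng(4)
    table = _make_table(rng.normal(size=(5, 3, 2)))
    df = table.data.drop(index=[("P01", 2)])
    table = rs.FeatureTable(df)
    with pytest.warns(UserWarning, match="P01"):
        sig = rs.assemble_signature(table, table.patients,
                                    [str(c) for c in df.columns])
    assert "P01" not in sig.patients
    assert sig.values.shape == (4, 6)


def test_zero_surviving_features_is_error():
    values = np.full((4, 2, 1), np.inf)
    table = _make_table(values)
    with pytest.raises(ValueError, match="zero features"):
        rs.assemble_signature(table, table.patients,
                              [str(c) for c in table.data.columns])


# ---------------------------------------------------------------------------
# Ward clustering


def _well_separated_signature(rng, n_a=18, n_b=18, n_cols=10, gap=10.0):
    X = np.vstack([rng.normal(0.0, 1.0, size=(n_a, n_cols)),
                   rng.normal(gap, 1.0, size=(n_b, n_cols))])
    patients = [f"P{i:02d}" for i in range(n_a + n_b)]
    return rs.SignatureMatrix(values=X, patients=patients,
                              columns=[(f"f{j}", 0) for j in range(n_cols)],
                              mode="stacked")


def test_ward_recovers_planted_partition():
    rng = np.random.default_rng(6)
    sig = _well_separated_signature(rng)
    asg = rs.ward_two_groups(sig)
    first_half = {p for p in sig.patients[:18]}
    assert asg.members(asg.groups["P00"]) == first_half


def test_ward_partition_invariant_to_row_order():
    rng = np.random.default_rng(7)
    sig = _well_separated_signature(rng, n_a=8, n_b=8, n_cols=6)
    asg = rs.ward_two_groups(sig)
    perm = rng.permutation(len(sig.patients))
    sig_p = rs.SignatureMatrix(values=sig.values[perm],
                               patients=[sig.patients[i] for i in perm],
                               columns=sig.columns, mode="stacked")
    asg_p = rs.ward_two_groups(sig_p)
    assert rs.clustering_similarity(asg, asg_p) == 100.0


def test_ward_identical_rows_single_group():
    sig = rs.SignatureMatrix(values=np.zeros((5, 3)),
                             patients=[f"P{i:02d}" for i in range(5)],
                             columns=[(f"f{j}", 0) for j in range(3)],
                             mode="stacked")
    asg = rs.ward_two_groups(sig)
    assert set(asg.groups.values()) == {"A"}


# ---------------------------------------------------------------------------
# threshold sweep


def _records_for(table_a, table_b):
    pairs = [rs.SharedFeaturePair(feature_a=a, feature_b=b, klass="SIM",
                                  match_basis="identical-name")
             for a, b in zip(table_a.data.columns, table_b.data.columns)]
    return rs.fit_feature_correlations(table_a, table_b, pairs)


def test_sweep_identical_tables_always_100():
    rng = np.random.default_rng(8)
    values = rng.normal(size=(10, 3, 5))
    values[:5] += 8.0  # two clear groups
    ta = _make_table(values, flavor="a")
    tb = _make_table(values, flavor="b")
    records = _records_for(ta, tb)
    grid = np.arange(0.0, 1.0, 0.1)
    sweep = rs.threshold_sweep(ta, tb, records, ta.patients, grid=grid)
    for res in sweep.results:
        if res.n_features > 0:
            assert res.similarity_percent == 100.0


def test_sweep_default_grid_has_1000_thresholds():
    grid = rs.default_threshold_grid()
    assert grid.size == 1000
    assert grid[0] == 0.0 and grid[-1] == 0.999


def test_sweep_n_features_monotone_and_undefined_sentinel():
    rng = np.random.default_rng(9)
    spec = rs.PairedSimSpec(n_observations=40,
                            target_r=(0.99, 0.9, 0.5, 0.2, 0.0))
    # give the rows a (patient, timepoint) structure usable for clustering
    ta, tb = rs.generate_paired_features(spec, seed=3)
    n = len(ta.data)
    idx = pd.MultiIndex.from_tuples(
        [(f"P{i % 10:02d}", i // 10) for i in range(n)],
        names=["patient_id", "timepoint"])
    ta = rs.FeatureTable(ta.data.set_index(idx))
    tb = rs.FeatureTable(tb.data.set_index(idx))
    records = _records_for(ta, tb)
    grid = np.append(np.arange(0.0, 1.0, 0.01), 0.9999)
    sweep = rs.threshold_sweep(ta, tb, records, ta.patients, grid=grid)
    counts = [r.n_features for r in sweep.results]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    tail = [r for r in sweep.results if r.n_features == 0]
    assert tail and all(np.isnan(r.similarity_percent) for r in tail)


def test_sweep_empty_grid_rejected():
    rng = np.random.default_rng(10)
    values = rng.normal(size=(6, 2, 2))
    ta = _make_table(values, flavor="a")
    tb = _make_table(values, flavor="b")
    with pytest.raises(ValueError, match="empty threshold grid"):
        rs.threshold_sweep(ta, tb, _records_for(ta, tb), ta.patients,
                           grid=np.array([]))
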