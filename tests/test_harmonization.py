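import numpy as np
import pandas as pd
import pytest

import radstab as rs


def _table(flavor, name, values, klass="IHIST"):
    index = pd.MultiIndex.from_tuples([(f"P{i}", 0) for i in range(len(values))],
                                      names=["patient_id", "timepoint"])
    col = str(rs.FeatureId(flavor, klass, name))
    return rs.FeatureTable(pd.DataFrame({col: values}, index=index))


def _pair(name_a="x", name_b="x", klass="IHIST"):
    return rs.SharedFeaturePair(
        feature_a=str(rs.FeatureId("a", klass, name_a)),
        feature_b=str(rs.FeatureId("b", klass, name_b)),
        klass=klass, match_basis="identical-name")


def test_shipped_registry_compositions(flavors):
    """Shared-pair totals and class breakdown match the published counts."""
    reg_ibex = rs.build_registry(flavors["reference"], flavors["ibex-emulation"])
    reg_mazda = rs.build_registry(flavors["reference"], flavors["mazda-emulation"])
    assert len(reg_ibex) == 83
    assert len(reg_mazda) == 49

    def by_class(reg):
        out = {}
        for p in reg:
            key = (p.klass, p.distance)
            out[key] = out.get(key, 0) + 1
        return out

    comp = by_class(reg_ibex)
    assert comp[("IHIST", None)] == 7
    assert comp[("SHAPE", None)] == 6
    assert comp[("GLRLM", None)] == 11
    assert comp[("NGTDM", None)] == 5
    assert all(comp[("GLCM", d)] == 18 for d in (1, 4, 7))

    comp = by_class(reg_mazda)
    assert comp[("IHIST", None)] == 6
    assert comp[("SHAPE", None)] == 6
    assert comp[("GLRLM", None)] == 7
    assert ("NGTDM", None) not in comp
    assert all(comp[("GLCM", d)] == 10 for d in (1, 4, 7))


def test_registry_includes_curated_dissimilar_pairs(flavors):
    reg = rs.build_registry(flavors["reference"], flavors["ibex-emulation"])
    curated = {(rs.FeatureId.parse(p.feature_a).name,
                rs.FeatureId.parse(p.feature_b).name)
               for p in reg if p.match_basis == "dissimilar-name-curated"}
    assert ("SurfaceArea", "Perimeter") in curated
    assert ("Flatness", "Roundness") in curated
    assert ("JointEnergy", "AngularSecondMoment") in curated
    assert ("ClusterTendency", "JointEnergy") in curated
    assert ("RunPercentage", "Fraction") in curated


def test_self_registry_is_identity(flavors):
    for flavor in flavors.values():
        reg = rs.build_registry(flavor, flavor)
        assert len(reg) == flavor.n_features
        assert all(p.match_basis == "identical-name" for p in reg)
        assert all(p.feature_a == p.feature_b for p in reg)


def test_alias_referencing_unknown_features_rejected(flavors):
    bogus = (("GLCM", "NoSuchFeature", "AlsoMissing"),)
    with pytest.raises(ValueError, match="unknown features"):
        rs.build_registry(flavors["reference"], flavors["ibex-emulation"],
                          aliases=bogus)


def test_exact_affine_fit():
    a = np.arange(10, dtype=float)
    records = rs.fit_feature_correlations(
        _table("a", "x", a), _table("b", "x", 2 * a + 3), [_pair()])
    rec = records[0]
    assert rec.r == pytest.approx(1.0, abs=1e-12)
    assert rec.slope == pytest.approx(2.0)
    assert rec.intercept == pytest.approx(3.0)


def test_anticorrelation():
    a = np.arange(8, dtype=float)
    rec = rs.fit_feature_correlations(
        _table("a", "x", a), _table("b", "x", -a), [_pair()])[0]
    assert rec.r == pytest.approx(-1.0, abs=1e-12)


def test_pairwise_invalid_exclusion_bookkeeping():
    a = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
    b = np.array([2.0, 4.0, 6.0, np.inf, 10.0, 12.0])
    rec = rs.fit_feature_correlations(
        _table("a", "x", a), _table("b", "x", b), [_pair()])[0]
    assert rec.n_used == 4 and rec.n_excluded == 2
    assert rec.n_used + rec.n_excluded == 6
    assert rec.r == pytest.approx(1.0, abs=1e-12)


def test_constant_column_flagged_undefined():
    a = np.full(10, 5.0)
    rec = rs.fit_feature_correlations(
        _table("a", "x", a), _table("b", "x", np.arange(10.0)), [_pair()])[0]
    assert not rec.defined
    assert np.isnan(rec.slope)


def test_too_few_usable_rows_flagged_undefined():
    a = np.array([1.0, 2.0, np.nan, np.nan])
    b = np.array([1.0, 2.0, 3.0, 4.0])
    rec = rs.fit_feature_correlations(
        _table("a", "x", a), _table("b", "x", b), [_pair()])[0]
    assert not rec.defined and rec.n_used == 2


def test_symmetry_of_r():
    rng = np.random.default_rng(0)
    x = rng.normal(size=50)
    y = 0.5 * x + rng.normal(size=50)
    r_ab = rs.fit_feature_correlations(
        _table("a", "x", x), _table("b", "x", y), [_pair()])[0].r
    r_ba = rs.fit_feature_correlations(
        _table("a", "x", y), _table("b", "x", x), [_pair()])[0].r
    assert r_ab == pytest.approx(r_ba, abs=1e-12)


def test_selection_strict_inequality_and_monotonicity():
    pairs = [_pair(f"f{i}", f"f{i}") for i in range(4)]
    rs_list = [0.95, 0.902, 0.900, np.nan]
    records = [rs.CorrelationRecord(p, r, 1.0, 0.0, 10, 0)
               for p, r in zip(pairs, rs_list)]
    # ties at the threshold and undefined records are excluded
    kept = rs.select_reproducible(records, 0.901)
    assert len(kept) == 2
    kept_900 = rs.select_reproducible(records, 0.900)
    assert len(kept_900) == 2  # 0.900 is NOT > 0.900
    assert len(rs.select_reproducible(records, -1.0)) == 3

    previous = None
    for thr in np.arange(0.0, 1.0, 0.05):
        current = {p.feature_a for p in rs.select_reproducible(records, thr)}
        if previous is not None:
            assert current <= previous
        previous = current


def test_correlation_recovery_accuracy():
    """Fitted r recovers the simulated correlation at n=334.

    The sampling error of a Pearson estimate scales as (1 - r^2)/sqrt(n),
    so the mean absolute error is checked against 1.5x that scale (with a
    small floor); for strong correlations (r >= 0.9) this is below 0.02.
    """
    n = 334
    targets = [0.0, 0.3, 0.6, 0.9, 0.99]
    spec = rs.PairedSimSpec(n_observations=n, target_r=tuple(targets))
    errors = {t: [] for t in targets}
    for seed in range(100):
        ta, tb = rs.generate_paired_features(spec, seed=seed)
        recs = rs.fit_feature_correlations(ta, tb, rs.paired_registry(spec))
        for t, rec in zip(targets, recs):
            errors[t].append(abs(rec.r - t))
    for t in targets:
        bound = max(0.004, 1.5 * (1 - t * t) / np.sqrt(n - 1))
        assert np.mean(errors[t]) < bound, t
        if t >= 0.9:
            assert np.mean(errors[t]) < 0.02, t


def test_mismatched_row_keys_rejected():
    a = _table("a", "x", np.arange(4.0))
    b_df = _table("b", "x", np.arange(4.0)).data
    b_df.index = pd.MultiIndex.from_tuples(
        [("Q0", 0), ("Q1", 0), ("Q2", 0), ("Q3", 0)],
        names=["patient_id", "timepoint"])
    with pytest.raises(ValueError, match="row keys"):
        rs.fit_feature_correlations(a, rs.FeatureTable(b_df), [_pair()])
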