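import numpy as np
import pytest

import radstab as rs
from radstab.features.glcm import (glcm_features, glcm_features_from_matrix,
                                   glcm_matrices)

from .oracles import glcm_features_bruteforce, glcm_matrix_bruteforce
from .conftest import random_discrete_roi

TWO_BY_TWO = np.array([[[1, 1], [1, 2]]])  # one axial slice


def test_hand_enumerated_pairs_asymmetric():
    mats = glcm_matrices(TWO_BY_TWO, n_levels=2, distance=1, symmetric=False,
                         directions=(0,))
    P = mats[0]
    # rightward pairs: (1,1) in the top row, (1,2) in the bottom row
    assert P[0, 0] == pytest.approx(0.5)
    assert P[0, 1] == pytest.approx(0.5)
    assert P[1, 0] == P[1, 1] == 0.0


def test_hand_enumerated_pairs_symmetric():
    mats = glcm_matrices(TWO_BY_TWO, n_levels=2, distance=1, symmetric=True,
                         directions=(0,))
    P = mats[0]
    assert P[0, 0] == pytest.approx(0.5)
    assert P[0, 1] == pytest.approx(0.25)
    assert P[1, 0] == pytest.approx(0.25)


def test_angular_second_moment_of_two_cell_matrix():
    P = np.array([[0.5, 0.5], [0.0, 0.0]])
    feats = glcm_features_from_matrix(P)
    assert feats["JointEnergy"] == pytest.approx(0.5)  # 0.5^2 + 0.5^2


def test_uniform_roi_has_zero_contrast():
    image, mask = rs.make_phantom_roi("uniform", shape=(2, 6, 6), value=300.0)
    levels = rs.features.discretize(image, mask, rs.DiscretizationSpec(100, 21.0))
    feats = glcm_features(glcm_matrices(levels, 100, 1, symmetric=False))
    assert feats["Contrast"] == 0.0
    assert np.isnan(feats["Correlation"])  # zero marginal variance


def test_matrices_normalized_per_direction():
    rng = np.random.default_rng(0)
    levels = random_discrete_roi(rng)
    for d in (1, 4, 7):
        for P in glcm_matrices(levels, 8, d, symmetric=False).values():
            if P is not None:
                assert P.sum() == pytest.approx(1.0, abs=1e-12)


def test_empty_direction_flagged():
    line = np.array([[[1, 2, 3]]])  # single row: no vertical pairs
    mats = glcm_matrices(line, 3, 1, symmetric=False)
    assert mats[90] is None and mats[0] is not None


def test_direction_average_invariant_to_inplane_rotation():
    """A 90-degree rotation permutes the direction set (up to pair order),
    so symmetric direction-averaged features are exactly invariant and
    asymmetric ones are invariant for transpose-symmetric definitions."""
    rng = np.random.default_rng(5)
    levels = np.where(rng.random((2, 9, 9)) < 0.8,
                      rng.integers(1, 7, (2, 9, 9)), 0)
    rotated = np.rot90(levels, k=1, axes=(1, 2)).copy()
    for d in (1, 2):
        f1 = glcm_features(glcm_matrices(levels, 6, d, symmetric=True))
        f2 = glcm_features(glcm_matrices(rotated, 6, d, symmetric=True))
        for name in ("Contrast", "JointEnergy", "JointEntropy", "Correlation",
                     "SumSquares", "InverseDifferenceMoment", "ClusterTendency"):
            assert f1[name] == pytest.approx(f2[name], rel=1e-10), name
        a1 = glcm_features(glcm_matrices(levels, 6, d, symmetric=False))
        a2 = glcm_features(glcm_matrices(rotated, 6, d, symmetric=False))
        for name in ("Contrast", "JointEnergy", "JointEntropy",
                     "InverseDifferenceMoment", "Correlation"):
            assert a1[name] == pytest.approx(a2[name], rel=1e-10), name


@pytest.mark.parametrize("symmetric", [False, True])
def test_matrix_and_features_match_bruteforce(symmetric):
    rng = np.random.default_rng(42)
    for _ in range(5):
        levels = random_discrete_roi(rng)
        for d in (1, 4):
            for angle in (0, 45, 90, 135):
                P_fast = glcm_matrices(levels, 8, d, symmetric,
                                       directions=(angle,))[angle]
                P_slow = glcm_matrix_bruteforce(levels, 8, d, angle, symmetric)
                if P_fast is None:
                    assert P_slow is None
                    continue
                np.testing.assert_allclose(P_fast, P_slow, atol=1e-12)
                fast = glcm_features_from_matrix(P_fast)
                slow = glcm_features_bruteforce(P_slow)
                for name, value in slow.items():
                    np.testing.assert_allclose(
                        fast[name], value, rtol=1e-10, atol=1e-12,
                        err_msg=f"{name} d={d} angle={angle}")
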