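"""Latent-factor pipeline tests: probit, feature matrix, PCA/ICA, clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cogbattery import cohort, latent, scoring
from cogbattery.errors import EstimationError


def _matrix_from_array(X: np.ndarray, names=None) -> latent.FeatureMatrix:
    """Wrap a raw array as a standardized FeatureMatrix for decomposition tests."""
    names = names or [f"v{i}" for i in range(X.shape[1])]
    raw = pd.DataFrame(X, columns=names)
    means, sds = raw.mean(), raw.std(ddof=1)
    data = (raw - means) / sds.replace(0.0, 1.0)
    return latent.FeatureMatrix(
        data=data, raw=raw, column_info={n: ("", "", "") for n in names},
        means=means, sds=sds,
    )


# ---------------------------------------------------------------------------
# Probit transform
# ---------------------------------------------------------------------------


def test_probit_midpoint_is_zero():
    assert latent.probit(0.5, 20) == pytest.approx(0.0)


def test_probit_boundary_correction_at_zero():
    # p = 0 with N = 20 clips to 0.025, whose normal quantile is -1.96
    assert latent.probit(0.0, 20) == pytest.approx(stats.norm.ppf(0.025))
    assert latent.probit(0.0, 20) == pytest.approx(-1.96, abs=0.005)
    assert latent.probit(1.0, 20) == pytest.approx(1.96, abs=0.005)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(p=st.floats(0.0, 1.0), n=st.integers(1, 500))
def test_probit_antisymmetric(p, n):
    assert latent.probit(p, n) == pytest.approx(-latent.probit(1.0 - p, n), abs=1e-9)


def test_probit_rejects_zero_trials():
    with pytest.raises(ValueError):
        latent.probit(0.5, 0)


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------


def test_feature_matrix_dimensions_and_standardization(small_scores):
    X = latent.build_feature_matrix(small_scores)
    assert X.data.shape == (16, 23)  # 8 participants x 2 days
    assert np.abs(X.data.mean(axis=0)).max() < 1e-10
    assert np.abs(X.data.std(ddof=1) - 1.0).max() < 1e-10
    assert len(set(X.feature_names)) == 23


def test_feature_matrix_far_column_of_perfect_cohort_hits_boundary():
    """A cohort that never false-alarms maps the go/no-go FAR column to the
    boundary-corrected probit(1/2N) uniformly."""
    profiles = cohort.sample_cohort(3, seed=0)
    for p in profiles:
        p.ability = {f: math.inf for f in cohort.FAMILIES}
        p.ability["speed"] = 0.0
    sessions = cohort.simulate_study(profiles, seed=1)
    X = latent.build_feature_matrix(scoring.score_table(sessions))
    expected = stats.norm.ppf(1.0 / 36.0)  # N = 18 no-go trials
    assert np.allclose(X.raw["gng_far"], expected)


def test_feature_matrix_drops_incomplete_observations(small_scores):
    broken = small_scores[
        ~(
            (small_scores.participant_id == "p000")
            & (small_scores.day == 1)
            & (small_scores.task == "mot")
        )
    ]
    X = latent.build_feature_matrix(broken)
    assert X.data.shape == (15, 23)
    assert "p000_d1" not in X.data.index


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def test_pca_planted_single_factor_dominates():
    rng = np.random.default_rng(0)
    factor = rng.normal(size=(300, 1))
    loadings = rng.choice([-1.0, 1.0], size=(1, 10))  # unit magnitude: noise
    # stays tiny relative to every column after standardization
    X = _matrix_from_array(factor @ loadings + 0.05 * rng.normal(size=(300, 10)))
    model = latent.fit_pca(X, k=2)
    assert model.explained_variance[0] > 95.0


def test_pca_scree_sums_to_all_variance(small_scores):
    X = latent.build_feature_matrix(small_scores)
    model = latent.fit_pca(X, k=6)
    assert model.scree.sum() == pytest.approx(100.0, abs=1e-6)
    assert np.all(np.diff(model.scree) <= 1e-9)  # non-increasing


def test_pca_equals_correlation_eigendecomposition():
    """Full-k loadings and variances reproduce the sample correlation matrix."""
    rng = np.random.default_rng(1)
    X = _matrix_from_array(rng.normal(size=(50, 8)))
    model = latent.fit_pca(X, k=8)
    L = model.loadings.to_numpy()
    assert np.allclose(L.T @ L, np.eye(8), atol=1e-8)  # orthonormal loadings
    corr = np.corrcoef(X.values, rowvar=False)
    eigvals = np.sort(np.linalg.eigvalsh(corr))[::-1]
    lam = model.explained_variance / 100.0 * eigvals.sum()
    assert np.allclose(L @ np.diag(lam) @ L.T, corr, atol=1e-6)


def test_pca_loadings_invariant_to_row_duplication(small_scores):
    X = latent.build_feature_matrix(small_scores)
    doubled = _matrix_from_array(
        np.vstack([X.values, X.values]), names=X.feature_names
    )
    a = latent.fit_pca(X, k=3).loadings.to_numpy()
    b = latent.fit_pca(doubled, k=3).loadings.to_numpy()
    for j in range(3):
        assert min(
            np.abs(a[:, j] - b[:, j]).max(), np.abs(a[:, j] + b[:, j]).max()
        ) < 1e-8


def test_pca_rejects_k_beyond_rank():
    rng = np.random.default_rng(2)
    X = _matrix_from_array(rng.normal(size=(5, 10)))  # rank 4 after centering
    with pytest.raises(ValueError, match="rank"):
        latent.fit_pca(X, k=9)


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------


def test_ica_recovers_independent_heavy_tailed_sources():
    rng = np.random.default_rng(3)
    S = np.column_stack([rng.laplace(size=5000), rng.uniform(-1, 1, size=5000)])
    A = np.array([[1.0, 0.6, -0.4, 0.2], [0.3, -1.0, 0.8, 0.7]])
    X = _matrix_from_array(S @ A + 0.01 * rng.normal(size=(5000, 4)))
    model = latent.fit_ica(X, k=2, seed=0)
    C = np.abs(np.corrcoef(model.scores.T, S.T)[:2, 2:])
    # each source matched by some component up to sign/order
    assert max(min(C[0, 0], C[1, 1]), min(C[0, 1], C[1, 0])) > 0.95


def test_ica_flags_gaussian_components_as_unidentifiable():
    rng = np.random.default_rng(4)
    X = _matrix_from_array(rng.normal(size=(5000, 5)))
    model = latent.fit_ica(X, k=3, seed=1)
    assert np.all(model.non_gaussianity < 0.2)


def test_ica_deterministic_and_sign_normalized(small_scores):
    X = latent.build_feature_matrix(small_scores)
    a = latent.fit_ica(X, k=4, seed=9)
    b = latent.fit_ica(X, k=4, seed=9)
    assert np.allclose(a.loadings, b.loadings)
    L = a.loadings.to_numpy()
    for j in range(4):
        assert L[np.argmax(np.abs(L[:, j])), j] > 0


def test_ica_nonconvergence_names_budget():
    rng = np.random.default_rng(5)
    X = _matrix_from_array(rng.normal(size=(40, 10)))
    with pytest.raises(EstimationError, match="budget of 1"):
        latent.fit_ica(X, k=8, seed=0, max_iter=1)


# ---------------------------------------------------------------------------
# Loading clusters
# ---------------------------------------------------------------------------


def test_identical_loading_vectors_merge_at_height_zero():
    rng = np.random.default_rng(6)
    L = rng.normal(size=(6, 3))
    L[1] = L[0] * 2.0  # same direction, different magnitude -> distance 0
    model = latent.FactorModel(
        method="pca", k=3,
        loadings=pd.DataFrame(L, index=[f"v{i}" for i in range(6)]),
        scores=np.zeros((1, 3)),
    )
    tree = latent.cluster_loadings(model)
    assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
    first = {tree.labels[int(tree.linkage[0, 0])], tree.labels[int(tree.linkage[0, 1])]}
    assert first == {"v0", "v1"}


def test_planted_two_block_loadings_recovered_at_cut_two():
    rng = np.random.default_rng(7)
    block = np.zeros((10, 2))
    block[:5, 0] = 1.0
    block[5:, 1] = 1.0
    L = block + 0.05 * rng.normal(size=(10, 2))
    model = latent.FactorModel(
        method="pca", k=2,
        loadings=pd.DataFrame(L, index=[f"v{i}" for i in range(10)]),
        scores=np.zeros((1, 2)),
    )
    labels = latent.cluster_loadings(model).cut(2)
    a = {labels[f"v{i}"] for i in range(5)}
    b = {labels[f"v{i}"] for i in range(5, 10)}
    assert len(a) == 1 and len(b) == 1 and a != b


def test_tree_has_exactly_n_minus_one_merges(small_scores):
    X = latent.build_feature_matrix(small_scores)
    tree = latent.cluster_loadings(latent.fit_pca(X, k=6))
    assert tree.linkage.shape == (22, 4)
    assert sorted(tree.leaf_order) == sorted(X.feature_names)
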