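"""Feature extraction against brute-force texture oracles, Boruta behavior,
and the random-forest baseline."""

import numpy as np
import pandas as pd
import pytest

from sonomtl.radiomics import (
    BorutaResult,
    RadiomicsSettings,
    RFSettings,
    boruta_select,
    extract_features,
    first_order_features,
    glcm_matrix,
    quantize,
    rf_classify,
    _run_length_matrix,
)


def test_constant_image_first_order_degenerates():
    feats = extract_features(np.full((16, 16), 100, dtype=np.uint8))
    assert feats["fo_variance"] == 0.0
    assert feats["fo_entropy"] == 0.0
    assert feats["fo_energy"] == 1.0
    assert all(np.isfinite(v) for v in feats.values())


def test_extraction_is_deterministic():
    img = np.random.default_rng(0).integers(0, 256, (20, 20)).astype(np.uint8)
    assert extract_features(img) == extract_features(img)


def _glcm_bruteforce(q, levels, dy, dx, symmetric=True):
    """Exhaustive pixel-pair enumeration oracle."""
    h, w = q.shape
    mat = np.zeros((levels, levels))
    for y in range(h):
        for x in range(w):
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w:
                mat[q[y, x], q[yy, xx]] += 1
    if symmetric:
        mat = mat + mat.T
    return mat


def test_glcm_checkerboard_matches_pair_enumeration():
    board = np.array([[0, 255], [255, 0]], dtype=np.uint8)
    q = quantize(board, 2)
    got = glcm_matrix(board, 2, 1, 0.0, normed=False)
    want = _glcm_bruteforce(q, 2, 0, 1)
    np.testing.assert_array_equal(got, want)
    # contrast of the normalized matrix: all mass on |i-j|=1 -> exactly 1
    norm = glcm_matrix(board, 2, 1, 0.0, normed=True)
    contrast = sum(norm[i, j] * (i - j) ** 2 for i in range(2) for j in range(2))
    assert contrast == pytest.approx(1.0)


@pytest.mark.parametrize("angle, dydx", [(0.0, (0, 1)), (np.pi / 2, (1, 0))])
def test_glcm_random_image_matches_pair_enumeration(angle, dydx):
    rng = np.random.default_rng(1)
    img = rng.integers(0, 256, (8, 8)).astype(np.uint8)
    q = quantize(img, 4)
    got = glcm_matrix(img, 4, 1, angle, normed=False)
    # skimage's angle=pi/2 direction is (-1, 0); symmetric counting makes
    # (1,0) and (-1,0) equivalent
    want = _glcm_bruteforce(q, 4, *dydx)
    np.testing.assert_array_equal(got, want)


def test_run_length_matrix_hand_case():
    # rows: [0,0,1] -> runs (0,len2),(1,len1); [1,1,1] -> (1,len3)
    img = np.array([[0, 0, 1], [1, 1, 1]])
    mat = _run_length_matrix(img, 2, (0, 1))
    assert mat[0, 1] == 1  # one run of level 0, length 2
    assert mat[1, 0] == 1  # one run of level 1, length 1
    assert mat[1, 2] == 1  # one run of level 1, length 3
    assert mat.sum() == 3


def test_run_length_diagonal_directions():
    img = np.eye(4, dtype=int)
    down_diag = _run_length_matrix(img, 2, (1, 1))
    # the main diagonal is a single run of four 1s
    assert down_diag[1, 3] == 1


def test_feature_table_has_stable_columns_and_no_missing(small_records):
    from sonomtl.radiomics import build_feature_table

    df1 = build_feature_table(small_records[:5])
    df2 = build_feature_table(small_records[:5])
    assert list(df1.columns) == list(df2.columns)
    assert not df1.isna().any().any()
    pd.testing.assert_frame_equal(df1, df2)
    assert df1.shape[1] >= 45


# ---------------------------------------------------------------------------
# Boruta


def _noise_X(rng, n=200, p=20):
    return pd.DataFrame(rng.standard_normal((n, p)),
                        columns=[f"f{j}" for j in range(p)])


def test_boruta_rejects_pure_noise_single_seed():
    rng = np.random.default_rng(0)
    X = _noise_X(rng)
    y = rng.integers(0, 2, len(X))
    res = boruta_select(X, y, max_iter=30, alpha=0.01, n_estimators=50, seed=0)
    assert res.confirmed == []


def test_boruta_confirms_planted_signal_single_seed():
    rng = np.random.default_rng(1)
    X = _noise_X(rng)
    y = rng.integers(0, 2, len(X))
    X["f0"] = y + 0.1 * rng.standard_normal(len(X))
    res = boruta_select(X, y, max_iter=30, alpha=0.01, n_estimators=50, seed=1)
    assert "f0" in res.confirmed


def test_boruta_reports_tentative_not_confirmed_at_budget():
    rng = np.random.default_rng(2)
    X = _noise_X(rng, n=60, p=10)
    y = rng.integers(0, 2, 60)
    res = boruta_select(X, y, max_iter=1, n_estimators=30, seed=2)
    assert res.n_iterations == 1
    assert res.confirmed == []
    assert set(res.tentative) | set(res.rejected) == set(X.columns)


def test_boruta_auto_rejects_constant_columns():
    rng = np.random.default_rng(3)
    X = _noise_X(rng, n=80, p=5)
    X["const"] = 1.0
    y = rng.integers(0, 2, 80)
    res = boruta_select(X, y, max_iter=5, n_estimators=30, seed=3)
    assert "const" in res.rejected


def test_boruta_requires_two_classes():
    X = _noise_X(np.random.default_rng(4), n=20, p=3)
    with pytest.raises(ValueError):
        boruta_select(X, np.zeros(20))


# ---------------------------------------------------------------------------
# random forest


def test_rf_separable_toy_reaches_training_auc_one():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, 100)
    X = pd.DataFrame({"a": y + 0.01 * rng.standard_normal(100),
                      "b": rng.standard_normal(100)})
    rf = rf_classify(X, y, RFSettings(n_estimators=50, seed=0))
    assert roc_auc_score(y, rf.predict_proba(X.to_numpy())[:, 1]) == 1.0


def test_rf_is_seed_deterministic():
    rng = np.random.default_rng(6)
    y = rng.integers(0, 2, 80)
    X = _noise_X(rng, n=80, p=5)
    a = rf_classify(X, y, RFSettings(n_estimators=50, seed=7)).predict_proba(X.to_numpy())
    b = rf_classify(X, y, RFSettings(n_estimators=50, seed=7)).predict_proba(X.to_numpy())
    np.testing.assert_array_equal(a, b)


def test_rf_single_class_raises():
    X = _noise_X(np.random.default_rng(7), n=10, p=2)
    with pytest.raises(ValueError):
        rf_classify(X, np.ones(10))


def test_rf_uninformative_features_near_chance():
    """Labels independent of features: held-out AUC stays within 0.5 +/- 0.1
    on average over seeds."""
    from sklearn.metrics import roc_auc_score

    aucs = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        X = _noise_X(rng, n=300, p=10)
        y = rng.integers(0, 2, 300)
        rf = rf_classify(X.iloc[:200], y[:200], RFSettings(n_estimators=100, seed=seed))
        aucs.append(roc_auc_score(y[200:], rf.predict_proba(X.iloc[200:].to_numpy())[:, 1]))
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)
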