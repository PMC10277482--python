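import numpy as np
import pandas as pd
import pytest

from cld4 import (FeatureTable, band_tsb, correlation_matrix, flag_risks,
                  pca, standardize)


def test_standardize_simple_column():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
    std, dropped = standardize(df)
    assert np.allclose(std["x"], [-1.0, 0.0, 1.0])
    assert dropped == []


def test_standardize_is_idempotent():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
    once, _ = standardize(df)
    twice, _ = standardize(once)
    assert np.allclose(once, twice, atol=1e-12)


def test_constant_column_dropped():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
    std, dropped = standardize(df)
    assert dropped == ["flat"] and list(std.columns) == ["x"]
    with pytest.raises(ValueError):
        standardize(df.iloc[:1])


def test_one_dimensional_data_explained_by_pc1():
    t = np.linspace(0, 1, 10)
    df = pd.DataFrame({"a": t, "b": 2 * t, "c": -t})
    std, _ = standardize(df)
    res = pca(std)
    assert res.explained_variance_fraction[0] == pytest.approx(1.0)
    assert res.n_components == 1  # capped at rank


def _eig_oracle(std: pd.DataFrame):
    """Independent oracle: eigendecomposition of the correlation matrix."""
    x = std.to_numpy()
    n = x.shape[0]
    corr = x.T @ x / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    return evals / evals.sum(), evecs


def test_pca_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(42)
    df = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"))
    std, _ = standardize(df)
    res = pca(std)
    frac_oracle, evecs = _eig_oracle(std)
    assert np.allclose(res.explained_variance_fraction,
                       frac_oracle[:res.n_components], atol=1e-10)
    for j in range(res.n_components):
        got = res.loadings.iloc[:, j].to_numpy()
        ref = evecs[:, j]
        if np.sign(got[np.argmax(np.abs(got))]) != np.sign(ref[np.argmax(np.abs(ref))]):
            ref = -ref
        assert np.allclose(got, ref, atol=1e-8)
    # scores reproduce the standardized matrix with all components kept
    recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
    assert np.allclose(recon, std.to_numpy(), atol=1e-8)


def test_explained_fractions_conserve_variance():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(rng.normal(size=(30, 6)))
    std, _ = standardize(df)
    res = pca(std)
    fr = res.explained_variance_fraction
    assert np.all(np.diff(fr) <= 1e-12)          # non-increasing
    assert fr.sum() == pytest.approx(1.0)
    assert np.all((fr >= 0) & (fr <= 1))
    # loadings columns orthonormal
    gram = res.loadings.to_numpy().T @ res.loadings.to_numpy()
    assert np.allclose(gram, np.eye(res.n_components), atol=1e-10)


def test_pca_sign_convention_is_deterministic():
    rng = np.random.default_rng(9)
    df = pd.DataFrame(rng.normal(size=(12, 4)))
    std, _ = standardize(df)
    a, b = pca(std), pca(std)
    assert np.allclose(a.loadings, b.loadings)
    for j in range(a.n_components):
        col = a.loadings.iloc[:, j].to_numpy()
        assert col[np.argmax(np.abs(col))] > 0


def test_correlation_identities_and_hand_oracle():
    x = np.array([1.0, 2.0, 4.0, 7.0])
    y = np.array([2.0, 1.0, 5.0, 6.0])
    df = pd.DataFrame({"x": x, "neg": -x, "y": y})
    corr = correlation_matrix(df)
    assert corr.r("x", "x") == 1.0
    assert corr.r("x", "neg") == pytest.approx(-1.0)
    # hand-computed covariance / (sd_x * sd_y) oracle
    r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
              / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
    assert corr.r("x", "y") == pytest.approx(r_hand)
    m = corr.matrix.to_numpy()
    assert np.allclose(m, m.T) and np.allclose(np.diag(m), 1.0)
    assert np.linalg.eigvalsh(m).min() >= -1e-10  # PSD on complete data


def test_pairs_with_too_few_observations_masked():
    df = pd.DataFrame({"x": [1.0, 2.0, np.nan, np.nan],
                       "y": [1.0, np.nan, 2.0, np.nan]})
    corr = correlation_matrix(df, min_observations=3)
    assert np.isnan(corr.r("x", "y"))


@pytest.mark.parametrize("tsb, band", [
    (0.0, "low"), (6.99, "low"), (7.0, "medium"), (13.99, "medium"),
    (14.0, "high"), (20.0, "high"), (25.0, "high"),
])
def test_tsb_banding(tsb, band):
    assert band_tsb(tsb) == band


def test_negative_tsb_rejected():
    with pytest.raises(ValueError):
        band_tsb(-0.1)


def _corr_fixture():
    rng = np.random.default_rng(5)
    z = rng.normal(size=24)
    df = pd.DataFrame({
        "pH:avg": z + rng.normal(0, 0.3, 24),
        "DO2:avg": rng.normal(size=24),
        "TSB:end_point": z + rng.normal(0, 0.3, 24),
    })
    return correlation_matrix(df)


def test_flag_risks_threshold_and_ordering():
    corr = _corr_fixture()
    assert flag_risks(corr, ["pH:avg", "DO2:avg"], ["TSB:end_point"],
                      threshold=1.01) == []
    findings = flag_risks(corr, ["pH:avg", "DO2:avg"], ["TSB:end_point"],
                          threshold=0.7)
    assert [f.process_feature for f in findings] == ["pH:avg"]
    assert abs(findings[0].r) >= 0.7
    # order of the feature lists does not change the findings
    flipped = flag_risks(corr, ["DO2:avg", "pH:avg"], ["TSB:end_point"],
                         threshold=0.7)
    assert flipped == findings


def test_generator_induces_ph_tsb_risk_finding(default_warehouse):
    from cld4 import build_feature_table, load_plan
    from cld4.analytics import DEFAULT_PROCESS_FEATURES, DEFAULT_QUALITY_FEATURES
    table = build_feature_table(default_warehouse, load_plan("analytics"))
    corr = correlation_matrix(table)
    findings = flag_risks(corr, DEFAULT_PROCESS_FEATURES,
                          DEFAULT_QUALITY_FEATURES, threshold=0.7)
    pairs = {(f.process_feature, f.quality_feature) for f in findings}
    assert ("pH:avg:d0-7", "TSB:end_point") in pairs


def test_feature_table_accepted_everywhere(small_features):
    std, _ = standardize(small_features)
    assert isinstance(std, pd.DataFrame)
    corr = correlation_matrix(small_features)
    assert isinstance(corr.matrix, pd.DataFrame)
    assert isinstance(small_features, FeatureTable)
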