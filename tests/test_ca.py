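"""Correspondence analysis: inertia accounting, coordinates, contributions."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from oacsafety.ca import (
    CAResult,
    fit_ca,
    profile_distance_ranking,
    retain_dimensions,
    select_variables,
)
from oacsafety.contingency import ContingencyTable


def make_table(counts, socs=None, drugs=None):
    counts = np.asarray(counts)
    socs = socs or tuple(f"S{i}" for i in range(counts.shape[0]))
    drugs = drugs or tuple(f"d{j}" for j in range(counts.shape[1]))
    return ContingencyTable(tuple(socs), tuple(drugs), counts)


def standardized_residual_matrix(counts):
    """Independent first-principles construction of S (explicit loops)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    S = np.empty_like(counts)
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            r_i = counts[i].sum() / n
            c_j = counts[:, j].sum() / n
            S[i, j] = (counts[i, j] / n - r_i * c_j) / np.sqrt(r_i * c_j)
    return S


def test_independent_table_has_zero_inertia():
    result = fit_ca(make_table([[2, 4], [3, 6]]))
    assert result.total_inertia == pytest.approx(0.0, abs=1e-14)
    np.testing.assert_allclose(result.row_principal, 0.0, atol=1e-7)
    np.testing.assert_allclose(result.col_principal, 0.0, atol=1e-7)


def test_inertia_equals_pearson_chi2_over_n(rng):
    for _ in range(30):
        counts = rng.integers(1, 40, size=rng.integers(2, 7, size=2))
        result = fit_ca(make_table(counts))
        chi2 = chi2_contingency(counts, correction=False)[0]
        assert result.total_inertia == pytest.approx(chi2 / counts.sum(), rel=1e-9)


def test_contributions_sum_to_one_per_dimension(rng):
    counts = rng.integers(1, 40, size=(6, 4))
    result = fit_ca(make_table(counts))
    np.testing.assert_allclose(result.row_contrib.sum(axis=0), 1.0, rtol=1e-9)
    np.testing.assert_allclose(result.col_contrib.sum(axis=0), 1.0, rtol=1e-9)
    # contribution-biplot scaling: squared vector coordinate == contribution
    np.testing.assert_allclose(result.biplot_vectors**2, result.row_contrib, atol=1e-12)


def test_row_distances_equal_chi2_profile_distances(rng):
    counts = rng.integers(1, 30, size=(4, 3))
    result = fit_ca(make_table(counts))
    dense = counts.astype(float)
    n = dense.sum()
    c = dense.sum(axis=0) / n
    profiles = dense / dense.sum(axis=1, keepdims=True)
    for i in range(4):
        for k in range(i + 1, 4):
            chi_dist = np.sqrt((((profiles[i] - profiles[k]) ** 2) / c).sum())
            coord_dist = np.linalg.norm(result.row_principal[i] - result.row_principal[k])
            assert coord_dist == pytest.approx(chi_dist, rel=1e-9)


def test_eigenvalues_match_brute_force_on_3x3(rng):
    for _ in range(10):
        counts = rng.integers(1, 25, size=(3, 3))
        result = fit_ca(make_table(counts))
        S = standardized_residual_matrix(counts)
        eigs = np.sort(np.linalg.eigvalsh(S @ S.T))[::-1]
        np.testing.assert_allclose(result.inertia, eigs[:2], atol=1e-10)


def test_orthogonality_and_transition_formulas(rng):
    counts = rng.integers(1, 40, size=(6, 5))
    result = fit_ca(make_table(counts))
    # mass-weighted covariance across distinct dimensions is zero
    F, G = result.row_principal, result.col_principal
    gram_r = (F * result.row_masses[:, None]).T @ F
    gram_c = (G * result.col_masses[:, None]).T @ G
    np.testing.assert_allclose(gram_r, np.diag(result.inertia), atol=1e-9)
    np.testing.assert_allclose(gram_c, np.diag(result.inertia), atol=1e-9)
    # F = Dr^-1 P G Dsigma^-1 on dimensions with nonzero inertia
    P = counts / counts.sum()
    keep = result.singular_values > 1e-10
    rhs = (P @ G[:, keep]) / result.row_masses[:, None] / result.singular_values[keep]
    np.testing.assert_allclose(F[:, keep], rhs, atol=1e-9)


def test_sign_convention_makes_fits_reproducible(rng):
    counts = rng.integers(1, 40, size=(5, 4))
    a = fit_ca(make_table(counts))
    b = fit_ca(make_table(counts))
    np.testing.assert_array_equal(a.row_principal, b.row_principal)
    for k in range(a.row_principal.shape[1]):
        pivot = np.argmax(np.abs(a.biplot_vectors[:, k]))
        assert a.biplot_vectors[pivot, k] >= 0


def _dummy_result(shares):
    shares = np.asarray(shares, dtype=float)
    lam = shares  # total 1, so shares == inertia
    k = len(shares)
    return CAResult(
        socs=tuple(f"S{i}" for i in range(k + 1)), drugs=tuple(f"d{j}" for j in range(k + 1)),
        row_masses=np.full(k + 1, 1 / (k + 1)), col_masses=np.full(k + 1, 1 / (k + 1)),
        singular_values=np.sqrt(lam), inertia=lam, inertia_share=shares,
        row_principal=np.zeros((k + 1, k)), col_principal=np.zeros((k + 1, k)),
        row_contrib=np.zeros((k + 1, k)), col_contrib=np.zeros((k + 1, k)),
        biplot_vectors=np.zeros((k + 1, k)),
    )


def test_dimension_retention_rule():
    # shares above the uniform expectation 1/K are kept, floor of two
    assert retain_dimensions(_dummy_result([0.6, 0.3, 0.05, 0.03, 0.02])) == 2
    assert retain_dimensions(_dummy_result([0.4, 0.3, 0.28, 0.02])) == 3
    assert retain_dimensions(_dummy_result([0.25, 0.25, 0.25, 0.25])) == 2  # floor


def test_variable_selection_threshold_and_ranking(rng):
    counts = np.full((26, 6), 10)
    counts[3, 0] = 400  # one SOC concentrated in one drug
    result = fit_ca(make_table(counts))
    sel = select_variables(result, top_n=5)
    assert sel.threshold == pytest.approx(1 / 26)
    assert sel.top[0] == "S3"
    assert "S3" in sel.selected
    # uniform table: nothing exceeds the threshold
    uniform = fit_ca(make_table(np.full((6, 4), 7)))
    assert select_variables(uniform).selected == ()
    # top_n larger than the SOC count clamps
    assert len(select_variables(result, top_n=99).top) == 26


def test_profile_distances_identical_columns_and_1d_ranking():
    counts = np.array([[5, 5, 20], [10, 10, 3], [7, 7, 30]])
    result = fit_ca(make_table(counts))
    ranking = profile_distance_ranking(result, dims=result.row_principal.shape[1])
    first = ranking.iloc[0]
    assert {first["drug_a"], first["drug_b"]} == {"d0", "d1"}
    assert first["distance"] == pytest.approx(0.0, abs=1e-12)
    one_d = profile_distance_ranking(result, dims=1)
    g1 = dict(zip(result.drugs, result.col_principal[:, 0]))
    diffs = [abs(g1[a] - g1[b]) for a, b in zip(one_d["drug_a"], one_d["drug_b"])]
    np.testing.assert_allclose(one_d["distance"], diffs, atol=1e-12)
    assert diffs == sorted(diffs)


def test_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        fit_ca(make_table([[1], [2]]))  # single column
    with pytest.raises(ValueError):
        fit_ca(make_table([[0, 0], [3, 6]]))  # zero margin
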