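import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syndromap.cde_io import CohortTable, VariableSpec, default_specs
from syndromap.syndromic_distance import (
    AllMissingColumnError,
    DistanceMatrix,
    StandardizedMatrix,
    UndefinedCorrelationError,
    norm_corr,
    pairwise_distances,
    pearson_r,
    standardize_columns,
)


def _std_matrix(values):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return StandardizedMatrix(
        values=values,
        impute_mask=np.zeros((n, p), bool),
        column_stats=pd.DataFrame(),
        columns=[f"v{j}" for j in range(p)],
        patient_ids=[f"p{i}" for i in range(n)],
    )


# -- column standardization -------------------------------------------------

def _tiny_cohort(**overrides):
    specs = default_specs()
    base = pd.DataFrame(
        0.0, index=pd.Index(["a", "b", "c"]),
        columns=[s.name for s in specs if s.role == "tda-input"],
    )
    base["marshall_ct"] = 1.0
    base["rotterdam_ct"] = 2.0
    base["pcl_6m"] = [20.0, 25.0, 30.0]
    base["wais_psi_6m"] = [90.0, 100.0, 110.0]
    base["cvlt_sdc_6m"] = [0.0, 1.0, -1.0]
    base["cvlt_ldc_6m"] = [-1.0, 0.0, 1.0]
    for name, vals in overrides.items():
        base[name] = vals
    return CohortTable(base, [s for s in specs if s.name in base.columns])


def test_zscore_uses_population_sd():
    # [20, 30, 40] standardizes to [-1.2247, 0, 1.2247] under the
    # divide-by-N convention (SD of centered [1, 2, 3] = sqrt(2/3))
    cohort = _tiny_cohort(pcl_6m=[20.0, 30.0, 40.0])
    std = standardize_columns(cohort)
    j = std.columns.index("pcl_6m")
    np.testing.assert_allclose(std.values[:, j],
                               np.array([-1.22474487, 0.0, 1.22474487]),
                               atol=1e-8)


def test_nondegenerate_columns_have_zero_mean_unit_sd(small_cohort):
    std = standardize_columns(small_cohort)
    for j, name in enumerate(std.columns):
        if name in std.degenerate_columns:
            assert np.allclose(std.values[:, j], 0.0)
        else:
            assert abs(std.values[:, j].mean()) < 1e-10
            assert abs(std.values[:, j].std() - 1.0) < 1e-10


def test_constant_column_zeroed_with_warning(small_cohort):
    df = small_cohort.data.copy()
    df["epidural_hematoma"] = 0.0
    cohort = CohortTable(df, small_cohort.specs)
    with pytest.warns(UserWarning, match="epidural_hematoma"):
        std = standardize_columns(cohort)
    j = std.columns.index("epidural_hematoma")
    assert np.allclose(std.values[:, j], 0.0)
    assert "epidural_hematoma" in std.degenerate_columns


def test_median_imputation_value_and_flag():
    cohort = _tiny_cohort(cvlt_sdc_6m=[0.0, 1.0, np.nan])
    std = standardize_columns(cohort, impute="median")
    j = std.columns.index("cvlt_sdc_6m")
    assert std.impute_mask[2, j]
    # imputed raw value 0.5 -> exactly the column mean -> z-score 0
    assert std.values[2, j] == pytest.approx(0.0, abs=1e-12)
    assert std.column_stats.loc["cvlt_sdc_6m", "mean"] == pytest.approx(0.5)


def test_all_missing_column_is_error(small_cohort):
    df = small_cohort.data.copy()
    df["pcl_6m"] = np.nan
    cohort = CohortTable(df, small_cohort.specs)
    with pytest.raises(AllMissingColumnError, match="pcl_6m"):
        standardize_columns(cohort)


# -- Pearson correlation ------------------------------------------------------

@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([1, 2, 3], [1, 2, 3], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
    ],
)
def test_pearson_known_values(x, y, expected):
    assert pearson_r(np.array(x), np.array(y)) == pytest.approx(expected)
    assert pearson_r(np.array(y), np.array(x)) == pytest.approx(expected)


def test_pearson_requires_non_constant_vectors():
    with pytest.raises(UndefinedCorrelationError):
        pearson_r(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))
    with pytest.raises(ValueError, match="at least 3"):
        pearson_r(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


# -- norm-correlation distance ----------------------------------------------

def test_norm_corr_identical_and_opposite_rows(rng):
    row = rng.standard_normal(17)
    assert norm_corr(row, row) == pytest.approx(0.0, abs=1e-12)
    assert norm_corr(row, -row) == pytest.approx(2.0, abs=1e-12)


def test_norm_corr_from_known_correlation():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 3.0, 2.0, 4.0])
    assert norm_corr(x, y) == pytest.approx(0.2)


def test_pairwise_matches_bruteforce_loops(rng):
    values = rng.standard_normal((10, 17))
    d = pairwise_distances(_std_matrix(values)).values
    for i in range(10):
        for j in range(10):
            expected = 0.0 if i == j else norm_corr(values[i], values[j])
            assert abs(d[i, j] - expected) < 1e-12


def test_pairwise_identical_and_negated_patients(rng):
    row = rng.standard_normal(17)
    d = pairwise_distances(_std_matrix([row, row])).values
    np.testing.assert_allclose(d, 0.0, atol=1e-12)
    d3 = pairwise_distances(_std_matrix([row, rng.standard_normal(17), -row]))
    assert d3.values[0, 2] == pytest.approx(2.0, abs=1e-12)


def test_constant_profile_fallback_and_error(rng):
    values = rng.standard_normal((4, 17))
    values[2] = 5.0
    with pytest.warns(UserWarning, match="constant"):
        d = pairwise_distances(_std_matrix(values), fallback_max=True)
    assert d.values[2, 0] == 2.0 and d.values[2, 2] == 0.0
    with pytest.raises(UndefinedCorrelationError):
        pairwise_distances(_std_matrix(values), fallback_max=False)


def test_distance_matrix_invariants(default_distance):
    v = default_distance.values
    assert np.allclose(v, v.T)
    assert np.allclose(np.diag(v), 0.0)
    assert v.min() >= 0.0 and v.max() <= 2.0


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    shift=st.floats(-50, 50, allow_nan=False),
    scale=st.floats(0.1, 20, allow_nan=False),
)
def test_distance_invariant_to_column_affine_transform(shift, scale):
    rng = np.random.default_rng(99)
    raw = rng.standard_normal((12, 17))
    specs = [
        VariableSpec(f"v{j}", "continuous", (-1e6, 1e6), "tda-input")
        for j in range(17)
    ]
    cols = [f"v{j}" for j in range(17)]
    idx = pd.Index([f"p{i}" for i in range(12)])
    base = CohortTable(pd.DataFrame(raw, index=idx, columns=cols), specs)
    moved = raw.copy()
    moved[:, 3] = moved[:, 3] * scale + shift
    other = CohortTable(pd.DataFrame(moved, index=idx, columns=cols), specs)

    def dist(c):
        std = standardize_columns(c)
        m = StandardizedMatrix(std.values, std.impute_mask, std.column_stats,
                               std.columns, std.patient_ids)
        return pairwise_distances(m).values

    np.testing.assert_allclose(dist(base), dist(other), atol=1e-10)


def test_pairwise_complete_agrees_on_complete_data(rng):
    values = rng.standard_normal((8, 17))
    dense = pairwise_distances(_std_matrix(values)).values
    with_nan_path = _std_matrix(values.copy())
    with_nan_path.values[0, 0] = with_nan_path.values[0, 0]  # still complete
    # force the pairwise code path by inserting one NaN then restoring overlap
    masked = values.copy()
    masked[0, 0] = np.nan
    sparse = pairwise_distances(_std_matrix(masked)).values
    # all pairs not involving patient 0 are identical to the dense result
    np.testing.assert_allclose(sparse[1:, 1:], dense[1:, 1:], atol=1e-12)


def test_pairwise_complete_minimum_overlap(rng):
    values = rng.standard_normal((3, 17))
    values[0, 10:] = np.nan
    values[1, :10] = np.nan  # only 0 shared with patient 0
    with pytest.warns(UserWarning, match="overlap"):
        d = pairwise_distances(_std_matrix(values), fallback_max=True)
    assert d.values[0, 1] == 2.0


def test_distance_csv_roundtrip(tmp_path, rng):
    d = pairwise_distances(_std_matrix(rng.standard_normal((6, 17))))
    path = tmp_path / "d.csv"
    d.to_csv(path)
    back = DistanceMatrix.from_csv(path)
    np.testing.assert_allclose(back.values, d.values, atol=1e-12)
    assert back.patient_ids == d.patient_ids
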