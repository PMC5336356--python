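import numpy as np
import pandas as pd
import pytest

from syndromap.cde_io import CohortTable, VariableSpec
from syndromap.glm_hypothesis import (
    DesignError,
    GlmDataset,
    anova_oneway_genotype,
    anova_type3,
    build_glm_dataset,
    repeated_measures_suite,
    tukey_posthoc,
)
from syndromap.synthetic_cohort import SimulationConfig, generate_cohort


def _cohort_from(gose3, gose6, ct, snp):
    n = len(gose3)
    idx = pd.Index([f"p{i}" for i in range(n)])
    specs = [
        VariableSpec("gose_3m", "ordinal", (1, 8), "outcome"),
        VariableSpec("gose_6m", "ordinal", (1, 8), "outcome"),
        VariableSpec("ct_brain_pathology", "binary", (0, 1), "tda-input"),
        VariableSpec("snp", "categorical-genotype", (1, 2, 3), "genotype"),
    ]
    frame = pd.DataFrame(
        {"gose_3m": gose3, "gose_6m": gose6, "ct_brain_pathology": ct,
         "snp": snp},
        index=idx, dtype=float,
    )
    return CohortTable(frame, specs)


def _dataset(y, ct, geno, response="change"):
    """Directly assemble a GlmDataset with the chosen response values."""
    n = len(y)
    frame = pd.DataFrame(
        {
            "gose_3m": np.full(n, 4.0),
            "gose_6m": np.full(n, 4.0),
            "change": np.zeros(n),
            "ct": np.asarray(ct, dtype=int),
            "genotype": np.asarray(geno, dtype=int),
        },
        index=pd.Index([f"p{i}" for i in range(n)]),
    )
    col = {"3m": "gose_3m", "6m": "gose_6m", "change": "change"}[response]
    frame[col] = np.asarray(y, dtype=float)
    return GlmDataset(frame=frame, snp="snp", exclusions=pd.DataFrame())


# -- dataset construction ------------------------------------------------------

def test_listwise_inclusion_logs_exclusions():
    cohort = _cohort_from(
        gose3=[5, 6, 7, 4, 5],
        gose6=[6, np.nan, 8, 5, 6],
        ct=[0, 0, 1, 1, 0],
        snp=[1, 2, 3, 2, 2],
    )
    ds = build_glm_dataset(cohort, "snp")
    assert ds.n == 4
    assert list(ds.exclusions["patient_id"]) == ["p1"]
    assert "gose_6m" in ds.exclusions["reason"].iloc[0]
    assert ds.frame.loc["p0", "change"] == 1.0


def test_inclusion_matches_bruteforce_filter():
    cohort = generate_cohort(SimulationConfig(
        n_patients=400, seed=13,
        missing_rates={"gose_6m": 0.3, "PARP1_rs3219119": 0.2},
    ))
    ds = build_glm_dataset(cohort, "PARP1_rs3219119")
    manual = cohort.data[
        ["gose_3m", "gose_6m", "ct_brain_pathology", "PARP1_rs3219119"]
    ].dropna()
    assert ds.n == len(manual)
    assert ds.n + len(ds.exclusions) == cohort.n_patients


def test_single_level_factor_is_design_error():
    cohort = _cohort_from([5] * 6, [6] * 6, [0] * 6, [1, 2, 3, 1, 2, 3])
    with pytest.raises(DesignError):
        build_glm_dataset(cohort, "snp")


# -- Type III engine -----------------------------------------------------------

def test_constant_response_gives_zero_f():
    ds = _dataset([4.0] * 12, ct=[0, 1] * 6, geno=[1, 2, 3] * 4)
    table = anova_type3(ds, "change")
    for term in ("ct", "genotype", "ct:genotype"):
        assert table.loc[term, "SS"] == pytest.approx(0.0, abs=1e-20)


def test_balanced_one_factor_hand_value():
    # groups {1,2,3} vs {4,5,6}: F = 13.5
    frame = pd.DataFrame(
        {"gose_3m": 0.0, "gose_6m": 0.0,
         "change": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
         "ct": 0, "genotype": [1, 1, 1, 2, 2, 2]},
        index=pd.Index([f"p{i}" for i in range(6)]),
    )
    table = anova_oneway_genotype(frame, "change")
    assert table.loc["genotype", "F"] == pytest.approx(13.5)
    assert table.loc["genotype", "df"] == 1
    assert table.loc["residual", "df"] == 4


def _type3_oracle(y, ct, geno):
    """Model-comparison Type III SS via sum-to-zero regression."""
    y = np.asarray(y, dtype=float)
    ct = np.asarray(ct)
    geno = np.asarray(geno)
    n = len(y)

    def sum_code(levels, values):
        levels = np.sort(np.unique(levels))
        cols = []
        for lv in levels[:-1]:
            col = (values == lv).astype(float) - (values == levels[-1])
            cols.append(col)
        return np.column_stack(cols) if cols else np.empty((n, 0))

    a = sum_code(ct, ct)
    b = sum_code(geno, geno)
    ab = np.column_stack([a[:, i] * b[:, j]
                          for i in range(a.shape[1])
                          for j in range(b.shape[1])])
    one = np.ones((n, 1))

    def rss(*blocks):
        x = np.column_stack(blocks)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        return ((y - x @ beta) ** 2).sum()

    full = rss(one, a, b, ab)
    out = {
        "ct": rss(one, b, ab) - full,
        "genotype": rss(one, a, ab) - full,
        "ct:genotype": rss(one, a, b) - full,
        "residual": full,
    }
    out["df_resid"] = n - (1 + a.shape[1] + b.shape[1] + ab.shape[1])
    return out


def test_type3_matches_regression_oracle_on_unbalanced_design(rng):
    ct = np.array([0] * 7 + [1] * 11)
    geno = np.array([1, 1, 2, 2, 2, 3, 3] + [1, 1, 1, 1, 2, 2, 3, 3, 3, 3, 3])
    y = rng.standard_normal(18) + 0.5 * ct + 0.3 * (geno == 2)
    ds = _dataset(y, ct, geno)
    table = anova_type3(ds, "change")
    oracle = _type3_oracle(y, ct, geno)
    for term in ("ct", "genotype", "ct:genotype"):
        assert table.loc[term, "SS"] == pytest.approx(oracle[term], abs=1e-8)
    assert table.loc["residual", "SS"] == pytest.approx(oracle["residual"],
                                                        abs=1e-8)
    assert table.loc["residual", "df"] == oracle["df_resid"]

    # independent library oracle: statsmodels Type III on the same data
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = ds.frame.rename(columns={"change": "y"})
    smt = sm.stats.anova_lm(
        smf.ols("y ~ C(ct, Sum) * C(genotype, Sum)", data=data).fit(), typ=3)
    pairs = {"ct": "C(ct, Sum)", "genotype": "C(genotype, Sum)",
             "ct:genotype": "C(ct, Sum):C(genotype, Sum)"}
    for term, smname in pairs.items():
        assert table.loc[term, "F"] == pytest.approx(smt.loc[smname, "F"],
                                                     rel=1e-8)


def test_type3_invariant_to_relabeling_and_row_order(rng):
    ct = rng.integers(0, 2, 24)
    geno = rng.integers(1, 4, 24)
    while len(np.unique(ct)) < 2 or len(np.unique(geno)) < 3:
        ct = rng.integers(0, 2, 24)
        geno = rng.integers(1, 4, 24)
    y = rng.standard_normal(24)
    base = anova_type3(_dataset(y, ct, geno), "change")
    relabeled = anova_type3(_dataset(y, 1 - ct, 4 - geno), "change")
    perm = rng.permutation(24)
    shuffled = anova_type3(_dataset(y[perm], ct[perm], geno[perm]), "change")
    for term in ("ct", "genotype", "ct:genotype"):
        assert base.loc[term, "F"] == pytest.approx(relabeled.loc[term, "F"],
                                                    rel=1e-9)
        assert base.loc[term, "F"] == pytest.approx(shuffled.loc[term, "F"],
                                                    rel=1e-9)


def test_type3_equals_type1_under_balance(rng):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    cells = [(c, g) for c in (0, 1) for g in (1, 2, 3)]
    ct = np.repeat([c for c, _ in cells], 4)
    geno = np.repeat([g for _, g in cells], 4)
    y = rng.standard_normal(24)
    ds = _dataset(y, ct, geno)
    t3 = anova_type3(ds, "change")
    data = ds.frame.rename(columns={"change": "y"})
    t1 = sm.stats.anova_lm(
        smf.ols("y ~ C(ct, Sum) * C(genotype, Sum)", data=data).fit(), typ=1)
    pairs = {
        "ct": "C(ct, Sum)",
        "genotype": "C(genotype, Sum)",
        "ct:genotype": "C(ct, Sum):C(genotype, Sum)",
    }
    for term, t1name in pairs.items():
        assert t3.loc[term, "SS"] == pytest.approx(t1.loc[t1name, "sum_sq"],
                                                   rel=1e-9)


def test_empty_cell_reported(rng):
    ct = np.array([0] * 6 + [1] * 6)
    geno = np.array([1, 1, 2, 2, 3, 3, 1, 1, 2, 2, 1, 1])  # no (1, 3) cell
    with pytest.raises(DesignError, match="empty design cell"):
        anova_type3(_dataset(rng.standard_normal(12), ct, geno), "change")


def test_change_score_f_equals_mixed_anova_oracle(rng):
    pingouin = pytest.importorskip("pingouin")
    n = 30
    geno = rng.integers(1, 4, n)
    while len(np.unique(geno)) < 3:
        geno = rng.integers(1, 4, n)
    y3 = rng.standard_normal(n) + 5
    y6 = y3 + rng.standard_normal(n) + 0.3 * (geno == 2)
    frame = pd.DataFrame({
        "gose_3m": y3, "gose_6m": y6, "change": y6 - y3,
        "ct": 0, "genotype": geno,
    }, index=pd.Index([f"p{i}" for i in range(n)]))
    ours = anova_oneway_genotype(frame, "change").loc["genotype", "F"]

    long = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "time": np.repeat(["3m", "6m"], n),
        "genotype": np.tile(geno, 2),
        "y": np.concatenate([y3, y6]),
    })
    aov = pingouin.mixed_anova(long, dv="y", within="time", between="genotype",
                               subject="subject")
    oracle = float(aov.loc[aov["Source"] == "Interaction", "F"].iloc[0])
    assert ours == pytest.approx(oracle, rel=1e-6)


# -- Tukey-Kramer posthocs ----------------------------------------------------

def test_tukey_identical_groups_p_one():
    # the two genotype groups have identical value multisets
    y = [2.0, 4.0, 2.0, 4.0, 2.0, 4.0, 2.0, 4.0]
    ds = _dataset(y, ct=[0, 1] * 4, geno=[1, 1, 1, 1, 2, 2, 2, 2])
    table = tukey_posthoc(ds, "change", "all")
    assert table["p_adjusted"].iloc[0] == pytest.approx(1.0)
    assert table["q"].iloc[0] == pytest.approx(0.0)


def test_tukey_matches_statsmodels_oracle(rng):
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    geno = np.repeat([1, 2, 3], 8)
    y = rng.standard_normal(24) + np.repeat([0.0, 0.8, 0.2], 8)
    frame = pd.DataFrame({
        "gose_3m": 0.0, "gose_6m": 0.0, "change": y,
        "ct": np.tile([0, 1], 12), "genotype": geno,
    }, index=pd.Index([f"p{i}" for i in range(24)]))
    ds = GlmDataset(frame=frame, snp="snp", exclusions=pd.DataFrame())
    ours = tukey_posthoc(ds, "change", "ct-")
    sub = frame[frame.ct == 0]
    oracle = pairwise_tukeyhsd(sub["change"], sub["genotype"])
    np.testing.assert_allclose(
        ours["p_adjusted"].to_numpy(), oracle.pvalues, atol=1e-6)


def test_tukey_critical_value_against_published_table():
    # studentized range upper 5% point for k=3 groups, 12 error df is 3.77
    from scipy.stats import studentized_range

    assert studentized_range.sf(3.77, 3, 12) == pytest.approx(0.05, abs=2e-3)


def test_tukey_single_group_errors():
    ds = _dataset([1.0, 2.0, 3.0, 4.0], ct=[0, 1, 0, 1], geno=[2, 2, 2, 2])
    with pytest.raises(DesignError):
        tukey_posthoc(ds, "change", "all")


# -- full report ---------------------------------------------------------------

def test_equal_timepoint_effects_cancel_in_change(rng):
    n = 60
    geno = np.concatenate([np.full(20, g) for g in (1, 2, 3)])
    ct = np.tile([0, 1], 30)
    effect = 0.8 * (geno == 2)
    y3 = 4.0 + effect + 0.0
    y6 = 4.0 + effect + 0.0
    frame = pd.DataFrame({
        "gose_3m": y3, "gose_6m": y6, "change": y6 - y3,
        "ct": ct, "genotype": geno,
    }, index=pd.Index([f"p{i}" for i in range(n)]))
    # add subject noise equally to both timepoints so change stays exactly 0
    noise = rng.standard_normal(n) * 0.5
    frame["gose_3m"] += noise
    frame["gose_6m"] += noise
    frame["change"] = 0.0  # identical timepoint effects cancel exactly
    ds = GlmDataset(frame=frame, snp="snp", exclusions=pd.DataFrame())
    report = repeated_measures_suite(ds)
    ss_change = report.effect_tables["change"].loc["genotype", "SS"]
    assert ss_change == pytest.approx(0.0, abs=1e-18)
    # but the per-timepoint genotype effect is large
    assert report.effect_tables["3m"].loc["genotype", "F"] > 10


def test_report_layout_and_export(tmp_path):
    cohort = generate_cohort(SimulationConfig(n_patients=400, seed=17))
    ds = build_glm_dataset(cohort, "PARP1_rs3219119")
    report = repeated_measures_suite(ds)
    assert set(report.effect_tables) == {"3m", "6m", "change"}
    assert set(report.stratified) == {"ct-", "ct+"}
    assert "all" in report.posthoc
    assert len(report.posthoc["all"]) == 3  # all genotype pairs
    written = report.write_csv(tmp_path)
    assert all(p.exists() for p in written)
    assert report.genotype_counts.sum() == ds.n
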