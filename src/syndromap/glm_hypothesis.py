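"""Confirmatory repeated-measures factorial GLM on GOS-E recovery.

The design is a 3-way factorial: time (3 vs 6 months, within subject),
head-CT pathology (yes/no, between subjects) and SNP genotype (3 levels,
between subjects), fit on GOS-E treated as a numeric interval scale with
Type III sums of squares.  With exactly two timepoints the within-subject
effects reduce algebraically to between-subjects effects on the 6m - 3m
change score, so the report carries three response columns — GOS-E at 3
months, at 6 months, and the 3-to-6-month change — each analyzed by a full
factorial CT x genotype model, plus genotype-only models within each CT
stratum and Tukey-Kramer all-pair genotype comparisons on the change score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import studentized_range

from .cde_io import CohortTable

RESPONSES = ("3m", "6m", "change")
STRATA = ("all", "ct-", "ct+")


class DesignError(ValueError):
    """The factorial design cannot be estimated (missing levels/cells)."""


@dataclass
class GlmDataset:
    """Listwise-complete analysis rows for one SNP.

    ``frame`` columns: gose_3m, gose_6m, change, ct (0/1), genotype (1/2/3).
    ``exclusions`` logs every dropped patient with the reason.
    """

    frame: pd.DataFrame
    snp: str
    exclusions: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.frame)

    def cell_counts(self) -> pd.DataFrame:
        return self.frame.groupby(["ct", "genotype"]).size().unstack(fill_value=0)

    def genotype_counts(self) -> pd.Series:
        return self.frame["genotype"].value_counts().sort_index()


@dataclass
class AnovaReport:
    snp: str
    effect_tables: dict[str, pd.DataFrame]          # response -> Type III table
    stratified: dict[str, dict[str, pd.DataFrame]]  # stratum -> response -> table
    posthoc: dict[str, pd.DataFrame]                # stratum -> Tukey pairs (change)
    n: int
    genotype_counts: pd.Series

    def write_csv(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for resp, table in self.effect_tables.items():
            p = outdir / f"effects_{self.snp}_{resp}.csv"
            table.to_csv(p, encoding="utf-8")
            written.append(p)
        for stratum, tables in self.stratified.items():
            tag = {"ct-": "ctneg", "ct+": "ctpos"}.get(stratum, stratum)
            for resp, table in tables.items():
                p = outdir / f"effects_{self.snp}_{tag}_{resp}.csv"
                table.to_csv(p, encoding="utf-8")
                written.append(p)
        for stratum, table in self.posthoc.items():
            tag = {"ct-": "ctneg", "ct+": "ctpos"}.get(stratum, stratum)
            p = outdir / f"tukey_{self.snp}_{tag}_change.csv"
            table.to_csv(p, index=False, encoding="utf-8")
            written.append(p)
        return written


def build_glm_dataset(
    cohort: CohortTable, snp: str, ct_variable: str = "ct_brain_pathology"
) -> GlmDataset:
    """Listwise inclusion of patients with GOS-E at both timepoints, the CT
    indicator, and the genotype all observed; exclusions are logged."""
    needed = ["gose_3m", "gose_6m", ct_variable, snp]
    for col in needed:
        if col not in cohort.data.columns:
            raise KeyError(f"cohort lacks required column {col!r}")
    sub = cohort.data[needed]
    rows, excl = [], []
    for pid, row in sub.iterrows():
        missing = [c for c in needed if np.isnan(row[c])]
        if missing:
            excl.append({"patient_id": pid, "reason": f"missing {','.join(missing)}"})
            continue
        rows.append(
            {
                "patient_id": pid,
                "gose_3m": row["gose_3m"],
                "gose_6m": row["gose_6m"],
                "change": row["gose_6m"] - row["gose_3m"],
                "ct": int(row[ct_variable]),
                "genotype": int(row[snp]),
            }
        )
    frame = pd.DataFrame(rows).set_index("patient_id") if rows else pd.DataFrame()
    exclusions = pd.DataFrame(excl, columns=["patient_id", "reason"])
    if frame.empty or frame["ct"].nunique() < 2 or frame["genotype"].nunique() < 2:
        raise DesignError(
            f"fewer than 2 observed levels for CT or genotype after inclusion "
            f"(N={len(frame)})"
        )
    return GlmDataset(frame=frame, snp=snp, exclusions=exclusions)


_RESPONSE_COLUMN = {"3m": "gose_3m", "6m": "gose_6m", "change": "change"}


def _sum_code(values: np.ndarray) -> np.ndarray:
    """Sum-to-zero (deviation) coding: one column per non-reference level."""
    levels = np.sort(np.unique(values))
    cols = [
        (values == lv).astype(float) - (values == levels[-1]).astype(float)
        for lv in levels[:-1]
    ]
    return np.column_stack(cols) if cols else np.empty((len(values), 0))


def _rss(y: np.ndarray, blocks: list[np.ndarray]) -> float:
    x = np.column_stack(blocks)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return float(((y - x @ beta) ** 2).sum())


def _effect_rows(
    y: np.ndarray, terms: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Type III table by model comparison: each term's SS is the residual-SS
    increase when that term alone is dropped from the full sum-coded model."""
    n = len(y)
    intercept = np.ones((n, 1))
    full_blocks = [intercept] + list(terms.values())
    x_full = np.column_stack(full_blocks)
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise DesignError("singular design matrix")
    rss_full = _rss(y, full_blocks)
    df_resid = n - x_full.shape[1]
    ms_error = rss_full / df_resid if df_resid > 0 else np.nan
    rows = []
    for name, block in terms.items():
        others = [intercept] + [b for t, b in terms.items() if t != name]
        ss = max(_rss(y, others) - rss_full, 0.0)
        df = block.shape[1]
        ms = ss / df
        if df_resid <= 0:
            f_val, p = np.nan, np.nan
        elif ms_error > 0:
            f_val = ms / ms_error
            p = float(stats.f.sf(f_val, df, df_resid))
        else:
            # perfect fit: no effect variance left -> F pinned at 0 or inf
            f_val = 0.0 if ss <= 1e-12 else np.inf
            p = 1.0 if ss <= 1e-12 else 0.0
        rows.append({"source": name, "SS": ss, "df": df, "MS": ms,
                     "F": f_val, "p": p})
    rows.append({"source": "residual", "SS": rss_full, "df": df_resid,
                 "MS": ms_error, "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows).set_index("source")


def anova_type3(dataset: GlmDataset, response: str) -> pd.DataFrame:
    """Type III effect table for the full-factorial CT x genotype model.

    Sum-to-zero contrasts make each term's marginal (fitted-last) sum of
    squares well-defined under imbalance; each SS comes from comparing the
    full model with the model lacking that term, F = MS_effect / MS_error,
    p from the F distribution.  Empty design cells are reported as a design
    error rather than silently aliased.
    """
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {RESPONSES}")
    frame = dataset.frame
    cells = dataset.cell_counts()
    if (cells.to_numpy() == 0).any():
        raise DesignError(f"empty design cell(s) for CT x genotype:\n{cells}")
    y = frame[_RESPONSE_COLUMN[response]].to_numpy(dtype=float)
    a = _sum_code(frame["ct"].to_numpy())
    b = _sum_code(frame["genotype"].to_numpy())
    ab = np.column_stack(
        [a[:, i] * b[:, j] for i in range(a.shape[1]) for j in range(b.shape[1])]
    )
    return _effect_rows(y, {"ct": a, "genotype": b, "ct:genotype": ab})


def anova_oneway_genotype(frame: pd.DataFrame, response: str) -> pd.DataFrame:
    """Genotype-only model within a stratum (Type III = Type I for a single
    factor)."""
    y = frame[_RESPONSE_COLUMN[response]].to_numpy(dtype=float)
    return _effect_rows(y, {"genotype": _sum_code(frame["genotype"].to_numpy())})


def tukey_posthoc(
    dataset: GlmDataset, response: str = "change", stratum: str = "all"
) -> pd.DataFrame:
    """Tukey-Kramer all-pair genotype comparisons.

    The error term is the stratum's model error: the full factorial model's
    MS_error for ``all``, the one-way genotype model's within each CT
    stratum.  Unequal group sizes use the Kramer harmonic form, and adjusted
    p-values come from the studentized-range distribution.
    """
    frame = _stratum_frame(dataset, stratum)
    y = frame[_RESPONSE_COLUMN[response]]
    groups = frame["genotype"]
    levels = np.sort(groups.unique())
    if len(levels) < 2:
        raise DesignError("Tukey comparisons need at least 2 genotype groups")
    sizes = {g: int((groups == g).sum()) for g in levels}
    if min(sizes.values()) < 2:
        raise DesignError("each genotype group needs at least 2 observations")
    if stratum == "all":
        eff = anova_type3(dataset, response)
    else:
        eff = anova_oneway_genotype(frame, response)
    mse = float(eff.loc["residual", "MS"])
    df_err = float(eff.loc["residual", "df"])
    k = len(levels)
    means = {g: float(y[groups == g].mean()) for g in levels}
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = levels[i], levels[j]
            se = np.sqrt(mse / 2.0 * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            diff = means[gi] - means[gj]
            q = abs(diff) / se if se > 0 else 0.0
            p = float(studentized_range.sf(q, k, df_err)) if q > 0 else 1.0
            rows.append(
                {
                    "group_1": gi,
                    "group_2": gj,
                    "mean_diff": diff,
                    "q": q,
                    "p_adjusted": min(p, 1.0),
                }
            )
    return pd.DataFrame(rows)


def _stratum_frame(dataset: GlmDataset, stratum: str) -> pd.DataFrame:
    if stratum == "all":
        return dataset.frame
    if stratum == "ct-":
        return dataset.frame[dataset.frame["ct"] == 0]
    if stratum == "ct+":
        return dataset.frame[dataset.frame["ct"] == 1]
    raise ValueError(f"stratum must be one of {STRATA}")


def repeated_measures_suite(dataset: GlmDataset) -> AnovaReport:
    """Assemble the full report: factorial Type III tables for the 3-month,
    6-month and change responses (time x between effects are exactly the
    change-score between effects at two timepoints), genotype-only models in
    each CT stratum, and Tukey-Kramer change-score posthocs."""
    effect_tables = {r: anova_type3(dataset, r) for r in RESPONSES}
    stratified = {}
    posthoc = {}
    for stratum in ("ct-", "ct+"):
        frame = _stratum_frame(dataset, stratum)
        if frame["genotype"].nunique() >= 2 and len(frame) > frame["genotype"].nunique():
            stratified[stratum] = {
                r: anova_oneway_genotype(frame, r) for r in RESPONSES
            }
            posthoc[stratum] = tukey_posthoc(dataset, "change", stratum)
    posthoc["all"] = tukey_posthoc(dataset, "change", "all")
    return AnovaReport(
        snp=dataset.snp,
        effect_tables=effect_tables,
        stratified=stratified,
        posthoc=posthoc,
        n=dataset.n,
        genotype_counts=dataset.genotype_counts(),
    )
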