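"""Subgroup selection on the Mapper graph and enrichment statistics.

A region of the graph is selected by a predicate over node-level summary
statistics (e.g. nodes whose mean 6-month GOS-E is poor and whose members
are CT-negative).  The union of the selected nodes' patients forms the
subgroup; because Mapper nodes overlap, any patient appearing on both sides
is assigned to the subgroup and removed from the comparison set, so the
two-sample tests see a clean partition.

Continuous variables are compared subgroup-vs-rest by the two-sample
Kolmogorov-Smirnov test; genotype (and other categorical) variables by the
R x 2 chi-square test of independence without continuity correction, with
Fisher's exact test substituted for 2 x 2 tables.  Benjamini-Hochberg
adjustment is applied within each tested family as a guard against the
multiplicity of the exploratory screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cde_io import CohortTable
from .mapper_core import MapperGraph


class EmptySelectionError(ValueError):
    """The predicate selected no nodes / left no comparison patients."""


@dataclass
class SubgroupSelection:
    node_ids: list[str]
    member_ids: list[str]
    complement_ids: list[str]

    def __post_init__(self) -> None:
        if set(self.member_ids) & set(self.complement_ids):
            raise ValueError("subgroup and complement overlap")


@dataclass
class EnrichmentResult:
    variable: str
    test: str
    statistic: float
    p_value: float
    q_value: float | None = None
    testable: bool = True
    note: str = ""
    detail: dict = field(default_factory=dict)


def select_subgroup(
    graph: MapperGraph,
    predicate: str | Callable[[pd.Series], bool] | Sequence[str],
    comparison: str = "all-others",
) -> SubgroupSelection:
    """Select nodes by a predicate over node statistics.

    ``predicate`` may be a pandas-eval expression over node-level variable
    means (e.g. ``"gose_6m < 5 and ct_brain_pathology < 0.5"``), a callable
    applied to each node's stats row, or an explicit list of node ids.
    ``comparison`` is ``"all-others"`` or a second predicate expression
    defining the comparison set (overlapping patients go to the subgroup).
    """
    frame = graph.node_stats_frame()

    def _nodes_for(pred) -> list[str]:
        if isinstance(pred, str):
            mask = frame.eval(pred)
            return list(frame.index[mask.fillna(False).astype(bool)])
        if callable(pred):
            return [nid for nid, row in frame.iterrows() if pred(row)]
        unknown = [nid for nid in pred if nid not in frame.index]
        if unknown:
            raise KeyError(f"unknown node ids {unknown}")
        return list(pred)

    node_ids = _nodes_for(predicate)
    if not node_ids:
        raise EmptySelectionError("predicate selected no nodes")
    selected = set(node_ids)
    members: set[str] = set()
    for n in graph.nodes:
        if n.node_id in selected:
            members.update(n.member_ids)

    if comparison == "all-others":
        complement = [p for p in graph.patient_ids if p not in members]
    else:
        comp_nodes = set(_nodes_for(comparison))
        comp_members: set[str] = set()
        for n in graph.nodes:
            if n.node_id in comp_nodes:
                comp_members.update(n.member_ids)
        complement = [p for p in graph.patient_ids if p in comp_members - members]
    if not complement:
        raise EmptySelectionError("comparison set is empty")
    member_list = [p for p in graph.patient_ids if p in members]
    return SubgroupSelection(sorted(node_ids), member_list, complement)


def _split_values(
    sel: SubgroupSelection, cohort: CohortTable, variable: str
) -> tuple[np.ndarray, np.ndarray]:
    if variable not in cohort.data.columns:
        raise KeyError(f"unknown variable {variable!r}")
    col = cohort.data[variable]
    a = col.loc[sel.member_ids].to_numpy(dtype=float)
    b = col.loc[sel.complement_ids].to_numpy(dtype=float)
    return a[~np.isnan(a)], b[~np.isnan(b)]


def ks_enrichment(
    sel: SubgroupSelection, cohort: CohortTable, variable: str
) -> EnrichmentResult:
    """Two-sample KS comparison of a continuous variable (asymptotic p)."""
    a, b = _split_values(sel, cohort, variable)
    if len(a) < 3 or len(b) < 3:
        return EnrichmentResult(
            variable, "ks", float("nan"), float("nan"), testable=False,
            note="fewer than 3 non-missing values on one side",
        )
    res = stats.ks_2samp(a, b, mode="asymp")
    return EnrichmentResult(
        variable,
        "ks",
        float(res.statistic),
        float(res.pvalue),
        detail={
            "subgroup_n": len(a),
            "complement_n": len(b),
            "subgroup_mean": float(a.mean()),
            "complement_mean": float(b.mean()),
        },
    )


def categorical_enrichment(
    sel: SubgroupSelection, cohort: CohortTable, variable: str
) -> EnrichmentResult:
    """Chi-square (R x 2, no continuity correction) test of independence of
    category membership and subgroup status; Fisher exact for 2 x 2 tables."""
    a, b = _split_values(sel, cohort, variable)
    cats = np.unique(np.concatenate([a, b]))
    if len(cats) < 2:
        return EnrichmentResult(
            variable, "chi-square", float("nan"), float("nan"), testable=False,
            note="variable constant over tested patients",
        )
    table = np.array(
        [[(a == c).sum() for c in cats], [(b == c).sum() for c in cats]]
    )
    detail = {
        "categories": cats.tolist(),
        "subgroup_counts": table[0].tolist(),
        "complement_counts": table[1].tolist(),
    }
    if len(cats) == 2:
        odds, p = stats.fisher_exact(table)
        return EnrichmentResult(
            variable, "fisher", float(odds), float(p), detail=detail
        )
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    detail["df"] = int(dof)
    return EnrichmentResult(variable, "chi-square", float(chi2), float(p),
                            detail=detail)


def adjust_bh(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Benjamini-Hochberg step-up q-values within the testable family."""
    testable = [r for r in results if r.testable and np.isfinite(r.p_value)]
    if testable:
        _, q, _, _ = multipletests([r.p_value for r in testable], method="fdr_bh")
        for r, qv in zip(testable, q):
            r.q_value = float(qv)
    return results


def enrichment_screen(
    sel: SubgroupSelection,
    cohort: CohortTable,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Run KS tests on the given continuous variables and chi-square/Fisher
    tests on the categorical ones (default: all genotype columns), BH-adjust
    each family separately, and return a tidy result table sorted by q."""
    if categorical is None:
        categorical = cohort.columns_with_role("genotype")
    cont = adjust_bh([ks_enrichment(sel, cohort, v) for v in continuous])
    cat = adjust_bh([categorical_enrichment(sel, cohort, v) for v in categorical])
    rows = []
    for r in cont + cat:
        rows.append(
            {
                "variable": r.variable,
                "test": r.test,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "q_value": r.q_value if r.q_value is not None else np.nan,
                "testable": r.testable,
                "note": r.note,
                "detail": repr(r.detail),
            }
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["q_value", "p_value"], na_position="last", kind="stable"
    ).reset_index(drop=True)
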