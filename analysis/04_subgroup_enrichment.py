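"""Select the poor-recovery CT-negative region of the map and screen it for
variable and genotype enrichment.

Reads results/cohort.csv, distance.csv, graph artifacts (rebuilt in memory);
writes results/enrichment.csv and prints recovery of the planted subgroup.
"""

from pathlib import Path

import pandas as pd

from syndromap import (
    CoverConfig,
    build_graph,
    load_cohort,
    optimize_lens,
    pairwise_distances,
    standardize_columns,
)
from syndromap.pipeline import DEFAULT_PREDICATE
from syndromap.subgroup_enrichment import enrichment_screen, select_subgroup

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = load_cohort(OUT / "cohort.csv")
    dist = pairwise_distances(standardize_columns(cohort))
    lens = optimize_lens(dist)
    graph = build_graph(lens, dist, CoverConfig(), cohort=cohort)

    sel = select_subgroup(graph, DEFAULT_PREDICATE)
    screen = enrichment_screen(
        sel, cohort,
        continuous=("pcl_6m", "wais_psi_6m", "cvlt_sdc_6m", "cvlt_ldc_6m"),
    )
    screen.to_csv(OUT / "enrichment.csv", index=False, encoding="utf-8")

    print(f"selected {len(sel.node_ids)} nodes with {DEFAULT_PREDICATE!r}")
    print(f"subgroup: {len(sel.member_ids)} patients vs "
          f"{len(sel.complement_ids)} comparison patients")
    truth_path = OUT / "cohort.truth.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, index_col=0)
        planted = set(truth.index[truth.planted_member])
        rec = len(planted & set(sel.member_ids)) / max(len(planted), 1)
        print(f"recovers {rec:.0%} of the {len(planted)} planted members")
    cat = screen[screen.test != "ks"]
    top = cat.iloc[0]
    print(f"top categorical enrichment: {top.variable} "
          f"({top.test} = {top.statistic:.2f}, q = {top.q_value:.2g})")
    print(screen[["variable", "test", "statistic", "p_value", "q_value"]]
          .to_string(index=False))


if __name__ == "__main__":
    main()
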