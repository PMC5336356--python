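"""Build the Mapper graph (resolution 30, gain 3, equalized cover) and color
it by CT pathology, PTSD and GOS-E.

Reads results/cohort.csv, distance.csv, lens.csv; writes results/graph.json,
results/graph.graphml and results/node_colors.csv.
"""

from pathlib import Path

import pandas as pd

from syndromap import CoverConfig, build_graph, color_graph, load_cohort
from syndromap.mds_lens import LensEmbedding
from syndromap.syndromic_distance import DistanceMatrix

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = load_cohort(OUT / "cohort.csv")
    dist = DistanceMatrix.from_csv(OUT / "distance.csv")
    coords = pd.read_csv(OUT / "lens.csv", comment="#", index_col=0)
    lens = LensEmbedding(
        coords=coords.to_numpy(), raw_coords=coords.to_numpy(),
        stress=0.0, patient_ids=[str(i) for i in coords.index],
    )
    graph = build_graph(lens, dist, CoverConfig(), cohort=cohort)
    graph.to_json(OUT / "graph.json")
    graph.to_graphml(OUT / "graph.graphml")

    colors = {
        var: color_graph(graph, cohort, var)["value"]
        for var in ("ct_brain_pathology", "ptsd_dx_6m", "gose_3m", "gose_6m")
    }
    pd.DataFrame(colors).to_csv(OUT / "node_colors.csv", encoding="utf-8")

    sizes = [len(n.member_ids) for n in graph.nodes]
    print(f"syndromic map: {len(graph.nodes)} nodes, {len(graph.edges)} edges")
    print(f"node sizes: median {pd.Series(sizes).median():.0f}, "
          f"max {max(sizes)}")
    ct_means = colors["ct_brain_pathology"].dropna()
    print(f"CT-positivity coloring is strongly bimodal: "
          f"{(ct_means < 0.2).mean():.0%} of nodes < 0.2, "
          f"{(ct_means > 0.8).mean():.0%} > 0.8")


if __name__ == "__main__":
    main()
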