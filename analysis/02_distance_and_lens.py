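"""Standardize the 17 CDEs, compute norm-correlation distances, and fit the
2-D stress-minimized MDS lens.

Reads results/cohort.csv; writes results/distance.csv and results/lens.csv.
"""

from pathlib import Path

from syndromap import load_cohort, optimize_lens, pairwise_distances, \
    standardize_columns

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = load_cohort(OUT / "cohort.csv")
    std = standardize_columns(cohort)
    dist = pairwise_distances(std)
    dist.to_csv(OUT / "distance.csv")
    lens = optimize_lens(dist)
    lens.to_csv(OUT / "lens.csv")
    print(f"distances: {dist.n} x {dist.n}, range "
          f"[{dist.values.min():.3f}, {dist.values.max():.3f}]")
    print(f"lens: stress {lens.stress:.1f} after {lens.iterations} "
          f"majorization iterations (coordinates range-scaled to [0, 1])")


if __name__ == "__main__":
    main()
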