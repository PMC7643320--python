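"""Cross-comparison analyses on synthetic data: extended overlap between a
strict DMR set and a relaxed-threshold set, Venn counts of two seeded
phenotype comparisons, and PCA of RPKM depth at DMR windows.

The strict-vs-relaxed self comparison must come out at 100% (every strict DMR
is rediscovered at the looser threshold); two independently seeded phenotypes
share planted positions only by chance, so their Venn overlap is near zero.
"""

import numpy as np

from epidmr import (
    DMRSet,
    SimulationConfig,
    assemble_dmrs,
    extended_overlap,
    group_silhouette,
    pca_rpkm,
    rpkm_matrix,
    simulate_dataset,
    test_all_windows,
    venn_counts,
)


def call(seed):
    genome, truth, matrix = simulate_dataset(SimulationConfig(seed=seed))
    results = test_all_windows(matrix)
    return matrix, results, assemble_dmrs(results)


matrix_a, results_a, dmrs_a = call(seed=1)
matrix_b, results_b, dmrs_b = call(seed=2)

strict = DMRSet("phenoA", dmrs_a[["chrom", "start", "end"]])
relaxed = DMRSet(
    "phenoA_relaxed", assemble_dmrs(results_a, 0.05)[["chrom", "start", "end"]]
)
self_overlap = extended_overlap(strict, relaxed)
print(f"extended overlap, phenotype A strict (p<1e-4) vs its own relaxed "
      f"(p<0.05) set: {self_overlap['percent']:.0f}%")

other = DMRSet("phenoB", dmrs_b[["chrom", "start", "end"]])
venn = venn_counts([strict, other])
print("\nVenn regions (two independently seeded phenotypes):")
print(venn.to_string(index=False))

rpkm = rpkm_matrix(matrix_a)
in_dmr = np.zeros(matrix_a.n_windows, dtype=bool)
for _, reg in dmrs_a.iterrows():
    in_dmr |= (
        (matrix_a.windows["chrom"] == reg["chrom"])
        & (matrix_a.windows["start"] >= reg["start"])
        & (matrix_a.windows["end"] <= reg["end"])
    ).to_numpy()
coords, var = pca_rpkm(rpkm[in_dmr], matrix_a.groups)
print(f"\nPCA at {int(in_dmr.sum())} DMR windows: "
      f"PC1 {100 * var[0]:.0f}%, PC2 {100 * var[1]:.0f}% of variance; "
      f"disease/no-disease silhouette {group_silhouette(coords):.2f}")
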