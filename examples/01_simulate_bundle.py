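"""Generate a synthetic four-genotype proteomics study with ground truth.

The bundle contains everything the pipeline consumes: a log2 intensity
matrix (4 genotypes x 6 replicates) with intensity-dependent missingness,
a scale-free interaction network with dense modules planted on the
foxo-dependent proteins, a small ontology DAG with one term per module, and
1 kb promoters with planted forkhead-motif occurrences.
"""

from foxodep import SimConfig, make_bundle

bundle = make_bundle(SimConfig(n_proteins=2000, seed=1))

gt = bundle.ground_truth
print("planted classes:")
print(gt["class"].value_counts().to_string())

missing_rate = bundle.observed.mask.to_numpy().mean()
print(f"\noverall missingness: {missing_rate:.3f}")
low = bundle.complete.values.to_numpy() < 24
print(
    "missingness below / above 24 log2 units: "
    f"{bundle.observed.mask.to_numpy()[low].mean():.3f} / "
    f"{bundle.observed.mask.to_numpy()[~low].mean():.4f}"
)
print(
    f"\nnetwork: {len(bundle.network_edges)} edges, "
    f"{len(bundle.module_of)} proteins in {len(bundle.module_term)} planted modules"
)
print(f"promoters with planted motif: {int(gt['motif_planted'].sum())}")
# Low-abundance values go missing far more often (left-censoring), which is
# exactly the situation downshifted-normal imputation is designed for.
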