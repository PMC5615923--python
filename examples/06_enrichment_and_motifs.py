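"""Interpret a protein set: elim-Fisher term enrichment, promoter motif
overlap, PCA contribution tails and a directional t-test.
"""

from foxodep import (
    ImputationParams,
    Ontology,
    SimConfig,
    classify_dependency,
    direction_test,
    elim_fisher,
    equivalence_threshold,
    filter_min_valid,
    impute_downshift,
    make_bundle,
    motif_overlap_test,
    pca_contribution_sets,
    run_contrasts,
    scan_promoters,
)

bundle = make_bundle(SimConfig(n_proteins=2000, seed=1))
matrix = impute_downshift(filter_min_valid(bundle.observed, 4), ImputationParams(seed=102))
de = run_contrasts(matrix)
thr = equivalence_threshold(de["interaction"])
calls = classify_dependency(de["CvsA"], de["DvsB"], de["interaction"], thr)
dependent = sorted(calls.index[calls["label"] == "foxo_dependent"])
background = list(calls.index)

# --- ontology enrichment (elim removes explained genes from ancestors) ----
onto = Ontology(bundle.term_parents, bundle.term_genes)
table = elim_fisher(onto, dependent, background, alpha=0.05, min_significant=5)
print("top enriched terms for the dependent set:")
print(table.head(4)[["term", "observed", "expected", "score", "p_elim"]].round(4).to_string(index=False))

# --- promoter motif overlap ------------------------------------------------
hits = scan_promoters({g: bundle.promoters[g] for g in background}, bundle.motif, p_threshold=1e-4)
overlap = motif_overlap_test(hits["gene"].unique(), dependent, background)
print(
    f"\nmotif: {overlap['overlap']}/{overlap['regulated']} dependent genes with promoter hits "
    f"(fraction {overlap['fraction']:.3f}, hypergeometric p = {overlap['pvalue']:.3g})"
)

# --- PCA contribution tails ------------------------------------------------
top, bottom = pca_contribution_sets(matrix.values, dimension=0, q=0.05)
print(f"\nPC1 contribution tails: {len(top)} top and {len(bottom)} bottom proteins")

# --- directional shift of the dependent fold changes -----------------------
t, p, _ = direction_test(de["CvsA"].loc[dependent, "estimate"].to_numpy())
print(f"direction test on dependent log2 FCs: t = {t:.2f}, p = {p:.3g}")
# The planted module terms (TM...) should top the list; roughly half the
# dependent genes carry a planted motif, so the overlap p-value is tiny.
# Planted effects have random signs, so the direction test stays null here.
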