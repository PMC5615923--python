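"""Moderated linear models for the three study contrasts.

Per protein, a one-way model over the genotypes is fit; per-protein variances
are shrunk toward an empirical-Bayes prior, and three contrasts are tested:
the ablation response with foxo (C - A), without foxo (D - B), and the
interaction (C - A) - (D - B), all BH-corrected at FDR 0.1.
"""

from foxodep import (
    ImputationParams,
    SimConfig,
    filter_min_valid,
    fit_group_means,
    impute_downshift,
    make_bundle,
    moderate_variances,
    run_contrasts,
)

bundle = make_bundle(SimConfig(n_proteins=2000, seed=1))
matrix = impute_downshift(filter_min_valid(bundle.observed, 4), ImputationParams(seed=102))

fit = fit_group_means(matrix)
moderation = moderate_variances(fit.s2, fit.df)
print(
    f"variance prior: d0 = {moderation.prior_df:.2f}, s0^2 = {moderation.prior_var:.4f} "
    f"(median raw s^2 = {fit.s2.median():.4f})"
)

de = run_contrasts(matrix, fdr=0.1)
for name, table in de.items():
    print(f"significant in {name}: {int(table['significant'].sum())}")

top = de["interaction"].nsmallest(3, "adj_p")[["estimate", "t", "adj_p"]]
print("\nstrongest interaction effects:")
print(top.round(4).to_string())
# A significant interaction means the ablation response differs between the
# wild-type and foxo-null backgrounds, i.e. the response needs foxo.
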