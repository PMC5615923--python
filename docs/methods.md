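# Methods

`foxodep` implements the statistical chain used to dissect which proteomic
responses to reduced insulin/IGF signalling (IIS) require the FoxO
transcription factor. The study design has four genotypes — wild type (A),
foxo-null (B), insulin-producing-cell ablated (C, the reduced-IIS condition)
and the ablated foxo-null double (D) — measured per tissue as label-free
quantification (LFQ) intensities on the log2 scale, six biological replicates
per genotype. Tissues are analysed independently; one run of this pipeline is
one tissue.

## Synthetic data model

The generator (`foxodep.simulate`) emulates the statistical structure of such
an experiment with complete ground truth.

Per protein *g*, a baseline log2 abundance `b_g ~ Uniform(22, 38)` and a class
in {null, foxo_dependent, foxo_independent, exaggerated} with default
fractions 0.70 / 0.12 / 0.12 / 0.06. Group means are

    A = B = b_g,   C = b_g + delta_CA,   D = b_g + delta_DB

with `|delta| = 1.0` log2 units by default (random sign; any callable
magnitude distribution can be supplied) and

* null: `delta_CA = delta_DB = 0`;
* foxo_independent: `delta_DB = delta_CA` (identical response in both
  backgrounds);
* foxo_dependent: `delta_DB = 0` (full abrogation without foxo);
* exaggerated: `delta_DB = 2 * delta_CA` (stronger response without foxo).

Residuals are i.i.d. Normal(0, 0.3²) — the default residual sd of 0.3 log2
units and effect size 1.0 are the conditions the recovery checks are stated
for. Replicate imbalance is supported through a drop list of sample names.

Missingness is missing-not-at-random: each value is censored independently
with probability `logistic((21.5 − value) × 0.8)`. Against the baseline range
[22, 38] this yields ≈ 4–5% missingness overall, concentrated entirely in the
low-intensity tail (≈ 25% below 24 log2 units, ≈ 1% above). This left-
censoring mechanism is the assumption that justifies downshifted-normal
imputation; the real data's missingness rates are unknown, so these defaults
are plausible rather than fitted.

The auxiliary inputs planted in each bundle:

* **Network** — a Barabási–Albert backbone (heavy-tailed degrees, connected)
  of one node per protein, plus `n_modules` (default 3) dense modules of 12
  nodes filled preferentially with foxo-dependent proteins. Backbone edge
  confidences are Uniform(0, 1); planted module edges Uniform(0.4, 1), so the
  40%-confidence filter keeps every planted edge.
* **Ontology** — a rooted DAG with `n_terms` random terms over up to
  `dag_depth` levels, plus one term per planted module annotated exactly to
  the module's members, so module recovery can be read out as term
  enrichment.
* **Promoters** — 1,000 bp of i.i.d. background sequence per gene, with one
  exact consensus of a FoxO-like forkhead motif (TTGTTTAC; 0.91/0.03 columns)
  inserted for 50% of foxo-dependent genes and 5% of all others.

What the generator does **not** emulate: peptide-level structure, retention
time, between-tissue correlation, intensity-dependent variance trends,
correlated missingness within samples, or annotation noise. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not performance on real mass-spectrometry data.

## Preprocessing

Proteins are kept when at least `min_valid = 4` values are observed in at
least one genotype. Remaining missing cells are imputed per sample column
from `Normal(m − 1.8 s, (0.3 s)²)` where `m`, `s` are the mean and sd of the
column's *observed* values (mean/sd rather than median-based column
statistics, the more common convention). Observed cells are never altered; imputed cells carry an audit mask.
Downstream stages treat imputed values as ordinary values.

## Moderated linear model

Each protein is fit by OLS on the one-way genotype layout (cell means), with
pooled residual variance `s_g²` on `d_g = n − 4` df. Variances are shrunk by
empirical Bayes under the standard scaled-F marginal model: `(d0, s0²)` are
estimated by matching the mean and variance of `log s_g²` to their
theoretical digamma/trigamma expressions, with the trigamma inverse solved by
Newton iteration. When the observed spread of log-variances is at or below
the sampling minimum, `d0 = ∞` and every posterior variance equals the mean
variance. Otherwise

    s_post² = (d0 s0² + d_g s_g²) / (d0 + d_g).

Contrasts `C−A`, `D−B` and `(C−A)−(D−B)` are tested with
`t = cᵀμ̂ / sqrt(s_post² Σ c_j²/n_j)` on `d0 + d_g` df (normal when `d0 = ∞`);
the 95% CI uses the same moderated df, so tests and intervals stay
consistent. Benjamini–Hochberg
adjustment is applied per contrast, with significance at adjusted p ≤ 0.1 by
default. One test cross-checks this whole chain against an independent
R/limma run on a small matrix; the implementation itself is pure Python.
Zero-variance proteins are excluded from moment estimation but still receive
a posterior variance; zero-SE contrasts get p ∈ {0, 1} by convention and an
audit flag.

## Dependency classification

Only C-vs-A-significant proteins are labelled. The margin `t` is the minimum
|interaction log2 FC| among interaction-significant proteins of the tissue,
recomputed for every run. Rules, in precedence order:

1. **foxo_dependent (rule i)** — interaction significant; if the D-vs-B
   response is significant and same-directional, the C-vs-A response must be
   the stronger.
2. **foxo_independent (rule iv)** — interaction significant with a stronger
   same-directional response in the foxo-null background (the exaggerated
   pattern).
3. **foxo_independent (rule iii)** — the interaction 95% CI lies inside the
   closed interval [−t, t] (equivalence).

A protein satisfying a dependent and an independent rule simultaneously is
resolved in favour of the interaction-significance branch and flagged. Two
documented variants are off by default: `allow_abrogation_without_interaction`
labels same-direction, wild-type-stronger responses dependent without
interaction significance (rule ii), and `exaggeration_requires_interaction=False`
lets rule iv fire without interaction significance. Rule ii is off because a
truly foxo-independent protein (equal effects in both backgrounds) satisfies
its strength comparison with probability 1/2 by noise alone, which would make
roughly a third of dependent labels false at equal class prevalences; the
strict interaction-based definition is the one the equivalence margin is
built around. The equivalence CI is the moderated interaction CI (not a
separate responsiveness statistic), and the interval is closed at its
boundaries.

Classifier recovery under the default conditions (|Δ| = 1.0, sd 0.3, n = 6):
sensitivity ≈ 0.96–0.98 for planted dependent proteins, false labelling
≈ 0.03–0.06, exaggerated responders never labelled dependent. Run end-to-end
through MNAR censoring and imputation, sensitivity drops to ≈ 0.71–0.76:
left-censoring genuinely destroys information for low-abundance proteins and
imputation restores completeness, not power. Both figures are recomputed by
`scripts/acceptance.py`.

## Network propagation

The interaction network is filtered to edges with confidence ≥ 0.4, made
simple (self-loops dropped, parallel edges collapsed keeping maximum
confidence), and normalized symmetrically, `W = D^{−1/2} A D^{−1/2}` on the
binary adjacency (confidence-weighted available by flag). The
graph-Laplacian-style normalization is implemented in this degree-symmetric
form because propagating with `I − W` itself would not spread scores. Raw (unadjusted) p-values of the
protein set are mapped as `Y = −log2 p`, with excluded proteins set to p = 1
(score 0), and diffused by

    F ← α W F + (1 − α) Y,   F₀ = Y,   α = 0.8,

iterated until the maximum absolute change falls below 1e-9 (convergence is
guaranteed since the spectral radius of αW is below 1; the fixed point solves
`(I − αW) F = (1 − α) Y`). The topology bias `b` is the same propagation run
on an all-ones input; on any k-regular graph `b = 1` exactly, and in general
it measures how much score a node accumulates from topology alone. Corrected
scores are `F − b`. Scores are deliberately not renormalized between
iterations: that keeps the operator linear and the fixed point well-defined.

The dependent and independent sets are propagated separately; their corrected
profiles are subtracted for the combined view and the per-node
(corrected_dep, corrected_indep) profiles are clustered agglomeratively with
complete linkage on Euclidean distances, cut to a configurable number of
clusters (default 6). scipy's deterministic lowest-index merge order makes clustering reproducible
for a fixed input order; a Newick dendrogram is written for audit.

## Enrichment

*Term enrichment.* One-sided hypergeometric (Fisher) tests over a true-path-
closed ontology. The elim traversal processes terms from the deepest DAG
level upward (lexical order within a level); when a term's elim p ≤ α
(default 0.05), its genes are removed from all ancestors before they are
tested, concentrating signal on the most specific terms. Both classic and
elim p-values are reported, along with the enrichment score
`log2(observed/expected)` where `expected = |term ∩ background| × |sig| / |background|`,
and a reporting flag for terms with ≥ 5 significant genes.

*PCA tails.* Proteins as observations, samples centred, SVD; a protein's
contribution to a dimension is its signed squared share of that component,
with the orientation fixed so the largest-|score| protein is positive. The
top and bottom `q = 0.05` quantile tails are returned (ties at the median go
to the bottom set, so `q = 0.5` partitions the proteins).

*Motif scanning.* PWM log2-odds scores against a 0-order background,
discretized to 1e-3 bins; the null score distribution of a background-
generated word is computed exactly by dynamic programming (convolution of
per-column score distributions), giving exact score p-values. A window is a
hit at p ≤ 1e-4 (both strands, N positions scoring as background). The
promoter window (1,000 bp upstream of the TSS) is the caller's
responsibility. Motif/regulation overlap is a hypergeometric test restricted
to the measured-gene universe, reported with the fraction of regulated genes
carrying a hit. Full FIMO compatibility (higher-order backgrounds, q-values)
is out of scope.

*Direction test.* Two-sided one-sample t-test of a set's log2 fold changes
against zero; zero-variance inputs are flagged degenerate.

## Pipeline, determinism and problem sizes

`run_pipeline` chains simulate → preprocess → de → classify → propagate →
enrich, writing TSV/JSON outputs per stage plus a manifest (seeds, config
hash, row counts) and a summary. All randomness derives from one seed via
fixed offsets, and no output embeds a timestamp, so repeated runs are
byte-identical. Stages can be skipped and reloaded from a previous run
directory. If no interaction protein is significant and no manual `t` is
supplied, the equivalence rule is disabled for the run (logged, `t` recorded
as null) rather than aborting — relevant only for near-null data.

Default problem sizes — 2,000 proteins, ≈ 6,000 network edges, 40 ontology
terms, 1 kb promoters — keep a full run under a few seconds while leaving
every statistical regime (nulls, all three effect classes, hubs, modules)
well populated; the numerical cross-checks use up to 500-node graphs against
dense solves and 4^w enumeration for motif widths ≤ 6.

## Known limitations

* The generator's independence assumptions (residuals, missingness, edges)
  are simplifications; real LFQ data show correlated noise and batch
  structure that the model does not probe.
* The equivalence margin `t` is estimated from the same data it is applied
  to; its sampling variability is not propagated into the calls.
* Elim enrichment depends on the traversal order for equal-depth ties;
  lexical order is a documented convention, not the only defensible one.
* PCA "contribution" has several definitions in the literature; the signed
  squared-share convention used here selects the same proteins as ranking by
  |score| within each sign.
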