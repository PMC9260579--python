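# Methods

`cytonet` re-implements, as a tested library, a complete single-cell
mass-cytometry cohort analysis for intestinal inflammation: immune-subset
identification from per-cell marker intensities, sample-level subset
frequencies, differential abundance with FDR control, co-abundance
correlation networks, LDA-based label transfer with a rejection option,
and sample-level embedding statistics. Because the analysis is validated
end to end on synthetic cohorts, the synthetic-study generator is a
first-class, fully specified component; this note documents both the
generator and the analysis stages, the numerical choices, and what the
passing tests do and do not establish about real data.

## The synthetic-study generator

### Composition model

Each sample's subset composition follows a logistic-normal model with
latent module factors. For subset *k* in sample *s* of subject *j*:

    log a_sk = b_{k,tissue(s)} + u_jk + λ_k f_{s,m(k)} + δ_k·[s inflamed] + ε_sk
    p_s = softmax(log a_s)

* `b_{k,tissue}` — per-subset baseline log-abundance for gut (ileum/colon)
  and blood. Chosen so that gut tissue is dominated by resident/memory
  populations and blood by naive/central-memory ones, every subset keeps a
  mean frequency ≥ ~0.5% in its home tissue, and no single co-varying
  module carries so much mass that compositional closure couples the
  other modules through the denominator (see "Closure" below).
* `u_jk ~ N(0, σ_subj²)`, σ_subj = 0.3 — subject random effect shared
  across a subject's samples; induces the stable within-individual
  composition that sample embeddings should reveal.
* `f_{s,m} ~ N(0, σ_mod²)`, σ_mod = 1.0 — per-sample latent factor shared
  by all members of module *m*, entering through per-subset loadings
  λ_k ∈ [0.55, 0.85]. This is what creates the block-structured Spearman
  matrix the network stage detects. The three residual subsets
  (module "none") share a weaker factor (σ_res = 0.8 with the same
  loadings, within-module ρ ≈ 0.5) so that they form a detectable but
  small cluster: with the qualification rule (≥ 4 members) they are
  found by the hierarchical cut yet never qualify as a network.
* `δ_k` — inflammation effect on log-abundance: +δ for the 11 designed
  enriched subsets (all members of the enriched 21-subset module), −δ for
  the 10 designed depleted subsets (members of the 11-subset depleted
  module), 0 otherwise; δ = 1.0 (≈ 2.7-fold), chosen so that
  inflamed-vs-rest tests at the default cohort sizes have power ≈ 1 for
  true effects while null subsets stay controlled at FDR 5%.
* `ε_sk ~ N(0, σ_noise²)`, σ_noise = 0.3 — independent residual noise.

Cell counts per sample are drawn log-normally around tissue means
(ileum 2,000; colon 1,000; blood 5,000; dispersion 0.35 on the log
scale), with inflamed biopsies 3× larger on average — emulating, at desk
scale, both the study's per-tissue cell yields and the higher immune
infiltrate of inflamed tissue. Subset counts are multinomial given the
softmax composition; marker intensities per cell are Gaussian around the
subset's designed arcsinh-scale mean vector (sd 0.35), truncated at zero
by clipping. Intensities are generated directly on the arcsinh scale
because every analysis stage operates after transformation; raw ion
counts are never needed.

An optional inflammation shift of the module factor means themselves
(`module_shift`) is exposed but defaults to 0: a factor-mean shift would
drag *every* member of the enriched module past the FDR threshold,
whereas the designed condition is that exactly 11 of its 21 members (and
10 of 11 in the depleted module) carry a real effect.

### Cohorts, tissues and designed structure

* Primary cohort: 11 controls, 13 CD, 10 UC on a 36-marker panel.
  Controls contribute noninflamed ileum + colon; each patient an inflamed
  biopsy in the disease-typical tissue (ileum for CD, colon for UC), a
  paired noninflamed biopsy, and a noninflamed biopsy of the other
  tissue — 91 intestinal samples. Every subject also contributes blood.
* Validation cohort: 15 controls and 19 patients on a 39-marker panel
  (three extra channels filled from subset-specific means); same subset
  phenotypes, so label transfer across cohorts is well-posed. No batch
  shift is applied by default (`batch_shift` knob; no principled default
  magnitude exists).
* 44 designed subsets across six lineages (9 CD4 T, 8 CD8 T, 5 TCRγδ,
  7 ILC/NK, 6 B, 9 myeloid), each a near-binary marker template
  (low 0.5 / high 3.5–4.5 arcsinh units, CD45 bright everywhere). Any
  two subsets differ by ≥ 1.5 arcsinh units in ≥ 2 markers — a
  separability guarantee enforced by a validator at config construction.
* Module structure: 21 subsets form the inflammation-enriched module,
  11 the depleted module, 9 naive/central-memory subsets the
  blood-infiltrate module, 3 remain outside.
* Seven internal-control samples replicate one fixed blood composition
  and differ only by multinomial and expression noise, emulating a
  standardized donor aliquot acquired across batches.
* Blood of IBD subjects carries a +2.0 log-abundance spike of the
  activated HLA-DR+CD38+ EM CD4 subset, so blood-to-tissue matching can
  recover a disease-associated circulating population.
* An optional designated "high network-2" patient subgroup
  (`n_high_n2`, off by default) adds an extra shift of the enriched
  effect subsets in those patients' inflamed samples; it exists for
  controlled stratification experiments. With defaults, strong (>50%
  collective) inflamed enrichment already emerges in roughly half the
  patients from the effect shifts interacting with per-sample factor
  noise.

### Closure

Softmax composition makes subset frequencies sum to one, so a module
carrying a large mass fraction and swinging with its latent factor
squeezes all other subsets and induces spurious positive correlations
among them (and negative correlation with itself). The baselines and
loadings are balanced so no module dominates the denominator; residual
closure correlations stay ≈ |ρ| < 0.1, well below the ρ ≥ 0.3
qualification threshold. This is a real property of compositional
cytometry data, not an artifact of the generator.

### What the generator does not emulate

Doublets, beads, dead cells and acquisition drift (removed upstream in
the emulated workflow); batch/technical shifts between cohorts by
default; heavy-tailed or bimodal marker distributions within a subset;
cluster-shape anisotropy (within-subset covariance is diagonal); any
CD/UC compositional difference. Passing tests therefore establish that
the *pipeline logic* is correct under the study's statistical structure
— not that the clustering stage would resolve arbitrarily subtle real
populations, nor that FDR control survives strong unmodeled batch
effects.

## Analysis stages

### Gating and frequencies

An automated CD45 ≥ 1.0 (arcsinh) gate stands in for manual
live/singlet/CD45+ gating: the generator places all immune subsets at
CD45 ≈ 4.5, so the gate retains ≥ 99% of cells, and the threshold is
exposed for data where debris is present. Frequencies are percentages
under two denominators: all assigned cells of a sample (total-CD45 mode)
or the subset's parent lineage. Rejected cells (label transfer) are
excluded from numerator and denominator; the all-cells denominator
variant used for blood matched fractions is a documented flag.

### Pre-processing

"Standard pre-processing" for sample-level analyses is arcsine-square-
root variance stabilization of percentages followed by per-column
z-scoring (constant columns map to zero). Rank statistics (Spearman,
Kruskal-Wallis) are computed on raw percentages — strictly monotone maps
cannot change them, which the suite asserts. t-tests default to
arcsine-sqrt values; a raw-percentage mode exists since the emulated
workflow does not state its choice.

### Subset identification

Interactive hierarchical-embedding clustering is replaced by a
deterministic two-level scheme: (1) lineage assignment by signature
score (mean of required-high markers minus mean of required-low
markers; ties break by a fixed lineage order), (2) per-lineage
full-covariance Gaussian mixtures with the component count chosen by
minimum BIC over k = 1..12 (n_init = 5, fixed seed, reg_covar 1e-4).
The stage is pluggable so an embedding-based backend could be swapped
in. Numerical choices made for tractability on one CPU:

* mixtures are fitted in a per-lineage 12-component PCA space (the
  designed templates are low-rank; d² cost drops ~9×);
* the BIC scan uses a 4,000-cell subsample and stops after three
  consecutive non-improving k; the selected model is refitted on 8,000
  cells and all cells are assigned by maximum responsibility;
* lineages with fewer than 10 × max(k) cells are scanned over a reduced
  k range with a warning.

BIC is preferred over AIC because the desk-scale cell numbers make AIC
prone to splitting clusters to absorb the slight skew that zero-
truncation introduces in low markers. Recovered subsets are matched to
ground truth by Hungarian maximal-overlap assignment; agreement is
summarized by the adjusted Rand index.

### Differential abundance

Welch two-sample t-tests per subset compare inflamed samples against
pooled noninflamed/control samples (the unequal group sizes make the
unequal-variance test the safe default; the pooled-variance variant is a
flag), with Benjamini-Hochberg step-up control at FDR 5% (statsmodels
implementation behind the module surface; a brute-force step-up oracle
verifies it in the tests). Multi-group comparisons use Kruskal-Wallis
with tie correction and Dunn's rank-based post-hoc z-tests, Bonferroni-
adjusted over the pairs — Dunn's classical form; no installed package
provides it, so it is implemented here and checked against hand-computed
rank arithmetic. Samples are treated as independent, as in the emulated
workflow; per-subject repeated measures are *not* modeled — a documented
limitation, partially defended by the FDR-calibration test under the
null generator.

### Correlation networks

Pairwise Spearman ρ over intestinal samples (blood excluded; constant
columns get ρ = 0 with a warning), average-linkage hierarchical
clustering on distance 1 − ρ, and a cut at the k ∈ {2..8} maximizing the
mean silhouette (the emulated workflow states no cut rule; silhouette is
the standard internal criterion). Clusters qualify as networks when they
have ≥ m_min = 4 members and mean within-pair ρ ≥ ρ_min = 0.3 — so a
weak residual cluster is detected but unqualified, and qualification is
monotone in ρ_min by construction. Network numbering is label metadata:
the qualified module with the most significantly depleted members is
network 1, the most enriched network 2, the rest follow by size.
Collective network frequency is the per-sample sum of member-subset
percentages (total-CD45 mode); a patient is stratified as "high
network 2" when any inflamed sample exceeds the 50% collective cutoff.
The edge-list export threshold (default |ρ| ≥ 0.4) is a drawing choice
with no claimed provenance.

### Label transfer

Homoscedastic LDA: class means, pooled within-class covariance
Σ = Σ_k scatter_k / (N − K) regularized by ε·I with ε = 1e-6 × mean
diagonal, empirical priors. Posteriors are computed in log space via
Cholesky solves and log-sum-exp (no overflow for arcsinh-scale values).
A cell is assigned to the argmax class only if its maximum posterior
reaches τ − 1e-6, else rejected; τ = 1 therefore means "posterior
≥ 1 − 1e-6", preserving the 100%-confidence semantics without relying on
floating-point saturation. Because posteriors normalize over known
classes, a cell far from *all* classes can still be confidently
assigned; an optional Mahalanobis χ² flag (0.999 quantile) provides true
novelty rejection. Cross-cohort concordance is the Pearson R over all
flattened (sample, subset) frequency entries; a per-subset variant is a
flag, since the pooling convention is not stated in the emulated
workflow. Blood matched fractions default to the all-CD45+ denominator.

### Sample embeddings and Hotelling T²

Sample-level t-SNE (Barnes-Hut, perplexity 15 for ~100–200 samples,
PCA initialization, fixed seed) on the pre-processed frequency matrix;
replicate QC is the mean silhouette of the internal-control samples
treated as one cluster against all others. PCA provides scores, group
centroids and explained variance; Hotelling's two-sample T² compares
group mean vectors in the pooled-sample PCA score space (d = 2 as
plotted, configurable), with
F = T²·(n₁+n₂−d−1)/(d·(n₁+n₂−2)) on (d, n₁+n₂−d−1) degrees of freedom.
The pooled-projection convention (PCA on all samples, then split) was
chosen over per-group projections for symmetry.

## Problem sizes and determinism

Default studies are desk-scale: ~380k cells per cohort (91 intestinal +
41 blood samples in the primary cohort), chosen so the complete pipeline
— simulation, clustering, networks, transfer, embeddings — runs in a few
minutes on one CPU; cell counts are configurable, and multi-seed
recovery summaries (medians/modes over 20 seeds) are used wherever a
single draw would be noisy. All randomness flows through explicit seeds
(`numpy.random.default_rng`); two runs with the same config and seed are
bit-identical, which the suite asserts.

## Known limitations

* The consolidation of fine-grained partitions into final subsets in the
  emulated workflow is undocumented; the generator defines the 44-subset
  truth directly and the clustering stage is evaluated against it.
* Blood cells share the intestinal subsets' phenotypes, so blood-to-
  tissue matching rates are high by construction; the near-total
  rejection of blood cells observed on real tissue-trained classifiers
  would require blood-specific phenotype variants the generator does not
  model.
* FrequencyMatrix rows from very small samples are noisy; no shrinkage
  is applied before correlation analysis.
* The Dunn adjustment is Bonferroni over pairs; other multiplicity
  schemes for the post-hoc are not implemented.
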