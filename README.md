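# cytonet

Immune-subset discovery and co-abundance network analysis for mass-
cytometry (CyTOF) cohort studies of intestinal inflammation — from
per-cell marker matrices to subset identification, differential
abundance with FDR control, correlation-network modules, cross-cohort
label transfer, and sample-level embedding statistics. A fully
ground-truthed synthetic-study generator makes every stage testable
end to end without any data download.

## Who this is for

Computational immunologists and cytometry bioinformaticians who need a
scripted, reproducible version of the now-standard "cluster, count,
correlate, classify" tissue-cytometry workflow: gated CD45+ cells from
paired intestinal biopsies (inflamed/noninflamed) and blood of IBD
patients and controls, analyzed across two cohorts.

## The analysis in brief

1. **Subset identification.** Cells are assigned to six immune lineages
   (CD4 T, CD8 T, TCRγδ T, ILC/NK, B, myeloid) by marker-signature
   scoring, then clustered within lineage with full-covariance Gaussian
   mixtures, choosing the component count k by minimum BIC. On the
   default synthetic cohort this recovers the designed inventory of 44
   subsets.
2. **Differential abundance.** Per subset, Welch t-tests compare
   inflamed versus pooled noninflamed/control samples on arcsine-√
   percentages, with Benjamini–Hochberg control at FDR < 5%:
   q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j.
3. **Correlation networks.** Spearman ρ between subset frequencies over
   intestinal samples; average-linkage clustering on 1 − ρ with a
   silhouette-chosen cut. Clusters with ≥ 4 members and mean within-pair
   ρ ≥ 0.3 qualify as networks; collective network frequency is the
   summed % of CD45+ cells over a network's members, and patients are
   stratified by whether an inflamed sample exceeds 50% collective
   frequency of the inflammation-enriched network.
4. **Label transfer.** A pooled-covariance LDA (class means μ_k, shared
   Σ, priors π_k) trained on the clustered primary cohort assigns
   validation-cohort and blood cells via posteriors
   p(k|x) ∝ π_k·exp(−½(x−μ_k)ᵀΣ⁻¹(x−μ_k)), abstaining when the maximum
   posterior is below a threshold τ (τ ∈ {0.95, 1}).
5. **Sample embeddings.** t-SNE / PCA of preprocessed frequency
   matrices, replicate QC by silhouette of internal-control samples, and
   Hotelling's two-sample T² on PCA scores:
   T² = (n₁n₂/(n₁+n₂))·(x̄₁−x̄₂)ᵀS⁻¹(x̄₁−x̄₂).

The synthetic generator draws per-sample compositions from a
logistic-normal model with latent co-varying modules (one depleted and
one enriched in inflamed tissue, one blood-infiltrate), subject-level
random effects, and replicate internal controls; see
[`docs/methods.md`](docs/methods.md) for the model and all defaults.

## Worked example

```sh
cytonet demo --out-dir demo_report --seed 42
```

regenerates the full synthetic two-cohort study and runs every stage
(~6 minutes on one CPU). The summary it printed:

```json
{
  "n_subsets_recovered": 44,
  "clustering_ari": 0.9995312790162738,
  "n_qualified_networks": 3,
  "network_sizes": [21, 9, 11],
  "da_n_significant": 21,
  "up_in_largest_module": 11,
  "patients_flagged": "16/23",
  "transfer_concordance_R": 0.9999962226084678,
  "blood_matched_fraction": {"0.95": 0.9999, "1.0": 0.9976},
  "ic_replicate_silhouette": 0.9639302191077025,
  "hotelling": {"t2": 39.98, "f": 19.76, "df": [2, 88], "p": 8.14e-08},
  "gate_retained_fraction": 1.0
}
```

Reading it: the two-level clustering recovered all **44** designed
subsets (adjusted Rand index 0.9995 against ground truth); the
correlation stage found exactly **3** qualified networks of **21**, 11
and 9 subsets plus an unqualified residual cluster; **21** subsets
changed significantly with inflammation at FDR < 5%, **11** of them
up-regulated members of the enriched 21-subset network; 16 of 23
patients had an inflamed sample dominated (> 50% of CD45+ cells) by that
network; label transfer to the held-out validation cohort reproduced
the subset frequencies with Pearson R > 0.999; the seven internal-
control replicates formed the tightest group in the sample t-SNE
(silhouette 0.96); and inflamed-versus-rest sample groups separated in
PCA space with Hotelling T² p ≈ 8×10⁻⁸.

The same stages are available as library functions
(`cytonet.simulate_study`, `cluster_within_lineage`,
`ttest_inflamed_vs_rest`, `extract_modules`, `fit_lda`,
`hotelling_t2`, …) and as CLI subcommands (`simulate`, `preprocess`,
`cluster`, `abundance`, `network`, `transfer`, `embed`, `report`).

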