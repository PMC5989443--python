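# drivernmf

Prioritizing mutated cancer **driver genes** from binary somatic-mutation
profiles by a robust, sparse **co-regularized nonnegative matrix
factorization** that folds in two sources of prior information: sample–sample
similarity derived from mRNA expression, and a gene–gene interaction network.

## The problem

Tumour sequencing yields, for a cohort of n samples and p genes, a binary
matrix X ∈ {0,1}^{n×p} marking which genes carry somatic mutations in which
samples. Most of those mutations are passengers; the drivers — genes whose
mutation confers a growth advantage — are often mutated at low frequency and
cannot be separated from passengers by recurrence alone. Two widely available
side-channels help: drivers cluster in interaction-network neighbourhoods,
and tumours with similar expression programmes tend to share driver biology.

## The model

`drivernmf` factorizes X ≈ U Vᵀ with nonnegative factors U ∈ R₊^{n×K}
(sample representations) and V ∈ R₊^{p×K} (latent mutation profiles over
genes), minimizing

```
‖X − UVᵀ‖²_F + λ_LU Tr(Uᵀ L_W U) + λ_RU ‖U‖²_F
            + λ_LV Tr(Vᵀ L̂_Â V) + λ_RV Σ_k ‖v_{*,k}‖₁²
```

where

* **W** is the sample-similarity kernel W_ij = exp{−(1−ρ_ij)²/(2σ²)} built
  from pairwise expression correlation ρ (bandwidth σ = 1), with
  un-normalized Laplacian L_W = D_W − W;
* **Â** = D_A^{−1/2} A D_A^{−1/2} is the symmetrically normalized network
  adjacency with normalized Laplacian L̂_Â = I − Â (the normalized degree
  matrix reduces to the identity);
* the Frobenius penalty on U guards against a few samples dominating the
  reconstruction, and the squared-L1 penalty on each column of V drives most
  gene coefficients to zero, matching the expectation that few genes are
  drivers.

The objective is minimized by alternating multiplicative updates that
preserve nonnegativity and never increase the objective; with all λ = 0 they
reduce to classical Lee–Seung NMF. Defaults are K = 4 and
λ_LU = λ_RU = λ_LV = λ_RV = 1. Each gene's **mutation score** is the
maximum of its K coefficients (max over latent profiles, so a driver active
in one subtype still scores high), and genes are ranked by that score.

Ablation variants zero out parts of the objective: `only_network`
(λ_LU = λ_RU = 0), `only_expression` (λ_LV = λ_RV = 0) and `no_prior`
(plain NMF), allowing the contribution of each prior to be measured.

## Worked example

The built-in simulator plants subtype-specific driver modules in a cohort
(100 samples × 300 genes, 3 subtypes × 10 drivers by default) so the whole
pipeline can be exercised without external data:

```python
import drivernmf as d

cohort = d.generate_cohort(d.SimulationConfig(seed=42))
data = d.align_datasets(cohort.mutation, cohort.expression, cohort.network)
res = d.CoRegularizedNMF.from_dataset(data).fit()
print(res.summary())
```

```
Co-regularized NMF results
==========================================
samples (n):        100
genes (p):          300
latent dims (K):    4
lambda LU/RU/LV/RV: 1/1/1/1
iterations:         159
converged:          True
final objective:    744.072
------------------------------------------
top genes by mutation score:
    1  g275             0.107831
    2  g230             0.0553821
    3  g130             0.0485092
    ...
```

Evaluating the ranking against the planted truth:

```python
curve = d.precision_recall(res.ranking(), cohort.true_drivers)
print(f"planted-driver PR-AUC: {d.pr_auc(curve):.3f}")
enr = d.fisher_enrichment(d.top_k(res.ranking(), 50), cohort.true_drivers,
                          data.mutation.gene_ids)
print(f"top-50 overlap: {enr.overlap}/30  (p = {enr.p_value:.3g})")
```

```
planted-driver PR-AUC: 0.901
top-50 overlap: 28/30  (p = 1.6e-23)
```

The PR-AUC sweeps precision = TP/r against recall = TP/positives over every
cutoff rank r; the enrichment p-value is the one-sided Fisher's exact
(hypergeometric upper-tail) probability of drawing that many true drivers in
the top 50 by chance.

The same pipeline is available from the shell for on-disk TSV inputs
(mutation matrix, expression matrix, edge list, gene lists):

```
drivernmf simulate --outdir sim --seed 42
drivernmf discover --mutation sim/mutation.tsv --expression sim/expression.tsv \
                   --network sim/network.tsv --outdir run --seed 0
drivernmf evaluate --ranking run/ranking.tsv --benchmark sim/true_drivers.txt \
                   --outdir eval --cutoffs 50,100,150,200
```

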