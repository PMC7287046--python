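# drugatlas

Tools for mapping drug-effect relationships across cancer cell-line panels
and using those maps to predict and score drug-combination synergy.

The package is aimed at computational pharmacologists working with
pharmacogenomic screens (drug × cell-line AUC/IC50 panels, checkerboard
viability matrices, curated synergy annotations). It implements one idea
end to end: two drugs are good combination candidates in a cell line when
their *effects are dissimilar* (they hit independent survival processes)
and the line is *sensitive to both* — especially when one of them targets a
gene that is mutated or amplified in that line.

## What it computes

**Drug distance.** Each drug's effect vector is 1 − AUC over the cell
lines. The dissimilarity of drugs *i, j* is 1 − cos α of their effect
vectors on shared lines. The dissimilarity matrix is clustered (Ward.D2 or
average linkage) and the drug distance *d(i, j)* is the cophenetic
distance: the merge height of the pair's lowest common ancestor, optionally
normalized by the root height so *d* ∈ [0, 1]. Clustering quality is
reported as the cophenetic correlation

c = Σ_{i<j} (x(i,j) − x̄)(t(i,j) − t̄) / √[Σ(x − x̄)² · Σ(t − t̄)²].

**Drug atlas.** The dendrogram is flattened into a 2-D Voronoi treemap:
branches merging below a grouping threshold *b* form top-level regions,
each region is split recursively along the tree by an additively weighted
centroidal Voronoi (power-diagram) iteration until cell areas are
weight-proportional, and border thickness encodes the cophenetic distance
of the separating split.

**Sensitivity.** log2 IC50 values are normalized per (tissue, drug) stratum
so the stratum average is 1 (S = 1 + Δlog2 IC50; S < 1 = more sensitive
than the tissue average), or min–max scaled to [0, 1] over a panel. The
targeted variable is T = 1 when a drug's target gene is affected in the
line, 0.01 otherwise.

**Synergy models.** With t = max(T_i, T_j), four nested logistic models are
fitted per tissue with balanced negative resampling (all positive rows plus
an equal random draw of negatives, iterated):

    IA :  logit(θ) = α + β t
    IB :  logit(θ) = α + β t + δ d
    IIA:  logit(θ) = α + β t + γ (S_i + S_j)
    IIB:  logit(θ) = α + β t + δ d + γ (S_i + S_j)

plus the closed-form score θ = t·e^d / (1 + t·e^d) and a linear objective
C[−s·S̄ + d·D₁₂ + t·ΣT] as diagnostics. Comparing IB vs IA and IIB vs IIA
by ROC AUC quantifies the added value of the distance covariate.

**Combination index.** Checkerboard plates are scored per dose cell with
the n-drug median-effect combination index

    CI = [Σ_k 1/V_k − (n − 1)/100] / (1 / V_comb),

viabilities in percent; CI < 0.8 is synergy, ≈ 1 additive, > 1 antagonism.
The secondary CI treats a (k−1)-drug combination as one agent to score the
k-th drug on top. Bliss and HSA excesses are provided as reference
metrics. Dual synergies form a graph whose triangles (k-cliques) are
ranked multi-drug candidates.

A full synthetic-data generator (`drugatlas.simulate`) plants the
process/co-vulnerability mechanism with known ground truth and emulates
every input: response panels, mutations, targets, synergy labels and
checkerboard plates.

## Worked example

```python
import drugatlas as da

cfg = da.SimConfig(seed=1)                     # 4 processes x 8 drugs, 60 lines
panel = da.generate_panel(cfg)

d = da.cosine_dissimilarity(panel.response)
tree = da.cluster_drugs(d, method="ward_d2")
print(f"cophenetic correlation c = {da.cophenetic_correlation(d, tree).c:.3f}")

atlas = da.layout_voronoi_treemap(tree, seed=1)
print(f"atlas: {len(atlas.cells)} cells, worst area error "
      f"{atlas.achieved_tol:.2%}")

table, feats = da.generate_labels(panel)
fit = da.SynergyLogit(feats, model="IIB").fit(n_resamples=100, seed=1)
print(fit.summary())

res = da.combination_index([50.0, 50.0], 25.0)
print(f"CI = {res.ci:.2f} -> {res.classification}")
```

Output:

```
cophenetic correlation c = 0.959
atlas: 32 cells, worst area error 0.31%
Synergy logistic model IIB
  rows: 29760   positives: 11433
  balanced resamples: 100   ridge fallbacks (separation): 0

  coef            mean   resample sd
  alpha        -1.4640        0.0266
  beta          1.9678        0.0184
  delta         2.9099        0.0411
  gamma        -0.9795        0.0061
CI = 0.75 -> synergy
```

c near 1 says the tree distances faithfully represent the cosine
dissimilarities. The fitted β, δ, γ sit close to the generator's (2, 3, −1)
— targeting and distance raise synergy odds, insensitivity lowers them (α
is shifted by the balanced case–control sampling and is not comparable to
the generating intercept). The dose point (50%, 50%) → 25% is exactly the
Bliss-independence surface, which the median-effect index scores at 0.75,
below the 0.8 synergy threshold.

The same steps are available from a shell:
`drugatlas simulate | distances | build-atlas | fit-model | predict |
score-ci | multidrug | report` (see `drugatlas --help`).

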