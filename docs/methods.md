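# Methods

## Model overview

The package operationalizes one mechanistic picture of drug-combination
synergy. Tumor cell populations survive through a small number of
semi-independent processes; a drug that works in a given cell line does so
by hitting a process that line depends on. Two drugs whose response
profiles across a large cell-line panel are *dissimilar* are evidence that
they act on different processes, and a cell line that is *sensitive to
both* drugs is co-vulnerable: knocking out two independent survival routes
at once is the proposed substrate of synergy. Mutation data sharpen the
picture — a drug whose annotated target gene is mutated or amplified in
the line ("targeted") is more likely to be acting on a genuine dependency.

Everything downstream is a quantification of that sentence: a drug-pair
distance (effect dissimilarity), a per-line sensitivity pair, a targeted
indicator, logistic models combining them into a synergy probability, and
a combination index that scores whether a measured checkerboard actually
shows more killing than independence.

## Drug distance

Effect vectors are 1 − AUC per cell line (AUC in [0, 1], 0 = maximal
response, so 1 − AUC is "how much the drug did"). Pairwise dissimilarity
is 1 − cosine similarity on the cell lines where both drugs were measured;
pairs sharing fewer than `min_overlap` (default 5) lines are left missing
and imputed by the matrix median only at the clustering step (imputation
is logged, never silent). Cosine geometry needs a direction: an all-zero
effect vector is rejected rather than silently assigned a distance.

The dissimilarity matrix is always the clustering input. Two linkages are
exposed: `ward_d2` (scipy's distance-input Ward, the default for distance
analyses) and `average` (UPGMA, the default for the map layout). Leaves
are sorted lexicographically before linkage, which makes the merge set
invariant under input row order and reproducible across platforms.

The drug distance used everywhere downstream is the *cophenetic* distance:
the merge height of the two leaves' lowest common ancestor. By default it
is normalized by the root height so d ∈ [0, 1] — this makes distances
comparable across datasets and usable directly as a bounded regression
covariate; raw heights are available via `normalize=False`. Whether
to normalize before regression is genuinely open; both modes are exposed
and the normalized form is the package default. Cophenetic matrices are
exactly ultrametric, which the test suite asserts on every triple, and the
implementation is cross-checked against an independent union-find
merge-height oracle. Clustering quality is summarized by the cophenetic
correlation coefficient, computed by the explicit product-moment formula
over all i < j pairs (and verified against a textbook Pearson routine to
1e-12).

Target-level distances average the drug-level cophenetic distances over
all cross pairs of drugs carrying the two targets (identical-drug pairs
excluded; a target pair with no valid cross pair stays missing). Pathway
analyses split pairwise distances into within- and between-ontology-group
sets after removing drugs flagged cross-reactive over multiple pathways.

## Atlas layout

The dendrogram is flattened into a 2-D map by recursive weighted
centroidal Voronoi tessellation:

1. A grouping threshold b is the merge height at which the cumulative
   fraction of merges (from the leaves) first reaches `depth_fraction`
   (default 0.25; the right fraction is a presentation choice, not a
   statistical one). Branches merging strictly below b become top-level
   groups.
2. Groups are ordered by decreasing attach height and their initial sites
   are seeded at maximally separated container-boundary points, so the
   earliest-diverging branches land at the rim ("corners") — with a
   circular container, corners become rim positions.
3. Each region is partitioned by an additively weighted Voronoi (power)
   diagram iterated with Lloyd centroid moves and additive per-cell weight
   adaptation (w_i += 0.7·(target_i − area_i), recentred each step) until
   every cell is within tolerance of its weight-proportional target area.
   Cells are computed by clipping half-planes
   2(p_j − p_i)·x ≤ |p_j|² − |p_i|² + w_i − w_j against the convex region,
   which yields the same diagram as the classical 3-D convex-hull lift;
   convex regions guarantee convex cells, so the recursion's precondition
   is self-maintaining.
4. Below the top level, regions split along the binary tree (children
   weighted by their leaf-weight sums) down to one cell per drug. A final
   smoothing pass re-relaxes each bottom-level tessellation from its
   converged sites and weights with the site-to-region assignment frozen,
   and keeps the result only when it does not worsen that region's error.

Nested tessellations compound area error multiplicatively down a
root-to-leaf path, so inner tessellations are iterated to
`area_tol / max(8, recursion depth)` and the layout reports the measured
worst *global* leaf-area error (`achieved_tol`); `converged` means the
end-to-end `area_tol` (default 2%) holds. Non-convergence returns the
best-seen layout with a warning, never an exception. Leaf weights are
uniform by default (no per-drug weighting is implied by the method); any
positive map is accepted. All randomness (site initialization via
scrambled Halton, boundary-offset draw) flows from one seeded generator,
so layouts are bit-reproducible given (inputs, seed).

Borders between adjacent cells are annotated with the raw cophenetic
distance of the separating split — siblings get thin borders, root-split
neighbours the thickest. The map is an embedding of an ultrametric into
the plane, which cannot be isometric; the guaranteed property (tested) is
a positive rank correlation between map centroid distances and cophenetic
distances, i.e. the map is an overview, and all quantitative analyses use
the cophenetic distance itself.

## Sensitivity

Raw sensitivities are log2 IC50 (log2 µM). `normalize_tissue` centres them
per (tissue, drug) stratum and stores S = 1 + Δlog2 IC50, so the stratum
mean is exactly 1 and S < 1 means more sensitive than the tissue-typical
response to that drug; this removes tissue-specific dynamic range before
sensitivities are compared or used as covariates. `scale01` min–max scales
per drug over a small analysis panel (0 = most, 1 = least sensitive; a
constant panel has no ordering and returns 0.5 with a warning).

The targeted variable is T = 1 when targets(drug) ∩ affected(line) ≠ ∅ and
T = 0.01 otherwise — the 0.01 (rather than 0) keeps the closed-form score
t·e^d/(1 + t·e^d) strictly positive and encodes "almost no synergy
without a targeted lesion". Amplified genes count as affected whenever the
annotation table lists them; content is the annotation's responsibility.

Dose–response reduction uses log-linear interpolation for the absolute
IC50 (missing when 50% viability is never crossed) and a normalized
trapezoid over log2 dose for AUC. This is a deliberately simple,
documented reduction — four-parameter logistic fitting parity with
commercial curve-fitting software is out of scope. Wildly non-monotone
curves are still reduced but flagged for QC.

## Synergy models

A feature row is one (cell line k, unordered pair i < j): distance d_ij,
sensitivities S_ik, S_jk, targeted values T_i, T_j, their max t, a
data-availability indicator C and the binary label. Pairs are stored
canonically (lexicographic) so duplicate-row ambiguity cannot arise.

Two closed forms are kept as diagnostics: the linear objective
C[−s·S̄ + d·D₁₂ + t·(T₁+T₂)] with a bounded parameter search (no loss
function is implied by the formulation, so it is never used to predict),
and θ = t·e^d/(1+t·e^d), which is algebraically the logistic inverse-link
of d + log t (a property test asserts this identity on a grid).

The four nested logistic models IA/IB/IIA/IIB are fitted by maximum
likelihood (statsmodels) under balanced negative resampling: per tissue,
every positive row plus an equal-size uniform draw of negatives, pooled
and fitted; repeated `n_resamples` times; reported coefficients are means
over resamples. Unlabelled rows may be unknown rather than truly negative
— balanced case–control sampling is the design answer to that (no
positive-unlabelled correction is attempted); it biases only the
intercept, so slope estimates remain consistent. Perfect separation in a
resample falls back to an L2 ridge of 1e-6 (scikit-learn) and is counted
in the results object. A single γ is shared by the two sensitivity
covariates: with per-drug-per-line coefficients the model is
unidentifiable, and exchangeability of the unordered pair forces one
coefficient. The Gaussian error term and σ² that a linear-model reading
of the specification would add are documented fields on the results
object, not estimated — they are non-standard in a logistic likelihood.

Models with sensitivity covariates (IIA/IIB) require both sensitivities
observed; the target/distance models (IA/IB) require at least one (C = 1).
Tissue strata with fewer than 5 positives are skipped with a log message.

Evaluation is rank-based ROC AUC. Cross-validation groups folds by drug
pair (default k = 5) so no pair contributes to both train and test — pair
structure is the dominant leakage risk in this design. The covariate-
contribution analysis fits each nested pair (IA, IB) and (IIA, IIB) on the
same balanced draw per resample and tests ΔAUC > 0 with a one-sided paired
t-test across resamples. Candidate ranking sorts by predicted θ, breaking
ties by larger distance then lexicographic pair.

## Combination index

For n single-agent viabilities V_k and combined viability V_comb (percent
of untreated control):

    CI = [Σ_k 1/V_k − (n−1)/100] / (1/V_comb)

CI < 0.8 synergy, [0.8, 1] additive band, > 1 antagonism. The (n−1)/100
correction hard-wires the percent scale, so inputs that look fractional
(all values ≤ 1.5) are rejected outright. Viabilities at or below 0 are
floored to V_floor = 1% (flagged) to avoid 1/V blow-up near complete
kill. The secondary CI treats a (k−1)-drug combination as one agent and
is by construction `combination_index([V_pair, V_third], V_triple)`; all
three rotations of a triple are computable.

Plate summaries score every full-combination cell against the plate's own
single-agent edges at matching doses; the summary is the mean (median by
flag) over cells whose combined viability lies in [1%, 99%] — outside that
band the index is numerically uninformative. When no cell is in the band
(an all-100% null plate), the summary falls back to all computed cells so
a null plate still reads additive. Bliss excess (product surface) and HSA
excess (best single agent) are reported per cell as reference metrics.
The constants 7.8 (Loewe) and 2.5 (Bliss) are stored solely for
interoperability with external Loewe/Bliss software output; Loewe surface
fitting itself is not re-implemented. The same machinery accepts
normalized tumor-burden ratios (treated/control × 100) in place of
viability for in-vivo use.

Multi-drug discovery builds a graph with an edge for every pair whose
summary CI fell below threshold in ≥ `min_cell_lines` lines (default 1 —
a single supporting line suffices, matching how few lines typically back
any given pair; raise it for stricter support), enumerates k-cliques
exactly (k ≥ 3, node-count guard with warning), and ranks candidates by
ascending mean edge CI. Dual-vs-multi CI agreement is a per-triple Pearson
correlation across cell lines with a one-sided p for r > 0.

## Synthetic data

`SimConfig` defaults define the study conditions: 4 processes × 8 drugs,
60 cell lines over 3 tissues, baseline vulnerability probability 0.35,
driver-mutation rate 0.25 with P(vulnerable | mutated) = 0.9, AUC 0.9
(resistant) dropping by 0.55 when the drug's process is vulnerable,
response noise σ = 0.08, log2 IC50 dropping 3 units in vulnerable lines
(σ = 0.5). These sizes keep the planted structure recoverable (clustering
at the process count reproduces the partition exactly at low noise) while
the full test suite runs in minutes. Labels are drawn from
logit θ = α + β t + δ d + γ(S_i + S_j) with defaults (−2, 2, 3, −1) and a
cross-process indicator smoothed to [0, 1] (0.15 within, 0.85 across,
σ = 0.05) standing in for the distance.

Checkerboards use Hill single-agent curves, twofold dose ladders capped at
the line's IC50, a Bliss product combination surface, and a multiplicative
synergy factor (0.5 on co-vulnerable pairs, 1 elsewhere) with 1%
multiplicative noise. The factor-1 surface must read near-additive under
the CI — with ladders capped at the IC50 the Bliss surface averages
CI ≈ 0.94 over eligible cells — which ties the generator's null to the 0.8
synergy threshold: the generator and the index are calibrated as a pair.

What the generator does *not* emulate: batch/site structure in multi-site
encyclopedias (a loader warning only; no correction is attempted),
off-target pharmacology, dose-dependent synergy shape, resistance
evolution, assay-plate spatial artifacts. Passing tests therefore show the
statistical machinery is correct and the mechanism is recoverable when
present — not that real panels satisfy the mechanism.

## Numerical choices and degenerate inputs

- Linkage ties broken by lexicographic leaf order; merge heights clamped
  monotone against floating-point jitter.
- Missing pairwise distances imputed by matrix median before linkage
  (count logged).
- Cophenetic correlation with constant tree distances returns NaN with a
  warning rather than raising.
- Treemap: half-plane proxies extend 1e3 units; cells below 1e-14 area
  are treated as empty and their sites nudged toward the region centre;
  weights are clipped to the squared region spread.
- CI floor/ceiling: 1% / 99%; percent-scale guard at 1.5.
- Logistic refits under separation use ridge 1e-6; detection is
  non-finite standard errors or |coef| > 50.
- χ² is uncorrected by default (Yates by flag); expected cell < 1 warns
  toward an exact test. Welch (unequal-variance) one-sided t-tests are
  used for distance/sensitivity set comparisons. No multiple-testing
  correction is applied to primary p-values; reports carry a
  Benjamini–Hochberg column for transparency.

## Known limitations

- The atlas is a planar embedding of an ultrametric: only rank-level
  agreement between map distance and tree distance is guaranteed.
- The CI percent-scale guard cannot distinguish a genuinely all-≤1.5%
  viability plate (total kill everywhere) from fractional input; such a
  plate must be rescaled by the caller.
- Balanced resampling calibrates slopes, not the intercept: predicted θ
  values are ranking scores, not absolute synergy probabilities.
- Exact k-clique enumeration is exponential in k; the node cap warns
  rather than truncating silently.
- The acceptance/benchmark quantities are computed on synthetic panels at
  the sizes above; headline numbers from external encyclopedias (e.g.
  cross-validated AUC on curated real data) require those datasets and
  are out of scope here.
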