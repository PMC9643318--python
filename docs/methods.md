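# Methods

This note documents the models and numerical choices behind each stage of
the pipeline, what the synthetic-data generators emulate, and the known
limitations.

## Disease signature selection

The pipeline starts from a differential-expression table (gene, log2FC,
adjusted p) produced upstream by any standard moderated-statistics tool;
differential-expression estimation itself is deliberately out of scope.
Genes pass when adjusted p < 0.05 **and** |log2FC| > 1, both inequalities
strict — a literal reading of the stated thresholds, pinned by boundary
tests (log2FC = 1.0 and p = 0.05 are excluded). The filter is idempotent
and monotone in both thresholds.

The macrophage-association screen computes Pearson r between a gene's
per-sample expression and a cell-type abundance estimate, with the p-value
from the two-sided t-transform at n−2 degrees of freedom. Whether the
"r > 0.3" rule means signed or absolute correlation is ambiguous; the
default is signed (the screen targets positively macrophage-associated
genes), with `mode="absolute"` exposed. Zero-variance input is an error,
never a silent NaN. The multi-method consensus is a support-counting
intersection; support defaults to "all sets".

## Consensus ranking and composite score

Sources are truncated to a common 50-drug cutoff (the most restrictive
source's limit). The prior

    prior = (k/K) · (1 − (mean_rank − 1)/cutoff)

is the package's single normative choice where only a verbal description
("weighting of the average ranking and the number of occurrences") exists:
it is multiplicative in the occurrence fraction and the normalized mean
rank, attains 1 only for a drug ranked first in every source, and is
monotone in both factors. Ties in any sorted output break lexicographically
by drug id, making all outputs byte-deterministic.

The composite score re-implements the weighted-sum contract with the stated
weights (0.45, 0.45, 0.1). The three components are proxies, pluggable via
arguments: activity = consensus prior, functional = |targets ∩ disease
genes| / |targets|, structural = satisfied Lipinski rules / 4 (MW ≤ 500,
logP ≤ 5, donors ≤ 5, acceptors ≤ 10). The external composite-scoring tool
is treated as a black box whose published weights are the only fixed part.

## Chemical redundancy clustering

Fingerprints are hashed circular (Morgan) substructure vectors, radius 2,
2048 bits — the fingerprint family is not fixed by the screening protocol,
so family and length are configurable. Tanimoto similarity is |a∧b|/|a∨b|,
defined as 1 when both vectors are empty (identical absence of features).

Ward linkage is applied to the 1 − Tanimoto distance matrix. This distance
is not Euclidean, so Ward's variance interpretation is formally improper
here; the practice mirrors the common chemoinformatics workflow and is
validated against a from-definition Lance–Williams agglomeration oracle on
random matrices (n ≤ 8, 200 trials). The dendrogram is cut at height
1 − min_similarity on the merge-height (cophenetic) scale — whether the
upstream tool cuts at raw distance or merge height is not recoverable, so
the merge-height convention is chosen and documented. Cluster ids are
1-based, ordered by each cluster's lexicographically smallest member,
making assignments exactly invariant to input order. Representatives are
the highest-composite member per cluster (ties to the smallest id).
Candidates clustered jointly with clinical-trial drugs are flagged
`in_trial` (identical canonical SMILES), `trial_similar` (a trial drug in
the same cluster) or `structurally_specific`.

## Network criticality score

Each compound's signed target set is intersected with a signed reference
set; a shared gene is a `reverse` edge when the directions oppose and a
`mimic` edge otherwise, so Degree_reverse + Degree_mimic always equals the
intersection size (a tested conservation law). The raw score
(rev − mim)/|intersection| lies in [−1, 1]; an empty intersection yields 0
with a logged warning rather than an undefined value, keeping the weighted
score total and deterministic. Normalization divides by the absolute
maximum raw score (the formula's verbal description; a multiplicative
reading cannot land in (−1, 1)). The M2 score is normalized by its own
maximum rather than the BM maximum so both spans are comparable; a flag
(`m2_norm_by_bm`) switches to the alternative reading. The final
DR = 0.3·Score_BM + 0.7·Score_M2.

## Sensitivity stage

Drugs missing in strictly more than 20% of cell lines are discarded.
Remaining gaps are filled by k-nearest-neighbor averaging over cell lines
(k = 5 by default; orientation and k are not fixed by the protocol and are
configurable): distances are root-mean-square differences over jointly
observed drugs after per-drug mean scaling, neighbors tie-break by line id,
donors must observe the drug, and imputed values are clamped to the drug's
observed range (preserving IC50 positivity).

The response model is ridge regression of ln IC50 on expression with an
unpenalized intercept, solved via the centered normal equations; when λ is
not given it is chosen by leave-one-out generalized cross-validation over a
fixed log-spaced grid (10⁻³…10⁴, 15 points) using the SVD identity
GCV(λ) = n·RSS/(n − edf)², edf = Σ s²/(s²+λ) + 1. λ = 0 reduces exactly to
OLS; λ → ∞ predicts the training geometric mean. The upstream package this
contract mirrors performs additional gene filtering/homogenization that is
out of scope here.

A drug is sensitive when its *mean* predicted IC50 in the bone-metastasis
group is strictly below 10 μM (the per-sample alternative is not stated;
the mean is used), and must qualify in every screen (co-occurrence).
Group comparisons use the two-sided Wilcoxon rank-sum test — the protocol
reports only a significance level without naming a test — computed exactly
when the pooled sample is tie-free, else with the tie-corrected normal
approximation.

## Thermodynamics and trajectory statistics

Ki = exp(ΔG/RT) with R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and T = 298.15 K by
default. Published binding tables printing energies to one decimal place
reproduce to ~0.3%, so 1% is the appropriate comparison tolerance. The DCC
matrix uses the scalar-product convention
C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) with frames equally weighted;
zero-variance particles are an error naming the particle. RMSD performs no
optimal superposition (inputs are assumed pre-aligned, as for
post-processed trajectories); RMSF is the per-particle fluctuation about
the time mean; Rg is mass-weighted with uniform masses by default. All
coordinates are in nm.

## Synthetic data

Generators are pure functions of (spec, seed) using an explicitly seeded
PCG64 generator; outputs are byte-identical across runs and platforms, and
every generator returns machine-readable ground truth.

- **DEG tables** plant a differential fraction (default 10% of 2000 genes,
  mean |log2FC| 2.0) whose adjusted p is drawn strictly below 0.05 and
  whose background draws p uniformly on [0.05, 1] — so the stated filter
  recovers the truth set exactly. Real moderated p-value distributions and
  expression covariance are *not* emulated; passing tests demonstrate the
  filter logic, not robustness to correlated noise.
- **Rankings** draw a latent efficacy score per drug (three sources of 50,
  60% core overlap by default); each source ranks latent + N(0, 0.5) noise.
  At zero noise and full overlap the consensus provably recovers the latent
  order; at the default noise the mean Spearman correlation with truth is
  ≈ 0.95.
- **Signatures** give each compound 50 genes sampled from the disease set
  (opposing the disease direction with the compound's recorded reversal
  probability) plus an equal number of off-set distractors.
- **The SMILES library** enumerates a packaged fragment grammar — long-chain
  alkyl/aromatic scaffolds with connector and terminal substituents — and
  plants near-duplicate pairs by chain homologation, which leaves the binary
  Morgan environment set essentially unchanged (pair Tanimoto ≈ 1) while
  unrelated scaffolds stay below 0.5. No external structure catalogue is
  touched.
- **Response matrices** plant sensitive drugs (IC50 uniform on
  [0.05, 9] μM in every line) versus resistant ones ([10, 200] μM), mask
  entries missing-completely-at-random (5% default), and can mask extra
  drugs past the 20% discard boundary.
- **Trajectories** move particle blocks coherently along a shared axis with
  a sinusoidal displacement of amplitude 1 nm, plus isotropic N(0, 0.1 nm)
  noise; two anti-phase half-blocks by default, giving within-block DCC
  ≈ +0.94 and cross-block ≈ −0.94 at the default noise.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: 2000-gene DEG
tables, 60–120 drug rankings, 10–12 compound signatures with 50 shared
genes, 30–60 cell lines × 10–80 drugs, 20 particles × 200 frames, and
100–1000 replicates for the property suites. These sizes were chosen so a
full verification completes in well under a minute while every statistical
claim (recovery rates, imputation wins, rank correlations) remains sharply
separated from chance. The study-scale counts reported for the original
cohorts (hundreds of DEGs, dozens of clusters) depend on proprietary-scale
external retrievals and are intentionally not reproduced; the property
suites verify the same machinery on planted ground truth instead.

## Known limitations

- Ward-on-Tanimoto is a formal impropriety inherited from standard
  chemoinformatics practice (documented above).
- The composite-score components beyond the published weights are proxies.
- The ridge contract omits the upstream tool's gene homogenization steps.
- The synthetic generators emulate marginal structure, not realistic
  covariance between genes, drugs or cell lines.
- Docking, molecular dynamics, pocket detection and allosteric ΔΔG
  prediction are upstream tools whose *outputs* this package consumes.
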