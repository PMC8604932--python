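# Methods

## Model and assumptions

`compnoise` fits, per strain, a hierarchical Poisson–Gamma count model in
which the gene-specific latent fluctuation ρ is integrated out
analytically, giving a negative-binomial likelihood with mean ν_j·μ_i and
dispersion δ_i. The model assumes:

* UMI counts whose sampling noise is Poisson at fixed rate;
* a cell-specific scaling ν_j with prior mean equal to the supplied size
  factor s_j and batch-specific relative variance θ_b — variability that
  differs between biological replicate batches is treated as technical;
* biological over-dispersion δ_i shared across all batches of a strain;
* a smooth mean–dispersion trend log δ = f(log μ) + ε with Gaussian
  residuals. ε (residual over-dispersion) is the noise measure used in
  all downstream comparisons because it is uncorrelated with mean
  expression by construction.

Identifiability notes. Technical noise is only identifiable with at least
two replicate batches; the fit refuses single-batch input. When size
factors are estimated from library sizes of the same data, they already
absorb most cell-level scaling, and θ is correctly driven toward zero;
the technical/biological separation (θ absorbing between-replicate
variability while δ is unchanged) holds when size factors are supplied
externally, and is verified that way in the test suite.

## Inference

Metropolis-within-Gibbs. Per-gene random-walk updates of log μ and
log δ and per-cell updates of log ν are vectorised (each gene/cell is an
independent accept/reject given the conditioning variables); θ_b is
updated per batch; the trend coefficients and residual variance σ² have
conjugate Gaussian/inverse-gamma draws each sweep. ε is recomputed at
every stored draw from the current trend, so trend uncertainty propagates
into the noise comparison. Proposal scales adapt toward a 0.44 acceptance
rate during burn-in only, in windows of 50 sweeps, keeping the post-burn-in
chain a fixed-kernel Markov chain. All randomness flows from one
`numpy.random.Generator(seed)`, so runs are bit-reproducible.

The expensive likelihood term Σ_j Γln(x_ij + r_i) is evaluated once per
distinct count value per gene (UMI counts repeat heavily), which makes a
sweep O(G·N) in cheap log/multiply operations; 300 genes × 600 cells runs
at ≈5 ms per sweep on one core.

Defaults (`ModelSpec`): 20 000 iterations, 10 000 burn-in, thinning 10,
10 Gaussian RBFs with centres spanning the observed log-mean range and
width 1.2× the centre spacing. The basis additionally always contains an
intercept and a linear column so that a purely log-linear mean–dispersion
relationship is represented exactly and ε is exactly zero-mean in that
case; the RBFs capture curvature. Priors are weakly informative:
log μ ~ N(data mean, 5²), trend coefficients N(0, 25), σ² ~ InvGamma(2, 0.5),
log θ ~ N(log 0.05, 2²). Much shorter chains (≈1 000–2 500 iterations)
are adequate at the few-hundred-gene scale of the bundled scenarios and
are what the tests use.

## Size factors

Pooling-and-deconvolution estimates in the scran style: cells are ordered
on a ring by library size, windows of each pool size contribute one
equation (sum of member factors ≈ median ratio of pooled counts to the
average pseudo-cell), low-weight (0.1) anchor equations tie each cell to
its relative library size for full rank, and the sparse system is solved
by least squares and rescaled to mean 1. With pooling disabled the
estimator reduces to library-size factors. Cells with zero total counts
are rejected with a message directing the caller to filter them.

## Differential testing and classification

Posterior draws of independently fitted strains are paired by stored-draw
index (both chains use the same length settings). Tail probabilities use
tolerance bands τ₀ = ω₀ = 0.4 (log₂ fold change; ε distance): a
"change" must exceed a scientifically negligible magnitude, which keeps
microscopic but certain shifts out of the discovery sets. The EFDR
calibration scans probability cutoffs α ∈ {0.50, …, 0.99} (step 0.01) and
picks the α whose achieved EFDR, Σ(1−p_i)·1[p_i ≥ α] / max(1, #disc), is
closest to the 0.01 target, breaking ties toward the stricter cutoff; when
no grid point reaches the target the calibration is flagged
(`on_target=False`) and the closest (largest-α) point is used. An empty
discovery set has EFDR 0.

Call semantics: *MeanChange* means "at least mean change" — a gene with
both significant mean and significant noise counts as MeanChange, never
NoiseOnly; *NoiseOnly* requires significant noise and non-significant
mean. Every tested gene gets exactly one call; genes failing the
expression filter are *Excluded*. For interaction listings, genes with
significant noise regardless of mean are additionally reported under the
wider *NoiseChange* basis.

## Clustering (progressive mode)

Cells of both compared strains are embedded together: log(count/s + 1),
gene-centred (not scaled) full-SVD PCA to 20 components, Euclidean
20-nearest neighbours, shared-nearest-neighbour graph with Jaccard
weights |shared|/|union| (pairs sharing no neighbours get no edge), and
seeded Louvain at resolution 1.0. Per-cluster comparisons run only where
both strains have ≥ 50 cells (the minimum-sample-size skip); the
per-cluster EFDR target is the global target divided by the number of
retained clusters (a Bonferroni-style correction applied to the target
level), and a gene is a candidate when significant in at least one
retained cluster. With one retained cluster containing all cells the code
path is identical to the unclustered analysis.

On generator data with three planted cell-cycle-like phases the defaults
recover the phases with ARI > 0.9 and both strains mix within every
cluster — provided the planted deletion effects are absent or modest. The
headline redundant-pair preset deliberately plants large effects
(40/300 genes at Δε = 2, i.e. ≈7.4× over-dispersion) for test power;
effects that widespread dominate the joint embedding and split clusters
by strain, which is why the phase-recovery and strain-mixing properties
are evaluated on no-effect / modest-effect scenarios. This mirrors the
reason within-cluster ("progressive") results are treated as
clustering-sensitive and reported separately from the all-cells
("conservative") analysis.

## Enrichment and interaction calls

Shared downstream targets of a regulator group are the intersection of
the group members' target sets in the regulation matrix (a regulator
missing from the matrix yields an empty set plus a warning). Enrichment
uses Fisher's exact test, one-sided ("greater") by default since the
hypothesis is enrichment; the 2×2 table is built over the expressed-gene
universe of the specific strain pair, with the target set intersected
with that universe first. Degenerate tables (a zero margin) return p = 1
with a warning. Change genes are labelled *Known* when the (regulator,
gene) edge exists in the evidence-filtered regulation matrix and *Novel*
otherwise; genes called NoiseOnly in every deletion strain of a pair are
flagged as redundancy candidates.

## Synthetic data

The generator emulates a yeast TF-knockout panel: wildtype plus deletion
strains, 6 separately constructed replicates of 100 cells each per strain
(defaults), log-normal baseline means (log μ ~ N(1, 1), i.e. typical
means of ≈3 counts/cell), trend log δ = −0.8 − 0.5·log μ with residual
sd 0.5, per-replicate technical θ_b ~ U(0.01, 0.05), size factors
log-normal (sd 0.2), three equiprobable phases with 10% marker genes
multiplied by U_log(2, 4) in their phase. Planted effects: mean changes
|log₂FC| = 1.5 with random sign (over-dispersion follows the trend at the
new mean, so ε is untouched); noise-only changes shift ε by +2.0 with μ
exactly unchanged. Effect magnitudes have no empirical anchor — the
source experiments report no quantitative compensation-induced noise
change — and are chosen for testability at the 300-gene scale rather
than realism; real compensation effects are likely smaller and sparser.
Phase multipliers act on the Poisson rate, not on the truth-table μ/δ, so
the unclustered analysis sees genuinely inflated apparent noise for
marker genes.

What passing tests show, and what they do not: the generator draws counts
from exactly the hierarchy the model assumes, so parameter-recovery and
calibration results demonstrate correctness of the inference, not
robustness to model misspecification (ambient RNA, doublets, zero
inflation beyond NB, batch effects other than scaling, and real
cell-cycle programmes are all absent).

## Problem sizes used in the automated checks

Chosen as desk-scale runs: parameter recovery fits 150 genes × 900 cells
(6 batches) with a 2 500-iteration chain; null calibration uses 5 seeds
of 300 genes × 300 cells per strain; planted-effect recovery runs the
full default preset (300 genes, 600 cells per strain, both deletions) at
1 500 iterations; the enrichment-logic replicates use 10 seeds per
scenario at 200 genes × 240 cells per strain; clustering recovery uses
600 cells. The acceptance script repeats these computations from scratch
under a caller-supplied seed.

## Known limitations

* θ is weakly identified when size factors come from the same data's
  library sizes (see above); this matches the intended use, where θ's job
  is to keep batch artefacts out of δ rather than to be interpreted.
* EFDR calibration is per comparison; with very few tested genes the
  achieved EFDR is granular and the target may be unattainable (flagged).
* The progressive mode inherits every instability of clustering; its
  outputs are reported alongside, not merged with, the conservative mode,
  and only the consistency set of both modes should be treated as
  high-confidence.
* GO-term enrichment, paralog discovery, and read-level QC are out of
  scope; the regulation matrix is taken as given (Yeastract-style TSV).
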