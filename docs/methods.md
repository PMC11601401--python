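# Methods

`plaqueniche` implements a distance-anchored analysis of the neuritic
plaque microenvironment in Visium-style spatial transcriptomics and
matched immunofluorescence images, together with a synthetic-data
generator that provides ground truth for every stage. This note records
the models, the parameters that matter, the numerical choices, and what
the synthetic experiments do and do not demonstrate.

## Distance geometry

Every spot is annotated with the Euclidean distance from its centre to
the centre of the nearest plaque in the same section (plaques are treated
as points; no within-tissue geodesics). Spots at most 150 um from a
plaque form the plaque-proximal stratum and spots at least 500 um away
the control stratum, both thresholds inclusive; spots in between are kept
but excluded from contrasts, and spots in plaque-free sections are
flagged separately. Plaques are assigned a cortical layer by an
inverse-distance-weighted vote over the layer labels of spots within
200 um, with the distance floored at 1 um so a plaque lying exactly on a
spot centre dominates without a division by zero. Ties are broken by the
smallest distance to a spot of the tied label, then lexicographically.
The deep/upper plaque-rate ratio pools L4–L6 against L1–L3 plaques per
spot; its two-sided p-value conditions the deep plaque count on the
grey-matter total with expected proportion equal to the deep spot
fraction (exact binomial).

## Preprocessing and layer annotation

Section QC removes sections with median UMI < 2,000, median detected
genes < 1,000, or fewer than 1,000 tissue spots; spot QC removes spots
with fewer than 500 detected genes or 1,000 UMIs. Normalisation is
`log2(count / sf + 1)` with library-size factors scaled to mean 1.
Highly variable genes are ranked by the residual of per-gene variance
from a quadratic fit on the per-gene mean (a deliberately simple
mean-variance trend), and intersected with a supplied marker list.

Dimensionality reduction is PCA on the selected genes followed by
per-section mean-centering of every component. This is the minimal
batch-alignment that preserves the contract "section means agree on every
PC"; it does not model nonlinear batch structure the way diffusion-based
integration methods do, which is acceptable here because the synthetic
batches are additive shifts.

Layer annotation is a Potts-regularised clustering: iterated conditional
modes on

    sum_i ||x_i - mu_{z_i}||^2  -  gamma * sum_{i~j} 1[z_i = z_j]

over the first 35 components (globally rescaled to unit average variance
so that gamma has a data-independent scale), with hexagonal-lattice
neighbours at distance <= 1.2 x pitch, k-means initialisation, and
sequential label updates, which cannot increase the objective for fixed
centroids; centroids are re-estimated each sweep and the objective is
asserted non-increasing. Defaults: k = 7 (six layers plus white matter),
gamma = 2. Cluster naming matches cluster mean profiles to per-layer
signature vectors by Hungarian assignment on the Pearson correlation
matrix, enforcing a one-to-one layer naming. White-matter spots are
excluded from all downstream contrasts.

## Hurdle differential expression

For each gene detected in at least 5% of the pooled plaque/control spots,
a two-part model is fitted to the normalised values: a logistic component
for the detection indicator and a Gaussian component for the level among
detected spots. Both components share the fixed effects status
(plaque/control), cortical layer, and cell detection rate (CDR, the
fraction of the tested gene universe detected in the spot), with a
section random intercept. The status effect is tested by a likelihood
ratio that sums the two components' chi-squares (each clipped at zero)
with summed degrees of freedom; degenerate components (detection
constant, or detected values confined to one stratum, or separation of
the status coefficient) contribute zero with zero df, so the test falls
back to the informative component.

The continuous component is a random-intercept linear mixed model fitted
by maximum likelihood with the variance ratio profiled out (closed-form
GLS per candidate ratio via the Sherman–Morrison structure of the
intercept blocks; 1-D bounded search). The discrete component is a
logistic mixed model fitted by penalised IRLS over the joint fixed and
random coefficients with a Laplace approximation to the marginal
likelihood, maximised over the random-intercept standard deviation on a
bounded log grid with the zero-variance boundary checked explicitly.
With fewer than three sections, or when the variance estimate hits the
boundary, both the full and reduced models switch to section fixed
effects, keeping the LRT nested. Both fitters are verified against
statsmodels (`MixedLM` ML and `Logit`) in the test suite.

The reported log2 fold change is the two-part expectation difference
E[value | plaque] − E[value | control] at the average CDR and the
reference layer, where E = detection probability x conditional mean; when
detection is saturated it reduces to the continuous status coefficient.
FDR is Benjamini–Hochberg across tested genes, and a gene is called only
when FDR < 0.05 *and* |log2FC| > 0.05.

## Deconvolution and enrichment

Reference signatures are per-state means of library-size-normalised
nucleus counts rescaled to counts per nucleus, after removing
uninformative genes (present in < 0.1% of nuclei with nonzero mean
< 1.06) and states below a configurable within-type frequency (e.g. the
5% microglial cutoff). Spot abundances solve a penalised nonnegative
Poisson regression of spot counts on the signature matrix by
multiplicative updates (all spots as one matrix operation), with a soft
quadratic penalty (strength 0.1) pulling the total towards a prior of 4
cells per spot; mitochondrial/ribosomal-style genes (MT-, RPL/RPS,
MRPL/MRPS prefixes, configurable) are excluded beforehand. On disjoint
signature supports the estimator has a closed form matched to 1e-6 in
tests, and against an NNLS oracle to 0.05 on Poisson mixtures.

Abundances are converted to proportions of each state within its major
cell type. Enrichment at plaques fits, per state, a Gaussian linear
mixed model on logit-transformed proportions (clipped at 1e-3) with
status, sex, and layer fixed effects and a section random intercept; the
status coefficient is a log odds ratio, reported also as
100·(exp(beta)−1) "% higher odds", tested by Wald and BH-adjusted across
states. The AD-versus-control variant removes all plaque-proximal spots,
keeps control-stratum spots of AD sections plus all spots of plaque-free
control sections, and replaces spot status with donor AD status.

## Image quantification

Nuclei are segmented from DAPI with a robust-background threshold
(trimmed 5%/5% mean + 2 SD), distance-transform watershed declumping,
and an 18–80 px equivalent-diameter filter. GFAP objects are segmented
after line-structure enhancement (the original image plus white top-hats
with 15 px linear structuring elements at 8 orientations), with fragments
below 10 px diameter merged into any larger object within 10 px and a
10–300 px size window; objects without at least one pixel of nuclear
overlap are discarded. Per-cell MFI is the median pixel intensity over
the object mask. Cells within 100 um of a plaque are proximal, cells at
350–500 um distant, all others excluded. The proximal/distant contrast
on log2 MFI is a mixed model with random intercepts for section and for
the nearest plaque nested within section (statsmodels `MixedLM` variance
components; every cell, including distant ones, maps to its nearest
plaque), falling back to a plaque-only intercept for single-section data.
Because the segmented mask includes the blurred rim of each object, the
absolute MFI sits a few percent below the planted plateau; and because a
brighter cell clears the global threshold over a slightly larger area,
the mask grows with intensity and dilutes its own median ("mask-size
coupling"). The net effect is a modest attenuation of multiplicative
intensity contrasts (about a fifth of a 10% planted increase on the
synthetic images) — a behaviour shared by any intensity-dependent
segmentation, including CellProfiler-style pipelines on real sections.

## Synthetic data: what it emulates, and what it does not

Sections are odd-row-offset hexagonal lattices at 100 um pitch (55 um
spot diameter recorded as metadata), 36 x 16 spots by default, with
horizontal layer bands L1–L6 + WM in fractions
(0.08, 0.10, 0.20, 0.15, 0.20, 0.17, 0.10). Default experiments use four
AD sections (plus optional plaque-free control sections) from four
donors with alternating sex. Plaques follow a Poisson process
(12/section) whose intensity in L4–L6 is `deep_layer_plaque_bias` (2.0)
times the upper-layer intensity and zero in WM.

The reference has 14 states across Exc/Ast/Mic/Oli (including the
plaque-reactive astrocyte analogue Ast.5 and microglial states
Mic.12/13). Marker blocks cover half the 600-gene universe, are drawn
from adequately expressed genes, elevated in the owning state and
suppressed (x0.1) elsewhere — the specificity of curated cell-state
markers. Layer base compositions give each state a Gaussian laminar
affinity (width 0.6 layer units) under major-type budgets (neuron-rich
grey matter, oligodendrocyte-dominated WM), making layers the dominant
axis of spot-level variation, as in cortex. Per-spot compositions are
Dirichlet draws (concentration 30) around the layer base; planted
enrichment multiplies the odds of a state in each affected spot's drawn
composition (within 150 um of a plaque, or section-wide in AD tissue for
the global variant), so the planted log-odds is the exact per-spot
estimand. Counts are negative binomial (dispersion 10) around the
mixture-weighted signature sum at 3.7 cells per spot, with planted
distance-dependent fold changes 2^(effect · exp(−d/decay)); a step
profile (full effect within 150 um) is available and is used when the
estimand of the dichotomous contrast must equal the planted value.
Recovery studies plant effects on adequately expressed genes (pooled
signature mean between 1.2 and 25 counts per nucleus), since the +1
pseudo-count compresses fold changes of near-zero-count genes — a
property of log-normalised counts, not of the test.

Images are 1024 px at 1 um/px with 110 cells: nuclei as Gaussian-blurred
disks (radius 9–13 px), ~55% of cells astrocytes with a GFAP soma
(1.5x the nuclear radius) and three 8 px processes plus SERPINA3 signal,
plaques as disks restricted to the left third of the frame so that both
proximal (<= 100 um) and distant (350–500 um) cells exist, 10% lognormal
intensity variation, planted x1.10 proximal GFAP/SERPINA3 factors,
additive Gaussian noise (sd 3). Cells sit on a jittered grid whose step
budgets the full cell reach (soma + process + blur halo) plus the
worst-case +-4 px jitter, so cells can never touch and zero-noise
segmentation recall/precision is exactly measurable.

Not emulated: curved laminae, spot-swapping or diffusion artifacts,
sequencing reads, segmentation-resistant cell morphologies, overlapping
cells, autofluorescence. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated generative assumptions,
not robustness to all failure modes of real tissue data.

## Desk-scale study sizes and known behaviour

The validation experiments (`plaqueniche.experiments`) use these problem
sizes, chosen to make every recovery property measurable on a single CPU:

- Type-I error: three independent default datasets, ~600 testable null
  genes each, rates pooled (~1,800 gene tests). Per-gene tests within a
  dataset share composition and section draws, so per-dataset rejection
  rates have extra-binomial spread; pooling estimates the true rate,
  which is slightly conservative (≈0.045 at alpha 0.05 across seeds).
- Effect recovery: 30 planted step-profile effects (0.25/0.5/1.0 log2,
  alternating sign) at ~2,000 included spots per dataset (40 x 20 grids,
  8 plaques/section). Each effect size is planted in its own pair of
  replicate datasets, on the ten most-expressed genes: planting strong
  and weak effects together shifts plaque-spot library sizes enough that
  the size-factor offset eats a quarter of a 0.25 log2 effect, and
  low-count genes lose over 20% of a planted fold change to the +1
  pseudo-count alone. The residual systematic bias (~ −8%) is the
  pseudo-count attenuation at realized counts of 10–25 per spot.
- Deconvolution: default sections; mean per-state Pearson r between true
  and estimated within-type proportions ≈ 0.9; noiseless pure spots
  recover their state's proportion to ≥ 0.98 (the soft total-abundance
  prior keeps it marginally below 1).
- Enrichment: 20 replicates of a planted odds ratio 1.5 on Ast.5; Wald
  95% CIs cover the target in ≥ 18/20 with log-scale bias ≈ +0.05; a
  six-section design (4 AD + 2 control) shows the focal/global
  dissociation between the plaque and AD contrasts.
- Clustering: adjusted Rand index vs true layers ≈ 0.98 at gamma = 2.
- Plaque rate: ~240 plaques (60/section) recover the 2.0 deep/upper bias
  within ±0.3.
- Images: one zero-noise image for segmentation fidelity; ten replicates
  of four-section cohorts for the planted 10% proximal MFI increase
  (single images have too few proximal astrocytes for a stable
  per-replicate contrast). The recovered increase sits near 8-9% because
  of the mask-size coupling described above, within the +-3 percentage
  point band around the planted 10%.

## Known limitations

- The Laplace approximation of the logistic mixed likelihood is exact
  only as section sizes grow; with very small sections the LRT inherits
  its error. The section-fixed-effect fallback bounds the damage.
- The logit-Gaussian proportion model ignores the estimation error of
  deconvolved proportions (errors-in-variables attenuates log-ORs by a
  few percent at the default noise level).
- The HVG trend is a quadratic fit, not a loess; for very long-tailed
  mean distributions the residual ranking can differ from scran-style
  trends.
- Potts-ICM is a mode-finding approximation to a full spatial Bayesian
  clustering; it inherits k-means initialisation sensitivity, mitigated
  with 10 restarts under a fixed seed.
- The deconvolution stand-in estimates point abundances only; no
  posterior uncertainty is propagated into the enrichment tests.
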