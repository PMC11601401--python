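# plaqueniche

Distance-anchored analysis of the neuritic plaque microenvironment in
spatial transcriptomics and immunofluorescence data.

Neuritic amyloid plaques are a defining lesion of Alzheimer's disease,
and the transcriptional changes they induce are local: a few hundred
micrometres from a plaque, expression looks normal. `plaqueniche` is a
toolkit for asking, with Visium-style spot data and plaque coordinates
from the same tissue section, *what changes near plaques* — which genes,
which cell states, and with what spatial reach — and for validating the
answer at the protein level in segmented immunofluorescence images. It
is aimed at computational neuropathology groups who have spot-level
count matrices, annotated plaque positions, a single-nucleus reference,
and stained sections.

Every analysis stage is paired with a synthetic-data generator with
known ground truth, so the whole pipeline is testable by parameter
recovery at desk scale.

## The models

**Spot stratification.** Each spot is annotated with the Euclidean
distance d to the nearest plaque in its section; spots with d ≤ 150 um
are plaque-proximal, spots with d ≥ 500 um are controls. Plaques are
assigned a cortical layer by an inverse-distance-weighted vote of spot
labels within 200 um.

**Hurdle mixed-model DE.** For gene g with normalised expression
Y = log2(count/sf + 1), a two-part model is fitted:

    logit P(Y > 0)      = b0 + b1·status + layer + b2·CDR + u_section
    E[Y | Y > 0]        = c0 + c1·status + layer + c2·CDR + u_section

with section random intercepts u. The status effect is tested by a
likelihood ratio summing the logistic and Gaussian components
(chi-square with summed df); the reported log2FC is the two-part
expectation difference P(detect)·E[Y | detect] between strata at the
average CDR. Genes are called at FDR < 0.05 **and** |log2FC| > 0.05.

**Deconvolution and enrichment.** Spot counts y are regressed on
single-nucleus state signatures S by penalised nonnegative Poisson
regression, y ~ Poisson(S a), with a soft prior pulling the total
abundance Σa toward 4 cells per spot. Within-major-type proportions are
logit-transformed and modelled per state by a linear mixed model with
status, sex and layer fixed effects and a section random intercept; the
status coefficient is a log odds ratio. An AD-versus-control variant
replaces spot status with donor diagnosis on plaque-distant spots.

**Layer annotation.** Spots are clustered into 6 layers + white matter
by Potts-regularised ICM on batch-centred principal components:
minimise Σ‖x_i − mu_{z_i}‖² − gamma·Σ_{i~j} 1[z_i = z_j] over the hex
lattice (gamma = 2, 35 PCs, k = 7), then name clusters by Hungarian
matching to layer signatures.

**Image quantification.** DAPI nuclei (robust-background threshold,
watershed, 18–80 px), GFAP objects (oriented top-hat line enhancement,
fragment merging, 10–300 px), GFAP+DAPI+ cells by nuclear overlap;
per-cell median intensities; proximal (≤ 100 um) versus distant
(350–500 um) contrast on log2 MFI with plaque-within-section random
intercepts.

## Worked example

Simulate four AD sections with one planted distance-dependent gene
effect (+1 log2 within 150 um of plaques on gene G0042) and a planted
astrocyte-state enrichment (odds x1.5 for Ast.5 at plaque spots), then
run the DE and enrichment stages:

```python
from plaqueniche import (SyntheticConfig, PlantedEffect, PlantedEnrichment,
                         synthdata, geometry, preprocess, hurdle_de,
                         deconv, enrich)

cfg = SyntheticConfig(
    seed=42,
    planted_de=[PlantedEffect("G0042", 1.0, decay_um=None)],
    planted_state_enrichment=[PlantedEnrichment("Ast.5", 1.5)],
)
data = synthdata.generate_dataset(cfg)
adata = data.concatenated()
preprocess.lognormalize(adata)
adata.obs = geometry.annotate_spots(
    adata.obs.assign(layer=adata.obs["true_layer"]), data.plaques)

table = hurdle_de.run_de(adata)
print(table.head(3)[["gene", "log2fc", "p", "fdr", "significant"]])

est = deconv.estimate_abundance(adata, data.reference)
res = enrich.test_enrichment(est.proportions, adata.obs)
top = res.iloc[0]
print(top["state"], top["log_or"], top["fdr"])
```

Output:

```
 gene   log2fc            p      fdr  significant
G0080 0.476767 2.152009e-07 0.000129         True
G0313 0.438841 6.280638e-07 0.000188         True
G0042 0.293106 1.096218e-06 0.000219         True
top state: Ast.5  log OR 0.634 (88.6% higher odds), FDR 2.83e-07
```

Reading this: the two strongest differential genes, G0080 and G0313,
were never planted directly — they are marker genes of the Ast.5 state,
upregulated at plaques because that state is enriched there. The
directly planted gene G0042 ranks third (its estimate is attenuated by
the +1 pseudo-count of the log-normalisation at modest counts). The
enrichment test then identifies Ast.5 itself as the top enriched state.
This is the signature chain the method is designed to expose: a focal
cell state drags its markers into the plaque-proximal DE list, and
deconvolution attributes the signal to the state.

A thin CLI covers the file-based entry points:

```bash
plaqueniche simulate --seed 1 --outdir sim/ --image
plaqueniche distances --spots sim/S00/coords.tsv --plaques sim/plaques.tsv --out dist.tsv
plaqueniche imagequant --image sim/section_if.tiff --plaques sim/if_plaques.tsv --out cells.tsv
```

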