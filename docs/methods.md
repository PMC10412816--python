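# Methods

This note documents the models, numerical choices and limitations behind
`cyp2d6es`, in the order the pipeline runs them.

## Star-allele model and panel

The panel covers twelve SNPs: the core variants of \*2 (rs16947), \*3
(rs35742686 del), \*4 (rs3892097), \*6 (rs5030655 del), \*9 (rs5030656
del), \*10 (rs1065852), \*17 (rs28371706), \*29 (rs59421388), \*39
(rs1135840) and \*41 (rs28371725), plus the two regulatory-only SNPs
rs5758550 (enhancer) and rs1058164 (exon 3, G/C). Definitions ship as a
versioned YAML config (`data/alleles.yaml`), frozen as defaults but
user-replaceable.

Matching semantics: a definition matches a phased gene copy when all of
its `core` variants are present; specificity counts the observed variants
the definition explains, where `extras` list variants known to co-occur
on the allele (e.g. rs1065852 on \*4) without being required. \*1 is the
empty default. \*17, \*29 and \*41 require rs16947 in core, encoding
their \*2 backbone; rs1135840 (\*39) is recorded but carries no scoring
consequence in any model. \*5 (whole-gene deletion) is never called from
the panel: it is represented as a zero-copy haplotype inferred from CNV
totals (total 1 with a fully homozygous-appearing panel, or total 0),
which is the only information the assay provides.

Variant alleles not explained by any definition (e.g. the \*41 SNP
without its rs16947 backbone) do not invent labels; they are counted and
penalise the phase assignment that strands them (factor 1e-3 each in the
phasing score).

## Phasing and copy number

The wet-lab workflow phases physically; in software, all 2^(h−1) phase
assignments over the h heterozygous sites are enumerated and scored by
the product of the two haplotype frequencies. Frequencies are the
star-label marginals of the packaged cohort diplotype table times
per-star conditional probabilities for the regulatory triple (see LD
below), with conditionals clamped to [0.01, 0.99] so no candidate gets
exactly zero prior mass. Ties break parsimony-first (fewer defining
variants in total), then lexicographically by star label — deterministic
by construction. An exhaustive-enumeration oracle in the test suite
checks the top call on every ≤2-het genotype.

Hybrid genes (CYP2D6/CYP2D7 fusions) are flagged when the intron-6 and
exon-9 probe copies disagree; flagged samples are excluded, not resolved.
For >2-copy samples, each (k, n−k) copy split predicts a variant-signal
fraction k/n at every site heterozygous between the haplotypes; observed
allelic ratios — rescaled by the cohort's mean 2-copy heterozygote ratio,
computed per rsID from at least 5 informative heterozygotes, otherwise
the theoretical 0.5 — pick the split with the smallest summed absolute
deviation. With no discriminating site the extra copies go to the first
haplotype by default and the call is marked ambiguous.

A sample missing any of rs16947/rs5758550/rs1058164 cannot be scored
under models 2–3 and is excluded with a logged reason rather than
imputed.

## Expression scores

Scoring rules are given in the README. Two choices deserve note:

* Model 2 supersedes model 1's label-based 0.5 for \*41: every
  rs16947-bearing allele (\*2, \*17, \*29, \*41) is scored by its
  regulatory pair, consistent with the finding that \*41's apparent
  effect is carried by the enhancer-less (H3) haplotype class it usually
  sits on, not by its own SNP.
* Model 3's 50% reduction applies once per haplotype, after copy-number
  scaling: tandem copies share the haplotype's rs1058164 allele and no
  per-copy compounding rule is established. All shipped scores are exact
  binary decimals (multiples of 0.25), so tests compare them exactly.

## Synthetic cohort

Sampling is at the diplotype level (the published frequency table is the
ground truth and CNV labels live on diplotypes); an HWE-style product
sampler over haplotypes is available via the restricted/override API.
The packaged table carries an explicit `unlisted` remainder row (2 AA
donors) so group totals equal the published cohort sizes (244/123/121)
and every printed percentage reproduces exactly; the sampler skips the
placeholder and renormalises.

Regulatory triples are drawn per star allele under the cohort's LD
structure: every \*1 carries rs1058164 G; rs16947-bearing haplotypes
carry G with probability 0.03 (the observed near-mutual-exclusivity);
\*41 lacks the enhancer with probability 1.00 (EA) / 0.81 (AA); and the
enhancer probability for non-\*41 rs16947 alleles is solved from the
published composition of the enhancer-less class (6.5% / 18.1% of H3
haplotypes lacking \*41 in EA / AA). Enhancer alleles on
non-rs16947 haplotypes were not observed in the cohort, so their default
frequency is 0 — the model-2 score of 2 appears in the scoring universe
and unit tests but not in default cohorts.

**Protein.** Each functional gene copy contributes
`baseline + 72.3·enh − 44.5·rs16947 − 41.8·G` protein units; null
alleles (\*3, \*4, \*5, \*6) contribute 0; extra tandem copies of a
haplotype add only 15% of its single-copy contribution each, following
the observed plateau of measured protein beyond two total copies (the
downstream enhancer is not duplicated with the gene). Gaussian noise is
added and values truncate at zero (truncations are counted; ~1-2% at
defaults, driven by null/null diplotypes whose expectation is zero). On
two-copy, null-free samples the generator reduces exactly to the linear
dosage model, so OLS refits recover the three betas — the basis of the
recovery experiment. The per-copy baseline (115 units) is a free
calibration constant: the cohort's protein scale is arbitrary
(β-actin-normalised) and no intercept is published; 115 places a
single-copy \*1 near the reported single-functional-copy mean.
`protein_noise_sd` = 36 units was calibrated once so the model-1 ES
regression on default 189-donor cohorts explains ≈37% of variance, the
published operating point of the standard model; the model-2/3 R² values
(≈48%/≈71%) then emerge from the structure rather than being targeted.

**Splice.** Two measurement paths are generated with their own published
coefficient sets. Fragment analysis: the log10 skip odds (ΔE3 vs
full-length signal) is linear in the additive dosages of rs1058164 G
(+0.1708), rs16947 (+0.1552) and rs3892097 (−0.2849) plus N(0, 0.30)
noise, with the baseline solved by Brent's method (Gauss–Hermite
quadrature over the noise, exact enumeration over diplotype frequencies)
so the population-mean skip fraction is 0.21; the noise SD was chosen so
the simulated fraction span matches the reported 1%–48% range. qPCR: the
total-normalised ΔE3 ratio uses the qPCR coefficients (+0.419, +0.332,
−0.133) around a baseline of log10(0.68) (the reference-genotype median);
log10 total mRNA carries the enhancer effect (+0.0987). qPCR relative
quantities assume perfect doubling (efficiency 2.0, configurable); zero
or below-detection measurements are excluded with a logged reason, never
imputed, because downstream models work on log10 scales.

Genotype dosages are counted per haplotype side (0/1/2), not per tandem
copy, matching the additive genotype coding of the association models.

## Association stage

OLS goes through statsmodels with an explicit intercept; rank-deficient
designs raise an error naming the collinear columns. Stepwise screening
is forward inclusion of the smallest p < 0.05 (ties by input order, the
documented panel order), then backward elimination of any p ≥ 0.05,
iterated to a fixpoint. A `forced` argument keeps a hypothesis variable
in the model while its covariates are screened; this matters here because
rs1058164 G and rs16947 form a suppressor pair (same-sign effects,
strongly negative dosage correlation), on which unconditional forward
selection stalls in roughly a third of simulated cohorts. Group
comparisons use the pooled-variance two-sample t-test or one-way ANOVA;
correlations are Pearson with t-distribution p-values. No
multiple-testing correction is applied anywhere. The copy-number
saturation analysis (correlations within CNV strata, pairwise t-tests
between copy-number groups) is composed from `pearson_r` and
`group_compare` rather than shipped as a bespoke operation.

Exclusion filters mirror the cohort analyses: the protein-SNP regression
keeps two-copy samples free of null alleles (n=108-equivalent stratum);
the CNV-protein analysis drops samples with a duplicated \*3/\*4/\*6 or
\*41 haplotype or more than four total copies. Every excluded sample
appears in exactly one log row with a machine-readable reason code.

## What the simulations do and do not show

Passing tests demonstrate internal consistency: the pipeline recovers
what the generator encodes (phase, betas, R² ordering) at realistic
sample sizes and noise. They do not validate the scoring models against
real livers — the generator has no rare star alleles beyond the panel,
no genotyping error, no hybrid-gene structural diversity (hybrids are
injected only as discordant probe pairs), treats TF covariates as inert
standardised normals, and encodes the very LD and effect-size structure
the models are designed to exploit. Problem sizes in the shipped
experiments (200 replicates of n=108/189) match the cohort's own strata
sizes and give each rate estimate a binomial standard error of a few
percent.

## Known limitations

* The 12-SNP panel cannot resolve sub-alleles (e.g. \*2 vs \*2.004) or
  rare loss-of-function alleles; unexplained variants are flagged, not
  named.
* \*5 vs a homozygous panel in 1-copy samples is inferred from CNV
  totals alone.
* Model 3's behaviour for a duplicated G-carrying haplotype assumes no
  per-copy compounding (see above); the alternative is one config flag
  away but untested against data.
* The printed qPCR "2.5-fold" for the rs1058164 coefficient 0.419 is not
  10^0.419 (= 2.62); the conversion utility follows the 10^coef
  definition and no check pins the 2.5 figure.
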