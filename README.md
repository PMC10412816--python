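# cyp2d6es

CYP2D6 genotype-to-expression toolkit: star-allele diplotype calling from a
12-SNP panel plus copy-number probes, three expression-score models for
predicting full-length hepatic CYP2D6 protein, splice-isoform
quantification, the accompanying association statistics, and a synthetic
liver-cohort simulator.

## The problem

CYP2D6 metabolizes ~25% of prescribed drugs, and clinical panels translate
its star-allele diplotype into an activity score (AS): 0 for null alleles
(\*3, \*4, \*5, \*6), 0.5 for the reduced allele \*41, 1 for everything
else, summed over both haplotypes and multiplied by gene copy number.
Three frequent regulatory SNPs complicate this picture:

* **rs16947** (the \*2 core SNP) promotes skipping of exon 6; the skipped
  transcript is frameshifted and degraded, lowering full-length mRNA.
* **rs5758550**, a downstream enhancer variant in strong but imperfect LD
  with rs16947, raises transcription and offsets the rs16947 loss.
* **rs1058164 G** — carried by the reference allele \*1 and nearly
  mutually exclusive with rs16947 T — promotes skipping of exon 3, whose
  in-frame product is unstable at the protein level, roughly halving
  full-length protein per G allele.

The package implements an **expression score (ES)** in three nested
variants. For a haplotype *h* with copy number *c*:

* **Model 1** (the AS standard): ES = base(star) x *c*.
* **Model 2**: non-null haplotypes are scored by the
  (rs16947, rs5758550) pair — (+,+) → 1, (+,−) → 0.5, (−,+) → 2,
  (−,−) → 1 — and each extra tandem copy adds only half the base:
  ES = base x (1 + 0.5 (c − 1)).
* **Model 3**: model 2 x 0.5 if the haplotype carries rs1058164 G.

A diplotype's ES is the sum over its two haplotypes; protein is modelled
as `protein ~ ES` by simple linear regression and models are compared by
R². Under model 3 a plain \*1 scores 0.5 — *below* an enhancer-bearing
\*2 — reversing the standard assumption that \*1 is a top-expressing
allele.

Because the underlying liver cohort is not public, the package ships a
simulator that reproduces the cohort's published structure — the
diplotype frequency table (121 EA + 123 AA donors), the regulatory-SNP LD
constraints, CNV rates, the ~21% mean exon-3-skip fraction, and the
published per-allele protein effects (+72.3 enhancer, −44.5 rs16947,
−41.8 rs1058164 G, in β-actin-normalised protein units) — so every stage
is testable end to end.

## Worked example

```sh
python examples/score_expression.py
```

```
haplotype                 model 1  model 2  model 3
*1 (carries G)               1.00     1.00     0.50
*2 + enhancer (H1)           1.00     1.00     1.00
*2 no enhancer (H3)          1.00     0.50     0.50
*41 (on H3)                  0.50     0.50     0.50
*1 duplicated                2.00     1.50     0.75
*4 (null)                    0.00     0.00     0.00
```

`examples/model_comparison.py` simulates a 189-donor cohort and refits
protein on each model's score:

```
model     group     coef          p   R^2 %    n
    1  combined     55.0   2.45e-17    31.9  189
    2  combined     86.7   1.27e-26    45.7  189
    3  combined    113.3   2.68e-54    72.5  189
```

Model 3 explains the most protein variance, model 2 is intermediate and
the AS standard trails — the ordering the regulatory-SNP models were
built to capture. `examples/call_diplotypes.py` and
`examples/splice_quantification.py` demonstrate the calling and
splice-quantification stages; the same stages are available as a shell
pipeline via the `cyp2d6` command (`call`, `score`, `splice`, `evaluate`,
`simulate`, `run`).

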