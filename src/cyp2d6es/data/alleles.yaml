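# CYP2D6 12-SNP panel and star-allele definitions (frozen defaults, v1).
#
# Allele symbols below are the panel's bookkeeping symbols (cDNA-style);
# `ref` is the panel reference symbol, `var` the variant symbol scored by
# the definitions. `del` marks single- or multi-base deletion alleles.
# rs5758550 (downstream enhancer) and rs1058164 (exon 3, G carried by *1)
# are regulatory-only: they never define a star allele but are recorded on
# every haplotype as the regulatory triple.
version: 1
snps:
  rs1065852: {ref: C, var: T}    # *10 core (also on the *4 haplotype)
  rs28371706: {ref: C, var: T}   # *17 core
  rs5030655: {ref: T, var: del}  # *6 core (frameshift deletion)
  rs3892097: {ref: G, var: A}    # *4 core (splice defect)
  rs35742686: {ref: A, var: del} # *3 core (frameshift deletion)
  rs5030656: {ref: AAG, var: del} # *9 core (in-frame K281del)
  rs16947: {ref: C, var: T}      # *2 core (R296C; promotes exon-6 skipping)
  rs1135840: {ref: C, var: G}    # *39 core (S486T; expression-neutral)
  rs28371725: {ref: C, var: T}   # *41 core (intronic, on an rs16947 backbone)
  rs59421388: {ref: G, var: A}   # *29 core (on an rs16947 backbone)
  rs5758550: {ref: G, var: A}    # enhancer variant (regulatory-only)
  rs1058164: {ref: C, var: G}    # exon-3 G allele (regulatory-only; on *1)

# Star-allele definitions. `core` variants are all required for a match;
# `extras` are variants known to co-occur on the allele and count toward
# match specificity without being required. *1 is the empty-definition
# default, *5 is the whole-gene deletion (called from copy number, never
# from the SNP panel).
alleles:
  "*1":  {core: {}, extras: {}, base_es_model1: 1.0}
  "*2":  {core: {rs16947: var}, extras: {rs1135840: var}, base_es_model1: 1.0}
  "*3":  {core: {rs35742686: var}, extras: {}, base_es_model1: 0.0}
  "*4":  {core: {rs3892097: var}, extras: {rs1065852: var, rs1135840: var}, base_es_model1: 0.0}
  "*5":  {core: {}, extras: {}, base_es_model1: 0.0, gene_deletion: true}
  "*6":  {core: {rs5030655: var}, extras: {}, base_es_model1: 0.0}
  "*9":  {core: {rs5030656: var}, extras: {}, base_es_model1: 1.0}
  "*10": {core: {rs1065852: var}, extras: {rs1135840: var}, base_es_model1: 1.0}
  "*17": {core: {rs28371706: var, rs16947: var}, extras: {rs1135840: var}, base_es_model1: 1.0}
  "*29": {core: {rs59421388: var, rs16947: var}, extras: {rs1135840: var}, base_es_model1: 1.0}
  "*39": {core: {rs1135840: var}, extras: {}, base_es_model1: 1.0}
  "*41": {core: {rs28371725: var, rs16947: var}, extras: {rs1135840: var}, base_es_model1: 0.5}
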