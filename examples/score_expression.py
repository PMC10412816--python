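"""Score CYP2D6 haplotypes under the three expression-score models.

Builds a few representative haplotypes (the reference *1, which carries
the exon-3-skipping rs1058164 G allele; *2 with and without the enhancer;
a duplicated *1; and the null *4) and prints their scores. Model 1 is the
accepted activity-score standard; model 2 scores by the rs16947/enhancer
pair with damped copy-number gain; model 3 halves the score of every
G-carrying haplotype.
"""

from cyp2d6es import get_model, haplotype_es
from cyp2d6es.types import Haplotype, RegTriple

HAPS = [
    ("*1 (carries G)", Haplotype("*1", RegTriple(False, False, True))),
    ("*2 + enhancer (H1)", Haplotype("*2", RegTriple(True, True, False))),
    ("*2 no enhancer (H3)", Haplotype("*2", RegTriple(True, False, False))),
    ("*41 (on H3)", Haplotype("*41", RegTriple(True, False, False))),
    ("*1 duplicated", Haplotype("*1", RegTriple(False, False, True), 2)),
    ("*4 (null)", Haplotype("*4", RegTriple(False, False, False))),
]

models = {k: get_model(k) for k in (1, 2, 3)}

print(f"{'haplotype':24s} {'model 1':>8s} {'model 2':>8s} {'model 3':>8s}")
for name, h in HAPS:
    scores = [haplotype_es(h, models[k]) for k in (1, 2, 3)]
    print(f"{name:24s} " + " ".join(f"{s:8.2f}" for s in scores))

print(
    "\nA diplotype's score is the sum of its two haplotype scores; higher"
    "\nscores predict more full-length CYP2D6 protein. Note how model 3"
    "\nseparates *1 (0.5) from an enhancer-bearing *2 (1.0), reversing the"
    "\nstandard model's assumption that *1 is the top-expressing allele."
)
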