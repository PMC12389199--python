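"""Translate star-allele diplotypes to metabolizer phenotypes.

Parses a handful of CYP2C19 and CYP2D6 diplotype strings — including a
gene duplication (x2) and a hybrid tandem (*36+*10) — and prints the
phenotype call, with the CYP2D6 activity score that drives its binning.
"""

from pgxeval import Gene, call_phenotype, load_allele_definitions, parse_diplotype

defs = load_allele_definitions()

cases = [
    (Gene.CYP2C19, "*1/*1"),
    (Gene.CYP2C19, "*1/*2"),
    (Gene.CYP2C19, "*2/*2"),
    (Gene.CYP2C19, "*1/*17"),
    (Gene.CYP2C19, "*17/*17"),
    (Gene.CYP2D6, "*4/*4"),
    (Gene.CYP2D6, "*1/*4"),
    (Gene.CYP2D6, "*1/*41"),
    (Gene.CYP2D6, "*1/*1x2"),
    (Gene.CYP2D6, "*4/*36+*10"),
]

print(f"{'gene':<9}{'diplotype':<14}{'phenotype':<15}activity score")
for gene, text in cases:
    call = call_phenotype(parse_diplotype(text, gene), defs)
    score = "" if call.activity_score is None else f"{call.activity_score:g}"
    print(f"{gene.value:<9}{text:<14}{call.phenotype.value:<15}{score}")

# PM = poor, IM = intermediate, NM = normal, RM = rapid (CYP2C19 only),
# UM = ultrarapid metabolizer. The CYP2D6 phenotype is the binned activity
# score (0 -> PM, <=1 -> IM, <=2.25 -> NM, >2.25 -> UM); CYP2C19 uses the
# allele function-pair lookup.
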