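"""Query the CPIC/DPWG knowledge base for dosing actionability.

Looks up the guideline rule for a few medication/phenotype combinations
and prints the recommendation, dose adjustment and risk flags: the raw
material for both the actionability and the consistency analyses.
"""

from pgxeval import Gene, Phenotype, load_knowledge_base

kb = load_knowledge_base()

cases = [
    ("risperidone", Gene.CYP2D6, Phenotype.PM),
    ("sertraline", Gene.CYP2C19, Phenotype.PM),
    ("sertraline", Gene.CYP2C19, Phenotype.UM),
    ("aripiprazole", Gene.CYP2D6, Phenotype.PM),
    ("aripiprazole", Gene.CYP2D6, Phenotype.IM),
    ("escitalopram", Gene.CYP2C19, Phenotype.RM),
]

for med, gene, pheno in cases:
    rule = kb.rule_for(med, gene, pheno)
    adjust = rule.dose_adjust_percent
    adjust_txt = (
        "-" if adjust is None
        else f"{adjust[0]:g}-{adjust[1]:g}%" if isinstance(adjust, tuple)
        else f"{adjust:g}%"
    )
    print(
        f"{med:<13}{gene.value:<9}{pheno.value:<4} -> {rule.recommendation.value:<27}"
        f"reduce {adjust_txt:<8} adr_risk={rule.adr_risk} "
        f"inefficacy_risk={rule.inefficacy_risk}"
    )

# A non-standard recommendation means the test result is "actionable": the
# guideline would have changed dosing or drug choice preemptively. The risk
# flags drive consistency adjudication — note the exceptions: sertraline
# UM carries no inefficacy risk, aripiprazole IM no ADR risk.
print()
print("medications without a CYP2C19/CYP2D6 guideline are flagged, e.g.:")
print("  methylphenidate ->", kb.lookup("methylphenidate", {}).no_guideline and "no_guideline")
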