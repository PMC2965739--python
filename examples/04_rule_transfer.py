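"""Transferring a regulatory network to a related organism.

Carries Boolean rules across a two-column ortholog map onto a target
metabolic network: rules survive only if the regulated gene and every
regulator it references have orthologs, otherwise the target gene is left
unregulated and the drop is reported.
"""

from geneforce import rules as rl
from geneforce.model import MetabolicModel, Metabolite, Reaction, RegulatoryModel
from geneforce.transfer import transfer_rules

source = RegulatoryModel(
    gene_rules={
        "gA": rl.parse_rule("TF1"),
        "gB": rl.parse_rule("NOT TF2"),
        "gC": rl.parse_rule("TF2 AND S(e)>0"),
        "gD": rl.parse_rule("TF3"),        # TF3 has no ortholog
        "gE": rl.parse_rule("ON"),         # gE itself has no ortholog
    },
    tf_rules={"TF1": rl.parse_rule("ON"), "TF2": rl.parse_rule("S(e)>0"),
              "TF3": rl.parse_rule("OFF")},
)
ortholog_map = {"gA": "oA", "gB": "oB", "gC": "oC", "gD": "oD",
                "TF1": "oTF1", "TF2": "oTF2"}

mets = {"S(e)": Metabolite("S", "e"), "C(c)": Metabolite("C", "c")}
rxns = {"EX_S": Reaction("EX_S", {"S(e)": -1.0}, -1000, 1000),
        "R": Reaction("R", {"S(e)": -1.0, "C(c)": 1.0}, 0, 1000,
                      rl.parse_rule("oA OR oB OR oC OR oD")),
        "Biomass": Reaction("Biomass", {"C(c)": -1.0}, 0, 1000)}
target = MetabolicModel(mets, rxns, "Biomass")

chimera, report = transfer_rules(source, ortholog_map, target)
print(f"transferred {len(report.transferred)}/{report.n_source_rules} rules "
      f"({report.fraction_transferred:.0%})")
for gene, reason in sorted(report.dropped.items()):
    print(f"  dropped {gene}: {reason}")
print("chimeric gene rules:",
      {g: r.to_text() for g, r in sorted(chimera.gene_rules.items())})

# Meaning: 3 of 5 rules carry over under renaming; gD drops because its
# regulator has no ortholog (the target gene stays unregulated rather than
# inheriting partial logic), and gE drops with its gene.
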