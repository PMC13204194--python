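"""Pathway convergence between transcriptome enrichment and miRNA targets.

Loads the shipped table of pathway p-values from the two evidence sides
(transcriptome enrichment of EV-treated cells; over-representation of
predicted EV-miRNA targets) and reports the terms significant in both.
"""

from mircargo import overlap_pathways
from mircargo.datasets import load_convergent_pathways

tab = load_convergent_pathways()
overlap = overlap_pathways(
    tab.rename(columns={"p_rnaseq": "p_value"})[["pathway", "p_value"]],
    tab.rename(columns={"p_mirna_targets": "p_value"})[["pathway", "p_value"]],
    alpha=0.05,
)
print("Venn counts:", overlap.venn)
print("most significant convergent pathways (by transcriptome p):")
print(overlap.common.head(5).to_string(index=False))
# Every pathway returned here passed p < 0.05 on both sides; WNT-related
# terms rank near the top on the transcriptome side.
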