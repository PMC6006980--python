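"""Phylogenetic placement of a query AT among reference ATs.

Aligns the query with the packaged specificity panel (progressive MSA),
builds a neighbor-joining tree from p-distances, bootstraps column
resamples, and reports the class of the smallest pure reference clade
containing the query together with that clade's bootstrap support.
"""

from pksline import classify_at_phylo
from pksline.phylo import at_alignment_and_tree
from pksline.resources import load_at_panel

panel = load_at_panel()
query = panel.class_consensus("methylmalonyl")

call = classify_at_phylo(query, n_bootstrap=100, seed=42)
print(f"placement: {call.specificity}, clade support {call.tree_support:.0f}%")

records = [("query", query)] + [(mid, seq) for mid, _, seq in panel.members]
_, tree = at_alignment_and_tree(records, n_bootstrap=100, seed=42)
print("newick:", tree.to_newick(precision=3))
# Internal-node labels are bootstrap percentages: the fraction of 100
# column-resampled replicate trees containing that bipartition.
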