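"""Read gene-class emergence order off a class-labeled rooted tree.

Classes are ranked by how early their lineage splits from the others
(node depth from the root, ties allowed); monophyly of each class is
checked.  The packaged example topology is a synthetic transcription of
the stated subfamily order B -> CD -> AGL6/E/A, not an inferred tree.
"""

import floralquant as fq
from floralquant.tree_order import parse_labeled_tree

labeled = fq.packaged_example_tree()
order = fq.emergence_order(labeled)
print("packaged example topology:")
print("  ranks:", order.ranks)
print("  emergence order:", order.describe())
print("  all classes monophyletic:", all(order.monophyletic.values()))

# any rooted Newick works; here a small tree with one tip per class
other = parse_labeled_tree("(((A1,E1),AGL6_1),(CD1,B1));",
                           {"A": "A", "E": "E", "AGL6_": "AGL6", "CD": "CD", "B": "B"})
print("alternative topology:", fq.emergence_order(other).describe())
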