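"""Build a somatic-hypermutation lineage tree for an IG clone family.

Constructs a clone family by hand: a germline-configuration root plus
variants at increasing Levenshtein distance, including one orphan two steps
from its closest observed relative (which forces a hypothetical node).
Prints the layered tree and its Newick text.
"""

from lymprofiler import build_lineage_tree, to_newick, validate_lineage_tree

root = "TGTGCAAGAGATCGGGACTACGGTTACTACTTTGACTAC"
v1 = root[:12] + "A" + root[13:]  # 1 substitution from the root
v2 = v1[:25] + "T" + v1[26:]  # 2 steps from the root, child of v1
v3 = root[:3] + "C" + root[4:20] + "G" + root[21:]  # 2 steps, no layer-1 parent
variants = {v1: 14, v2: 6, v3: 3}

tree = build_lineage_tree(root, variants, root_count=40, root_label="germline")
validate_lineage_tree(tree)


def show(node, indent=0):
    kind = "hypothetical" if node.is_hypothetical else f"count {node.count}"
    print(f"{'  ' * indent}layer {node.layer}: {node.label} ({kind})")
    for child in node.children:
        show(child, indent + 1)


show(tree)
print("\nNewick:", to_newick(tree))
print("\nadjacent layers differ by one edit step; HYP nodes stand for")
print("unobserved intermediates on the minimal mutation path")
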