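"""Layered lineage mutation trees for somatically hypermutated IG clones.

Somatic hypermutation diversifies the rearranged IG genes of proliferating
B cells.  A lineage tree summarises the *minimal* mutational steps that
could explain the observed sequences — not the true mutation history.  The
root of each tree is a sequence in the original germline configuration
(zero mismatches to its assigned V and J references); every other clone
within ``max_radius`` Levenshtein steps of the root is placed on the layer
equal to its edit distance from the root.  Adjacent layers differ by one
edit step; where no observed parent one step away exists, unobserved
intermediates are represented by hypothetical nodes, one per skipped layer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import edlib

from .align import ReadAnnotation


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


@dataclass
class TreeParams:
    """``max_radius``: largest Levenshtein distance from the root included."""

    max_radius: int = 10

    def __post_init__(self) -> None:
        if self.max_radius <= 0:
            raise ValueError("max_radius must be positive")


@dataclass
class LineageNode:
    label: str
    sequence: Optional[str]
    count: int
    layer: int
    is_hypothetical: bool = False
    children: list["LineageNode"] = field(default_factory=list)

    def walk(self) -> Iterable["LineageNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class LineageGroup:
    """All clones of one V/J rearrangement group, with its chosen root."""

    v_gene: str
    j_gene: str
    root_sequence: str
    root_count: int
    members: dict[str, int]  # sequence -> count, root excluded


def identify_roots(annotations: Iterable[ReadAnnotation]) -> list[LineageGroup]:
    """Pick one germline-configuration root per (V, J) group.

    Identical oriented read sequences are collapsed with counts.  A sequence
    qualifies as root when its V and J alignments are mismatch-free; among
    several, the most abundant wins (ties: lexicographically smallest).
    Groups with no mutation-free sequence yield no tree.
    """
    groups: dict[tuple[str, str], Counter] = {}
    germline: dict[tuple[str, str], Counter] = {}
    for ann in annotations:
        if not ann.mapped:
            continue
        key = (ann.v_hit.gene_id, ann.j_hit.gene_id)
        groups.setdefault(key, Counter())[ann.sequence] += 1
        clean = (
            ann.v_hit.matched_bases == ann.v_hit.aligned_length
            and ann.j_hit.matched_bases == ann.j_hit.aligned_length
        )
        if clean:
            germline.setdefault(key, Counter())[ann.sequence] += 1
    out: list[LineageGroup] = []
    for key in sorted(groups):
        candidates = germline.get(key)
        if not candidates:
            continue
        root = min(candidates, key=lambda s: (-candidates[s], s))
        members = dict(groups[key])
        root_count = members.pop(root)
        out.append(
            LineageGroup(
                v_gene=key[0],
                j_gene=key[1],
                root_sequence=root,
                root_count=root_count,
                members=members,
            )
        )
    return out


def build_lineage_tree(
    root: str,
    members: Mapping[str, int] | Iterable[tuple[str, int]],
    params: Optional[TreeParams] = None,
    *,
    root_count: int = 0,
    root_label: str = "root",
    labels: Optional[Mapping[str, str]] = None,
) -> LineageNode:
    """Assemble the layered tree for one root and its member clones.

    Members beyond ``max_radius`` are dropped.  A node on layer k attaches
    to an observed layer-(k-1) node at distance 1 (ties: highest count, then
    lexicographic sequence); otherwise it hangs from its nearest observed
    ancestor on a minimal path (the root at worst) through a chain of shared
    hypothetical nodes, one per intervening layer.
    """
    params = params or TreeParams()
    if not isinstance(members, Mapping):
        members = dict(members)
    labels = labels or {}

    root_node = LineageNode(
        label=labels.get(root, root_label),
        sequence=root,
        count=root_count,
        layer=0,
    )
    layers: dict[int, list[LineageNode]] = {0: [root_node]}
    placed: list[tuple[int, LineageNode]] = []
    seq_counter = 0
    for seq in sorted(members, key=lambda s: (-members[s], s)):
        if seq == root:
            continue
        dist = levenshtein(root, seq)
        if dist > params.max_radius:
            continue
        seq_counter += 1
        node = LineageNode(
            label=labels.get(seq, f"n{seq_counter}"),
            sequence=seq,
            count=members[seq],
            layer=dist,
        )
        layers.setdefault(dist, []).append(node)
        placed.append((dist, node))

    def _observed(layer: int) -> list[LineageNode]:
        return [n for n in layers.get(layer, []) if not n.is_hypothetical]

    def _hyp_child(parent: LineageNode, layer: int) -> LineageNode:
        for child in parent.children:
            if child.is_hypothetical and child.layer == layer:
                return child
        hyp = LineageNode(
            label=f"HYP{layer}",
            sequence=None,
            count=0,
            layer=layer,
            is_hypothetical=True,
        )
        parent.children.append(hyp)
        layers.setdefault(layer, []).append(hyp)
        return hyp

    # attach shallow layers first so parents exist before their children
    for dist, node in sorted(placed, key=lambda t: (t[0], -t[1].count, t[1].sequence)):
        parents = [
            p for p in _observed(dist - 1) if levenshtein(p.sequence, node.sequence) == 1
        ]
        if parents:
            parent = min(parents, key=lambda p: (-p.count, p.sequence))
            parent.children.append(node)
            continue
        # nearest observed ancestor on a minimal path; the root always
        # qualifies (its distance to the node is the node's layer)
        ancestor = root_node
        for layer in range(dist - 2, 0, -1):
            cands = [
                p
                for p in _observed(layer)
                if levenshtein(p.sequence, node.sequence) == dist - layer
            ]
            if cands:
                ancestor = min(cands, key=lambda p: (-p.count, p.sequence))
                break
        current = ancestor
        for layer in range(ancestor.layer + 1, dist):
            current = _hyp_child(current, layer)
        current.children.append(node)

    return root_node


def validate_lineage_tree(
    tree: LineageNode, params: Optional[TreeParams] = None
) -> None:
    """Assert the structural invariants of a lineage tree (raises on breach)."""
    params = params or TreeParams()
    assert tree.layer == 0, "root must be on layer 0"
    root_seq = tree.sequence
    assert root_seq is not None, "root must be an observed sequence"
    for node in tree.walk():
        assert node.layer <= params.max_radius
        if not node.is_hypothetical and node is not tree:
            assert levenshtein(root_seq, node.sequence) == node.layer
        for child in node.children:
            assert child.layer == node.layer + 1, "layers must increase by 1"
            if not node.is_hypothetical and not child.is_hypothetical:
                assert levenshtein(node.sequence, child.sequence) == 1


def to_newick(tree: LineageNode) -> str:
    """Newick text: observed nodes as ``label_count``, hypothetical as HYP<k>."""

    def render(node: LineageNode) -> str:
        name = node.label if node.is_hypothetical else f"{node.label}_{node.count}"
        if node.children:
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){name}"
        return name

    return render(tree) + ";"
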