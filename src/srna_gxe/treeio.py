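"""Newick serialization of scipy hierarchical-clustering trees."""

from __future__ import annotations

from scipy.cluster.hierarchy import to_tree


def linkage_to_newick(z, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a rooted Newick string.

    Branch lengths are differences of merge heights, so leaf-to-root path
    lengths equal the final merge height.
    """
    root = to_tree(z)

    def render(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = render(root.left, root.dist)
    right = render(root.right, root.dist)
    return f"({left},{right});"
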