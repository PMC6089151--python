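"""Complete-linkage agglomeration of learned dissimilarities, and cutting.

The merge tree is represented explicitly (leaf ids 0..n-1, internal node
ids n..2n-2 in merge order) so that cuts, serialisation and round-trips are
exact.  Complete linkage is monotone, so merge heights never decrease.

Ties in the minimum inter-cluster distance break toward the smallest
(older, then younger) node id, making the tree a deterministic function of
the input matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .dissimilarity import DissimilarityMatrix
from .exceptions import EaccdError


@dataclass(frozen=True)
class Merge:
    left: int
    right: int
    height: float
    node_id: int


@dataclass(frozen=True)
class Dendrogram:
    leaves: tuple[str, ...]
    merges: tuple[Merge, ...]

    @property
    def n(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])

    def to_json(self) -> str:
        payload = {
            "leaves": list(self.leaves),
            "merges": [
                {"left": m.left, "right": m.right, "height": m.height, "node_id": m.node_id}
                for m in self.merges
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "Dendrogram":
        payload = json.loads(text)
        return cls(
            leaves=tuple(payload["leaves"]),
            merges=tuple(
                Merge(m["left"], m["right"], m["height"], m["node_id"])
                for m in payload["merges"]
            ),
        )

    def to_newick(self) -> str:
        """Newick string; branch length = parent height - child height.

        Children are ordered lower-height (then lower-id) first.  Leaf
        heights are 0, so the tree is ultrametric: every leaf's distance to
        the root equals the final merge height.
        """
        children = {m.node_id: m for m in self.merges}
        node_height = {i: 0.0 for i in range(self.n)}
        for m in self.merges:
            node_height[m.node_id] = m.height

        def name(leaf: int) -> str:
            label = self.leaves[leaf]
            for ch in "(),:; \t\n'":
                label = label.replace(ch, "_")
            return label

        def render(node: int, parent_height: float) -> str:
            length = parent_height - node_height[node]
            if node < self.n:
                return f"{name(node)}:{length:.10g}"
            m = children[node]
            kids = sorted(
                (m.left, m.right), key=lambda c: (node_height[c], c)
            )
            inner = ",".join(render(c, m.height) for c in kids)
            return f"({inner}):{length:.10g}"

        root = self.merges[-1]
        kids = sorted((root.left, root.right), key=lambda c: (node_height[c], c))
        inner = ",".join(render(c, root.height) for c in kids)
        return f"({inner});\n"


@dataclass(frozen=True)
class GroupAssignment:
    """A cut of the dendrogram into k groups.

    ``group_of[i]`` is the 0-based group index of leaf i.  Groups are
    numbered by their smallest leaf index unless ``ordered_groups`` has been
    filled with a risk ordering downstream (index 0 = best survival).
    """

    k: int
    group_of: tuple[int, ...]
    ordered_groups: tuple[int, ...] | None = None


def complete_linkage(d: DissimilarityMatrix | np.ndarray) -> Dendrogram:
    """Agglomerative clustering with maximum inter-cluster distance.

    Raises
    ------
    EaccdError
        If the matrix is not symmetric, has negative entries, or n < 2.
    """
    if isinstance(d, DissimilarityMatrix):
        labels, D = d.labels, d.values
    else:
        D = np.asarray(d, dtype=float)
        labels = tuple(str(i) for i in range(D.shape[0]))
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-10):
        raise EaccdError("complete linkage requires a symmetric square matrix")
    if np.any(D < 0):
        raise EaccdError("complete linkage requires nonnegative dissimilarities")
    if n < 2:
        raise EaccdError("need at least 2 leaves")

    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D[i, j])
    active = list(range(n))
    merges: list[Merge] = []

    for step in range(n - 1):
        best = None
        best_d = np.inf
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                dv = dist[(a, b)]
                if dv < best_d:
                    best_d = dv
                    best = (a, b)
        a, b = best
        new_id = n + step
        merges.append(Merge(left=a, right=b, height=best_d, node_id=new_id))
        for x in active:
            if x in (a, b):
                continue
            da = dist[(min(a, x), max(a, x))]
            db = dist[(min(b, x), max(b, x))]
            dist[(x, new_id)] = max(da, db)
        active = [x for x in active if x not in (a, b)] + [new_id]
        active.sort()

    return Dendrogram(leaves=labels, merges=tuple(merges))


def cut_dendrogram(tree: Dendrogram, k: int) -> GroupAssignment:
    """Groups = connected components after removing the top k-1 merges."""
    n = tree.n
    if not 1 <= k <= n:
        raise EaccdError(f"k must be in [1, {n}], got {k}")

    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in tree.merges[: n - k]:
        for child in (m.left, m.right):
            parent[find(child)] = find(m.node_id)

    roots: dict[int, int] = {}
    group_of = []
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots)  # first-leaf order = smallest leaf index
        group_of.append(roots[r])
    assert len(roots) == k
    return GroupAssignment(k=k, group_of=tuple(group_of))


def cut_at_height(tree: Dendrogram, height: float) -> GroupAssignment:
    """Secondary entry point: cut just above the given dissimilarity level."""
    n_below = int(np.sum(tree.heights <= height))
    return cut_dendrogram(tree, tree.n - n_below)
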