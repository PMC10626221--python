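"""Clonal-hierarchy inference over hematopoietic populations.

Sorted cell populations (plasma cells, myeloblasts, neutrophils, ...) are
scored for binary "characters" — groups of co-occurring aberrations (CNA
groups, SNV groups).  Under the infinite-sites assumption each character
arises once, so a population-by-character 0/1 matrix is consistent with a
rooted clone tree iff the characters' supporting population sets form a
laminar family (every pair nested or disjoint) — the classic binary
perfect-phylogeny condition.  The tree places each character on exactly one
edge; a population's character set equals the union of edge labels on its
root path.  The tree can then be annotated against a hematopoiesis template
(classical or composite) to name the progenitor compartment where each
change plausibly arose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "CharacterMatrix", "CloneNode", "CloneTree", "HematopoiesisTemplate",
    "check_perfect_phylogeny", "infer_clone_tree", "map_to_template",
    "load_template",
]

CELL_TYPES = {"PC", "MB", "neutrophil", "eosinophil", "erythrocyte",
              "megakaryocyte", "lymphocyte", "other"}


@dataclass
class CharacterMatrix:
    """Binary presence of aberration groups across cell populations."""

    matrix: pd.DataFrame  # rows: populations, columns: characters, values 0/1
    cell_types: dict[str, str] = field(default_factory=dict)  # population -> type
    members: dict[str, list[str]] = field(default_factory=dict)  # character -> aberrations

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy()
        if not ((vals == 0) | (vals == 1)).all():
            raise ValueError("matrix entries must be 0/1")
        if self.matrix.columns.duplicated().any():
            raise ValueError("duplicate character labels")
        empty = [c for c in self.matrix.columns if self.matrix[c].sum() == 0]
        if empty:
            raise ValueError(f"characters present in no population: {empty}")
        for pop, t in self.cell_types.items():
            if t not in CELL_TYPES:
                raise ValueError(f"unknown cell type {t!r} for population {pop!r}")

    def support(self, character: str) -> frozenset[str]:
        col = self.matrix[character]
        return frozenset(col.index[col == 1])

    def row_set(self, population: str) -> frozenset[str]:
        row = self.matrix.loc[population]
        return frozenset(row.index[row == 1])

    def to_tsv(self, path: str | Path) -> None:
        out = self.matrix.copy()
        out.insert(0, "cell_type", [self.cell_types.get(p, "other") for p in out.index])
        out.to_csv(path, sep="\t", index_label="population")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CharacterMatrix":
        df = pd.read_csv(path, sep="\t", index_col="population")
        cell_types = df.pop("cell_type").to_dict() if "cell_type" in df else {}
        return cls(matrix=df.astype(int), cell_types=cell_types)


def check_perfect_phylogeny(matrix: CharacterMatrix):
    """``"compatible"`` or the list of character pairs violating laminarity.

    Two characters conflict when their supporting population sets overlap
    without either containing the other.
    """
    chars = list(matrix.matrix.columns)
    supports = {c: matrix.support(c) for c in chars}
    conflicts = []
    for i, a in enumerate(chars):
        for b in chars[i + 1:]:
            sa, sb = supports[a], supports[b]
            inter = sa & sb
            if inter and not (sa <= sb or sb <= sa):
                conflicts.append((a, b))
    return "compatible" if not conflicts else conflicts


@dataclass
class CloneNode:
    characters: tuple[str, ...]        # characters gained on the edge into this node
    children: list["CloneNode"] = field(default_factory=list)
    populations: list[str] = field(default_factory=list)
    template_assignment: str | None = None

    @property
    def label(self) -> str:
        return "+".join(self.characters) if self.characters else "root"


@dataclass
class CloneTree:
    root: CloneNode
    matrix: CharacterMatrix

    def iter_nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def path_characters(self, population: str) -> frozenset[str]:
        """Union of edge labels from the root to the population's node."""
        def walk(node: CloneNode, acc: frozenset[str]):
            acc = acc | set(node.characters)
            if population in node.populations:
                return acc
            for ch in node.children:
                got = walk(ch, acc)
                if got is not None:
                    return got
            return None

        res = walk(self.root, frozenset())
        if res is None:
            raise KeyError(population)
        return res

    def to_newick(self) -> str:
        """Newick with populations as leaves and edge characters as internal labels.

        Labels are single-quoted so underscores survive round-trips through
        standard readers.
        """
        def q(label: str) -> str:
            return "'" + label.replace("'", "''") + "'"

        def render(node: CloneNode) -> str:
            parts = [q(p) for p in sorted(node.populations)]
            parts += [render(c) for c in node.children]
            inner = ",".join(parts)
            if node is self.root:
                return f"({inner})root;" if inner else "root;"
            return f"({inner}){q(node.label)}" if inner else q(node.label)
        return render(self.root)

    def to_dict(self) -> dict:
        def conv(node: CloneNode) -> dict:
            return {
                "characters": list(node.characters),
                "populations": sorted(node.populations),
                "template_assignment": node.template_assignment,
                "children": [conv(c) for c in node.children],
            }
        return conv(self.root)


def infer_clone_tree(matrix: CharacterMatrix) -> CloneTree:
    """Build the unique clone tree of a laminar character matrix.

    Characters with identical support sets merge onto one multi-character
    edge (lexicographically ordered); edges nest by strict support-set
    containment; each population attaches below the deepest character it
    carries.  Raises on an incompatible matrix, listing the conflicts.
    """
    result = check_perfect_phylogeny(matrix)
    if result != "compatible":
        raise ValueError(f"matrix is not a perfect phylogeny; conflicting pairs: {result}")

    groups: dict[frozenset[str], list[str]] = {}
    for c in matrix.matrix.columns:
        groups.setdefault(matrix.support(c), []).append(c)
    for chars in groups.values():
        chars.sort()

    root = CloneNode(characters=())
    nodes: dict[frozenset[str], CloneNode] = {}
    # larger supports first so parents exist before children
    for sup in sorted(groups, key=lambda s: (-len(s), sorted(s))):
        node = CloneNode(characters=tuple(groups[sup]))
        parent = root
        best: frozenset[str] | None = None
        for other, onode in nodes.items():
            if sup < other and (best is None or len(other) < len(best)):
                best, parent = other, onode
        parent.children.append(node)
        nodes[sup] = node

    for pop in matrix.matrix.index:
        carried = [s for s in nodes if pop in s]
        target = root if not carried else nodes[min(carried, key=len)]
        target.populations.append(str(pop))

    for node in [root, *nodes.values()]:
        node.children.sort(key=lambda n: n.characters)
        node.populations.sort()
    return CloneTree(root=root, matrix=matrix)


# --------------------------------------------------------------------------
# hematopoiesis templates


@dataclass(frozen=True)
class HematopoiesisTemplate:
    """Rooted scaffold of progenitor compartments with cell-type leaf slots."""

    name: str
    root: str
    children: dict[str, list[str]]          # node -> child nodes
    leaf_slots: dict[str, str]              # cell type -> parent compartment

    def parent_map(self) -> dict[str, str]:
        out = {}
        for parent, kids in self.children.items():
            for k in kids:
                out[k] = parent
        for cell_type, slot in self.leaf_slots.items():
            out[f"leaf:{cell_type}"] = slot
        return out

    def path_to_root(self, node: str) -> list[str]:
        parents = self.parent_map()
        path = [node]
        while path[-1] != self.root:
            path.append(parents[path[-1]])
        return path

    def lca(self, nodes: list[str]) -> str:
        paths = [self.path_to_root(n) for n in nodes]
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        # deepest common ancestor = first hit walking up any path
        for n in paths[0]:
            if n in common:
                return n
        raise AssertionError("trees are rooted; root is always common")


def load_template(variant: str = "classical") -> HematopoiesisTemplate:
    """Load a packaged hematopoiesis template ("classical" or "composite")."""
    text = resources.files("hemaseq.data").joinpath(f"template_{variant}.json").read_text()
    raw = json.loads(text)
    return HematopoiesisTemplate(
        name=raw["name"], root=raw["root"],
        children=raw["children"], leaf_slots=raw["leaf_slots"],
    )


def map_to_template(tree: CloneTree, template: HematopoiesisTemplate) -> CloneTree:
    """Annotate each character edge with its hematopoietic compartment.

    An edge's assignment is the deepest template node ancestral to every
    cell type found below that edge: a character shared by PC and MB leaves
    lands at (or above) the LMPP split of the classical template, while a
    character private to erythrocytes sits below MEP.  Populations carrying
    no characters belong to the normal-karyotype root lineage.  The clone
    tree's topology is never altered.
    """
    for pop, cell_type in tree.matrix.cell_types.items():
        if cell_type not in template.leaf_slots:
            raise ValueError(f"cell type {cell_type!r} has no slot in template "
                             f"{template.name!r}")

    def populations_below(node: CloneNode) -> list[str]:
        pops = list(node.populations)
        for c in node.children:
            pops.extend(populations_below(c))
        return pops

    def annotate(node: CloneNode) -> None:
        if node.characters:
            pops = populations_below(node)
            types = sorted({tree.matrix.cell_types.get(p, "other") for p in pops})
            leaves = [f"leaf:{t}" for t in types]
            lca = template.lca(leaves) if leaves else template.root
            if lca.startswith("leaf:"):
                slot = template.leaf_slots[lca[5:]]
                node.template_assignment = f"{lca[5:]} (below {slot})"
            else:
                node.template_assignment = lca
        for c in node.children:
            annotate(c)

    annotate(tree.root)
    tree.root.template_assignment = "normal lineage"
    return tree
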