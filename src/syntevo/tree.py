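"""Minimal rooted species tree with named branches and durations in Myr.

Every non-root node names the branch leading into it, so rearrangement events
can be addressed to branches by label. The default tree is the three-species
island/mainland topology used throughout: two sister tips splitting 0.92 Myr
ago inside a subgroup whose common ancestor lies 1.72 Myr back, with the third
tip as the other subgroup lineage. An outgroup, when needed for polarity, is
handled outside the tree (its arrangement equals the root's).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SpeciesTree:
    """Rooted tree: ``parent[child] = parent_name``, root has no entry."""

    root: str
    parent: dict[str, str]
    length: dict[str, float]  # branch duration (Myr) above each non-root node

    children: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        self.children = {self.root: []}
        for child, par in self.parent.items():
            self.children.setdefault(par, []).append(child)
            self.children.setdefault(child, [])
        for name in self.parent:
            if name not in self.length or self.length[name] < 0:
                raise ValueError(f"branch {name}: missing or negative duration")
        # every parent must be reachable from the root
        for par in set(self.parent.values()):
            if par != self.root and par not in self.parent:
                raise ValueError(f"node {par} is disconnected from the root")

    # -- queries ---------------------------------------------------------
    @property
    def branches(self) -> list[str]:
        return list(self.parent)

    def is_tip(self, name: str) -> bool:
        return not self.children.get(name)

    @property
    def tips(self) -> list[str]:
        return [n for n in self.children if self.is_tip(n)]

    def path_to(self, tip: str) -> list[str]:
        """Branch labels from the root down to ``tip`` (inclusive)."""
        if tip not in self.children:
            raise KeyError(f"unknown node {tip}")
        path = []
        node = tip
        while node != self.root:
            path.append(node)
            node = self.parent[node]
        return path[::-1]

    def tips_below(self, branch: str) -> set[str]:
        """Tips in the clade subtended by ``branch``."""
        stack, out = [branch], set()
        while stack:
            node = stack.pop()
            kids = self.children.get(node, [])
            if not kids:
                out.add(node)
            stack.extend(kids)
        return out

    def mrca(self, tips: set[str]) -> str:
        """Most recent common ancestor node of a set of tips."""
        if not tips:
            raise ValueError("mrca of an empty tip set")
        paths = [[self.root] + self.path_to(t) for t in tips]
        anc = self.root
        for level in zip(*paths):
            if len(set(level)) == 1:
                anc = level[0]
            else:
                break
        return anc

    def root_to_tip_time(self, tip: str) -> float:
        return sum(self.length[b] for b in self.path_to(tip))


def subgroup_tree(
    t_subgroup: float = 1.72,
    t_island_split: float = 0.92,
    mainland: str = "subobscura",
    island_sister: str = "madeirensis",
    island_lineage: str = "guanche",
    ancestor: str = "ms",
) -> SpeciesTree:
    """The default subgroup topology ((mainland, island_sister), island_lineage).

    ``t_subgroup`` is the age of the subgroup common ancestor and
    ``t_island_split`` the age of the mainland/sister split, both in Myr
    (defaults 1.72 and 0.92).
    """
    if not 0 < t_island_split < t_subgroup:
        raise ValueError("need 0 < t_island_split < t_subgroup")
    return SpeciesTree(
        root="root",
        parent={
            ancestor: "root",
            island_lineage: "root",
            mainland: ancestor,
            island_sister: ancestor,
        },
        length={
            ancestor: t_subgroup - t_island_split,
            island_lineage: t_subgroup,
            mainland: t_island_split,
            island_sister: t_island_split,
        },
    )
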