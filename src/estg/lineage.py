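"""Lineage forest: complete execution history of a run.

Every individual ever alive is a node with birth/end times, an end cause
(``division``, ``death``, ``transform`` or ``censored``), parent/children
links and its internal-state values.  Each initial individual roots one tree;
extinct lineages are kept, which is the point -- the forest records the
dynamics that led to dead individuals as well as to survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "MERGED_SPECIES",
    "LineageNode",
    "LineageForest",
    "living_population",
    "to_newick",
    "merge_forest",
    "internal_state_table",
]

#: species label of the synthetic zero-length root created by merge_forest;
#: excluded from all statistics
MERGED_SPECIES = "__merged__"

_STATE_TABLE_HEADER = (
    "node_id\tspecies\tbirth_time\tend_time\tdup_index\t"
    "value_at_birth\tvalue_at_end"
)


@dataclass(slots=True)
class LineageNode:
    node_id: int
    species: str
    parent: int | None
    birth_time: float
    children: list[int] = field(default_factory=list)
    end_time: float | None = None
    end_cause: str | None = None
    #: internal-state values at creation, name -> tuple of dup values;
    #: None when the species has no internal states
    states: dict[str, tuple[float, ...]] | None = None

    @property
    def state_values_at_birth(self):
        return self.states or {}

    @property
    def state_values_at_end(self):
        # state values are set at creation and constant over a node's life
        return self.states or {}

    def is_alive_at(self, t: float) -> bool:
        """Alive at ``t``; censored nodes count as alive through their
        censoring time."""
        if t < self.birth_time:
            return False
        if self.end_time is None:
            return True
        if t < self.end_time:
            return True
        return self.end_cause == "censored" and t <= self.end_time


class LineageForest:
    """Map of nodes plus the ordered roots. Node ids start at 1 in creation
    order; id 0 is reserved for the synthetic merged root."""

    def __init__(self):
        self.nodes: dict[int, LineageNode] = {}
        self.roots: list[int] = []
        self.end_time: float = 0.0
        self._next_id = 1

    def new_node(
        self,
        species: str,
        parent: int | None,
        birth_time: float,
        states: dict[str, tuple[float, ...]] | None = None,
    ) -> int:
        node_id = self._next_id
        self._next_id += 1
        node = LineageNode(node_id, species, parent, birth_time, states=states)
        self.nodes[node_id] = node
        if parent is None:
            self.roots.append(node_id)
        else:
            self.nodes[parent].children.append(node_id)
        return node_id

    def close(self, node_id: int, end_time: float, end_cause: str) -> None:
        node = self.nodes[node_id]
        node.end_time = end_time
        node.end_cause = end_cause

    def __len__(self) -> int:
        return len(self.nodes)

    def subtree_ids(self, root: int) -> list[int]:
        """All node ids in the subtree of ``root`` (preorder)."""
        out = []
        stack = [root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self.nodes[n].children))
        return out


def living_population(
    forest: LineageForest, t: float, species: str | None = None
) -> dict[str, int]:
    """Count living nodes per species at time ``t``.

    Censored nodes count as alive through the censoring time.  The merged
    pseudo-root, if present, is never counted.
    """
    if not 0.0 <= t <= forest.end_time:
        raise ValueError(
            f"t = {t} outside the recorded span [0, {forest.end_time}]"
        )
    counts: dict[str, int] = {}
    for node in forest.nodes.values():
        if node.species == MERGED_SPECIES:
            continue
        if species is not None and node.species != species:
            continue
        if node.is_alive_at(t):
            counts[node.species] = counts.get(node.species, 0) + 1
    if species is not None and species not in counts:
        counts[species] = 0
    return counts


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

def _fmt_len(x: float) -> str:
    return f"{x:.12g}"


def _label(node: LineageNode) -> str:
    suffix = "_dead" if node.end_cause == "death" else ""
    return f"{node.species}_{node.node_id}{suffix}"


def to_newick(
    forest: LineageForest, root: int, living_only: bool = False, label=None
) -> str:
    """Newick string for the tree under ``root``, terminated by ``;``.

    Branch length of each node is ``end_time - birth_time`` (censored nodes
    run to the censoring time).  Labels are ``<species>_<node_id>`` with a
    ``_dead`` suffix on death-terminated leaves.  With ``living_only`` dead
    subtrees are pruned and unary chains collapsed (branch lengths summed,
    the surviving child's label kept).
    """
    if root not in forest.nodes:
        raise ValueError(f"unknown root node id {root}")
    label = label or _label
    nodes = forest.nodes

    surviving: set[int] | None = None
    if living_only:
        surviving = _surviving_set(forest, root)
        if root not in surviving:
            raise ValueError(
                f"tree under root {root} has no living individuals; nothing "
                "to export with living_only"
            )

    # iterative post-order: children strings first, then the node
    order: list[int] = []
    stack = [root]
    while stack:
        n = stack.pop()
        order.append(n)
        for c in nodes[n].children:
            if surviving is None or c in surviving:
                stack.append(c)

    # entry per node: (core string, accumulated branch length)
    entries: dict[int, tuple[str, float]] = {}
    for n in reversed(order):
        node = nodes[n]
        length = (node.end_time if node.end_time is not None else forest.end_time) \
            - node.birth_time
        kids = [
            c for c in node.children if surviving is None or c in surviving
        ]
        if not kids:
            entries[n] = (label(node), length)
        elif living_only and len(kids) == 1:
            core, sub_len = entries.pop(kids[0])
            entries[n] = (core, sub_len + length)
        else:
            parts = ",".join(
                f"{entries[c][0]}:{_fmt_len(entries[c][1])}" for c in kids
            )
            for c in kids:
                del entries[c]
            entries[n] = (f"({parts}){label(node)}", length)

    core, length = entries[root]
    return f"{core}:{_fmt_len(length)};"


def _surviving_set(forest: LineageForest, root: int) -> set[int]:
    """Ids in the subtree whose subtree contains a censored (living) node."""
    nodes = forest.nodes
    order = forest.subtree_ids(root)
    alive: set[int] = set()
    for n in reversed(order):  # children before parents
        node = nodes[n]
        if node.end_cause == "censored" or any(c in alive for c in node.children):
            alive.add(n)
    return alive


def merge_forest(forest: LineageForest, roots: list[int]) -> LineageForest:
    """Join the selected trees under a synthetic zero-length pseudo-root.

    Returns a new forest (the input is untouched) whose single root is node 0
    of pseudo-species :data:`MERGED_SPECIES`; the pseudo-root is display
    plumbing and is excluded from every statistic.
    """
    if len(roots) < 2:
        raise ValueError("merging requires at least two roots")
    for r in roots:
        if r not in forest.nodes:
            raise ValueError(f"unknown root node id {r}")
        if forest.nodes[r].parent is not None:
            raise ValueError(f"node {r} is not a root")

    merged = LineageForest()
    merged.end_time = forest.end_time
    merged.nodes = dict(forest.nodes)
    pseudo = LineageNode(
        node_id=0,
        species=MERGED_SPECIES,
        parent=None,
        birth_time=0.0,
        children=list(roots),
        end_time=0.0,
        end_cause="merged",
    )
    merged.nodes[0] = pseudo
    for r in roots:
        merged.nodes[r] = replace(
            forest.nodes[r], parent=0, children=list(forest.nodes[r].children)
        )
    merged.roots = [0]
    merged._next_id = forest._next_id
    return merged


def internal_state_table(
    forest: LineageForest, state_name: str, program=None
) -> str:
    """Tab-separated table of one internal state across the forest.

    One row per node per dup instance; nodes of species lacking the state are
    omitted.  When a validated ``program`` is supplied the state name is
    checked against its declarations (unknown name -> error); without a
    program an absent state yields a header-only table.
    """
    if program is not None:
        declared = {
            ist.name
            for defs in program.internal_states.values()
            for ist in defs
        }
        if state_name not in declared:
            raise ValueError(f"unknown internal state {state_name!r}")

    lines = [_STATE_TABLE_HEADER]
    for node_id in sorted(forest.nodes):
        node = forest.nodes[node_id]
        if node.species == MERGED_SPECIES or not node.states:
            continue
        values = node.states.get(state_name)
        if values is None:
            continue
        end = node.end_time if node.end_time is not None else forest.end_time
        for k, v in enumerate(values):
            lines.append(
                f"{node.node_id}\t{node.species}\t{node.birth_time!r}\t"
                f"{end!r}\t{k}\t{v!r}\t{v!r}"
            )
    return "\n".join(lines) + "\n"
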