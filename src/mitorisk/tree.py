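"""Mutation-annotated reference haplogroup tree.

The reference phylogeny of human mtDNA (PhyloTree-style) is a rooted tree
whose nodes are haplogroup labels and whose edges carry the single-nucleotide
substitutions that define each haplogroup relative to its parent.  The root
carries a full reference allele assignment over the genotyped locus panel
(for the real tree, the RSRS sequence restricted to the panel), so the allele
state of any node over the panel is obtained by replaying the substitutions
on the root-to-node path.

The canonical on-disk form is a TSV edge list (``parent``, ``child``,
comma-separated mutation tokens such as ``G13708A``), rows sorted by
(parent, child).  A Newick exporter (topology and names only) is provided
for interoperability with generic tree viewers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    ConsistencyError,
    DataError,
    MutationParseError,
    TreeStructureError,
)

MT_GENOME_LENGTH = 16_569
VALID_ALLELES = frozenset("ACGT")

_MUTATION_RE = re.compile(r"^([ACGT])(\d+)([ACGT])(!?)$")


@dataclass(frozen=True)
class Locus:
    """One panel SNP on the mtDNA coordinate system (1-based)."""

    position: int
    ref_allele: str
    alt_allele: str
    label: str = ""
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not (1 <= self.position <= MT_GENOME_LENGTH):
            raise DataError(f"position {self.position} outside 1..{MT_GENOME_LENGTH}")
        if self.ref_allele not in VALID_ALLELES or self.alt_allele not in VALID_ALLELES:
            raise DataError(f"invalid alleles at position {self.position}")
        if self.ref_allele == self.alt_allele:
            raise DataError(f"ref == alt at position {self.position}")


class LocusPanel:
    """Ordered panel of biallelic mtDNA loci.

    Positions are strictly increasing and unique; each locus carries the
    reference (root/RSRS) allele, the alternate allele and optional
    annotation flags (``triallelic``, ``crossmap``).
    """

    def __init__(self, loci: Sequence[Locus]):
        loci = list(loci)
        positions = [l.position for l in loci]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise DataError("panel positions must be strictly increasing")
        self.loci: list[Locus] = loci
        self._by_position: dict[int, Locus] = {l.position: l for l in loci}
        self._index: dict[int, int] = {l.position: i for i, l in enumerate(loci)}

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __contains__(self, position: int) -> bool:
        return position in self._by_position

    def __eq__(self, other) -> bool:
        return isinstance(other, LocusPanel) and self.loci == other.loci

    @property
    def positions(self) -> list[int]:
        return [l.position for l in self.loci]

    def locus(self, position: int) -> Locus:
        return self._by_position[position]

    def index_of(self, position: int) -> int:
        return self._index[position]

    def restrict(self, positions: Iterable[int]) -> "LocusPanel":
        keep = set(positions)
        return LocusPanel([l for l in self.loci if l.position in keep])

    # --- serialization -------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "LocusPanel":
        df = pd.read_csv(path, sep="\t", dtype={"label": str}, keep_default_na=False)
        loci = [
            Locus(
                position=int(r.position),
                ref_allele=str(r.ref),
                alt_allele=str(r.alt),
                label=str(r.label),
                flags=frozenset(f for f in str(r.flags).split(",") if f),
            )
            for r in df.itertuples()
        ]
        return cls(loci)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "position": [l.position for l in self.loci],
                "ref": [l.ref_allele for l in self.loci],
                "alt": [l.alt_allele for l in self.loci],
                "label": [l.label for l in self.loci],
                "flags": [",".join(sorted(l.flags)) for l in self.loci],
            }
        )
        df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Mutation:
    """A point substitution, e.g. ``G13708A`` = G→A at position 13708."""

    position: int
    from_allele: str
    to_allele: str

    def __post_init__(self):
        if self.from_allele == self.to_allele:
            raise DataError(f"degenerate mutation at {self.position}")
        if self.from_allele not in VALID_ALLELES or self.to_allele not in VALID_ALLELES:
            raise DataError(f"invalid alleles in mutation at {self.position}")

    @property
    def name(self) -> str:
        return f"{self.from_allele}{self.position}{self.to_allele}"

    @classmethod
    def parse(cls, token: str) -> "Mutation":
        """Parse a PhyloTree-style token.

        A trailing ``!`` (back-mutation marker) is accepted and stripped;
        any other decoration is a parse error.
        """
        m = _MUTATION_RE.match(token.strip())
        if m is None:
            raise MutationParseError(f"malformed mutation token {token!r}")
        return cls(position=int(m.group(2)), from_allele=m.group(1), to_allele=m.group(3))


@dataclass(frozen=True)
class NodeState:
    """Allele vector of one haplogroup node over the panel, in panel order."""

    node: str
    alleles: tuple

    def key(self) -> tuple:
        return self.alleles

    def __str__(self) -> str:
        return "".join(self.alleles)


class ReferenceTree:
    """Rooted haplogroup tree with substitutions annotated on edges."""

    def __init__(
        self,
        root: str,
        parent: Mapping[str, str],
        edge_mutations: Mapping[str, Sequence[Mutation]],
    ):
        self.root = root
        self.parent: dict[str, str] = dict(parent)
        self.edge_mutations: dict[str, tuple] = {
            c: tuple(m) for c, m in edge_mutations.items()
        }
        self.children: dict[str, list[str]] = {root: []}
        for child in self.parent:
            self.children.setdefault(child, [])
        for child, par in self.parent.items():
            self.children.setdefault(par, []).append(child)
        for node in self.children:
            self.children[node].sort()  # canonical child order
        self._validate_structure()
        self.depth: dict[str, int] = {}
        self._compute_depths()

    # --- construction --------------------------------------------------

    @classmethod
    def from_edge_table(
        cls, rows: Iterable[tuple], panel: LocusPanel | None = None
    ) -> "ReferenceTree":
        """Build a tree from (parent, child, mutation-token-string) rows.

        ``rows`` may come from :func:`read_tree_tsv` or be given directly.
        Mutation tokens are comma separated; the empty string means an edge
        with no panel-relevant annotation (allowed, though unusual).
        """
        rows = list(rows)
        if not rows:
            raise TreeStructureError("empty edge table")
        parent: dict[str, str] = {}
        edge_mutations: dict[str, list[Mutation]] = {}
        nodes: set[str] = set()
        for i, (par, child, tokens) in enumerate(rows):
            par, child = str(par), str(child)
            if child in parent:
                raise TreeStructureError(f"row {i}: child {child!r} listed twice")
            try:
                muts = [
                    Mutation.parse(t)
                    for t in str(tokens or "").split(",")
                    if t.strip()
                ]
            except MutationParseError as e:
                raise MutationParseError(f"row {i}: {e}") from e
            parent[child] = par
            edge_mutations[child] = muts
            nodes.add(par)
            nodes.add(child)
        roots = nodes - set(parent)
        if len(roots) != 1:
            raise TreeStructureError(
                f"expected exactly one root, found {sorted(roots) or 'none (cycle)'}"
            )
        tree = cls(roots.pop(), parent, edge_mutations)
        if panel is not None:
            tree.validate_mutation_consistency(panel)
        return tree

    def _validate_structure(self) -> None:
        # walk from root; every node must be reached exactly once
        seen = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node in seen:
                raise TreeStructureError(f"cycle involving {node!r}")
            seen.add(node)
            stack.extend(self.children.get(node, []))
        if seen != set(self.children):
            missing = set(self.children) - seen
            raise TreeStructureError(f"unreachable nodes (cycle?): {sorted(missing)}")

    def _compute_depths(self) -> None:
        self.depth[self.root] = 0
        for node in self.preorder():
            for c in self.children[node]:
                self.depth[c] = self.depth[node] + 1

    # --- queries -------------------------------------------------------

    def nodes(self) -> list[str]:
        return list(self.preorder())

    def __contains__(self, node: str) -> bool:
        return node in self.children

    def __len__(self) -> int:
        return len(self.children)

    def preorder(self, start: str | None = None):
        stack = [start or self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(self.children[node]))

    def root_path(self, node: str) -> list[str]:
        """Nodes from the root down to ``node`` inclusive."""
        if node not in self.children:
            raise DataError(f"unknown node {node!r}")
        path = [node]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path[::-1]

    def is_ancestor_or_self(self, ancestor: str, node: str) -> bool:
        return ancestor in self.root_path(node)

    def subtree_nodes(self, node: str) -> list[str]:
        return list(self.preorder(node))

    def mrca(self, nodes: Iterable[str]) -> str:
        """Most recent common ancestor of a nonempty set of nodes."""
        nodes = list(nodes)
        if not nodes:
            raise DataError("mrca of an empty node set")
        common = set(self.root_path(nodes[0]))
        for n in nodes[1:]:
            common &= set(self.root_path(n))
        return max(common, key=lambda n: self.depth[n])

    def node_haplotype(self, node: str, panel: LocusPanel) -> NodeState:
        """Panel-restricted allele state of ``node``.

        The root state is the panel's reference alleles; mutations on the
        root-to-node path are applied in path order, so repeated mutation
        of the same position (back mutation) applies sequentially.
        """
        state = {l.position: l.ref_allele for l in panel}
        for member in self.root_path(node)[1:]:
            for mut in self.edge_mutations[member]:
                if mut.position not in panel:
                    continue
                if state[mut.position] != mut.from_allele:
                    raise ConsistencyError(
                        f"edge into {member!r}: mutation {mut.name} expects "
                        f"{mut.from_allele} at {mut.position} but state is "
                        f"{state[mut.position]}"
                    )
                state[mut.position] = mut.to_allele
        return NodeState(node=node, alleles=tuple(state[p] for p in panel.positions))

    def validate_mutation_consistency(self, panel: LocusPanel) -> None:
        """Check every edge's mutations chain correctly along root paths.

        On-panel positions start from the panel reference allele; off-panel
        positions are unconstrained at first use but must chain on reuse.
        """
        ref = {l.position: l.ref_allele for l in panel}

        def walk(node: str, state: dict):
            for child in self.children[node]:
                delta = {}
                for mut in self.edge_mutations[child]:
                    current = state.get(mut.position)
                    if current is None and mut.position in panel:
                        current = ref[mut.position]
                    if current is not None and current != mut.from_allele:
                        raise ConsistencyError(
                            f"edge {node!r}->{child!r}: mutation {mut.name} "
                            f"expects {mut.from_allele} but lineage state is {current}"
                        )
                    delta[mut.position] = (current, mut.to_allele)
                    state[mut.position] = mut.to_allele
                walk(child, state)
                for pos, (old, _new) in delta.items():
                    if old is None:
                        del state[pos]
                    else:
                        state[pos] = old

        import sys

        old_limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old_limit, 10 * len(self) + 100))
        try:
            walk(self.root, {})
        finally:
            sys.setrecursionlimit(old_limit)

    def on_panel_mutations(self, panel: LocusPanel) -> dict[str, tuple]:
        """Per-child edge mutations restricted to panel positions."""
        return {
            c: tuple(m for m in muts if m.position in panel)
            for c, muts in self.edge_mutations.items()
        }

    # --- serialization -------------------------------------------------

    def edge_table(self) -> list[tuple]:
        rows = [
            (self.parent[c], c, ",".join(m.name for m in self.edge_mutations[c]))
            for c in self.parent
        ]
        rows.sort(key=lambda r: (r[0], r[1]))
        return rows

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.edge_table(), columns=["parent", "child", "mutations"])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, panel: LocusPanel | None = None) -> "ReferenceTree":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        rows = [(r.parent, r.child, r.mutations) for r in df.itertuples()]
        return cls.from_edge_table(rows, panel=panel)

    def to_newick(self) -> str:
        """Topology + node names only (no branch lengths, no mutations)."""

        def fmt(node: str) -> str:
            name = re.sub(r"[\s(),:;\[\]']", "_", node)
            kids = self.children[node]
            if not kids:
                return name
            return "(" + ",".join(fmt(k) for k in kids) + ")" + name

        return fmt(self.root) + ";"
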