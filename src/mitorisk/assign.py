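"""Haplogroup imputation from panel-restricted haplotypes.

Every node of the reference tree has a full haplotype; restricted to the
genotyped panel, several haplogroups usually collapse onto the same "short
haplotype".  Each distinct short haplotype is therefore labelled with the
most recent common ancestor (MRCA) of all haplogroups sharing it, and each
individual's observed short haplotype is matched exactly against this index.
Unmatched individuals (e.g. chimeric haplotypes produced by genotyping
error) are retained with no label and excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .errors import ConfigurationError, DataError
from .qc import GenotypeMatrix
from .tree import LocusPanel, ReferenceTree


@dataclass(frozen=True)
class IndexEntry:
    nodes: frozenset
    label: str


@dataclass
class ShortHaplotypeIndex:
    """Mapping from short-haplotype allele key to (node set, MRCA label)."""

    entries: dict
    panel: LocusPanel

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, key: tuple) -> IndexEntry | None:
        return self.entries.get(key)


@dataclass(frozen=True)
class Assignment:
    sample_id: str
    short_haplotype: str
    haplogroup: str | None
    matched: bool


def build_short_haplotype_index(
    tree: ReferenceTree, panel: LocusPanel
) -> ShortHaplotypeIndex:
    """Group node haplotypes by their panel restriction; label groups by MRCA."""
    groups: dict[tuple, list[str]] = {}
    for node in tree.nodes():
        key = tree.node_haplotype(node, panel).key()
        groups.setdefault(key, []).append(node)
    entries = {
        key: IndexEntry(nodes=frozenset(nodes), label=tree.mrca(nodes))
        for key, nodes in groups.items()
    }
    return ShortHaplotypeIndex(entries=entries, panel=panel)


def assign_individuals(
    gm: GenotypeMatrix, index: ShortHaplotypeIndex
) -> list[Assignment]:
    """Exact-match lookup of each sample's short haplotype in the index.

    Requires a sample-filtered matrix (no N/H codes).
    """
    if gm.panel.positions != index.panel.positions:
        raise ConfigurationError("genotype panel does not match index panel")
    out = []
    values = gm.calls.to_numpy()
    for i, sample in enumerate(gm.calls.index):
        key = tuple(values[i])
        if "N" in key or "H" in key:
            raise DataError(f"sample {sample!r} has missing calls; run QC first")
        entry = index.lookup(key)
        out.append(
            Assignment(
                sample_id=str(sample),
                short_haplotype="".join(key),
                haplogroup=entry.label if entry else None,
                matched=entry is not None,
            )
        )
    return out


def assignment_rate(assignments: list[Assignment]) -> float:
    if not assignments:
        return float("nan")
    return sum(a.matched for a in assignments) / len(assignments)


def assignments_to_frame(assignments: list[Assignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in assignments],
            "haplogroup": [a.haplogroup or "" for a in assignments],
            "matched": [a.matched for a in assignments],
            "short_haplotype": [a.short_haplotype for a in assignments],
        }
    )


def main_clade(tree: ReferenceTree, node: str, clade_root: str | None = None) -> str:
    """Top-level clade of ``node``: its ancestor at depth 1 below the root.

    The root itself maps to itself (no named top-level clade above it).
    """
    clade_root = clade_root or tree.root
    path = tree.root_path(node)
    try:
        start = path.index(clade_root)
    except ValueError:
        raise DataError(f"{node!r} is not within clade {clade_root!r}")
    if len(path) == start + 1:
        return node
    return path[start + 1]


@dataclass
class AccuracySummary:
    level: str
    n: int
    n_correct: int
    per_clade: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n if self.n else float("nan")


def evaluate_accuracy(
    assignments: list[Assignment],
    truth: Mapping[str, str],
    tree: ReferenceTree,
    level: str = "main",
) -> AccuracySummary:
    """Score matched assignments against known haplogroups.

    ``main``: correct when the assigned label's top-level clade equals the
    truth's.  ``exact``: correct when the truth is the assigned label itself
    or one of its descendants (an MRCA label is deliberately coarse, so an
    ancestral call covering the truth counts as correct).
    """
    if level not in ("main", "exact"):
        raise ConfigurationError(f"unknown accuracy level {level!r}")
    rows = []
    for a in assignments:
        if not a.matched:
            continue
        if a.sample_id not in truth:
            raise DataError(f"no truth label for matched sample {a.sample_id!r}")
        true_label = truth[a.sample_id]
        if true_label not in tree:
            raise DataError(f"truth label {true_label!r} not in tree")
        if level == "main":
            correct = main_clade(tree, a.haplogroup) == main_clade(tree, true_label)
        else:
            correct = tree.is_ancestor_or_self(a.haplogroup, true_label)
        rows.append(
            {
                "sample_id": a.sample_id,
                "clade": main_clade(tree, true_label),
                "correct": correct,
            }
        )
    df = pd.DataFrame(rows, columns=["sample_id", "clade", "correct"])
    per_clade = (
        df.groupby("clade")["correct"].agg(["size", "mean"]).reset_index()
        if len(df)
        else pd.DataFrame(columns=["clade", "size", "mean"])
    )
    per_clade = per_clade.rename(columns={"size": "n", "mean": "accuracy"})
    return AccuracySummary(
        level=level, n=len(df), n_correct=int(df["correct"].sum()) if len(df) else 0,
        per_clade=per_clade,
    )
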