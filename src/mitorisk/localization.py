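"""Susceptibility-site localization via correlated evolution with S.

Each observed short haplotype receives a binary disease character S:
case-associated when its affected/unaffected ratio exceeds the cohort-wide
ratio by more than a sensitivity factor epsilon, control-associated
otherwise.  Haplotypes (panel sites encoded ancestral=0 / derived=1, plus S)
are attached as pendant leaves under their assigned haplogroup node, states
are reconstructed at ancestral nodes (minimum-change parsimony with an
ACCTRAN-style tie-break, or marginal maximum likelihood under a symmetric
two-state model with unit branch lengths), and every site is scored by the
correlation between its changes and the changes of S along tree edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .tree import LocusPanel, ReferenceTree

CASE_ASSOCIATED = "case_associated"
CONTROL_ASSOCIATED = "control_associated"


@dataclass
class SCharacterConfig:
    """epsilon > 1 demands a stronger case excess before labelling a
    haplotype case-associated; the conventional default is 1."""

    epsilon: float = 1.0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be positive")


@dataclass
class HaplotypeStatusCounts:
    """Affected/unaffected counts per short haplotype and overall."""

    per_haplotype: dict  # key -> (n_affected, n_unaffected)

    @property
    def totals(self) -> tuple[int, int]:
        a = sum(v[0] for v in self.per_haplotype.values())
        u = sum(v[1] for v in self.per_haplotype.values())
        return a, u

    @classmethod
    def from_data(cls, haplotypes: Mapping, statuses: Mapping) -> "HaplotypeStatusCounts":
        per: dict = {}
        for sample, hap in haplotypes.items():
            a, u = per.get(hap, (0, 0))
            if int(statuses[sample]) == 1:
                per[hap] = (a + 1, u)
            else:
                per[hap] = (a, u + 1)
        return cls(per_haplotype=per)


def compute_S(counts: HaplotypeStatusCounts, cfg: SCharacterConfig | None = None) -> dict:
    """Label each haplotype case_associated or control_associated.

    case_associated iff n_affected * N_unaffected > epsilon * n_unaffected *
    N_affected; equality falls to control_associated (conservative).
    Haplotypes with zero members are excluded.
    """
    cfg = cfg or SCharacterConfig()
    N_aff, N_unaff = counts.totals
    if N_aff <= 0 or N_unaff <= 0:
        raise DataError("both overall affected and unaffected counts must be positive")
    out = {}
    for hap, (a, u) in counts.per_haplotype.items():
        if a + u == 0:
            continue
        out[hap] = (
            CASE_ASSOCIATED
            if a * N_unaff > cfg.epsilon * u * N_aff
            else CONTROL_ASSOCIATED
        )
    return out


# ---------------------------------------------------------------------------
# ancestral reconstruction on a simple rooted tree


@dataclass
class AnalysisTree:
    """Rooted tree (children adjacency) used for character reconstruction."""

    root: str
    children: dict

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(self.children.get(node, [])))

    def postorder(self):
        return reversed(list(self.preorder()))

    def edges(self):
        """(parent, child) pairs in deterministic preorder."""
        for node in self.preorder():
            for c in self.children.get(node, []):
                yield node, c


@dataclass
class AncestralReconstruction:
    tree: AnalysisTree
    node_states: dict  # node -> np.ndarray of 0/1 over characters
    char_names: list
    method: str
    scores: np.ndarray | None = None  # per-character parsimony score (Fitch only)

    def edge_changes(self, char_index: int):
        """(parent, child, direction) for every edge where the character
        changes; direction is '01' (ancestral->derived) or '10'."""
        out = []
        for p, c in self.tree.edges():
            a = self.node_states[p][char_index]
            b = self.node_states[c][char_index]
            if a != b:
                out.append((p, c, f"{a}{b}"))
        return out


def _min_change_states(
    tree: AnalysisTree, leaf_states: Mapping, fixed_root: Mapping | None = None
) -> tuple[dict, np.ndarray]:
    """Unit-cost Sankoff DP over binary characters, vectorised per character.

    Ties at the root prefer state 0 (ancestral) unless the root is fixed;
    ties on an edge place the change on that edge (closest to the root),
    which is the ACCTRAN-style disambiguation.
    """
    some = next(iter(leaf_states.values()))
    n_char = len(some)
    INF = 10**6
    cost: dict = {}
    order = list(tree.postorder())
    for node in order:
        kids = tree.children.get(node, [])
        c = np.zeros((2, n_char))
        for k in kids:
            ck = cost[k]
            # cost of child subtree given this node's state s:
            # min(ck[s], ck[1-s] + 1)
            c[0] += np.minimum(ck[0], ck[1] + 1)
            c[1] += np.minimum(ck[1], ck[0] + 1)
        if node in leaf_states:
            obs = np.asarray(leaf_states[node])
            c[0] = np.where(obs == 0, c[0], INF)
            c[1] = np.where(obs == 1, c[1], INF)
        elif not kids:
            raise DataError(f"node {node!r} has neither states nor descendants")
        cost[node] = c

    states: dict = {}
    root_cost = cost[tree.root]
    if fixed_root is not None:
        root_state = np.asarray(fixed_root)
    else:
        root_state = (root_cost[1] < root_cost[0]).astype(np.int8)  # tie -> 0
    states[tree.root] = root_state
    score = root_cost[np.asarray(root_state, dtype=int), np.arange(n_char)]
    for node in tree.preorder():
        s_p = states[node]
        for k in tree.children.get(node, []):
            ck = cost[k]
            keep = ck[s_p, np.arange(n_char)]
            flip = ck[1 - s_p, np.arange(n_char)] + 1
            # tie (keep == flip): change on this edge, i.e. prefer flip
            states[k] = np.where(flip <= keep, 1 - s_p, s_p).astype(np.int8)
    return states, score


def _ml_marginal_states(
    tree: AnalysisTree, leaf_states: Mapping, branch_length: float = 1.0
) -> dict:
    """Marginal ML states under a symmetric 2-state model, unit branches.

    P(change) on a branch of length t is (1 - exp(-2t))/2; prior 1/2.
    Ties prefer state 0.
    """
    p_change = 0.5 * (1.0 - np.exp(-2.0 * branch_length))
    P = np.array([[1 - p_change, p_change], [p_change, 1 - p_change]])
    some = next(iter(leaf_states.values()))
    n_char = len(some)

    down: dict = {}  # P(data below node | node state), shape (2, n_char)
    for node in tree.postorder():
        d = np.ones((2, n_char))
        for k in tree.children.get(node, []):
            d *= P @ down[k]
        if node in leaf_states:
            obs = np.asarray(leaf_states[node])
            mask = np.vstack([(obs == 0), (obs == 1)]).astype(float)
            d *= mask
        down[node] = d

    up: dict = {tree.root: np.full((2, n_char), 0.5)}  # prior at root
    for node in tree.preorder():
        for k in tree.children.get(node, []):
            sib = np.ones((2, n_char))
            for k2 in tree.children[node]:
                if k2 != k:
                    sib *= P @ down[k2]
            up[k] = P.T @ (up[node] * sib)

    states = {}
    for node in tree.preorder():
        marg = up[node] * down[node]
        states[node] = (marg[1] > marg[0]).astype(np.int8)  # tie -> 0
    return states


def build_analysis_tree(
    tree: ReferenceTree, clade_root: str, observed_nodes: Mapping
) -> tuple[AnalysisTree, dict]:
    """Clade subtree pruned to observed lineages, with pendant leaves.

    ``observed_nodes`` maps haplogroup label -> list of (leaf name, state
    vector).  Internal haplogroups carrying observations get a pendant leaf
    so observed states never constrain ancestral nodes directly.
    """
    keep = set()
    for label in observed_nodes:
        path = tree.root_path(label)
        if clade_root not in path:
            raise DataError(f"{label!r} outside clade {clade_root!r}")
        keep.update(path[path.index(clade_root):])
    children = {}
    leaf_states = {}
    for node in keep:
        children[node] = [c for c in tree.children.get(node, []) if c in keep]
    for label, leaves in observed_nodes.items():
        for leaf_name, vec in leaves:
            children[label].append(leaf_name)
            children[leaf_name] = []
            leaf_states[leaf_name] = np.asarray(vec, dtype=np.int8)
    return AnalysisTree(root=clade_root, children=children), leaf_states


def reconstruct_ancestral(
    tree: AnalysisTree,
    leaf_states: Mapping,
    char_names: Sequence[str],
    method: str = "fitch_acctran",
    fixed_root: Mapping | None = None,
) -> AncestralReconstruction:
    """Reconstruct binary character states at all internal nodes."""
    if method == "fitch_acctran":
        states, score = _min_change_states(tree, leaf_states, fixed_root=fixed_root)
        return AncestralReconstruction(tree, states, list(char_names), method, score)
    if method == "ml_unit_branch":
        states = _ml_marginal_states(tree, leaf_states)
        return AncestralReconstruction(tree, states, list(char_names), method, None)
    raise ConfigurationError(f"unknown reconstruction method {method!r}")


# ---------------------------------------------------------------------------
# correlated evolution index


@dataclass
class CorrelatedEvolutionResult:
    site: int  # panel index (position of the locus in the panel), -1 for named chars
    mutation: str
    direction: str  # "ancestral->derived" or "derived->ancestral"
    index: float | None
    rank: int | None = None


def _signed_s_changes(recon: AncestralReconstruction, s_index: int) -> np.ndarray:
    """+1 where S changes toward case on an edge, -1 toward control, else 0."""
    z = []
    for p, c in recon.tree.edges():
        a = recon.node_states[p][s_index]
        b = recon.node_states[c][s_index]
        z.append(int(b) - int(a))
    return np.array(z, dtype=float)


def correlated_evolution_index(
    recon: AncestralReconstruction,
    s_index: int,
    panel: LocusPanel | None = None,
    site_indices: Sequence[int] | None = None,
) -> list[CorrelatedEvolutionResult]:
    """Correlation between each site's changes and the S changes over edges.

    For a site and a direction, x(edge) indicates a change of the site in
    that direction; the S changes enter with their sign (+ toward
    case-associated).  The index is the Pearson correlation of x with the
    signed S variable; when all S changes share one direction this is
    exactly the phi coefficient of the two binary indicators.  Constant x or
    absent S changes make the index undefined (None).  Results are ranked by
    index, descending, undefined last.
    """
    edges = list(recon.tree.edges())
    n_edges = len(edges)
    z = _signed_s_changes(recon, s_index)
    if site_indices is None:
        site_indices = [i for i in range(len(recon.char_names)) if i != s_index]

    results = []
    for i in site_indices:
        deltas = np.array(
            [
                int(recon.node_states[c][i]) - int(recon.node_states[p][i])
                for p, c in edges
            ]
        )
        name = recon.char_names[i]
        if panel is not None and i < len(panel):
            locus = panel.loci[i]
            name = f"{locus.ref_allele}{locus.position}{locus.alt_allele}"
        for direction, sign in (("ancestral->derived", 1), ("derived->ancestral", -1)):
            x = (deltas == sign).astype(float)
            if x.std() == 0 or np.abs(z).sum() == 0 or n_edges < 2 or z.std() == 0:
                idx = None
            else:
                idx = float(np.corrcoef(x, z)[0, 1])
            results.append(
                CorrelatedEvolutionResult(
                    site=i, mutation=name, direction=direction, index=idx
                )
            )
    ranked = sorted(
        [r for r in results if r.index is not None],
        key=lambda r: -r.index,
    )
    for rank, r in enumerate(ranked, start=1):
        r.rank = rank
    return results


# ---------------------------------------------------------------------------
# driver


def localize_susceptibility_sites(
    tree: ReferenceTree,
    panel: LocusPanel,
    data: pd.DataFrame,
    clade_root: str,
    epsilon: float = 1.0,
    method: str = "fitch_acctran",
) -> pd.DataFrame:
    """End-to-end localization for one clade.

    ``data`` needs columns sample_id, haplogroup, short_haplotype, status.
    Returns a ranked table (site, mutation, direction, index, rank).
    """
    subtree = set(tree.subtree_nodes(clade_root))
    data = data[data["haplogroup"].isin(subtree)]
    if len(data) == 0:
        raise DataError(f"no individuals assigned within clade {clade_root!r}")

    counts = HaplotypeStatusCounts.from_data(
        dict(zip(data["sample_id"], data["short_haplotype"])),
        dict(zip(data["sample_id"], data["status"])),
    )
    s_labels = compute_S(counts, SCharacterConfig(epsilon=epsilon))

    # one pendant leaf per observed short haplotype, under its label node
    hap_label = (
        data.drop_duplicates("short_haplotype")
        .set_index("short_haplotype")["haplogroup"]
        .to_dict()
    )
    ref_vec = "".join(l.ref_allele for l in panel)
    observed: dict = {}
    for hap, label in hap_label.items():
        site_bits = [0 if a == r else 1 for a, r in zip(hap, ref_vec)]
        s_bit = 1 if s_labels[hap] == CASE_ASSOCIATED else 0
        observed.setdefault(label, []).append((f"hap:{hap}", site_bits + [s_bit]))

    atree, leaf_states = build_analysis_tree(tree, clade_root, observed)
    char_names = [str(l.position) for l in panel] + ["S"]
    recon = reconstruct_ancestral(atree, leaf_states, char_names, method=method)
    results = correlated_evolution_index(
        recon, s_index=len(panel), panel=panel,
        site_indices=list(range(len(panel))),
    )
    df = pd.DataFrame(
        {
            "site": [r.site for r in results],
            "mutation": [r.mutation for r in results],
            "direction": [r.direction for r in results],
            "index": [r.index for r in results],
            "rank": [r.rank for r in results],
        }
    )
    return df.sort_values(
        by=["rank"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
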