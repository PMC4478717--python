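"""Clade-tree association testing with nested permutation homogeneity tests.

At each depth level of a clade subtree, individuals are collapsed into the
branch (level-d ancestor) containing their assigned haplogroup; individuals
whose label sits above the level form their own paragroup branch.  A Pearson
chi-square homogeneity statistic compares affected/unaffected counts across
branches, its p-value is obtained by permuting affection labels, and the
tree-level result is the Westfall–Young min-p over levels: the observed
minimum p is compared against the permutation distribution of the minimum.

Because relatives share their mtDNA haplotype, the cohort is first reduced
to genetically independent sets by sampling one individual per
(family, short haplotype) group; the whole analysis is repeated over many
such resamplings and averaged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .tree import ReferenceTree


@dataclass
class CladeLevelTable:
    """Affected/unaffected counts per branch at one tree level.

    ``counts`` has shape (k, 2) with columns (affected, unaffected); rows
    follow ``branches`` (preorder within the clade subtree).
    """

    level: int
    branches: list[str]
    counts: np.ndarray

    @property
    def k(self) -> int:
        return len(self.branches)


@dataclass
class LevelTestResult:
    level: int
    statistic: float
    df: int
    raw_p: float
    table: CladeLevelTable


@dataclass
class TreeTestResult:
    levels: list[LevelTestResult]
    min_raw_p: float
    corrected_p: float
    B: int
    seed: int | None
    mode: str  # "sampled" | "exhaustive" | "degenerate"

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class ResamplingPlan:
    """Family-aware resampling: one individual per (family, short haplotype)."""

    R: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if self.R < 1:
            raise DataError("R must be >= 1")


@dataclass
class AggregatedAssociation:
    mean_corrected_p: float
    corrected_p_values: list[float]
    levels: pd.DataFrame
    branches: pd.DataFrame
    n_resamplings: int
    n_skipped: int
    B: int
    plan: ResamplingPlan = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# level construction


class _LevelDesign:
    """Per-level branch membership of a fixed set of individuals."""

    def __init__(
        self,
        tree: ReferenceTree,
        labels: Sequence[str],
        clade_root: str,
    ):
        if clade_root not in tree:
            raise DataError(f"clade root {clade_root!r} not in tree")
        root_depth = tree.depth[clade_root]
        subtree = set(tree.subtree_nodes(clade_root))
        for lab in labels:
            if lab not in subtree:
                raise DataError(f"label {lab!r} outside clade {clade_root!r}")
        preorder_index = {n: i for i, n in enumerate(tree.preorder(clade_root))}
        max_depth = max(tree.depth[n] - root_depth for n in subtree)

        paths = {lab: tree.root_path(lab) for lab in set(labels)}
        self.levels: list[int] = []
        self.branch_labels: dict[int, list[str]] = {}
        self.membership: dict[int, np.ndarray] = {}
        for d in range(1, max_depth + 1):
            branch_of = []
            for lab in labels:
                rel = tree.depth[lab] - root_depth
                branch_of.append(lab if rel < d else paths[lab][root_depth + d])
            present = sorted(set(branch_of), key=preorder_index.__getitem__)
            if len(present) < 2:
                continue  # all individuals in one branch: no test at this level
            pos = {b: i for i, b in enumerate(present)}
            self.levels.append(d)
            self.branch_labels[d] = present
            self.membership[d] = np.array([pos[b] for b in branch_of], dtype=np.intp)

    def tables(self, statuses: np.ndarray) -> list[CladeLevelTable]:
        out = []
        for d in self.levels:
            m = self.membership[d]
            k = len(self.branch_labels[d])
            aff = np.bincount(m, weights=statuses, minlength=k)
            tot = np.bincount(m, minlength=k)
            counts = np.column_stack([aff, tot - aff]).astype(int)
            out.append(CladeLevelTable(level=d, branches=self.branch_labels[d], counts=counts))
        return out


def level_tables(
    tree: ReferenceTree,
    assignments: Mapping[str, str],
    statuses: Mapping[str, int],
    clade_root: str,
) -> list[CladeLevelTable]:
    """One affected/unaffected table per level of the clade subtree.

    Empty branches are pruned and levels with fewer than two occupied
    branches are skipped.
    """
    samples = [s for s in assignments]
    labels = [assignments[s] for s in samples]
    status = np.array([int(statuses[s]) for s in samples])
    design = _LevelDesign(tree, labels, clade_root)
    return design.tables(status)


# ---------------------------------------------------------------------------
# statistics


def homogeneity_statistic(table: CladeLevelTable) -> tuple[float, int]:
    """Pearson chi-square over the 2 x k table; df = k - 1.

    Branches with zero members are pruned before computation.
    """
    counts = np.asarray(table.counts, dtype=float)
    counts = counts[counts.sum(axis=1) > 0]
    if len(counts) < 2:
        raise DataError("fewer than two occupied branches")
    row = counts.sum(axis=1)  # branch totals
    col = counts.sum(axis=0)  # (affected, unaffected) totals
    if (col == 0).any():
        raise DataError("zero marginal: all individuals share one status")
    n = counts.sum()
    expected = np.outer(row, col) / n
    stat = float(((counts - expected) ** 2 / expected).sum())
    return stat, len(counts) - 1


def _level_stats(design: _LevelDesign, status_matrix: np.ndarray) -> np.ndarray:
    """Chi-square statistics, shape (n_status_vectors, n_levels).

    Branch totals are fixed by membership, so expected counts depend only on
    the (fixed) affected total; this makes permutation recomputation cheap.
    """
    n_vec = status_matrix.shape[0]
    out = np.empty((n_vec, len(design.levels)))
    n = status_matrix.shape[1]
    A = status_matrix[0].sum()  # affected total, invariant under permutation
    U = n - A
    for j, d in enumerate(design.levels):
        m = design.membership[d]
        k = len(design.branch_labels[d])
        one_hot = np.zeros((n, k))
        one_hot[np.arange(n), m] = 1.0
        tot = one_hot.sum(axis=0)
        ea = tot * A / n
        eu = tot * U / n
        aff = status_matrix @ one_hot  # (n_vec, k)
        una = tot[None, :] - aff
        out[:, j] = ((aff - ea) ** 2 / ea + (una - eu) ** 2 / eu).sum(axis=1)
    return out


def _pool_pvalues(stats: np.ndarray) -> np.ndarray:
    """Per-level p of each pool member: fraction of pool with stat >= own."""
    n_pool, n_levels = stats.shape
    p = np.empty_like(stats)
    for j in range(n_levels):
        col = stats[:, j]
        order = np.sort(col)
        p[:, j] = (n_pool - np.searchsorted(order, col, side="left")) / n_pool
    return p


def permutation_test(
    tree: ReferenceTree,
    assignments: Mapping[str, str],
    statuses: Mapping[str, int],
    clade_root: str,
    B: int = 1000,
    seed=None,
    exhaustive_cap: int = 1000,
) -> TreeTestResult:
    """Permutation homogeneity tests at every level, plus min-p correction.

    Affection labels are shuffled over individuals; per level,
    raw_p = (b+1)/(B+1) with b the number of permutations whose statistic
    reaches the observed one.  The corrected p compares the observed minimum
    (on the p scale, via pooled ranks) against the permutation distribution
    of the minimum.  When the number of distinct affected-label placements
    C(n, n_affected) does not exceed ``exhaustive_cap``, all placements are
    enumerated instead of sampled.
    """
    if B < 1:
        raise DataError("B must be >= 1")
    samples = list(assignments)
    labels = [assignments[s] for s in samples]
    status = np.array([int(statuses[s]) for s in samples])
    if not np.isin(status, (0, 1)).all():
        raise DataError("statuses must be binary")
    design = _LevelDesign(tree, labels, clade_root)
    observed_tables = design.tables(status)

    if not design.levels:
        return TreeTestResult([], float("nan"), float("nan"), B, seed, "degenerate")

    n = len(samples)
    n_aff = int(status.sum())
    if n_aff == 0 or n_aff == n:
        warnings.warn("all individuals share one status; no signal possible")
        levels = [
            LevelTestResult(t.level, 0.0, t.k - 1, 1.0, t) for t in observed_tables
        ]
        return TreeTestResult(levels, 1.0, 1.0, B, seed, "degenerate")

    n_arrangements = math.comb(n, n_aff)
    if n_arrangements <= exhaustive_cap:
        mode = "exhaustive"
        status_matrix = np.zeros((n_arrangements, n))
        for i, combo in enumerate(combinations(range(n), n_aff)):
            status_matrix[i, list(combo)] = 1.0
        stats = _level_stats(design, status_matrix)
        obs_stats = _level_stats(design, status[None, :].astype(float))[0]
        p = _pool_pvalues(stats)
        raw_p = np.array(
            [(stats[:, j] >= obs_stats[j]).mean() for j in range(len(design.levels))]
        )
        minp = p.min(axis=1)
        obs_minp = raw_p.min()
        corrected = float((minp <= obs_minp).mean())
    else:
        mode = "sampled"
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        perms = np.empty((B, n))
        for b in range(B):
            perms[b] = rng.permutation(status)
        pool = np.vstack([status[None, :].astype(float), perms])
        stats = _level_stats(design, pool)
        p = _pool_pvalues(stats)  # observed is pool member 0
        raw_p = p[0]
        minp = p.min(axis=1)
        corrected = float((minp <= minp[0]).mean())

    obs = _level_stats(design, status[None, :].astype(float))[0]
    levels = [
        LevelTestResult(
            level=t.level,
            statistic=float(obs[j]),
            df=t.k - 1,
            raw_p=float(raw_p[j]),
            table=t,
        )
        for j, t in enumerate(observed_tables)
    ]
    return TreeTestResult(
        levels=levels,
        min_raw_p=float(raw_p.min()),
        corrected_p=corrected,
        B=B,
        seed=None if isinstance(seed, np.random.Generator) else seed,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# family-aware resampling


def resample_independent(data: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """One uniformly chosen member per (family_id, short_haplotype) group.

    Singleton groups are always retained; members of the same family with
    different short haplotypes (non-maternal relatives) count as distinct
    groups.  Row order of the input is preserved.
    """
    for col in ("family_id", "short_haplotype"):
        if col not in data.columns:
            raise DataError(f"missing column {col!r}")
    chosen = []
    for _, group in data.groupby(["family_id", "short_haplotype"], sort=True):
        chosen.append(group.index[int(rng.integers(len(group)))])
    chosen_set = set(chosen)
    return data.loc[[i for i in data.index if i in chosen_set]]


def run_resampled_association(
    tree: ReferenceTree,
    data: pd.DataFrame,
    clade_root: str,
    plan: ResamplingPlan | None = None,
    B: int = 1000,
    exhaustive_cap: int = 1000,
) -> AggregatedAssociation:
    """Average the permutation test over family-aware resamplings.

    ``data`` needs columns sample_id, family_id, haplogroup,
    short_haplotype, status; rows with haplogroups outside the clade are
    ignored.  Fully reproducible from (plan.seed, plan.R, B).
    """
    plan = plan or ResamplingPlan()
    subtree = set(tree.subtree_nodes(clade_root))
    data = data[data["haplogroup"].isin(subtree)]
    ss = np.random.SeedSequence(plan.seed)
    children = ss.spawn(plan.R)

    corrected: list[float] = []
    level_acc: dict[int, list[float]] = {}
    branch_acc: dict[tuple, list[tuple]] = {}
    n_skipped = 0
    for r in range(plan.R):
        rng = np.random.default_rng(children[r])
        subset = resample_independent(data, rng)
        if len(subset) == 0:
            n_skipped += 1
            continue
        result = permutation_test(
            tree,
            dict(zip(subset["sample_id"], subset["haplogroup"])),
            dict(zip(subset["sample_id"], subset["status"])),
            clade_root,
            B=B,
            seed=rng,
            exhaustive_cap=exhaustive_cap,
        )
        if not result.levels or math.isnan(result.corrected_p):
            n_skipped += 1
            continue
        corrected.append(result.corrected_p)
        for lv in result.levels:
            level_acc.setdefault(lv.level, []).append(lv.raw_p)
            for b, (a, u) in zip(lv.table.branches, lv.table.counts):
                branch_acc.setdefault((lv.level, b), []).append((int(a), int(u)))

    levels_df = pd.DataFrame(
        [
            {"level": d, "mean_raw_p": float(np.mean(ps)), "n_resamplings": len(ps)}
            for d, ps in sorted(level_acc.items())
        ]
    )
    branch_rows = []
    for (d, b), pairs in sorted(branch_acc.items()):
        arr = np.array(pairs)
        branch_rows.append(
            {
                "level": d,
                "branch": b,
                "mean_affected": float(arr[:, 0].mean()),
                "min_affected": int(arr[:, 0].min()),
                "max_affected": int(arr[:, 0].max()),
                "mean_unaffected": float(arr[:, 1].mean()),
                "min_unaffected": int(arr[:, 1].min()),
                "max_unaffected": int(arr[:, 1].max()),
            }
        )
    return AggregatedAssociation(
        mean_corrected_p=float(np.mean(corrected)) if corrected else float("nan"),
        corrected_p_values=corrected,
        levels=levels_df,
        branches=pd.DataFrame(branch_rows),
        n_resamplings=plan.R,
        n_skipped=n_skipped,
        B=B,
        plan=plan,
    )
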