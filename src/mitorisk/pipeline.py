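"""End-to-end pipeline: QC -> assignment -> association -> localization -> Cox.

Every stage writes its outputs to the run directory, so each stage is also
independently invocable from the previous stage's files; a machine-readable
manifest (config hash, seed, package version) makes runs reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assign import (
    assign_individuals,
    assignment_rate,
    assignments_to_frame,
    build_short_haplotype_index,
)
from .association import ResamplingPlan, run_resampled_association
from .errors import ConfigurationError, DataError
from .localization import localize_susceptibility_sites
from .qc import GenotypeMatrix, QCConfig, run_qc
from .risk import IncidenceTable, compute_weights, fit_weighted_cox, survival_frame
from .tree import LocusPanel, ReferenceTree


@dataclass
class PipelineConfig:
    """Paths plus analysis settings; defaults B=1000, R=1000, epsilon=1."""

    tree: str
    panel: str
    genotypes: str
    metadata: str
    incidence: str | None = None
    clade_roots: list = field(default_factory=list)
    permutations: int = 1000
    resamplings: int = 1000
    epsilon: float = 1.0
    seed: int | None = None
    outdir: str = "mitorisk_out"
    localization_alpha: float = 0.05
    cox_exposure_node: str | None = None
    cox_reference_clade: str | None = None
    max_missing_fraction: float = 0.05
    max_het_fraction: float = 0.05

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _check_inputs(cfg: PipelineConfig) -> None:
    for name in ("tree", "panel", "genotypes", "metadata"):
        path = getattr(cfg, name)
        if not Path(path).is_file():
            raise ConfigurationError(f"{name} file not found: {path}")
    if cfg.incidence is not None and not Path(cfg.incidence).is_file():
        raise ConfigurationError(f"incidence file not found: {cfg.incidence}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns a summary dict (also written as JSON)."""
    _check_inputs(cfg)
    panel = LocusPanel.from_tsv(cfg.panel)
    tree = ReferenceTree.from_tsv(cfg.tree, panel=panel)
    gm, n_bad = GenotypeMatrix.from_tsv(cfg.genotypes, panel)
    metadata = pd.read_csv(cfg.metadata, sep="\t")
    if set(metadata["sample_id"].astype(str)) != set(map(str, gm.samples)):
        raise ConfigurationError("metadata and genotype samples disagree")

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    qc_cfg = QCConfig(
        max_missing_fraction=cfg.max_missing_fraction,
        max_het_fraction=cfg.max_het_fraction,
    )
    clean, qc_report = run_qc(gm, tree, qc_cfg)
    qc_report.to_tsv(outdir / "qc_loci.tsv", outdir / "qc_samples.tsv")
    qc_report.to_json(outdir / "qc_summary.json")

    index = build_short_haplotype_index(tree, clean.panel)
    assignments = assign_individuals(clean, index)
    assign_df = assignments_to_frame(assignments)
    assign_df.to_csv(outdir / "assignments.tsv", sep="\t", index=False)

    metadata = metadata.copy()
    metadata["sample_id"] = metadata["sample_id"].astype(str)
    data = assign_df[assign_df["matched"]].merge(metadata, on="sample_id")
    data = data[data["haplogroup"] != ""]

    assoc_summaries = {}
    flagged = []
    for i, clade in enumerate(cfg.clade_roots):
        agg = run_resampled_association(
            tree,
            data,
            clade,
            plan=ResamplingPlan(
                R=cfg.resamplings,
                seed=None if cfg.seed is None else cfg.seed + i,
            ),
            B=cfg.permutations,
        )
        agg.levels.to_csv(outdir / f"assoc_{clade}_levels.tsv", sep="\t", index=False)
        agg.branches.to_csv(outdir / f"assoc_{clade}_branches.tsv", sep="\t", index=False)
        assoc_summaries[clade] = {
            "mean_corrected_p": agg.mean_corrected_p,
            "n_resamplings": agg.n_resamplings,
            "n_skipped": agg.n_skipped,
        }
        if np.isfinite(agg.mean_corrected_p) and agg.mean_corrected_p <= cfg.localization_alpha:
            flagged.append(clade)

    localization_files = {}
    for clade in flagged:
        loc = localize_susceptibility_sites(
            tree, clean.panel, data, clade, epsilon=cfg.epsilon
        )
        path = outdir / f"localization_{clade}.tsv"
        loc.to_csv(path, sep="\t", index=False)
        localization_files[clade] = str(path)

    cox_summary = None
    if cfg.cox_exposure_node is not None:
        cox_data = data
        if cfg.cox_reference_clade is not None:
            subtree = set(tree.subtree_nodes(cfg.cox_reference_clade))
            cox_data = data[data["haplogroup"].isin(subtree)]
        exposure_subtree = set(tree.subtree_nodes(cfg.cox_exposure_node))
        cox_data = survival_frame(cox_data)
        cox_data = cox_data.assign(
            exposure=np.where(
                cox_data["haplogroup"].isin(exposure_subtree),
                cfg.cox_exposure_node,
                "other",
            )
        )
        if cfg.incidence is not None:
            incidence = IncidenceTable.from_tsv(cfg.incidence)
            _, weights = compute_weights(cox_data, incidence)
        else:
            weights = None
        result = fit_weighted_cox(cox_data, weights, exposure="exposure", reference="other")
        cox_summary = result.to_dict()
        with open(outdir / "cox.json", "w") as fh:
            json.dump(cox_summary, fh, indent=2)

    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "invalid_calls_recoded": n_bad,
        "qc": qc_report.summary(),
        "assignment_rate": assignment_rate(assignments),
        "association": assoc_summaries,
        "flagged_clades": flagged,
        "localization_files": localization_files,
        "cox": cox_summary,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
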