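"""SNP- and sample-level quality filtering of mtDNA genotype matrices.

Call codes: A/C/G/T observed allele, N missing, H heterozygous-like call
(heteroplasmy or artefact on a haploid genome).  Filtering mirrors array-QC
practice for mitochondrial panels: drop annotated triallelic and
cross-mapping loci, monoallelic loci, loci with excess missingness or excess
heterozygous calls, and "private" loci absent from the reference tree; then
recode surviving H calls to missing and keep only samples with complete
haplotypes over the retained loci.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, EmptyCohortError, EmptyPanelError
from .tree import LocusPanel, ReferenceTree

CALL_CODES = frozenset("ACGTNH")


@dataclass
class GenotypeMatrix:
    """Samples x panel-loci matrix of call codes.

    ``calls`` is a pandas DataFrame indexed by sample id with one column per
    panel position (int), values in {A,C,G,T,N,H}.
    """

    calls: pd.DataFrame
    panel: LocusPanel

    def __post_init__(self):
        if list(self.calls.columns) != self.panel.positions:
            raise ConfigurationError("genotype columns do not match panel positions")

    @property
    def samples(self) -> list[str]:
        return list(self.calls.index)

    @property
    def positions(self) -> list[int]:
        return list(self.calls.columns)

    def restrict_loci(self, positions) -> "GenotypeMatrix":
        positions = list(positions)
        return GenotypeMatrix(self.calls[positions].copy(), self.panel.restrict(positions))

    def restrict_samples(self, samples) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.loc[list(samples)].copy(), self.panel)

    @classmethod
    def from_tsv(cls, path, panel: LocusPanel) -> tuple["GenotypeMatrix", int]:
        """Read a genotype TSV (``sample_id`` + one column per position).

        Calls that are neither N/H nor one of the locus's two alleles are
        counted and recoded to N; the count is returned alongside.
        """
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if df.columns[0] != "sample_id":
            raise DataError("first genotype column must be sample_id")
        df = df.set_index("sample_id")
        df.columns = [int(c) for c in df.columns]
        if list(df.columns) != panel.positions:
            raise ConfigurationError("genotype file positions do not match panel")
        bad = 0
        for locus in panel:
            col = df[locus.position]
            ok = col.isin([locus.ref_allele, locus.alt_allele, "N", "H"])
            bad += int((~ok).sum())
            if (~ok).any():
                df.loc[~ok, locus.position] = "N"
        return cls(df, panel), bad

    def to_tsv(self, path) -> None:
        out = self.calls.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


@dataclass
class QCConfig:
    """Filtering thresholds; the 5% defaults are strict ('more than 5%')."""

    max_missing_fraction: float = 0.05
    max_het_fraction: float = 0.05
    drop_triallelic: bool = True
    drop_crossmap: bool = True
    drop_private: bool = True

    def __post_init__(self):
        for f in (self.max_missing_fraction, self.max_het_fraction):
            if not 0 <= f <= 1:
                raise ConfigurationError("QC fractions must lie in [0,1]")


@dataclass
class QCReport:
    """Per-locus and per-sample dispositions plus reconciled counts."""

    loci: pd.DataFrame = field(default_factory=pd.DataFrame)
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_loci_kept(self) -> int:
        return int((self.loci["disposition"] == "kept").sum()) if len(self.loci) else 0

    @property
    def n_samples_kept(self) -> int:
        return (
            int((self.samples["disposition"] == "kept").sum()) if len(self.samples) else 0
        )

    def summary(self) -> dict:
        out = {}
        if len(self.loci):
            out["loci_in"] = int(len(self.loci))
            out["loci_kept"] = self.n_loci_kept
            out["loci_dropped_by_reason"] = (
                self.loci.loc[self.loci["disposition"] == "dropped", "reason"]
                .value_counts()
                .to_dict()
            )
        if len(self.samples):
            out["samples_in"] = int(len(self.samples))
            out["samples_kept"] = self.n_samples_kept
        return out

    def to_tsv(self, loci_path=None, samples_path=None) -> None:
        if loci_path is not None:
            self.loci.to_csv(loci_path, sep="\t", index=False)
        if samples_path is not None:
            self.samples.to_csv(samples_path, sep="\t", index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def apply_snp_filters(
    gm: GenotypeMatrix, tree: ReferenceTree, cfg: QCConfig | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop loci in a fixed order and recode surviving H calls to N.

    Order: annotated triallelic; annotated crossmap; monoallelic (minor
    allele count 0 among non-N, non-H calls); missing (N) fraction above
    threshold; heterozygous (H) fraction above threshold; private loci
    (panel positions appearing in no tree-edge mutation).  Each locus is
    attributed the first reason that applies.
    """
    cfg = cfg or QCConfig()
    if len(gm.calls) == 0 or len(gm.panel) == 0:
        raise DataError("empty genotype matrix")
    n = len(gm.calls)
    tree_positions = {m.position for muts in tree.edge_mutations.values() for m in muts}

    records = []
    kept = []
    for locus in gm.panel:
        col = gm.calls[locus.position]
        n_missing = int((col == "N").sum())
        n_het = int((col == "H").sum())
        called = col[~col.isin(["N", "H"])]
        minor_count = 0
        if len(called):
            counts = called.value_counts()
            minor_count = int(len(called) - counts.max())
        reason = None
        if cfg.drop_triallelic and "triallelic" in locus.flags:
            reason = "triallelic"
        elif cfg.drop_crossmap and "crossmap" in locus.flags:
            reason = "crossmap"
        elif minor_count == 0:
            reason = "monoallelic"
        elif n_missing / n > cfg.max_missing_fraction:
            reason = "missingness"
        elif n_het / n > cfg.max_het_fraction:
            reason = "heterozygosity"
        elif cfg.drop_private and locus.position not in tree_positions:
            reason = "private"
        records.append(
            {
                "position": locus.position,
                "disposition": "kept" if reason is None else "dropped",
                "reason": reason or "",
                "n_missing": n_missing,
                "n_het": n_het,
                "minor_allele_count": minor_count,
            }
        )
        if reason is None:
            kept.append(locus.position)

    if not kept:
        raise EmptyPanelError("all loci removed by SNP filters")
    out = gm.restrict_loci(kept)
    out.calls = out.calls.replace("H", "N")
    report = QCReport(loci=pd.DataFrame.from_records(records))
    return out, report


def apply_sample_filter(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, QCReport]:
    """Keep exactly the samples with fully defined haplotypes (no N)."""
    has_n = (gm.calls == "N").any(axis=1)
    if (gm.calls == "H").any().any():
        warnings.warn("H calls present; expected SNP filters to have recoded them")
        has_n = has_n | (gm.calls == "H").any(axis=1)
    report = QCReport(
        samples=pd.DataFrame(
            {
                "sample_id": gm.calls.index,
                "disposition": np.where(has_n, "dropped", "kept"),
                "reason": np.where(has_n, "incomplete haplotype", ""),
            }
        )
    )
    keep = gm.calls.index[~has_n]
    if len(keep) == 0:
        raise EmptyCohortError("no sample has a complete haplotype")
    return gm.restrict_samples(keep), report


def run_qc(
    gm: GenotypeMatrix, tree: ReferenceTree, cfg: QCConfig | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """SNP filters followed by the complete-haplotype sample filter."""
    out, locus_report = apply_snp_filters(gm, tree, cfg)
    out, sample_report = apply_sample_filter(out)
    return out, QCReport(loci=locus_report.loci, samples=sample_report.samples)
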