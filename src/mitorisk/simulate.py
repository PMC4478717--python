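"""Synthetic reference trees, panels and carrier cohorts with known truth.

The generator emulates the structure of a multi-centre BRCA1/2
mutation-carrier cohort genotyped on a sparse (~93-locus) mtDNA panel:
maternally shared haplotypes within families, haplogroup frequencies of the
analysed clades, country strata, age-dependent disease incidence under a
piecewise-exponential hazard with a multiplicative per-haplogroup effect,
censoring at a drawn interview age, and 5%-scale missingness, heteroplasmic
calls and genotyping errors injected into the emitted genotypes.

One global seed governs all draws through an explicit stream-splitting
scheme (numpy SeedSequence spawning one child stream per stage), so
demography, disease and genotype noise are independently reproducible.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .qc import GenotypeMatrix
from .tree import MT_GENOME_LENGTH, Locus, LocusPanel, Mutation, ReferenceTree

ALLELES = np.array(list("ACGT"))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# reference tree simulation


def simulate_reference_tree(
    n_nodes: int,
    seed=None,
    panel_fraction: float = 1.0,
    mean_extra_mutations: float = 0.3,
    back_mutation_rate: float = 0.0,
    n_private_loci: int = 0,
) -> tuple[ReferenceTree, LocusPanel]:
    """Random rooted haplogroup tree plus a panel covering a fraction of it.

    Every edge carries at least one substitution at a fresh genome position;
    ``panel_fraction`` of the mutated positions enter the panel (lower
    fractions create MRCA ambiguity).  With ``back_mutation_rate`` an edge
    may additionally revert an upstream substitution to the reference
    allele.  ``n_private_loci`` appends panel loci never touched by the tree
    (exercising the private-locus QC rule).
    """
    if n_nodes < 3:
        raise ConfigurationError("need at least 3 nodes")
    rng = _rng(seed)
    genome_ref: dict[int, str] = {}
    derived: dict[int, str] = {}
    free_positions = rng.permutation(np.arange(1, MT_GENOME_LENGTH + 1)).tolist()

    names = ["RSRS"]
    parent: dict[str, str] = {}
    edge_mutations: dict[str, list[Mutation]] = {}
    node_state: dict[str, dict[int, str]] = {"RSRS": {}}
    n_children: dict[str, int] = {"RSRS": 0}
    letters = list(string.ascii_uppercase)

    for _ in range(n_nodes - 1):
        par = names[int(rng.integers(len(names)))]
        n_children[par] += 1
        if par == "RSRS":
            i = n_children[par] - 1
            child = letters[i % 26] + ("" if i < 26 else str(i // 26))
        else:
            child = f"{par}{n_children[par]}"
        state = dict(node_state[par])
        muts: list[Mutation] = []
        n_new = 1 + int(rng.poisson(mean_extra_mutations))
        for _ in range(n_new):
            pos = int(free_positions.pop())
            ref = str(rng.choice(ALLELES))
            alt = str(rng.choice([a for a in "ACGT" if a != ref]))
            genome_ref[pos] = ref
            derived[pos] = alt
            muts.append(Mutation(position=pos, from_allele=ref, to_allele=alt))
            state[pos] = alt
        if back_mutation_rate > 0 and rng.random() < back_mutation_rate:
            off_ref = [p for p, a in state.items() if a != genome_ref[p]]
            if off_ref:
                pos = int(off_ref[int(rng.integers(len(off_ref)))])
                muts.append(
                    Mutation(
                        position=pos, from_allele=state[pos], to_allele=genome_ref[pos]
                    )
                )
                state[pos] = genome_ref[pos]
        parent[child] = par
        edge_mutations[child] = muts
        node_state[child] = state
        n_children[child] = 0
        names.append(child)

    positions = sorted(genome_ref)
    n_panel = int(round(panel_fraction * len(positions)))
    panel_positions = sorted(
        rng.choice(positions, size=n_panel, replace=False).tolist()
    )
    loci = [
        Locus(position=p, ref_allele=genome_ref[p], alt_allele=derived[p])
        for p in panel_positions
    ]
    for _ in range(n_private_loci):
        pos = int(free_positions.pop())
        ref = str(rng.choice(ALLELES))
        alt = str(rng.choice([a for a in "ACGT" if a != ref]))
        loci.append(Locus(position=pos, ref_allele=ref, alt_allele=alt))
    loci.sort(key=lambda l: l.position)
    panel = LocusPanel(loci)
    tree = ReferenceTree("RSRS", parent, edge_mutations)
    tree.validate_mutation_consistency(panel)
    return tree, panel


# ---------------------------------------------------------------------------
# curated miniature reference tree (clades relevant to the analysis)


_CURATED_EDGES = [
    ("RSRS", "H", "G2706A,T7028C"),
    ("H", "H1", "G3010A"),
    ("H", "H2", "G1438A"),
    ("H", "H3", "T6776C"),
    ("H1", "H1a", "T3796C"),
    ("H1", "H1b", "T16189C"),
    ("RSRS", "T", "A4917G,C10463T"),
    ("T", "T1", "T9899C,G12633A"),
    ("T1", "T1a", "G9117A"),
    ("T1a", "T1a1", "C152T"),
    ("T", "T2", "G11812A,G13708A"),
    ("T2", "T2a", "C5187T"),
    ("T2", "T2b", "G930A"),
    ("T2b", "T2b1", "C16294T"),
    ("T2", "T2c", "T146C"),
    ("T2", "T2e", "A11251G"),
    ("RSRS", "U", "A11467G"),
    ("U", "U5", "C16270T"),
    ("U5", "U5a", "A14793G"),
    ("U5", "U5b", "C150T"),
    ("U", "U8", "A1811G"),
    ("U8", "K", "G9055A"),
    ("K", "K1a", "A10550G"),
    ("RSRS", "J", "T4216C,C295T"),
    ("J", "J1", "C462T"),
    ("J1", "J1c", "G185A"),
    ("J", "J2", "C7476T"),
    ("RSRS", "X", "T6221C"),
    ("X", "X2", "G225A"),
]


def curated_tree() -> tuple[ReferenceTree, LocusPanel]:
    """Miniature mtDNA-like reference tree (clades H, T, U/K, J, X).

    Synthetic stand-in for a PhyloTree-style reference: topology and
    mutation positions echo the real clade structure but are a hand-built
    miniature, at full panel resolution (every defining substitution is on
    the panel).
    """
    loci = []
    for _, _, tokens in _CURATED_EDGES:
        for token in tokens.split(","):
            m = Mutation.parse(token)
            loci.append(
                Locus(position=m.position, ref_allele=m.from_allele, alt_allele=m.to_allele)
            )
    loci.sort(key=lambda l: l.position)
    panel = LocusPanel(loci)
    tree = ReferenceTree.from_edge_table(_CURATED_EDGES, panel=panel)
    return tree, panel


def clade_t_frequencies() -> dict:
    """Haplogroup frequencies within clade T, echoing the observed mix:
    ~5% paragroup T, ~17% T1a1 lineage, ~78% T2 subclades."""
    return {
        "T": 0.051,
        "T1a1": 0.169,
        "T2": 0.080,
        "T2a": 0.180,
        "T2b": 0.160,
        "T2b1": 0.080,
        "T2c": 0.150,
        "T2e": 0.130,
    }


def clade_th_frequencies() -> dict:
    """Clade T plus clade H, sized like a BRCA2 carrier set (~651 T vs
    ~1,967 H, i.e. T fraction ~0.249)."""
    t_share = 651 / (651 + 1967)
    freqs = {hg: f * t_share for hg, f in clade_t_frequencies().items()}
    h_mix = {"H": 0.20, "H1": 0.25, "H1a": 0.10, "H1b": 0.05, "H2": 0.20, "H3": 0.20}
    freqs.update({hg: f * (1 - t_share) for hg, f in h_mix.items()})
    return freqs


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class SimConfig:
    """Generative settings for a carrier cohort.

    Hazard-ratio keys are haplogroup names; the multiplier applies to the
    named haplogroup and its whole subclade (multipliers multiply if
    nested).  Rates are per-call probabilities.
    """

    n_individuals: int = 650
    haplogroup_freqs: dict = field(default_factory=clade_t_frequencies)
    family_size_probs: dict = field(default_factory=lambda: {1: 0.80, 2: 0.15, 3: 0.05})
    share_haplotype_prob: float = 1.0
    countries: dict = field(
        default_factory=lambda: {
            "FR": 0.20, "UK": 0.20, "US": 0.20, "DE": 0.15, "IT": 0.15, "NL": 0.10,
        }
    )
    gene: str = "BRCA2"
    baseline_hazard: list = field(
        default_factory=lambda: [
            (20.0, 30.0, 0.002),
            (30.0, 40.0, 0.008),
            (40.0, 50.0, 0.018),
            (50.0, 60.0, 0.022),
            (60.0, 70.0, 0.020),
            (70.0, 80.0, 0.015),
        ]
    )
    hazard_ratios: dict = field(default_factory=dict)
    interview_age_mean: float = 50.0
    interview_age_sd: float = 12.0
    interview_age_range: tuple = (21.0, 80.0)
    missing_rate: float = 0.002
    het_rate: float = 0.001
    error_rate: float = 0.0005
    seed: int | None = None

    def __post_init__(self):
        total = sum(self.haplogroup_freqs.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ConfigurationError(f"haplogroup frequencies sum to {total}, not 1")
        for r in (self.missing_rate, self.het_rate, self.error_rate,
                  self.share_haplotype_prob):
            if not 0 <= r <= 1:
                raise ConfigurationError("rates must lie in [0,1]")
        if any(hr <= 0 for hr in self.hazard_ratios.values()):
            raise ConfigurationError("hazard ratios must be positive")
        if all(rate <= 0 for _, _, rate in self.baseline_hazard):
            raise ConfigurationError("degenerate baseline hazard (all zero)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated cohort."""

    frame: pd.DataFrame  # per sample: haplogroup, family, multiplier, ages
    injections: pd.DataFrame  # sample_id, position, kind in {missing,het,error}
    config: SimConfig


def _hazard_multiplier(tree: ReferenceTree, node: str, hazard_ratios: dict) -> float:
    mult = 1.0
    path = set(tree.root_path(node))
    for key, hr in hazard_ratios.items():
        if key in path:
            mult *= hr
    return mult


def _draw_event_age(bands, multiplier: float, u: float) -> float:
    """Invert the piecewise-exponential cumulative hazard at -log(u)."""
    target = -np.log(u) / multiplier
    acc = 0.0
    for lo, hi, rate in bands:
        seg = rate * (hi - lo)
        if acc + seg >= target and rate > 0:
            return lo + (target - acc) / rate
        acc += seg
    return float("inf")


def simulate_cohort(
    tree: ReferenceTree,
    panel: LocusPanel,
    cfg: SimConfig,
    seed=None,
) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Families, disease histories and noisy genotypes with known truth."""
    for hg in cfg.haplogroup_freqs:
        if hg not in tree:
            raise ConfigurationError(f"frequency given for unknown haplogroup {hg!r}")
    base = cfg.seed if seed is None else seed
    ss = (
        base
        if isinstance(base, np.random.SeedSequence)
        else np.random.SeedSequence(base)
    )
    rng_demo, rng_disease, rng_geno = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )

    hgs = sorted(cfg.haplogroup_freqs)
    hg_p = np.array([cfg.haplogroup_freqs[h] for h in hgs])
    hg_p = hg_p / hg_p.sum()
    sizes = sorted(cfg.family_size_probs)
    size_p = np.array([cfg.family_size_probs[s] for s in sizes], dtype=float)
    size_p /= size_p.sum()
    countries = sorted(cfg.countries)
    country_p = np.array([cfg.countries[c] for c in countries], dtype=float)
    country_p /= country_p.sum()

    rows = []
    fam = 0
    while len(rows) < cfg.n_individuals:
        fam += 1
        fam_id = f"F{fam:05d}"
        size = int(rng_demo.choice(sizes, p=size_p))
        size = min(size, cfg.n_individuals - len(rows))
        country = str(rng_demo.choice(countries, p=country_p))
        fam_hg = str(rng_demo.choice(hgs, p=hg_p))
        for _ in range(size):
            hg = fam_hg
            if rng_demo.random() >= cfg.share_haplotype_prob:
                hg = str(rng_demo.choice(hgs, p=hg_p))
            rows.append(
                {
                    "sample_id": f"S{len(rows) + 1:06d}",
                    "family_id": fam_id,
                    "country": country,
                    "gene": cfg.gene,
                    "haplogroup": hg,
                }
            )
    demo = pd.DataFrame(rows)

    lo, hi = cfg.interview_age_range
    mult = np.array(
        [_hazard_multiplier(tree, h, cfg.hazard_ratios) for h in demo["haplogroup"]]
    )
    u = rng_disease.random(len(demo))
    event_age = np.array(
        [_draw_event_age(cfg.baseline_hazard, m, ui) for m, ui in zip(mult, u)]
    )
    interview = np.clip(
        rng_disease.normal(cfg.interview_age_mean, cfg.interview_age_sd, len(demo)),
        lo,
        hi,
    )
    status = (event_age <= interview).astype(int)

    metadata = demo[["sample_id", "family_id", "country", "gene"]].copy()
    metadata["status"] = status
    metadata["age_diagnosis"] = np.where(status == 1, event_age, np.nan)
    metadata["age_censor"] = interview

    # genotypes from true node states, then injected noise
    node_keys = {h: tree.node_haplotype(h, panel).key() for h in hgs}
    n, L = len(demo), len(panel)
    calls = np.empty((n, L), dtype="<U1")
    for i, h in enumerate(demo["haplogroup"]):
        calls[i] = node_keys[h]
    r = rng_geno.random((n, L))
    miss = r < cfg.missing_rate
    het = (~miss) & (r < cfg.missing_rate + cfg.het_rate)
    err = (~miss) & (~het) & (r < cfg.missing_rate + cfg.het_rate + cfg.error_rate)
    inj_rows = []
    refs = np.array([l.ref_allele for l in panel])
    alts = np.array([l.alt_allele for l in panel])
    for i, j in zip(*np.nonzero(err)):
        calls[i, j] = alts[j] if calls[i, j] == refs[j] else refs[j]
        inj_rows.append((demo["sample_id"].iat[i], panel.positions[j], "error"))
    for i, j in zip(*np.nonzero(het)):
        calls[i, j] = "H"
        inj_rows.append((demo["sample_id"].iat[i], panel.positions[j], "het"))
    for i, j in zip(*np.nonzero(miss)):
        calls[i, j] = "N"
        inj_rows.append((demo["sample_id"].iat[i], panel.positions[j], "missing"))

    gm = GenotypeMatrix(
        pd.DataFrame(calls, index=demo["sample_id"], columns=panel.positions),
        panel,
    )
    truth_frame = demo.assign(
        hazard_multiplier=mult,
        event_age=event_age,
        interview_age=interview,
        status=status,
        short_haplotype=["".join(node_keys[h]) for h in demo["haplogroup"]],
    )
    injections = pd.DataFrame(inj_rows, columns=["sample_id", "position", "kind"])
    return gm, metadata, SimTruth(frame=truth_frame, injections=injections, config=cfg)


def empirical_incidence(metadata: pd.DataFrame, band_width: float = 5.0,
                        age_range: tuple = (20.0, 80.0)):
    """Affected fraction per (gene, age band) from a (large) cohort.

    Serves as the external age-by-gene incidence input for the weighted Cox
    model; classes with few members fall back to the gene-wide fraction.
    Probabilities are clamped into (0, 1).
    """
    from .risk import IncidenceTable, survival_frame

    df = survival_frame(metadata)
    lo, hi = age_range
    edges = np.arange(lo, hi + band_width, band_width)
    rows = []
    for gene, sub in df.groupby("gene"):
        overall = sub["status"].mean()
        for a, b in zip(edges[:-1], edges[1:]):
            in_band = sub[(sub["time"] >= a) & (sub["time"] < b)]
            if b == edges[-1]:
                in_band = sub[(sub["time"] >= a) & (sub["time"] <= b)]
            p = in_band["status"].mean() if len(in_band) >= 10 else overall
            p = float(np.clip(p, 1e-4, 1 - 1e-4))
            rows.append({"gene": gene, "age_low": a, "age_high": b, "p": p})
    return IncidenceTable(pd.DataFrame(rows))
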