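"""Synthetic cohort generator.

Emulates the statistical structure of a staged canine heart-disease
(MMVD) gut-microbiome study: four ACVIM stages (A, B1, B2, CD) with an
age-stage confound, stage effects on community evenness and on marker
taxa, a qPCR panel tied to matched OTUs, a threshold-governed
primary-to-secondary bile-acid conversion driven by the abundance of a
converter bacterium (C. hiranonis-like), serum metabolites carrying
microbe associations, and stage-free short-chain fatty acids.

Every output is a pure function of (config, seed): per-operation RNG
streams are spawned from ``numpy.random.SeedSequence([seed, offset])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import (
    OtuTable,
    STAGES,
    QPCR_TARGETS,
    BILE_ACIDS,
    SCFAS,
)

#: OTU roles with built-in stage effects; lineages mirror the marker taxa.
ROLE_LINEAGES = {
    "ecoli_like": "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacteriales;f__Enterobacteriaceae;g__Escherichia;s__coli",
    "turicibacter_like": "k__Bacteria;p__Firmicutes;c__Bacilli;o__Turicibacterales;f__Turicibacteraceae;g__Turicibacter;s__",
    "fusobacterium_like": "k__Bacteria;p__Fusobacteria;c__Fusobacteriia;o__Fusobacteriales;f__Fusobacteriaceae;g__Fusobacterium;s__",
    "faecalibacterium_like": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Ruminococcaceae;g__Faecalibacterium;s__prausnitzii",
    "chiranonis_like": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Clostridiaceae;g__Clostridium;s__hiranonis",
    "erysipelotrichaceae_like": "k__Bacteria;p__Firmicutes;c__Erysipelotrichi;o__Erysipelotrichales;f__Erysipelotrichaceae;g__Eubacterium;s__dolichum",
    "megamonas_like": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Veillonellaceae;g__Megamonas;s__",
    "streptococcus_like": "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;f__Streptococcaceae;g__Streptococcus;s__",
    "blautia_like": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Blautia;s__",
}

#: qPCR panel target -> OTU role carrying its signal.
TARGET_ROLES = {
    "faecalibacterium": "faecalibacterium_like",
    "turicibacter": "turicibacter_like",
    "streptococcus": "streptococcus_like",
    "e_coli": "ecoli_like",
    "blautia": "blautia_like",
    "fusobacterium": "fusobacterium_like",
    "c_hiranonis": "chiranonis_like",
}

_FILLER_FAMILIES = [
    "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__;s__",
    "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Ruminococcaceae;g__;s__",
    "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Bacteroidaceae;g__Bacteroides;s__",
    "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Prevotellaceae;g__Prevotella;s__",
    "k__Bacteria;p__Actinobacteria;c__Coriobacteriia;o__Coriobacteriales;f__Coriobacteriaceae;g__;s__",
    "k__Bacteria;p__Proteobacteria;c__Betaproteobacteria;o__Burkholderiales;f__Alcaligenaceae;g__Sutterella;s__",
    "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__;g__;s__",
    "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;f__Lactobacillaceae;g__Lactobacillus;s__",
]


def _default_effect_table() -> dict:
    # log2 shifts per stage; directions follow the study's findings:
    # E. coli enriched in advanced disease, the marker commensals depleted.
    return {
        "ecoli_like": {"A": 0.0, "B1": 0.0, "B2": 1.0, "CD": 2.0},
        "turicibacter_like": {"A": 0.0, "B1": -1.0, "B2": -1.5, "CD": -2.0},
        "fusobacterium_like": {"A": 0.0, "B1": -0.5, "B2": -1.0, "CD": -1.5},
        "faecalibacterium_like": {"A": 0.0, "B1": -0.5, "B2": -1.0, "CD": -1.5},
        "chiranonis_like": {"A": 0.0, "B1": -0.5, "B2": -1.5, "CD": -2.5},
        "erysipelotrichaceae_like": {"A": 0.0, "B1": -0.5, "B2": -1.0, "CD": -1.5},
        "megamonas_like": {"A": 0.0, "B1": -0.5, "B2": -1.0, "CD": -1.5},
        "streptococcus_like": {"A": 0.0, "B1": 0.5, "B2": 1.0, "CD": 1.5},
        "blautia_like": {"A": 0.0, "B1": -0.3, "B2": -0.6, "CD": -1.0},
    }


@dataclass
class CohortConfig:
    """Generative parameters of the synthetic cohort.

    Defaults reproduce the study conditions: group sizes 17/23/27/25 for
    stages A/B1/B2/CD, group mean ages 8.9/10.3/10.2/11.5 years (the age
    confound), mean body weights 10.4/9.2/8.1/7.8 kg, a converter
    threshold of 4.5 log10 units, and a near-step logistic conversion
    (steepness 8).
    """

    group_sizes: dict = field(default_factory=lambda: {"A": 17, "B1": 23, "B2": 27, "CD": 25})
    n_otus: int = 300
    age_means: dict = field(default_factory=lambda: {"A": 8.9, "B1": 10.3, "B2": 10.2, "CD": 11.5})
    # Table 1 prints means +/- SE; SE * sqrt(n) puts the within-group age
    # SD near 2 years, which is what makes age-balanced subsamples findable
    age_sd: float = 2.0
    bw_means: dict = field(default_factory=lambda: {"A": 10.4, "B1": 9.2, "B2": 8.1, "CD": 7.8})
    bw_sd: float = 3.0
    evenness_concentration: dict = field(
        default_factory=lambda: {"A": 250.0, "B1": 150.0, "B2": 90.0, "CD": 50.0}
    )
    effect_table: dict = field(default_factory=_default_effect_table)
    depth_median: int = 15000
    depth_sigma: float = 0.3
    conversion_threshold: float = 4.5
    conversion_steepness: float = 8.0
    qpcr_noise_sd: float = 0.3
    qpcr_intercept: float = 8.0
    qpcr_slope: float = 1.0
    chiranonis_stage_centers: dict = field(
        default_factory=lambda: {"A": 6.0, "B1": 5.5, "B2": 4.8, "CD": 4.0}
    )
    ba_total_median: float = 20.0
    ba_total_sigma: float = 0.5
    ba_split_concentration: float = 50.0
    assoc_beta: float = 0.3
    # noise scaled so planted partial correlations land near |r| 0.2-0.5,
    # the range serum-metabolite screens typically report as significant
    metabolite_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("all group sizes must be >= 2")
        if self.n_otus < 10:
            raise ValueError("n_otus must be >= 10")
        if any(c <= 0 for c in self.evenness_concentration.values()):
            raise ValueError("evenness concentrations must be > 0")
        centers = self.chiranonis_stage_centers.values()
        if not (min(centers) <= self.conversion_threshold <= max(centers)):
            raise ValueError("conversion threshold outside the simulated C. hiranonis range")
        unknown = set(self.effect_table) - set(ROLE_LINEAGES)
        if unknown:
            raise ValueError(f"unknown role(s) in effect_table: {sorted(unknown)}")

    def null(self) -> "CohortConfig":
        """A copy with every group effect switched off (for calibration runs)."""
        mean_age = float(np.mean(list(self.age_means.values())))
        mean_bw = float(np.mean(list(self.bw_means.values())))
        mean_conc = float(np.mean(list(self.evenness_concentration.values())))
        mid = self.conversion_threshold
        return replace(
            self,
            age_means={s: mean_age for s in self.group_sizes},
            bw_means={s: mean_bw for s in self.group_sizes},
            evenness_concentration={s: mean_conc for s in self.group_sizes},
            effect_table={r: {s: 0.0 for s in self.group_sizes} for r in self.effect_table},
            chiranonis_stage_centers={s: mid for s in self.group_sizes},
            assoc_beta=0.0,
        )


@dataclass
class SyntheticCohort:
    otu_table: OtuTable
    tree: TreeNode
    metadata: pd.DataFrame
    qpcr: pd.DataFrame
    bile_acids: pd.DataFrame
    scfa: pd.DataFrame
    metabolites: pd.DataFrame
    truth: dict


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def simulate_tree(n_otus: int, seed: int) -> TreeNode:
    """Random rooted bifurcating tree over OTU tips.

    Built by repeatedly joining two uniformly chosen clades; branch
    lengths are exponential with mean 0.1.  The same seed yields an
    identical Newick serialization.
    """
    if n_otus < 2:
        raise ValueError("n_otus must be >= 2")
    rng = _rng(seed, 0)
    clades = [TreeNode(name=f"OTU{i+1:04d}") for i in range(n_otus)]
    while len(clades) > 1:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        right = clades.pop(j)
        left = clades.pop(i)
        left.length = float(rng.exponential(0.1))
        right.length = float(rng.exponential(0.1))
        clades.append(TreeNode(children=[left, right]))
    root = clades[0]
    root.length = None
    return root


def _truncated_normal(rng, mean, sd, size, floor):
    x = rng.normal(mean, sd, size)
    while np.any(x < floor):
        n_bad = int(np.sum(x < floor))
        x[x < floor] = rng.normal(mean, sd, n_bad)
    return x


def simulate_counts(config: CohortConfig, tree: TreeNode) -> tuple[OtuTable, pd.DataFrame, dict]:
    """Draw per-sample metadata and multinomial OTU counts.

    Composition per sample is a softmax of shared baseline log-abundances
    (Normal, SD 2) plus role-specific per-stage log2 shifts, perturbed by
    a Dirichlet draw whose total concentration is the stage's evenness
    parameter (healthier stages are more even, hence more diverse after
    rarefaction).  Sequencing depth is log-normal around the median depth.
    """
    n_otus = config.n_otus
    tips = sorted(t.name for t in tree.tips())
    if len(tips) != n_otus:
        raise ValueError(f"tree has {len(tips)} tips, config expects {n_otus}")
    unknown = set(config.effect_table) - set(ROLE_LINEAGES)
    if unknown:
        raise ValueError(f"unknown role(s) in effect_table: {sorted(unknown)}")

    rng = _rng(config.seed, 1)

    # stages and metadata
    stages = [s for s in STAGES if s in config.group_sizes] + [
        s for s in config.group_sizes if s not in STAGES
    ]
    stage_col, sample_ids = [], []
    for s in stages:
        n = config.group_sizes[s]
        for i in range(n):
            sample_ids.append(f"{s}{i+1:03d}")
            stage_col.append(s)
    n_samples = len(sample_ids)
    stage_arr = np.array(stage_col)
    age = np.concatenate(
        [
            _truncated_normal(rng, config.age_means[s], config.age_sd, config.group_sizes[s], 1.0)
            for s in stages
        ]
    )
    bw = np.concatenate(
        [
            _truncated_normal(rng, config.bw_means[s], config.bw_sd, config.group_sizes[s], 2.0)
            for s in stages
        ]
    )
    bcs = np.clip(rng.normal(5.4, 0.8, n_samples), 1.0, 9.0)
    sex = np.where(rng.random(n_samples) < 0.5, "M", "F")
    metadata = pd.DataFrame(
        {"stage": stage_arr, "age": age, "body_weight": bw, "bcs": np.round(bcs, 1), "sex": sex},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # role -> OTU assignment: deterministic, the first len(roles) tips
    roles = sorted(config.effect_table)
    role_to_otu = {role: tips[i] for i, role in enumerate(roles)}
    lineage = pd.Series("", index=tips, dtype=object)
    for k, tip in enumerate(tips):
        lineage[tip] = _FILLER_FAMILIES[k % len(_FILLER_FAMILIES)]
    for role, tip in role_to_otu.items():
        lineage[tip] = ROLE_LINEAGES[role]

    baseline = rng.normal(0.0, 2.0, n_otus)  # shared log-abundance profile
    # marker OTUs start at a common, comfortably detectable baseline
    otu_index = {o: i for i, o in enumerate(tips)}
    for role, tip in role_to_otu.items():
        baseline[otu_index[tip]] = 2.0

    shift = np.zeros((len(stages), n_otus))
    for role, per_stage in config.effect_table.items():
        j = otu_index[role_to_otu[role]]
        for si, s in enumerate(stages):
            shift[si, j] = np.log(2.0) * per_stage.get(s, 0.0)

    stage_idx = {s: i for i, s in enumerate(stages)}
    counts = np.zeros((n_samples, n_otus), dtype=np.int64)
    depth = np.maximum(
        np.round(np.exp(rng.normal(np.log(config.depth_median), config.depth_sigma, n_samples))),
        100,
    ).astype(np.int64)
    for i in range(n_samples):
        logp = baseline + shift[stage_idx[stage_arr[i]]]
        p = np.exp(logp - logp.max())
        p /= p.sum()
        conc = config.evenness_concentration[stage_arr[i]]
        p = rng.dirichlet(np.maximum(conc * p, 1e-8))
        counts[i] = rng.multinomial(depth[i], p)

    otu_table = OtuTable(
        pd.DataFrame(counts, index=metadata.index, columns=tips), lineage
    )
    truth = {
        "role_to_otu": role_to_otu,
        "baseline_log_abundance": baseline,
        "stages": stages,
        "depth": depth,
        "config": _config_record(config),
    }
    return otu_table, metadata, truth


def _config_record(config: CohortConfig) -> dict:
    rec = asdict(config)
    return rec


def simulate_qpcr(otu_table: OtuTable, metadata: pd.DataFrame, truth: dict,
                  config: CohortConfig) -> pd.DataFrame:
    """qPCR panel of 8 targets tied to the matched marker OTUs.

    Each taxon target is an affine map of the matched OTU's log10
    relative abundance (floored at 1e-6) plus Gaussian noise; the
    C. hiranonis target is re-centered per stage so the cohort spans the
    conversion threshold; total bacteria is stage-independent.
    """
    role_to_otu = truth.get("role_to_otu")
    if role_to_otu is None:
        raise ValueError("truth lacks role_to_otu")
    missing = [r for r in TARGET_ROLES.values() if r not in role_to_otu]
    if missing:
        raise ValueError(f"missing role(s) for qPCR targets: {missing}")
    rng = _rng(config.seed, 2)
    rel = otu_table.counts.div(otu_table.counts.sum(axis=1), axis=0)
    out = pd.DataFrame(index=otu_table.counts.index, columns=list(QPCR_TARGETS), dtype=float)
    out["total_bacteria"] = rng.normal(10.0, 0.2, len(out))
    a, b = config.qpcr_intercept, config.qpcr_slope
    for target, role in TARGET_ROLES.items():
        x = np.log10(np.maximum(rel[role_to_otu[role]].to_numpy(), 1e-6))
        noise = rng.normal(0.0, config.qpcr_noise_sd, len(out))
        if target == "c_hiranonis":
            centers = metadata["stage"].map(config.chiranonis_stage_centers).to_numpy()
            stage_mean = (
                pd.Series(x, index=out.index).groupby(metadata["stage"]).transform("mean").to_numpy()
            )
            out[target] = centers + b * (x - stage_mean) + noise
        else:
            out[target] = a + b * x + noise
    truth["qpcr_intercept"] = a
    truth["qpcr_slope"] = b
    return out


def logistic_conversion(x, threshold: float, steepness: float):
    """Fraction of the bile-acid pool converted to secondary BAs."""
    return 1.0 / (1.0 + np.exp(-steepness * (np.asarray(x, dtype=float) - threshold)))


def simulate_bile_acids(qpcr: pd.DataFrame, config: CohortConfig, truth: dict = None) -> pd.DataFrame:
    """Threshold-governed conversion of a log-normal bile-acid pool.

    The converted fraction is logistic in the C. hiranonis log10
    abundance; the primary mass splits CA:CDCA 60:40 and the secondary
    mass DCA:LCA:UDCA 70:25:5, each split jittered by a Dirichlet draw.
    Mass is conserved: the five concentrations sum to the pool total.
    """
    if "c_hiranonis" not in qpcr.columns:
        raise ValueError("qPCR panel lacks c_hiranonis column")
    rng = _rng(config.seed, 3)
    n = len(qpcr)
    x = qpcr["c_hiranonis"].to_numpy()
    f = logistic_conversion(x, config.conversion_threshold, config.conversion_steepness)
    total = np.exp(rng.normal(np.log(config.ba_total_median), config.ba_total_sigma, n))
    c = config.ba_split_concentration
    prim_w = rng.dirichlet(c * np.array([0.6, 0.4]), size=n)
    sec_w = rng.dirichlet(c * np.array([0.70, 0.25, 0.05]), size=n)
    prim = (1.0 - f)[:, None] * total[:, None] * prim_w
    sec = f[:, None] * total[:, None] * sec_w
    out = pd.DataFrame(
        np.column_stack([prim, sec]), index=qpcr.index, columns=list(BILE_ACIDS)
    )
    if truth is not None:
        truth["ba_total"] = total
        truth["conversion_fraction"] = f
    return out


def simulate_metabolites(otu_table: OtuTable, metadata: pd.DataFrame, truth: dict,
                         config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serum metabolites with planted microbe associations, plus SCFAs.

    Acylcarnitines load positively on the standardized log10 proportion
    of the Megamonas-like OTU; TMAO rises with stage and loads negatively
    on the Erysipelotrichaceae-like OTU.  SCFAs are log-normal with no
    stage effect (fecal SCFAs showed no group difference in this design).
    """
    role_to_otu = truth.get("role_to_otu", {})
    for role in ("megamonas_like", "erysipelotrichaceae_like"):
        if role not in role_to_otu:
            raise ValueError(f"missing role {role!r}")
    rng = _rng(config.seed, 4)
    rel = otu_table.counts.div(otu_table.counts.sum(axis=1), axis=0)

    def z_logprop(role):
        x = np.log10(np.maximum(rel[role_to_otu[role]].to_numpy(), 1e-6))
        sd = x.std(ddof=0)
        return (x - x.mean()) / (sd if sd > 0 else 1.0), sd

    z_mega, sd_mega = z_logprop("megamonas_like")
    z_ery, sd_ery = z_logprop("erysipelotrichaceae_like")
    stages = metadata["stage"]
    stage_effect = stages.map({"A": 0.0, "B1": 0.3, "B2": 0.6, "CD": 1.0}).fillna(0.0).to_numpy()
    beta, noise_sd = config.assoc_beta, config.metabolite_noise_sd
    n = len(metadata)
    cols = {}
    for name in ("carnitine", "acetylcarnitine", "propionylcarnitine", "butyrylcarnitine"):
        cols[name] = beta * z_mega + stage_effect + rng.normal(0, noise_sd, n)
    cols["tmao"] = stage_effect - beta * z_ery + rng.normal(0, noise_sd, n)
    for k in range(10):  # pure-noise metabolites to exercise FDR control
        cols[f"metabolite_{k+1:02d}"] = rng.normal(0, 1.0, n)
    metabolites = pd.DataFrame(cols, index=metadata.index)

    scfa = pd.DataFrame(
        {name: np.exp(rng.normal(np.log(50.0), 0.4, n)) for name in SCFAS},
        index=metadata.index,
    )
    truth["metabolite_roles"] = {
        "carnitine_family": "megamonas_like",
        "tmao": "erysipelotrichaceae_like",
    }
    truth["log10_prop_sd"] = {"megamonas_like": sd_mega, "erysipelotrichaceae_like": sd_ery}
    return metabolites, scfa


def simulate_cohort(config: CohortConfig = None) -> SyntheticCohort:
    """Generate the full synthetic cohort from a single config/seed."""
    config = config or CohortConfig()
    tree = simulate_tree(config.n_otus, config.seed)
    otu_table, metadata, truth = simulate_counts(config, tree)
    qpcr = simulate_qpcr(otu_table, metadata, truth, config)
    bile_acids = simulate_bile_acids(qpcr, config, truth)
    metabolites, scfa = simulate_metabolites(otu_table, metadata, truth, config)
    return SyntheticCohort(otu_table, tree, metadata, qpcr, bile_acids, scfa, metabolites, truth)
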