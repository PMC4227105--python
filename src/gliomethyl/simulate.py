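"""Synthetic cohort generator emulating the paired early/late glioma study
design on a 450K-like array, with a ground-truth ledger for recovery tests.

The default configuration reproduces the study conditions: 4 normal brain
samples and 20 tumour pairs (5 grade II->III, 5 grade II->IV, 10 grade
III->IV, hence grade groups of 10/15/15 samples), 70% of pairs IDH1-mutant.
IDH1-mutant pairs carry the CpG island methylator phenotype (CIMP): a planted
beta shift of ``cimp_delta`` at a random subset of autosomal island loci, in
the early lesion and — except for a configurable number of pairs that lose
CIMP on progression — in the late lesion as well.  Each grade additionally
receives its own planted set of hypermethylated genes (beta mean 0.8 at the
planted probes in that grade's tumours).  All beta values are drawn from Beta
distributions parameterized by (mean, concentration) so they stay in [0, 1]
without clipping; sporadic detection failures are planted i.i.d. per cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cloneseq import CloneMatrix
from .model import BetaMatrix, ProbeManifest, SampleSheet, SignalSet

DEFAULT_TRANSITIONS = (("II", "III"),) * 5 + (("II", "IV"),) * 5 + (("III", "IV"),) * 10

# category mixes emulating the analyzed-array background (island 35.6%,
# open sea 31.4%; shores/shelves share the remainder)
DEFAULT_ISLAND_PROPORTIONS = {
    "Island": 0.356, "N_Shore": 0.11, "S_Shore": 0.10,
    "N_Shelf": 0.06, "S_Shelf": 0.06, "OpenSea": 0.314,
}
DEFAULT_FEATURE_PROPORTIONS = {
    "TSS1500": 0.21, "TSS200": 0.15, "UTR5": 0.12,
    "FirstExon": 0.09, "Body": 0.36, "UTR3": 0.07,
}


@dataclass
class SimulationConfig:
    seed: int = 17
    n_probes: int = 40000
    n_genes: int = 4000
    probes_per_gene: tuple = (3, 9)          # inclusive uniform range
    island_proportions: dict = field(default_factory=lambda: dict(DEFAULT_ISLAND_PROPORTIONS))
    feature_proportions: dict = field(default_factory=lambda: dict(DEFAULT_FEATURE_PROPORTIONS))
    x_fraction: float = 0.025
    y_fraction: float = 0.004
    snp_fraction: float = 0.02
    n_normal: int = 4
    grade_transitions: tuple = DEFAULT_TRANSITIONS
    idh1_mut_fraction: float = 0.70
    n_cimp_loss_pairs: int = 4               # mutant pairs whose late lesion loses CIMP
    cimp_locus_fraction: float = 0.05
    cimp_delta: float = 0.4
    cimp_island_weight: float = 0.8          # fraction of CIMP loci drawn from islands (rest from shores)
    n_grade_genes: int = 50                  # planted hypermethylated genes per grade
    n_conserved_genes: int = 30              # planted hypermethylated in every grade's tumours
    planted_probes_per_gene: int = 3
    hyper_mean: float = 0.8
    background_mean: float = 0.1
    beta_noise: float = 80.0                 # Beta concentration (a+b)
    detection_fail_rate: float = 1e-4
    red_channel_bias: float = 1.3            # multiplicative dye bias for signal mode

    def __post_init__(self) -> None:
        if not 0 <= self.cimp_delta <= 1:
            raise ValueError("cimp_delta must lie in [0, 1]")
        for props in (self.island_proportions, self.feature_proportions):
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError("category proportions must sum to 1")
        lo, hi = self.probes_per_gene
        if self.n_probes < self.n_genes * lo:
            raise ValueError("n_probes too small for n_genes x min probes_per_gene")

    @property
    def n_pairs(self) -> int:
        return len(self.grade_transitions)


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    cimp_loci: set
    cimp_samples: set                       # samples carrying the planted CIMP shift
    cimp_label: dict                        # sample -> 'CIMP+' | 'CIMP-'
    hyper_genes_by_grade: dict              # grade -> {gene: set(planted probes)}, incl. conserved
    conserved_genes: dict                   # gene -> set(planted probes), hyper in all grades
    cimp_genes: set                         # genes carrying >=1 planted CIMP locus
    idh1_mut_pairs: set
    cimp_loss_pairs: set

    def to_json(self, path) -> None:
        payload = {
            "cimp_loci": sorted(self.cimp_loci),
            "cimp_samples": sorted(self.cimp_samples),
            "cimp_label": dict(sorted(self.cimp_label.items())),
            "hyper_genes_by_grade": {
                g: {gene: sorted(ps) for gene, ps in sorted(d.items())}
                for g, d in sorted(self.hyper_genes_by_grade.items())
            },
            "conserved_genes": {g: sorted(ps) for g, ps in sorted(self.conserved_genes.items())},
            "cimp_genes": sorted(self.cimp_genes),
            "idh1_mut_pairs": sorted(self.idh1_mut_pairs),
            "cimp_loss_pairs": sorted(self.cimp_loss_pairs),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def generate_manifest(cfg: SimulationConfig, seed: int | None = None) -> ProbeManifest:
    """Deterministic synthetic probe manifest.

    Genes live on one chromosome each with 3-9 consecutive probes; leftover
    probes are intergenic.  X/Y and SNP-flagged probes are included so every
    filter in the cascade is exercised.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_probes
    probe_ids = [f"cg{i:07d}" for i in range(n)]

    lo, hi = cfg.probes_per_gene
    gene_sizes = rng.integers(lo, hi + 1, size=cfg.n_genes)
    while gene_sizes.sum() > n:
        gene_sizes = gene_sizes[:-1]
    n_gene_probes = int(gene_sizes.sum())

    chroms = np.empty(n, dtype=object)
    genes_col: list = [()] * n
    features = np.empty(n, dtype=object)

    chrom_pool = [str(c) for c in range(1, 23)]
    p_x, p_y = cfg.x_fraction, cfg.y_fraction
    feat_names = list(cfg.feature_proportions)
    feat_probs = np.array([cfg.feature_proportions[f] for f in feat_names])

    pos = 0
    for gi, size in enumerate(gene_sizes):
        symbol = f"GENE{gi:05d}"
        u = rng.random()
        if u < p_x:
            chrom = "X"
        elif u < p_x + p_y:
            chrom = "Y"
        else:
            chrom = chrom_pool[rng.integers(0, 22)]
        for _ in range(int(size)):
            chroms[pos] = chrom
            genes_col[pos] = (symbol,)
            features[pos] = feat_names[rng.choice(len(feat_names), p=feat_probs)]
            pos += 1
    # a sprinkling of multi-gene probes (overlapping transcripts)
    n_multi = max(1, n_gene_probes // 200)
    multi_idx = rng.choice(n_gene_probes, size=n_multi, replace=False)
    for i in multi_idx:
        other = f"GENE{int(rng.integers(0, cfg.n_genes)):05d}"
        genes_col[i] = tuple(sorted(set(genes_col[i]) | {other}))

    for i in range(pos, n):
        u = rng.random()
        if u < p_x:
            chroms[i] = "X"
        elif u < p_x + p_y:
            chroms[i] = "Y"
        else:
            chroms[i] = chrom_pool[rng.integers(0, 22)]
        features[i] = "Intergenic"

    island_names = list(cfg.island_proportions)
    island_probs = np.array([cfg.island_proportions[c] for c in island_names])
    islands = rng.choice(island_names, size=n, p=island_probs)

    design = np.where(rng.random(n) < 0.28, "I", "II")   # ~28% type I, as on the array
    channel = np.where(design == "II", "Both",
                       np.where(rng.random(n) < 0.5, "Grn", "Red"))
    snp = rng.random(n) < cfg.snp_fraction
    positions = rng.integers(1, 2_000_000_00, size=n)

    df = pd.DataFrame(
        {
            "chromosome": chroms,
            "position": positions,
            "design_type": design,
            "channel": channel,
            "genes": genes_col,
            "gene_feature": features,
            "island_relation": islands,
            "snp_flag": snp,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ProbeManifest(df)


def _build_sample_sheet(cfg: SimulationConfig, rng) -> tuple[SampleSheet, set, set]:
    pair_ids = [f"P{i + 1:02d}" for i in range(cfg.n_pairs)]
    n_mut = int(round(cfg.idh1_mut_fraction * cfg.n_pairs))
    mut_pairs = set(rng.choice(pair_ids, size=n_mut, replace=False))
    loss_pairs = set(
        rng.choice(sorted(mut_pairs), size=min(cfg.n_cimp_loss_pairs, n_mut),
                   replace=False)
    )
    rows = []
    for pid, (g_early, g_late) in zip(pair_ids, cfg.grade_transitions):
        idh1 = "mut" if pid in mut_pairs else "wt"
        for role, grade, suffix in (("Early", g_early, "E"), ("Late", g_late, "L")):
            rows.append({
                "sample_id": f"{pid}{suffix}", "pair_id": pid, "role": role,
                "who_grade": grade, "idh1_status": idh1, "idh2_status": "wt",
                "cohort": "sGBM",
            })
    for i in range(cfg.n_normal):
        rows.append({
            "sample_id": f"N{i + 1}", "pair_id": None, "role": "Normal",
            "who_grade": "NA", "idh1_status": "wt", "idh2_status": "wt",
            "cohort": "normal",
        })
    df = pd.DataFrame(rows).set_index("sample_id")
    return SampleSheet(df), mut_pairs, loss_pairs


def generate_cohort(
    cfg: SimulationConfig,
    manifest: ProbeManifest,
    seed: int | None = None,
    emit: str = "beta",
):
    """Generate (BetaMatrix | SignalSet+detection_p), SampleSheet, GroundTruth.

    ``emit='beta'`` returns a BetaMatrix with detection p-values;
    ``emit='signals'`` returns a SignalSet whose intensities carry a Red-dye
    bias, plus the detection p-value frame, for exercising normalization.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sheet, mut_pairs, loss_pairs = _build_sample_sheet(cfg, rng)
    samples = sorted(sheet.sample_ids)
    probes = list(manifest.probe_ids)
    n_p, n_s = len(probes), len(samples)
    probe_pos = {p: i for i, p in enumerate(probes)}
    sample_pos = {s: j for j, s in enumerate(samples)}

    # CIMP carrier samples: early lesions of mutant pairs always; late unless lost
    cimp_samples: set = set()
    for pid, (early, late) in sheet.pairs().items():
        if pid in mut_pairs:
            cimp_samples.add(early)
            if pid not in loss_pairs:
                cimp_samples.add(late)
    cimp_label = {s: ("CIMP+" if s in cimp_samples else "CIMP-") for s in samples}

    # eligible genes for grade planting: every probe autosomal and SNP-free
    df = manifest.df
    gene_map = manifest.gene_to_probes()
    bad_probes = set(df.index[df["chromosome"].isin(["X", "Y"]) | df["snp_flag"]])
    eligible = sorted(
        g for g, ps in gene_map.items()
        if len(ps) >= cfg.planted_probes_per_gene and not (ps & bad_probes)
    )
    grades = sorted({g for t in cfg.grade_transitions for g in t},
                    key=["II", "III", "IV"].index)
    need = cfg.n_grade_genes * len(grades) + cfg.n_conserved_genes
    if len(eligible) < need:
        raise ValueError("not enough eligible genes for the requested planting")
    chosen = rng.choice(eligible, size=need, replace=False)

    def _plant(block) -> dict:
        return {
            str(gene): set(sorted(gene_map[gene])[: cfg.planted_probes_per_gene])
            for gene in block
        }

    hyper_genes_by_grade: dict = {}
    for i, grade in enumerate(grades):
        hyper_genes_by_grade[grade] = _plant(
            chosen[i * cfg.n_grade_genes:(i + 1) * cfg.n_grade_genes]
        )
    conserved_genes = _plant(chosen[cfg.n_grade_genes * len(grades):])
    planted_probe_set: set = set()
    for d in (*hyper_genes_by_grade.values(), conserved_genes):
        for ps in d.values():
            planted_probe_set |= ps
    # conserved genes are truly hypermethylated in every grade's tumours
    for grade in grades:
        hyper_genes_by_grade[grade].update(conserved_genes)

    # CIMP loci: mostly island probes, the rest shores; autosomal, SNP-free,
    # outside the planted gene probes
    n_cimp = int(round(cfg.cimp_locus_fraction * n_p))
    n_cimp_island = int(round(cfg.cimp_island_weight * n_cimp))
    island_pool = sorted(
        set(df.index[df["island_relation"] == "Island"]) - bad_probes - planted_probe_set
    )
    shore_pool = sorted(
        set(df.index[df["island_relation"].isin(["N_Shore", "S_Shore"])])
        - bad_probes - planted_probe_set
    )
    if len(island_pool) < n_cimp_island or len(shore_pool) < n_cimp - n_cimp_island:
        raise ValueError("not enough island/shore probes for the requested CIMP loci")
    cimp_loci = set(rng.choice(island_pool, size=n_cimp_island, replace=False)) | set(
        rng.choice(shore_pool, size=n_cimp - n_cimp_island, replace=False)
    )
    cimp_genes = {
        g for p in cimp_loci for g in df.loc[p, "genes"]
    }

    # mean matrix
    mean = np.full((n_p, n_s), cfg.background_mean)
    cimp_rows = np.array([probe_pos[p] for p in sorted(cimp_loci)])
    cimp_cols = np.array([sample_pos[s] for s in sorted(cimp_samples)])
    if len(cimp_rows) and len(cimp_cols):
        mean[np.ix_(cimp_rows, cimp_cols)] += cfg.cimp_delta
    for grade in grades:
        cols = np.array([sample_pos[s] for s in sheet.grade_group(grade)])
        rows = np.array(sorted(
            probe_pos[p] for d in [hyper_genes_by_grade[grade]] for ps in d.values() for p in ps
        ))
        if len(rows) and len(cols):
            mean[np.ix_(rows, cols)] = cfg.hyper_mean
    np.clip(mean, 1e-3, 1 - 1e-3, out=mean)

    nu = cfg.beta_noise
    beta = rng.beta(mean * nu, (1.0 - mean) * nu)

    detection_p = rng.uniform(0.0, 0.005, size=(n_p, n_s))
    fails = rng.random((n_p, n_s)) < cfg.detection_fail_rate
    detection_p[fails] = rng.uniform(0.02, 0.5, size=int(fails.sum()))

    truth = GroundTruth(
        cimp_loci=cimp_loci,
        cimp_samples=cimp_samples,
        cimp_label=cimp_label,
        hyper_genes_by_grade=hyper_genes_by_grade,
        conserved_genes=conserved_genes,
        cimp_genes=cimp_genes,
        idh1_mut_pairs=mut_pairs,
        cimp_loss_pairs=loss_pairs,
    )

    beta_df = pd.DataFrame(beta, index=pd.Index(probes, name="probe_id"), columns=samples)
    detp_df = pd.DataFrame(detection_p, index=beta_df.index, columns=samples)

    if emit == "beta":
        return BetaMatrix(beta=beta_df, detection_p=detp_df), sheet, truth
    if emit == "signals":
        total = rng.gamma(shape=4.0, scale=1000.0, size=(n_p, n_s))
        m = beta * total
        u = (1.0 - beta) * total
        red = (manifest.df.loc[probes, "channel"] == "Red").to_numpy()
        m[red] *= cfg.red_channel_bias
        u[red] *= cfg.red_channel_bias
        signals = SignalSet(
            methylated=pd.DataFrame(m, index=beta_df.index, columns=samples),
            unmethylated=pd.DataFrame(u, index=beta_df.index, columns=samples),
        )
        return signals, detp_df, sheet, truth
    raise ValueError("emit must be 'beta' or 'signals'")


def generate_clones(true_mi: float, n_clones: int, n_cpgs: int, seed: int,
                    sample_id: str = "S1", gene: str = "GENE") -> CloneMatrix:
    """i.i.d. Bernoulli clone-call matrix at rate true_mi/100."""
    if not 0 <= true_mi <= 100:
        raise ValueError("true_mi must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    calls = (rng.random((n_clones, n_cpgs)) < true_mi / 100.0).astype(float)
    positions = sorted(rng.choice(10**6, size=n_cpgs, replace=False).tolist())
    df = pd.DataFrame(calls, index=[f"clone{i + 1}" for i in range(n_clones)],
                      columns=positions)
    return CloneMatrix(sample_id=sample_id, gene=gene, calls=df)
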