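"""Hypermethylation calling: the multi-stage probe filter cascade and
gene-level aggregation.

Stages, applied in order with per-probe exclusion provenance:

1. detection QC  — drop a probe if its detection p-value exceeds 0.01 in ANY
   sample of the run (bound exclusive: p = 0.01 survives);
2. sex chromosomes — drop X/Y probes;
3. normal exclusion — drop a probe whose beta is >= 0.25 in ANY normal sample
   (tumour-specific hypermethylation only);
4. hypermethylation call — a surviving probe is called when beta >= 0.5 in
   strictly more than 30% of the grade group's tumour samples;
5. gene aggregation — a gene is retained when >= 3 of its annotated probes
   are called.

All boundary semantics are inclusive/exclusive exactly as listed; fraction
comparisons are exact rationals (count * 10 > 3 * n style), never rounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

from .model import BetaMatrix, GeneList, ProbeManifest, SampleSheet


@dataclass
class FilterConfig:
    detection_p_max: float = 0.01       # removed when p > this (exclusive bound)
    drop_sex_chromosomes: bool = True
    normal_beta_max: float = 0.25       # removed when beta >= this in any normal
    hyper_beta_min: float = 0.5         # called when beta >= this
    tumor_fraction_min: float = 0.30    # relevant when fraction > this (strict)
    min_probes_per_gene: int = 3        # gene kept when called probes >= this
    exclude_snp_probes: bool = False
    missing_detection_p: str = "error"  # or "pass"

    def __post_init__(self) -> None:
        for name in ("detection_p_max", "normal_beta_max", "hyper_beta_min",
                     "tumor_fraction_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.min_probes_per_gene < 1:
            raise ValueError("min_probes_per_gene must be >= 1")


@dataclass
class CallSet:
    """Result of one grade's cascade, with filter provenance."""

    grade_label: str
    surviving_probes: set
    hyper_probes: set
    hyper_probes_gene_associated: set
    hyper_genes: GeneList
    exclusion_log: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.hyper_probes <= self.surviving_probes:
            raise ValueError("hyper_probes must be a subset of surviving_probes")


def filter_detection(beta: BetaMatrix, cfg: FilterConfig | None = None) -> set:
    """Probes whose detection p-value is <= the bound in EVERY sample."""
    cfg = cfg or FilterConfig()
    if beta.detection_p is None:
        if cfg.missing_detection_p == "pass":
            import warnings
            warnings.warn("no detection p-values; detection filter passes all probes")
            return set(beta.probe_ids)
        raise ValueError("detection p-values missing (set missing_detection_p='pass' to skip)")
    ok = (beta.detection_p.to_numpy() <= cfg.detection_p_max).all(axis=1)
    return set(beta.probe_ids[ok])


def filter_sex_chromosomes(probes, manifest: ProbeManifest) -> set:
    """Probes not on chromosomes X or Y."""
    probes = set(probes)
    sub = manifest.df.loc[manifest.df.index.isin(probes)]
    if len(sub) < len(probes):
        raise KeyError("probe(s) missing from manifest")
    keep = ~sub["chromosome"].isin(["X", "Y"])
    return set(sub.index[keep])


def filter_snp_probes(probes, manifest: ProbeManifest) -> set:
    probes = set(probes)
    sub = manifest.df.loc[manifest.df.index.isin(probes)]
    return set(sub.index[~sub["snp_flag"]])


def filter_normal_methylated(beta: BetaMatrix, normals,
                             cfg: FilterConfig | None = None) -> set:
    """Probes with beta strictly below the bound in EVERY normal sample."""
    cfg = cfg or FilterConfig()
    normals = sorted(normals)
    if not normals:
        raise ValueError("at least one normal sample is required")
    sub = beta.beta[normals]
    ok = (sub.to_numpy() < cfg.normal_beta_max).all(axis=1)
    return set(beta.probe_ids[ok])


def call_hypermethylated(beta: BetaMatrix, tumor_samples,
                         cfg: FilterConfig | None = None) -> set:
    """Probes with beta >= hyper_beta_min in strictly more than
    tumor_fraction_min of the tumour samples."""
    cfg = cfg or FilterConfig()
    tumors = sorted(tumor_samples)
    if not tumors:
        raise ValueError("tumour sample set must be non-empty")
    counts = (beta.beta[tumors].to_numpy() >= cfg.hyper_beta_min).sum(axis=1)
    threshold = Fraction(cfg.tumor_fraction_min).limit_denominator(10**6)
    called = [
        p for p, c in zip(beta.probe_ids, counts)
        if Fraction(int(c), len(tumors)) > threshold
    ]
    return set(called)


def aggregate_genes(hyper_probes, manifest: ProbeManifest,
                    cfg: FilterConfig | None = None, label: str = "") -> GeneList:
    """Genes supported by >= min_probes_per_gene called probes.

    A probe annotated to several genes counts once toward each symbol;
    probes with empty annotation contribute nowhere.
    """
    cfg = cfg or FilterConfig()
    gene_map = manifest.gene_to_probes(hyper_probes)
    kept = {g: ps for g, ps in gene_map.items() if len(ps) >= cfg.min_probes_per_gene}
    return GeneList(label=label, genes=tuple(kept), supporting_probes=kept)


def gene_associated(probes, manifest: ProbeManifest) -> set:
    """Subset of probes annotated to at least one gene."""
    sub = manifest.df.loc[manifest.df.index.isin(set(probes))]
    return set(sub.index[[len(g) > 0 for g in sub["genes"]]])


def run_grade_cascade(beta: BetaMatrix, sheet: SampleSheet, grade: str,
                      manifest: ProbeManifest,
                      cfg: FilterConfig | None = None) -> CallSet:
    """Full cascade for one WHO grade group.

    The exclusion log records, for every removed probe, the first stage that
    removed it; the log plus the survivors partition the input probe set.
    """
    cfg = cfg or FilterConfig()
    tumors = sheet.grade_group(grade)
    if not tumors:
        raise ValueError(f"no tumour samples of grade {grade!r}")
    normals = sheet.normals()

    all_probes = set(beta.probe_ids)
    exclusion: dict = {}
    stage_counts = {"input": len(all_probes)}

    surviving = filter_detection(beta, cfg)
    for p in all_probes - surviving:
        exclusion[p] = "detection_p"
    stage_counts["after_detection"] = len(surviving)

    if cfg.drop_sex_chromosomes:
        kept = filter_sex_chromosomes(surviving, manifest)
        for p in surviving - kept:
            exclusion[p] = "sex_chromosome"
        surviving = kept
    stage_counts["after_sex"] = len(surviving)

    if cfg.exclude_snp_probes:
        kept = filter_snp_probes(surviving, manifest)
        for p in surviving - kept:
            exclusion[p] = "snp"
        surviving = kept
        stage_counts["after_snp"] = len(surviving)

    normal_pass = filter_normal_methylated(beta, normals, cfg)
    kept = surviving & normal_pass
    for p in surviving - kept:
        exclusion[p] = "normal_methylated"
    surviving = kept
    stage_counts["after_normal"] = len(surviving)

    called_all = call_hypermethylated(beta, tumors, cfg)
    hyper = surviving & called_all
    stage_counts["hyper_probes"] = len(hyper)

    hyper_gene_assoc = gene_associated(hyper, manifest)
    stage_counts["hyper_probes_gene_associated"] = len(hyper_gene_assoc)

    genes = aggregate_genes(hyper_gene_assoc, manifest, cfg, label=f"grade_{grade}")
    stage_counts["hyper_genes"] = len(genes)
    stage_counts["hyper_probes_in_kept_genes"] = len(genes.probes)

    return CallSet(
        grade_label=grade,
        surviving_probes=surviving,
        hyper_probes=hyper,
        hyper_probes_gene_associated=hyper_gene_assoc,
        hyper_genes=genes,
        exclusion_log=exclusion,
        stage_counts=stage_counts,
    )


def intersect_grades(callsets, manifest: ProbeManifest,
                     cfg: FilterConfig | None = None):
    """Probes hypermethylated in every grade, and the gene list re-filtered
    at >= min_probes_per_gene conserved probes per gene."""
    cfg = cfg or FilterConfig()
    callsets = list(callsets)
    if len(callsets) < 2:
        raise ValueError("need at least two callsets to intersect")
    conserved = set.intersection(*(cs.hyper_probes_gene_associated for cs in callsets))
    genes = aggregate_genes(conserved, manifest, cfg, label="conserved")
    return conserved, genes


def venn_partition(callsets) -> dict:
    """Region -> probe count over 2 or 3 callsets.

    Counts are over called probes restricted to genes retained at the
    >= min-probe rule (i.e. each callset's ``hyper_genes.probes``); region
    counts sum to the size of the union.
    """
    callsets = list(callsets)
    if len(callsets) not in (2, 3):
        raise ValueError("venn_partition takes exactly 2 or 3 callsets")
    sets = [cs.hyper_genes.probes for cs in callsets]
    labels = [cs.grade_label for cs in callsets]
    out = {}
    n = len(sets)
    for mask in range(1, 2 ** n):
        inside = [sets[i] for i in range(n) if mask >> i & 1]
        outside = [sets[i] for i in range(n) if not mask >> i & 1]
        region = set.intersection(*inside) - set().union(*outside)
        key = "&".join(labels[i] for i in range(n) if mask >> i & 1)
        out[key] = len(region)
    return out


def exclusive_gene_lists(list_a: GeneList, list_b: GeneList):
    """Exact three-way partition of two gene lists by symbol."""
    a, b = set(list_a.genes), set(list_b.genes)

    def _sub(src: GeneList, symbols, label) -> GeneList:
        symbols = tuple(sorted(symbols))
        return GeneList(
            label=label, genes=symbols,
            supporting_probes={g: src.supporting_probes[g] for g in symbols},
        )

    only_a = _sub(list_a, a - b, f"{list_a.label}_only")
    only_b = _sub(list_b, b - a, f"{list_b.label}_only")
    shared = _sub(list_a, a & b, "shared")
    return only_a, only_b, shared


def exclusion_log_frame(callset: CallSet) -> pd.DataFrame:
    """Tidy exclusion log (probe_id, stage) for TSV export."""
    rows = sorted(callset.exclusion_log.items())
    return pd.DataFrame(rows, columns=["probe_id", "stage"])
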