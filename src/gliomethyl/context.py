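"""Genomic-context distributions of called probes.

Tabulates a probe set over gene-feature categories (TSS1500, TSS200, 5'UTR,
first exon, body, 3'UTR, intergenic) and CpG-island geography (island, shores,
shelves, open sea) against the analyzed-array background, and computes
per-category enrichment ratios.
"""

from __future__ import annotations

import pandas as pd

from .model import ProbeManifest, VALID_GENE_FEATURES, VALID_ISLAND_RELATIONS

FEATURE_ORDER = ["TSS1500", "TSS200", "UTR5", "FirstExon", "Body", "UTR3", "Intergenic"]
ISLAND_ORDER = ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"]


def analyzed_background(manifest: ProbeManifest) -> set:
    """The background universe for context comparisons: probes associated
    with a gene, autosomal, and not SNP-flagged."""
    df = manifest.df
    keep = (
        df["genes"].map(len).gt(0)
        & ~df["chromosome"].isin(["X", "Y"])
        & ~df["snp_flag"]
    )
    return set(df.index[keep])


def _tabulate(column: pd.Series, order: list, probes: set, background: set) -> pd.DataFrame:
    set_counts = column.loc[column.index.isin(probes)].value_counts()
    bg_counts = column.loc[column.index.isin(background)].value_counts()
    rows = []
    for cat in order:
        c = int(set_counts.get(cat, 0))
        b = int(bg_counts.get(cat, 0))
        rows.append({
            "category": cat,
            "count": c,
            "fraction": c / len(probes),
            "background_count": b,
            "background_fraction": b / len(background),
        })
    return pd.DataFrame(rows)


def tabulate_context(probes, manifest: ProbeManifest, background) -> dict:
    """Context tables (category counts/fractions vs background) for both the
    gene-feature and the island-relation classification.

    ``probes`` must be a subset of ``background`` which must be a subset of
    the manifest.
    """
    probes, background = set(probes), set(background)
    if not probes:
        raise ValueError("probe set is empty")
    if not probes <= background:
        raise ValueError("probe set must be a subset of the background")
    if not background <= set(manifest.probe_ids):
        raise ValueError("background must be a subset of the manifest")
    df = manifest.df
    return {
        "gene_feature": _tabulate(df["gene_feature"], FEATURE_ORDER, probes, background),
        "island_relation": _tabulate(df["island_relation"], ISLAND_ORDER, probes, background),
    }


def enrichment_ratio(table: pd.DataFrame) -> dict:
    """category -> set fraction / background fraction (None where the
    background fraction is zero)."""
    out = {}
    for _, row in table.iterrows():
        if row["background_fraction"] == 0:
            out[row["category"]] = None
        else:
            out[row["category"]] = float(row["fraction"] / row["background_fraction"])
    return out
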