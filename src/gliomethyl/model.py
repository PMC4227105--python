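"""Core data model and tabular I/O for the methylation pipeline.

The in-memory containers are thin dataclasses around :class:`pandas.DataFrame`,
keyed by probe id (rows) and sample id (columns).  All tabular files are UTF-8
CSV or TSV; the delimiter is sniffed from the header line, so both flavours can
be read with the same functions.

Coordinates are 1-based point positions as printed in Infinium manifests and
are never converted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])
VALID_DESIGN_TYPES = frozenset(["I", "II"])
VALID_CHANNELS = frozenset(["Grn", "Red", "Both"])
VALID_GENE_FEATURES = frozenset(
    ["TSS1500", "TSS200", "UTR5", "FirstExon", "Body", "UTR3", "Intergenic"]
)
VALID_ISLAND_RELATIONS = frozenset(
    ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"]
)
VALID_ROLES = frozenset(["Early", "Late", "Normal"])
VALID_GRADES = frozenset(["II", "III", "IV", "NA"])
VALID_COHORTS = frozenset(["sGBM", "pGBM", "normal"])

_GRADE_ORDER = {"II": 2, "III": 3, "IV": 4}


class ModelError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _sniff_sep(path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


# ---------------------------------------------------------------------------
# Probe manifest
# ---------------------------------------------------------------------------

@dataclass
class ProbeManifest:
    """Per-probe annotation: genomic location, design chemistry, gene and
    CpG-island context.

    ``df`` is indexed by probe id with columns ``chromosome``, ``position``,
    ``design_type``, ``channel``, ``gene_feature``, ``island_relation``,
    ``snp_flag`` plus ``genes`` holding a tuple of unique gene symbols
    (empty tuple for intergenic probes).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ModelError(f"duplicate probe_id(s): {dups[:5]}")
        bad_chrom = ~df["chromosome"].astype(str).isin(VALID_CHROMOSOMES)
        if bad_chrom.any():
            rows = list(np.flatnonzero(bad_chrom.to_numpy())[:5])
            raise ModelError(f"malformed chromosome at row(s) {rows}")
        for col, valid in [
            ("design_type", VALID_DESIGN_TYPES),
            ("channel", VALID_CHANNELS),
            ("gene_feature", VALID_GENE_FEATURES),
            ("island_relation", VALID_ISLAND_RELATIONS),
        ]:
            bad = ~df[col].isin(valid)
            if bad.any():
                token = df.loc[bad, col].iloc[0]
                raise ModelError(f"unknown {col} token: {token!r}")
        if (df["position"] < 1).any():
            raise ModelError("position must be >= 1")
        type2 = df["design_type"] == "II"
        if (df.loc[type2, "channel"] != "Both").any():
            raise ModelError("type II probes must have channel 'Both'")
        if (~df.loc[~type2, "channel"].isin(["Grn", "Red"])).any():
            raise ModelError("type I probes must have channel 'Grn' or 'Red'")

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    def subset(self, probes) -> "ProbeManifest":
        return ProbeManifest(self.df.loc[sorted(probes)])

    def autosomal_probes(self) -> set:
        keep = ~self.df["chromosome"].isin(["X", "Y"])
        return set(self.df.index[keep])

    def gene_to_probes(self, probes=None) -> dict:
        """Invert the probe->genes annotation; a multi-gene probe counts once
        toward each of its symbols."""
        sub = self.df if probes is None else self.df.loc[self.df.index.isin(set(probes))]
        out: dict[str, set] = {}
        for pid, genes in sub["genes"].items():
            for g in genes:
                out.setdefault(g, set()).add(pid)
        return out


def _parse_genes(raw) -> tuple:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return ()
    text = str(raw).strip()
    if not text:
        return ()
    symbols = {tok.strip() for tok in text.split(";") if tok.strip()}
    return tuple(sorted(symbols))


_BOOL_TOKENS = {"true": True, "1": True, "false": False, "0": False, "": False}


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return _BOOL_TOKENS[str(v).strip().lower()]


def read_manifest(path) -> ProbeManifest:
    """Read a probe manifest CSV/TSV (semicolon-delimited gene column)."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {
        "probe_id", "chromosome", "position", "design_type", "channel",
        "genes", "gene_feature", "island_relation", "snp_flag",
    }
    missing = required - set(df.columns)
    if missing:
        raise ModelError(f"manifest missing column(s): {sorted(missing)}")
    out = pd.DataFrame(index=pd.Index(df["probe_id"], name="probe_id"))
    out["chromosome"] = df["chromosome"].str.strip().values
    try:
        out["position"] = df["position"].astype(int).values
    except ValueError as exc:
        raise ModelError(f"non-integer position: {exc}") from None
    out["design_type"] = df["design_type"].str.strip().values
    out["channel"] = df["channel"].str.strip().values
    out["genes"] = [_parse_genes(v) for v in df["genes"]]
    out["gene_feature"] = df["gene_feature"].str.strip().values
    out["island_relation"] = df["island_relation"].str.strip().values
    out["snp_flag"] = [_parse_bool(v) for v in df["snp_flag"]]
    return ProbeManifest(out)


def write_manifest(manifest: ProbeManifest, path) -> None:
    df = manifest.df.copy()
    df["genes"] = [";".join(g) for g in df["genes"]]
    df["snp_flag"] = df["snp_flag"].map({True: "True", False: "False"})
    df.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Sample metadata: pairing, lesion role, WHO grade, IDH genotype, cohort.

    ``df`` is indexed by sample id; ``pair_id`` is None for normal samples.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        if df.index.duplicated().any():
            raise ModelError("duplicate sample_id")
        for col, valid in [
            ("role", VALID_ROLES), ("who_grade", VALID_GRADES),
            ("idh1_status", frozenset(["mut", "wt", "unknown"])),
            ("idh2_status", frozenset(["mut", "wt", "unknown"])),
            ("cohort", VALID_COHORTS),
        ]:
            bad = ~df[col].isin(valid)
            if bad.any():
                raise ModelError(f"unknown {col} token: {df.loc[bad, col].iloc[0]!r}")
        normals = df["role"] == "Normal"
        if (df.loc[normals, "who_grade"] != "NA").any():
            raise ModelError("Normal samples must have who_grade NA")
        if df.loc[normals, "pair_id"].notna().any():
            raise ModelError("Normal samples must not carry a pair_id")
        tumors = df[~normals]
        if tumors["pair_id"].isna().any():
            raise ModelError("tumor samples must carry a pair_id")
        for pid, grp in tumors.groupby("pair_id"):
            roles = sorted(grp["role"])
            if roles != ["Early", "Late"]:
                raise ModelError(
                    f"pair {pid!r} must have exactly one Early and one Late sample, got {roles}"
                )
            early = grp[grp["role"] == "Early"].iloc[0]
            late = grp[grp["role"] == "Late"].iloc[0]
            if _GRADE_ORDER[early["who_grade"]] > _GRADE_ORDER[late["who_grade"]]:
                raise ModelError(f"pair {pid!r}: grade decreases Early->Late")

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index

    def normals(self) -> list:
        return sorted(self.df.index[self.df["role"] == "Normal"])

    def tumors(self) -> list:
        return sorted(self.df.index[self.df["role"] != "Normal"])

    def grade_group(self, grade: str) -> list:
        """Tumor samples of a WHO grade, pooling early and late lesions."""
        sel = (self.df["who_grade"] == grade) & (self.df["role"] != "Normal")
        return sorted(self.df.index[sel])

    def pairs(self) -> dict:
        """pair_id -> (early sample_id, late sample_id)."""
        out = {}
        tumors = self.df[self.df["role"] != "Normal"]
        for pid, grp in tumors.groupby("pair_id"):
            early = grp.index[grp["role"] == "Early"][0]
            late = grp.index[grp["role"] == "Late"][0]
            out[pid] = (early, late)
        return out

    def count_idh1_mut_pairs(self) -> int:
        tumors = self.df[self.df["role"] != "Normal"]
        return int(sum(
            (grp["idh1_status"] == "mut").any() for _, grp in tumors.groupby("pair_id")
        ))


def read_sample_sheet(path) -> SampleSheet:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"sample_id", "pair_id", "role", "who_grade",
                "idh1_status", "idh2_status", "cohort"}
    missing = required - set(df.columns)
    if missing:
        raise ModelError(f"sample sheet missing column(s): {sorted(missing)}")
    out = df.set_index("sample_id")
    out["pair_id"] = out["pair_id"].replace("", None)
    return SampleSheet(out)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    df = sheet.df.copy()
    df["pair_id"] = df["pair_id"].fillna("")
    df.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# Signal and beta containers
# ---------------------------------------------------------------------------

@dataclass
class SignalSet:
    """Per-sample methylated (M) and unmethylated (U) bead intensities."""

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame

    def __post_init__(self) -> None:
        m, u = self.methylated, self.unmethylated
        if m.shape != u.shape or not m.index.equals(u.index) or not m.columns.equals(u.columns):
            raise ModelError("methylated/unmethylated matrices must share shape and keys")
        if (m.to_numpy() < 0).any() or (u.to_numpy() < 0).any():
            raise ModelError("intensities must be non-negative")

    @property
    def probe_ids(self) -> pd.Index:
        return self.methylated.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.methylated.columns


@dataclass
class BetaMatrix:
    """Probes x samples beta values in [0, 1] plus detection p-values."""

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        b = self.beta.to_numpy()
        if np.nanmin(b) < -1e-12 or np.nanmax(b) > 1 + 1e-12:
            raise ModelError("beta values must lie in [0, 1]")
        if self.detection_p is not None:
            dp = self.detection_p
            if not dp.index.equals(self.beta.index) or not dp.columns.equals(self.beta.columns):
                raise ModelError("detection_p must share row/column keys with beta")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns


def read_matrix(path) -> pd.DataFrame:
    """Read a probes x samples TSV/CSV matrix keyed by probe_id."""
    sep = _sniff_sep(path)
    return pd.read_csv(path, sep=sep, index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------

@dataclass
class GeneList:
    """An ordered gene list with, per gene, the probes supporting its call."""

    label: str
    genes: tuple = ()
    supporting_probes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = tuple(sorted(set(self.genes)))
        for g in self.genes:
            if not self.supporting_probes.get(g):
                raise ModelError(f"gene {g!r} has no supporting probes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene) -> bool:
        return gene in set(self.genes)

    @property
    def probes(self) -> set:
        out: set = set()
        for g in self.genes:
            out |= set(self.supporting_probes[g])
        return out


def write_gene_list(gene_list: GeneList, path) -> None:
    """Write a gene list TSV, sorted by symbol, with supporting probe ids."""
    rows = []
    for g in gene_list.genes:  # already sorted ascending
        probes = sorted(gene_list.supporting_probes[g])
        rows.append({"gene": g, "n_probes": len(probes), "probes": ";".join(probes)})
    pd.DataFrame(rows, columns=["gene", "n_probes", "probes"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_list(path, label: str = "") -> GeneList:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    genes, support = [], {}
    for _, row in df.iterrows():
        genes.append(row["gene"])
        support[row["gene"]] = set(p for p in row["probes"].split(";") if p)
    return GeneList(label=label or str(path), genes=tuple(genes), supporting_probes=support)
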