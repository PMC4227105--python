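"""Bisulfite clone-sequencing methylation index and array concordance.

After bisulfite PCR, cloning and Sanger sequencing of up to 12 colonies per
amplicon, each clone reports a binary methylation call per CpG.  The
methylation index (MI) is the percentage of methylated CpGs among all CpGs
observed; ambiguous/unreadable calls are encoded as missing and excluded from
both numerator and denominator.

Concordance with array beta values uses the pipeline's own thresholds: a CpG
agrees when (beta > 0.5 and MI > 50%) or (beta < 0.25 and MI < 25%); anything
else is indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import BetaMatrix, _sniff_sep

MAX_CLONES = 12


@dataclass
class CloneMatrix:
    """Clones x CpG-positions binary call matrix for one sample and gene.

    ``calls`` cells are 0, 1 or NaN (unreadable); columns are genomic CpG
    positions; ``array_probe_overlap`` maps a position to the 450K probe id
    interrogating it, where one exists.
    """

    sample_id: str
    gene: str
    calls: pd.DataFrame
    array_probe_overlap: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy(dtype=float)
        observed = vals[~np.isnan(vals)]
        if not np.isin(observed, [0.0, 1.0]).all():
            raise ValueError("clone calls must be 0, 1 or missing")
        if self.calls.shape[0] > MAX_CLONES:
            raise ValueError(f"more than {MAX_CLONES} clones")

    @property
    def cpg_positions(self) -> list:
        return list(self.calls.columns)


def methylation_index(clones: CloneMatrix) -> float:
    """100 x methylated CpGs / CpGs observed, over all clones."""
    vals = clones.calls.to_numpy(dtype=float)
    observed = ~np.isnan(vals)
    n = int(observed.sum())
    if n == 0:
        raise ValueError("no observed CpG calls")
    return 100.0 * float(np.nansum(vals)) / n


def column_methylation_index(clones: CloneMatrix) -> pd.Series:
    """Per-CpG-position MI across clones (missing calls excluded)."""
    return clones.calls.mean(axis=0, skipna=True) * 100.0


def beta_concordance(clones: CloneMatrix, beta: BetaMatrix) -> pd.DataFrame:
    """Per overlapping CpG: column MI vs array beta with an agreement flag.

    ``agreement`` is 'agree' when (beta > 0.5 and MI > 50) or
    (beta < 0.25 and MI < 25), else 'indeterminate'.
    """
    if not clones.array_probe_overlap:
        raise ValueError("no overlapping array probes")
    mi = column_methylation_index(clones)
    rows = []
    for pos, probe in sorted(clones.array_probe_overlap.items()):
        if pos not in clones.calls.columns or probe not in beta.probe_ids:
            continue
        b = float(beta.beta.loc[probe, clones.sample_id])
        m = float(mi[pos])
        if (b > 0.5 and m > 50.0) or (b < 0.25 and m < 25.0):
            flag = "agree"
        else:
            flag = "indeterminate"
        rows.append({"position": pos, "probe_id": probe, "mi": m,
                     "beta": b, "agreement": flag})
    if not rows:
        raise ValueError("no overlapping positions found in beta matrix")
    return pd.DataFrame(rows)


def read_clone_matrix(path, sample_id: str, gene: str,
                      probe_map: dict | None = None) -> CloneMatrix:
    """Read a clones x positions TSV with cells in {0, 1, NA}."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"])
    df.columns = [int(c) for c in df.columns]
    return CloneMatrix(sample_id=sample_id, gene=gene, calls=df,
                       array_probe_overlap=probe_map or {})


def write_clone_matrix(clones: CloneMatrix, path) -> None:
    out = clones.calls.copy()
    out.to_csv(path, sep="\t", index_label="clone", na_rep="NA")
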