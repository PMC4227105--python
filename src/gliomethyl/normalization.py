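"""Two-channel Infinium preprocessing and beta computation.

The 450K array mixes two probe chemistries: type I probes read both bead types
on a single colour channel (Grn or Red), type II probes read methylated signal
on Grn and unmethylated on Red.  The two dyes have different brightness, so
raw type I Red-channel intensities are biased relative to Grn.  The pipeline
follows the classic intensity-domain recipe:

1. split probes by (design type, channel);
2. per array, map the type I Red-channel intensity distribution onto the Grn
   quantile function through a smoothed monotone quantile map (colour-bias
   correction; type II probes have a single effective channel and are left
   untouched);
3. recombine and quantile-normalize intensities between arrays;
4. compute beta = M / (M + U + alpha).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import rankdata

from .model import BetaMatrix, ProbeManifest, SignalSet


@dataclass
class NormalizationConfig:
    alpha_offset: float = 100.0
    apply_type_correction: bool = True
    apply_between_array: bool = True
    smooth_grid_points: int = 1000

    def __post_init__(self) -> None:
        if self.alpha_offset < 0:
            raise ValueError("alpha_offset must be >= 0")
        if self.smooth_grid_points < 2:
            raise ValueError("smooth_grid_points must be >= 2")


def partition_signals(signals: SignalSet, manifest: ProbeManifest) -> dict:
    """Split a SignalSet into {(design_type, channel): SignalSet} groups.

    The partition is exact: groups are disjoint and their union is the input.
    """
    missing = signals.probe_ids.difference(manifest.probe_ids)
    if len(missing):
        raise KeyError(f"probe(s) missing from manifest: {list(missing[:5])}")
    ann = manifest.df.loc[signals.probe_ids]
    out = {}
    for (dtype, channel), sub in ann.groupby(["design_type", "channel"], sort=True):
        idx = sub.index
        out[(dtype, channel)] = SignalSet(
            methylated=signals.methylated.loc[idx],
            unmethylated=signals.unmethylated.loc[idx],
        )
    return out


def recombine_signals(groups: dict) -> SignalSet:
    """Inverse of :func:`partition_signals`; rows sorted by probe id."""
    m = pd.concat([g.methylated for g in groups.values()]).sort_index()
    u = pd.concat([g.unmethylated for g in groups.values()]).sort_index()
    return SignalSet(methylated=m, unmethylated=u)


def _smooth_quantile_map(source: np.ndarray, target: np.ndarray,
                         grid_points: int) -> np.ndarray:
    """Map ``source`` values onto the quantile function of ``target`` through
    a monotone (PCHIP) interpolation of the empirical quantile map on
    ``grid_points`` probability anchors.  Rank order is preserved because the
    interpolant is monotone."""
    grid = np.linspace(0.0, 1.0, grid_points)
    src_q = np.quantile(source, grid)
    tgt_q = np.quantile(target, grid)
    # collapse duplicate abscissae (ties in the source) keeping monotonicity
    src_anchor, keep = np.unique(src_q, return_index=True)
    tgt_anchor = tgt_q[keep]
    if len(src_anchor) < 2:
        return np.full_like(source, float(np.mean(tgt_anchor)))
    interp = PchipInterpolator(src_anchor, np.maximum.accumulate(tgt_anchor),
                               extrapolate=True)
    mapped = interp(source)
    lo, hi = tgt_anchor[0], np.maximum.accumulate(tgt_anchor)[-1]
    return np.clip(mapped, lo, hi)


def smooth_quantile_between_channels(
    groups: dict, config: NormalizationConfig | None = None
) -> SignalSet:
    """Within-array colour-bias correction for type I probes.

    Per array, the Red-channel intensities (M and U pooled) are mapped onto
    the Grn-channel quantile function through a smoothed monotone quantile
    map.  Type II probes rejoin unchanged at recombination.
    """
    config = config or NormalizationConfig()
    grn = groups.get(("I", "Grn"))
    red = groups.get(("I", "Red"))
    if grn is None or red is None:
        warnings.warn("one colour channel is empty; skipping colour-bias correction")
        return recombine_signals(groups)

    red_m = red.methylated.copy()
    red_u = red.unmethylated.copy()
    n_red = red_m.shape[0]
    for sample in red_m.columns:
        grn_vals = np.concatenate(
            [grn.methylated[sample].to_numpy(), grn.unmethylated[sample].to_numpy()]
        )
        red_vals = np.concatenate(
            [red_m[sample].to_numpy(), red_u[sample].to_numpy()]
        )
        if len(red_vals) < 2 or len(grn_vals) < 2:
            warnings.warn(f"array {sample!r}: <2 probes in a channel; correction skipped")
            continue
        mapped = _smooth_quantile_map(red_vals, grn_vals, config.smooth_grid_points)
        red_m[sample] = mapped[:n_red]
        red_u[sample] = mapped[n_red:]

    corrected = dict(groups)
    corrected[("I", "Red")] = SignalSet(methylated=red_m, unmethylated=red_u)
    return recombine_signals(corrected)


def quantile_normalize_between_arrays(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force identical value distributions across columns (arrays).

    Each column's sorted values are replaced by the column-wise mean of order
    statistics; tied entries within a column receive the average of the mean
    order statistics they span.
    """
    if matrix.shape[1] < 2:
        warnings.warn("between-array quantile normalization needs >=2 columns; identity")
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, mean_sorted)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def compute_beta(signals: SignalSet, config: NormalizationConfig | None = None) -> BetaMatrix:
    """beta = M / (M + U + alpha), elementwise, in [0, 1]."""
    config = config or NormalizationConfig()
    m = signals.methylated.to_numpy(dtype=float)
    u = signals.unmethylated.to_numpy(dtype=float)
    denom = m + u + config.alpha_offset
    if config.alpha_offset == 0 and (denom == 0).any():
        warnings.warn("M = U = 0 with alpha = 0; beta defined as 0 for those cells")
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, m / np.where(denom == 0, 1.0, denom), 0.0)
    return BetaMatrix(
        beta=pd.DataFrame(beta, index=signals.probe_ids, columns=signals.sample_ids)
    )


def normalize_signals(
    signals: SignalSet,
    manifest: ProbeManifest,
    config: NormalizationConfig | None = None,
    detection_p: pd.DataFrame | None = None,
) -> BetaMatrix:
    """Full preprocessing: colour-bias correction, between-array quantile
    normalization of the stacked (M, U) intensity matrix, beta computation.

    With ``apply_type_correction=False`` and ``apply_between_array=False``
    this reduces to plain beta computation on the raw intensities.
    """
    config = config or NormalizationConfig()
    current = signals
    if config.apply_type_correction:
        current = smooth_quantile_between_channels(
            partition_signals(current, manifest), config
        )
    if config.apply_between_array and current.methylated.shape[1] >= 2:
        # stack M over U so each array is normalized as one intensity vector
        stacked = pd.concat(
            [current.methylated.add_suffix("", axis=0), current.unmethylated], axis=0,
            keys=["M", "U"],
        )
        normed = quantile_normalize_between_arrays(stacked)
        current = SignalSet(
            methylated=normed.loc["M"], unmethylated=normed.loc["U"]
        )
    result = compute_beta(current, config)
    if detection_p is not None:
        result = BetaMatrix(beta=result.beta,
                            detection_p=detection_p.loc[result.probe_ids, result.sample_ids])
    return result
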