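"""Euclidean-distance (ED) bulked-segregant genome scan.

For each biallelic SNP the two pools' alternate-allele frequencies
``f_G, f_Y`` are estimated from read depths, the ED statistic

    ED = sqrt((f_G - f_Y)^2 + ((1-f_G) - (1-f_Y))^2) = sqrt(2) * |f_G - f_Y|

is squared to suppress background noise, smoothed along each chromosome by
LOESS (degree-1 local regression, tricube weights), aggregated in sliding
windows, and thresholded at the genome-wide top quantile to call candidate
regions.  At a recessive causal locus with pools drawn from an F2, the
expected green-pool frequency is 1/3 and the yellow-pool frequency 1, so the
expected ED^2 approaches 8/9 as coverage grows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SQRT2 = math.sqrt(2.0)

__all__ = [
    "ScanParams",
    "RegionCall",
    "allele_frequencies",
    "ed_statistic",
    "association_value",
    "loess_fit",
    "sliding_window",
    "top_quantile_threshold",
    "call_regions",
    "scan",
]


@dataclass(frozen=True)
class ScanParams:
    """Tunable knobs of the scan with the package defaults."""

    min_depth: int = 10
    span: float = 0.1
    window_bp: int = 1_000_000
    step_bp: int = 100_000
    quantile: float = 0.99
    merge_gap_bp: int = 100_000
    threshold_on: str = "windows"  # or "sites"

    def __post_init__(self) -> None:
        if not (0 < self.span <= 1):
            raise ValueError("span must be in (0, 1]")
        if not (0 < self.quantile < 1):
            raise ValueError("quantile must be in (0, 1)")
        if self.step_bp <= 0 or self.window_bp < self.step_bp:
            raise ValueError("require window_bp >= step_bp > 0")
        if self.threshold_on not in ("windows", "sites"):
            raise ValueError("threshold_on must be 'windows' or 'sites'")


@dataclass(frozen=True)
class RegionCall:
    """A contiguous interval of above-threshold windows (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    peak_pos: int
    peak_fitted: float
    n_sites: int

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


def allele_frequencies(table: pd.DataFrame, min_depth: int = 10) -> pd.DataFrame:
    """Per-pool alternate-allele frequencies; drops low-depth sites.

    A site is retained only when *both* pools reach ``min_depth`` total reads,
    so zero-depth sites can never divide by zero.  Returns the retained rows
    with added ``f_g`` and ``f_y`` columns.
    """
    g_tot = table["g_ref"] + table["g_alt"]
    y_tot = table["y_ref"] + table["y_alt"]
    keep = (g_tot >= min_depth) & (y_tot >= min_depth)
    out = table.loc[keep].copy()
    out["f_g"] = out["g_alt"] / (out["g_ref"] + out["g_alt"])
    out["f_y"] = out["y_alt"] / (out["y_ref"] + out["y_alt"])
    return out


def ed_statistic(f_g, f_y):
    """ED over the two pools' (alt, ref) frequency vectors: sqrt(2)*|f_G-f_Y|."""
    f_g = np.asarray(f_g, dtype=float)
    f_y = np.asarray(f_y, dtype=float)
    if np.any((f_g < 0) | (f_g > 1)) or np.any((f_y < 0) | (f_y > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return SQRT2 * np.abs(f_g - f_y)


def association_value(ed):
    """ED squared — the per-site association value."""
    ed = np.asarray(ed, dtype=float)
    if np.any(ed < 0):
        raise ValueError("ED must be >= 0")
    return ed**2


def _loess_chromosome(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    n = len(x)
    k = max(2, int(math.ceil(span * n)))
    k = min(k, n)
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        # span-nearest neighbours by genomic distance
        nn = np.argpartition(d, k - 1)[:k]
        dmax = d[nn].max()
        if dmax == 0:
            fitted[i] = y[nn].mean()
            continue
        w = (1 - (d[nn] / dmax) ** 3) ** 3
        sw = w.sum()
        if sw <= 0:
            fitted[i] = y[i]
            continue
        # weighted degree-1 fit, evaluated at x[i]; centred for stability
        xc = x[nn] - x[i]
        xbar = (w * xc).sum() / sw
        ybar = (w * y[nn]).sum() / sw
        sxx = (w * (xc - xbar) ** 2).sum()
        if sxx <= 0:
            fitted[i] = ybar
        else:
            slope = (w * (xc - xbar) * (y[nn] - ybar)).sum() / sxx
            fitted[i] = ybar - slope * xbar
    return fitted


def loess_fit(
    positions: np.ndarray,
    values: np.ndarray,
    span: float = 0.1,
) -> np.ndarray:
    """LOESS (degree 1, tricube) fitted values at every input position.

    The neighbourhood of a site is its ``ceil(span * n)`` nearest sites by
    genomic distance (at least 2); tricube weights use the distance to the
    farthest neighbour as bandwidth.  Positions need not be sorted; fewer
    than 2 sites returns the raw values with a warning.
    """
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if positions.shape != values.shape:
        raise ValueError("positions and values must have equal length")
    if len(positions) < 2:
        logger.warning("fewer than 2 sites; returning raw values")
        return values.copy()
    return _loess_chromosome(positions, values, span)


def sliding_window(
    track: pd.DataFrame,
    window_bp: int = 1_000_000,
    step_bp: int = 100_000,
    value_col: str = "fitted",
) -> pd.DataFrame:
    """Mean of ``value_col`` in windows tiling each chromosome from position 1.

    Windows are [start, start + window_bp) at ``step_bp`` strides; empty
    windows carry NaN (and are excluded from thresholding downstream).
    Returns columns ``chrom, start, end, mean_fitted, n_sites`` with 1-based
    inclusive coordinates.
    """
    if not (window_bp >= step_bp > 0):
        raise ValueError("require window_bp >= step_bp > 0")
    out = []
    for chrom, grp in track.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        vals = grp[value_col].to_numpy()
        order = np.argsort(pos)
        pos, vals = pos[order], vals[order]
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        last = int(pos[-1]) if len(pos) else 0
        start = 1
        while start <= last:
            end = start + window_bp - 1
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            n = hi - lo
            mean = (csum[hi] - csum[lo]) / n if n else np.nan
            out.append((chrom, start, end, mean, int(n)))
            start += step_bp
    return pd.DataFrame(
        out, columns=["chrom", "start", "end", "mean_fitted", "n_sites"]
    )


def top_quantile_threshold(values, q: float = 0.99) -> float:
    """Genome-wide top-quantile threshold (linear-interpolation quantile).

    Selection downstream is ``value >= threshold`` so ties at the threshold
    are all selected.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        raise ValueError("no non-missing values to threshold")
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    return float(np.quantile(values, q))


def call_regions(
    windows: pd.DataFrame,
    threshold: float,
    merge_gap_bp: int = 100_000,
    track: pd.DataFrame | None = None,
) -> list[RegionCall]:
    """Merge above-threshold windows into candidate regions.

    Maximal runs of selected windows per chromosome are merged when separated
    by less than ``merge_gap_bp``; a region spans min start to max end of its
    windows, and its peak is the member window with the largest mean.
    ``n_sites`` counts track sites inside the region when a track is given,
    else the sum of member-window site counts.
    """
    regions: list[RegionCall] = []
    sel = windows.loc[windows["mean_fitted"] >= threshold]
    for chrom, grp in sel.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cluster: list[pd.Series] = []
        for _, win in grp.iterrows():
            if cluster and win["start"] - cluster[-1]["end"] - 1 >= merge_gap_bp:
                regions.append(_make_region(chrom, cluster, track))
                cluster = []
            cluster.append(win)
        if cluster:
            regions.append(_make_region(chrom, cluster, track))
    return regions


def _make_region(chrom, cluster, track) -> RegionCall:
    start = int(min(w["start"] for w in cluster))
    end = int(max(w["end"] for w in cluster))
    peak = max(cluster, key=lambda w: w["mean_fitted"])
    if track is not None:
        mask = (track["chrom"] == chrom) & track["pos"].between(start, end)
        n_sites = int(mask.sum())
    else:
        n_sites = int(sum(w["n_sites"] for w in cluster))
    return RegionCall(
        chrom=chrom,
        start=start,
        end=end,
        peak_pos=int((peak["start"] + peak["end"]) // 2),
        peak_fitted=float(peak["mean_fitted"]),
        n_sites=n_sites,
    )


def scan(
    table: pd.DataFrame,
    params: ScanParams = ScanParams(),
) -> tuple[pd.DataFrame, list[RegionCall], dict]:
    """Full ED scan: filter -> frequencies -> ED -> ED^2 -> LOESS -> windows
    -> genome-wide top-quantile threshold -> regions.

    Returns ``(track, regions, report)`` where the track has one row per
    retained site (``chrom, pos, f_g, f_y, ed, ed2, fitted``) and the report
    records site counts at each stage.  The result is invariant to input row
    order (sites are sorted per chromosome before fitting).
    """
    report = {"n_input": int(len(table))}
    if len(table) == 0:
        track = pd.DataFrame(
            columns=["chrom", "pos", "f_g", "f_y", "ed", "ed2", "fitted"]
        )
        report.update(
            n_retained=0, n_windows=0, n_windows_nonempty=0,
            threshold=float("nan"), n_selected=0, n_regions=0,
        )
        return track, [], report

    table = table.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
        drop=True
    )
    track = allele_frequencies(table, params.min_depth).reset_index(drop=True)
    report["n_retained"] = int(len(track))
    track["ed"] = ed_statistic(track["f_g"], track["f_y"])
    track["ed2"] = association_value(track["ed"])
    fitted = np.empty(len(track))
    for chrom, grp in track.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if len(grp) < 2:
            logger.warning("chromosome %s has <2 sites; fitted = raw", chrom)
            fitted[idx] = grp["ed2"].to_numpy()
        else:
            fitted[idx] = loess_fit(
                grp["pos"].to_numpy(), grp["ed2"].to_numpy(), params.span
            )
    track["fitted"] = fitted
    track = track[["chrom", "pos", "f_g", "f_y", "ed", "ed2", "fitted"]]

    windows = sliding_window(track, params.window_bp, params.step_bp)
    nonempty = windows["mean_fitted"].notna()
    report["n_windows"] = int(len(windows))
    report["n_windows_nonempty"] = int(nonempty.sum())
    if params.threshold_on == "windows":
        pool = windows.loc[nonempty, "mean_fitted"]
    else:
        pool = track["fitted"]
    if len(pool) == 0:
        report.update(threshold=float("nan"), n_selected=0, n_regions=0)
        return track, [], report
    threshold = top_quantile_threshold(pool, params.quantile)
    report["threshold"] = threshold
    report["n_selected"] = int((windows["mean_fitted"] >= threshold).sum())
    regions = call_regions(windows, threshold, params.merge_gap_bp, track)
    report["n_regions"] = len(regions)
    return track, regions, report
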