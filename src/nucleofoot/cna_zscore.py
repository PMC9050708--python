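"""Genome-wide z-score: chromosomal instability from binned LC-WGS counts.

Reads are counted in 1 Mbp autosomal bins, corrected for library size,
GC content and mappability, smoothed with 50-bin moving-window averages,
and each window is z-scored against a panel of healthy samples. The
scalar genome-wide z-score of a sample is the z-score — again against
the healthy panel — of the sum of squares of all its window z-values.
High values indicate copy-number alterations spread across the genome,
the hallmark of high-grade serous ovarian carcinoma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_tracks import BinAnnotation, ReadStartTrack

logger = logging.getLogger(__name__)

WINDOW_BINS = 50
SD_FLOOR = 1e-8


@dataclass
class BinnedCoverage:
    """Per-bin raw counts and (optionally) bias-corrected values."""

    raw: np.ndarray
    corrected: np.ndarray | None = None
    n_dropped: int = 0  # reads outside any bin

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=np.float64)
        if np.any(self.raw < 0):
            raise ValueError("negative raw counts")
        if self.corrected is not None:
            self.corrected = np.asarray(self.corrected, dtype=np.float64)

    def to_tsv(self, path: str, bins: BinAnnotation) -> None:
        t = bins.table[["chrom", "start", "end"]].copy()
        t["raw"] = self.raw
        t["corrected"] = np.nan if self.corrected is None else self.corrected
        t.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class WindowZ:
    """Moving-window means and z-values vs the reference panel."""

    window_start_bin: np.ndarray  # index of first bin of each window
    values: np.ndarray  # 50-bin means of corrected values
    z: np.ndarray | None = None


@dataclass
class ReferencePanel:
    """Healthy-panel window statistics and the reference SS distribution.

    Window means/sds are taken across panel samples; the sum-of-squares
    (SS) reference distribution is built leave-one-out: each member is
    z-scored against the panel without itself, so a sample's own noise
    does not deflate its reference.
    """

    window_start_bin: np.ndarray
    window_mean: np.ndarray
    window_sd: np.ndarray
    ss_mean: float
    ss_sd: float
    n_samples: int
    loo_ss: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_files(self, prefix: str) -> None:
        import json

        pd.DataFrame(
            {
                "window_start_bin": self.window_start_bin,
                "mean": self.window_mean,
                "sd": self.window_sd,
            }
        ).to_csv(f"{prefix}.tsv", sep="\t", index=False)
        with open(f"{prefix}.json", "w") as fh:
            json.dump(
                {
                    "ss_mean": self.ss_mean,
                    "ss_sd": self.ss_sd,
                    "n_samples": self.n_samples,
                },
                fh,
            )


@dataclass
class GenomeWideZ:
    zscore: float
    sum_of_squares: float
    n_windows: int


def bin_reads(starts: ReadStartTrack, bins: BinAnnotation) -> BinnedCoverage:
    """Count read starts per annotation bin (half-open intervals)."""
    t = bins.table
    counts = np.zeros(len(t), dtype=np.int64)
    dropped = 0
    for chrom, sub in t.groupby("chrom", sort=False):
        pos = starts.starts.get(chrom)
        if pos is None or pos.size == 0:
            continue
        edges_start = sub["start"].to_numpy()
        edges_end = sub["end"].to_numpy()
        idx = np.searchsorted(edges_start, pos, side="right") - 1
        ok = (idx >= 0) & (pos < edges_end[np.clip(idx, 0, None)])
        dropped += int((~ok).sum())
        np.add.at(counts, sub.index.to_numpy()[idx[ok]], 1)
    in_bins = set(t["chrom"])
    dropped += sum(
        v.size for c, v in starts.starts.items() if c not in in_bins
    )
    logger.info("binned %d reads, %d outside bins", counts.sum(), dropped)
    return BinnedCoverage(raw=counts, n_dropped=dropped)


def correct_bins(
    cov: BinnedCoverage,
    bins: BinAnnotation,
    loess_span: float = 0.3,
) -> BinnedCoverage:
    """Adjust bin counts for library size, GC content and mappability.

    (1) counts are scaled to counts-per-million of the usable-bin total;
    (2) a lowess trend of CPM against GC, fitted on usable bins, is
    divided out; (3) the result is divided by bin mappability. Unusable
    bins (short terminal bins, low mappability) keep NaN corrected values.
    """
    usable = bins.usable
    if not usable.any():
        raise ValueError("no usable bins")
    gc = bins.table["gc"].to_numpy()
    mapp = bins.table["mappability"].to_numpy()
    total = cov.raw[usable].sum()
    if total == 0:
        raise ValueError("zero usable read count")
    cpm = cov.raw * 1e6 / total
    if np.ptp(gc[usable]) < 1e-9:  # constant GC: trend is the mean
        trend = np.full(len(gc), cpm[usable].mean())
    else:
        trend_pts = lowess(
            cpm[usable], gc[usable], frac=loess_span, return_sorted=True
        )
        trend = np.interp(gc, trend_pts[:, 0], trend_pts[:, 1])
    trend = np.maximum(trend, SD_FLOOR)
    corrected = np.full(len(cpm), np.nan)
    corrected[usable] = cpm[usable] / trend[usable] / mapp[usable]
    return BinnedCoverage(raw=cov.raw, corrected=corrected,
                          n_dropped=cov.n_dropped)


def _window_index(bins: BinAnnotation, usable: np.ndarray) -> np.ndarray:
    """Start-bin indices of all 50-usable-bin windows within chromosomes."""
    starts = []
    chroms = bins.table["chrom"].to_numpy()
    idx = np.arange(len(chroms))
    for chrom in pd.unique(chroms):
        sel = idx[(chroms == chrom) & usable]
        if sel.size < WINDOW_BINS:
            logger.info("chromosome %s: <%d usable bins, no windows",
                        chrom, WINDOW_BINS)
            continue
        starts.extend(sel[: sel.size - WINDOW_BINS + 1])
    return np.asarray(starts, dtype=np.int64)


def _window_means(
    corrected: np.ndarray, bins: BinAnnotation, usable: np.ndarray,
    win_starts: np.ndarray,
) -> np.ndarray:
    """Mean corrected value over each run of 50 consecutive usable bins."""
    usable_idx = np.flatnonzero(usable)
    vals = corrected[usable_idx]
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    pos_of = {b: i for i, b in enumerate(usable_idx)}
    first = np.array([pos_of[s] for s in win_starts])
    return (csum[first + WINDOW_BINS] - csum[first]) / WINDOW_BINS


def window_values(
    sample: BinnedCoverage, bins: BinAnnotation
) -> WindowZ:
    """50-bin moving-window averages (step 1 bin, within one chromosome)."""
    if sample.corrected is None:
        raise ValueError("run correct_bins first")
    usable = bins.usable  # corrected is NaN exactly off the usable mask
    ws = _window_index(bins, usable)
    if ws.size == 0:
        raise ValueError("no 50-bin windows available")
    return WindowZ(ws, _window_means(sample.corrected, bins, usable, ws))


def window_zscores(
    sample: BinnedCoverage, panel: ReferencePanel, bins: BinAnnotation
) -> WindowZ:
    """z-value of each window against the healthy panel."""
    wv = window_values(sample, bins)
    if not np.array_equal(wv.window_start_bin, panel.window_start_bin):
        raise ValueError("window grid does not match the reference panel")
    wv.z = (wv.values - panel.window_mean) / panel.window_sd
    return wv


def build_reference_panel(
    panels: list[BinnedCoverage], bins: BinAnnotation
) -> ReferencePanel:
    """Window statistics and leave-one-out SS distribution from healthy samples."""
    if len(panels) < 3:
        raise ValueError("panel too small: need >= 3 healthy samples")
    wvs = [window_values(p, bins) for p in panels]
    ws = wvs[0].window_start_bin
    for w in wvs[1:]:
        if not np.array_equal(w.window_start_bin, ws):
            raise ValueError("mismatched bin grids across panel samples")
    mat = np.vstack([w.values for w in wvs])  # samples x windows
    mean = mat.mean(axis=0)
    sd = np.maximum(mat.std(axis=0, ddof=1), SD_FLOOR)
    loo_ss = np.empty(len(panels))
    for i in range(len(panels)):
        rest = np.delete(mat, i, axis=0)
        m = rest.mean(axis=0)
        s = np.maximum(rest.std(axis=0, ddof=1), SD_FLOOR)
        z = (mat[i] - m) / s
        loo_ss[i] = float(np.sum(z**2))
    ss_sd = float(loo_ss.std(ddof=1))
    return ReferencePanel(
        window_start_bin=ws,
        window_mean=mean,
        window_sd=sd,
        ss_mean=float(loo_ss.mean()),
        ss_sd=ss_sd,
        n_samples=len(panels),
        loo_ss=loo_ss,
    )


def genome_wide_zscore(wz: WindowZ, panel: ReferencePanel) -> GenomeWideZ:
    """Scalar instability score: z of the sample's window-z sum of squares."""
    if wz.z is None or wz.z.size == 0:
        raise ValueError("no window z-values")
    if panel.ss_sd <= SD_FLOOR:
        raise ValueError(
            "degenerate reference SS distribution; enlarge the healthy panel"
        )
    ss = float(np.sum(wz.z**2))
    return GenomeWideZ(
        zscore=(ss - panel.ss_mean) / panel.ss_sd,
        sum_of_squares=ss,
        n_windows=int(wz.z.size),
    )


def score_sample_gwz(
    sample: BinnedCoverage, panel: ReferencePanel, bins: BinAnnotation
) -> GenomeWideZ:
    """Convenience: window z-scores then the genome-wide z-score."""
    return genome_wide_zscore(window_zscores(sample, panel, bins), panel)
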