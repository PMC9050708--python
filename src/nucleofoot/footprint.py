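"""Read-start-to-nucleosome-center distance histograms.

The per-sample observation of the mixture model: signed distances from each
read start to the nearest nucleosome center, counted over [-300, +300] bp.
Healthy cfDNA gives an M-shaped profile — fragment boundaries pile up at
nucleosome edges and are depleted at centers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_tracks import NucleosomeMap, ReadStartTrack

logger = logging.getLogger(__name__)

MAX_DISTANCE = 300
N_BINS = 2 * MAX_DISTANCE + 1  # 601
DISTANCE_INDEX = np.arange(-MAX_DISTANCE, MAX_DISTANCE + 1)


@dataclass
class DistanceHistogram:
    """Counts ``y_i`` of signed distances i in [-300, +300] (601 bins)."""

    counts: np.ndarray
    sample_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# sample={self.sample_id} n={self.n}\n")
            for d, c in zip(DISTANCE_INDEX, self.counts):
                fh.write(f"{d}\t{c}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "DistanceHistogram":
        sample_id = ""
        counts = np.zeros(N_BINS, dtype=np.int64)
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if tok.startswith("sample="):
                            sample_id = tok[len("sample="):]
                    continue
                d, c = line.split("\t")
                counts[int(d) + MAX_DISTANCE] = int(c)
        return cls(counts, sample_id=sample_id)


def nearest_center_distances(
    starts: ReadStartTrack, nmap: NucleosomeMap
) -> np.ndarray:
    """Signed distance from each read start to its nearest map center.

    For read start ``s`` and nearest center ``c``, the distance is
    ``s - c``; distances beyond +/-300 bp are discarded. When a start is
    exactly equidistant between two centers it is assigned to the
    smaller-coordinate center, so the reported distance is positive.
    Reads on chromosomes absent from the map are skipped.
    """
    shared = set(starts.starts) & set(nmap.centers)
    if not shared:
        raise ValueError("no chromosome overlap between reads and map")
    skipped = sum(
        starts.starts[c].size for c in set(starts.starts) - shared
    )
    if skipped:
        logger.info("%d reads on chromosomes absent from the map", skipped)
    out = []
    for chrom in sorted(shared):
        s = starts.starts[chrom]
        centers = nmap.centers[chrom]
        if s.size == 0 or centers.size == 0:
            continue
        # nearest neighbour by binary search on the sorted center array
        right = np.searchsorted(centers, s)
        left = np.clip(right - 1, 0, centers.size - 1)
        right = np.clip(right, 0, centers.size - 1)
        d_left = s - centers[left]
        d_right = s - centers[right]
        # ties (|d_left| == |d_right|) go to the smaller-coordinate center
        use_left = np.abs(d_left) <= np.abs(d_right)
        d = np.where(use_left, d_left, d_right)
        out.append(d[np.abs(d) <= MAX_DISTANCE])
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def build_distance_histogram(
    distances: np.ndarray, sample_id: str = ""
) -> DistanceHistogram:
    """Count signed distances into the 601-bin histogram ``y``."""
    distances = np.asarray(distances, dtype=np.int64)
    if distances.size and np.abs(distances).max() > MAX_DISTANCE:
        raise ValueError(f"distance outside [-{MAX_DISTANCE}, {MAX_DISTANCE}]")
    counts = np.bincount(distances + MAX_DISTANCE, minlength=N_BINS)
    return DistanceHistogram(counts, sample_id=sample_id)


def footprint_histogram(
    starts: ReadStartTrack, nmap: NucleosomeMap, sample_id: str = ""
) -> DistanceHistogram:
    """Convenience: distances then histogram, with provenance metadata."""
    d = nearest_center_distances(starts, nmap)
    h = build_distance_histogram(d, sample_id=sample_id)
    h.meta["n_reads_input"] = starts.n_reads
    h.meta["n_reads_in_range"] = int(d.size)
    return h
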