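"""Genomic input tracks: nucleosome maps, read starts, fragments, bin grids.

All coordinates are 0-based; intervals are half-open ``[start, end)``.
Only autosomes (``chr1``–``chr22``, with or without the ``chr`` prefix) are
retained; sex chromosomes, mitochondria and non-canonical contigs are
dropped at load time because every downstream statistic is defined on
autosomes only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOMES = frozenset(
    name for i in range(1, 23) for name in (f"chr{i}", str(i))
)


def is_autosome(chrom: str) -> bool:
    return chrom in AUTOSOMES


def _norm_chrom(chrom: str) -> str:
    """Canonical chromosome name: 'chr1'..'chr22'."""
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


class TrackParseError(ValueError):
    """Raised for malformed records in BED-like inputs."""


@dataclass
class NucleosomeMap:
    """Sorted nucleosome-center positions per autosome.

    The reference footprint atlas: read starts are measured against the
    nearest center in this map.
    """

    centers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, arr in self.centers.items():
            arr = np.asarray(arr, dtype=np.int64)
            if arr.size and arr.min() < 0:
                raise ValueError(f"negative center position on {chrom}")
            self.centers[chrom] = np.sort(arr)
        if not any(a.size for a in self.centers.values()):
            raise ValueError("empty map after autosome filter")

    @property
    def n_centers(self) -> int:
        return sum(a.size for a in self.centers.values())

    def chromosomes(self) -> list[str]:
        return sorted(self.centers)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in self.chromosomes():
                for c in self.centers[chrom]:
                    fh.write(f"{chrom}\t{c}\t{c + 1}\n")


@dataclass
class ReadStartTrack:
    """Per-chromosome sorted read-start positions (one per retained read)."""

    starts: dict[str, np.ndarray]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        for chrom, arr in self.starts.items():
            self.starts[chrom] = np.sort(np.asarray(arr, dtype=np.int64))

    @property
    def n_reads(self) -> int:
        return sum(a.size for a in self.starts.values())

    def chromosomes(self) -> list[str]:
        return sorted(self.starts)

    def to_bed(self, path: str, read_length: int = 51) -> None:
        with open(path, "w") as fh:
            for chrom in self.chromosomes():
                for s in self.starts[chrom]:
                    fh.write(f"{chrom}\t{s}\t{s + read_length}\n")


@dataclass
class FragmentTrack:
    """Paired-end fragment intervals per chromosome, sorted by start."""

    intervals: dict[str, np.ndarray]  # (n, 2) int64, [start, end)

    def __post_init__(self) -> None:
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size and np.any(arr[:, 1] <= arr[:, 0]):
                bad = int(np.nonzero(arr[:, 1] <= arr[:, 0])[0][0])
                raise ValueError(
                    f"non-positive fragment length on {chrom}, record {bad}"
                )
            self.intervals[chrom] = arr[np.argsort(arr[:, 0], kind="stable")]

    @property
    def n_fragments(self) -> int:
        return sum(a.shape[0] for a in self.intervals.values())

    def lengths(self) -> np.ndarray:
        if not self.intervals:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(
            [a[:, 1] - a[:, 0] for a in self.intervals.values()]
        )

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for a, b in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{a}\t{b}\n")


@dataclass
class BinAnnotation:
    """Fixed-width genomic bins with GC fraction and mappability.

    ``usable`` marks bins eligible for coverage correction: full-width,
    mappability at or above the threshold.
    """

    table: pd.DataFrame  # chrom, start, end, gc, mappability
    bin_width: int = 1_000_000
    mappability_min: float = 0.8
    usable: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"chrom", "start", "end", "gc", "mappability"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if np.any((t["gc"] < 0) | (t["gc"] > 1)):
            raise ValueError("gc outside [0,1]")
        # overlap check within chromosome
        for chrom, sub in t.groupby("chrom", sort=False):
            s = sub.sort_values("start")
            if np.any(s["start"].values[1:] < s["end"].values[:-1]):
                raise ValueError(f"overlapping bins on {chrom}")
        width = (t["end"] - t["start"]).to_numpy()
        self.usable = (
            (width == self.bin_width)
            & (t["mappability"].to_numpy() >= self.mappability_min)
        )

    @property
    def n_bins(self) -> int:
        return len(self.table)

    @classmethod
    def from_tsv(cls, path: str, **kw) -> "BinAnnotation":
        t = pd.read_csv(path, sep="\t", comment="#")
        return cls(t, **kw)

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _read_bedlike(path: str, min_cols: int) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_cols:
                raise TrackParseError(
                    f"{path}:{lineno}: expected >= {min_cols} columns, "
                    f"got {len(parts)}"
                )
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise TrackParseError(f"{path}:{lineno}: {exc}") from None
            rows.append((chrom, start, end, parts[3:], lineno))
    return rows


def load_nucleosome_map(path: str) -> NucleosomeMap:
    """Load a BED-like nucleosome-position list into a :class:`NucleosomeMap`.

    The center of each record is ``floor((start + end) / 2)``; records whose
    interval is a single position are taken as centers directly (the same
    formula covers both). Sex chromosomes and non-canonical contigs are
    dropped; duplicates are retained.
    """
    centers: dict[str, list[int]] = {}
    kept = dropped = 0
    for chrom, start, end, _, _lineno in _read_bedlike(path, 3):
        if not is_autosome(chrom):
            dropped += 1
            continue
        centers.setdefault(_norm_chrom(chrom), []).append((start + end) // 2)
        kept += 1
    logger.info("nucleosome map: %d kept, %d dropped (non-autosome)", kept, dropped)
    if kept == 0:
        raise ValueError("empty map after autosome filter")
    return NucleosomeMap({c: np.array(v) for c, v in centers.items()})


def _load_starts_bam(path: str, min_mapq: int, leftmost: bool):
    import pysam

    starts: dict[str, list[int]] = {}
    kept = excluded = 0
    with pysam.AlignmentFile(path) as bam:
        for aln in bam.fetch(until_eof=True):
            if (
                aln.is_unmapped
                or aln.is_duplicate
                or aln.is_secondary
                or aln.is_supplementary
                or aln.mapping_quality < min_mapq
                or not is_autosome(aln.reference_name)
            ):
                excluded += 1
                continue
            if leftmost or not aln.is_reverse:
                pos = aln.reference_start
            else:
                pos = aln.reference_end - 1  # 5' end of a reverse read
            starts.setdefault(_norm_chrom(aln.reference_name), []).append(pos)
            kept += 1
    return starts, kept, excluded


def load_read_starts(
    path: str,
    min_mapq: int = 30,
    leftmost: bool = True,
) -> ReadStartTrack:
    """Load single-end read starts from a BED-like file or SAM/BAM.

    One position per retained read: the reference-leftmost aligned
    coordinate by default, or the 5' end on the read's own strand when
    ``leftmost=False`` (BED inputs then use the strand column, falling back
    to leftmost where it is absent). Unmapped, duplicate-flagged, sex-
    chromosome and low-MAPQ alignments are excluded and counted.
    """
    if path.endswith((".bam", ".sam", ".cram")):
        starts, kept, excluded = _load_starts_bam(path, min_mapq, leftmost)
    else:
        starts = {}
        kept = excluded = 0
        for chrom, start, end, extra, _lineno in _read_bedlike(path, 3):
            if not is_autosome(chrom):
                excluded += 1
                continue
            strand = extra[2] if len(extra) >= 3 else (
                extra[0] if extra and extra[0] in "+-" else "+"
            )
            pos = start if (leftmost or strand != "-") else end - 1
            starts.setdefault(_norm_chrom(chrom), []).append(pos)
            kept += 1
    logger.info("read starts: %d kept, %d excluded", kept, excluded)
    if kept == 0:
        raise ValueError("zero retained reads")
    return ReadStartTrack(
        {c: np.array(v) for c, v in starts.items()}, n_excluded=excluded
    )


def load_fragments(path: str) -> FragmentTrack:
    """Load paired-end fragments from a BED(PE)-like file or name-paired BAM.

    Each record becomes one 0-based half-open interval; for BAM input one
    interval per properly-paired, forward-of-pair alignment using the
    template length.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    if path.endswith((".bam", ".sam", ".cram")):
        import pysam

        with pysam.AlignmentFile(path) as bam:
            for aln in bam.fetch(until_eof=True):
                if (
                    aln.is_unmapped
                    or aln.is_duplicate
                    or aln.is_secondary
                    or aln.is_supplementary
                    or not aln.is_proper_pair
                    or aln.template_length <= 0  # keep the leftmost mate only
                    or not is_autosome(aln.reference_name)
                ):
                    continue
                a = aln.reference_start
                intervals.setdefault(_norm_chrom(aln.reference_name), []).append(
                    (a, a + aln.template_length)
                )
    else:
        for chrom, start, end, _, lineno in _read_bedlike(path, 3):
            if not is_autosome(chrom):
                continue
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: fragment end <= start ({start}, {end})"
                )
            intervals.setdefault(_norm_chrom(chrom), []).append((start, end))
    if not intervals:
        raise ValueError("no fragments retained")
    return FragmentTrack({c: np.array(v) for c, v in intervals.items()})


def fragment_size_histogram(
    track: FragmentTrack, max_len: int = 500
) -> pd.DataFrame:
    """Fragment-length counts for lengths ``1..max_len``.

    Lengths beyond ``max_len`` are pooled into a single overflow row with
    length ``-1`` so the total count is conserved. cfDNA fragment sizes
    peak at ~167 bp, the length of DNA around one nucleosome plus linker.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    lengths = track.lengths()
    if lengths.size == 0:
        raise ValueError("empty fragment track")
    in_range = lengths[lengths <= max_len]
    counts = np.bincount(in_range, minlength=max_len + 1)[1:]
    overflow = int((lengths > max_len).sum())
    rows = [(l, int(c)) for l, c in enumerate(counts, start=1) if c]
    if overflow:
        rows.append((-1, overflow))
    return pd.DataFrame(rows, columns=["length", "count"])
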