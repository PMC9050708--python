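"""Synthetic inputs with the statistical structure the method assumes.

Every generator is seeded and bit-reproducible, and emits the ground
truth alongside the data, so each analysis module can be tested against
known mixture fractions, nucleosome positions and copy-number states.

The healthy M-shaped distance profile is a parametric stand-in for the
empirical one: a flat base with a Gaussian dip at the nucleosome center
and symmetric Gaussian edge peaks near +/-85 bp. The tumor-like profile
flattens that shape toward uniform — the direction of the deviation seen
in HGSOC plasma, where footprints of the healthy reference atlas are
partially washed out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cna_zscore import (
    BinnedCoverage,
    build_reference_panel,
    correct_bins,
    score_sample_gwz,
)
from .footprint import DISTANCE_INDEX, N_BINS, DistanceHistogram
from .io_tracks import BinAnnotation, FragmentTrack, NucleosomeMap, ReadStartTrack
from .mixture_model import (
    ClassProfiles,
    MixtureSettings,
    estimate_nucleosome_score,
)


@dataclass
class MProfileParams:
    """Shape parameters of the synthetic M-profile (all lengths in bp)."""

    edge_offset: float = 85.0  # edge-peak position mu
    edge_width: float = 25.0  # edge-peak sd
    dip_width: float = 40.0  # center-dip sd
    dip_depth: float = 0.5  # a in [0, 1)
    edge_height: float = 0.6  # e >= 0
    flattening: float = 0.7  # s in [0, 1]: tumor profile pull to uniform

    def __post_init__(self) -> None:
        if not (0 <= self.dip_depth < 1):
            raise ValueError("dip_depth must be in [0, 1)")
        if self.edge_height < 0:
            raise ValueError("edge_height must be >= 0")
        if not (0 <= self.flattening <= 1):
            raise ValueError("flattening must be in [0, 1]")


def make_m_profiles(params: MProfileParams | None = None) -> ClassProfiles:
    """Healthy and tumor-like distance profiles over the 601 bins.

    healthy f(d) ∝ 1 - a*exp(-d²/2σ_c²)
                   + e*[exp(-(d-μ)²/2σ_e²) + exp(-(d+μ)²/2σ_e²)]
    tumor = (1-s)*healthy + s*uniform.
    """
    p = params or MProfileParams()
    d = DISTANCE_INDEX.astype(float)
    f = (
        1.0
        - p.dip_depth * np.exp(-(d**2) / (2 * p.dip_width**2))
        + p.edge_height
        * (
            np.exp(-((d - p.edge_offset) ** 2) / (2 * p.edge_width**2))
            + np.exp(-((d + p.edge_offset) ** 2) / (2 * p.edge_width**2))
        )
    )
    if np.any(f <= 0):
        raise ValueError("parameters yield a non-positive density")
    healthy = f / f.sum()
    tumor = (1 - p.flattening) * healthy + p.flattening / N_BINS
    tumor /= tumor.sum()
    return ClassProfiles(healthy, tumor, meta={"generator": "m_profile"})


def sample_distance_histogram(
    profiles: ClassProfiles,
    lam_true: float,
    n: int,
    seed: int,
    sample_id: str = "",
) -> DistanceHistogram:
    """One multinomial draw of size n from the lam_true mixture."""
    if not (0.0 <= lam_true <= 1.0):
        raise ValueError("lam_true outside [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, profiles.mixture(lam_true))
    return DistanceHistogram(
        counts, sample_id=sample_id, meta={"lam_true": lam_true, "seed": seed}
    )


def make_nucleosome_map_and_reads(
    n_nucleosomes: int,
    profile: np.ndarray,
    n_reads: int,
    seed: int,
    spacing: int = 190,
    jitter_sd: float = 0.0,
    chrom: str = "chr1",
    origin: int = 1_000,
) -> tuple[NucleosomeMap, ReadStartTrack]:
    """Regularly spaced nucleosome centers plus reads phased to them.

    Centers sit at ``origin + i*spacing`` with optional Gaussian jitter;
    each read start is a randomly chosen center plus an offset drawn from
    ``profile`` over [-300, +300]. When the spacing is much larger than
    300 bp the footprint histogram recovers the profile exactly; at
    nucleosomal spacing (~190 bp) neighbor attribution folds the tails.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if spacing < 20:
        raise ValueError("spacing must be >= 20")
    rng = np.random.default_rng(seed)
    centers = origin + spacing * np.arange(n_nucleosomes, dtype=np.int64)
    if jitter_sd > 0:
        centers = centers + np.round(
            rng.normal(0, jitter_sd, n_nucleosomes)
        ).astype(np.int64)
        centers = np.maximum(centers, 0)
    which = rng.integers(0, n_nucleosomes, n_reads)
    offsets = rng.choice(DISTANCE_INDEX, size=n_reads, p=profile)
    starts = np.maximum(centers[which] + offsets, 0)
    return (
        NucleosomeMap({chrom: centers}),
        ReadStartTrack({chrom: starts}),
    )


def make_phased_fragments(
    n_nucleosomes: int,
    n_fragments: int,
    seed: int,
    spacing: int = 190,
    length_mode: int = 167,
    length_sd: float = 3.0,
    center_jitter_sd: float = 5.0,
    chrom: str = "chr1",
    origin: int = 1_000,
) -> tuple[FragmentTrack, np.ndarray]:
    """Paired-end-like fragments centered on phased nucleosomes.

    Fragment midpoints fall on nucleosome centers (with tight jitter).
    Lengths follow the cfDNA size ladder: a dominant mononucleosome mode
    (167 bp) with sub-peaks every 10 bp — the helical pitch of DNA on the
    nucleosome — plus small within-peak jitter. Returns the track and the
    true center positions.
    """
    rng = np.random.default_rng(seed)
    centers = origin + spacing * np.arange(n_nucleosomes, dtype=np.int64)
    which = rng.integers(0, n_nucleosomes, n_fragments)
    mids = centers[which] + rng.normal(0, center_jitter_sd, n_fragments)
    ladder = rng.choice(
        [-20, -10, 0, 10, 20],
        size=n_fragments,
        p=[0.08, 0.18, 0.48, 0.18, 0.08],
    )
    lengths = np.maximum(
        np.round(
            length_mode + ladder + rng.normal(0, length_sd, n_fragments)
        ),
        50,
    ).astype(np.int64)
    starts = np.round(mids - lengths / 2).astype(np.int64)
    starts = np.maximum(starts, 0)
    ivs = np.column_stack([starts, starts + lengths])
    return FragmentTrack({chrom: ivs}), centers


@dataclass
class CnaSimParams:
    """Binned-coverage simulation: segmental CNAs, GC bias, Poisson noise."""

    n_bins: int
    segments: list[tuple[int, int, int]] = field(default_factory=list)
    # (start bin, end bin (exclusive), integer copy number)
    tumor_fraction: float = 0.0
    depth: float = 500.0  # mean reads per bin before bias
    gc_slope: float = 1.0  # linear GC bias: 1 + slope*(gc - 0.45)
    overdispersion: float = 0.0  # 0 = Poisson; else NB with var = m + a*m^2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tumor_fraction <= 1.0):
            raise ValueError("tumor_fraction outside [0, 1]")
        prev_end = 0
        for s, e, cn in sorted(self.segments):
            if s < prev_end or e > self.n_bins or cn < 0:
                raise ValueError(f"bad segment ({s}, {e}, {cn})")
            prev_end = e

    def copy_numbers(self) -> np.ndarray:
        cn = np.full(self.n_bins, 2, dtype=float)
        for s, e, c in self.segments:
            cn[s:e] = c
        return cn


def make_bin_annotation(
    n_chroms: int = 4,
    bins_per_chrom: int = 550,
    seed: int = 0,
    bin_width: int = 1_000_000,
    frac_low_mappability: float = 0.02,
) -> BinAnnotation:
    """Synthetic autosome-like bin grid with GC and mappability columns."""
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        gc = np.clip(rng.normal(0.45, 0.06, bins_per_chrom), 0.25, 0.7)
        mapp = np.clip(rng.normal(0.97, 0.02, bins_per_chrom), 0.5, 1.0)
        low = rng.random(bins_per_chrom) < frac_low_mappability
        mapp[low] = rng.uniform(0.3, 0.75, low.sum())
        for i in range(bins_per_chrom):
            rows.append(
                (chrom, i * bin_width, (i + 1) * bin_width, gc[i], mapp[i])
            )
    return BinAnnotation(
        pd.DataFrame(
            rows, columns=["chrom", "start", "end", "gc", "mappability"]
        ),
        bin_width=bin_width,
    )


def simulate_binned_sample(
    params: CnaSimParams, annotation: BinAnnotation
) -> BinnedCoverage:
    """Raw bin counts: depth x GC bias x mappability x CNA dosage + noise.

    Expected count per bin b:
    ``depth * (1 + gc_slope*(gc_b - 0.45)) * mapp_b *
    (1 + tf * (cn_b/2 - 1))``; observed counts are Poisson (or negative
    binomial when ``overdispersion > 0``).
    """
    if annotation.n_bins != params.n_bins:
        raise ValueError("annotation length != n_bins")
    rng = np.random.default_rng(params.seed)
    gc = annotation.table["gc"].to_numpy()
    mapp = annotation.table["mappability"].to_numpy()
    dosage = 1.0 + params.tumor_fraction * (params.copy_numbers() / 2.0 - 1.0)
    expected = params.depth * (1 + params.gc_slope * (gc - 0.45)) * mapp * dosage
    if np.any(expected < 0):
        raise ValueError("negative expected count; reduce gc_slope")
    if params.overdispersion > 0:
        a = params.overdispersion
        lam = rng.gamma(shape=1 / a, scale=a * expected)
        raw = rng.poisson(lam)
    else:
        raw = rng.poisson(expected)
    return BinnedCoverage(raw=raw)


def default_cna_segments(
    n_bins: int, gained_fraction: float = 0.2, copy_number: int = 3
) -> list[tuple[int, int, int]]:
    """One gained segment covering the leading fraction of the genome."""
    return [(0, int(round(gained_fraction * n_bins)), copy_number)]


@dataclass
class CohortSimSettings:
    """Study-like conditions for the simulated benign vs invasive cohort."""

    n_reads: int = 200_000  # distance-histogram counts per sample
    lam_range: tuple[float, float] = (0.4, 0.8)  # invasive mixture weights
    tf_range: tuple[float, float] = (0.05, 0.2)  # invasive tumor fractions
    gained_fraction: float = 0.2
    copy_number: int = 3
    depth: float = 500.0
    n_panel: int = 30
    profile_params: MProfileParams = field(default_factory=MProfileParams)
    annotation_seed: int = 7


def simulate_cohort(
    n_per_group: int,
    seed: int,
    settings: CohortSimSettings | None = None,
    mixture_settings: MixtureSettings | None = None,
):
    """Benign-like and invasive-like samples through the full scoring stack.

    Benign samples have mixture weight 0 and tumor fraction 0; invasive
    samples draw both from the configured ranges. Each sample's distance
    histogram and binned coverage are generated, then scored with the
    mixture model and the genome-wide z-score against a simulated healthy
    panel. Returns ``(CohortTable, ground_truth_DataFrame)``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    st = settings or CohortSimSettings()
    rng = np.random.default_rng(seed)
    profiles = make_m_profiles(st.profile_params)
    annotation = make_bin_annotation(seed=st.annotation_seed)
    n_bins = annotation.n_bins
    segments = default_cna_segments(
        n_bins, st.gained_fraction, st.copy_number
    )

    panel_cov = [
        correct_bins(
            simulate_binned_sample(
                CnaSimParams(
                    n_bins=n_bins,
                    depth=st.depth,
                    seed=int(rng.integers(2**31)),
                ),
                annotation,
            ),
            annotation,
        )
        for _ in range(st.n_panel)
    ]
    panel = build_reference_panel(panel_cov, annotation)

    rows, truth = [], []
    for group in ("benign", "invasive"):
        for i in range(n_per_group):
            if group == "benign":
                lam_true, tf = 0.0, 0.0
            else:
                lam_true = float(rng.uniform(*st.lam_range))
                tf = float(rng.uniform(*st.tf_range))
            sid = f"{group}_{i:03d}"
            hist = sample_distance_histogram(
                profiles, lam_true, st.n_reads,
                seed=int(rng.integers(2**31)), sample_id=sid,
            )
            res = estimate_nucleosome_score(hist, profiles, mixture_settings)
            cov = correct_bins(
                simulate_binned_sample(
                    CnaSimParams(
                        n_bins=n_bins,
                        segments=segments if tf > 0 else [],
                        tumor_fraction=tf,
                        depth=st.depth,
                        seed=int(rng.integers(2**31)),
                    ),
                    annotation,
                ),
                annotation,
            )
            gwz = score_sample_gwz(cov, panel, annotation)
            rows.append(
                (sid, res.score, gwz.zscore, group)
            )
            truth.append((sid, lam_true, tf))
    from .evaluation import CohortTable

    cohort = CohortTable(
        pd.DataFrame(
            rows,
            columns=[
                "sample_id", "nucleosome_score", "genome_wide_z", "label",
            ],
        )
    )
    truth_df = pd.DataFrame(
        truth, columns=["sample_id", "lam_true", "tumor_fraction"]
    )
    return cohort, truth_df
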