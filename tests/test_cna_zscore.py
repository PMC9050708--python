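import numpy as np
import pandas as pd
import pytest

from nucleofoot.cna_zscore import (
    WINDOW_BINS,
    BinnedCoverage,
    bin_reads,
    build_reference_panel,
    correct_bins,
    genome_wide_zscore,
    score_sample_gwz,
    window_values,
    window_zscores,
)
from nucleofoot.io_tracks import BinAnnotation, ReadStartTrack
from nucleofoot.synthetic import CnaSimParams, simulate_binned_sample


def flat_annotation(n_bins, chrom="chr1", gc=0.45, mapp=1.0, width=10**6):
    t = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n_bins) * width,
            "end": (np.arange(n_bins) + 1) * width,
            "gc": gc,
            "mappability": mapp,
        }
    )
    return BinAnnotation(t)


class TestBinReads:
    def test_counts_by_position(self):
        ann = flat_annotation(3)
        t = ReadStartTrack(
            {"chr1": np.array([500_000, 1_500_000, 1_600_000])}
        )
        cov = bin_reads(t, ann)
        assert cov.raw.tolist() == [1, 2, 0]

    def test_boundary_read_goes_to_next_bin(self):
        ann = flat_annotation(2)
        cov = bin_reads(ReadStartTrack({"chr1": np.array([1_000_000])}), ann)
        assert cov.raw.tolist() == [0, 1]

    def test_reads_outside_bins_dropped_and_counted(self):
        ann = flat_annotation(2)
        t = ReadStartTrack({"chr1": np.array([100]), "chr5": np.array([100])})
        cov = bin_reads(t, ann)
        assert cov.raw.sum() + cov.n_dropped == t.n_reads
        assert cov.n_dropped == 1

    def test_matches_brute_force_assignment(self, small_annotation, rng):
        t = small_annotation.table
        starts = {}
        for chrom in t["chrom"].unique():
            hi = t.loc[t["chrom"] == chrom, "end"].max()
            starts[chrom] = rng.integers(0, hi, 30_000)
        track = ReadStartTrack(starts)
        cov = bin_reads(track, small_annotation)
        brute = np.zeros(len(t), dtype=int)
        for i, row in t.iterrows():
            pos = starts[row["chrom"]]
            brute[i] = int(
                ((pos >= row["start"]) & (pos < row["end"])).sum()
            )
        np.testing.assert_array_equal(cov.raw, brute)

    def test_overlapping_bins_rejected(self):
        t = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [0, 500_000],
                "end": [10**6, 1_500_000],
                "gc": 0.4,
                "mappability": 1.0,
            }
        )
        with pytest.raises(ValueError, match="overlap"):
            BinAnnotation(t)


class TestCorrectBins:
    def test_flat_counts_fixed_point(self):
        ann = flat_annotation(200)
        cov = BinnedCoverage(raw=np.full(200, 100))
        cc = correct_bins(cov, ann)
        np.testing.assert_allclose(cc.corrected, 1.0, atol=1e-9)

    def test_mappability_division(self):
        # threshold lowered so the half-mappability bin stays usable and
        # the division itself is observable
        ann = flat_annotation(100)
        ann.table.loc[0, "mappability"] = 0.5
        ann = BinAnnotation(ann.table, mappability_min=0.5)
        raw = np.full(100, 20)
        raw[0] = 10
        cc = correct_bins(BinnedCoverage(raw=raw), ann)
        assert cc.corrected[0] == pytest.approx(cc.corrected[1], rel=1e-6)

    def test_low_mappability_bins_unusable(self):
        ann = flat_annotation(60)
        ann.table.loc[5, "mappability"] = 0.5
        ann = BinAnnotation(ann.table)
        cc = correct_bins(BinnedCoverage(raw=np.full(60, 50)), ann)
        assert np.isnan(cc.corrected[5])

    def test_gc_bias_removed(self, rng):
        n = 2_000
        gc = np.clip(rng.normal(0.45, 0.07, n), 0.25, 0.7)
        t = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n) * 10**6,
                "end": (np.arange(n) + 1) * 10**6,
                "gc": gc,
                "mappability": 1.0,
            }
        )
        ann = BinAnnotation(t)
        cov = simulate_binned_sample(
            CnaSimParams(n_bins=n, depth=2_000, gc_slope=1.0, seed=5), ann
        )
        cc = correct_bins(cov, ann)
        slope = np.polyfit(gc, cc.corrected, 1)[0]
        assert abs(slope) < 0.02

    def test_scale_invariance(self, small_annotation):
        cov = simulate_binned_sample(
            CnaSimParams(n_bins=small_annotation.n_bins, seed=3),
            small_annotation,
        )
        a = correct_bins(cov, small_annotation)
        b = correct_bins(
            BinnedCoverage(raw=cov.raw * 7), small_annotation
        )
        ok = small_annotation.usable
        np.testing.assert_allclose(a.corrected[ok], b.corrected[ok])


class TestPanelAndWindows:
    def _corrected(self, ann, seed, **kw):
        return correct_bins(
            simulate_binned_sample(
                CnaSimParams(n_bins=ann.n_bins, seed=seed, **kw), ann
            ),
            ann,
        )

    def test_panel_too_small(self, small_annotation):
        covs = [self._corrected(small_annotation, s) for s in range(2)]
        with pytest.raises(ValueError, match="panel too small"):
            build_reference_panel(covs, small_annotation)

    def test_identical_members_floor_sd_zero_loo_ss(self, small_annotation):
        cov = self._corrected(small_annotation, 1)
        panel = build_reference_panel([cov] * 4, small_annotation)
        assert np.all(panel.window_sd == 1e-8)
        np.testing.assert_allclose(panel.loo_ss, 0.0)

    def test_window_means_equal_brute_force(self, small_annotation):
        cov = self._corrected(small_annotation, 2)
        wv = window_values(cov, small_annotation)
        t = small_annotation.table
        usable = small_annotation.usable
        for k in [0, 5, len(wv.window_start_bin) - 1]:
            b0 = wv.window_start_bin[k]
            chrom = t.loc[b0, "chrom"]
            idx = [
                i
                for i in range(b0, len(t))
                if usable[i] and t.loc[i, "chrom"] == chrom
            ][:WINDOW_BINS]
            assert wv.values[k] == pytest.approx(
                float(np.mean(cov.corrected[idx]))
            )

    def test_windows_do_not_cross_chromosomes(self, small_annotation):
        cov = self._corrected(small_annotation, 3)
        wv = window_values(cov, small_annotation)
        chroms = small_annotation.table["chrom"].to_numpy()
        usable = small_annotation.usable
        for b0 in wv.window_start_bin:
            run = [
                i
                for i in range(b0, small_annotation.n_bins)
                if usable[i]
            ][:WINDOW_BINS]
            assert len(set(chroms[run])) == 1

    def test_sample_equal_to_panel_mean_gives_zero_z(self, small_annotation):
        covs = [self._corrected(small_annotation, s) for s in range(5)]
        panel = build_reference_panel(covs, small_annotation)
        mean_cov = BinnedCoverage(
            raw=covs[0].raw,
            corrected=np.vstack([c.corrected for c in covs]).mean(axis=0),
        )
        wz = window_zscores(mean_cov, panel, small_annotation)
        assert np.allclose(wz.z, 0.0, atol=1e-9)
        gw = genome_wide_zscore(wz, panel)
        assert gw.sum_of_squares == pytest.approx(0.0, abs=1e-12)
        assert gw.zscore <= 0.0

    def test_single_window_z_formula(self):
        from nucleofoot.cna_zscore import ReferencePanel, WindowZ

        panel = ReferencePanel(
            window_start_bin=np.array([0]),
            window_mean=np.array([1.0]),
            window_sd=np.array([2.0]),
            ss_mean=1.0,
            ss_sd=1.0,
            n_samples=3,
        )
        wz = WindowZ(np.array([0]), np.array([5.0]))
        wz.z = (wz.values - panel.window_mean) / panel.window_sd
        assert wz.z[0] == pytest.approx(2.0)

    def test_degenerate_reference_ss_is_error(self, small_annotation):
        cov = self._corrected(small_annotation, 1)
        panel = build_reference_panel([cov] * 4, small_annotation)
        wz = window_zscores(cov, panel, small_annotation)
        with pytest.raises(ValueError, match="enlarge"):
            genome_wide_zscore(wz, panel)

    def test_gwz_increases_with_tumor_fraction(self, small_annotation):
        covs = [self._corrected(small_annotation, 100 + s) for s in range(8)]
        panel = build_reference_panel(covs, small_annotation)
        n = small_annotation.n_bins
        segs = [(0, n // 5, 3)]
        means = []
        for tf in (0.0, 0.1, 0.3):
            vals = [
                score_sample_gwz(
                    self._corrected(
                        small_annotation,
                        1000 + rep,
                        segments=segs if tf else [],
                        tumor_fraction=tf,
                    ),
                    panel,
                    small_annotation,
                ).zscore
                for rep in range(4)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
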