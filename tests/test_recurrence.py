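import numpy as np
import pytest

from clonecna import ValidationError
from clonecna.genome import GenomeModel
from clonecna.recurrence import (
    call_recurrent_regions,
    gain_loss_frequency,
    make_bins,
    permutation_null,
)
from conftest import make_meta, make_segments


@pytest.fixture()
def genome():
    return GenomeModel(("chr1", "chr2"), (10_000_000, 6_000_000))


BIN = 1_000_000


class TestFrequencyTrack:
    def test_whole_chromosome_clonal_gain(self, genome):
        segs = make_segments([
            ("R1", "chr1", 0, 10_000_000, 5.0), ("R2", "chr1", 0, 10_000_000, 5.0),
        ])
        meta = make_meta([("R1", "T1", 2.0), ("R2", "T1", 2.0)])
        track = gain_loss_frequency(segs, meta, genome, BIN)
        chr1 = track.bins["chromosome"] == "chr1"
        assert (track.gain_freq[chr1] == 1.0).all()
        assert (track.clonal_gain_freq[chr1] == 1.0).all()
        assert (track.subclonal_gain_freq[chr1] == 0.0).all()
        assert (track.gain_freq[~chr1.to_numpy()] == 0.0).all()

    def test_one_of_two_tumours_gives_half(self, genome):
        segs = make_segments([
            ("R1", "chr1", 0, 2_000_000, 5.0), ("R2", "chr1", 0, 2_000_000, 2.0),
        ])
        meta = make_meta([("R1", "T1", 2.0), ("R2", "T2", 2.0)])
        track = gain_loss_frequency(segs, meta, genome, BIN)
        assert track.gain_freq[0] == 0.5

    def test_one_bp_overlap_counts(self, genome):
        segs = make_segments([("R1", "chr1", BIN - 1, BIN + 1, 5.0)])
        meta = make_meta([("R1", "T1", 2.0)])
        track = gain_loss_frequency(segs, meta, genome, BIN)
        assert track.gain_freq[0] == 1.0 and track.gain_freq[1] == 1.0
        assert track.gain_freq[2] == 0.0

    def test_subclonal_decomposition_sums_to_total(self, genome):
        segs = make_segments([
            ("R1", "chr1", 0, 3_000_000, 5.0),
            ("R2", "chr1", 0, 1_000_000, 5.0),
            ("R2", "chr1", 1_000_000, 3_000_000, 2.0),
        ])
        meta = make_meta([("R1", "T1", 2.0), ("R2", "T1", 2.0)])
        track = gain_loss_frequency(segs, meta, genome, BIN)
        np.testing.assert_allclose(
            track.clonal_gain_freq + track.subclonal_gain_freq, track.gain_freq)
        assert track.clonal_gain_freq[0] == 1.0  # both regions cover bin 0
        assert track.subclonal_gain_freq[1] == 1.0  # only R1 covers bin 1

    def test_empty_cohort_rejected(self, genome):
        with pytest.raises(ValidationError, match="empty"):
            gain_loss_frequency(make_segments([]), make_meta([]), genome, BIN)


class TestPermutationNull:
    def test_same_seed_is_bit_identical(self, genome):
        segs = make_segments([("R1", "chr1", 0, 2_000_000, 5.0)])
        meta = make_meta([("R1", "T1", 2.0)])
        a = permutation_null(segs, meta, genome, BIN, B=50, seed=9)
        b = permutation_null(segs, meta, genome, BIN, B=50, seed=9)
        assert a.gain_threshold == b.gain_threshold
        np.testing.assert_array_equal(a.pooled_gain, b.pooled_gain)

    def test_no_gains_gives_zero_threshold(self, genome):
        segs = make_segments([("R1", "chr1", 0, 2_000_000, 2.0)])
        meta = make_meta([("R1", "T1", 2.0)])
        null = permutation_null(segs, meta, genome, BIN, B=1, seed=0)
        assert null.gain_threshold == 0.0 and null.loss_threshold == 0.0

    def test_mean_null_frequency_matches_closed_form(self):
        """One tumour, one gained segment exactly one bin wide, single
        chromosome: under uniform integer placement the segment covers two
        bins except for the n_bins aligned starts, so the expected pooled
        mean is (2 - n_bins/(L-b+1)) / n_bins.  Checked within Monte-Carlo
        error at B=2,000."""
        L, b = 20_000_000, 1_000_000
        g = GenomeModel(("chr1",), (L,))
        segs = make_segments([("R1", "chr1", 0, b, 5.0)])
        meta = make_meta([("R1", "T1", 2.0)])
        null = permutation_null(segs, meta, g, b, B=2000, seed=5)
        n_bins = L // b
        expected = (2 - n_bins / (L - b + 1)) / n_bins
        got = null.pooled_gain.mean()
        # binomial-ish MC standard error over B=2000 permutations
        assert got == pytest.approx(expected, abs=4 * np.sqrt(expected / (2000 * n_bins)))

    def test_gained_bases_conserved_under_relocation(self, genome):
        """Total per-tumour gained bins in each permutation stay within the
        bin-count bounds implied by the preserved segment lengths."""
        segs = make_segments([
            ("R1", "chr1", 0, 2_500_000, 5.0), ("R1", "chr2", 0, 1_000_000, 5.0),
        ])
        meta = make_meta([("R1", "T1", 2.0)])
        null = permutation_null(segs, meta, genome, BIN, B=200, seed=1)
        per_perm_bins = null.pooled_gain.reshape(200, -1).sum(axis=1) * null.n_tumours
        # 2.5 Mb and 1 Mb segments cover 3-4 and 1-2 bins; unions can only shrink
        assert per_perm_bins.max() <= 6 and per_perm_bins.min() >= 3

    def test_oversized_segment_rejected(self, genome):
        segs = make_segments([("R1", "chr1", 0, 10_000_000, 5.0)])
        meta = make_meta([("R1", "T1", 2.0)])
        tiny = GenomeModel(("chr1",), (1_000_000,))
        with pytest.raises(ValidationError, match="fits no chromosome"):
            permutation_null(segs, meta, tiny, 100_000, B=1, seed=0)


class TestRecurrentRegions:
    def _track_null(self, genome, segs, meta, B=20, seed=0):
        track = gain_loss_frequency(segs, meta, genome, BIN)
        null = permutation_null(segs, meta, genome, BIN, B=B, seed=seed)
        return track, null

    def test_zero_threshold_calls_any_nonzero_bin(self, genome):
        segs = make_segments([("R1", "chr1", 0, 1_000_000, 2.0),
                              ("R2", "chr1", 0, 1_000_000, 5.0)])
        meta = make_meta([("R1", "T1", 2.0), ("R2", "T2", 2.0)])
        track = gain_loss_frequency(segs, meta, genome, BIN)
        null = permutation_null(make_segments([("R1", "chr1", 0, 1_000_000, 2.0)]),
                                make_meta([("R1", "T1", 2.0)]), genome, BIN, B=1)
        regions = call_recurrent_regions(track, null)
        gains = regions[regions["kind"] == "gain"]
        assert len(gains) == 1 and gains.iloc[0]["n_bins"] == 1
        assert gains.iloc[0]["max_freq"] == 0.5

    def test_all_below_threshold_gives_empty_list(self, genome):
        segs = make_segments([("R1", "chr1", 0, 1_000_000, 2.0)])
        meta = make_meta([("R1", "T1", 2.0)])
        track, null = self._track_null(genome, segs, meta)
        assert call_recurrent_regions(track, null).empty

    def test_runs_do_not_cross_chromosomes(self, genome):
        segs = make_segments([("R1", "chr1", 9_000_000, 10_000_000, 5.0),
                              ("R1", "chr2", 0, 1_000_000, 5.0)])
        meta = make_meta([("R1", "T1", 2.0)])
        track = gain_loss_frequency(segs, meta, genome, BIN)
        null = permutation_null(make_segments([("R1", "chr1", 0, 1_000_000, 2.0)]),
                                make_meta([("R1", "T1", 2.0)]), genome, BIN, B=1)
        regions = call_recurrent_regions(track, null)
        gains = regions[regions["kind"] == "gain"]
        assert len(gains) == 2
        assert set(gains["chromosome"]) == {"chr1", "chr2"}

    def test_binning_mismatch_rejected(self, genome):
        segs = make_segments([("R1", "chr1", 0, 1_000_000, 5.0)])
        meta = make_meta([("R1", "T1", 2.0)])
        track = gain_loss_frequency(segs, meta, genome, BIN)
        null = permutation_null(segs, meta, genome, 2 * BIN, B=1)
        with pytest.raises(ValidationError, match="binning"):
            call_recurrent_regions(track, null)


def test_make_bins_covers_genome_exactly(genome):
    bins = make_bins(genome, 3_000_000)
    assert int((bins["end"] - bins["start"]).sum()) == genome.total_length
    assert bins.iloc[3]["end"] == 10_000_000  # last chr1 bin is truncated
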