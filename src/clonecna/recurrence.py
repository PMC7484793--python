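"""Genome-wide gain/loss frequency tracks and permutation-calibrated recurrence.

Frequencies are computed on fixed-width bins (default 1 Mb).  A tumour
counts once towards a bin's gain frequency when *any* of its regions has a
gain-state segment overlapping the bin (any-overlap, matching the step-like
frequency tracks such data are usually drawn with); the gain frequency
decomposes into a clonal part (every region of the tumour covers the bin
with a gain) and a subclonal remainder.  Losses are counted the same way.

Recurrence thresholds come from a permutation null built under the
assumption that gains and losses occur randomly along the genome: in each
permutation every tumour's gained (respectively lost) intervals are
relocated independently and uniformly — a chromosome drawn with probability
proportional to its length (redrawn when the interval does not fit), a
start drawn uniformly among valid positions, length preserved — and per-bin
frequencies are recomputed.  The ``B × n_bins`` null frequencies for gains
(and, separately, losses) are pooled into one empirical distribution whose
95% quantile (linear interpolation) is the recurrence threshold.  Maximal
runs of contiguous bins whose observed frequency strictly exceeds the
threshold are reported as recurrent regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cna_calling import GAIN_STATES, STATE_LOSS, Thresholds, segment_states
from .errors import ValidationError
from .genome import GenomeModel

__all__ = [
    "FrequencyTrack",
    "PermutationNull",
    "make_bins",
    "gain_loss_frequency",
    "permutation_null",
    "call_recurrent_regions",
]


def make_bins(genome: GenomeModel, bin_size: int) -> pd.DataFrame:
    """Fixed-width bins per chromosome; the last bin of each chromosome may be short."""
    if bin_size <= 0:
        raise ValidationError("bin_size must be > 0")
    rows = []
    for name, length in zip(genome.names, genome.lengths):
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chromosome": name, "start": starts, "end": ends}))
    bins = pd.concat(rows, ignore_index=True)
    bins.index.name = "bin"
    return bins


def _bin_layout(genome: GenomeModel, bin_size: int):
    """(first bin index, n bins) per chromosome."""
    layout = {}
    first = 0
    for name, length in zip(genome.names, genome.lengths):
        n = int(np.ceil(length / bin_size))
        layout[name] = (first, n)
        first += n
    return layout, first


def _cover(mask_row: np.ndarray, layout, bin_size, chrom, start, end) -> None:
    first, n = layout[chrom]
    b0 = int(start // bin_size)
    b1 = int((end - 1) // bin_size) + 1  # any-overlap: 1 bp into a bin counts
    mask_row[first + b0 : first + min(b1, n)] = True


@dataclass
class FrequencyTrack:
    bins: pd.DataFrame
    bin_size: int
    n_tumours: int
    gain_freq: np.ndarray
    clonal_gain_freq: np.ndarray
    subclonal_gain_freq: np.ndarray
    loss_freq: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        out = self.bins.copy()
        out["gain_freq"] = self.gain_freq
        out["clonal_gain_freq"] = self.clonal_gain_freq
        out["subclonal_gain_freq"] = self.subclonal_gain_freq
        out["loss_freq"] = self.loss_freq
        return out


def _tumour_cover_masks(states: pd.DataFrame, meta: pd.DataFrame, genome, bin_size, which: str):
    """Per-tumour (any-region, all-region) boolean bin coverage for gain or loss."""
    layout, n_bins = _bin_layout(genome, bin_size)
    wanted = GAIN_STATES if which == "gain" else (STATE_LOSS,)
    tumours = sorted(meta["tumour_id"].unique())
    regions_of = meta.groupby("tumour_id")["region_id"].apply(list)
    any_mask = np.zeros((len(tumours), n_bins), dtype=bool)
    all_mask = np.zeros((len(tumours), n_bins), dtype=bool)
    hits = states[states["state"].isin(wanted)]
    by_region = dict(tuple(hits.groupby("region_id")))
    for ti, tumour in enumerate(tumours):
        region_rows = []
        for region in regions_of[tumour]:
            row = np.zeros(n_bins, dtype=bool)
            sub = by_region.get(region)
            if sub is not None:
                for seg in sub.itertuples():
                    _cover(row, layout, bin_size, seg.chromosome, seg.start, seg.end)
            region_rows.append(row)
        stacked = np.vstack(region_rows)
        any_mask[ti] = stacked.any(axis=0)
        all_mask[ti] = stacked.all(axis=0)
    return tumours, any_mask, all_mask


def gain_loss_frequency(
    segments: pd.DataFrame,
    meta: pd.DataFrame,
    genome: GenomeModel,
    bin_size: int = 1_000_000,
    thresholds: Thresholds = Thresholds(),
) -> FrequencyTrack:
    """Observed per-bin gain/loss frequencies with clonal/subclonal decomposition."""
    if meta.empty:
        raise ValidationError("gain_loss_frequency: empty cohort")
    states = segment_states(segments, meta, thresholds)
    unknown = sorted(set(states["chromosome"]) - set(genome.names))
    if unknown:
        raise ValidationError(f"segments on chromosome(s) not in genome: {', '.join(unknown)}")
    tumours, gain_any, gain_all = _tumour_cover_masks(states, meta, genome, bin_size, "gain")
    _, loss_any, _ = _tumour_cover_masks(states, meta, genome, bin_size, "loss")
    n = len(tumours)
    gain_freq = gain_any.sum(axis=0) / n
    clonal = gain_all.sum(axis=0) / n
    return FrequencyTrack(
        bins=make_bins(genome, bin_size),
        bin_size=bin_size,
        n_tumours=n,
        gain_freq=gain_freq,
        clonal_gain_freq=clonal,
        subclonal_gain_freq=gain_freq - clonal,
        loss_freq=loss_any.sum(axis=0) / n,
    )


def _merged_intervals_per_tumour(states: pd.DataFrame, meta: pd.DataFrame, wanted) -> dict[str, list]:
    """Union of a tumour's state-matching intervals across its regions, per chromosome."""
    tumour_of = meta.set_index("region_id")["tumour_id"]
    out: dict[str, list] = {t: [] for t in meta["tumour_id"].unique()}
    hits = states[states["state"].isin(wanted)].copy()
    if hits.empty:
        return out
    hits["tumour_id"] = tumour_of.reindex(hits["region_id"]).to_numpy()
    for (tumour, chrom), grp in hits.groupby(["tumour_id", "chromosome"]):
        ivs = sorted(zip(grp["start"], grp["end"]))
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[tumour].extend((chrom, s, e) for s, e in merged)
    return out


@dataclass
class PermutationNull:
    bin_size: int
    n_bins: int
    n_tumours: int
    B: int
    seed: int
    gain_threshold: float
    loss_threshold: float
    pooled_gain: np.ndarray = field(repr=False)
    pooled_loss: np.ndarray = field(repr=False)


def _relocate_and_count(
    tumour_intervals: dict[str, list], genome: GenomeModel, bin_size: int, B: int, rng: np.random.Generator
) -> np.ndarray:
    """B × n_bins matrix of null frequencies under uniform relocation."""
    layout, n_bins = _bin_layout(genome, bin_size)
    chrom_names = list(genome.names)
    chrom_lens = np.asarray(genome.lengths, dtype=np.int64)
    probs = chrom_lens / chrom_lens.sum()
    n_tumours = len(tumour_intervals)
    lengths, owners = [], []
    for ti, (tumour, ivs) in enumerate(sorted(tumour_intervals.items())):
        for _, s, e in ivs:
            L = int(e - s)
            if L > chrom_lens.max():
                raise ValidationError(f"segment of length {L} fits no chromosome")
            lengths.append(L)
            owners.append(ti)
    lengths = np.asarray(lengths, dtype=np.int64)
    owners = np.asarray(owners, dtype=np.int64)
    null = np.zeros((B, n_bins), dtype=np.float64)
    if len(lengths) == 0 or n_tumours == 0:
        return null
    for b in range(B):
        present = np.zeros((n_tumours, n_bins), dtype=bool)
        # draw chromosomes length-proportionally, redrawing where the segment
        # does not fit; lengths are preserved exactly
        chrom_idx = rng.choice(len(chrom_names), size=len(lengths), p=probs)
        bad = lengths > chrom_lens[chrom_idx]
        while bad.any():
            chrom_idx[bad] = rng.choice(len(chrom_names), size=int(bad.sum()), p=probs)
            bad = lengths > chrom_lens[chrom_idx]
        max_start = chrom_lens[chrom_idx] - lengths
        starts = rng.integers(0, max_start + 1)
        for i in range(len(lengths)):
            _cover(present[owners[i]], layout, bin_size, chrom_names[chrom_idx[i]],
                   int(starts[i]), int(starts[i] + lengths[i]))
        null[b] = present.sum(axis=0) / n_tumours
    return null


def permutation_null(
    segments: pd.DataFrame,
    meta: pd.DataFrame,
    genome: GenomeModel,
    bin_size: int = 1_000_000,
    B: int = 1_000,
    seed: int = 0,
    thresholds: Thresholds = Thresholds(),
    quantile: float = 0.95,
) -> PermutationNull:
    """Pooled permutation null and its ``quantile`` recurrence thresholds.

    Gains and losses get separate nulls.  One tumour's gained intervals are
    first merged across regions (their union is what the observed
    any-region frequency scores), then each merged interval is relocated
    independently.  All ``B × n_bins`` frequencies are pooled; the
    threshold is the empirical quantile with linear interpolation.
    """
    if B < 1:
        raise ValidationError("permutation_null: B must be >= 1")
    if meta.empty:
        raise ValidationError("permutation_null: empty cohort")
    states = segment_states(segments, meta, thresholds)
    _, n_bins = _bin_layout(genome, bin_size)
    rng = np.random.default_rng(seed)
    gains = _merged_intervals_per_tumour(states, meta, GAIN_STATES)
    losses = _merged_intervals_per_tumour(states, meta, (STATE_LOSS,))
    null_gain = _relocate_and_count(gains, genome, bin_size, B, rng)
    null_loss = _relocate_and_count(losses, genome, bin_size, B, rng)
    return PermutationNull(
        bin_size=bin_size,
        n_bins=n_bins,
        n_tumours=len(set(meta["tumour_id"])),
        B=B,
        seed=seed,
        gain_threshold=float(np.quantile(null_gain.ravel(), quantile)),
        loss_threshold=float(np.quantile(null_loss.ravel(), quantile)),
        pooled_gain=null_gain.ravel(),
        pooled_loss=null_loss.ravel(),
    )


def call_recurrent_regions(track: FrequencyTrack, null: PermutationNull) -> pd.DataFrame:
    """Maximal runs of contiguous bins whose frequency strictly exceeds the threshold.

    Returns one row per region with ``kind`` (gain/loss), coordinates, bin
    count, and the max and mean frequency inside the run.  Runs never cross
    a chromosome boundary.
    """
    if len(track.gain_freq) != null.n_bins or track.bin_size != null.bin_size:
        raise ValidationError("call_recurrent_regions: track and null binning differ")
    bins = track.bins
    rows = []
    for kind, freq, thr in (
        ("gain", track.gain_freq, null.gain_threshold),
        ("loss", track.loss_freq, null.loss_threshold),
    ):
        above = freq > thr
        if not above.any():
            continue
        chroms = bins["chromosome"].to_numpy()
        new_run = above & (
            ~np.roll(above, 1) | (chroms != np.roll(chroms, 1)) | (np.arange(len(above)) == 0)
        )
        run_id = np.where(above, np.cumsum(new_run), 0)
        for rid in np.unique(run_id[run_id > 0]):
            ix = np.flatnonzero(run_id == rid)
            rows.append({
                "kind": kind,
                "chromosome": chroms[ix[0]],
                "start": int(bins["start"].iloc[ix[0]]),
                "end": int(bins["end"].iloc[ix[-1]]),
                "n_bins": len(ix),
                "max_freq": float(freq[ix].max()),
                "mean_freq": float(freq[ix].mean()),
                "threshold": thr,
            })
    return pd.DataFrame(rows, columns=["kind", "chromosome", "start", "end", "n_bins",
                                       "max_freq", "mean_freq", "threshold"])
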