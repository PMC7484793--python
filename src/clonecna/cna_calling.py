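"""Categorical CNA calling from absolute copy number and ploidy.

The copy-number *state* of a segment is its ploidy-adjusted log ratio
``r = log2(total_cn / ploidy)``.  States are assigned by strict
thresholds on ``r``:

* gain:       ``r > log2(2.5/2)``  (i.e. > 2.5 copies in a diploid tumour)
* high_gain:  ``r > log2(4/2)``    (> twice ploidy)
* loss:       ``r < log2(1.5/2)``  (mirror of the gain rule on the linear
  copy-number scale; a loss threshold is a package choice — see the
  methods note)
* neutral otherwise.

A gain's *focality* is decided by the supporting segment's length: focal
below 20 Mb, broad at or above.

Gene-level calls project segment states onto gene loci: among the segments
overlapping a locus the *supporting segment* is the one with the largest
overlap (ties: higher copy number, then leftmost), so a gene has exactly one
state per region.  A locus with no overlapping segment yields a ``missing``
call, which is a value, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "STATE_LOSS",
    "STATE_NEUTRAL",
    "STATE_GAIN",
    "STATE_HIGH_GAIN",
    "STATE_MISSING",
    "GAIN_STATES",
    "STATE_ORDER",
    "Thresholds",
    "ploidy_adjusted_log_ratio",
    "classify_state",
    "classify_focality",
    "gene_state",
    "call_genes",
    "segment_states",
]

STATE_LOSS = "loss"
STATE_NEUTRAL = "neutral"
STATE_GAIN = "gain"
STATE_HIGH_GAIN = "high_gain"
STATE_MISSING = "missing"

GAIN_STATES = (STATE_GAIN, STATE_HIGH_GAIN)
STATE_ORDER = (STATE_LOSS, STATE_NEUTRAL, STATE_GAIN, STATE_HIGH_GAIN)

FOCAL = "focal"
BROAD = "broad"
FOCALITY_NA = "not_applicable"


@dataclass(frozen=True)
class Thresholds:
    """Log-ratio thresholds for state calling and the focal/broad length cut.

    Defaults correspond, at ploidy 2, to calling a gain above 2.5 copies, a
    high-level gain above 4 copies, a loss below 1.5 copies, and to calling
    events shorter than 20 Mb focal.
    """

    gain_log_ratio: float = math.log2(2.5 / 2)
    high_gain_log_ratio: float = math.log2(4 / 2)
    loss_log_ratio: float = math.log2(1.5 / 2)
    focal_max_len: int = 20_000_000

    def __post_init__(self) -> None:
        if not (self.loss_log_ratio < 0 < self.gain_log_ratio < self.high_gain_log_ratio):
            raise ValidationError(
                "thresholds: require loss_log_ratio < 0 < gain_log_ratio < high_gain_log_ratio"
            )
        if self.focal_max_len <= 0:
            raise ValidationError("thresholds: focal_max_len must be > 0")


def ploidy_adjusted_log_ratio(total_cn, ploidy):
    """``log2(total_cn / ploidy)``; ``total_cn == 0`` maps to ``-inf``.

    Accepts scalars or arrays.  ``ploidy`` must be strictly positive.
    """
    cn = np.asarray(total_cn, dtype=float)
    pl = np.asarray(ploidy, dtype=float)
    if np.any(pl <= 0):
        raise ValidationError("ploidy must be > 0")
    if np.any(cn < 0):
        raise ValidationError("total_cn must be >= 0")
    with np.errstate(divide="ignore"):
        r = np.log2(cn / pl)
    return float(r) if np.isscalar(total_cn) and np.isscalar(ploidy) else r


def classify_state(log_ratio, thresholds: Thresholds = Thresholds()):
    """Map log ratio(s) to ``loss/neutral/gain/high_gain`` (strict inequalities)."""
    r = np.asarray(log_ratio, dtype=float)
    out = np.select(
        [r > thresholds.high_gain_log_ratio, r > thresholds.gain_log_ratio, r < thresholds.loss_log_ratio],
        [STATE_HIGH_GAIN, STATE_GAIN, STATE_LOSS],
        default=STATE_NEUTRAL,
    )
    return str(out[()]) if np.isscalar(log_ratio) else out


def classify_focality(segment_length: int, thresholds: Thresholds = Thresholds()) -> str:
    """Focal below ``focal_max_len``, broad at or above it."""
    if segment_length <= 0:
        raise ValidationError("segment_length must be > 0")
    return FOCAL if segment_length < thresholds.focal_max_len else BROAD


def segment_states(segments: pd.DataFrame, meta: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Annotate a segment table with per-segment log ratio and state.

    ``segments`` uses internal 0-based half-open coordinates; ``meta`` maps
    region_id → (tumour_id, ploidy).
    """
    ploidy = meta.set_index("region_id")["ploidy"]
    missing = sorted(set(segments["region_id"]) - set(ploidy.index))
    if missing:
        raise ValidationError(f"segments reference region(s) without metadata: {', '.join(missing)}")
    out = segments.copy()
    out["log_ratio"] = ploidy_adjusted_log_ratio(
        out["total_cn"].to_numpy(), ploidy.reindex(out["region_id"]).to_numpy()
    )
    out["state"] = classify_state(out["log_ratio"].to_numpy(), thresholds)
    out["tumour_id"] = meta.set_index("region_id")["tumour_id"].reindex(out["region_id"]).to_numpy()
    return out


def gene_state(
    region_segments: pd.DataFrame,
    ploidy: float,
    locus,
    thresholds: Thresholds = Thresholds(),
    projection: str = "max_overlap",
) -> dict:
    """Project one region's segments onto one gene locus.

    ``locus`` needs attributes/keys ``name, chromosome, start, end``.
    Returns a dict with the gene call fields; ``state == "missing"`` when no
    segment overlaps the locus.

    ``projection="max_overlap"`` (default) picks the overlapping segment
    with the largest overlap (tie → higher total_cn → leftmost).
    ``projection="any_gain"`` prefers the most severe state among
    overlapping segments (sensitivity-analysis mode).
    """
    if isinstance(locus, dict):
        l_name, l_chrom, l_start, l_end = locus["name"], locus["chromosome"], locus["start"], locus["end"]
    else:
        l_name, l_chrom, l_start, l_end = locus.name, locus.chromosome, locus.start, locus.end
    sub = region_segments[region_segments["chromosome"] == l_chrom]
    ov_start = np.maximum(sub["start"].to_numpy(), l_start)
    ov_end = np.minimum(sub["end"].to_numpy(), l_end)
    ov_len = ov_end - ov_start
    hit = ov_len > 0
    base = {"gene": l_name}
    if not hit.any():
        base.update(
            log_ratio=np.nan, state=STATE_MISSING, focality=FOCALITY_NA,
            seg_chromosome="", seg_start=-1, seg_end=-1, seg_total_cn=np.nan,
        )
        return base
    cand = sub.loc[hit].copy()
    cand["_overlap"] = ov_len[hit]
    cand["_lr"] = ploidy_adjusted_log_ratio(cand["total_cn"].to_numpy(), ploidy)
    cand["_state"] = classify_state(cand["_lr"].to_numpy(), thresholds)
    if projection == "any_gain":
        severity = {s: i for i, s in enumerate(STATE_ORDER)}
        cand["_sev"] = cand["_state"].map(severity)
        cand = cand.sort_values(["_sev", "_overlap", "total_cn", "start"],
                                ascending=[False, False, False, True], kind="mergesort")
    elif projection == "max_overlap":
        cand = cand.sort_values(["_overlap", "total_cn", "start"],
                                ascending=[False, False, True], kind="mergesort")
    else:
        raise ValidationError(f"unknown projection mode {projection!r}")
    best = cand.iloc[0]
    state = str(best["_state"])
    seg_len = int(best["end"] - best["start"])
    focality = FOCALITY_NA if state == STATE_NEUTRAL else classify_focality(seg_len, thresholds)
    base.update(
        log_ratio=float(best["_lr"]), state=state, focality=focality,
        seg_chromosome=str(best["chromosome"]), seg_start=int(best["start"]),
        seg_end=int(best["end"]), seg_total_cn=float(best["total_cn"]),
    )
    return base


def call_genes(
    segments: pd.DataFrame,
    meta: pd.DataFrame,
    loci: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    projection: str = "max_overlap",
) -> pd.DataFrame:
    """Per-region gene calls for every (region, locus) pair.

    Returns one row per region × gene with columns ``tumour_id, region_id,
    gene, log_ratio, state, focality, seg_chromosome, seg_start, seg_end,
    seg_total_cn``.
    """
    meta_ix = meta.set_index("region_id")
    missing = sorted(set(segments["region_id"].unique()) - set(meta_ix.index))
    if missing:
        raise ValidationError(f"segments reference region(s) without metadata: {', '.join(missing)}")
    rows = []
    loci_t = list(loci.itertuples(index=False))
    for region_id, reg_segs in segments.groupby("region_id", sort=True):
        m = meta_ix.loc[region_id]
        for locus in loci_t:
            call = gene_state(reg_segs, float(m["ploidy"]), locus, thresholds, projection)
            call["region_id"] = region_id
            call["tumour_id"] = m["tumour_id"]
            rows.append(call)
    # regions with metadata but no segments at all: every gene is missing there
    for region_id in meta_ix.index.difference(segments["region_id"].unique()):
        m = meta_ix.loc[region_id]
        for locus in loci_t:
            rows.append({
                "gene": locus.name, "log_ratio": np.nan, "state": STATE_MISSING,
                "focality": FOCALITY_NA, "seg_chromosome": "", "seg_start": -1,
                "seg_end": -1, "seg_total_cn": np.nan,
                "region_id": region_id, "tumour_id": m["tumour_id"],
            })
    cols = ["tumour_id", "region_id", "gene", "log_ratio", "state", "focality",
            "seg_chromosome", "seg_start", "seg_end", "seg_total_cn"]
    return pd.DataFrame(rows)[cols].sort_values(["tumour_id", "region_id", "gene"], kind="mergesort").reset_index(drop=True)
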