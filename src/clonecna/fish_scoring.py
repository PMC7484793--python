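"""Dual-colour FISH scoring of target-gene copy number per tissue core.

Each core contributes paired per-cell signal counts for the target probe
(e.g. MCL-1 at 1q21.3) and a same-chromosome reference probe (1p12).  The
core-level ratio is ``mean(target) / mean(reference)`` over the evaluated
cells.  Categories:

* ``high_level_gain``  — ratio >= 4.0 (the boundary belongs to the more
  severe category);
* ``low_level_gain``   — 2.0 <= ratio < 4.0;
* ``polysomy``         — ratio < 2.0 but mean target count > 3 signals/cell
  (whole-arm/chromosome elevation without relative amplification);
* ``no_gain``          — otherwise.

Cores with fewer evaluable cells than the minimum (default 20) or a zero
mean reference count are QC failures: reported unscorable, never
categorised, and never an exception for the rest of the batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association_stats import fisher_exact_two_sided
from .clonality import round_half_up_percent
from .errors import ValidationError

__all__ = [
    "CATEGORY_HLG",
    "CATEGORY_LLG",
    "CATEGORY_POLYSOMY",
    "CATEGORY_NO_GAIN",
    "FishCall",
    "TmaSummary",
    "score_core",
    "score_cores",
    "summarize_tma",
    "fish_ihc_association",
]

CATEGORY_HLG = "high_level_gain"
CATEGORY_LLG = "low_level_gain"
CATEGORY_POLYSOMY = "polysomy"
CATEGORY_NO_GAIN = "no_gain"
GAIN_CATEGORIES = (CATEGORY_HLG, CATEGORY_LLG)

HLG_RATIO = 4.0
GAIN_RATIO = 2.0
POLYSOMY_MEAN_CN = 3.0


@dataclass(frozen=True)
class FishCall:
    core_id: str
    n_cells: int
    mean_target: float
    mean_reference: float
    ratio: float  # NaN when unscorable
    category: str  # one of the categories above, or "unscorable"
    scorable: bool
    qc_reason: str = ""


def score_core(target_counts, reference_counts, core_id: str = "", min_cells: int = 20) -> FishCall:
    """Score one core from paired per-cell signal counts."""
    t = np.asarray(target_counts, dtype=float)
    r = np.asarray(reference_counts, dtype=float)
    if t.size != r.size:
        raise ValidationError("score_core: target and reference counts must be paired per cell")
    if (t < 0).any() or (r < 0).any():
        raise ValidationError("score_core: negative signal count")
    n = int(t.size)
    if n < min_cells:
        return FishCall(core_id, n, float(t.mean()) if n else np.nan,
                        float(r.mean()) if n else np.nan, np.nan, "unscorable", False,
                        f"fewer than {min_cells} cells")
    mean_t, mean_r = float(t.mean()), float(r.mean())
    if mean_r == 0:
        return FishCall(core_id, n, mean_t, mean_r, np.nan, "unscorable", False,
                        "zero mean reference count")
    ratio = mean_t / mean_r
    if ratio >= HLG_RATIO:
        cat = CATEGORY_HLG
    elif ratio >= GAIN_RATIO:
        cat = CATEGORY_LLG
    elif mean_t > POLYSOMY_MEAN_CN:
        cat = CATEGORY_POLYSOMY
    else:
        cat = CATEGORY_NO_GAIN
    return FishCall(core_id, n, mean_t, mean_r, ratio, cat, True)


def score_cores(cells: pd.DataFrame, min_cells: int = 20) -> pd.DataFrame:
    """Score every core in a per-cell count table (``clonecna.io_formats.read_fish_cells``)."""
    calls = []
    for core_id, grp in cells.groupby("core_id", sort=True):
        call = score_core(grp["target_signals"].to_numpy(),
                          grp["reference_signals"].to_numpy(), str(core_id), min_cells)
        calls.append(vars(call))
    return pd.DataFrame(calls)


@dataclass(frozen=True)
class TmaSummary:
    """Tissue-microarray level breakdown over scorable cores.

    ``gain_pct`` counts high- plus low-level gains; because published
    summaries sometimes fold polysomies into the same figure,
    ``gain_or_polysomy_pct`` is reported alongside.  Percentages use one
    decimal with half-away-from-zero rounding.  All None when nothing is
    scorable.
    """

    n_cores: int
    n_scorable: int
    n_hlg: int
    n_llg: int
    n_polysomy: int
    n_no_gain: int

    @property
    def n_gained(self) -> int:
        return self.n_hlg + self.n_llg

    @property
    def gain_pct(self):
        if not self.n_scorable:
            return None
        return round_half_up_percent(self.n_gained / self.n_scorable, decimals=1)

    @property
    def gain_or_polysomy_pct(self):
        if not self.n_scorable:
            return None
        return round_half_up_percent((self.n_gained + self.n_polysomy) / self.n_scorable, decimals=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "n_cores": self.n_cores, "n_scorable": self.n_scorable,
            "n_high_level_gain": self.n_hlg, "n_low_level_gain": self.n_llg,
            "n_polysomy": self.n_polysomy, "n_no_gain": self.n_no_gain,
            "gain_pct": np.nan if self.gain_pct is None else self.gain_pct,
            "gain_or_polysomy_pct": (np.nan if self.gain_or_polysomy_pct is None
                                     else self.gain_or_polysomy_pct),
        }])


def summarize_tma(calls: pd.DataFrame) -> TmaSummary:
    counts = calls.loc[calls["scorable"], "category"].value_counts()
    return TmaSummary(
        n_cores=len(calls),
        n_scorable=int(calls["scorable"].sum()),
        n_hlg=int(counts.get(CATEGORY_HLG, 0)),
        n_llg=int(counts.get(CATEGORY_LLG, 0)),
        n_polysomy=int(counts.get(CATEGORY_POLYSOMY, 0)),
        n_no_gain=int(counts.get(CATEGORY_NO_GAIN, 0)),
    )


def fish_ihc_association(
    fish_categories,
    ihc_intensities,
    high_levels=("high",),
) -> tuple[pd.DataFrame, float]:
    """Fisher test of FISH gain status against IHC staining intensity.

    Collapses FISH to gain (HLG/LLG) vs no-gain and IHC to ``high_levels``
    vs the rest, then applies the two-sided Fisher exact test.  Returns the
    collapsed 2 × 2 table (for the record) and the p-value.
    """
    fish = pd.Series(list(fish_categories), dtype=object)
    ihc = pd.Series(list(ihc_intensities), dtype=object)
    if len(fish) != len(ihc):
        raise ValidationError("fish_ihc_association: unpaired sample lists")
    if len(fish) < 2:
        raise ValidationError("fish_ihc_association: need at least 2 paired samples")
    gain = fish.isin(GAIN_CATEGORIES)
    high = ihc.isin(high_levels)
    table = pd.DataFrame(
        [[int((gain & high).sum()), int((gain & ~high).sum())],
         [int((~gain & high).sum()), int((~gain & ~high).sum())]],
        index=["fish_gain", "fish_no_gain"], columns=["ihc_high", "ihc_not_high"],
    )
    return table, fisher_exact_two_sided(table.to_numpy())
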