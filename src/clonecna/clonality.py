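"""Clonal vs subclonal classification of gene-level gains across tumour regions.

A gain is *clonal* in a tumour when every sequenced region of that tumour
carries it, and *subclonal* when at least one but not all regions do.
Regions where the gene has no supporting segment (missing call) carry no
information and are excluded from both numerator and denominator; their
count is reported.  A tumour where every region is missing is
*undetermined*, never silently absent.

Gains are placed on the tumour's phylogeny at the edge above the most
recent common ancestor (MRCA) of the gain-bearing leaves: clonal gains map
to the trunk.  A subclonal gain whose bearing leaves' MRCA is the root —
a parallel-gain / homoplasy-like pattern that no single edge explains — is
mapped to the trunk edge but flagged ``discordant``; it is never promoted
to clonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import dendropy
import numpy as np
import pandas as pd

from .cna_calling import GAIN_STATES, STATE_HIGH_GAIN, STATE_MISSING
from .errors import ValidationError

__all__ = [
    "TRUNK",
    "STATUS_ABSENT",
    "STATUS_SUBCLONAL",
    "STATUS_CLONAL",
    "STATUS_UNDETERMINED",
    "classify_clonality",
    "map_to_tree",
    "classify_cohort",
    "summarize_cohort",
    "CohortClonalitySummary",
    "round_half_up_percent",
]

TRUNK = "trunk"
STATUS_ABSENT = "absent"
STATUS_SUBCLONAL = "subclonal"
STATUS_CLONAL = "clonal"
STATUS_UNDETERMINED = "undetermined"

LEVEL_NONE = "none"
LEVEL_LOW = "low"
LEVEL_HIGH = "high"


def round_half_up_percent(fraction: float, decimals: int = 0) -> float:
    """Percentage with half-away-from-zero rounding (74% from 34/46, 48.8% from 39/80)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(fraction * 100).quantize(q, rounding=ROUND_HALF_UP))


def classify_clonality(states_by_region: dict[str, str], high_only: bool = False) -> dict:
    """Classify one tumour × gene from its per-region states.

    ``states_by_region`` maps region_id → state string.  Presence means
    ``gain`` or ``high_gain`` (``high_gain`` only when ``high_only``).
    Returns a dict with status, level, gained region list and counts.
    """
    if not states_by_region:
        raise ValidationError("classify_clonality: no regions supplied")
    present_states = (STATE_HIGH_GAIN,) if high_only else GAIN_STATES
    informative = {r: s for r, s in states_by_region.items() if s != STATE_MISSING}
    n_missing = len(states_by_region) - len(informative)
    gained = sorted(r for r, s in informative.items() if s in present_states)
    n_total = len(informative)
    if n_total == 0:
        status = STATUS_UNDETERMINED
    elif len(gained) == 0:
        status = STATUS_ABSENT
    elif len(gained) == n_total:
        status = STATUS_CLONAL
    else:
        status = STATUS_SUBCLONAL
    if any(informative.get(r) == STATE_HIGH_GAIN for r in gained):
        level = LEVEL_HIGH
    elif gained:
        level = LEVEL_LOW
    else:
        level = LEVEL_NONE
    return {
        "status": status,
        "level": level,
        "gained_regions": gained,
        "n_regions_gained": len(gained),
        "n_regions_total": n_total,
        "n_regions_missing": n_missing,
    }


def _clade_leaves(node: dendropy.Node) -> set[str]:
    return {leaf.taxon.label for leaf in node.leaf_iter()}


def map_to_tree(tree: dendropy.Tree, gained_regions: list[str]) -> tuple[str, bool]:
    """Edge placement of a gain: (edge label, discordant flag).

    The gain maps to the edge above the MRCA of the gain-bearing leaves;
    the trunk when that MRCA is the root (or subtends all leaves).  The
    edge label is ``"trunk"`` or the sorted ``|``-joined leaf set below the
    edge.  ``discordant`` is True when the MRCA clade contains leaves
    without the gain (a pattern no single edge explains).
    """
    all_leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    gained = set(map(str, gained_regions))
    if not gained:
        raise ValidationError("map_to_tree: empty gain-bearing leaf set")
    unknown = gained - all_leaves
    if unknown:
        raise ValidationError(f"map_to_tree: region(s) not in tree: {', '.join(sorted(unknown))}")
    if len(gained) == 1:
        (only,) = gained
        clade = {only}
        edge = TRUNK if clade == all_leaves else only
        return edge, False
    mrca = tree.mrca(taxon_labels=sorted(gained))
    clade = _clade_leaves(mrca)
    discordant = clade != gained
    edge = TRUNK if clade == all_leaves else "|".join(sorted(clade))
    return edge, discordant


def classify_cohort(
    gene_calls: pd.DataFrame,
    trees: dict[str, dendropy.Tree] | None = None,
    high_only: bool = False,
) -> pd.DataFrame:
    """Per-tumour × gene clonality table from per-region gene calls.

    ``gene_calls`` is the output of :func:`clonecna.cna_calling.call_genes`.
    When ``trees`` provides a phylogeny for a tumour, each present gain is
    placed on an edge; tumours without a tree get an empty ``tree_edge``.
    """
    rows = []
    for (tumour, gene), grp in gene_calls.groupby(["tumour_id", "gene"], sort=True):
        states = dict(zip(grp["region_id"], grp["state"]))
        res = classify_clonality(states, high_only=high_only)
        edge, discordant = "", False
        if res["status"] in (STATUS_CLONAL, STATUS_SUBCLONAL) and trees and tumour in trees:
            edge, discordant = map_to_tree(trees[tumour], res["gained_regions"])
        rows.append({
            "tumour_id": tumour, "gene": gene, "status": res["status"],
            "level": res["level"], "n_regions_gained": res["n_regions_gained"],
            "n_regions_total": res["n_regions_total"],
            "n_regions_missing": res["n_regions_missing"],
            "tree_edge": edge, "discordant": discordant,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortClonalitySummary:
    """Cohort-level breakdown of one gene's gain status.

    Fractions of gained tumours (``clonal_fraction`` etc.) are None when no
    tumour is gained.  ``*_pct`` attributes round half away from zero to
    integer percent, the convention used when such splits are printed.
    """

    gene: str
    n_tumours: int
    n_absent: int
    n_subclonal: int
    n_clonal: int
    n_undetermined: int
    n_high_level: int  # gained tumours whose gain is high-level in >=1 region

    @property
    def n_gained(self) -> int:
        return self.n_subclonal + self.n_clonal

    @property
    def gained_fraction(self) -> float:
        return self.n_gained / self.n_tumours if self.n_tumours else float("nan")

    @property
    def clonal_fraction(self):
        return self.n_clonal / self.n_gained if self.n_gained else None

    @property
    def subclonal_fraction(self):
        return self.n_subclonal / self.n_gained if self.n_gained else None

    @property
    def high_level_fraction(self):
        return self.n_high_level / self.n_gained if self.n_gained else None

    @property
    def gained_pct(self) -> float:
        return round_half_up_percent(self.gained_fraction)

    @property
    def clonal_pct(self):
        return None if self.clonal_fraction is None else round_half_up_percent(self.clonal_fraction)

    @property
    def subclonal_pct(self):
        return None if self.subclonal_fraction is None else round_half_up_percent(self.subclonal_fraction)

    @property
    def high_level_pct(self):
        return None if self.high_level_fraction is None else round_half_up_percent(self.high_level_fraction)

    def to_frame(self) -> pd.DataFrame:
        na = np.nan
        return pd.DataFrame([{
            "gene": self.gene, "n_tumours": self.n_tumours, "n_absent": self.n_absent,
            "n_subclonal": self.n_subclonal, "n_clonal": self.n_clonal,
            "n_undetermined": self.n_undetermined, "n_gained": self.n_gained,
            "n_high_level": self.n_high_level,
            "gained_pct": self.gained_pct,
            "clonal_pct": na if self.clonal_pct is None else self.clonal_pct,
            "subclonal_pct": na if self.subclonal_pct is None else self.subclonal_pct,
            "high_level_pct": na if self.high_level_pct is None else self.high_level_pct,
        }])


def summarize_cohort(clonality: pd.DataFrame, gene: str) -> CohortClonalitySummary:
    """Count clonal/subclonal/absent tumours for one gene across the cohort."""
    sub = clonality[clonality["gene"] == gene]
    if sub.empty:
        raise ValidationError(f"summarize_cohort: no clonality calls for gene {gene!r}")
    if sub["tumour_id"].duplicated().any():
        raise ValidationError("summarize_cohort: more than one call per tumour")
    counts = sub["status"].value_counts()
    gained = sub["status"].isin([STATUS_CLONAL, STATUS_SUBCLONAL])
    return CohortClonalitySummary(
        gene=gene,
        n_tumours=len(sub),
        n_absent=int(counts.get(STATUS_ABSENT, 0)),
        n_subclonal=int(counts.get(STATUS_SUBCLONAL, 0)),
        n_clonal=int(counts.get(STATUS_CLONAL, 0)),
        n_undetermined=int(counts.get(STATUS_UNDETERMINED, 0)),
        n_high_level=int((gained & (sub["level"] == LEVEL_HIGH)).sum()),
    )
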